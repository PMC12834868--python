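# iterfs — iterative feature selection and rejection

`iterfs` answers a question that plain feature selection leaves open in
biomedical tabular data: after a selector names its "important" features,
can the *unselected* features still classify? If they can, interpreting
the selected set as the biologically relevant one is unsafe. The package
implements an iterative, model-agnostic framework that partitions the
features of a binary-labelled numeric table (rows = cases, columns =
features) into

* a **selected** set, verified to support classification, and
* a **rejected** set, verified to classify *at chance level* — individually
  and in every selector-derived combination,

together with the classical-statistics battery (effect sizes, VIF and
aliasing diagnostics, all-subsets logistic-regression stability scans,
penalised regression) a reviewer would want beside it, and synthetic
generators to exercise everything without external data.

## The method

Classification *success* for a feature subset S is defined over repeated
random splits: a fixed stratified validation partition (20%) is set aside
before any selection; then, for each classifier c, 100 Monte-Carlo
cross-validation iterations train c on a fresh stratified 80% subsample of
the training partition and score it on a fresh stratified 80% subsample of
the validation partition. With BA the balanced accuracy
(sensitivity + specificity)/2,

&nbsp;&nbsp;&nbsp;&nbsp;success(S) ⇔ ∃ c : CI₉₅,low(BA_c(S)) > 0.5,

where the CI is the non-parametric percentile interval over the 100
iterations. The framework then loops over four phases on the current
feature set F_cur (initially all features):

* **Phase 0** — run the feature-selection experts (an all-relevant
  shadow-feature random-forest selector and an l1-penalised logistic
  selector at λ_min) on the training partition; evaluate F_cur, each
  expert's selected set, and all their unions and intersections; keep the
  smallest successful subset. No success on the first pass ⇒
  `not_classifiable`.
* **Phase 1** — backward elimination: drop single features (least
  important first, restart after every removal) while success holds,
  yielding a 1-minimal subset.
* **Phase 2** — rescue: every discarded feature is evaluated alone;
  individually successful features re-enter the selected set, so
  redundancy masking cannot silently discard predictive features.
* **Phase 3** — verification: the selected set must still succeed; the
  rejected set is attacked the same way (experts re-run on it, all subset
  combinations evaluated). If anything succeeds there, the loop repeats on
  the rejected set — unless no rejected feature was expert-chosen or
  individually successful, in which case the run ends with an
  **interaction warning** (the rejected features carry information only
  through interactions invisible to every selector).

The loop strictly shrinks F_cur, so it terminates in at most p passes.

## Worked example

A 150 × 10 Gaussian table with one planted feature (standardised effect
d = 2 on `f00`), analysed with two classifier families:

```python
from iterfs import IterativeFeatureSelector, PlantedSpec, generate_planted

dataset = generate_planted(PlantedSpec(n=150, p=10, informative=((0, 2.0),), seed=5))
frame = dataset.to_frame()

selector = IterativeFeatureSelector(
    classifier_ids=("logistic", "knn"), boruta_trees=100, random_state=7,
)
selector.fit(frame.drop(columns="label"), frame["label"])
print("status :", selector.status_)
print("selected:", selector.selected_)
print("rejected:", selector.rejected_)
```

prints

```
status : ok
selected: ('f00', 'f03')
rejected: ('f01', 'f02', 'f04', 'f05', 'f06', 'f07', 'f08', 'f09')
```

The planted feature `f00` is recovered (`f03` is a borderline Phase-2
rescue of a noise feature — the rescue step deliberately errs on the side
of keeping anything that classifies alone at the 95% level). The report
table mirrors the conventional layout, one `median [low, high]` balanced
accuracy cell per classifier; its final rows show the guarantee at work —
every rejected-side combination sits at chance:

```
      Dataset  Features                LR_BA               KNN_BA  Success  Phase
 All_Features         2 0.917 [0.875, 0.958] 0.917 [0.833, 0.980]        1  Phase_3_Final_Selected
 All_Features         8 0.500 [0.353, 0.647] 0.542 [0.375, 0.667]        0  Phase_3_Final_Rejected
Boruta_Selected        2 0.583 [0.500, 0.667] 0.583 [0.417, 0.708]        0  Phase_3_Final_Rejected
Boruta_Rejected        6 0.458 [0.270, 0.583] 0.479 [0.353, 0.625]        0  Phase_3_Final_Rejected
```

The same machinery is available from the shell:

```bash
iterfs simulate --kind atom --out atom.csv --seed 42
iterfs run --data atom.csv --label class --seed 42
iterfs evaluate-subset --data atom.csv --label class --features X1,X2
iterfs stats --data atom.csv --label class
```

## Layout

`src/iterfs/` — `data` (labelled tables, IO), `config` (run protocol),
`evaluation` (MC-CV engine, balanced accuracy, CIs), `classifiers`
(pluggable registry of the five families), `selectors` (shadow-forest and
sparse-logistic experts), `framework` (the phase 0–3 loop and the
scikit-learn `IterativeFeatureSelector`), `stats` (classical battery),
`simulate` (generators), `report`, `cli`. See `docs/methods.md` for the
modelling choices and their rationale.
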