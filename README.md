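# iegdecode

Decoding a mouse's recent experience from immediate-early gene (IEG)
induction signatures measured across brain structures.

Salient experiences — a drug injection, a foot shock, renewed access to
food — trigger rapid transcription of immediate-early genes (*Arc*,
*Fos*, *Egr2*, ...) in limbic and mesolimbic structures. The pattern of
induction across a small panel of genes and structures is
experience-specific enough that the identity of the experience can be
read back from a single animal's expression profile. `iegdecode`
implements that analysis end to end for multiplexed qPCR data:

1. **ΔΔCt normalization** — raw cycle-threshold (Ct) values are
   normalized per sample to a *global-normalization* value (the mean Ct
   of a set of stably expressed reference genes), then to the mean ΔCt
   of a matched control cohort; fold induction is `2^-ΔΔCt`.
2. **Marker ranking** — candidate genes are scored by how often their
   mean induction exceeds two-fold across structure x experience cells
   (`#`), and by the average within-cell variance of their induction
   (`S²`); the combined rank-sum picks the marker panel.
3. **Decoding** — each mouse is a vector of (gene, structure) features;
   a k-nearest-neighbor classifier (k = 1, Euclidean) is evaluated by
   leave-one-out, reported as a confusion matrix.
4. **Permutation validation** — the mouse-to-experience assignment is
   shuffled N times and the decoder re-evaluated each time; the
   empirical p-value is `(1/N) Σ 1[acc(S_i) > acc(S)]`.
5. **Feature selection** — Random-KNN *support* (mean LOO accuracy of
   all sampled feature subsets containing a feature), random-forest
   mean decrease in Gini impurity (MDG), and a descriptive CART tree
   grown with information gain.

A synthetic-data module generates Ct-level datasets with known class
effect sizes and an informative-feature mask, so the entire pipeline is
testable without any external data.

## Worked example

```python
from iegdecode import (default_config, generate_ct_dataset, delta_ct,
                       fold_induction, assemble_features, loo_evaluate,
                       permutation_test, select_markers)

cfg = default_config(seed=1)            # 10 experiences, 5 genes x 5 structures
ct, truth = generate_ct_dataset(cfg)    # raw Ct table incl. reference genes
folds = fold_induction(delta_ct(ct))    # ΔΔCt fold induction vs control cohorts

ranking, markers = select_markers(folds, threshold=2.0, n_select=5)
print("marker panel:", ", ".join(markers))

fm = assemble_features(folds)           # 50 mice x 25 log2-fold features
cm = loo_evaluate(fm, k=1)
print(f"decoded {cm.total} mice at {cm.overall_accuracy:.1%} (LOO, k=1)")

res = permutation_test(fm, n_permutations=10_000, seed=2)
print(f"empirical p = {res.empirical_p:.4g} (add-one bound {res.p_add_one:.4g})")
```

prints

```
marker panel: Arc, Egr4, Fosb, Egr2, Fos
decoded 50 mice at 100.0% (LOO, k=1)
empirical p = 0 (add-one bound 9.999e-05)
```

With class effects of 3 log2 units and within-class noise of 0.5 the
ten experiences are perfectly decodable, and none of the 10,000 label
shuffles matches the observed accuracy (the strict-inequality p is 0;
the add-one bound `(r+1)/(N+1)` is reported alongside).

The same stages are available from the shell:

```sh
iegdecode simulate --seed 1 --out run/
iegdecode normalize --in run/ct.csv --out run/folds.csv
iegdecode assemble --folds run/folds.csv --out run/features.csv
iegdecode decode --features run/features.csv --out run/confusion.csv
iegdecode run-all --seed 1 --out run/     # everything, plus a manifest
```

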