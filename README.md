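# traitspace

Functional trait-space analysis for fuzzy-coded trait tables.

Community ecologists describe taxa — here, freshwater macroinvertebrates —
by *fuzzy-coded* functional traits: each taxon's affinity to every state of a
trait group (feeding habit, locomotion, respiration, body size, ...) is
scored on an integer scale from 0 (no affinity) to 3 or 5 (high affinity).
Two questions recur. How much of the possible trait space does an assemblage
actually occupy, given that trade-offs and evolutionary history forbid many
trait combinations?  And is that occupancy structured by taxonomy — do
related taxa cluster in the trait space?

`traitspace` implements the full pipeline:

1. **Data model** — taxa-by-traits affinity tables with an explicit
   missing-cell mask, a trait dictionary (the bundled default has 11 trait
   groups and 63 traits, abbreviated FH1 … RP8), table merging across
   databases recorded with slightly different trait sets, and group-wise
   standardization of scores to [0, 1].
2. **Centred PCA of incomplete data** — covariances by pairwise deletion,
   available-case centring, scores summed over observed traits only; axis
   significance by the broken-stick model
   (b_k = (1/p) Σ_{i=k}^{p} 1/i) and trait–axis screening at |r| > 0.5.
   Variance-standardized PCA is deliberately not used: equalizing trait
   variances would destroy the relatedness of traits within a group.
3. **Convex-hull occupancy** — the occupied trait space is the d-dimensional
   hull volume of the taxa in the retained axes (optionally trimmed to the
   95% of taxa closest to the centroid), compared against three Monte-Carlo
   null models in which axes vary independently: per-axis uniform, per-axis
   normal, and per-axis random permutation of the observed scores.
   Occupancy is reported as 100 · observed / mean(null) with a one-sided
   Monte-Carlo p-value, small when taxa are *concentrated*.
4. **Taxonomic constraint** — one-way PERMANOVA (Euclidean distance, pseudo-F
   by label permutation) and PERMDISP (dispersion around group spatial
   medians, Weiszfeld algorithm) on the component scores, with a three-way
   relatedness suite that repeats both tests with rare groups pooled, broken
   out, and omitted.
5. **Synthetic data** — a seeded generator of realistic fuzzy-coded tables
   (596 taxa in 12 taxonomic groups by default, planted group-level trait
   syndromes, ~1% missing cells) so the whole pipeline runs and is testable
   without any external database.

## Worked example

```python
import traitspace as ts

table = ts.simulate_dataset(ts.SyntheticConfig(seed=42))   # 596 x 63, ~1% missing
std   = ts.standardize_by_group(table)
model = ts.fit_incomplete_pca(std)
print(ts.select_axes(model).retained)                      # 8 significant axes

scores = model.scores[:, :4]
vols = ts.group_volumes(scores, table.groups, table.taxon_ids)
print(round(vols.whole_volume, 2))                         # 7.04
for m in ("uniform", "normal", "permutation"):
    r = ts.null_model_test(scores, m, n_reps=999, seed=42)
    print(m, round(r.occupancy_percent, 2), r.p_value)
# uniform 14.86 0.001
# normal 25.02 0.001
# permutation 34.39 0.001

pa = ts.permanova(scores, table.groups, n_perms=999, seed=42)
print(round(pa.pseudo_F, 1), round(pa.R2, 2), pa.p_value)  # 870.6 0.94 0.001
```

Reading the output: the broken-stick rule keeps 8 PCA axes; the first four
carry 17.0, 9.9, 9.2 and 7.4% of the variance.  The 596 synthetic taxa fill a
4-D hull of volume 7.04 — only 15–34% of what the three null models predict
if the axes varied independently (p = 0.001, the minimum at 999 replicates),
so the planted trait syndromes concentrate the assemblage exactly as trait
trade-offs do in real data.  PERMANOVA confirms that taxonomic groups occupy
distinct regions (R² = 0.94), while PERMDISP finds no dispersion differences
between groups (F = 1.34, p = 0.19), as expected when every synthetic group
shares the same noise level.

The same pipeline runs from a shell:

```sh
traitspace simulate --seed 42 --out table.tsv
traitspace pca table.tsv --out run/
traitspace nullmodel run/scores.tsv --model uniform --reps 999 --seed 42
traitspace permanova run/scores.tsv --perms 999 --seed 42
traitspace all --seed 42 --out run_all/        # everything, one command
```

`traitspace all` writes `scores.tsv`, `loadings.tsv`, `eigenvalues.tsv`,
`correlations.tsv`, per-group moment and volume tables, the null-model
report, the PERMANOVA/PERMDISP report, and a JSON metadata sidecar; the same
config and seed reproduce every file byte for byte.

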