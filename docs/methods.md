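# Methods

## Statistical model for gene classification

Each gene in the multi-tissue experiment is modelled on the log2 scale as

    y_ijk = μ + T_i + t(T)_ij + D_k + (TD)_ik + ε_ijk

with tissue `T` (7 levels), dye `D` (2 levels) and their interaction as
fixed effects and tree-within-tissue `t(T)` (4 biological replicates per
tissue) as a random blocking effect shared by the two dye-swap technical
replicates of a biological sample. Because the design is balanced and
complete, the mixed model has a closed-form solution via the balanced
sum-of-squares decomposition, and the expected-mean-squares argument gives
the F-ratios directly:

- `F_tissue = MS_tissue / MS_tree(tissue)` with (T−1, T(b−1)) df — the
  random blocking term, not the residual, is the correct denominator for
  the tissue effect;
- `F_dye` and `F_tissue×dye` are tested against the residual mean square.

The implementation is vectorized across genes (group means along axes of a
genes × tissue × tree × dye array), so classifying thousands of genes takes
well under a second. Unbalanced designs are rejected with an explicit error
rather than silently falling back to an approximate fit; per-gene REML or
moderated-variance estimators are out of scope. The decomposition satisfies
`SS_total = SS_tissue + SS_tree + SS_dye + SS_tissue×dye + SS_residual` to
machine precision, which the test suite asserts against a term-by-term
textbook computation.

Degenerate genes (all values equal) report F = 0 and p = 1 for every
effect.

### Assumption screening

Before classification, each gene passes four screens:

- **Normality** — Anderson–Darling A² on tissue-centered values, with the
  small-sample adjustment `A²(1 + 0.75/n + 2.25/n²)` and the standard
  piecewise p-value approximation for the estimated-parameters case (the
  implementation agrees with the classical published approximation to six
  digits). Tissue-centered values are used rather than full-model
  residuals: the saturated fixed-effect fit absorbs 35 of the 56 df and
  with it most of the distributional signal, roughly halving the power to
  detect genuinely heavy-tailed genes while the tissue-centered version
  stays calibrated under the null.
- **Variance homogeneity** — classical Levene (mean-centered absolute
  deviations; the median-centered Brown–Forsythe variant is available) on
  the tissue groups.
- **Dye main effect** and **tissue × dye interaction** — from the ANOVA
  itself.

Each screening family is BH-adjusted across genes and a gene is excluded
when any adjusted screening p falls below `alpha_screen` (default 0.05
after adjustment). Screening on unadjusted per-gene p-values was
considered and rejected: four unadjusted α = 0.05 screens exclude ~20% of
perfectly well-behaved genes, which both misrepresents the small excluded
fraction such studies report and destroys the invariant-gene recovery the
generator's conditions support. With BH screening, measured false
exclusion on clean synthetic genes is ~2–3%, while planted dye-effect
violators are excluded with the correct reason in 100% of cases and
heavy-tailed violators in roughly two thirds.

Tested genes are classified by the BH-adjusted tissue p-value:
`variable_high` below 0.0001, `variable_low` in [0.0001, 0.05),
`invariant` at or above 0.05. The BH family is all tested genes of the
experiment.

## Module detection

High-confidence variable genes are clustered on the
technical-replicate-averaged matrix:

1. Pearson correlation matrix (pairwise-complete over missing values).
2. Unsigned soft-threshold adjacency `a_ij = |r_ij|^β`; unsigned because a
   module is defined here as a cluster of positively *and* negatively
   correlated genes that splits into two anticorrelated groups. β defaults
   to 14 (tissue experiment) and 18 (seasonal experiment). A signed variant
   is deliberately not offered.
3. Topological overlap
   `TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,
   `TOM_ii = 1`; dissimilarity 1 − TOM.
4. Average-linkage hierarchical clustering with a **static** branch cut;
   clusters below `min_module_size` (default 30) are pooled into an
   `unassigned` bin. Modules are labelled M1, M2, … by decreasing size.

Static-cut heights: TOM dissimilarities under a high soft power crowd
toward 1 — planted near-orthogonal tissue modules merge with each other
only around 0.995–1.0 while their internal joins finish by ~0.75 even at
noise sd 0.3 — so the tissue-analysis default cut is **0.99**, the
conventional static cut for topological-overlap dendrograms. Temporal
profiles over four timepoints are much more mutually correlated (a step
change and a progressive decline share r ≈ 0.87), which pushes
between-cluster merges down to ~0.85–0.91; the seasonal default cut is
therefore **0.8**, chosen from the gap between within-cluster joins
(≤ ~0.5) and between-cluster merges in the generator's regime. Dynamic
tree cutting and eigengene-similarity module merging are intentionally out
of scope; the static cut is the principal deviation from common practice
and is the reason no claim is made of reproducing any particular published
module count.

**Eigengene and groups.** The module eigengene is the first right singular
vector of the gene-standardized member submatrix (unit norm, per-sample
scores); its orientation makes the majority of members positively
correlated (ties break toward the lexicographically first member). Members
with eigengene correlation ≥ 0 form group *a*, the rest group *b*; a
correlation of exactly 0 goes to *a* by the stated tie rule. Group
templates are per-sample means of the group members on the averaged
matrix. Variance explained equals the top eigenvalue share of the
standardized covariance, verified against a full spectral decomposition.

Group–tissue relationships are Pearson correlations between the signed
group eigengene (group b uses the negated module eigengene) and 0/1 tissue
indicators; tissue–tissue correlations are computed across the groups'
per-tissue eigengene means.

## Template matching

Each low-confidence gene is correlated with every group template on their
common samples (≥ 4 required); the best candidate is the template with the
largest r (ties: larger group, then lexicographic id — a probability-zero
event on continuous data, fixed for determinism). Significance is the
two-sided t-test `t = r√(n−2)/√(1−r²)`; |r| = 1 maps to the smallest
positive float. The BH family is the set of best-candidate tests across all
candidate genes — one test per gene rather than all 2M tests per gene,
which keeps the family interpretable; assignment requires adjusted p < α
**and** r > 0, since groups are defined by positively correlated profiles.

## Representation analysis

For a gene set of size K in a population of N partitioned into cells, the
cell with n genes and k set members is tested both ways with the exact
hypergeometric tails P(X ≥ k) and P(X ≤ k) — two one-tailed tests rather
than one two-tailed test, because over- and under-representation are
reported as distinct calls. BH families: `per_set` (all cells and both
tails of one set; default), `per_cell` (the by-column convention used for
quartile tables), or `global`. A call requires the adjusted tail p below α
*and* the observed count on the corresponding side of the expectation
`Kn/N`.

Invariant genes are partitioned into four expression classes by the rank of
their mean expression over all samples; class sizes differ by at most one
with the remainder allocated to the lowest classes first (4805 genes →
1202/1201/1201/1201), and ties are broken by stable gene-id order so the
partition is deterministic.

## Signed correlation-threshold networks

Edges connect gene pairs with |Pearson r| strictly above the threshold
(default 0.9) on the averaged-replicate matrix, carrying the correlation's
sign; degree counts edges of both signs. Hub ranks use competition ("1224")
ranking: ties share the minimum rank and the following ranks are skipped.
Network intersection keeps edges present in both networks with the same
sign (conflicting signs are dropped and logged) and the nodes incident to
them. The scale-free diagnostic bins positive degrees into 10 logarithmic
bins and reports the slope and R² of the log10(frequency) on log10(degree)
OLS fit; graphs with fewer than three distinct degrees are rejected as
degenerate.

## Seasonal analysis

A balanced two-way fixed-effects ANOVA (species × timepoint, 6 trees per
cell; species is a fixed effect with two named levels) is applied per probe;
time-effect p-values are BH-adjusted across all probes globally, and a gene
is temporally variable if at least one of its probes is significant (the
any-probe collapse rule). Temporal clusters reuse the module machinery with
β = 18 and cut 0.8, labelled T1a, T1b, …

Phase integration crosses the temporal clusters with the tissue-based
partition: each temporal group is tested for overrepresentation across
tissue groups, and members of a June–July-preferential cluster inside a
tissue group where that cluster is significantly overrepresented are
**earlywood** genes; September symmetrically gives **latewood**. Cluster
preference is decided automatically from the per-timepoint template means —
June–July mean vs September mean, with intermediate timepoints yielding
"other" only when they dominate both ends by 10% of the seasonal range (a
step profile that is flat June–August must not flip on replicate noise) —
and can be overridden by explicit configuration. Earlywood and latewood
sets are disjoint by construction (a gene belongs to one temporal group).

## Synthetic data generator

The generator is first-class, tested code and defines the conditions under
which the pipeline is validated.

- **Tissue experiment**: 7 tissues × 4 trees × 2 dyes (56 arrays). Gene
  value = baseline + group sign × amplitude × tissue profile + tree
  intercept + dye offset + iid Gaussian noise, all log2. Baselines are
  uniform on (6, 12) so quartile analyses have spread. Planted modules use
  mean-zero tissue-preferential profiles (1 in the preferred tissue,
  −1/(T−1) elsewhere) so distinct modules are near-orthogonal, mirroring
  tissue-preferential coexpression groups. Defaults: amplitude 2, noise sd
  0.2, tree-effect sd 0.1 (the within/between variance magnitudes are not
  externally calibrated — they are chosen as plausible log2-scale values
  and are tunable). Assumption violators alternate between heavy-tailed
  noise (Student-t, 2 df) and a strong additive dye main effect so both
  screening branches are exercised.
- **Seasonal experiment**: 2 species × 4 timepoints (June, July, August,
  September) × 6 trees. Default planted clusters: a *step* shape (stable
  June–August, sharp change into September) and a *progressive* shape
  (decline starting in August), each as an anticorrelated a/b pair; truth
  records an earlywood/latewood phase from where each profile peaks.
- **Determinism**: a single seed spawns one independent substream per gene
  (`numpy` SeedSequence spawning), so identical parameters and seed give
  bit-identical matrices and truth tables.

What the generator does **not** emulate: probe-level image artefacts,
background/flag structure, intensity-dependent (banana-shaped) dye bias,
correlated noise between genes beyond planted modules, and any real
normalization pipeline (an optional quantile normalization stand-in is
available at ingest, default off). Passing the recovery suites therefore
demonstrates correctness of the statistical machinery under the stated
noise model, not performance on raw two-colour array data.

## Problem sizes used in the validation suites

Parameter-recovery runs use 20 seeded datasets of ~2000 genes (2–6 planted
module pairs of 150+150 genes, noise sd 0.1–0.3) for module recovery
(median adjusted Rand index against planted truth), 200-gene pairs of
experiments for template-matching accuracy at noise sd 0.4, a 131-gene hub
scenario at noise sd 0.1 for exact signed-neighborhood recovery, and
4000-gene pure-noise matrices for type-I-error calibration. The exhaustive
hypergeometric check enumerates every cell with N ≤ 30. The full synthetic
pipeline at ~2000 genes completes in a few seconds on one CPU.

## Known limitations

- The mixed ANOVA requires a balanced complete design; missing cells
  exclude a gene (reason `incomplete`) rather than triggering an
  approximate fit.
- The static TOM cut is scale-dependent: very different noise regimes or
  profile geometries may need a different `cut_height`; no automatic cut
  selection is provided.
- Soft-threshold power is taken as given (14/18); scale-free-fit reporting
  exists but automatic β selection does not.
- The hypergeometric machinery is partition-based and knows nothing about
  ontology DAG structure.
- With four timepoints, temporal shapes are inherently correlated; very
  similar planted shapes (|r| ≳ 0.95) will merge into one cluster and be
  separated only by the a/b split.
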