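# Methods

This note documents the statistical models, the defaults and why they
were chosen, the behaviour of the synthetic-data generator, and the
numerical and design choices made where the design was genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

The central object is a replicate-collapsed **ratio matrix**: rows are
modified phosphopeptide sequences (peptide identity *is* the modified
sequence string — the same backbone with a different phosphosite
placement is a different peptide), columns are the eight kinase-dead
conditions, cells are mutant/WT fold-change ratios on the linear scale
with an explicit missingness mask. Replicates collapse by the **median of
the linear ratios** (the log2 layer is derived afterwards; the median
commutes with the monotone log, so the choice of scale only matters for
even replicate counts, where we follow the linear presentation of the
source tables). Significance B collapses to the **minimum** across
replicates — a conservative "at least this significant" summary — and
variability to the median. Phosphosite coordinates are 1-based protein
positions. Peptides shared by isoforms map to every listed protein; this
multimap drives all protein-level summaries, including network
self-connections (two peptides of one protein).

## Significance B (per-ratio outlier p-value)

Given the log2 ratio distribution of one experiment, the distribution is
centred at its median and each side scaled by the robust one-sigma
percentile distance (84.13th percentile − median on the right, median −
15.87th percentile on the left). The standardized deviation of a target
ratio is referred to a standard normal, two-sided. Consuming precomputed
values from upstream software is the default path; this fallback needs
≥ 20 finite ratios and raises on degenerate (zero-scale) sides, naming
the side.

## Extended Fisher combination

Per-condition two-tailed p-values are twice the significance B value,
capped at 1 (the doubling can exceed 1 for ratios on the "short" side of
the median). For peptide *i* with `m_i ≥ 1` available conditions,

    X_i = -2 Σ ln p_ic   over available c,    X_i ~ χ²(2 m_i) under H0.

With all 8 conditions present this is classical Fisher. There is no
minimum `m_i` for combining — the "significant in ≥ 4 of 8" selection
rule already gates the final candidate list, and `m_i` is reported so
users can filter. p-values of exactly 0 are floored at 1e-300 before the
log (with a warning); an all-missing row yields an NaN sentinel rather
than an exception. BH q-values are computed over **all** peptides with a
defined combined p (complete and incomplete pooled). The selection rule —
combined p < 0.05 AND q < 0.05 AND significance B < 0.05 in ≥ 4 of 8
conditions, with *high confidence* requiring complete measurements — is
monotone: lowering any per-condition p never unselects a peptide.

## Adaptively weighted (AW) cross-check

For complete 8-vectors only: over all 255 nonzero binary weight vectors
`w`, the weighted statistic `Σ w_c (-2 ln p_c)` is referred to
`χ²(2|w|)`; the AW statistic is the minimum of the 255 p-values. Because
a minimum over correlated tests is not a p-value, it is calibrated
against a Monte-Carlo null of uniform 8-vectors with add-one smoothing,
`(#{null ≤ obs} + 1) / (n_null + 1)`; the null sample is shared across
peptides (it depends only on the dimension) and is deterministic under
the configured seed. Default `n_null` = 10,000.

## 5-nearest-neighbour imputation

Only peptides observed in ≥ 4 of 8 conditions enter (excluded peptides
are counted, not errors). Neighbour distance is Euclidean over
co-observed conditions scaled by `sqrt(8 / n_overlap)`, which makes
distances comparable across overlap patterns; candidate donors must share
≥ 2 observed conditions. A missing cell becomes the unweighted mean of
the 5 nearest donors observing that condition; with fewer than 5 eligible
donors the peptide's own row mean is used. Observed cells are never
altered, and an imputed value necessarily lies within its donors' range.

## Tight clustering

The goal is ordered, stable clusters of co-responding peptides without
forcing every peptide into a cluster. Two design choices precede the
resampling machinery:

* **Rows are standardized** (mean 0, sd 1) before clustering, because the
  scientific object is the *pattern* of change across mutants, not its
  magnitude. Without this, unresponsive peptides — all sitting near log2
  = 0 — would form the tightest cluster in the data.
* **k-means** is scikit-learn's (k-means++ initialisation, 10 restarts
  per subsample, seeded from the run RNG), which is deterministic under a
  fixed seed; the contribution of this module is the resampling,
  co-membership and stability layer around it.

The procedure: at the current candidate number of clusters `k`, draw B
subsamples (fraction f of the remaining peptides), run k-means on each,
and record the **co-membership** frequency of every peptide pair (runs
where both were drawn and co-clustered, over runs where both were drawn).
Candidate tight sets are the groups of a complete-linkage cut of the
co-membership distance at `1 − alpha` — complete linkage guarantees
every within-group pair has co-membership ≥ alpha. Candidates are
computed at `k` and `k + 1`; the candidate pair with the highest Jaccard
overlap, if ≥ beta, yields the next cluster (the set from the smaller-k
scan; ties broken by larger set, then lexicographic order). Because
k-means assigns *every* point somewhere, a scattered peptide lying
nearest a tight cluster's centroid co-clusters with it in every run;
such hangers-on are removed by a **Tukey fence** (> Q3 + 1.5 IQR) on
member-to-centroid distances before the cluster is reported. Extracted
members are removed, `k` decrements by one (floor 2), and the search
repeats; when no stable pair exists `k` climbs (up to 3 past its start)
before the search stops. Everything left is *scattered*.

Defaults: `k0` = 10, B = 50 subsamples at 70%, alpha = 0.8, beta = 0.7,
up to 8 clusters, minimum reported cluster size 5. The source analyses
published no hyperparameters for this stage; these values suit the
hundreds-of-peptides scale the pipeline targets, and the number of
clusters is deliberately the least critical knob — clusters arrive in
decreasing stability order and extraction simply stops when stability
runs out.

## Mutant similarity and the stringent correlation network

The 8×8 mutant similarity is Spearman's rho (average ranks for ties) on
log2 ratios, restricted per mutant pair to peptides observed in both with
≥ 2-fold change in both — otherwise the unresponsive majority dominates
every correlation. Pairs with < 3 qualifying peptides yield an undefined
cell. The dendrogram uses average linkage on `1 − rho`; undefined
distances are filled with the largest observed distance (a
pairwise-complete compromise; hierarchical linkage cannot consume NaN).

The peptide network tests all pairs among complete-measurement peptides:
Pearson r on log2 ratios, two-sided p from `t = r sqrt((n−2)/(1−r²))`
with n − 2 = 6 df, retaining `p < 0.05 AND |r| ≥ 0.9`. At n = 8 the two
filters are nested: `|r| = 0.9` gives t ≈ 5.06 and p ≈ 0.0023, so the p
filter can never remove an `|r| ≥ 0.9` edge — the conjunction equals the
|r| screen (asserted in tests). Zero-variance peptides are skipped with a
warning. Protein lifting: an edge exists iff ≥ 1 supporting peptide edge
(multiplicity preserved as metadata, not degree); degree counts distinct
partners, self-connections (two peptides of one protein) are recorded
separately and never count; hubs are degree > 1.

## Causal Bayesian network scoring

Ratios discretize at the strict 2-fold boundaries: `r < 0.5` →
under-phosphorylation, `r > 2` → over-phosphorylation, else baseline
(0.5 and 2.0 are baseline). The 8 replicate-collapsed conditions are the
cases, so every pair is an 8-case, 3-state table — which is why most
posteriors are modest by construction.

For nodes X, Y three structures are scored: X→Y, Y→X, independent. Each
structure's log marginal likelihood is a sum of BDe family terms

    Σ_j [ ln Γ(α_j) − ln Γ(α_j + N_j) ] +
    Σ_jk [ ln Γ(α_jk + N_jk) − ln Γ(α_jk) ],

with BDeu hyperparameters `α_jk = ess / (q·3)` splitting an equivalent
sample size (default 1, configurable) evenly over the q parent
configurations and 3 child states. Counts come from usable cases only:

* **Interventions.** A kinase's own peptides are exogenously set exactly
  in that kinase's kinase-dead condition. An intervened node's own family
  term drops that case ("only the passively observed cases are counted"),
  but the node still serves as an observed parent value in the other
  node's term. On purely observational data the two directed structures
  are score-equivalent (asserted to 1e-10 for ess 1, 3, 9), so pairs of
  never-intervened proteins can never clear posterior 0.5 on complete
  data — they report as independent/undetermined, which is the intended
  reading of the strict "> 0.5" rule.
* **Missing values** are handled by available-case analysis per family
  term: a case contributes iff the child and all parents are observed in
  it. This keeps incomplete peptides in the analysis; note it also means
  asymmetric missingness can break the observational score tie.

Posteriors come from max-subtracted exponentiation of the three log
marginals under a uniform structure prior (all arithmetic in log space).
Zero jointly-observed cases yield an undefined-result sentinel. Sign
annotation is the Pearson sign of the co-change pattern over jointly
observed cases: r ≥ 0.3 activating, r ≤ −0.3 inhibitory, otherwise
undetermined — the directed structure itself carries no
activation/inhibition semantics. The screen scores all pairs among the
focus set (mutated kinases' peptides, high-confidence globally
significant peptides, hub-protein peptides) and reports directed best
structures with posterior strictly above the threshold (default 0.5).

With 8 cases and a single intervened case, the correct direction of a
planted edge is the best structure essentially always, but its posterior
exceeds 0.7 only in a minority of simulations — the package's benchmarks
therefore quantify direction recovery at the 0.5 reporting threshold
(≥ 90% over 100 seeded simulations at 10% leak, recomputed by
`scripts/acceptance.py`).

## Synthetic data generator

The generator emulates the study design the pipeline assumes: 8
conditions × 2 replicates (the reference scale is 1,000 peptides);
per-cell log2 ratio = planted mean + Normal(0, 0.25) — at this noise the
simulated MaxQuant-style "variability" (sd of scan-level ln ratios × 100,
emulated with 3 scan draws) lands mostly below 20, matching what such
experiments report. Missingness has two layers: whole triplex blocks
(the run's two mutant channels jointly) drop with probability 0.2, then
cells drop MCAR at 0.05 — reproducing the triplex-linked identification
of SILAC runs, where within-run overlap is near-total and between-run
overlap is not. The triplex pairing is fixed (KSP1+KSS1, SKS1+STE20,
SNF1+TPK2, ELM1+FUS3). Significance B columns are computed from each
(kinase, replicate) experiment's own generated ratio distribution.

Planted structure: clusters share sparse mean response vectors (reference
scenario: 6 clusters × 15 peptides, ±1.5 log2 units in 4 of 8
conditions); causal sources (kinase proteins) get a −2 log2 self-effect
in their own kinase-dead condition plus a sparse ±1 profile elsewhere,
which their targets mirror scaled by the edge effect and sign — providing
both the observational covariation and the intervention asymmetry the
scorer needs. All randomness flows from one named generator seeded by the
truth's seed; identical seeds give byte-identical tables.

Not emulated: raw spectra, intensity-dependent (MNAR) missingness,
retention-time structure, shared peptides between unrelated proteins, or
correlated noise between conditions of one run. Passing benchmarks
therefore demonstrate correctness of the statistical machinery under the
stated model, not performance on any particular real dataset.

## Benchmark problem sizes

The packaged benchmarks use: 20,000 peptides for the null calibration of
the extended Fisher test; a 90-peptide planted-cluster scenario (2 × 20
clustered + 50 scattered, 1 log2-unit effects) for clustering recovery;
a 100-peptide MCAR holdout for the imputation comparison; 100 seeded
8-case simulations for causal direction recovery; and the 1,000-peptide
reference pipeline for the end-to-end run, which completes in about a
minute on one CPU.

## Known limitations

* The significance B fallback assumes a unimodal, roughly symmetric null
  ratio distribution per experiment; heavy structure in a real experiment
  belongs upstream.
* Available-case BDe scoring is not a principled missing-data posterior;
  strongly informative missingness would bias it.
* The causal screen scores pairs only; no multi-node structure search,
  no latent confounders.
* Dense synthetic data (milder missingness than many real studies)
  produces many |r| ≥ 0.9 edges among hundreds of complete peptides at
  n = 8 simply because the null rate of that screen is ≈ 0.23%; hub
  counts scale accordingly.
* Enrichment is generic hypergeometric over user-supplied gene sets; no
  annotation databases ship with the package.
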