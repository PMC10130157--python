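# Methods

This note documents the models, conventions and numerical choices behind
`culturebench`, in the order data flows through the pipeline.

## Inputs and containers

The central object is the feature table: samples × taxa, non-negative
counts, canonical orientation samples-as-rows. All text I/O is TSV (tab
separator, `.` decimal, UTF-8); BIOM v1 (JSON, dense or sparse) feature
tables are read through the same interface. Validation is strict — duplicate
ids, negative entries and missing values are hard errors with cell
coordinates; all-zero samples are dropped with a logged count, because a
sample with no reads carries no compositional information. Metadata rows
carry donor, medium, time (h), replicate and a role in
{feces, culture, control}; feces rows must not carry a medium (a supplied
one is ignored with a warning). Unassigned taxonomy ranks map to
`unclassified_<rank>` so rank aggregation never silently drops counts;
aggregation is integer-exact (per-sample totals conserved bit-for-bit).

## Community metrics

All β-diversity metrics operate on relative abundances (total-sum scaling).
No rarefaction is performed: the metrics are functions of proportions, and
subsampling would only add variance. Profile sums are checked to 1e-9.

- Shannon H = −Σ p_i log₂ p_i (bits; 0·log 0 = 0).
- Simpson is reported as the Gini–Simpson index 1 − Σ p_i², the
  diversity-increasing variant. The choice matters only for the ranking
  direction (higher = more diverse = better), which is the convention the
  composite ranking uses; the plain dominance D or inverse 1/D would need a
  flipped direction.
- D_JS(P, Q) = ½ KL(P‖M) + ½ KL(Q‖M) with M = ½(P + Q) and base-2
  logarithms, so D_JS ∈ [0, 1]. It is the divergence itself, **not** its
  square root (the metric variant); base 2 matches the Shannon convention.
- Euclidean distance is computed on proportions, not counts and not CLR:
  it accompanies the ASV-level relative-abundance view of a sample.
- Bray–Curtis = Σ|p_i − q_i| / Σ(p_i + q_i), the distance the variance
  partitioning consumes.

Profiles over different taxon universes are compared after union-with-zero
fill. Mismatched levels (ASV vs family) are an error, not a silent union.

## Variance partitioning (PERMANOVA, sequential SS)

Given a distance matrix d over n samples and an **ordered** list of
categorical factors, the matrix A = −½ d² is double-centred to the Gower
matrix G; the total SS is tr(G). For the nested sequence of designs
X_0 = 1, X_k = [X_{k−1}, dummies(factor k)], with orthogonal projectors
H_k (via SVD, rank-revealing), the sequential SS of factor k is
tr(H_k G) − tr(H_{k−1} G); the residual SS is tr(G) − tr(H_m G). Order is
an explicit argument and is never inferred: sequential SS are
order-dependent by construction. Each factor's pseudo-F is its mean square
over the single residual mean square (one error stratum, matching the
one-`Residuals`-row table layout); R² = SS/SS_total. A factor whose dummy
columns add no rank to the design is reported as aliased, by name.

p-values come from free permutation of sample identities (permuting G
symmetrically, design fixed), with the (1 + #{F* ≥ F}) / (1 + N) estimator
so p is never zero. When the design admits at most N distinct arrangements
of its rows, the test switches to exhaustive enumeration (all multiset
permutations, observed arrangement included, p = #{F* ≥ F}/N) with a log
note. A deliberately independent oracle, `exhaustive_permutation_p`,
computes one-way SS from within-group pairwise distances
(SS_W = Σ_groups Σ_{i<j∈g} d²_ij / n_g) and enumerates arrangements; tests
require exact agreement between the two routes on all small designs, and
the projector route agrees with `vegan::adonis2(by="terms")` and
scikit-bio's one-way test to machine precision on shared fixtures.

Numerical notes: with non-Euclidean dissimilarities (Bray–Curtis), G is
indefinite and a near-null factor's sequential SS can be marginally
negative (observed ~−10⁻³ on the replicate factor), exactly as in adonis2;
the SS-additivity and R²-normalisation assertions allow this. A constant
distance matrix has SS_total = 0: F is reported as 0, p as 1, R² as NaN.
R² accounting defines Total SS as the **sum** of component SS, which keeps
the R² column summing to 1 even when inputs are rounded (relevant when
reconstructing R² from published, 3-decimal SS values, where the printed
total can disagree with the component sum in the last digit).

The degrees-of-freedom helper implements main effects only:
df = #levels − 1 per factor, residual = (n − 1) − Σ df. The replicate
("reproducibility") factor is coded as an ordinary categorical factor.

## Enterotyping

The canonical recipe: pairwise D_JS at genus level → partitioning around
medoids (classic BUILD + greedy SWAP on the precomputed distance matrix,
deterministic up to seeded tie-breaks) for each k in 2..6 → k chosen by the
Calinski–Harabasz index, computed from distances through the pairwise-SS
identity (W = Σ_clusters Σ_{i<j} d²/n_c, B = T − W, CH = (B/(k−1))/(W/(n−k))),
which coincides with the coordinate-based CH for Euclidean inputs. Each
cluster is labelled by the genus with the highest mean relative abundance
among its members, prefixed `g_`. Identical samples (zero distances
throughout) make PAM degenerate and are an error; a k with no defined CH
falls back to the smallest admissible k with a warning. The pipeline
enterotypes per donor by default (each donor's feces plus its cultures),
since dominant-genus configurations are donor-specific; any sample subset
can be passed.

## Growth, qPCR and functional assays

ΔOD600 = whole-culture OD − supernatant OD, a biomass proxy robust to
medium turbidity. Negative values (noise) are preserved and logged, not
clipped, so the ranking sees raw data. qPCR relative abundance is
2^(CT_16S − CT_target); fold change is log₂(culture/feces) against the same
donor's feces. A gene that fails to amplify within the 40-cycle protocol is
censored: its abundance is only bounded above by 2^(CT16S−40), so it is
excluded from fold-change aggregation with a log entry rather than imputed.
The per-culture gene-variation score is the mean |log₂ FC| across genes —
symmetric in direction, zero iff nothing changed, order-invariant;
alternative aggregations can be plugged in. Functional divergence is the
same base-2 D_JS applied to row-normalised pathway-level-1 abundances.

## Composite ranking

Within a ranking block, each metric's values are ranked (ties get the mean
of tied positions — deterministic and order-independent); divergence-type
metrics ascending, diversity/growth metrics descending; missing values get
the worst rank with a log entry (a failed assay should penalise, not
vanish). The comprehensive rank is the unweighted mean of per-metric ranks
(weights are exposed for sensitivity analysis but default to equal). Two
presets: the three-metric composition screen ranks one block of all
cultures; the seven-metric panel ranks per-donor blocks of media, then the
media summary averages comprehensive ranks per medium across donors and
reports ties rather than breaking them.

## Drug-metabolism quantification

Calibration is ordinary least squares on (concentration µM, peak-area
ratio) pairs, ≥3 points over ≥2 distinct concentrations; r² is stored, and
curves with r² < 0.99 are flagged (the conventional acceptance bar for
bioanalytical calibration; applied to r², which is marginally stricter than
applying it to |r|). Inverse prediction is x = (y − b)/a; results below the
intercept-implied zero clip to 0 with a warning ("nondetectable"), and
values outside the fitted range are flagged. A line with a negative
intercept implies a detection floor of −b/a: a true zero concentration
produces a negative predicted area, which the simulator clips to zero area
and quantification maps back to the floor, not to zero — the round-trip
identity therefore holds only above the floor, which tests assert
explicitly.

The remaining fraction of a parent drug defaults to the time-matched
no-microbiome control as the denominator, isolating microbial metabolism
from passive degradation; a nominal-dose (500 µM) mode is available because
published time-course plots are ambiguous between the two. Inter-donor
variation is mean/SD/CV with the n−1 SD; the CV of a near-zero mean (a
fully metabolised drug) is dominated by the detection floor and the SD is
the more interpretable spread in that regime.

## Synthetic data

The community generator is multiplicative on abundance (additive on
log-abundance): a global baseline b_i ~ N(0, 1) per taxon; a donor effect
δ_{d,i} ~ N(0, σ_donor) per donor and taxon; medium and time effects drawn
per *family* (taxa are evenly partitioned into families, two genera each)
and shared by all taxa of the family, mimicking coherent family-level
shifts. Expected proportions are the softmax of the summed log-abundances;
each sample draws p ~ Dirichlet(c · expected) and counts ~
Multinomial(depth, p), so rows sum to the requested depth exactly. Feces
samples carry the donor baseline only. One seed threads through every
sampler; no global state.

Defaults are the medium-screening design (3 donors × 7 media × {6, 24} h ×
2 replicates = 84 cultures + 3 feces) with σ_donor = 1.4 > σ_medium = 1.0 >
σ_time = 0.3, Dirichlet concentration 200 and depth 10,000 (a typical
post-denoising depth; depths are a choice, not a measured value). These
magnitudes put the simulated Bray–Curtis variance partition in the regime
the method is meant to detect — donor share ≈ 0.45 > medium ≈ 0.27 > time
≈ 0.015, replicate ≈ 0 — i.e. the donor ≫ medium ≫ time hierarchy, with
replicate noise carried entirely by the Dirichlet/multinomial stages.

What the generator does **not** emulate: phylogenetic correlation between
taxa, taxon–taxon interactions, compositional zero-inflation beyond
multinomial sampling, depth variation between samples, or chimeras and
other sequencing artifacts (the package consumes post-denoising tables by
design). Passing recovery tests therefore shows the estimators are
consistent under the assumed factorial log-linear structure, not that real
cultures satisfy it.

The pathway table is derived from family proportions through a fixed
non-negative random loading matrix — a deliberately crude stand-in for
function prediction that preserves the one property the functional metric
needs (compositionally similar samples get similar functional profiles).
The drug simulator is first-order decay C(t) = C₀e^(−k_d t) per donor with
metabolite M(t) = yield·(C₀ − C(t)), abiotic control decay, mapping to
areas through each analyte's calibration line and multiplicative lognormal
noise (mean-1, given CV). The default three-drug panel encodes the
qualitative phenotypes of interest: fast, donor-uniform hydrolysis
(aspirin-like, lognormal σ = 0.08 on k_d); a ~24 h half-life with large
donor spread (levodopa-like, σ = 0.6); fast conversion with large spread
(doxifluridine-like, σ = 0.5).

## Reproducibility

Every pipeline run requires a seed; all stochastic stages derive their
generators from it. Artifacts carry a `manifest.json` with the fully
resolved configuration (no silent defaults) and a SHA-256 digest per output
file; logs are timestamp-free, so two runs with the same config and seed
are byte-identical, which the test suite asserts by hashing complete
artifact trees.

## Problem sizes in the test suite

Simulated designs in the tests are scaled to 3 donors × 3 media × 2 time
points × 2 replicates at depth 1500–5000 with 40–60 taxa, 999 permutations
where a p-value is inspected and 49 where only SS/R² matter, and 200 null
datasets for the type-I-error calibration — sizes at which every check is
stable across seeds while the whole suite runs in well under a minute.
Exhaustive-enumeration oracles are capped at 10,000 arrangements.
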