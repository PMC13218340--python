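# Methods

This note records the models, conventions and numerical choices behind
`groupfdr`, and what the synthetic-data-based tests do and do not establish.

## Differential-expression testing

ΔΔCt = tumor ΔCt − normal ΔCt per (patient, miRNA). A positive ΔΔCt means
the miRNA amplified later in tumor tissue, i.e. is downregulated there; one
Ct unit corresponds to a 2-fold change. For each miRNA the direction of the
one-sided paired t-test is fixed by the sign of the median ΔΔCt across
patients (median = 0 falls back to the mean's sign; if that is also 0 the
miRNA is flagged untestable with p = 1). The null hypothesis places the mean
within δ Ct of zero in the chosen direction; δ defaults to 1.0 Ct,
encoding "not more than 2-fold deregulated". δ = 0 is supported but
anti-conservative: because the direction is chosen from the same data, the
δ = 0 procedure rejects true nulls at roughly twice the nominal rate (the
test suite demonstrates this). With δ ≥ 1 the data-driven direction choice
is immaterial in practice and p-values at the null boundary are
stochastically super-uniform.

Only complete tumor/normal pairs enter the statistics. If one half of a pair
is missing on input, the other half is discarded too (with a logged
warning), since a lone half-pair cannot contribute to a paired difference.
Untestable miRNAs (fewer than two complete pairs, zero variance, no
direction) are kept in the hypothesis family with p = 1 rather than silently
dropped, so multiplicity corrections always see the full family.

Median imputation (per-miRNA median of the observed ΔΔCt values) exists
solely for sensitivity comparisons. Imputing at the centre of the observed
values shrinks the sample variance, so p-values fall and step-up thresholds
rise; the pipeline test verifies this direction of effect. The imputation
acts on the ΔΔCt scale — the scale actually analyzed — not on the per-tissue
ΔCt values.

## Multiple testing

All procedures are step-up rules on (possibly weighted) p-values; ties at
the realized threshold are all rejected, and sorting is stabilised by
hypothesis id for determinism. p-values of exactly 0 and 1 are legal: the
least-slope rule handles 1 − p = 0 through infinite slopes, a per-group
estimate of 1 gives infinite weighted p-values (never rejected), and an
estimate of 0 gives weighted p-values of 0 (rejected whenever anything is —
an aggressive but algebraically forced limit of the weighting formula).

Estimator conventions:

- TST (two-stage step-up): π̂_g = (n_g − r)/n_g with r the BH rejection count
  inside the group at α′ = α/(1+α).
- LSL (least slope): with slopes l_i = (n_g + 1 − i)/(1 − p₍ᵢ₎) over sorted
  p-values, the estimate is (⌊l_i⌋ + 1)/n_g at the first i ≥ 2 where the
  slope increases, capped at 1; no increase gives 1.
- τ-censored (SABHA): q̂_g = #{p > τ}/(n_g(1 − τ)) clipped to [ε, 1], with
  τ = 0.5 and ε = 0.1 as defaults. No +1 correction is applied to the
  censored count. SABHA rejections are not additionally capped at p ≤ τ by
  default (at α = 0.05 the step-up threshold never approaches τ = 0.5); a
  `tau_cap` flag restores the cap.

The grouped step-up runs at level α_base/(1 − π̄₀) on the weighted p-values,
with α_base = α/(1+α) for TST-GBH and α for LSL-GBH, and π̄₀ the
size-weighted mean of the group estimates; π̄₀ = 1 rejects nothing. These
placements are forced by requiring the single-group cases to coincide
exactly with the cited adaptive procedures (BKY two-stage BH, LSL adaptive
BH, Storey's adaptive BH), which the test suite checks against
independently coded oracles. One edge is worth noting: classical LSL
adaptive BH with π̂₀ = 1 degenerates to plain BH, whereas the weighting
formulation used here (infinite weights) rejects nothing; the package
follows the weighting formulation consistently.

### Finite-sample FDR behavior

Under 1000 replicates of 500 independent p-values in 25 groups of 20 (five
signal groups, half non-null with p ~ Beta(0.1, 1)), measured empirical FDR
at α = 5% is ≈4.5% for BH, ≈6.6% for TST-GBH, ≈5.6% for LSL-GBH and ≈5.9%
for group SABHA. The single-group adaptive reductions all control at ≤5% in
the same harness, so the excess is not an implementation artifact: with many
small groups the per-group null-proportion estimates are noisy, and
selection across groups biases the weights liberally. The grouped
procedures' guarantees are asymptotic in group size; practitioners should
treat results from schemes with many small groups (roughly, maximum group
size below ten) with caution — the detections-vs-scheme sweep makes this
liberality directly visible as a sharp rise in detections.

## Grouping

Scheme keys are (chromosome), (chromosome, strand), (chromosome, strand,
arm); finer schemes chunk any level-(c) group with more than k members into
coordinate-adjacent blocks of size k (the final block may be smaller; a
final block of size 1 is folded into its neighbour, allowing one block of
k+1). Keys with no members never materialise. Single-member groups are
merged into the nearest neighbouring group, where nearness is tiered: same
chromosome first, then increasing chromosome distance in the order 1..22,
X, Y; within a tier the minimum |start difference| to any member decides,
and remaining ties go to the lexicographically smaller group id. The merge
is applied iteratively (two lone singletons merge with each other), so every
scheme built from ≥2 miRNAs has minimum group size ≥2. Coordinates are
1-based point locations; ordering ignores strand polarity. Grouping is fully
deterministic.

## Intra/inter-group association

The diagnostic assumes the exchangeable random-effects decomposition
z[j,i] = μᵢ + a_j + b[j,g(i)] + e[j,i] with independent components, under
which every within-group pair shares correlation (σ_a²+σ_b²)/(σ_a²+σ_b²+σ_e²)
and every between-group pair σ_a²/(σ_a²+σ_b²+σ_e²). The estimator is the
moment estimator: the average pairwise Pearson correlation over all
within-group pairs and over all between-group pairs, computed on
pairwise-complete observations with pairs sharing fewer than three patients
skipped. It is consistent under the model, assumption-light when the model
is violated, and absorbs per-miRNA means through the centering inside each
correlation. A likelihood/REML variance-component fit would be a natural
extension point but is not implemented.

## Control study

Group informativeness is probed by rerunning the grouped procedures under
uniformly random permutations of the hypothesis→group assignment, preserving
the multiset of group sizes and never touching the p-values (the paired
tumor/normal structure is computed once, upstream). Each replicate draws
from an RNG substream keyed by (seed, replicate index), so results are
reproducible and independent of execution order. Summaries report mean,
median and inclusive-midpoint (25th, 75th) percentiles of the per-replicate
detection counts and of their overlaps with a reference BH set and a
user-supplied comparison set. BH itself is excluded — it has no group
dependence. Sampling across replicates is independent (assignments may
repeat), and with a single group every replicate equals the uni-group
procedure.

## Synthetic miRNAome generator

Defaults emulate the motivating study design: 18 patients × 522 miRNAs on
22 chromosomes. What the generator reproduces, and how:

- **Positional structure.** miRNA counts per chromosome decay harmonically
  and strand/arm frequencies are mildly skewed, so the chromosome/strand/arm
  partition yields both small groups and groups above 25 members — every
  max-size split in k ∈ {25…5} is exercised. Start coordinates are unique
  uniform draws per chromosome.
- **Correlation structure.** Tumor-vs-normal (ΔΔCt) noise follows the
  exchangeable model with variance components in proportions
  0.04 : 0.11 : 0.85 of a total of 4 (sd 2 Ct), giving intra-group
  correlation 0.15 and inter-group 0.04. The per-tissue ΔCt layer uses the
  same proportions scaled by 6.25, so expression varies across patients with
  sd ≈ 5 Ct. Splitting the scales this way keeps per-tissue variation
  realistic for qPCR while keeping paired effects of ≥3 Ct detectable at
  p < 0.01 with power ≥0.9 in 18 patients — jointly unattainable with a
  single shared scale.
- **Sparse grouped signal.** By default 10% of the chromosome/strand/arm
  groups carry signal; within such a group half the members are non-null
  with |μ| uniform on [1.5, 7] Ct and random sign. This creates the
  across-group variation in null proportions that grouped methods exploit;
  the effect magnitudes span the range a screen of this kind reports.
- **MNAR missingness.** Per-miRNA raw-Ct baselines are Normal(31.5, 3.5);
  any raw Ct above the cutoff of 40 knocks out the whole tumor/normal pair,
  and miRNAs missing in more than half the patients are removed, mirroring
  standard pre-processing. At the defaults ≈60% of miRNAs have at least one
  missing pair, ≈18% are missing in more than 20% of patients, none exceed
  50% after the drop, and ≈2% of miRNAs are dropped. The baseline mean/sd
  were fixed once, by a design-time grid against that target profile.

What the generator does **not** reproduce: batch and array effects,
per-patient missingness clustering beyond what the detection limit induces,
heavy-tailed or heteroscedastic qPCR noise, and any sequence-level or
amplification-curve realism. Tests passing on this generator therefore
establish internal correctness of the procedures and the qualitative
phenomena (grouped power gain, imputation inflation, MNAR direction), not
performance guarantees on real qPCR data.

## Numerical conventions

- Missing values are read as empty fields or `NA` and written as `NA`.
- Result tables are sorted by (p_raw, mirna_id); all sorts are stable with
  deterministic tie-breaks.
- The step-up search replaces infinite weighted p-values by level + 1, which
  no step-up threshold can reach.
- IQR endpoints use the inclusive midpoint percentile convention.
- All randomness flows through `numpy.random.Generator` objects seeded
  explicitly; derived streams use integer-sequence seeds (seed, index).

## Known limitations

- The grouped procedures can exceed the nominal FDR with many small groups
  (see above); no finite-sample correction is attempted.
- The least-slope estimator is coarse in small groups (often exactly 1),
  which can make LSL-GBH reject nothing where BH rejects; this
  non-containment is by design and demonstrated in the tests.
- The association estimator reports a single pooled intra-group correlation;
  heterogeneous per-group correlations are out of scope.
- Coordinates are point locations; no liftover or annotation validation
  against a genome build is performed.
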