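# Methods

## Evidence model

The pipeline scores putative driver genes by counting, per gene and cancer
type, how many of five independent evidence conditions hold. Each condition
is a binary flag with a recorded provenance reason; flags are combined
additively (CS = Σ X_k, PCO = Σ_cancers CS) rather than probabilistically,
so a score is always interpretable as "number of orthogonal evidence
channels satisfied". An unevaluable stage (no matched normals, too few
survival events, constant covariate) contributes a false flag with its
reason — the denominator k = 1..5 is fixed, so cancers without normal
tissue can reach at most CS = 4 by construction.

### Focal SCNA recurrence ("GISTIC-lite")

Segments are collapsed to a gene × sample log2 copy-ratio matrix by
length-weighted averaging of overlapping segments; genes with no overlapping
segment are imputed diploid (0) and flagged, a conservative choice toward
"no call". The per-gene recurrence score in each direction is

    G_amp(g) = (1/N) Σ_s max(0, x_gs − θ),   θ = 0.1 (log2)

and symmetrically with −x for deletions: a frequency × amplitude score, the
simplified gene-level analogue of GISTIC's marker-level score. Significance
uses a permutation null — each sample's gene-value vector is independently
permuted across genes — pooled over genes and permutations (the same
stabilizing choice GISTIC makes conceptually); per-gene p is the inclusive
right-tail fraction of the pooled null, and q is Benjamini–Hochberg over the
panel. A gene is recurrent when q ≤ 0.25 and G ≥ 0.1, the published
thresholds. Peak deconvolution is out of scope: "located in a peak" is
approximated by gene-level significance in lite mode, and externally
computed G/q tables (with an optional in-peak boolean that is ANDed in) can
be ingested instead; the `provenance` column records which mode produced
each flag. The permutation is realized sparsely — only above-threshold
contributions are non-zero, so a permuted column is equivalent to placing
each sample's positive contributions at distinct uniform random genes —
which makes hundred-seed calibration runs cheap without changing the null.

### Mutation consensus

Frequency is mutated specimens over total specimens; a specimen with several
events in one gene counts once. Silent/synonymous and non-coding MAF classes
are excluded on read (documented mapping table, configurable in the sense
that the mapping is data, not logic). Driver significance is consensus: the
m-index counts how many of up to five external calling algorithms flag the
gene, significant at m ≥ 2. The five published algorithms are consumed,
never re-implemented; with fewer than two call columns the flag is false
with reason "insufficient coverage". For synthetic cohorts, five
pseudo-callers flag a gene when the one-sided binomial tail of its mutation
count against the background rate falls below a caller-specific alpha
(defaults 5e-4–1.2e-3), each call independently flipped with 0.5% noise —
enough caller disagreement to exercise the consensus rule without drowning
it.

### Fusion recurrence

Pairs are ordered (5′→3′) by default since fusion biology is
orientation-specific (configurable to unordered); a pair is recurrent at ≥ 2
events across all specimens. The published recurrence definition is
pan-cancer while the score is per-cancer; both readings are implemented:
`within_cancer` (default — the gene has ≥ 2 events in that cancer type,
keeping all five conditions cancer-specific) and `pan_cancer_pair` (≥ 1
event in the cancer and membership in a pan-cancer-recurrent pair). The
mode is recorded in every output row; neither is asserted as the original
intent.

### Differential expression

Differences d_i = log2(FPKM_t + 1) − log2(FPKM_n + 1) over matched pairs
(pseudocount 1, the standard FPKM transform). Zero differences are dropped
(Wilcoxon's convention). For effective n ≤ 25 the exact two-sided p is
computed from the convolution null of the positive rank sum — extended to
tied midranks via doubled ranks, so it agrees with full 2^n sign-flip
enumeration even under ties; above 25 a normal approximation with tie
correction is used (matching `scipy.stats.wilcoxon(method="approx",
correction=False)`). q is BH across the panel within a cancer type. The
significance rule behind the flag — BH q < 0.05 with a 1.5-fold median
fold-change floor, ≥ 10 pairs — is a declared default (the published
analysis states the test but not its threshold; 1.5-fold matches its own
fold-change convention elsewhere). The broad-expression filter (FPKM ≥ 1 in
≥ 90% of tumours, both bounds inclusive) gates the expression–copy-number
Pearson test (positive r at p < 0.001), which is reported as a side table;
it is not one of the five score conditions.

### Survival association

Each gene is the single covariate of a Cox proportional-hazards fit on
overall survival: standardized log2(FPKM+1) by default (HR per 1 SD), or an
above-median indicator with `covariate="median"` — the continuous form is
the less lossy reading of "univariate factor", and both are provided because
the original dichotomization choice is unstated. The solver is a vectorized
Newton iteration on the one-dimensional partial likelihood with Breslow tie
handling, fitting all panel genes in one pass of matrix algebra; on tie-free
data it matches lifelines to ~1e-5 (Breslow and Efron coincide without
ties), which the test suite checks. Cohorts under 20 samples or 5 events,
constant covariates and monotone likelihoods (perfect separation, detected
as non-convergence or |log HR| > 20 on a standardized covariate) are
reported unevaluable, never silently returned. Classification uses raw
p-values (poor: p < 0.1 and HR > 1; good: p < 0.1 and HR < 1), as published;
a BH column is emitted for transparency only.

### Scoring and ranking

CS/PCO conservation (PCO = Σ CS = Σ channel components) is asserted on
every run. Ranking is descending PCO with invented but fully deterministic
tie-breaks: maximum single-cancer CS, then pan-cancer G-score magnitude,
then lexicographic gene id.

## Synthetic cohorts

The generator emulates the data layers the pipeline consumes, with planted
drivers as ground truth. Defaults (the study conditions of the test suite):

| parameter | default | meaning |
|---|---|---|
| panel / decoys | 37 remodeller genes + 200 decoys | 237 genes, non-trivial rankings |
| background segment log2 | Normal(0, 0.05) | near-diploid arm-scale blocks (32.5 Mb) |
| focal amplitude μ (sd) | ±0.5 (0.05) log2 | straddles the 0.1 amplitude threshold |
| carrier fraction f | 0.4 | planted SCNA penetrance |
| focal length | U(0.5, 5) Mb | covers the planted gene |
| mutation background λ_bg | 0.01 /gene/sample | ~1% background frequency |
| driver multiplier ρ | 8 | echoes an 8% driver vs ~1% background |
| fusion background | 0.01 events/sample | fusions rare relative to SCNA/mutation |
| planted fusion events | 4 | echoes the most recurrent published pair |
| expression baseline | log2 FPKM ~ N(3, 1.5), noise σ = 0.5 | broadly expressed panel |
| DE effect δ | 1.5 log2 | planted over/under-expression |
| dosage slope β_cn | 1.0 | log2 expression tracks copy ratio |
| baseline hazard λ0 | 1e-3 /day | exponential PH survival |
| survival log-hazard θ | 0.7 per SD | planted prognosis effect |
| censoring | dropout 8e-4 /day + 2000-day horizon | ~50–60% events |

One master seed is spawned into per-cancer, per-layer child streams
(`numpy.random.SeedSequence`), so identical (config, seed) give
byte-identical cohorts and disabling one channel leaves the other layers'
draws unchanged. Copy number feeds expression through β_cn, so the
correlation stage has signal by construction; survival times follow an
exponential PH model in the standardized expression of prognosis-channel
genes. Null cohorts zero every planted effect and θ.

What the generator does **not** emulate: whole-genome SCNA process models
(breakage-fusion-bridge, chromothripsis), mutational signatures and
hypermutators, subclonality and purity, batch effects, covariate-dependent
censoring, and correlated expression programs beyond dosage. Passing
recovery and calibration tests therefore demonstrates the pipeline's
statistical behaviour under its own stated model, not performance on real
cohort extracts — for real data the ingestion paths (external GISTIC
tables, real caller matrices) carry the fidelity.

## Test-suite problem sizes and numerical choices

Monte-Carlo suites use sizes chosen once as desk-scale study conditions:
planted-SCNA recovery (f = 0.4, μ = 0.5, N = 200, 100 seeds, 100
permutations); Cox recovery (two-group exponential, true HR 2, n = 500, 200
seeds, < 10% mean log-HR bias); null calibration (32 cancer types × 237
genes × 60 tumours/15 pairs, 100 seeds for the PCO ceiling; 20 runs of
n = 300 for survival-p uniformity); end-to-end recovery (5 cancer types,
3 multi-channel planted drivers, 80 tumours/20 pairs, 100 seeds, top-3
ranks). Permutation p-values use inclusive tails (observed G = 0 ⇒ p = 1);
BH is `scipy.stats.false_discovery_control`. Newton convergence tolerance
is 1e-10 on the step with steps clipped to ±2; fisher information below
1e-12 or |β| > 20 marks a degenerate fit. Floating output is written at 6
significant digits with lexicographic (gene, cancer) row order, which is
what the byte-identical rerun guarantee refers to.

## Known limitations

* GISTIC-lite is not GISTIC: no marker-level peaks, no arm/focal
  separation, no confidence intervals. Real GISTIC output should be
  ingested when available.
* The five mutation callers are consensus inputs; their synthetic stand-ins
  share one binomial test family and differ only in alpha and noise.
* The within-cancer fusion default makes the headline worked example's
  fusion flag depend on events concentrating in one cancer type, which the
  published pair counts do not fully resolve.
* Survival fits are univariate by design; no adjustment for stage, age or
  subtype, mirroring the published analysis.
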