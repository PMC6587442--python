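# Methods

## Genotype allele-balance models

Allele balance (AB) at a position is the fraction of quality-passing reads
supporting the most frequent non-reference base. Three per-genotype
distributions describe its expectation:

* Het: `X ~ Binomial(D, p_het)`. `p_het` defaults to 0.5 and is estimated
  by the pooled MLE `Σalt/Σdepth` when training pairs are supplied; real
  cohorts typically fit slightly below 0.5 (reference-alignment bias).
* Hom-ref: zero-inflated beta `BEINF(α, γ≈0, μ, φ)`; hom-alt: the
  one-inflated mirror. `α` is the boundary point-mass weight, `γ` splits
  it between 1 and 0, the continuous beta is parameterized by mean `μ`
  and precision `φ` (shape1 = `μφ`, shape2 = `(1−μ)φ`).

Fitting: `α` and `γ` have closed-form MLEs (boundary fractions); `(μ, φ)`
maximize the interior beta log-likelihood numerically (Nelder–Mead on
`(logit μ, log φ)`, moment-matched start). A ridge penalty of `1e-3·(log
φ)²` keeps `φ` finite when interior data are nearly degenerate; on healthy
samples of ≥ a few hundred interior points it moves estimates by far less
than their sampling error. With no interior points at all the fit is
flagged `degenerate` and `(μ, φ)` fall back to orientation defaults
(0.01 or 0.99, φ = 50).

P-value conventions (not fully determined by the method's published
description; chosen once and isolated behind `genotype_pvalues`):

* het — exact two-sided binomial by minimum-likelihood ordering (sum of
  outcome probabilities ≤ the observed outcome's probability, with a
  `1+1e-7` relative tie tolerance). Deviation in either direction is an
  error signal.
* hom-ref — upper tail `P(AB ≥ observed)` including the point masses
  (so AB = 0 gives p = 1); hom-alt symmetric lower tail. One-sided because
  evidence against homozygosity can only point toward the opposing allele.

The largest of the three p-values names the genotype; ties break
hom_ref > het > hom_alt. devAB is `AB`, `|AB − 0.5|`, or `|AB − 1|` by
assigned genotype. Exact binomial p-values are discrete and conservative,
so under the null they are super-uniform rather than uniform; tests check
this with a one-sided Kolmogorov–Smirnov statistic.

## Per-position recurrence measures

Over informative samples (depth ≥ 20 at base quality ≥ 20; positions with
fewer than 80 informative samples excluded):
`RdAB1` = mean devAB; `RdAB2` = fraction of samples with best-genotype
p below 0.05 (the significance level is configurable — the published
description does not print it, and 0.05 is the level the method itself
uses for missed-call detection); `RdAB3` = mean of `−log10 max(p, 1e-12)`
— the floor keeps extreme-count zero tail probabilities from producing an
infinite mean. `RdAB3` uses the best-genotype p-value, consistent with
`RdAB2`'s framing.

## Callability classifier

Positions with enough het-called samples are labeled by a two-component
univariate Gaussian mixture on mean het devAB (EM, k-means init, tol
1e-8, fixed seed; larger-mean component = "recurrently deviated";
zero-variance input degenerates to all-clean with a warning). The default
labeling threshold is ≥ 60 het-called samples; the simulated benchmark
cohorts here use 100 samples, where 60 het carriers is unreachable at
realistic allele frequencies, so the bundled scenarios label at ≥ 20 —
a scaled-down cohort choice, not a change to the default.

The logistic regression on `(RdAB1, RdAB2, RdAB3, RdAB2·RdAB3)` is the
unpenalized maximum-likelihood fit. Splits are stratified train /
validation / test at 2/3, 1/6, 1/6; the response cutoff maximizes F1 on
validation (vectorized sweep over all distinct responses; ties take the
lowest threshold). The F1-optimal cutoff is a property of each cohort and
is recomputed per training run, never hard-coded.

The response→precision map pools validation+test responses, bins them
into 20 equal-count bins, computes empirical precision (label mean) per
bin, and enforces monotonicity by isotonic regression; scoring
interpolates linearly between the isotonic knots and clips outside them.
The estimator behind the published precision curve is not specified;
equal-count binning plus isotonic pooling guarantees a usable monotone
score. With few labeled positives the top of the curve saturates coarsely
(the top bin's precision is an average over its occupants), so very small
cohorts may never emit scores above 0.9.

Confidence bins: high ≤ 0.15 < medium ≤ 0.75 < low ≤ 0.9 < very_low. The
boundary 0.9 is assigned to "low" (the filter removes strictly ABB > 0.9);
published descriptions disagree between text and table on this boundary,
and the text convention is used.

Note on coefficient signs: although bias increases all three measures,
the interaction column is collinear with its factors and near-separated
training data leave the MLE direction for `β4` (and occasionally `β3`)
unstable. The guaranteed invariant — response monotone in each feature in
the direction of its fitted coefficient — is what the tests assert.

## Association screen

Missed call: a hom-ref call whose AB has upper-tail p < 0.05 under the
*cohort-wide* hom-ref zero-inflated beta. The cohort-wide model matters:
its interior is dominated by systematically noisy positions, so at a
clean site almost no sample reaches its tail, while a per-site calibrated
model would flag ~5% of hom-refs by construction and swamp the
called:missed test with background. Per variant, a two-sided Fisher exact
test compares called vs missed alternative genotypes between arms;
variant-level bias flags are BH-FDR < 0.1 across all candidate variants.

Per gene: (1) called-missed test on gene-aggregated counts (Pearson
chi-square without continuity correction, Fisher when any expected cell
< 5); (2) re-genotyped association — carriers-vs-noncarriers chi-square
counting called+missed as carriers; (3) cleaned association — called
genotypes at unflagged variants only (p = 1 when nothing usable remains).
Carrier counting is dominant (any alt allele ⇒ carrier), aggregated over
the gene's variants and capped at the arm size. BH-FDR is applied across
genes per test; a gene is `likely_false` iff FDR1 < 0.1, FDR2 > 0.1 or
FDR3 > 0.1. Under this rule any candidate that was never associated is
trivially `likely_false`; the screen is meant for genes that an upstream
RVAS already called significant. Upstream discovery tests (SKAT-O,
burden and kin) are out of scope — the candidate gene list is an input.

## Synthetic cohorts

`simulate_cohort` draws, per site, an allele frequency uniform on
[0.1, 0.5] with Hardy–Weinberg genotypes; per sample×site, depth from a
negative binomial (mean 60, dispersion 5 — WES-like coverage
heterogeneity) and alt counts binomial at the genotype's AB: 0.5 for het,
an inflated-beta draw for homozygotes (hom-ref default α = 0.9, γ = 0,
μ = 0.01, φ = 100 — small error contamination, a plausible-but-arbitrary
default). Bias sites (default 5% of sites) overwrite the evidence of a
penetrance-fraction of samples (default 30%, optionally restricted to a
batch prefix to mimic a capture-kit effect) with binomial draws at
AB = 0.25, inside the suspicious 0.2–0.35 band. Output is reproducible
byte-for-byte given the seed, as in-memory count matrices plus mpileup
text and a truth TSV.

The genotype model for scoring a simulated cohort is fitted on *caller*
labels by default: observations are pre-genotyped with the default AB
model and the class distributions refitted from those calls, mirroring
training on an upstream callset. Fitting on simulator truth labels
instead would assign bias-affected AB≈0.25 evidence to the hom-ref class
and inflate its beta mean several-fold, masking the bias the score is
meant to find.

`simulate_case_control` works at the read-evidence level with an explicit
caller stand-in (het call iff observed AB ≥ 0.3 with ≥ 3 alt reads).
Truly associated genes give cases a clean carrier excess (default 5× a
2% per-variant carrier frequency); confounded genes give both arms the
elevated frequency but shift the biased arm's carrier evidence to
AB = 0.2, which the caller misses — reproducing a burden signal created
entirely by differential genotyping efficiency. Non-carrier evidence is
tight (α = 0.95, μ = 0.005, φ = 200); missed-call detection uses the
fatter cohort-wide default (α = 0.8, μ = 0.05, φ = 20, flagging AB ≳
0.07).

What the simulator does **not** emulate: read-level artifacts (mapping
ambiguity, strand asymmetry, homopolymer/8-oxo-G error motifs), indels,
linkage between sites, per-sample depth correlation across sites, and
caller behavior beyond the AB threshold. Passing benchmarks therefore
demonstrate that the statistical machinery recovers planted AB bias under
its own generative assumptions — not calling accuracy on real reads.

## Problem sizes and runtime choices

The bundled benchmark cohort is 100 samples × 2,000 sites (5% bias
sites); the association scenario uses 300 cases / 300 controls, 10
candidate genes × 4 variants, over 20 seeds. Oracle-equivalence checks
cover every (alt, depth) pair to depth 100 for the binomial test and
every 2×2 table with margins ≤ 30 for the Fisher test (the acceptance
script reports the same statistics at margins ≤ 20). These sizes keep the
full pipeline deterministic and fast on a single CPU while leaving each
check statistically meaningful.

## Known limitations

* SNV-only: indel alleles are ignored at the pileup level.
* Phred+33 qualities only.
* The pileup alt allele is the single most frequent non-reference base;
  tie-break is lexicographic, so multi-allelic artifact mixtures at equal
  counts resolve deterministically but arbitrarily.
* Score tables must be regenerated per cohort/pipeline; scores learned
  under one aligner/caller combination describe that combination's
  artifacts.
* The precision map is a step-linear empirical curve; its resolution is
  bounded by the labeled-set size.
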