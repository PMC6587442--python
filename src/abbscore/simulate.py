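"""Synthetic cohorts with known genotype and bias ground truth.

The generator emulates a WES-like cohort at the read-count level: per-site
allele frequencies, Hardy-Weinberg genotypes, negative-binomial depth,
binomial het evidence around AB 0.5, inflated-beta homozygous error
contamination, and injected systematic-error sites where a fraction of
samples (optionally restricted to a batch, mimicking a capture-kit effect)
shows het-like evidence at a shifted AB (default 0.25, inside the
suspicious 0.2-0.35 band).

A case/control generator produces candidate-gene cohorts where a gene's
burden is either real (excess clean carriers in cases) or confounded
(equal true carrier frequency, but one arm's carrier evidence is shifted
to low AB so an AB-threshold caller misses it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ab_model import BeinfModel, HOM_REF, HET, HOM_ALT
from .association import VariantCohortCounts

_ALT_OF = {"A": "G", "C": "T", "G": "A", "T": "C"}


@dataclass
class SimConfig:
    """Cohort-simulation conditions.

    Depth is negative-binomial (mean ``depth_mean``, dispersion
    ``depth_dispersion``), per-site allele frequency uniform on
    ``af_range``, homozygous error evidence drawn from the inflated-beta
    models then binomially thinned onto reads.
    """

    n_samples: int = 100
    n_sites: int = 2000
    depth_mean: float = 60.0
    depth_dispersion: float = 5.0
    af_range: tuple[float, float] = (0.1, 0.5)
    het_p: float = 0.5
    bias_fraction: float = 0.05
    bias_ab: float = 0.25
    bias_penetrance: float = 0.3
    batch_fraction: float | None = None  # restrict bias to this sample prefix
    hom_ref_error: BeinfModel = field(
        default_factory=lambda: BeinfModel(0.9, 0.0, 0.01, 100.0)
    )
    hom_alt_error: BeinfModel = field(
        default_factory=lambda: BeinfModel(0.9, 1.0, 0.99, 100.0)
    )
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self):
        for name in ("bias_fraction", "bias_penetrance", "het_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")


@dataclass
class CohortData:
    """Simulated cohort: (samples x sites) count matrices plus truth."""

    config: SimConfig
    chrom: str
    positions: np.ndarray  # (n_sites,) 1-based
    ref_bases: np.ndarray  # (n_sites,) str
    alt_bases: np.ndarray
    genotypes: np.ndarray  # (n_samples, n_sites) codes 0/1/2
    depth: np.ndarray  # (n_samples, n_sites) int
    alt: np.ndarray  # (n_samples, n_sites) int
    bias_site: np.ndarray  # (n_sites,) bool truth labels
    affected: np.ndarray  # (n_samples, n_sites) bool


def _nb_depth(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def _beinf_ab(rng: np.random.Generator, model: BeinfModel, size) -> np.ndarray:
    y = rng.beta(model.shape1, model.shape2, size=size)
    boundary = rng.random(size) < model.alpha
    at_one = rng.random(size) < model.gamma
    y[boundary & ~at_one] = 0.0
    y[boundary & at_one] = 1.0
    return y


def simulate_cohort(cfg: SimConfig) -> CohortData:
    """Draw a cohort; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    S, N = cfg.n_samples, cfg.n_sites

    positions = np.arange(1, N + 1) * 100  # spaced, strictly increasing
    ref_idx = rng.integers(0, 4, size=N)
    bases = np.array(list("ACGT"))
    ref_bases = bases[ref_idx]
    alt_bases = np.array([_ALT_OF[b] for b in ref_bases])

    af = rng.uniform(*cfg.af_range, size=N)
    gprobs = np.stack([(1 - af) ** 2, 2 * af * (1 - af), af**2], axis=1)
    u = rng.random((S, N))
    cum = np.cumsum(gprobs, axis=1)
    genotypes = (u[:, :, None] > cum[None, :, :]).sum(axis=2).astype(np.int8)

    depth = _nb_depth(rng, cfg.depth_mean, cfg.depth_dispersion, (S, N))

    # per-entry success probability of a read supporting the alt allele
    p = np.empty((S, N))
    p[genotypes == HET] = cfg.het_p
    p[genotypes == HOM_REF] = _beinf_ab(
        rng, cfg.hom_ref_error, int((genotypes == HOM_REF).sum())
    )
    p[genotypes == HOM_ALT] = _beinf_ab(
        rng, cfg.hom_alt_error, int((genotypes == HOM_ALT).sum())
    )

    bias_site = rng.random(N) < cfg.bias_fraction
    affected = np.zeros((S, N), dtype=bool)
    eligible = np.ones(S, dtype=bool)
    if cfg.batch_fraction is not None:
        eligible[int(round(cfg.batch_fraction * S)) :] = False
    aff_draw = rng.random((S, N)) < cfg.bias_penetrance
    affected[:, bias_site] = (aff_draw & eligible[:, None])[:, bias_site]
    p[affected] = cfg.bias_ab

    alt = rng.binomial(depth, p)
    return CohortData(
        config=cfg,
        chrom=cfg.chrom,
        positions=positions,
        ref_bases=ref_bases,
        alt_bases=alt_bases,
        genotypes=genotypes,
        depth=depth,
        alt=alt,
        bias_site=bias_site,
        affected=affected,
    )


def write_pileups(cohort: CohortData, outdir, qual_char: str = "I") -> list[Path]:
    """One mpileup text file per sample; returns the paths.

    All emitted base qualities are ``qual_char`` (Q40), so parse-time
    quality filtering keeps every read.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    S, N = cohort.depth.shape
    for s in range(S):
        path = outdir / f"sample_{s:04d}.pileup"
        with open(path, "w") as fh:
            for i in range(N):
                d = int(cohort.depth[s, i])
                a = int(cohort.alt[s, i])
                if d == 0:
                    fh.write(f"{cohort.chrom}\t{cohort.positions[i]}\t{cohort.ref_bases[i]}\t0\t*\t*\n")
                    continue
                calls = "." * (d - a) + cohort.alt_bases[i] * a
                fh.write(
                    f"{cohort.chrom}\t{cohort.positions[i]}\t{cohort.ref_bases[i]}\t"
                    f"{d}\t{calls}\t{qual_char * d}\n"
                )
        paths.append(path)
    return paths


def write_truth(cohort: CohortData, dest) -> None:
    """Truth TSV: per-site bias label and per-sample true genotypes."""
    S, N = cohort.genotypes.shape
    with open(dest, "w") as fh:
        fh.write("chrom\tpos\tbias_site\t" + "\t".join(f"s{j:04d}" for j in range(S)) + "\n")
        for i in range(N):
            gts = "\t".join(str(int(g)) for g in cohort.genotypes[:, i])
            fh.write(f"{cohort.chrom}\t{cohort.positions[i]}\t{int(cohort.bias_site[i])}\t{gts}\n")


# ---------------------------------------------------------------------------
# case/control scenario


@dataclass(frozen=True)
class GeneSpec:
    """One candidate gene in the case/control scenario.

    kind: 'null' (no effect), 'associated' (true carrier excess in cases),
    'confounded' (equal carrier frequency, but carriers in the biased arm
    show low-AB evidence that the caller misses).
    """

    name: str
    kind: str = "null"
    n_variants: int = 4
    carrier_freq: float = 0.02
    effect: float = 5.0
    biased_arm: str = "controls"

    def __post_init__(self):
        if self.kind not in ("null", "associated", "confounded"):
            raise ValueError(f"unknown gene kind {self.kind!r}")


@dataclass
class CaseControlData:
    variants: list[VariantCohortCounts]
    truth: dict[str, str]  # gene -> kind
    hom_ref_model: BeinfModel


def _caller_het(alt: np.ndarray, depth: np.ndarray, min_ab: float = 0.3, min_alt: int = 3):
    """Stand-in for an upstream variant caller: het call iff observed AB
    reaches ``min_ab`` with at least ``min_alt`` supporting reads."""
    with np.errstate(invalid="ignore"):
        ab = np.divide(alt, depth, out=np.zeros_like(alt, dtype=float), where=depth > 0)
    return (ab >= min_ab) & (alt >= min_alt)


def simulate_case_control(
    n_cases: int,
    n_controls: int,
    genes: list[GeneSpec],
    depth_mean: float = 60.0,
    depth_dispersion: float = 5.0,
    bias_ab: float = 0.2,
    hom_ref_error: BeinfModel | None = None,
    detection_model: BeinfModel | None = None,
    missed_alpha: float = 0.05,
    seed: int = 0,
) -> CaseControlData:
    """Read-evidence-level case/control cohorts over candidate genes.

    For every variant and sample: carrier status is Bernoulli with the
    arm's carrier frequency; carrier evidence is binomial at AB 0.5
    (clean) or at ``bias_ab`` (confounded gene, biased arm); non-carrier
    evidence follows the clean hom-ref inflated-beta error model. The
    caller stand-in produces called genotypes; missed calls are then
    recovered from the hom-ref-called evidence using ``detection_model``,
    the cohort-wide hom-ref AB model. That model is fitted exome-wide in
    the real workflow and so has a fatter tail than any one clean site
    (systematically noisy positions dominate its interior); the default
    mirrors that, keeping the clean-site missed-call background low while
    low-AB carrier evidence lands deep in its tail.
    """
    if len({g.name for g in genes}) != len(genes):
        raise ValueError("gene names must be unique")
    rng = np.random.default_rng(seed)
    err = hom_ref_error or BeinfModel(0.95, 0.0, 0.005, 200.0)
    det = detection_model or BeinfModel(0.8, 0.0, 0.05, 20.0)

    arms = {"cases": n_cases, "controls": n_controls}
    records: list[dict] = []
    pos = 1000
    for gene in genes:
        for vi in range(gene.n_variants):
            pos += 500
            rec = {"gene": gene.name, "pos": pos, "per_arm": {}}
            for arm, n in arms.items():
                freq = gene.carrier_freq
                if gene.kind == "associated" and arm == "cases":
                    freq = min(1.0, freq * gene.effect)
                if gene.kind == "confounded":
                    freq = min(1.0, freq * gene.effect)
                carrier = rng.random(n) < freq
                depth = np.maximum(_nb_depth(rng, depth_mean, depth_dispersion, n), 1)
                p = _beinf_ab(rng, err, n)
                p[carrier] = 0.5
                if gene.kind == "confounded" and arm == gene.biased_arm:
                    p[carrier] = bias_ab
                alt = rng.binomial(depth, p)
                rec["per_arm"][arm] = (carrier, depth, alt)
            records.append(rec)

    from .association import missed_mask

    variants: list[VariantCohortCounts] = []
    for rec in records:
        counts = {}
        for arm, (carrier, depth, alt) in rec["per_arm"].items():
            called = _caller_het(alt, depth)
            hr_ab = alt[~called] / depth[~called]
            missed = missed_mask(hr_ab, det, alpha=missed_alpha)
            counts[arm] = (int(called.sum()), int(missed.sum()))
        variants.append(
            VariantCohortCounts(
                chrom="chr1",
                pos=rec["pos"],
                ref="A",
                alt="G",
                gene=rec["gene"],
                cases_called=counts["cases"][0],
                cases_missed=counts["cases"][1],
                controls_called=counts["controls"][0],
                controls_missed=counts["controls"][1],
            )
        )
    truth = {g.name: g.kind for g in genes}
    return CaseControlData(variants=variants, truth=truth, hom_ref_model=det)
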