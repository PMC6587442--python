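"""Association-ABB: screening rare-variant association candidates for
signals better explained by allele-balance bias than by true association.

A "missed" call is a homozygous-reference genotype whose alt-read evidence
is improbably strong: upper-tail p-value of the observed AB under the
hom-ref zero-inflated beta below 0.05. Per variant, a Fisher exact test
asks whether the called:missed ratio differs between cases and controls.
Per candidate gene, three tests are run:

1. called-missed ratio test on gene-aggregated counts;
2. re-genotyped association: Pearson chi-square on carriers vs
   non-carriers counting called + missed genotypes as carriers;
3. cleaned association: the same chi-square using only called genotypes at
   variants not flagged as AB-biased.

Benjamini-Hochberg FDR is applied across genes per test. A gene is a
likely false association if FDR1 < 0.1 (biased called:missed ratio), or if
the association disappears after re-genotyping (FDR2 > 0.1) or cleaning
(FDR3 > 0.1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ab_model import BeinfModel, beinf_upper_tail


@dataclass
class VariantCohortCounts:
    """Called/missed alternative-genotype counts for one variant."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    cases_called: int
    cases_missed: int
    controls_called: int
    controls_missed: int
    abb: Optional[float] = None

    def table(self) -> np.ndarray:
        return np.array(
            [
                [self.cases_called, self.cases_missed],
                [self.controls_called, self.controls_missed],
            ]
        )


@dataclass
class GeneAssociationReport:
    gene: str
    n_variants: int
    p_called_missed: float
    p_regenotyped: float
    p_cleaned: float
    fdr_called_missed: float = field(default=np.nan)
    fdr_regenotyped: float = field(default=np.nan)
    fdr_cleaned: float = field(default=np.nan)
    verdict: str = field(default="")


def detect_missed(
    obs, hom_ref_model: BeinfModel, alpha: float = 0.05, genotype: str = "hom_ref"
) -> bool:
    """True iff a hom-ref call's AB is improbably high under the
    zero-inflated beta (upper-tail p < alpha)."""
    if genotype != "hom_ref":
        raise ValueError("missed-call detection applies to hom_ref calls only")
    ab = obs.ab if hasattr(obs, "ab") else float(obs)
    return bool(beinf_upper_tail(ab, hom_ref_model) < alpha)


def missed_mask(ab, hom_ref_model: BeinfModel, alpha: float = 0.05) -> np.ndarray:
    """Vectorized missed-call detection over hom-ref-called AB values."""
    return beinf_upper_tail(np.asarray(ab, dtype=float), hom_ref_model) < alpha


def variant_called_missed_test(v: VariantCohortCounts) -> float:
    """Two-sided Fisher exact p for the called/missed 2x2 table."""
    t = v.table()
    if t.sum() == 0:
        warnings.warn("all-zero called/missed table; p = 1", RuntimeWarning, stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def _table_p(table: np.ndarray, allow_fisher: bool = True) -> float:
    """P-value for a 2x2 table: Pearson chi-square without continuity
    correction, falling back to Fisher when any expected cell < 5."""
    t = np.asarray(table, dtype=float)
    if t.sum() == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if allow_fisher and exp.min() < 5:
        return float(stats.fisher_exact(np.rint(t).astype(int))[1])
    return float(stats.chi2_contingency(t, correction=False)[1])


def _carrier_table(called_cases, called_controls, case_n, control_n) -> np.ndarray:
    cc = min(int(called_cases), case_n)
    ct = min(int(called_controls), control_n)
    return np.array([[cc, case_n - cc], [ct, control_n - ct]])


def gene_tests(
    variants: Sequence[VariantCohortCounts],
    case_n: int,
    control_n: int,
    bias_flags: Sequence[bool],
) -> tuple[float, float, float]:
    """The three gene-level p-values (called-missed, re-genotyped, cleaned).

    Carrier counting is dominant: any alternative allele makes a carrier,
    and gene-level carrier counts aggregate the variants' counts (capped at
    the arm size).
    """
    if len(variants) == 0:
        raise ValueError("gene has no variants")
    if len(bias_flags) != len(variants):
        raise ValueError("bias_flags must align with variants")

    agg = np.sum([v.table() for v in variants], axis=0)
    p1 = _table_p(agg, allow_fisher=True)

    carriers_case = sum(v.cases_called + v.cases_missed for v in variants)
    carriers_ctrl = sum(v.controls_called + v.controls_missed for v in variants)
    p2 = _table_p(
        _carrier_table(carriers_case, carriers_ctrl, case_n, control_n),
        allow_fisher=False,
    )

    clean = [v for v, b in zip(variants, bias_flags) if not b]
    if clean:
        cc = sum(v.cases_called for v in clean)
        ct = sum(v.controls_called for v in clean)
        p3 = _table_p(_carrier_table(cc, ct, case_n, control_n), allow_fisher=False)
    else:
        p3 = 1.0  # nothing usable remains: no evidence of association
    return p1, p2, p3


def run_association_qc(
    variants: Sequence[VariantCohortCounts],
    case_n: int,
    control_n: int,
    fdr_level: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full Association-ABB screen over a candidate-gene variant list.

    Returns (variant_table, gene_table). The variant table carries the
    per-variant Fisher p with BH-FDR across all candidate variants and the
    resulting bias flag (FDR < ``fdr_level``); the gene table carries the
    three tests, per-test BH-FDR across genes, and the verdict.
    """
    if len(variants) == 0:
        raise ValueError("no variants supplied")
    vp = np.array([variant_called_missed_test(v) for v in variants])
    v_fdr = multipletests(vp, method="fdr_bh")[1]
    flags = v_fdr < fdr_level
    variant_df = pd.DataFrame(
        {
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "ref": [v.ref for v in variants],
            "alt": [v.alt for v in variants],
            "gene": [v.gene for v in variants],
            "cases_called": [v.cases_called for v in variants],
            "cases_missed": [v.cases_missed for v in variants],
            "controls_called": [v.controls_called for v in variants],
            "controls_missed": [v.controls_missed for v in variants],
            "abb": [v.abb if v.abb is not None else np.nan for v in variants],
            "p_called_missed": vp,
            "fdr_called_missed": v_fdr,
            "bias_flag": flags,
        }
    )

    reports: list[GeneAssociationReport] = []
    for gene, idx in variant_df.groupby("gene", sort=True).groups.items():
        gv = [variants[i] for i in idx]
        gf = [bool(flags[i]) for i in idx]
        p1, p2, p3 = gene_tests(gv, case_n, control_n, gf)
        reports.append(GeneAssociationReport(str(gene), len(gv), p1, p2, p3))

    for attr_p, attr_f in (
        ("p_called_missed", "fdr_called_missed"),
        ("p_regenotyped", "fdr_regenotyped"),
        ("p_cleaned", "fdr_cleaned"),
    ):
        fdr = multipletests([getattr(r, attr_p) for r in reports], method="fdr_bh")[1]
        for r, q in zip(reports, fdr):
            setattr(r, attr_f, float(q))

    for r in reports:
        likely_false = (
            r.fdr_called_missed < fdr_level
            or r.fdr_regenotyped > fdr_level
            or r.fdr_cleaned > fdr_level
        )
        r.verdict = "likely_false" if likely_false else "keep"

    gene_df = pd.DataFrame([vars(r) for r in reports])
    return variant_df, gene_df
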