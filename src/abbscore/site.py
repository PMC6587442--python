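"""Per-position aggregation of sample-wise AB deviation into the three
recurrent-deviation measures.

For each genomic position, over all informative samples (>= 20 reads at
base quality >= 20 by default):

* ``rdab1`` — mean devAB;
* ``rdab2`` — fraction of samples whose best-genotype p-value is below the
  significance threshold (default 0.05);
* ``rdab3`` — mean of -log10(p) of the best-genotype p-value, with p
  floored at 1e-12 to keep the mean finite at extreme counts.

Positions covered by fewer than ``min_samples`` (default 80) informative
samples are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ab_model import GenotypeABModel, GenotypeCall, HET, dev_ab

P_FLOOR = 1e-12


@dataclass(frozen=True)
class SiteDeviationSummary:
    chrom: str
    pos: int
    n_informative: int
    rdab1: float
    rdab2: float
    rdab3: float


def informative_filter(obs, min_depth: int = 20) -> bool:
    """A sample is informative at a position iff its quality-filtered depth
    reaches ``min_depth`` (base-quality filtering happened at parse time)."""
    return obs.depth_informative >= min_depth


def summarize_site(
    calls: Sequence[GenotypeCall],
    chrom: str = "",
    pos: int = 0,
    min_samples: int = 80,
    sig_threshold: float = 0.05,
    p_floor: float = P_FLOOR,
) -> Optional[SiteDeviationSummary]:
    """Aggregate one position's informative-sample calls; None if excluded."""
    if len(calls) < min_samples:
        return None
    devs = np.array([c.dev_ab for c in calls])
    best_p = np.array([c.best_p for c in calls])
    return SiteDeviationSummary(
        chrom=chrom,
        pos=pos,
        n_informative=len(calls),
        rdab1=float(devs.mean()),
        rdab2=float((best_p < sig_threshold).mean()),
        rdab3=float(np.mean(-np.log10(np.maximum(best_p, p_floor)))),
    )


def summarize_cohort(
    alt: np.ndarray,
    depth: np.ndarray,
    model: GenotypeABModel,
    min_depth: int = 20,
    min_samples: int = 80,
    sig_threshold: float = 0.05,
    p_floor: float = P_FLOOR,
) -> pd.DataFrame:
    """Vectorized cohort summary over (samples x sites) count matrices.

    Returns one row per retained site with columns site (column index into
    the input matrices), n_informative, rdab1..rdab3, n_het (het-called
    informative samples) and mean_het_devab (mean devAB over those,
    NaN if none) — the last two feed classifier labeling.
    """
    alt = np.asarray(alt)
    depth = np.asarray(depth)
    n_samples, n_sites = depth.shape
    informative = depth >= min_depth

    # flatten informative entries only, compute p-values in one shot
    s_idx, t_idx = np.nonzero(informative)
    X = np.column_stack([alt[s_idx, t_idx], depth[s_idx, t_idx]])
    pv = model.predict_pvalues(X)
    codes = np.argmax(pv, axis=1)
    best_p = pv[np.arange(len(pv)), codes]
    ab = X[:, 0] / X[:, 1]
    devs = dev_ab(ab, codes)

    n_inf = np.bincount(t_idx, minlength=n_sites)
    sum_dev = np.bincount(t_idx, weights=devs, minlength=n_sites)
    sum_sig = np.bincount(t_idx, weights=(best_p < sig_threshold), minlength=n_sites)
    sum_nlp = np.bincount(
        t_idx, weights=-np.log10(np.maximum(best_p, p_floor)), minlength=n_sites
    )
    het_mask = codes == HET
    n_het = np.bincount(t_idx[het_mask], minlength=n_sites)
    sum_het_dev = np.bincount(t_idx[het_mask], weights=devs[het_mask], minlength=n_sites)

    keep = n_inf >= min_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        df = pd.DataFrame(
            {
                "site": np.nonzero(keep)[0],
                "n_informative": n_inf[keep],
                "rdab1": sum_dev[keep] / n_inf[keep],
                "rdab2": sum_sig[keep] / n_inf[keep],
                "rdab3": sum_nlp[keep] / n_inf[keep],
                "n_het": n_het[keep],
                "mean_het_devab": np.where(
                    n_het[keep] > 0, sum_het_dev[keep] / np.maximum(n_het[keep], 1), np.nan
                ),
            }
        )
    return df
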