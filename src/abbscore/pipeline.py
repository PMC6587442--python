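"""End-to-end cohort workflow: fit genotype AB models, summarize sites,
label by GMM, train the callability classifier, and score every site."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ab_model import GenotypeABModel
from .classifier import (
    CallabilityModel,
    RecurrentDeviationLabeler,
    confidence_level,
)
from .io import ScoreTableRow
from .simulate import CohortData
from .site import summarize_cohort


@dataclass
class CohortScoringResult:
    genotype_model: GenotypeABModel
    callability_model: CallabilityModel
    summaries: pd.DataFrame  # site summaries + lr_response, abb, confidence
    labels: pd.Series  # GMM labels on the labeled subset (indexed by site)


def fit_genotype_model(
    cohort: CohortData, min_depth: int = 20, labels: str = "caller"
) -> GenotypeABModel:
    """Fit the three AB distributions from the cohort's (evidence,
    genotype) pairs, using informative entries only.

    ``labels='caller'`` (default) mimics training on an upstream callset:
    observations are genotyped with the default AB model first and the
    class distributions refitted from those calls, so evidence that looks
    heterozygous trains the het class wherever it came from.
    ``labels='truth'`` uses the simulator's true genotypes instead.
    """
    mask = cohort.depth >= min_depth
    X = np.column_stack([cohort.alt[mask], cohort.depth[mask]])
    if labels == "truth":
        y = cohort.genotypes[mask]
    elif labels == "caller":
        from .ab_model import default_model

        y = default_model().predict(X)
    else:
        raise ValueError(f"labels must be 'caller' or 'truth', got {labels!r}")
    return GenotypeABModel().fit(X, y)


def score_cohort(
    cohort: CohortData,
    genotype_model: GenotypeABModel | None = None,
    min_depth: int = 20,
    min_samples: int = 80,
    sig_threshold: float = 0.05,
    min_het_calls: int = 60,
    random_state: int = 0,
) -> CohortScoringResult:
    """Run the whole scoring workflow on a simulated or loaded cohort.

    Positions with at least ``min_het_calls`` het-called informative
    samples form the GMM-labeled training set for the logistic model; the
    fitted model then scores every retained position.
    """
    gm = genotype_model or fit_genotype_model(cohort, min_depth=min_depth)
    summaries = summarize_cohort(
        cohort.alt,
        cohort.depth,
        gm,
        min_depth=min_depth,
        min_samples=min_samples,
        sig_threshold=sig_threshold,
    )
    labeled = summaries[summaries["n_het"] >= min_het_calls]
    if len(labeled) < 10:
        raise ValueError(
            f"only {len(labeled)} positions have >= {min_het_calls} het calls; "
            "not enough to label a training set"
        )
    labels = pd.Series(
        RecurrentDeviationLabeler(random_state=random_state).fit_predict(
            labeled["mean_het_devab"].to_numpy()
        ),
        index=labeled["site"].to_numpy(),
    )
    features = labeled[["rdab1", "rdab2", "rdab3"]].to_numpy()
    cm = CallabilityModel(random_state=random_state).fit(features, labels.to_numpy())

    feats_all = summaries[["rdab1", "rdab2", "rdab3"]].to_numpy()
    resp = cm.predict_response(feats_all)
    abb = cm.precision_map(resp)
    out = summaries.copy()
    out["lr_response"] = resp
    out["abb"] = abb
    out["confidence"] = [confidence_level(a) for a in abb]
    return CohortScoringResult(gm, cm, out, labels)


def score_table_rows(cohort: CohortData, summaries: pd.DataFrame) -> list[ScoreTableRow]:
    """Materialize score-table rows (sorted by position) from a scored
    summary frame."""
    rows = []
    for rec in summaries.sort_values("site").itertuples():
        rows.append(
            ScoreTableRow(
                chrom=cohort.chrom,
                pos=int(cohort.positions[rec.site]),
                n_informative=int(rec.n_informative),
                rdab1=float(rec.rdab1),
                rdab2=float(rec.rdab2),
                rdab3=float(rec.rdab3),
                lr_response=float(rec.lr_response),
                abb=float(rec.abb),
                confidence=str(rec.confidence),
            )
        )
    return rows
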