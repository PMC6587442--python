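"""Callability classifier: GMM labeling, logistic model, precision mapping.

Positions are labeled by a two-component Gaussian mixture on mean het
devAB (the component with the larger mean is the "recurrently deviated"
class). A logistic regression on (rdab1, rdab2, rdab3, rdab2*rdab3)
predicts that label; its response is mapped through an empirical,
monotone response->precision curve, and the resulting score is binned
into four confidence levels:

    high (<= 0.15) | medium (<= 0.75) | low (<= 0.9) | very_low (> 0.9)
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

CONFIDENCE_LEVELS = ("high", "medium", "low", "very_low")


def confidence_level(abb: float) -> str:
    """Deterministic binning of the callability score."""
    if abb <= 0.15:
        return "high"
    if abb <= 0.75:
        return "medium"
    if abb <= 0.9:
        return "low"
    return "very_low"


@dataclass
class ABBRecord:
    chrom: str
    pos: int
    lr_response: float
    abb: float
    confidence: str


class RecurrentDeviationLabeler(BaseEstimator):
    """Two-component univariate GMM splitting positions into non-deviated
    (0) and recurrently deviated (1) sets by mean devAB.

    EM with k-means initialization and tight tolerance; the component with
    the larger mean is class 1, and each point gets its maximum-posterior
    label. Degenerate (zero-variance) input yields all-zero labels.
    """

    def __init__(self, random_state: int = 0, tol: float = 1e-8):
        self.random_state = random_state
        self.tol = tol

    def fit_predict(self, values) -> np.ndarray:
        x = np.asarray(values, dtype=float).reshape(-1, 1)
        if x.size == 0:
            raise ValueError("no positions to label")
        if np.ptp(x) == 0.0:
            warnings.warn("degenerate (constant) devAB input; labeling all 0",
                          RuntimeWarning, stacklevel=2)
            self.means_ = np.array([float(x[0, 0]), float(x[0, 0])])
            return np.zeros(len(x), dtype=np.int8)
        gm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            init_params="kmeans",
            tol=self.tol,
            max_iter=500,
            random_state=self.random_state,
        ).fit(x)
        raw = gm.predict(x)
        hi = int(np.argmax(gm.means_.ravel()))
        self.means_ = gm.means_.ravel()
        self.gmm_ = gm
        return (raw == hi).astype(np.int8)


def _design(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("features must be (n, 3): rdab1, rdab2, rdab3")
    return np.column_stack([X, X[:, 1] * X[:, 2]])


def f1_scan(responses: np.ndarray, labels: np.ndarray):
    """F1 at every distinct response used as a >= threshold.

    Returns (thresholds, f1) with thresholds sorted ascending; vectorized
    sweep equivalent to a brute-force scan over distinct response values.
    """
    order = np.argsort(responses)[::-1]
    r = responses[order]
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    pos = y.sum()
    # keep only the last index of each tied response block
    last = np.r_[r[1:] != r[:-1], True]
    tp, fp, r = tp[last], fp[last], r[last]
    fn = pos - tp
    denom = 2 * tp + fp + fn
    f1 = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 0.0)
    return r[::-1], f1[::-1]


class CallabilityModel(BaseEstimator):
    """Logistic model over the three recurrent-deviation measures.

    fit() splits the labeled positions into train/validation/test
    (default 2/3, 1/6, 1/6, stratified), fits an unpenalized logistic
    regression with the rdab2*rdab3 interaction on the training split,
    picks the F1-optimal response cutoff on the validation split, and
    builds the response->precision map from validation+test responses by
    equal-count binning followed by isotonic pooling.

    Attributes
    ----------
    coef_ : array (5,) — beta0 (intercept), beta1..beta3, beta4 (interaction)
    cutoff_ : float — F1-optimal response threshold (validation split)
    f1_ : float — validation F1 at the chosen cutoff
    precision_x_, precision_y_ : knots of the monotone precision map
    """

    def __init__(
        self,
        validation_fraction: float = 1 / 6,
        test_fraction: float = 1 / 6,
        n_bins: int = 20,
        random_state: int = 0,
        tol: float = 1e-8,
    ):
        self.validation_fraction = validation_fraction
        self.test_fraction = test_fraction
        self.n_bins = n_bins
        self.random_state = random_state
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present to train")
        D = _design(X)

        holdout = self.validation_fraction + self.test_fraction
        X_tr, X_rest, y_tr, y_rest = train_test_split(
            D, y, test_size=holdout, stratify=y, random_state=self.random_state
        )
        X_val, X_te, y_val, y_te = train_test_split(
            X_rest,
            y_rest,
            test_size=self.test_fraction / holdout,
            stratify=y_rest,
            random_state=self.random_state,
        )

        # C=inf: unpenalized maximum-likelihood fit
        lr = LogisticRegression(
            C=np.inf, solver="lbfgs", tol=self.tol, max_iter=5000
        ).fit(X_tr, y_tr)
        self.coef_ = np.r_[lr.intercept_, lr.coef_.ravel()]

        r_val = self._response_design(X_val)
        thr, f1 = f1_scan(r_val, y_val)
        best = int(np.argmax(f1))  # first max -> lowest threshold on ties
        self.cutoff_ = float(thr[best])
        self.f1_ = float(f1[best])

        r_map = np.r_[r_val, self._response_design(X_te)]
        y_map = np.r_[y_val, y_te]
        self._build_precision_map(r_map, y_map)
        return self

    # -- internals -------------------------------------------------------

    def _response_design(self, D: np.ndarray) -> np.ndarray:
        z = self.coef_[0] + D @ self.coef_[1:]
        return 1.0 / (1.0 + np.exp(-z))

    def _build_precision_map(self, responses: np.ndarray, labels: np.ndarray) -> None:
        order = np.argsort(responses, kind="stable")
        chunks = np.array_split(order, min(self.n_bins, max(1, len(order))))
        bx = np.array([responses[c].mean() for c in chunks if len(c)])
        by = np.array([labels[c].mean() for c in chunks if len(c)])
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip").fit(bx, by)
        self.precision_x_ = np.asarray(iso.X_thresholds_, dtype=float)
        self.precision_y_ = np.asarray(iso.y_thresholds_, dtype=float)

    # -- inference -------------------------------------------------------

    def predict_response(self, X) -> np.ndarray:
        """Logistic response: P(recurrently deviated) in (0, 1)."""
        check_is_fitted(self, "coef_")
        return self._response_design(_design(X))

    def precision_map(self, responses) -> np.ndarray:
        """Monotone response -> precision mapping (the ABB score)."""
        check_is_fitted(self, "precision_x_")
        r = np.asarray(responses, dtype=float)
        return np.interp(r, self.precision_x_, self.precision_y_)

    def transform(self, X) -> np.ndarray:
        """ABB callability scores for feature rows."""
        return self.precision_map(self.predict_response(X))

    def predict(self, X) -> np.ndarray:
        """Binary labels at the F1-optimal response cutoff."""
        return (self.predict_response(X) >= self.cutoff_).astype(np.int8)

    # -- persistence -----------------------------------------------------

    def to_json(self, path) -> None:
        check_is_fitted(self, "coef_")
        doc = {
            "coef": list(map(float, self.coef_)),
            "cutoff": self.cutoff_,
            "f1": self.f1_,
            "precision_x": list(map(float, self.precision_x_)),
            "precision_y": list(map(float, self.precision_y_)),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CallabilityModel":
        with open(path) as fh:
            doc = json.load(fh)
        m = cls()
        m.coef_ = np.asarray(doc["coef"], dtype=float)
        m.cutoff_ = float(doc["cutoff"])
        m.f1_ = float(doc["f1"])
        m.precision_x_ = np.asarray(doc["precision_x"], dtype=float)
        m.precision_y_ = np.asarray(doc["precision_y"], dtype=float)
        return m


def gmm_label(mean_devabs, random_state: int = 0) -> np.ndarray:
    """Label positions as recurrently deviated (1) or not (0)."""
    return RecurrentDeviationLabeler(random_state=random_state).fit_predict(mean_devabs)


def train_lr(features, labels, **kwargs) -> CallabilityModel:
    """Fit the callability logistic model (thin estimator wrapper)."""
    return CallabilityModel(**kwargs).fit(features, labels)


def score_position(summary, model: CallabilityModel) -> ABBRecord:
    """Score one site summary into an ABB record with confidence level."""
    feats = np.array([[summary.rdab1, summary.rdab2, summary.rdab3]])
    resp = float(model.predict_response(feats)[0])
    abb = float(model.precision_map([resp])[0])
    return ABBRecord(summary.chrom, summary.pos, resp, abb, confidence_level(abb))


def filter_variants(rows, scores: dict, max_abb: float = 0.9):
    """Partition variant rows by the very-low-confidence score filter.

    Rows whose (chrom, pos) score is strictly above ``max_abb`` are
    removed; unscored positions are kept and counted.
    """
    kept, removed = [], []
    n_unscored = 0
    for row in rows:
        abb = scores.get((row.chrom, row.pos))
        if abb is None:
            n_unscored += 1
            kept.append(row)
        elif abb > max_abb:
            removed.append(row)
        else:
            kept.append(row)
    return kept, removed, n_unscored


def annotate_vcf(vcf_in, vcf_out, scores: dict, max_abb: float | None = None) -> int:
    """Copy a VCF adding an INFO ABB=<float> tag; optionally drop rows with
    ABB above ``max_abb``. Returns the number of rows written."""
    import pysam

    src = pysam.VariantFile(str(vcf_in))
    if "ABB" not in src.header.info:
        src.header.info.add("ABB", 1, "Float", "Allele balance bias callability score")
    dst = pysam.VariantFile(str(vcf_out), "w", header=src.header)
    n = 0
    for rec in src:
        abb = scores.get((rec.chrom, rec.pos))
        if abb is not None:
            rec.info["ABB"] = float(abb)
            if max_abb is not None and abb > max_abb:
                continue
        dst.write(rec)
        n += 1
    dst.close()
    return n
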