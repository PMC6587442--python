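"""Expected allele-balance distributions per diploid genotype.

For a diploid sample at a biallelic site the allele balance (AB, fraction of
reads supporting the alternative allele) is modeled per genotype class:

* heterozygous — the alternative read count is Binomial(depth, p) with
  p close to 0.5;
* homozygous reference — AB follows a zero-inflated beta distribution
  (point mass at 0 plus a beta component for residual error reads);
* homozygous alternative — the mirror image, a one-inflated beta.

The inflated beta (BEINF) has four parameters: mixture weight ``alpha`` of
the boundary point masses, Bernoulli split ``gamma`` of that mass between 1
and 0 (P(y=0) = alpha*(1-gamma), P(y=1) = alpha*gamma), and the continuous
beta part parameterized by mean ``mu`` and precision ``phi`` (shape1 =
mu*phi, shape2 = (1-mu)*phi).

Each observation receives one p-value per genotype class; the largest
p-value names the most likely genotype, and the deviation of observed from
expected AB (devAB) is measured relative to that genotype's ideal AB
(0 for hom-ref, 0.5 for het, 1 for hom-alt).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

GENOTYPES = ("hom_ref", "het", "hom_alt")
HOM_REF, HET, HOM_ALT = 0, 1, 2

# relative tolerance when comparing outcome probabilities in the exact
# two-sided binomial test (absorbs floating-point ties)
_PMF_RTOL = 1e-7


class ModelError(ValueError):
    """Invalid model parameters or unusable fitting input."""


@dataclass
class HetModel:
    """Binomial AB model for heterozygous genotypes."""

    p_het: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.p_het < 1.0:
            raise ModelError(f"p_het must be in (0,1), got {self.p_het}")


@dataclass
class BeinfModel:
    """Beta distribution inflated with point masses at 0 and/or 1.

    ``degenerate`` flags fits where no interior observations were available
    and (mu, phi) are placeholder defaults.
    """

    alpha: float
    gamma: float
    mu: float
    phi: float
    degenerate: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ModelError(f"alpha must be in [0,1], got {self.alpha}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ModelError(f"gamma must be in [0,1], got {self.gamma}")
        if not 0.0 < self.mu < 1.0:
            raise ModelError(f"mu must be in (0,1), got {self.mu}")
        if not self.phi > 0.0:
            raise ModelError(f"phi must be > 0, got {self.phi}")

    @property
    def shape1(self) -> float:
        return self.mu * self.phi

    @property
    def shape2(self) -> float:
        return (1.0 - self.mu) * self.phi

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw AB values from the inflated-beta mixture."""
        y = rng.beta(self.shape1, self.shape2, size=size)
        boundary = rng.random(size) < self.alpha
        at_one = rng.random(size) < self.gamma
        y[boundary & ~at_one] = 0.0
        y[boundary & at_one] = 1.0
        return y


def beinf_density(y, model: BeinfModel):
    """Density/mass of the inflated beta at ``y`` (scalar or array).

    Returns alpha*(1-gamma) at y=0, alpha*gamma at y=1 and
    (1-alpha)*beta_pdf(y; mu, phi) on the open interval.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("y must lie in [0, 1]")
    interior = (1.0 - model.alpha) * stats.beta.pdf(y, model.shape1, model.shape2)
    out = np.where(
        y == 0.0,
        model.alpha * (1.0 - model.gamma),
        np.where(y == 1.0, model.alpha * model.gamma, interior),
    )
    return out if out.ndim else float(out)


def beinf_upper_tail(y, model: BeinfModel):
    """P(Y >= y): point mass at 1, the beta upper tail, and the mass at 0
    when y == 0 (so the value at 0 is exactly 1)."""
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("y must lie in [0, 1]")
    p = (1.0 - model.alpha) * stats.beta.sf(y, model.shape1, model.shape2)
    p = p + model.alpha * model.gamma
    p = np.where(y == 0.0, 1.0, p)
    p = np.clip(p, 0.0, 1.0)
    return p if p.ndim else float(p)


def beinf_lower_tail(y, model: BeinfModel):
    """P(Y <= y), the symmetric convention (value at 1 is exactly 1)."""
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("y must lie in [0, 1]")
    p = (1.0 - model.alpha) * stats.beta.cdf(y, model.shape1, model.shape2)
    p = p + model.alpha * (1.0 - model.gamma)
    p = np.where(y == 1.0, 1.0, p)
    p = np.clip(p, 0.0, 1.0)
    return p if p.ndim else float(p)


def fit_beinf(
    values,
    orientation: str = "zero_inflated",
    ridge: float = 1e-3,
) -> BeinfModel:
    """Maximum penalized-likelihood fit of the inflated beta.

    alpha and gamma have closed-form MLEs (boundary fractions); (mu, phi)
    maximize the beta log-likelihood of the interior points numerically,
    with a small ridge penalty on log(phi) that keeps phi finite when the
    interior sample is nearly degenerate.
    """
    if orientation not in ("zero_inflated", "one_inflated"):
        raise ValueError(f"unknown orientation {orientation!r}")
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ModelError("cannot fit inflated beta on an empty sample")
    if np.any((x < 0) | (x > 1)):
        raise ModelError("AB values must lie in [0, 1]")

    boundary = (x == 0.0) | (x == 1.0)
    alpha = float(boundary.mean())
    if boundary.any():
        gamma = float((x[boundary] == 1.0).mean())
    else:
        gamma = 1.0 if orientation == "one_inflated" else 0.0

    interior = x[~boundary]
    if interior.size == 0:
        mu = 0.99 if orientation == "one_inflated" else 0.01
        warnings.warn(
            "no interior AB observations; (mu, phi) set to orientation defaults",
            RuntimeWarning,
            stacklevel=2,
        )
        return BeinfModel(alpha, gamma, mu, 50.0, degenerate=True)

    m = float(np.clip(interior.mean(), 1e-6, 1 - 1e-6))
    v = float(interior.var())
    phi0 = m * (1 - m) / v - 1.0 if v > 0 else 100.0
    phi0 = float(np.clip(phi0, 1e-2, 1e6))

    def nll(theta):
        mu_ = 1.0 / (1.0 + np.exp(-theta[0]))
        phi_ = np.exp(theta[1])
        ll = stats.beta.logpdf(interior, mu_ * phi_, (1 - mu_) * phi_).sum()
        return -(ll - ridge * theta[1] ** 2)

    x0 = np.array([np.log(m / (1 - m)), np.log(phi0)])
    res = optimize.minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    mu = float(1.0 / (1.0 + np.exp(-res.x[0])))
    phi = float(np.exp(res.x[1]))
    return BeinfModel(alpha, gamma, mu, phi)


def fit_het_binomial(alt_counts, depths) -> HetModel:
    """Pooled binomial MLE for heterozygous AB: p = sum(alt) / sum(depth)."""
    alt = np.asarray(alt_counts, dtype=np.int64)
    depth = np.asarray(depths, dtype=np.int64)
    if alt.size == 0:
        raise ModelError("cannot fit het binomial on an empty sample")
    if np.any(depth < 1) or np.any(alt < 0) or np.any(alt > depth):
        raise ModelError("need 0 <= alt <= depth and depth >= 1")
    p = float(alt.sum() / depth.sum())
    return HetModel(p_het=float(np.clip(p, 1e-9, 1 - 1e-9)))


def binom_two_sided_pvalues(k, n, p: float) -> np.ndarray:
    """Exact two-sided binomial p-values by minimum-likelihood ordering.

    p-value = sum of P(X=i) over all outcomes i with
    P(X=i) <= P(X=k) * (1 + 1e-7), the convention of the exact binomial
    test. Vectorized by grouping on the unique values of ``n``.
    """
    k = np.atleast_1d(np.asarray(k, dtype=np.int64))
    n = np.atleast_1d(np.asarray(n, dtype=np.int64))
    k, n = np.broadcast_arrays(k, n)
    if np.any(n < 1) or np.any(k < 0) or np.any(k > n):
        raise ValueError("need 0 <= k <= n and n >= 1")
    out = np.empty(k.shape, dtype=float)
    for nv in np.unique(n):
        pmf = stats.binom.pmf(np.arange(nv + 1), nv, p)
        order = np.sort(pmf)
        cum = np.cumsum(order)
        idx = np.searchsorted(order, pmf * (1.0 + _PMF_RTOL), side="right")
        table = np.clip(cum[idx - 1], 0.0, 1.0)
        mask = n == nv
        out[mask] = table[k[mask]]
    return out


@dataclass
class GenotypeCall:
    """Most-likely genotype of one observation with its three p-values."""

    genotype: str
    p_hom_ref: float
    p_het: float
    p_hom_alt: float
    dev_ab: float

    @property
    def best_p(self) -> float:
        return max(self.p_hom_ref, self.p_het, self.p_hom_alt)


def assign_genotype(pvals) -> str:
    """Largest p-value wins; ties break in the order hom_ref > het > hom_alt."""
    arr = np.asarray(pvals, dtype=float)
    order = (arr[HOM_REF], arr[HET], arr[HOM_ALT])
    return GENOTYPES[int(np.argmax(order))]


def dev_ab(ab, genotype):
    """Deviation of observed AB from the assigned genotype's expectation:
    AB for hom-ref, |AB - 0.5| for het, |AB - 1| for hom-alt."""
    ab = np.asarray(ab, dtype=float)
    if isinstance(genotype, str):
        code = GENOTYPES.index(genotype)
        out = np.select([code == HOM_REF, code == HET], [ab, np.abs(ab - 0.5)], 1.0 - ab)
    else:
        code = np.asarray(genotype)
        out = np.select([code == HOM_REF, code == HET], [ab, np.abs(ab - 0.5)], 1.0 - ab)
    return out if out.ndim else float(out)


class GenotypeABModel(BaseEstimator):
    """Cohort-level expected-AB model for the three diploid genotypes.

    Parameters
    ----------
    p_het : float or None
        Binomial parameter for het sites. None (default) estimates it from
        the training pairs; with no training it falls back to 0.5.
    ridge : float
        Weight of the log-phi ridge penalty in the inflated-beta fits.

    Attributes
    ----------
    het_ : HetModel
    hom_ref_ : BeinfModel (zero-inflated)
    hom_alt_ : BeinfModel (one-inflated)
    """

    def __init__(self, p_het: float | None = None, ridge: float = 1e-3):
        self.p_het = p_het
        self.ridge = ridge

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y):
        """Fit the three genotype AB distributions.

        X : array (n, 2) of (alt_count, depth); y : genotype labels
        (strings from GENOTYPES or codes 0/1/2).
        """
        X = np.asarray(X)
        alt, depth = X[:, 0].astype(np.int64), X[:, 1].astype(np.int64)
        codes = self._codes(y)
        if not np.all(np.isin(codes, (HOM_REF, HET, HOM_ALT))):
            raise ModelError("unknown genotype label in y")
        ab = np.divide(alt, depth, out=np.zeros(len(alt)), where=depth > 0)

        het_mask = codes == HET
        if self.p_het is not None:
            self.het_ = HetModel(self.p_het)
        elif het_mask.any():
            self.het_ = fit_het_binomial(alt[het_mask], depth[het_mask])
        else:
            self.het_ = HetModel(0.5)

        hr = ab[codes == HOM_REF]
        ha = ab[codes == HOM_ALT]
        if hr.size == 0 or ha.size == 0:
            raise ModelError("need observations for both homozygous classes")
        self.hom_ref_ = fit_beinf(hr, "zero_inflated", ridge=self.ridge)
        self.hom_alt_ = fit_beinf(ha, "one_inflated", ridge=self.ridge)
        return self

    def set_components(self, het: HetModel, hom_ref: BeinfModel, hom_alt: BeinfModel):
        """Install pre-fitted component distributions (e.g. defaults)."""
        self.het_, self.hom_ref_, self.hom_alt_ = het, hom_ref, hom_alt
        return self

    @staticmethod
    def _codes(y) -> np.ndarray:
        y = np.asarray(y)
        if y.dtype.kind in "US":
            lut = {g: i for i, g in enumerate(GENOTYPES)}
            try:
                return np.array([lut[g] for g in y], dtype=np.int8)
            except KeyError as e:  # pragma: no cover - message only
                raise ModelError(f"unknown genotype label {e.args[0]!r}") from None
        return y.astype(np.int8)

    # -- inference -------------------------------------------------------

    def predict_pvalues(self, X) -> np.ndarray:
        """(n, 3) array of p-values, columns (hom_ref, het, hom_alt).

        het: exact two-sided binomial; hom-ref: upper tail of the
        zero-inflated beta; hom-alt: lower tail of the one-inflated beta.
        """
        check_is_fitted(self, "het_")
        X = np.asarray(X)
        alt, depth = X[:, 0].astype(np.int64), X[:, 1].astype(np.int64)
        if np.any(depth < 1):
            raise ValueError("depth must be >= 1 for genotype p-values")
        ab = alt / depth
        p_het = binom_two_sided_pvalues(alt, depth, self.het_.p_het)
        p_hr = beinf_upper_tail(ab, self.hom_ref_)
        p_ha = beinf_lower_tail(ab, self.hom_alt_)
        return np.column_stack([p_hr, p_het, p_ha])

    def predict(self, X) -> np.ndarray:
        """Most-likely genotype codes (0 hom_ref, 1 het, 2 hom_alt)."""
        pv = self.predict_pvalues(X)
        # np.argmax returns the first maximum, which with column order
        # (hom_ref, het, hom_alt) is exactly the documented tie-break
        return np.argmax(pv, axis=1).astype(np.int8)

    def call(self, X) -> list[GenotypeCall]:
        """Full per-observation calls with devAB."""
        X = np.asarray(X)
        pv = self.predict_pvalues(X)
        codes = np.argmax(pv, axis=1)
        ab = X[:, 0] / X[:, 1]
        devs = dev_ab(ab, codes)
        return [
            GenotypeCall(GENOTYPES[c], float(p[0]), float(p[1]), float(p[2]), float(d))
            for c, p, d in zip(codes, pv, np.atleast_1d(devs))
        ]

    # -- persistence -----------------------------------------------------

    def to_json(self, path) -> None:
        check_is_fitted(self, "het_")
        doc = {
            "p_het": self.het_.p_het,
            "hom_ref": vars(self.hom_ref_),
            "hom_alt": vars(self.hom_alt_),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GenotypeABModel":
        with open(path) as fh:
            doc = json.load(fh)
        model = cls()
        model.set_components(
            HetModel(doc["p_het"]),
            BeinfModel(**doc["hom_ref"]),
            BeinfModel(**doc["hom_alt"]),
        )
        return model


def genotype_pvalues(alt_count: int, depth: int, model: GenotypeABModel):
    """P-values of one observation under the three genotype models."""
    pv = model.predict_pvalues(np.array([[alt_count, depth]]))
    return float(pv[0, 0]), float(pv[0, 1]), float(pv[0, 2])


def default_model(
    p_het: float = 0.5,
    hom_alpha: float = 0.9,
    hom_mu: float = 0.01,
    hom_phi: float = 100.0,
) -> GenotypeABModel:
    """Plausible WES default: small symmetric error contamination on the
    homozygous classes, het binomial at 0.5."""
    m = GenotypeABModel()
    return m.set_components(
        HetModel(p_het),
        BeinfModel(hom_alpha, 0.0, hom_mu, hom_phi),
        BeinfModel(hom_alpha, 1.0, 1.0 - hom_mu, hom_phi),
    )
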