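"""Continuous trait evolution on chronograms: BM, OU and EB likelihoods,
maximum-likelihood fitting, AIC model comparison, and phylogenetic signal.

All three models induce a multivariate normal distribution of tip values with
mean ``z0 * 1`` and a covariance that is a transform of the shared-path-length
(BM) matrix C of the tree (entries s_ij = age-depth of the MRCA of tips i, j;
T = root age; trees are ultrametric):

* Brownian motion (BM):      V_ij = sigma2 * s_ij
* Ornstein-Uhlenbeck (OU), root-conditioned (non-stationary) form:
      V_ij = sigma2/(2 alpha) * (1 - exp(-2 alpha s_ij)) * exp(-2 alpha (T - s_ij))
  which converges to BM as alpha -> 0.
* Early Burst (EB), rate sigma2(t) = sigma2 * exp(r t) with r <= 0:
      V_ij = sigma2 * (exp(r * s_ij) - 1) / r,   BM at r = 0.

For a fixed shape parameter (alpha or r) the mean and rate are profiled out in
closed form by GLS, leaving a bounded one-dimensional optimization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .tree import Chronogram

__all__ = [
    "TraitModelFit",
    "ModelComparison",
    "SignalStats",
    "TraitModelML",
    "bm_loglik",
    "fit_trait_model",
    "compare_models",
    "akaike_weights",
    "blomberg_k",
    "pagel_lambda",
]

MODELS = ("BM", "OU", "EB")


def align_trait(tree: Chronogram, trait: Mapping[str, float]) -> np.ndarray:
    """Trait values ordered by ``tree.tip_labels``; every tip must be present."""
    missing = [t for t in tree.tip_labels if t not in trait]
    if missing:
        raise ValueError(f"trait values missing for tips: {missing}")
    x = np.array([float(trait[t]) for t in tree.tip_labels])
    if not np.all(np.isfinite(x)):
        raise ValueError("trait values must be finite")
    return x


# ---------------------------------------------------------------------- #
# covariance transforms (unit rate; sigma2 multiplies the result)
# ---------------------------------------------------------------------- #
def _bm_structure(C: np.ndarray) -> np.ndarray:
    return C


def _ou_structure(C: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        return C
    T = np.max(np.diag(C))
    with np.errstate(over="raise"):
        return (1.0 - np.exp(-2.0 * alpha * C)) / (2.0 * alpha) * np.exp(
            -2.0 * alpha * (T - C)
        )


def _eb_structure(C: np.ndarray, r: float) -> np.ndarray:
    if r == 0:
        return C
    return (np.exp(r * C) - 1.0) / r


def _gls_profile(V0: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """Profile (z0, sigma2, lnL) for V = sigma2 * V0 by GLS/ML.

    Returns the analytic ML solution: z0 is the GLS mean, sigma2 the ML rate
    (divisor n), and lnL the maximized log likelihood.
    """
    n = len(x)
    L = np.linalg.cholesky(V0)
    one = np.ones(n)
    a = np.linalg.solve(L, x)
    b = np.linalg.solve(L, one)
    z0 = float(b @ a / (b @ b))
    resid = a - z0 * b
    q = float(resid @ resid)
    sigma2 = q / n
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    lnL = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2) + logdet + n)
    return z0, sigma2, lnL


def bm_loglik(
    tree: Chronogram, trait: Mapping[str, float], sigma2: float, z0: float
) -> float:
    """Brownian-motion log likelihood at given parameters.

    Multivariate normal log density with mean ``z0 * 1`` and covariance
    ``sigma2 * C``.
    """
    if not (sigma2 > 0):
        raise ValueError("sigma2 must be positive")
    x = align_trait(tree, trait)
    C = tree.covariance().matrix
    n = len(x)
    try:
        L = np.linalg.cholesky(sigma2 * C)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular BM covariance; duplicate tips at zero distance — prune "
            "zero-length duplicates or merge identical accessions"
        ) from exc
    r = np.linalg.solve(L, x - z0)
    return float(
        -0.5 * (n * np.log(2 * np.pi) + 2 * np.sum(np.log(np.diag(L))) + r @ r)
    )


@dataclass(frozen=True)
class TraitModelFit:
    """ML fit of a continuous trait model.

    ``aic = 2k - 2 lnL`` with k = 2 for BM (sigma2, z0) and k = 3 for OU/EB.
    """

    model: str
    sigma2: float
    z0: float
    loglik: float
    k: int
    alpha: float | None = None
    eb_rate: float | None = None
    at_bound: bool = False

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik


class TraitModelML(BaseEstimator):
    """Maximum-likelihood fit of a BM, OU or EB trait model.

    Parameters
    ----------
    model : {"BM", "OU", "EB"}
    shape_tol : float
        Tolerance of the bounded 1-D optimization of the shape parameter
        (OU alpha or EB rate).

    Attributes (after ``fit``)
    --------------------------
    sigma2_, z0_, loglik_, aic_, k_ : floats / int
    alpha_ : OU attraction (1/Mya), OU only
    eb_rate_ : EB exponential rate-change (<= 0, 1/Mya), EB only
    at_bound_ : True when the shape optimizer settled at a box bound
    """

    def __init__(self, model: str = "BM", shape_tol: float = 1e-8):
        self.model = model
        self.shape_tol = shape_tol

    def fit(self, tree: Chronogram, trait: Mapping[str, float]) -> "TraitModelML":
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        x = align_trait(tree, trait)
        if len(x) < 3:
            raise ValueError("need at least three tips to fit a trait model")
        C = tree.covariance().matrix
        T = float(np.max(np.diag(C)))
        self.at_bound_ = False
        self.alpha_ = None
        self.eb_rate_ = None

        z0_bm, s2_bm, lnl_bm = _gls_profile(C, x)
        if self.model == "BM":
            self.z0_, self.sigma2_, self.loglik_, self.k_ = z0_bm, s2_bm, lnl_bm, 2
        else:
            if self.model == "OU":
                lo, hi = 1e-9, 50.0 / T
                structure = lambda a: _ou_structure(C, a)
            else:  # EB
                lo, hi = -10.0 / T, -1e-12
                structure = lambda r: _eb_structure(C, r)

            def nll(theta: float) -> float:
                try:
                    return -_gls_profile(structure(theta), x)[2]
                except (np.linalg.LinAlgError, FloatingPointError):
                    return np.inf

            res = optimize.minimize_scalar(
                nll, bounds=(lo, hi), method="bounded",
                options={"xatol": self.shape_tol},
            )
            theta = float(res.x)
            lnl = -float(res.fun)
            # models nest BM at the shape-parameter boundary; never report a
            # fit worse than the nested limit
            if lnl < lnl_bm:
                theta = 0.0
                z0, s2, lnl = z0_bm, s2_bm, lnl_bm
                self.at_bound_ = True
            else:
                z0, s2, _ = _gls_profile(structure(theta), x)
                span = hi - lo
                if min(theta - lo, hi - theta) < 1e-6 * span:
                    self.at_bound_ = True
            self.z0_, self.sigma2_, self.loglik_, self.k_ = z0, s2, lnl, 3
            if self.model == "OU":
                self.alpha_ = theta
            else:
                self.eb_rate_ = theta
        self.aic_ = 2 * self.k_ - 2 * self.loglik_
        return self

    def result_(self) -> TraitModelFit:
        return TraitModelFit(
            model=self.model,
            sigma2=self.sigma2_,
            z0=self.z0_,
            loglik=self.loglik_,
            k=self.k_,
            alpha=self.alpha_,
            eb_rate=self.eb_rate_,
            at_bound=self.at_bound_,
        )


def fit_trait_model(
    tree: Chronogram, trait: Mapping[str, float], model: str = "BM"
) -> TraitModelFit:
    """ML fit of one model; see :class:`TraitModelML`."""
    return TraitModelML(model=model).fit(tree, trait).result_()


@dataclass(frozen=True)
class ModelComparison:
    models: tuple[str, ...]
    aic: tuple[float, ...]
    delta_aic: tuple[float, ...]
    weights: tuple[float, ...]

    def best(self) -> str:
        return self.models[int(np.argmin(self.delta_aic))]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "model": self.models,
                "AIC": self.aic,
                "dAIC": self.delta_aic,
                "w": self.weights,
            }
        ).set_index("model")


def akaike_weights(aic: Sequence[float]) -> np.ndarray:
    aic = np.asarray(aic, dtype=float)
    d = aic - aic.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


def compare_models(fits: Sequence[TraitModelFit]) -> ModelComparison:
    """Rank fits of the same data by delta-AIC and Akaike weights."""
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    aic = np.array([f.aic for f in fits])
    d = aic - aic.min()
    return ModelComparison(
        models=tuple(f.model for f in fits),
        aic=tuple(aic),
        delta_aic=tuple(d),
        weights=tuple(akaike_weights(aic)),
    )


# ---------------------------------------------------------------------- #
# phylogenetic signal
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class SignalStats:
    statistic: str
    estimate: float
    p_value: float
    null: str


def blomberg_k(
    tree: Chronogram,
    trait: Mapping[str, float],
    n_perm: int = 999,
    seed: int | None = None,
) -> SignalStats:
    """Blomberg's K with a tip-permutation significance test.

    K is the ratio (MSE0/MSE)_observed / (MSE0/MSE)_expected-under-BM, where
    MSE0 is the mean squared deviation from the phylogenetic (GLS) mean and
    MSE the C^-1-weighted one.  K ~ 1 under BM; K < 1 less signal, K > 1 more.
    The p-value is the proportion of tip permutations whose phylogenetically
    weighted MSE is <= the observed (add-one rule: (1 + hits)/(n_perm + 1)).
    """
    x = align_trait(tree, trait)
    n = len(x)
    if n < 4:
        raise ValueError("need at least four tips for Blomberg's K")
    if np.allclose(x, x[0]):
        raise ValueError("trait is constant across tips; K undefined")
    C = tree.covariance().matrix
    Cinv = np.linalg.inv(C)
    one = np.ones(n)
    denom_expect = (np.trace(C) - n / (one @ Cinv @ one)) / (n - 1)

    def mse_pair(v: np.ndarray) -> tuple[float, float]:
        abar = float(one @ Cinv @ v / (one @ Cinv @ one))
        d = v - abar
        return float(d @ d) / (n - 1), float(d @ Cinv @ d) / (n - 1)

    mse0, mse = mse_pair(x)
    k = (mse0 / mse) / denom_expect
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            if mse_pair(rng.permutation(x))[1] <= mse:
                hits += 1
        p = (1 + hits) / (n_perm + 1)
        null = f"{n_perm} tip permutations, add-one p"
    else:
        p, null = 1.0, "no permutations requested"
    return SignalStats(statistic="K", estimate=float(k), p_value=float(p), null=null)


def _lambda_structure(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


def lambda_profile_loglik(
    tree: Chronogram, trait: Mapping[str, float], lam: float
) -> float:
    """Profiled BM log likelihood at a fixed Pagel's lambda in [0, 1]."""
    x = align_trait(tree, trait)
    C = tree.covariance().matrix
    return _gls_profile(_lambda_structure(C, lam), x)[2]


def pagel_lambda(tree: Chronogram, trait: Mapping[str, float]) -> SignalStats:
    """ML Pagel's lambda in [0, 1] with a likelihood-ratio test against lambda=0.

    Lambda scales the off-diagonal phylogenetic covariance: lambda = 1 is BM,
    lambda = 0 an iid star phylogeny.  p is the upper tail of chi2(1) at
    2 * (lnL(lambda_hat) - lnL(0)).
    """
    x = align_trait(tree, trait)
    if len(x) < 4:
        raise ValueError("need at least four tips for Pagel's lambda")
    C = tree.covariance().matrix

    def nll(lam: float) -> float:
        try:
            return -_gls_profile(_lambda_structure(C, lam), x)[2]
        except np.linalg.LinAlgError:
            return np.inf

    res = optimize.minimize_scalar(
        nll, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-8}
    )
    cand = [(float(res.x), -float(res.fun)), (0.0, -nll(0.0)), (1.0, -nll(1.0))]
    lam, lnl = max(cand, key=lambda t: t[1])
    lr = max(0.0, 2.0 * (lnl - (-nll(0.0))))
    p = float(stats.chi2.sf(lr, df=1)) if lam > 0 else 1.0
    return SignalStats(
        statistic="lambda",
        estimate=lam,
        p_value=p,
        null="LR test vs lambda=0, chi2(1)",
    )
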