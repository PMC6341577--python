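"""Bayesian threshold-model regression between a continuous trait and a
binary trait on a chronogram.

The binary trait is modelled through an unobserved continuous *liability*:
the observed state is 1 exactly when the liability exceeds a threshold fixed
at 0.  The continuous trait x and the liability l jointly follow a bivariate
Brownian motion on the tree, with covariance ``Sigma (x) C`` where C is the
tree's shared-path-length matrix and

    Sigma = [[sigma_x^2,  r * sigma_x],
             [r * sigma_x,         1]]

The liability BM rate is fixed at 1 and the threshold at 0 for
identifiability; the parameter of interest is the liability correlation r.

Sampling is Metropolis-within-Gibbs: per-species liability updates constrained
to the observed sign, random-walk updates of the two ancestral means and of
sigma_x^2 (log scale, flat prior on the rate), and an update of r on Fisher's
z scale (flat prior on r in (-1, 1)).  Proposal scales adapt toward ~30%
acceptance during burn-in and are frozen afterwards.  The O(1)-per-proposal
quadratic-form bookkeeping is compiled with numba, so the long chains the
method calls for run in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from numba import njit

from .tree import Chronogram
from .trait_models import align_trait

__all__ = [
    "ThresholdPosterior",
    "ThresholdRegression",
    "threshold_mcmc",
    "hpd_interval",
    "effective_size",
]


@dataclass(frozen=True)
class ThresholdPosterior:
    """Thinned posterior sample of the liability correlation r."""

    samples: np.ndarray  # thinned, post-burnin r draws
    mean: float
    hpd_lower: float
    hpd_upper: float
    ess: float
    n_gen: int
    thin: int
    burnin: float
    seed: int | None
    converged: bool  # False flags ESS < 100
    extra: dict | None = None  # thinned draws of sigma_x^2 and the two means

    def summary(self) -> dict:
        return {
            "mean_r": self.mean,
            "hpd95_lower": self.hpd_lower,
            "hpd95_upper": self.hpd_upper,
            "ess": self.ess,
            "n_gen": self.n_gen,
            "thin": self.thin,
            "burnin": self.burnin,
        }


# ---------------------------------------------------------------------- #
# numba MCMC core
# ---------------------------------------------------------------------- #
@njit(cache=True)
def _run_chain(
    A, u, s11, x, sign, l0, mu_x0, mu_l0, sx20, n_gen, thin, seed, update_liab
):  # pragma: no cover - exercised through the wrapper
    np.random.seed(seed)
    n = x.shape[0]
    n_keep = n_gen // thin
    out = np.empty((n_keep, 4))

    mu_x = mu_x0
    mu_l = mu_l0
    sx2 = sx20
    r = 0.0
    lc = l0 - mu_l
    xc = x - mu_x
    Axc = A @ xc
    Alc = A @ lc
    Sxx = xc @ Axc
    Sxl = xc @ Alc
    Sll = lc @ Alc
    sumAxc = Axc.sum()
    sumAlc = Alc.sum()
    diagA = np.empty(n)
    for i in range(n):
        diagA[i] = A[i, i]

    # proposal scales: liabilities, mu_x, mu_l, log sx2, z(r)
    steps = np.array([0.5, 0.5, 0.5, 0.5, 0.5])
    acc = np.zeros(5)
    tries = np.zeros(5)
    adapt_until = n_gen // 5  # adaptation window; chain burnin is >= 20%

    for g in range(n_gen):
        sx = np.sqrt(sx2)
        det = sx2 * (1.0 - r * r)
        a11 = 1.0 / det
        a12 = -r * sx / det
        a22 = sx2 / det
        ldet_sigma = np.log(det)

        # --- liabilities ----------------------------------------------
        for i in range(n if update_liab else 0):
            tries[0] += 1.0
            delta = np.random.normal(0.0, steps[0])
            new_li = lc[i] + mu_l + delta
            if sign[i] * new_li <= 0.0:
                continue
            dSxl = delta * Axc[i]
            dSll = 2.0 * delta * Alc[i] + delta * delta * diagA[i]
            logacc = -0.5 * (2.0 * a12 * dSxl + a22 * dSll)
            if logacc >= 0.0 or np.log(np.random.random()) < logacc:
                acc[0] += 1.0
                lc[i] += delta
                Sxl += dSxl
                Sll += dSll
                for k in range(n):
                    Alc[k] += delta * A[k, i]
                sumAlc += delta * u[i]

        # --- mu_x ------------------------------------------------------
        tries[1] += 1.0
        delta = np.random.normal(0.0, steps[1])
        dSxx = -2.0 * delta * sumAxc + delta * delta * s11
        dSxl = -delta * sumAlc
        logacc = -0.5 * (a11 * dSxx + 2.0 * a12 * dSxl)
        if logacc >= 0.0 or np.log(np.random.random()) < logacc:
            acc[1] += 1.0
            mu_x += delta
            for k in range(n):
                xc[k] -= delta
                Axc[k] -= delta * u[k]
            Sxx += dSxx
            Sxl += dSxl
            sumAxc -= delta * s11

        # --- mu_l ------------------------------------------------------
        tries[2] += 1.0
        delta = np.random.normal(0.0, steps[2])
        dSll = -2.0 * delta * sumAlc + delta * delta * s11
        dSxl = -delta * sumAxc
        logacc = -0.5 * (a22 * dSll + 2.0 * a12 * dSxl)
        if logacc >= 0.0 or np.log(np.random.random()) < logacc:
            acc[2] += 1.0
            mu_l += delta
            for k in range(n):
                lc[k] -= delta
                Alc[k] -= delta * u[k]
            Sll += dSll
            Sxl += dSxl
            sumAlc -= delta * s11

        # --- sigma_x^2 (log-scale walk, flat prior on the rate) --------
        tries[3] += 1.0
        delta = np.random.normal(0.0, steps[3])
        sx2_new = sx2 * np.exp(delta)
        sx_new = np.sqrt(sx2_new)
        det_new = sx2_new * (1.0 - r * r)
        quad_old = a11 * Sxx + 2.0 * a12 * Sxl + a22 * Sll
        quad_new = (
            Sxx / det_new
            + 2.0 * (-r * sx_new / det_new) * Sxl
            + (sx2_new / det_new) * Sll
        )
        logacc = (
            -0.5 * (n * (np.log(det_new) - ldet_sigma) + quad_new - quad_old)
            + delta  # Jacobian of the log-scale proposal
        )
        if logacc >= 0.0 or np.log(np.random.random()) < logacc:
            acc[3] += 1.0
            sx2 = sx2_new

        # --- r (Fisher z walk, flat prior on (-1, 1)) ------------------
        sx = np.sqrt(sx2)
        det = sx2 * (1.0 - r * r)
        a11 = 1.0 / det
        a12 = -r * sx / det
        a22 = sx2 / det
        ldet_sigma = np.log(det)
        tries[4] += 1.0
        z = 0.5 * np.log((1.0 + r) / (1.0 - r))
        z_new = z + np.random.normal(0.0, steps[4])
        r_new = np.tanh(z_new)
        det_new = sx2 * (1.0 - r_new * r_new)
        quad_old = a11 * Sxx + 2.0 * a12 * Sxl + a22 * Sll
        quad_new = (
            Sxx / det_new
            + 2.0 * (-r_new * sx / det_new) * Sxl
            + (sx2 / det_new) * Sll
        )
        logacc = (
            -0.5 * (n * (np.log(det_new) - ldet_sigma) + quad_new - quad_old)
            + np.log(1.0 - r_new * r_new)
            - np.log(1.0 - r * r)  # Jacobian of z -> r
        )
        if logacc >= 0.0 or np.log(np.random.random()) < logacc:
            acc[4] += 1.0
            r = r_new

        # --- adaptation -----------------------------------------------
        if g < adapt_until and (g + 1) % 200 == 0:
            for k in range(5):
                if tries[k] > 0:
                    rate = acc[k] / tries[k]
                    if rate < 0.2:
                        steps[k] *= 0.7
                    elif rate > 0.45:
                        steps[k] *= 1.4
                acc[k] = 0.0
                tries[k] = 0.0

        if (g + 1) % thin == 0:
            idx = (g + 1) // thin - 1
            out[idx, 0] = r
            out[idx, 1] = sx2
            out[idx, 2] = mu_x
            out[idx, 3] = mu_l
    return out


class ThresholdRegression:
    """Threshold-model correlation between a continuous and a binary trait.

    Parameters mirror the published schedule: ``n_gen`` generations sampled
    every ``thin`` steps with a ``burnin`` fraction discarded from the thinned
    chain (defaults 3,000,000 / 1,000 / 0.20).

    Attributes (after ``fit``)
    --------------------------
    posterior_ : :class:`ThresholdPosterior`
    mean_r_, hpd_, ess_ : convenience views of the posterior summary
    """

    def __init__(
        self,
        n_gen: int = 3_000_000,
        thin: int = 1000,
        burnin: float = 0.20,
        seed: int | None = None,
    ):
        self.n_gen = n_gen
        self.thin = thin
        self.burnin = burnin
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_gen": self.n_gen,
            "thin": self.thin,
            "burnin": self.burnin,
            "seed": self.seed,
        }

    def set_params(self, **params) -> "ThresholdRegression":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(
        self,
        tree: Chronogram,
        cont: Mapping[str, float],
        bin: Mapping[str, int],
        observed_liability: Mapping[str, float] | None = None,
    ) -> "ThresholdRegression":
        """Sample the posterior of r.

        ``observed_liability`` fixes the liabilities at observed continuous
        values instead of sampling them (the binary trait is then only used
        for validation of signs); this degenerate mode estimates the plain
        phylogenetic correlation of two continuous traits.
        """
        if not (0.0 <= self.burnin < 1.0):
            raise ValueError("burnin must be a fraction in [0, 1)")
        shared = [t for t in tree.tip_labels if t in cont and t in bin]
        if len(shared) < 4:
            raise ValueError("need at least four species shared by tree and traits")
        if len(shared) < tree.n_tips:
            tree = tree.prune_to_species({t: t for t in shared})
        x = align_trait(tree, cont)
        b = np.array([int(bin[t]) for t in tree.tip_labels])
        if not set(np.unique(b)) <= {0, 1}:
            raise ValueError("binary trait values must be 0/1")
        if len(np.unique(b)) < 2:
            raise ValueError("binary trait is constant across species")
        C = tree.covariance().matrix
        A = np.linalg.inv(C)
        one = np.ones(len(x))
        u = A @ one
        s11 = float(one @ u)
        mu0 = float(u @ x / s11)
        sx20 = float((x - mu0) @ A @ (x - mu0) / len(x))
        sign = np.where(b == 1, 1.0, -1.0)
        if observed_liability is None:
            update_liab = True
            l0 = sign * np.sqrt(np.diag(C).mean())  # liability scale ~ BM sd
        else:
            update_liab = False
            l0 = np.array([float(observed_liability[t]) for t in tree.tip_labels])
        seed = 0 if self.seed is None else int(self.seed) % (2**31 - 1)
        draws = _run_chain(
            A,
            u,
            s11,
            x.astype(float),
            sign,
            l0,
            mu0,
            0.0,
            max(sx20, 1e-8),
            int(self.n_gen),
            int(self.thin),
            seed,
            update_liab,
        )
        n_burn = int(np.floor(self.burnin * draws.shape[0]))
        kept = draws[n_burn:]
        r = kept[:, 0]
        lo, hi = hpd_interval(r, 0.95)
        ess = effective_size(r)
        self.posterior_ = ThresholdPosterior(
            samples=r.copy(),
            mean=float(r.mean()),
            hpd_lower=lo,
            hpd_upper=hi,
            ess=ess,
            n_gen=self.n_gen,
            thin=self.thin,
            burnin=self.burnin,
            seed=self.seed,
            converged=bool(ess >= 100),
            extra={
                "sigma_x2": kept[:, 1].copy(),
                "mu_x": kept[:, 2].copy(),
                "mu_l": kept[:, 3].copy(),
            },
        )
        self.mean_r_ = self.posterior_.mean
        self.hpd_ = (lo, hi)
        self.ess_ = ess
        return self


def threshold_mcmc(
    tree: Chronogram,
    cont: Mapping[str, float],
    bin: Mapping[str, int],
    n_gen: int = 3_000_000,
    thin: int = 1000,
    burnin: float = 0.20,
    seed: int | None = None,
) -> ThresholdPosterior:
    """Posterior of the liability correlation r (see :class:`ThresholdRegression`)."""
    return (
        ThresholdRegression(n_gen=n_gen, thin=thin, burnin=burnin, seed=seed)
        .fit(tree, cont, bin)
        .posterior_
    )


def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` samples.

    Ties in window width are broken leftmost.
    """
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must lie in (0, 1)")
    s = np.sort(np.asarray(samples, dtype=float))
    n = len(s)
    if n < 10:
        raise ValueError("need at least 10 samples for an HPD interval")
    m = int(np.ceil(mass * n))
    widths = s[m - 1 :] - s[: n - m + 1]
    k = int(np.argmin(widths))
    return float(s[k]), float(s[k + m - 1])


def effective_size(samples: np.ndarray, max_order: int | None = None) -> float:
    """Effective sample size from the AR spectral density at frequency zero.

    Fits an AR(p) model by Yule-Walker with AIC order selection (orders 0..
    ``10 log10 n`` by default) and returns ``n * var / s0`` with
    ``s0 = sigma_resid^2 / (1 - sum(phi))^2``.  A zero-variance chain has
    ESS 0 by definition.
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples")
    v = float(np.var(x, ddof=1))
    if v <= 0 or not np.isfinite(v):
        return 0.0
    if max_order is None:
        max_order = int(min(n - 1, np.floor(10 * np.log10(n))))
    xc = x - x.mean()
    # autocovariances (biased, as in Yule-Walker)
    gamma = np.array(
        [xc[: n - k] @ xc[k:] / n for k in range(max_order + 1)]
    )
    best_aic = np.inf
    best_s0 = gamma[0]
    for p in range(0, max_order + 1):
        if p == 0:
            vp = gamma[0]
            phi_sum = 0.0
        else:
            R = np.array([[gamma[abs(i - j)] for j in range(p)] for i in range(p)])
            try:
                phi = np.linalg.solve(R, gamma[1 : p + 1])
            except np.linalg.LinAlgError:
                continue
            vp = gamma[0] - phi @ gamma[1 : p + 1]
            phi_sum = float(phi.sum())
            if vp <= 0 or abs(1.0 - phi_sum) < 1e-10:
                continue
        aic = n * np.log(max(vp, 1e-300)) + 2.0 * p
        if aic < best_aic:
            best_aic = aic
            best_s0 = vp / (1.0 - phi_sum) ** 2
    if best_s0 <= 0:
        return 0.0
    return float(min(n * v / best_s0, float(n)))
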