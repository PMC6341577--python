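"""Ancestral range estimation under the dispersal-extinction-cladogenesis
(DEC) model and its founder-event extension (DEC+J), on a fixed chronogram.

Geographic ranges are non-empty subsets of a small set of areas, capped at
``max_range`` areas (default 2).  Anagenetic evolution along branches is a
continuous-time Markov chain: range expansion R -> R + {a} at rate
``d * sum_{b in R} m(b, a)`` (m = pairwise dispersal multipliers) and range
contraction R -> R - {a} at rate ``e`` per occupied area (a singleton contracts
into the absorbing null range).  At each cladogenesis the parent range is
inherited by the two daughters through one of the event classes:

* single-area sympatry: parent {A} -> ({A}, {A})
* subset sympatry:      parent R (|R|>1) -> (R, {a}) with a in R
* vicariance:           parent R -> (R1, R2), disjoint, one daughter a singleton
* founder event (+J):   parent R -> (R, {a}) with a NOT in R

Each non-jump event carries weight (3 - j)/3 and each founder event weight
j / (number of jump targets); weights are normalized per parent state.  j = 0
recovers plain DEC (all allowed events equally weighted).

The likelihood is computed by Felsenstein pruning with matrix exponentials
along edges and the cladogenetic weight table at nodes; the root conditional
likelihoods are combined with a flat prior over non-null states.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import expm as _dense_expm
from sklearn.base import BaseEstimator

from .tree import Chronogram

__all__ = [
    "AreaSet",
    "DEFAULT_AREAS",
    "build_state_space",
    "build_anagenetic_Q",
    "cladogenesis_table",
    "dec_loglik",
    "DECModel",
    "fit_dec",
    "likelihood_ratio_test",
    "node_marginals",
    "LRTResult",
]

#: the six biogeographic areas used throughout: Mexico/Central America/NW South
#: America, Amazon (incl. Guiana Shield), Atlantic Forest, Africa, Madagascar,
#: Southeast Asia
DEFAULT_AREAS: tuple[str, ...] = ("CAM", "AMZ", "ATF", "AFR", "MAD", "SEA")


@dataclass(frozen=True)
class AreaSet:
    codes: tuple[str, ...] = DEFAULT_AREAS

    def __post_init__(self) -> None:
        if not (2 <= len(self.codes) <= 10):
            raise ValueError("between 2 and 10 areas supported")
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("area codes must be unique")

    def __len__(self) -> int:
        return len(self.codes)

    def index(self, code: str) -> int:
        return self.codes.index(code)


def build_state_space(
    areas: AreaSet | Sequence[str], max_range: int = 2
) -> list[frozenset[str]]:
    """All ranges of 1..max_range areas, ordered by size then lexicographically.

    The null range used internally by the CTMC is *not* included; it is always
    state index 0 in the rate matrix (see :func:`build_anagenetic_Q`).
    """
    codes = areas.codes if isinstance(areas, AreaSet) else tuple(areas)
    if max_range < 1:
        raise ValueError("max_range must be >= 1")
    if max_range > len(codes):
        raise ValueError("max_range cannot exceed the number of areas")
    states = []
    for k in range(1, max_range + 1):
        for combo in itertools.combinations(range(len(codes)), k):
            states.append(frozenset(codes[i] for i in combo))
    return states


def _state_index(states: Sequence[frozenset[str]]) -> dict[frozenset[str], int]:
    # +1 offset: index 0 is the null range
    return {s: i + 1 for i, s in enumerate(states)}


def _check_multipliers(m: np.ndarray, n_areas: int) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (n_areas, n_areas):
        raise ValueError(
            f"dispersal multiplier matrix must be {n_areas}x{n_areas}, got {m.shape}"
        )
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("dispersal multipliers must lie in [0, 1]")
    return m


def build_anagenetic_Q(
    states: Sequence[frozenset[str]],
    d: float,
    e: float,
    multipliers: np.ndarray | None = None,
    areas: AreaSet | Sequence[str] = DEFAULT_AREAS,
) -> np.ndarray:
    """Anagenetic rate matrix over (null + ranges); rows sum to zero.

    Row/column 0 is the absorbing null range.  Expansion R -> R+{a} occurs at
    rate ``d * sum_{b in R} m(b, a)``; every contraction R -> R-{a} at rate
    ``e`` (singletons contract to null).
    """
    if d < 0 or e < 0:
        raise ValueError("rates d and e must be non-negative")
    codes = areas.codes if isinstance(areas, AreaSet) else tuple(areas)
    n_areas = len(codes)
    if multipliers is None:
        multipliers = np.ones((n_areas, n_areas))
    m = _check_multipliers(multipliers, n_areas)
    pos = {c: i for i, c in enumerate(codes)}
    idx = _state_index(states)
    max_range = max(len(s) for s in states)
    S = len(states) + 1
    Q = np.zeros((S, S))
    for s in states:
        i = idx[s]
        # expansions
        if len(s) < max_range:
            for a in codes:
                if a in s:
                    continue
                target = frozenset(s | {a})
                if target in idx:
                    rate = d * sum(m[pos[b], pos[a]] for b in s)
                    Q[i, idx[target]] += rate
        # contractions
        for a in s:
            smaller = frozenset(s - {a})
            j = idx[smaller] if smaller else 0
            Q[i, j] += e
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


@dataclass(frozen=True)
class CladoEvent:
    left: frozenset[str]
    right: frozenset[str]
    kind: str  # sympatry | subset | vicariance | founder
    weight: float


def cladogenesis_table(
    states: Sequence[frozenset[str]],
    model: str = "DEC",
    j: float = 0.0,
    areas: AreaSet | Sequence[str] = DEFAULT_AREAS,
) -> dict[frozenset[str], list[CladoEvent]]:
    """Weighted daughter-pair table per parent range.

    Events are enumerated as ordered (left, right) pairs; asymmetric events
    appear in both orders with the weight split between them, so per-parent
    weights sum to exactly 1.
    """
    if model not in ("DEC", "DECJ"):
        raise ValueError("model must be 'DEC' or 'DECJ'")
    if model == "DEC" and j != 0.0:
        raise ValueError("j must be 0 under DEC")
    if not (0.0 <= j < 3.0):
        raise ValueError("j must lie in [0, 3)")
    codes = areas.codes if isinstance(areas, AreaSet) else tuple(areas)
    allowed = set(states)
    w_dec = (3.0 - j) / 3.0
    table: dict[frozenset[str], list[CladoEvent]] = {}
    for parent in states:
        events: list[CladoEvent] = []

        def add(left, right, kind, w):
            if w <= 0:
                return
            if left == right:
                events.append(CladoEvent(left, right, kind, w))
            else:
                events.append(CladoEvent(left, right, kind, w / 2.0))
                events.append(CladoEvent(right, left, kind, w / 2.0))

        if len(parent) == 1:
            add(parent, parent, "sympatry", w_dec)
        else:
            for a in parent:
                add(parent, frozenset({a}), "subset", w_dec)
            for k in range(1, len(parent)):
                for combo in itertools.combinations(sorted(parent), k):
                    left = frozenset(combo)
                    right = frozenset(parent - left)
                    # Lagrange convention: one daughter must be a singleton;
                    # count each unordered split once
                    if len(left) == 1 and (len(right) == 1 or len(left) <= len(right)):
                        if left in allowed and right in allowed:
                            if len(right) == 1 and sorted(left)[0] > sorted(right)[0]:
                                continue  # unordered singleton pair counted once
                            add(left, right, "vicariance", w_dec)
        if model == "DECJ" and j > 0:
            targets = [a for a in codes if a not in parent]
            if targets:
                wj = j / len(targets)
                for a in targets:
                    add(parent, frozenset({a}), "founder", wj)
        total = sum(ev.weight for ev in events)
        table[parent] = [
            CladoEvent(ev.left, ev.right, ev.kind, ev.weight / total) for ev in events
        ]
    return table


# ---------------------------------------------------------------------- #
# likelihood machinery
# ---------------------------------------------------------------------- #
class _EdgePropagator:
    """exp(Q t) for many t, via one eigendecomposition when well conditioned."""

    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self._cache: dict[float, np.ndarray] = {}
        self._eig = None
        try:
            vals, vecs = np.linalg.eig(Q)
            cond = np.linalg.cond(vecs)
            if np.isfinite(cond) and cond < 1e8:
                self._eig = (vals, vecs, np.linalg.inv(vecs))
        except np.linalg.LinAlgError:
            pass

    def __call__(self, t: float) -> np.ndarray:
        P = self._cache.get(t)
        if P is None:
            if self._eig is not None:
                vals, vecs, vinv = self._eig
                P = (vecs * np.exp(vals * t)) @ vinv
                P = np.real_if_close(P, tol=1e6).real
                np.clip(P, 0.0, None, out=P)
            else:
                P = _dense_expm(self.Q * t)
            self._cache[t] = P
        return P


def _tip_state_vectors(
    tree: Chronogram,
    tip_ranges: Mapping[str, frozenset[str] | set[str] | Sequence[str]],
    idx: dict[frozenset[str], int],
    S: int,
) -> dict[int, np.ndarray]:
    vecs = {}
    for label, node in zip(tree.tip_labels, tree.tip_ids):
        if label not in tip_ranges:
            raise ValueError(f"no observed range for tip {label!r}")
        r = frozenset(tip_ranges[label])
        if r not in idx:
            raise ValueError(
                f"tip {label!r} range {sorted(r)} is not in the state space "
                "(empty, unknown area, or exceeds max_range)"
            )
        v = np.zeros(S)
        v[idx[r]] = 1.0
        vecs[int(node)] = v
    return vecs


def _prepare(
    tree: Chronogram,
    tip_ranges,
    d: float,
    e: float,
    j: float,
    model: str,
    multipliers,
    areas,
    max_range: int,
):
    codes = areas.codes if isinstance(areas, AreaSet) else tuple(areas)
    states = build_state_space(codes, max_range=max_range)
    idx = _state_index(states)
    S = len(states) + 1
    Q = build_anagenetic_Q(states, d, e, multipliers, areas=codes)
    table = cladogenesis_table(states, model=model, j=j, areas=codes)
    # index the table once: per parent index, arrays of (left, right, weight)
    tbl_idx: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for parent, events in table.items():
        li = np.array([idx[ev.left] for ev in events], dtype=int)
        ri = np.array([idx[ev.right] for ev in events], dtype=int)
        wi = np.array([ev.weight for ev in events])
        tbl_idx[idx[parent]] = (li, ri, wi)
    tips = _tip_state_vectors(tree, tip_ranges, idx, S)
    return states, idx, S, Q, tbl_idx, tips


def _pruning_pass(tree, S, prop, tbl_idx, tips):
    """Conditional likelihoods L[node, state] of the data below each node."""
    L = np.zeros((tree.n_nodes, S))
    A = np.zeros((tree.n_nodes, S))  # corner likelihoods: expm(Q t) @ L[child]
    for i in tree.postorder():
        if tree.is_tip(i):
            L[i] = tips[i]
        else:
            kids = tree.children(i)
            for c in kids:
                A[c] = prop(float(tree.edge_lengths[c])) @ L[c]
            left, right = kids
            for s, (li, ri, wi) in tbl_idx.items():
                L[i, s] = np.sum(wi * A[left, li] * A[right, ri])
    return L, A


def dec_loglik(
    tree: Chronogram,
    tip_ranges: Mapping[str, Sequence[str]],
    d: float,
    e: float,
    j: float = 0.0,
    model: str = "DEC",
    multipliers: np.ndarray | None = None,
    areas: AreaSet | Sequence[str] = DEFAULT_AREAS,
    max_range: int = 2,
) -> float:
    """DEC / DEC+J log likelihood of observed tip ranges.

    Felsenstein pruning with matrix exponentials along edges, cladogenetic
    event weights at internal nodes and a flat root prior over non-null
    states.
    """
    states, idx, S, Q, tbl_idx, tips = _prepare(
        tree, tip_ranges, d, e, j, model, multipliers, areas, max_range
    )
    prop = _EdgePropagator(Q)
    L, _ = _pruning_pass(tree, S, prop, tbl_idx, tips)
    root = list(tree.postorder())[-1]
    prior = np.zeros(S)
    prior[1:] = 1.0 / len(states)
    like = float(prior @ L[root])
    if like <= 0:
        return -np.inf
    return float(np.log(like))


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float


def likelihood_ratio_test(lnL0: float, lnL1: float, df: int = 1) -> LRTResult:
    """LRT of nested fits: statistic 2(lnL1 - lnL0), upper-tail chi2(df) p."""
    if df < 1:
        raise ValueError("df must be >= 1")
    stat = 2.0 * (lnL1 - lnL0)
    if stat < 0:
        import warnings

        warnings.warn(
            "lnL1 < lnL0 for nominally nested models; statistic clamped at 0",
            stacklevel=2,
        )
        stat = 0.0
    return LRTResult(
        statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df=df))
    )


class DECModel(BaseEstimator):
    """ML ancestral range estimation under DEC or DEC+J.

    Parameters
    ----------
    model : {"DEC", "DECJ"}
    areas : sequence of area codes (default the six-area setup)
    max_range : maximum number of areas per range (default 2)
    multipliers : pairwise dispersal multipliers in [0, 1] (default all 1)
    n_starts : Nelder-Mead multistarts over log-parameterized (d, e[, j])
    seed : RNG seed for the multistart jitter

    Attributes (after ``fit``)
    --------------------------
    d_, e_, j_ : ML rates (j_ = 0.0 under DEC)
    loglik_ : maximized log likelihood
    node_marginals_, corner_marginals_ : per-node / per-corner state
        probability DataFrames (columns = range states as '+'-joined codes)
    converged_ : False when every optimizer start failed
    """

    _BOUNDS = (1e-12, 10.0)
    _JMAX = 2.99999

    def __init__(
        self,
        model: str = "DEC",
        areas: Sequence[str] = DEFAULT_AREAS,
        max_range: int = 2,
        multipliers: np.ndarray | None = None,
        n_starts: int = 5,
        seed: int | None = None,
    ):
        self.model = model
        self.areas = areas
        self.max_range = max_range
        self.multipliers = multipliers
        self.n_starts = n_starts
        self.seed = seed

    # parameter transforms: d, e on log scale; j through a scaled logistic
    def _unpack(self, theta: np.ndarray) -> tuple[float, float, float]:
        lo, hi = self._BOUNDS
        d = float(np.clip(np.exp(theta[0]), lo, hi))
        e = float(np.clip(np.exp(theta[1]), lo, hi))
        if self.model == "DECJ":
            jraw = float(theta[2])
            jv = self._JMAX / (1.0 + np.exp(-jraw))
        else:
            jv = 0.0
        return d, e, jv

    def fit(
        self, tree: Chronogram, tip_ranges: Mapping[str, Sequence[str]]
    ) -> "DECModel":
        if self.model not in ("DEC", "DECJ"):
            raise ValueError("model must be 'DEC' or 'DECJ'")
        if tree.n_tips < 3:
            raise ValueError("need at least three tips to fit DEC")
        from scipy.optimize import minimize

        def nll(theta):
            d, e, jv = self._unpack(theta)
            try:
                return -dec_loglik(
                    tree,
                    tip_ranges,
                    d,
                    e,
                    j=jv,
                    model=self.model,
                    multipliers=self.multipliers,
                    areas=self.areas,
                    max_range=self.max_range,
                )
            except (np.linalg.LinAlgError, FloatingPointError, OverflowError):
                return np.inf

        rng = np.random.default_rng(self.seed)
        base = [np.log(0.01), np.log(0.01)]
        if self.model == "DECJ":
            base.append(0.0)  # j around JMAX/2... logistic(0) = JMAX/2
        starts = [np.array(base)]
        for _ in range(max(0, self.n_starts - 1)):
            starts.append(np.array(base) + rng.normal(0.0, 2.0, size=len(base)))
        best = None
        for s in starts:
            res = minimize(
                nll, s, method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
        self.converged_ = bool(best is not None and np.isfinite(best.fun))
        if not self.converged_:
            raise RuntimeError("DEC optimization failed from every start")
        self.d_, self.e_, self.j_ = self._unpack(best.x)
        self.loglik_ = -float(best.fun)
        self.node_marginals_, self.corner_marginals_ = node_marginals(
            tree,
            tip_ranges,
            d=self.d_,
            e=self.e_,
            j=self.j_,
            model=self.model,
            multipliers=self.multipliers,
            areas=self.areas,
            max_range=self.max_range,
        )
        return self


def fit_dec(
    tree: Chronogram,
    tip_ranges: Mapping[str, Sequence[str]],
    model: str = "DEC",
    multipliers: np.ndarray | None = None,
    areas: Sequence[str] = DEFAULT_AREAS,
    max_range: int = 2,
    n_starts: int = 5,
    seed: int | None = None,
) -> DECModel:
    """Fit DEC or DEC+J by ML; see :class:`DECModel`."""
    return DECModel(
        model=model,
        areas=areas,
        max_range=max_range,
        multipliers=multipliers,
        n_starts=n_starts,
        seed=seed,
    ).fit(tree, tip_ranges)


def _state_name(s: frozenset[str]) -> str:
    return "+".join(sorted(s))


def node_marginals(
    tree: Chronogram,
    tip_ranges: Mapping[str, Sequence[str]],
    d: float,
    e: float,
    j: float = 0.0,
    model: str = "DEC",
    multipliers: np.ndarray | None = None,
    areas: AreaSet | Sequence[str] = DEFAULT_AREAS,
    max_range: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Marginal ancestral-range probabilities at nodes and corners.

    Down-pass conditional likelihoods are combined with up-pass messages; the
    null range is excluded from the report and rows sum to 1.  Corners are the
    daughter lineages immediately after cladogenesis, keyed by the child node
    id below the corner.
    """
    states, idx, S, Q, tbl_idx, tips = _prepare(
        tree, tip_ranges, d, e, j, model, multipliers, areas, max_range
    )
    prop = _EdgePropagator(Q)
    L, A = _pruning_pass(tree, S, prop, tbl_idx, tips)
    root = list(tree.postorder())[-1]
    prior = np.zeros(S)
    prior[1:] = 1.0 / len(states)

    U = np.zeros((tree.n_nodes, S))  # up message at each node (bottom of edge)
    M = np.zeros((tree.n_nodes, S))  # up message at each corner (top of edge)
    U[root] = prior
    node_rows: dict[int, np.ndarray] = {root: U[root] * L[root]}
    corner_rows: dict[int, np.ndarray] = {}
    for p in list(tree.postorder())[::-1]:
        if tree.is_tip(p):
            continue
        left, right = tree.children(p)
        for c, sib in ((left, right), (right, left)):
            m = np.zeros(S)
            for s, (li, ri, wi) in tbl_idx.items():
                if U[p, s] == 0:
                    continue
                contrib = U[p, s] * wi
                if c is left:
                    np.add.at(m, li, contrib * A[sib, ri])
                else:
                    np.add.at(m, ri, contrib * A[sib, li])
            M[c] = m
            corner_rows[c] = m * A[c]
            U[c] = prop(float(tree.edge_lengths[c])).T @ m
            node_rows[c] = U[c] * L[c]

    names = [_state_name(s) for s in states]

    def frame(rows: dict[int, np.ndarray]) -> pd.DataFrame:
        out = {}
        for i, v in rows.items():
            w = v[1:]
            tot = w.sum()
            out[i] = w / tot if tot > 0 else w
        df = pd.DataFrame.from_dict(out, orient="index", columns=names)
        df.index.name = "node_id"
        return df.sort_index()

    return frame(node_rows), frame(corner_rows)
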