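"""Forward simulators with known ground truth: Yule chronograms, BM/OU/EB
traits, correlated thresholded liabilities, DEC range histories and clustered
seed-measurement tables.

Every generator takes either an integer seed or a ``numpy.random.Generator``;
a single generator instance is threaded through all draws so entire synthetic
datasets are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .biogeography import (
    DEFAULT_AREAS,
    build_anagenetic_Q,
    build_state_space,
    cladogenesis_table,
)
from .fixture import (  # re-exported: the in-text reconstruction lives there
    DEFAULT_MULTIPLIERS,
    fixture_plukenetiinae,
    reconstruct_seed_measurements,
)
from .morphometrics import SIZE_CATEGORIES, SeedRecord
from .trait_models import _bm_structure, _eb_structure, _ou_structure
from .tree import Chronogram

__all__ = [
    "ROOT_CALIBRATION_MYA",
    "CROWN_CALIBRATION_MYA",
    "SeedClassSpec",
    "simulate_yule_tree",
    "simulate_continuous",
    "simulate_liability_pair",
    "simulate_dec_ranges",
    "generate_seed_dataset",
    "fixture_plukenetiinae",
    "reconstruct_seed_measurements",
    "default_seed_classes",
]

#: secondary calibration (mean, SD) in Mya for the root of the subtribe and
#: for the crown of the focal genus, as used by the dating analysis emulated
#: by the tree simulator
ROOT_CALIBRATION_MYA: tuple[float, float] = (36.43, 4.0)
CROWN_CALIBRATION_MYA: tuple[float, float] = (15.21, 4.0)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------- #
# trees
# ---------------------------------------------------------------------- #
def simulate_yule_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    seed=None,
    root_age: float | None = None,
    calibrated: bool = False,
) -> Chronogram:
    """Pure-birth (Yule) chronogram conditioned on ``n_tips`` extant tips.

    Starting from the root split (two lineages), waiting times between
    speciations are Exp(k * birth_rate) for k extant lineages and the
    splitting lineage is chosen uniformly; after the (n-1)-th split the tree
    is extended by a final Exp(n * birth_rate) waiting time so no tip edge has
    zero length.  With ``root_age`` set (or ``calibrated=True``, which draws
    the age from the root calibration normal, truncated positive) all branch
    lengths are rescaled so the root sits at that age.
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = _rng(seed)

    class _N:
        __slots__ = ("label", "children", "start", "length")

        def __init__(self, start):
            self.label = None
            self.children = []
            self.start = start
            self.length = 0.0

    root = _N(0.0)
    active = [_N(0.0), _N(0.0)]
    root.children = list(active)
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        node = active.pop(i)
        node.length = t - node.start
        node.children = [_N(t), _N(t)]
        active.extend(node.children)
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    for k, node in enumerate(active):
        node.length = t - node.start
        node.label = f"T{k + 1}"

    scale = 1.0
    if calibrated and root_age is None:
        mu, sd = ROOT_CALIBRATION_MYA
        draw = -1.0
        while draw <= 0:
            draw = rng.normal(mu, sd)
        root_age = float(draw)
    if root_age is not None:
        scale = root_age / t

    def render(node) -> str:
        if not node.children:
            return f"{node.label}:{node.length * scale:.12g}"
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}):{node.length * scale:.12g}"

    newick = f"({','.join(render(c) for c in root.children)}):0;"
    return Chronogram.from_newick(newick)


# ---------------------------------------------------------------------- #
# continuous traits
# ---------------------------------------------------------------------- #
def simulate_continuous(
    tree: Chronogram,
    model: str = "BM",
    params: Mapping[str, float] | None = None,
    seed=None,
) -> dict[str, float]:
    """Tip values drawn from the MVN implied by a BM/OU/EB model.

    ``params`` keys: sigma2 (required, >= 0), z0 (default 0), alpha (OU),
    eb_rate (EB, <= 0).
    """
    params = dict(params or {})
    sigma2 = float(params.get("sigma2", 1.0))
    z0 = float(params.get("z0", 0.0))
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    C = tree.covariance().matrix
    if model == "BM":
        V0 = _bm_structure(C)
    elif model == "OU":
        alpha = float(params.get("alpha", 1.0))
        if alpha < 0:
            raise ValueError("alpha must be non-negative")
        V0 = _ou_structure(C, alpha)
    elif model == "EB":
        r = float(params.get("eb_rate", 0.0))
        if r > 0:
            raise ValueError("eb_rate must be <= 0")
        V0 = _eb_structure(C, r)
    else:
        raise ValueError(f"unknown model {model!r}")
    rng = _rng(seed)
    if sigma2 == 0:
        x = np.full(tree.n_tips, z0)
    else:
        L = np.linalg.cholesky(sigma2 * V0 + 1e-12 * np.eye(len(C)))
        x = z0 + L @ rng.standard_normal(tree.n_tips)
    return dict(zip(tree.tip_labels, map(float, x)))


def simulate_liability_pair(
    tree: Chronogram,
    r: float,
    seed=None,
    sigma_x2: float = 1.0,
    means: tuple[float, float] = (0.0, 0.0),
    return_liability: bool = False,
):
    """Bivariate BM with correlation ``r``; the second trait thresholded at 0.

    The liability BM rate is fixed at 1 (the identifiable scale of the
    threshold model); returns (continuous trait, binary trait).
    """
    if not (-1.0 <= r <= 1.0):
        raise ValueError("r must lie in [-1, 1]")
    rng = _rng(seed)
    C = tree.covariance().matrix
    n = len(C)
    Lc = np.linalg.cholesky(C + 1e-12 * np.eye(n))
    sx = math.sqrt(sigma_x2)
    Sigma = np.array([[sigma_x2, r * sx], [r * sx, 1.0]])
    Ls = np.linalg.cholesky(Sigma + 1e-15 * np.eye(2))
    Z = rng.standard_normal((n, 2))
    XY = Lc @ Z @ Ls.T
    x = means[0] + XY[:, 0]
    liab = means[1] + XY[:, 1]
    cont = dict(zip(tree.tip_labels, map(float, x)))
    binary = {t: int(v > 0) for t, v in zip(tree.tip_labels, liab)}
    if return_liability:
        return cont, binary, dict(zip(tree.tip_labels, map(float, liab)))
    return cont, binary


# ---------------------------------------------------------------------- #
# geographic ranges
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class DECSimulation:
    tip_ranges: dict[str, frozenset[str]]
    node_states: dict[int, frozenset[str]]  # true range at every node
    n_restarts: int  # resimulations forced by a lineage dying to null range


def simulate_dec_ranges(
    tree: Chronogram,
    d: float,
    e: float,
    j: float = 0.0,
    multipliers: np.ndarray | None = None,
    seed=None,
    areas: Sequence[str] = DEFAULT_AREAS,
    max_range: int = 2,
    root_state: frozenset[str] | None = None,
    max_restarts: int = 1000,
) -> DECSimulation:
    """Forward-simulate a DEC/DEC+J history on the tree (Gillespie along
    edges, cladogenetic draws at nodes); the true node states are retained
    for recovery scoring.  A simulation in which any lineage contracts to the
    null range before reaching a tip is restarted (count reported).
    """
    rng = _rng(seed)
    codes = tuple(areas)
    states = build_state_space(codes, max_range=max_range)
    Q = build_anagenetic_Q(states, d, e, multipliers, areas=codes)
    model = "DECJ" if j > 0 else "DEC"
    table = cladogenesis_table(states, model=model, j=j, areas=codes)
    idx = {s: i + 1 for i, s in enumerate(states)}
    by_index: dict[int, frozenset[str]] = {i: s for s, i in idx.items()}

    def evolve(state_i: int, t: float) -> int | None:
        while True:
            if state_i == 0:
                return None
            rate = -Q[state_i, state_i]
            if rate <= 0:
                return state_i
            wait = rng.exponential(1.0 / rate)
            if wait >= t:
                return state_i
            t -= wait
            probs = Q[state_i].copy()
            probs[state_i] = 0.0
            probs = np.clip(probs, 0.0, None)
            probs /= probs.sum()
            state_i = int(rng.choice(len(probs), p=probs))

    order = list(tree.postorder())[::-1]  # preorder
    root = order[0]
    for attempt in range(max_restarts + 1):
        node_state: dict[int, int] = {}
        if root_state is None:
            node_state[root] = idx[states[int(rng.integers(len(states)))]]
        else:
            node_state[root] = idx[frozenset(root_state)]
        ok = True
        corner: dict[int, int] = {}
        for p in order:
            if tree.is_tip(p):
                continue
            s = by_index[node_state[p]]
            events = table[s]
            w = np.array([ev.weight for ev in events])
            ev = events[int(rng.choice(len(events), p=w / w.sum()))]
            for c, child_range in zip(tree.children(p), (ev.left, ev.right)):
                corner[c] = idx[child_range]
                got = evolve(corner[c], float(tree.edge_lengths[c]))
                if got is None:
                    ok = False
                    break
                node_state[c] = got
            if not ok:
                break
        if ok:
            tip_ranges = {
                lbl: by_index[node_state[int(t)]]
                for lbl, t in zip(tree.tip_labels, tree.tip_ids)
            }
            return DECSimulation(
                tip_ranges=tip_ranges,
                node_states={i: by_index[s] for i, s in node_state.items()},
                n_restarts=attempt,
            )
    raise RuntimeError(
        f"range simulation failed {max_restarts} times (extinction rate too "
        "high for this tree)"
    )


# ---------------------------------------------------------------------- #
# seed measurement tables
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class SeedClassSpec:
    """One size class: mean log10 dimension, spreads and a record count.

    ``sd_size`` is the SD of a shared log10 size factor (isometric seed-to-
    seed variation), ``sd_shape`` the per-dimension residual SD.  The defaults
    give a log10-volume SD of ~0.030, which keeps >99% of each class's volumes
    inside its (narrowest) published category interval.
    """

    label: str
    mean_log10_dim: float
    sd_size: float = 0.008
    sd_shape: float = 0.010
    n: int = 40


def default_seed_classes(n_per_class: int = 40) -> list[SeedClassSpec]:
    """Five classes centred on the geometric midpoints of the published
    volume categories (25–100, 100–500, 500–3000, 3000–13000, 26000–38000
    mm^3), converted to equivalent-sphere log10 diameters."""
    specs = []
    for label, lo, hi in SIZE_CATEGORIES:
        center_vol = math.sqrt(lo * hi)
        mean_dim = math.log10((6.0 * center_vol / math.pi) ** (1.0 / 3.0))
        specs.append(
            SeedClassSpec(label=label, mean_log10_dim=mean_dim, n=n_per_class)
        )
    return specs


def generate_seed_dataset(
    class_spec: Sequence[SeedClassSpec] | None = None, seed=None
) -> tuple[list[SeedRecord], list[str]]:
    """Seed records drawn from log-space classes; returns (records, labels).

    Each record's three dimensions share a size factor N(mean, sd_size) plus
    independent shape noise N(0, sd_shape), all in log10 mm.
    """
    specs = list(class_spec) if class_spec is not None else default_seed_classes()
    if not specs:
        raise ValueError("need at least one seed class")
    rng = _rng(seed)
    records: list[SeedRecord] = []
    labels: list[str] = []
    for spec in specs:
        for k in range(spec.n):
            size = rng.normal(spec.mean_log10_dim, spec.sd_size)
            dims = 10 ** (size + rng.normal(0.0, spec.sd_shape, size=3))
            records.append(
                SeedRecord(
                    taxon=f"class_{spec.label}",
                    voucher=f"{spec.label}-{k + 1}",
                    length=float(dims[0]),
                    width=float(dims[1]),
                    thickness=float(dims[2]),
                )
            )
            labels.append(spec.label)
    return records, labels
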