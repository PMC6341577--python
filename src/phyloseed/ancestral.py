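"""Ancestral state estimation for continuous traits under Brownian motion,
with along-branch interpolation and traitgram coordinates.

Internal-node states are estimated by exact Gaussian message passing (belief
propagation) on the tree: a postorder pass combines tip observations into
downward messages, a preorder pass sends the complementary upward messages,
and the marginal at each internal node is the precision-weighted combination
of the messages from all its neighbours.  With a flat prior on the root state
this reproduces the maximum-likelihood / conditional-expectation estimates of
the joint multivariate normal model, in linear time.

Estimated means do not depend on the BM rate; reported variances are scaled by
the ML rate estimate from :mod:`phyloseed.trait_models`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .tree import Chronogram
from .trait_models import _gls_profile, align_trait

__all__ = [
    "AncestralEstimate",
    "estimate_ancestral_states",
    "interpolate_edges",
    "traitgram_coordinates",
]

_INF = np.inf


@dataclass(frozen=True)
class AncestralEstimate:
    """Mean and variance of the BM state at every node (tips included).

    ``mean[node_id]`` / ``variance[node_id]`` are indexed by the chronogram's
    node ids; tip entries hold the observed values with zero variance.
    """

    mean: np.ndarray
    variance: np.ndarray
    sigma2: float
    method: str = "BM Gaussian message passing (flat root prior)"

    def at(self, node_id: int) -> tuple[float, float]:
        return float(self.mean[node_id]), float(self.variance[node_id])

    def to_dataframe(self, tree: Chronogram):
        import pandas as pd

        rows = [
            {
                "node_id": i,
                "age_mya": tree.node_age(i),
                "is_tip": tree.is_tip(i),
                "label": tree.node_label(i),
                "mean": float(self.mean[i]),
                "variance": float(self.variance[i]),
            }
            for i in tree.postorder()
        ]
        return pd.DataFrame(rows).set_index("node_id")


def _combine(messages) -> tuple[float, float]:
    """Precision-weighted combination of Gaussian messages (mu, v).

    A zero-variance message pins the state; conflicting zero-variance messages
    cannot arise on a valid chronogram (duplicate zero-distance tips are
    rejected upstream by the singular-covariance check).
    """
    for mu, v in messages:
        if v == 0.0:
            return mu, 0.0
    w = [1.0 / v for _, v in messages if np.isfinite(v)]
    m = [mu / v for mu, v in messages if np.isfinite(v)]
    prec = sum(w)
    return sum(m) / prec, 1.0 / prec


def estimate_ancestral_states(
    tree: Chronogram, trait: Mapping[str, float], sigma2: float | None = None
) -> AncestralEstimate:
    """BM ancestral means and variances at every node.

    The mean at each internal node is the conditional expectation of its state
    given the tip data (the root mean equals the GLS grand mean).  If
    ``sigma2`` is omitted the BM ML estimate is profiled from the data.
    """
    x = align_trait(tree, trait)
    if sigma2 is None:
        sigma2 = _gls_profile(tree.covariance().matrix, x)[1]
    tip_value = dict(zip(tree.tip_ids.tolist(), x))

    n = tree.n_nodes
    # downward messages: (mu, v) of the subtree below each node, measured at
    # the node itself (unit BM rate)
    down_mu = np.zeros(n)
    down_v = np.zeros(n)
    for i in tree.postorder():
        if tree.is_tip(i):
            down_mu[i], down_v[i] = tip_value[i], 0.0
        else:
            msgs = [
                (down_mu[c], down_v[c] + tree.edge_lengths[c])
                for c in tree.children(i)
            ]
            down_mu[i], down_v[i] = _combine(msgs)

    # upward messages: information from everything above/beside, measured at
    # each node; flat prior at the root
    up_mu = np.zeros(n)
    up_v = np.full(n, _INF)
    order = list(tree.postorder())[::-1]  # preorder
    for p in order:
        if tree.is_tip(p):
            continue
        kids = tree.children(p)
        for c in kids:
            msgs = [(up_mu[p], up_v[p])]
            for s in kids:
                if s is not c:
                    msgs.append((down_mu[s], down_v[s] + tree.edge_lengths[s]))
            mu, v = _combine(msgs)
            up_mu[c], up_v[c] = mu, v + tree.edge_lengths[c]

    mean = np.zeros(n)
    var = np.zeros(n)
    for i in tree.postorder():
        if tree.is_tip(i):
            mean[i], var[i] = tip_value[i], 0.0
        else:
            msgs = [
                (down_mu[c], down_v[c] + tree.edge_lengths[c])
                for c in tree.children(i)
            ]
            msgs.append((up_mu[i], up_v[i]))
            mu, v = _combine(msgs)
            mean[i], var[i] = mu, sigma2 * v
    return AncestralEstimate(mean=mean, variance=var, sigma2=float(sigma2))


@dataclass(frozen=True)
class EdgeProfile:
    """Ordered (age, state) samples along one edge, parent to child."""

    edge_id: int  # node id of the child below the edge
    ages: np.ndarray
    states: np.ndarray


def interpolate_edges(
    tree: Chronogram,
    trait: Mapping[str, float],
    estimates: AncestralEstimate | None = None,
    step: float | None = None,
) -> list[EdgeProfile]:
    """States along every edge at spacing ``step`` (Mya).

    The interpolated mean at fractional position t of an edge is the BM bridge
    expectation between the parent and child estimates, which is linear in t;
    endpoints equal the node estimates exactly (tips: the observed values).
    Default step is root_age / 500 (smooth-plot granularity).
    """
    if estimates is None:
        estimates = estimate_ancestral_states(tree, trait)
    if step is None:
        step = tree.root_age / 500.0
    if not (step > 0):
        raise ValueError("step must be positive")
    profiles = []
    for c in tree.postorder():
        p = tree.parent(c)
        if p == -1:
            continue
        a_p, a_c = tree.node_age(p), tree.node_age(c)
        length = a_p - a_c
        if length <= step:
            ages = np.array([a_p, a_c])
        else:
            interior = np.arange(a_p - step, a_c, -step)
            ages = np.concatenate(([a_p], interior, [a_c]))
        frac = np.where(length > 0, (a_p - ages) / max(length, 1e-300), 0.0)
        states = estimates.mean[p] + frac * (estimates.mean[c] - estimates.mean[p])
        profiles.append(EdgeProfile(edge_id=c, ages=ages, states=states))
    return profiles


def traitgram_coordinates(
    tree: Chronogram,
    trait: Mapping[str, float],
    estimates: AncestralEstimate | None = None,
) -> dict[str, np.ndarray]:
    """Phenogram polylines: one (age, state) path per root-to-tip lineage.

    Each polyline starts at (root_age, root state) and ends at (0, observed
    tip value); the age axis decreases monotonically along the path.
    """
    if estimates is None:
        estimates = estimate_ancestral_states(tree, trait)
    paths: dict[str, np.ndarray] = {}
    for label, t in zip(tree.tip_labels, tree.tip_ids):
        chain = [int(t)]
        while tree.parent(chain[-1]) != -1:
            chain.append(tree.parent(chain[-1]))
        chain = chain[::-1]
        ages = np.array([tree.node_age(i) for i in chain])
        states = np.array([estimates.mean[i] for i in chain])
        paths[label] = np.column_stack([ages, states])
    return paths
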