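"""Seed morphometrics: ellipsoid volumes, size categories, clustering and PCA.

Seed size is quantified from three calliper measurements per seed — length,
width and thickness in mm — converted to an estimated volume with the ellipsoid
formula v = 4/3 pi a b c, where a, b, c are the SEMI-axes (half the measured
dimensions), i.e. v = (pi/6) L W T.  Five empirical size categories (S, M, L,
XL, Max) are defined on volume intervals discovered by UPGMA clustering of
log10-transformed dimensions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "SeedRecord",
    "VolumeEstimate",
    "SIZE_CATEGORIES",
    "estimate_volume",
    "assign_size_category",
    "summarize_species",
    "cluster_seed_sizes",
    "pca_seed_dimensions",
    "species_trait_vector",
    "SeedSizeClusterer",
    "records_from_dataframe",
    "records_to_dataframe",
]

_MIN_DIM, _MAX_DIM = 0.1, 100.0  # mm sanity bounds


@dataclass(frozen=True)
class SeedRecord:
    """One measured seed: taxon, voucher and three dimensions in mm."""

    taxon: str
    voucher: str
    length: float
    width: float
    thickness: float

    def __post_init__(self) -> None:
        for name in ("length", "width", "thickness"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be positive, got {v!r}")
        if not (_MIN_DIM <= self.length <= _MAX_DIM):
            raise ValueError(f"length {self.length} mm outside sanity bounds")

    @property
    def dimensions(self) -> tuple[float, float, float]:
        return (self.length, self.width, self.thickness)


@dataclass(frozen=True)
class VolumeEstimate:
    """Ellipsoid volume of a seed, in mm^3, with its log10."""

    volume: float

    @property
    def log10_volume(self) -> float:
        return math.log10(self.volume)

    @property
    def rounded(self) -> int:
        """Volume rounded half-up to integer mm^3, as printed in summaries."""
        return _round_half_up(self.volume)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


#: canonical size-category bounds in mm^3 (half-open [lower, upper), except the
#: last which is closed).  The 13000–26000 gap and the region outside
#: [25, 38000] contain no observed seeds; volumes falling there are assigned to
#: the nearest interval and flagged "extrapolated".
SIZE_CATEGORIES: tuple[tuple[str, float, float], ...] = (
    ("S", 25.0, 100.0),
    ("M", 100.0, 500.0),
    ("L", 500.0, 3000.0),
    ("XL", 3000.0, 13000.0),
    ("Max", 26000.0, 38000.0),
)


def estimate_volume(length: float, width: float, thickness: float) -> VolumeEstimate:
    """Ellipsoid volume (pi/6 * L * W * T) of a seed, dimensions in mm.

    Uses semi-axes equal to half the measured dimensions; this convention
    reproduces the published integer volumes (e.g. 27 x 25 x 20 mm -> 7069).
    """
    for name, v in (("length", length), ("width", width), ("thickness", thickness)):
        if not (v > 0):
            raise ValueError(f"{name} must be positive, got {v!r}")
    return VolumeEstimate(volume=math.pi / 6.0 * length * width * thickness)


def assign_size_category(volume: float) -> tuple[str, bool]:
    """Map a volume (mm^3) to a size-category label.

    Returns ``(label, extrapolated)``; ``extrapolated`` is True when the volume
    lies in a gap between or outside the canonical intervals and was assigned
    to the nearest one.  Interval membership is half-open, so a boundary value
    such as 100 belongs to the upper category (M).
    """
    if not (volume > 0):
        raise ValueError(f"volume must be positive, got {volume!r}")
    last = len(SIZE_CATEGORIES) - 1
    for k, (label, lo, hi) in enumerate(SIZE_CATEGORIES):
        if (lo <= volume < hi) or (k == last and lo <= volume <= hi):
            return label, False
    # nearest interval by distance to [lo, hi]
    def dist(bounds):
        _, lo, hi = bounds
        return max(lo - volume, volume - hi, 0.0)

    label = min(SIZE_CATEGORIES, key=dist)[0]
    return label, True


def summarize_species(records: Sequence[SeedRecord]) -> pd.DataFrame:
    """Per-species summary: n, min–max and mean of each dimension and volume.

    The mean volume is the arithmetic mean of the per-seed volumes (not the
    volume of the mean dimensions), and the size category is assigned from the
    mean volume.  Mirrors the published per-species summary table.
    """
    if not records:
        raise ValueError("no seed records supplied")
    rows = []
    df = records_to_dataframe(records)
    df["volume"] = [
        estimate_volume(r.length, r.width, r.thickness).volume for r in records
    ]
    for taxon, g in df.groupby("taxon", sort=True):
        mean_vol = g["volume"].mean()
        label, extrapolated = assign_size_category(mean_vol)
        rows.append(
            {
                "taxon": taxon,
                "n_seeds": len(g),
                "length_min": g["length_mm"].min(),
                "length_max": g["length_mm"].max(),
                "length_mean": g["length_mm"].mean(),
                "width_min": g["width_mm"].min(),
                "width_max": g["width_mm"].max(),
                "width_mean": g["width_mm"].mean(),
                "thickness_min": g["thickness_mm"].min(),
                "thickness_max": g["thickness_mm"].max(),
                "thickness_mean": g["thickness_mm"].mean(),
                "volume_min": _round_half_up(g["volume"].min()),
                "volume_max": _round_half_up(g["volume"].max()),
                "volume_mean": _round_half_up(mean_vol),
                "category": label,
                "extrapolated": extrapolated,
            }
        )
    return pd.DataFrame(rows).set_index("taxon")


def _log_dimension_matrix(records: Sequence[SeedRecord]) -> np.ndarray:
    X = np.array([r.dimensions for r in records], dtype=float)
    if np.any(X <= 0):
        raise ValueError("all dimensions must be positive")
    return np.log10(X)


class SeedSizeClusterer(ClusterMixin, BaseEstimator):
    """UPGMA clustering of seeds in log10 dimension space.

    Seeds are represented by (log10 L, log10 W, log10 T); UPGMA (average
    linkage) on Euclidean distances is cut at ``cut_height`` (default 0.35,
    the height at which the published analysis separates five size groups).

    Attributes
    ----------
    labels_ : ndarray of int
        Cluster id per record (0-based, relabelled by lowest member index).
    linkage_ : ndarray
        scipy linkage matrix (merge heights non-decreasing).
    n_clusters_ : int
    """

    def __init__(self, cut_height: float = 0.35):
        self.cut_height = cut_height

    def fit(self, records: Sequence[SeedRecord], y=None) -> "SeedSizeClusterer":
        if len(records) < 2:
            raise ValueError("need at least two records to cluster")
        X = _log_dimension_matrix(records)
        self.linkage_ = linkage(pdist(X, metric="euclidean"), method="average")
        raw = fcluster(self.linkage_, t=self.cut_height, criterion="distance")
        # stable relabelling: cluster containing the lowest record index first
        order: dict[int, int] = {}
        for lab in raw:
            if lab not in order:
                order[lab] = len(order)
        self.labels_ = np.array([order[lab] for lab in raw], dtype=int)
        self.n_clusters_ = len(order)
        return self


@dataclass(frozen=True)
class ClusterResult:
    assignments: np.ndarray
    linkage: np.ndarray
    cut_height: float

    @property
    def n_clusters(self) -> int:
        return int(self.assignments.max()) + 1


def cluster_seed_sizes(
    records: Sequence[SeedRecord], cut_height: float = 0.35
) -> ClusterResult:
    """UPGMA size-class discovery (see :class:`SeedSizeClusterer`)."""
    est = SeedSizeClusterer(cut_height=cut_height).fit(records)
    return ClusterResult(
        assignments=est.labels_, linkage=est.linkage_, cut_height=cut_height
    )


def pca_seed_dimensions(records: Sequence[SeedRecord]):
    """PCA of log10 seed dimensions (covariance matrix, unstandardized).

    Returns ``(variance_fractions, scores)``: the fraction of variance per
    component (sums to 1) and the centered component scores.
    """
    if len(records) < 3:
        raise ValueError("need at least three records for PCA")
    X = _log_dimension_matrix(records)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (len(records) - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    fractions = evals / total if total > 0 else np.full_like(evals, 1.0 / len(evals))
    scores = Xc @ evecs
    return fractions, scores


def species_trait_vector(records: Sequence[SeedRecord]) -> dict[str, float]:
    """Per-species mean of per-seed log10 volumes (mean of logs, not log of mean)."""
    if not records:
        raise ValueError("no seed records supplied")
    acc: dict[str, list[float]] = {}
    for r in records:
        v = estimate_volume(r.length, r.width, r.thickness)
        acc.setdefault(r.taxon, []).append(v.log10_volume)
    return {sp: float(np.mean(vals)) for sp, vals in sorted(acc.items())}


# ---------------------------------------------------------------------- #
# CSV surface
# ---------------------------------------------------------------------- #
_COLUMNS = ["taxon", "voucher", "length_mm", "width_mm", "thickness_mm"]


def records_to_dataframe(records: Iterable[SeedRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "voucher": r.voucher,
                "length_mm": r.length,
                "width_mm": r.width,
                "thickness_mm": r.thickness,
            }
            for r in records
        ],
        columns=_COLUMNS,
    )


def records_from_dataframe(df: pd.DataFrame) -> list[SeedRecord]:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    return [
        SeedRecord(
            taxon=str(row.taxon),
            voucher=str(row.voucher),
            length=float(row.length_mm),
            width=float(row.width_mm),
            thickness=float(row.thickness_mm),
        )
        for row in df.itertuples()
    ]
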