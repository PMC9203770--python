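"""Comparing spatial population/traffic distributions.

Distributions produced by the model (per node or per cell) are compared
with reference data after aggregation onto a common region partition —
administrative units, label rasters, or polygon sets.  The headline metric
is the Kullback-Leibler distance from the simulated distribution q to the
reference p,

    D_KL(p||q) = sum_i p(i) * log(p(i) / q(i))    [natural log, nats]

on the normalised per-region vectors, supplemented by Pearson correlation
and cosine similarity on the raw vectors, and by rank-size (Zipf) tables of
block population densities.  Where q(i) = 0 on the support of p the KL
distance is +inf and is reported as such; an explicit epsilon-floor flag
exists for exploratory use but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RegionPartition",
    "ComparisonResult",
    "aggregate",
    "kl_distance",
    "similarity_metrics",
    "rank_size",
    "ensemble_statistics",
]

UNASSIGNED = -1


@dataclass
class RegionPartition:
    """Per-cell (or per-node) integer region labels; UNASSIGNED = -1."""

    labels: np.ndarray
    region_ids: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.region_ids = np.asarray(self.region_ids, dtype=int)

    @classmethod
    def from_label_array(cls, labels: np.ndarray) -> "RegionPartition":
        labels = np.asarray(labels, dtype=int)
        ids = np.unique(labels)
        return cls(labels, ids[ids != UNASSIGNED])

    @classmethod
    def from_geojson(
        cls,
        geojson: dict,
        points_xy: np.ndarray,
        id_property: str | None = None,
    ) -> "RegionPartition":
        """Label points by the polygon containing them (point-in-polygon on
        cell/node centres); ties across overlapping polygons go to the lowest
        region id; uncovered points stay unassigned."""
        from shapely.geometry import Point, shape

        feats = geojson["features"]
        polys = []
        for k, feat in enumerate(feats):
            rid = feat["properties"][id_property] if id_property else k
            polys.append((int(rid), shape(feat["geometry"])))
        polys.sort(key=lambda t: t[0])
        pts = np.asarray(points_xy, dtype=float)
        labels = np.full(pts.shape[0], UNASSIGNED)
        for n, (px, py) in enumerate(pts):
            p = Point(px, py)
            for rid, poly in polys:
                if poly.covers(p):
                    labels[n] = rid
                    break
        ids = np.unique(labels)
        return cls(labels, ids[ids != UNASSIGNED])


@dataclass
class ComparisonResult:
    """KL distance (nats), Pearson correlation and cosine similarity."""

    kl_nats: float
    pearson: float | None
    cosine: float

    def as_dict(self) -> dict:
        return {"kl_nats": self.kl_nats, "pearson": self.pearson, "cosine": self.cosine}


def aggregate(field: np.ndarray, partition: RegionPartition) -> np.ndarray:
    """Sum a per-cell/per-node field over regions (region_ids order).

    Raises if any populated entry is unassigned, listing the offenders —
    silent mass loss would bias every downstream comparison.
    """
    field = np.asarray(field, dtype=float).ravel()
    labels = partition.labels.ravel()
    if field.shape != labels.shape:
        raise ValueError("field and partition shapes differ")
    bad = np.nonzero((labels == UNASSIGNED) & (field != 0))[0]
    if bad.size:
        raise ValueError(f"populated entries without a region label: {bad[:20].tolist()}")
    return np.array([field[labels == rid].sum() for rid in partition.region_ids])


def kl_distance(p_raw: np.ndarray, q_raw: np.ndarray, epsilon_floor: float = 0.0) -> float:
    """D_KL(p||q) in nats between raw non-negative totals (normalised inside).

    Direction: q is the simulated distribution, p the reference.  Where
    q(i)=0 but p(i)>0 the result is +inf unless a positive ``epsilon_floor``
    (added to every q entry before normalising) is requested explicitly.
    """
    p = np.asarray(p_raw, dtype=float)
    q = np.asarray(q_raw, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have equal length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("raw totals must be non-negative")
    if p.sum() <= 0 or (q.sum() + epsilon_floor * q.size) <= 0:
        raise ValueError("distributions must have positive total")
    if epsilon_floor > 0:
        q = q + epsilon_floor
    p = p / p.sum()
    q = q / q.sum()
    support = p > 0
    if np.any(q[support] == 0):
        return float("inf")
    return float(np.sum(p[support] * np.log(p[support] / q[support])))


def similarity_metrics(p_raw: np.ndarray, q_raw: np.ndarray) -> ComparisonResult:
    """KL, Pearson and cosine between two raw non-negative vectors.

    Pearson is None (undefined) when either vector has zero variance.
    """
    p = np.asarray(p_raw, dtype=float)
    q = np.asarray(q_raw, dtype=float)
    if p.shape != q.shape or p.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    kl = kl_distance(p, q)
    if p.std() == 0 or q.std() == 0:
        pearson: float | None = None
    else:
        pearson = float(np.corrcoef(p, q)[0, 1])
    np_norm, nq_norm = np.linalg.norm(p), np.linalg.norm(q)
    cosine = float(p @ q / (np_norm * nq_norm)) if np_norm > 0 and nq_norm > 0 else 0.0
    return ComparisonResult(kl_nats=kl, pearson=pearson, cosine=cosine)


def rank_size(
    field: np.ndarray,
    cell_area_km2: float,
    grid_km: float,
    cell_size_km: float,
) -> pd.DataFrame:
    """Rank-size table of population densities on grid_km x grid_km blocks.

    Re-aggregates a per-cell population field onto coarse blocks, computes
    density (population per km^2), sorts descending and attaches ranks and
    the empirical CCDF P(density >= value).  The fat-tailed (Zipf-like)
    character of a distribution shows as an approximately straight rank-size
    line in log-log coordinates.
    """
    field = np.asarray(field, dtype=float)
    if field.ndim != 2 or field.size == 0:
        raise ValueError("field must be a non-empty 2-D population raster")
    if grid_km < cell_size_km:
        raise ValueError("block size must be at least the cell size")
    bs = max(1, int(round(grid_km / cell_size_km)))
    nr = int(np.ceil(field.shape[0] / bs))
    ncb = int(np.ceil(field.shape[1] / bs))
    dens = np.zeros(nr * ncb)
    area = np.zeros(nr * ncb)
    k = 0
    for br in range(0, field.shape[0], bs):
        for bc in range(0, field.shape[1], bs):
            block = field[br : br + bs, bc : bc + bs]
            area[k] = block.size * cell_area_km2
            dens[k] = block.sum() / area[k]
            k += 1
    order = np.argsort(-dens, kind="stable")
    dens_sorted = dens[order]
    n = dens_sorted.size
    return pd.DataFrame(
        {
            "rank": np.arange(1, n + 1),
            "density_per_km2": dens_sorted,
            "population": dens_sorted * area[order],
            "ccdf": np.arange(1, n + 1) / n,
        }
    )


def ensemble_statistics(runs: list[np.ndarray]) -> pd.DataFrame:
    """Per-region mean and sample standard deviation (n-1) over an ensemble."""
    if len(runs) < 2:
        raise ValueError("need at least two runs")
    arr = np.asarray(runs, dtype=float)
    if arr.ndim != 2:
        raise ValueError("runs must be equal-length per-region vectors")
    return pd.DataFrame(
        {
            "region": np.arange(arr.shape[1]),
            "mean": arr.mean(axis=0),
            "sd": arr.std(axis=0, ddof=1),
        }
    )
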