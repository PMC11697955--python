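"""Cluster-based permutation testing of group time-frequency maps.

The multiple-comparisons problem over a time-frequency grid is handled
nonparametrically: a Welch t-test is run at every grid point, points with
two-sided p below the cluster-forming threshold (0.025) are kept, and
connected clusters of such points are measured by their area (grid-point
count), separately for positive and negative t.  Group labels are then
shuffled (2000 times by default) and the same procedure applied to each
surrogate; observed clusters larger than 95% of the surrogate cluster
sizes are declared significant.

The null distribution records the **maximum** surrogate cluster area per
permutation by default (the standard max-statistic construction, which
controls family-wise error); a pooled-null variant that collects every
surrogate cluster area is available behind ``null_statistic="pool"``.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterConfig",
    "Cluster",
    "ClusterResult",
    "pointwise_tmap",
    "find_clusters",
    "permutation_test",
]

_STRUCTURES = {
    "4-neighbour": np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool),
    "8-neighbour": np.ones((3, 3), bool),
}


@dataclass(frozen=True)
class ClusterConfig:
    """Settings for the cluster permutation test."""

    point_alpha: float = 0.025
    n_permutations: int = 2000
    cluster_percentile: float = 95.0
    connectivity: str = "4-neighbour"
    null_statistic: str = "max"  # "max" (FWER max-statistic) or "pool"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.point_alpha < 1:
            raise ValueError("point_alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.connectivity not in _STRUCTURES:
            raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
        if self.null_statistic not in ("max", "pool"):
            raise ValueError("null_statistic must be 'max' or 'pool'")


@dataclass
class Cluster:
    """A connected supra-threshold region of the t-map."""

    mask: np.ndarray  # boolean over the map grid
    area: int
    sign: int  # +1 elevated in group A, -1 reduced
    freq_extent: tuple[int, int]  # inclusive row index range
    time_extent: tuple[int, int]  # inclusive column index range
    null_percentile: float | None = None
    significant: bool = False


@dataclass
class ClusterResult:
    t_map: np.ndarray
    p_map: np.ndarray
    sign_mask: np.ndarray  # int8: +1/-1 where supra-threshold, 0 elsewhere
    clusters: list[Cluster]
    null_areas: np.ndarray
    cfg: ClusterConfig
    method: str = "montecarlo"

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.significant]


def _as_stack(group) -> np.ndarray:
    """Coerce a list of STPMap / arrays into (n_subjects, ...) float array."""
    if isinstance(group, np.ndarray):
        return np.asarray(group, float)
    arrs = []
    for g in group:
        arrs.append(np.asarray(getattr(g, "power", g), float))
    return np.stack(arrs)


def _welch(meanA, varA, nA, meanB, varB, nB):
    """Welch t statistic and Satterthwaite df from group summary stats."""
    sa = varA / nA
    sb = varB / nB
    denom = np.sqrt(sa + sb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (meanA - meanB) / denom
        df = (sa + sb) ** 2 / (sa**2 / (nA - 1) + sb**2 / (nB - 1))
    t = np.where(denom == 0, 0.0, t)
    df = np.where(np.isfinite(df), df, 1.0)
    return t, df


def pointwise_tmap(groupA, groupB):
    """Two-sample Welch t and two-sided p at every map point.

    Groups are lists of per-animal STP maps (or stacked arrays); grids
    must match.  Returns ``(t_map, p_map)``.
    """
    A = _as_stack(groupA)
    B = _as_stack(groupB)
    if A.shape[1:] != B.shape[1:]:
        raise ValueError("group map grids do not match")
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least two animals per group")
    t, df = _welch(
        A.mean(0), A.var(0, ddof=1), A.shape[0], B.mean(0), B.var(0, ddof=1), B.shape[0]
    )
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def find_clusters(
    p_map: np.ndarray,
    t_map: np.ndarray,
    cfg: ClusterConfig = ClusterConfig(),
    valid_mask: np.ndarray | None = None,
) -> list[Cluster]:
    """Connected components of supra-threshold points, split by t sign.

    ``valid_mask`` (optional) excludes points — e.g. wavelet edge regions —
    from cluster membership.  Returned clusters are sorted by descending
    area.
    """
    if p_map.shape != t_map.shape:
        raise ValueError("p_map and t_map must have the same shape")
    supra = p_map < cfg.point_alpha
    if valid_mask is not None:
        supra = supra & valid_mask
    structure = _STRUCTURES[cfg.connectivity]
    clusters: list[Cluster] = []
    for sign in (1, -1):
        mask = supra & ((t_map > 0) if sign > 0 else (t_map < 0))
        labels, n = ndimage.label(mask, structure=structure)
        for k in range(1, n + 1):
            cm = labels == k
            rows, cols = np.nonzero(cm)
            clusters.append(
                Cluster(
                    mask=cm,
                    area=int(cm.sum()),
                    sign=sign,
                    freq_extent=(int(rows.min()), int(rows.max())),
                    time_extent=(int(cols.min()), int(cols.max())),
                )
            )
    clusters.sort(key=lambda c: c.area, reverse=True)
    return clusters


def _surrogate_areas(
    X: np.ndarray,
    assign: np.ndarray,
    nA: int,
    shape: tuple[int, ...],
    cfg: ClusterConfig,
    valid_flat: np.ndarray | None,
    structure: np.ndarray,
) -> list[list[int]]:
    """Cluster areas for each surrogate labeling.

    ``X`` is (n_subjects, n_points); ``assign`` is (n_perm, n_subjects)
    boolean, True marking surrogate group A.  Means/variances for all
    permutations are computed with matrix products, then each surrogate
    t/p map is clustered.
    """
    N = X.shape[0]
    nB = N - nA
    X2 = X * X
    out: list[list[int]] = []
    chunk = max(1, int(5e7 // max(X.size, 1)))  # keep work arrays modest
    for s in range(0, assign.shape[0], chunk):
        A = assign[s : s + chunk].astype(float)
        B = 1.0 - A
        meanA = A @ X / nA
        meanB = B @ X / nB
        varA = (A @ X2 / nA - meanA**2) * nA / (nA - 1)
        varB = (B @ X2 / nB - meanB**2) * nB / (nB - 1)
        t, df = _welch(meanA, varA, nA, meanB, varB, nB)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        supra = p < cfg.point_alpha
        if valid_flat is not None:
            supra &= valid_flat[None, :]
        for i in range(t.shape[0]):
            areas: list[int] = []
            for sign in (1, -1):
                m = (supra[i] & ((t[i] > 0) if sign > 0 else (t[i] < 0))).reshape(shape)
                labels, n = ndimage.label(m, structure=structure)
                if n:
                    areas.extend(np.bincount(labels.ravel())[1:].tolist())
            out.append(areas)
    return out


def permutation_test(
    groupA,
    groupB,
    cfg: ClusterConfig = ClusterConfig(),
    valid_mask: np.ndarray | None = None,
    method: str = "auto",
) -> ClusterResult:
    """Label-shuffling cluster test between two groups of maps.

    ``method`` is ``"montecarlo"`` (random relabelings, ``cfg.rng_seed``
    fixing the draw), ``"exhaustive"`` (all distinct assignments of
    subjects to groups), or ``"auto"`` which enumerates exhaustively when
    the number of assignments does not exceed ``cfg.n_permutations``.

    An observed cluster is significant when its area exceeds
    ``cfg.cluster_percentile`` percent of the surrogate null values
    (per-permutation maxima under ``null_statistic="max"``, every
    surrogate cluster under ``"pool"``).  Deterministic for a fixed seed.
    """
    A = _as_stack(groupA)
    B = _as_stack(groupB)
    t_map, p_map = pointwise_tmap(A, B)
    shape = t_map.shape
    structure = _STRUCTURES[cfg.connectivity]
    clusters = find_clusters(p_map, t_map, cfg, valid_mask)

    nA, nB = A.shape[0], B.shape[0]
    N = nA + nB
    n_comb = math.comb(N, nA)
    if n_comb < 20:
        logger.warning(
            "only %d distinct relabelings for %d vs %d subjects; "
            "permutation p-values are coarse",
            n_comb, nA, nB,
        )
    X = np.concatenate([A, B]).reshape(N, -1)
    valid_flat = valid_mask.ravel() if valid_mask is not None else None

    if method == "auto":
        method = "exhaustive" if n_comb <= cfg.n_permutations else "montecarlo"
    if method == "exhaustive":
        assign = np.zeros((n_comb, N), bool)
        for i, combo in enumerate(itertools.combinations(range(N), nA)):
            assign[i, list(combo)] = True
    elif method == "montecarlo":
        rng = np.random.default_rng(cfg.rng_seed)
        assign = np.zeros((cfg.n_permutations, N), bool)
        for i in range(cfg.n_permutations):
            assign[i, rng.choice(N, nA, replace=False)] = True
    else:
        raise ValueError("method must be 'auto', 'montecarlo' or 'exhaustive'")

    per_perm = _surrogate_areas(X, assign, nA, shape, cfg, valid_flat, structure)
    if cfg.null_statistic == "max":
        null_areas = np.array([max(a) if a else 0 for a in per_perm], float)
    else:
        pooled = [a for areas in per_perm for a in areas]
        null_areas = np.array(pooled if pooled else [0], float)

    for c in clusters:
        frac_below = float(np.mean(null_areas < c.area))
        c.null_percentile = 100.0 * frac_below
        c.significant = frac_below > cfg.cluster_percentile / 100.0

    sign_mask = np.zeros(shape, np.int8)
    supra = p_map < cfg.point_alpha
    if valid_mask is not None:
        supra = supra & valid_mask
    sign_mask[supra & (t_map > 0)] = 1
    sign_mask[supra & (t_map < 0)] = -1

    return ClusterResult(
        t_map=t_map,
        p_map=p_map,
        sign_mask=sign_mask,
        clusters=clusters,
        null_areas=null_areas,
        cfg=cfg,
        method=method,
    )
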