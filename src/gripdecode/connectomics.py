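"""Prediction network mapping: predict per-site decoding performance from
structural (fiber T-score) and functional-style (R-map) connectivity.

Structural route: a recording site is "connected" to a streamline when any
polyline segment passes within a radius (default 5 mm); fibers traversing to
no more than 20 % of sites are discarded. Each retained fiber gets a
two-sample pooled-variance t-score comparing performance of connected vs
unconnected sites; fibers surviving Benjamini-Hochberg FDR at alpha = 0.05
are aggregated (t-values as weights, normalized by connected-fiber count)
into a per-site score.

Voxel route: per-site connectivity fingerprints on a shared regular grid are
correlated voxel-wise with performance across sites ("R-map"); a held-out
site's predicted score is the spatial (Pearson) correlation between its
fingerprint and the R-map over valid voxels.

Both predictors are validated with leave-one-channel-out and
leave-one-subject-out cross-validation: the t-scores / R-map are fit on
training sites only, and predicted vs true performance is compared by rank
correlation with a permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .evaluation import fdr_adjust, permutation_pvalue

DEFAULT_RADIUS_MM = 5.0
MIN_SITE_FRACTION = 0.2


@dataclass(frozen=True)
class RecordingSite:
    site_id: str
    subject_id: str
    coordinate: tuple[float, float, float]
    performance: float  # floored R2 in [0, 1]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coordinate)):
            raise ValueError(f"site {self.site_id}: non-finite coordinate")
        if not 0.0 <= self.performance <= 1.0:
            raise ValueError(f"site {self.site_id}: performance must lie in [0, 1]")


def _segment_distances(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Min distance from each point to any segment of one polyline (S,)."""
    a = poly[:-1][None, :, :]  # (1, P-1, 3)
    b = poly[1:][None, :, :]
    p = points[:, None, :]  # (S, 1, 3)
    ab = b - a
    denom = np.maximum((ab**2).sum(-1), 1e-30)
    t = np.clip(((p - a) * ab).sum(-1) / denom, 0.0, 1.0)
    closest = a + t[..., None] * ab
    d = np.sqrt(((p - closest) ** 2).sum(-1))
    return d.min(axis=1)


def fiber_connectivity(
    site_coords: np.ndarray,
    fibers: Sequence[np.ndarray],
    radius_mm: float = DEFAULT_RADIUS_MM,
    min_fraction: float = MIN_SITE_FRACTION,
) -> tuple[np.ndarray, np.ndarray]:
    """Site x fiber connectivity with the >20 %-of-sites inclusion filter.

    Returns (connectivity matrix over *kept* fibers, kept fiber indices).
    A fiber is connected to a site iff any of its segments passes within
    ``radius_mm``; fibers connected to <= ``min_fraction`` of sites are
    removed. With ``min_fraction=0`` all fibers are kept (raw geometry).
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    coords = np.asarray(site_coords, dtype=float)
    S = coords.shape[0]
    conn = np.zeros((S, len(fibers)), dtype=bool)
    for f, poly in enumerate(fibers):
        poly = np.asarray(poly, dtype=float)
        if poly.shape[0] < 2:
            raise ValueError(f"fiber {f} has fewer than 2 vertices")
        conn[:, f] = _segment_distances(coords, poly) <= radius_mm
    frac = conn.mean(axis=0)
    kept = np.nonzero(frac > min_fraction)[0] if min_fraction > 0 else np.arange(len(fibers))
    if kept.size == 0 and min_fraction > 0:
        raise ValueError(
            f"no fiber traverses more than {min_fraction:.0%} of the {S} sites "
            f"(max fraction {frac.max():.0%}) — check geometry or radius"
        )
    return conn[:, kept], kept


@dataclass
class FiberScores:
    t_values: np.ndarray  # per kept fiber; NaN where degenerate
    p_values: np.ndarray
    significant: np.ndarray  # FDR mask at alpha
    alpha: float


def fiber_t_scores(
    conn: np.ndarray, performances: np.ndarray, alpha: float = 0.05
) -> FiberScores:
    """Mass-univariate two-sample (pooled-variance) t per fiber: performance
    of connected vs unconnected sites, FDR-corrected across fibers.
    Fibers with fewer than 2 sites in either group are flagged NaN."""
    conn = np.asarray(conn, dtype=bool)
    perf = np.asarray(performances, dtype=float)
    S, F = conn.shape
    n1 = conn.sum(axis=0).astype(float)
    n2 = S - n1
    sum1 = conn.T @ perf
    sumsq1 = conn.T @ perf**2
    sum_all, sumsq_all = perf.sum(), (perf**2).sum()
    t = np.full(F, np.nan)
    p = np.full(F, np.nan)
    valid = (n1 >= 2) & (n2 >= 2)
    m1 = sum1[valid] / n1[valid]
    m2 = (sum_all - sum1[valid]) / n2[valid]
    ss1 = sumsq1[valid] - n1[valid] * m1**2
    ss2 = (sumsq_all - sumsq1[valid]) - n2[valid] * m2**2
    df = n1[valid] + n2[valid] - 2
    sp2 = (ss1 + ss2) / df
    se = np.sqrt(sp2 * (1 / n1[valid] + 1 / n2[valid]))
    with np.errstate(divide="ignore", invalid="ignore"):
        tv = np.where(se > 0, (m1 - m2) / se, 0.0)
    t[valid] = tv
    p[valid] = 2 * stats.t.sf(np.abs(tv), df)
    sig = np.zeros(F, dtype=bool)
    if valid.any():
        sig[valid] = fdr_adjust(p[valid], alpha=alpha)
    return FiberScores(t_values=t, p_values=p, significant=sig, alpha=alpha)


def aggregated_fiber_predict(
    conn_row: np.ndarray, scores: FiberScores, normalize_by_count: bool = False
) -> float:
    """Aggregated fiber score for one site: t-weighted sum over the
    significant fibers it connects to (0 when it connects to none).

    The default is the plain t-sum, which keeps the site-degree signal —
    how many discriminative fibers a site reaches is itself predictive.
    ``normalize_by_count`` switches to the mean t-value instead.
    """
    sel = np.asarray(conn_row, dtype=bool) & scores.significant & np.isfinite(scores.t_values)
    if not sel.any():
        return 0.0
    total = float(scores.t_values[sel].sum())
    return total / sel.sum() if normalize_by_count else total


# ---------------------------------------------------------------------------
# voxel fingerprints / R-map


@dataclass
class RMap:
    values: np.ndarray  # voxel grid of across-site correlations
    valid: np.ndarray  # mask of voxels with defined correlation


def build_rmap(fingerprints: np.ndarray, performances: np.ndarray) -> RMap:
    """Voxel-wise Pearson correlation across sites between fingerprint value
    and performance. Constant-fingerprint voxels are stored as 0 and masked."""
    fp = np.asarray(fingerprints, dtype=float)
    perf = np.asarray(performances, dtype=float)
    if fp.shape[0] != perf.size:
        raise ValueError("fingerprint count does not match performance count")
    if fp.shape[0] < 4:
        raise ValueError("need at least 4 sites to build an R-map")
    S = fp.shape[0]
    grid_shape = fp.shape[1:]
    flat = fp.reshape(S, -1)
    sd = flat.std(axis=0)
    # relative tolerance: std of a constant voxel is round-off, not signal
    valid = sd > 1e-12 * (np.abs(flat).mean(axis=0) + 1.0)
    z = np.zeros_like(flat)
    z[:, valid] = (flat[:, valid] - flat[:, valid].mean(axis=0)) / sd[valid]
    if perf.std() == 0:
        raise ValueError("performance vector is constant")
    zp = (perf - perf.mean()) / perf.std()
    r = np.zeros(flat.shape[1])
    r[valid] = zp @ z[:, valid] / S
    return RMap(values=r.reshape(grid_shape), valid=valid.reshape(grid_shape))


def rmap_predict(fingerprint: np.ndarray, rmap: RMap) -> float:
    """Spatial similarity: Pearson correlation between a site's fingerprint
    and the R-map over valid voxels."""
    fp = np.asarray(fingerprint, dtype=float).ravel()
    mask = rmap.valid.ravel()
    if not mask.any():
        raise ValueError("R-map has no valid voxels")
    a, b = fp[mask], rmap.values.ravel()[mask]
    if a.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


# ---------------------------------------------------------------------------
# cross-validated prediction


@dataclass
class LoocvReport:
    predicted: np.ndarray  # per site
    true: np.ndarray
    rho: float  # Spearman predicted vs true
    p: float
    mode: str  # "channel" | "subject"
    predictor: str  # "fiber" | "rmap"


def loocv(
    site_coords: np.ndarray,
    performances: np.ndarray,
    predictor: str,
    mode: str = "channel",
    subjects: Optional[np.ndarray] = None,
    fibers: Optional[Sequence[np.ndarray]] = None,
    fingerprints: Optional[np.ndarray] = None,
    radius_mm: float = DEFAULT_RADIUS_MM,
    alpha: float = 0.05,
    seed: int = 0,
    n_perm: int = 2000,
) -> LoocvReport:
    """Leave-one-channel-out / leave-one-subject-out performance prediction.

    Per fold, the fiber t-scores (or the R-map) are fit on training sites
    only and the held-out site(s) are scored; every site is predicted exactly
    once. The report carries the Spearman correlation of predicted vs true
    performance with a permutation p-value.
    """
    perf = np.asarray(performances, dtype=float)
    S = perf.size
    if mode == "channel":
        folds = [np.array([i]) for i in range(S)]
    elif mode == "subject":
        if subjects is None:
            raise ValueError("subject mode needs a subjects array")
        subjects = np.asarray(subjects)
        folds = [np.nonzero(subjects == s)[0] for s in np.unique(subjects)]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if predictor == "fiber":
        if fibers is None:
            raise ValueError("fiber predictor needs fibers")
        conn, _ = fiber_connectivity(site_coords, fibers, radius_mm=radius_mm)
    elif predictor == "rmap":
        if fingerprints is None:
            raise ValueError("rmap predictor needs fingerprints")
        fingerprints = np.asarray(fingerprints, dtype=float)
    else:
        raise ValueError(f"unknown predictor {predictor!r}")

    predicted = np.empty(S)
    for held in folds:
        train = np.setdiff1d(np.arange(S), held)
        if predictor == "fiber":
            scores = fiber_t_scores(conn[train], perf[train], alpha=alpha)
            for i in held:
                predicted[i] = aggregated_fiber_predict(conn[i], scores)
        else:
            rmap = build_rmap(fingerprints[train], perf[train])
            for i in held:
                predicted[i] = rmap_predict(fingerprints[i], rmap)

    if np.ptp(predicted) == 0 or np.ptp(perf) == 0:
        # constant predictions (e.g. no significant fibers anywhere under a
        # null fixture) carry no association: rho = 0, maximally non-significant
        rho, p = 0.0, 1.0
    else:
        rho = float(stats.spearmanr(predicted, perf).statistic)
        p = permutation_pvalue(
            lambda a, b: stats.spearmanr(a, b).statistic,
            predicted, perf, n_perm=n_perm, seed=seed, scheme="shuffle",
        )
    return LoocvReport(predicted=predicted, true=perf, rho=rho, p=p, mode=mode, predictor=predictor)
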