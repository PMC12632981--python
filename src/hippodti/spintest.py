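"""Spatial-permutation ("spin") tests for unfolded-space surface maps.

Two surface maps are compared by their Pearson correlation over a regular
raster in the unfolded rectangle (u = anterior-posterior, v =
proximal-distal).  Significance comes from a permutation null that preserves
each map's spatial autocorrelation: one map is rigidly displaced by random
toroidal shifts in the unfolded plane (optionally combined with random u/v
axis flips) and the correlation recomputed.  This is the planar analogue of
spherical spin tests.  The test is two-sided through |R|, and the p-value
uses the add-one rule ``p = (1 + #{|R_null| >= |R_obs|}) / (1 + n_perm)``,
so the smallest attainable p at 2500 permutations is 1/2501.

The null generator is pluggable: pass ``null_fn(rng, raster) -> raster`` to
substitute a different surrogate scheme.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import DataError
from .surface import HippSurface, SurfaceMetric

DEFAULT_GRID = (126, 32)  # (u, v) cells


@dataclass
class SpinResult:
    r_observed: float
    null_distribution: np.ndarray
    p: float
    n_perm: int
    seed: int | None
    n_redrawn: int = 0


def resample_to_grid(
    metric: SurfaceMetric, surface: HippSurface, grid: tuple[int, int] = DEFAULT_GRID
) -> np.ndarray:
    """Rasterise a vertex map onto a regular u x v grid.

    Each valid vertex contributes to the cell containing its unfolded
    coordinate; cells holding several vertices take their mean and cells with
    none are NaN (missing).
    """
    nu, nv = grid
    ok = metric.valid & np.isfinite(metric.values)
    if not ok.any():
        raise DataError("empty map: no valid vertices to rasterise")
    uv = surface.unfolded_uv[ok]
    iu = np.clip((uv[:, 0] * nu).astype(int), 0, nu - 1)
    iv = np.clip((uv[:, 1] * nv).astype(int), 0, nv - 1)
    acc = np.zeros((nu, nv))
    cnt = np.zeros((nu, nv))
    np.add.at(acc, (iu, iv), metric.values[ok])
    np.add.at(cnt, (iu, iv), 1.0)
    with np.errstate(invalid="ignore"):
        out = acc / cnt
    out[cnt == 0] = np.nan
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    am = a - a.mean()
    bm = b - b.mean()
    denom = np.sqrt(np.sum(am * am) * np.sum(bm * bm))
    if denom == 0:
        raise DataError("zero variance: constant map")
    return float(np.sum(am * bm) / denom)


def _toroidal_null(rng: np.random.Generator, raster: np.ndarray, flips: bool = True):
    """Random flip + toroidal shift; the identity draw is excluded (the
    observed arrangement already enters through the add-one rule)."""
    while True:
        fu = fv = 0
        if flips:
            fu, fv = int(rng.integers(2)), int(rng.integers(2))
        du = int(rng.integers(raster.shape[0]))
        dv = int(rng.integers(raster.shape[1]))
        if fu or fv or du or dv:
            break
    out = raster
    if fu:
        out = out[::-1, :]
    if fv:
        out = out[:, ::-1]
    return np.roll(np.roll(out, du, axis=0), dv, axis=1)


def spin_correlate(
    map_a: np.ndarray,
    map_b: np.ndarray,
    n_perm: int = 2500,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    flips: bool = True,
    null_fn=None,
    min_overlap: float = 0.5,
    max_redraws: int = 100,
) -> SpinResult:
    """Spin-test correlation between two unfolded rasters.

    ``map_a`` is the map that gets displaced.  Cells missing (NaN) in either
    map are excluded from each correlation; a permutation whose overlap with
    ``map_b`` falls below ``min_overlap`` of the observed overlap is redrawn
    (bounded by ``max_redraws`` per permutation).
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise DataError("maps must share the raster grid")
    if n_perm < 100:
        raise DataError("n_perm must be >= 100")
    joint = np.isfinite(a) & np.isfinite(b)
    if joint.sum() < 3:
        raise DataError("fewer than 3 jointly valid cells")
    r_obs = _pearson(a[joint], b[joint])
    n_obs = int(joint.sum())

    if rng is None:
        rng = np.random.default_rng(seed)
    if null_fn is None:
        def null_fn(rng_, raster):
            return _toroidal_null(rng_, raster, flips=flips)

    null = np.empty(n_perm)
    n_redrawn = 0
    for i in range(n_perm):
        for _ in range(max_redraws):
            shifted = null_fn(rng, a)
            ok = np.isfinite(shifted) & np.isfinite(b)
            if ok.sum() >= min_overlap * n_obs:
                break
            n_redrawn += 1
        else:
            raise DataError("could not find a permutation with sufficient overlap")
        null[i] = _pearson(shifted[ok], b[ok])

    p = (1.0 + np.sum(np.abs(null) >= np.abs(r_obs))) / (1.0 + n_perm)
    return SpinResult(
        r_observed=r_obs,
        null_distribution=null,
        p=float(p),
        n_perm=n_perm,
        seed=seed,
        n_redrawn=n_redrawn,
    )


def correlate_map_set(
    maps: dict[str, np.ndarray],
    n_perm: int = 2500,
    seed: int | None = None,
    alpha: float = 0.05,
    n_comparisons: int | None = None,
) -> dict[str, pd.DataFrame]:
    """All pairwise spin tests among named rasters, with Bonferroni control.

    ``n_comparisons`` sets the Bonferroni family size m (threshold alpha/m);
    defaults to the number of pairs.  Returns symmetric R, p and significance
    matrices as data frames plus the threshold used.
    """
    names = list(maps)
    if len(names) < 2:
        raise DataError("need at least two maps")
    m = n_comparisons if n_comparisons else len(names) * (len(names) - 1) // 2
    threshold = alpha / m
    R = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    P = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    rng = np.random.default_rng(seed)
    for i, j in combinations(range(len(names)), 2):
        res = spin_correlate(maps[names[i]], maps[names[j]], n_perm=n_perm, rng=rng)
        R.iloc[i, j] = R.iloc[j, i] = res.r_observed
        P.iloc[i, j] = P.iloc[j, i] = res.p
    sig = (P < threshold) & ~np.eye(len(names), dtype=bool)
    return {"R": R, "p": P, "significant": sig, "threshold": threshold, "m": m}
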