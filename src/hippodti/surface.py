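"""Midthickness-surface sampling and parcel aggregation.

Volumetric metrics are sampled at surface vertices by trilinear
interpolation (world -> voxel through the inverse affine).  Voxel validity is
honoured by re-weighting the 8 trilinear corners over valid voxels only;
a vertex whose corners are all invalid becomes invalid.  Orientation metrics
are sampled by interpolating the six tensor components (sign-blind, unlike
eigenvectors) and eigendecomposing at the vertex.

Parcels are the five subfields (Sub, CA1, CA2, CA3, DG/CA4) along the
proximal-distal axis and the head/body/tail bins along the anterior-posterior
axis.  Parcel means are unweighted over valid vertices by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dti import TensorVolume, _eigensystem
from .errors import DataError
from .laplace import AxisVectorField

logger = logging.getLogger(__name__)

SUBFIELDS = ("Sub", "CA1", "CA2", "CA3", "DG/CA4")
AP_BINS = ("head", "body", "tail")


@dataclass
class HippSurface:
    """Midthickness mesh with unfolded coordinates, labels and macrostructure.

    ``unfolded_uv`` holds (u, v) in the unit square with u the
    anterior-posterior and v the proximal-distal coordinate.
    """

    vertices: np.ndarray           # (N, 3) world mm
    faces: np.ndarray              # (M, 3) vertex indices
    unfolded_uv: np.ndarray        # (N, 2)
    subfield: np.ndarray           # (N,) strings from SUBFIELDS
    ap_bin: np.ndarray             # (N,) strings from AP_BINS
    thickness: np.ndarray          # (N,) mm
    gyrification: np.ndarray = None

    def __post_init__(self):
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise DataError("faces index out-of-range vertices")
        for name in ("unfolded_uv", "subfield", "ap_bin", "thickness"):
            if len(getattr(self, name)) != n:
                raise DataError(f"{name} length must match vertex count")
        if np.any(self.thickness <= 0):
            raise DataError("thickness must be strictly positive")
        if self.gyrification is None:
            self.gyrification = np.ones(n)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass
class SurfaceMetric:
    values: np.ndarray
    name: str
    valid: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.values.shape:
            raise DataError("validity mask must match values")


def _trilinear(points_vox: np.ndarray, shape: tuple[int, int, int]):
    """Corner indices (P, 8, 3), weights (P, 8) and an in-FOV flag (P,)."""
    p = np.asarray(points_vox, dtype=float)
    lo = np.floor(p).astype(int)
    frac = p - lo
    offs = np.array([[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)])
    corners = lo[:, None, :] + offs[None, :, :]
    w = np.prod(
        np.where(offs[None, :, :] == 1, frac[:, None, :], 1.0 - frac[:, None, :]),
        axis=2,
    )
    inside = np.all(corners >= 0, axis=(1, 2)) & np.all(
        corners < np.asarray(shape)[None, None, :], axis=(1, 2)
    )
    corners = np.clip(corners, 0, np.asarray(shape) - 1)
    return corners, w, inside


def _world_to_vox(vertices: np.ndarray, affine: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    return vertices @ inv[:3, :3].T + inv[:3, 3]


def _sample_components(
    volume: np.ndarray, valid_mask: np.ndarray, points_vox: np.ndarray
):
    """Validity-weighted trilinear sampling of (..., C) or scalar volumes."""
    scalar = volume.ndim == 3
    vol = volume[..., None] if scalar else volume
    corners, w, inside = _trilinear(points_vox, vol.shape[:3])
    ci, cj, ck = corners[..., 0], corners[..., 1], corners[..., 2]
    cvalid = valid_mask[ci, cj, ck] & inside[:, None]
    w = w * cvalid
    wsum = w.sum(axis=1)
    ok = wsum > 1e-12
    vals = np.zeros((len(points_vox), vol.shape[3]))
    vals[ok] = np.einsum("pc,pck->pk", w[ok], vol[ci[ok], cj[ok], ck[ok]]) / wsum[
        ok, None
    ]
    return (vals[:, 0] if scalar else vals), ok


def sample_scalar(
    volume: np.ndarray,
    surface: HippSurface,
    affine: np.ndarray,
    valid_mask: np.ndarray | None = None,
    name: str = "metric",
) -> SurfaceMetric:
    """Trilinear sampling of a scalar volume at the surface vertices."""
    volume = np.asarray(volume, dtype=float)
    if valid_mask is None:
        valid_mask = np.isfinite(volume)
    pts = _world_to_vox(surface.vertices, affine)
    vals, ok = _sample_components(volume, valid_mask, pts)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%d vertices outside the valid volume for %s", n_bad, name)
    vals[~ok] = np.nan
    return SurfaceMetric(values=vals, name=name, valid=ok)


def sample_orientation(
    tensor: TensorVolume,
    axes: dict[str, AxisVectorField],
    surface: HippSurface,
    affine: np.ndarray | None = None,
) -> dict[str, SurfaceMetric]:
    """Vertex-level long-axis / tangentiality / radiality.

    The six tensor components are interpolated to each vertex and
    eigendecomposed there (tensor interpolation is blind to the V1 sign
    ambiguity); axis-field components are interpolated and renormalised.
    Returns {"long_axis": ..., "tangentiality": ..., "radiality": ...}.
    """
    affine = tensor.affine if affine is None else affine
    pts = _world_to_vox(surface.vertices, affine)
    tvalid = tensor.valid
    t6, t_ok = _sample_components(tensor.tensor, tvalid, pts)
    w, v1, _, degen = _eigensystem(t6)
    v1_ok = t_ok & ~degen

    names = {"AP": "long_axis", "PD": "tangentiality", "IO": "radiality"}
    out = {}
    for axis, metric_name in names.items():
        f = axes[axis]
        vec, a_ok = _sample_components(f.vectors, f.valid, pts)
        norm = np.linalg.norm(vec, axis=1)
        a_ok &= norm > 1e-8
        vec[a_ok] /= norm[a_ok, None]
        ok = v1_ok & a_ok
        vals = np.full(surface.n_vertices, np.nan)
        vals[ok] = np.abs(np.sum(vec[ok] * v1[ok], axis=1))
        out[metric_name] = SurfaceMetric(values=vals, name=metric_name, valid=ok)
    return out


def parcel_average(
    metric: SurfaceMetric,
    surface: HippSurface,
    scheme: str = "subfield",
    area_weighted: bool = False,
) -> pd.DataFrame:
    """Mean of a surface metric over subfield or head/body/tail parcels.

    Returns a frame with columns (parcel, n_vertices, mean).  Raises
    :class:`DataError` if a parcel has no valid vertex.
    """
    if scheme == "subfield":
        labels, order = surface.subfield, SUBFIELDS
    elif scheme == "ap_bin":
        labels, order = surface.ap_bin, AP_BINS
    else:
        raise DataError(f"unknown parcellation scheme {scheme!r}")
    weights = _vertex_areas(surface) if area_weighted else np.ones(surface.n_vertices)
    rows = []
    for parcel in order:
        sel = (labels == parcel) & metric.valid
        if not sel.any():
            raise DataError(f"empty parcel {parcel}")
        w = weights[sel]
        rows.append(
            {
                "parcel": parcel,
                "n_vertices": int(sel.sum()),
                "mean": float(np.sum(w * metric.values[sel]) / np.sum(w)),
            }
        )
    return pd.DataFrame(rows)


def _vertex_areas(surface: HippSurface) -> np.ndarray:
    v = surface.vertices
    f = surface.faces
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    area = 0.5 * np.linalg.norm(cross, axis=1)
    out = np.zeros(surface.n_vertices)
    for c in range(3):
        np.add.at(out, f[:, c], area / 3.0)
    return out


def average_hemispheres(left, right):
    """Average left/right data for one participant.

    Accepts either two parcel tables (frames with 'parcel' and 'mean') or two
    :class:`SurfaceMetric` vertex maps in unfolded correspondence.  For maps,
    a vertex is valid only if valid in both hemispheres.
    """
    if isinstance(left, pd.DataFrame) and isinstance(right, pd.DataFrame):
        if not left["parcel"].tolist() == right["parcel"].tolist():
            raise DataError("parcel mismatch between hemispheres")
        out = left.copy()
        out["mean"] = (left["mean"].to_numpy() + right["mean"].to_numpy()) / 2.0
        out["n_vertices"] = left["n_vertices"].to_numpy() + right["n_vertices"].to_numpy()
        return out
    if isinstance(left, SurfaceMetric) and isinstance(right, SurfaceMetric):
        if left.values.shape != right.values.shape:
            raise DataError("vertex count mismatch between hemispheres")
        valid = left.valid & right.valid
        vals = np.full_like(left.values, np.nan)
        vals[valid] = (left.values[valid] + right.values[valid]) / 2.0
        return SurfaceMetric(values=vals, name=left.name, valid=valid)
    raise DataError("hemisphere inputs must both be parcel tables or both vertex maps")
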