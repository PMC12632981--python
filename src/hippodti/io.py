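"""File I/O: NIfTI volumes, FSL bval/bvec tables, TSV surfaces and metrics."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .dti import GradientScheme
from .errors import DataError
from .laplace import LabeledVolume
from .surface import HippSurface, SurfaceMetric


def save_nifti(data: np.ndarray, affine: np.ndarray, path, dtype=np.float32):
    img = nib.Nifti1Image(np.asarray(data).astype(dtype), np.asarray(affine))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def load_labeled_volume(path, boundary_labels=None) -> LabeledVolume:
    data, affine = load_nifti(path)
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    kwargs = {} if boundary_labels is None else {"boundary_labels": boundary_labels}
    return LabeledVolume(
        labels=np.rint(data).astype(np.int16), spacing=spacing, affine=affine, **kwargs
    )


def read_bvals_bvecs(bval_path, bvec_path) -> GradientScheme:
    """FSL-style text: one row of b-values; three rows of vector components."""
    for p in (bval_path, bvec_path):
        if not Path(p).exists():
            raise DataError(f"no such file: {p}")
    bvals = np.loadtxt(str(bval_path)).ravel()
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return GradientScheme(bvals=bvals, bvecs=bvecs)


def write_bvals_bvecs(scheme: GradientScheme, bval_path, bvec_path):
    np.savetxt(str(bval_path), scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(str(bvec_path), scheme.bvecs.T, fmt="%.8f")


def write_surface_tsv(surface: HippSurface, vertices_path, faces_path):
    df = pd.DataFrame(
        {
            "x": surface.vertices[:, 0],
            "y": surface.vertices[:, 1],
            "z": surface.vertices[:, 2],
            "u": surface.unfolded_uv[:, 0],
            "v": surface.unfolded_uv[:, 1],
            "subfield": surface.subfield,
            "ap_bin": surface.ap_bin,
            "thickness": surface.thickness,
            "gyrification": surface.gyrification,
        }
    )
    df.to_csv(vertices_path, sep="\t", index=False, float_format="%.8g")
    pd.DataFrame(surface.faces, columns=["v0", "v1", "v2"]).to_csv(
        faces_path, sep="\t", index=False
    )


def read_surface_tsv(vertices_path, faces_path) -> HippSurface:
    for p in (vertices_path, faces_path):
        if not Path(p).exists():
            raise DataError(f"no such file: {p}")
    df = pd.read_csv(vertices_path, sep="\t")
    faces = pd.read_csv(faces_path, sep="\t").to_numpy(int)
    return HippSurface(
        vertices=df[["x", "y", "z"]].to_numpy(float),
        faces=faces,
        unfolded_uv=df[["u", "v"]].to_numpy(float),
        subfield=df["subfield"].to_numpy(),
        ap_bin=df["ap_bin"].to_numpy(),
        thickness=df["thickness"].to_numpy(float),
        gyrification=df["gyrification"].to_numpy(float),
    )


def write_metric_tsv(metric: SurfaceMetric, path):
    pd.DataFrame(
        {"value": metric.values, "valid": metric.valid.astype(int)}
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_metric_tsv(path, name="metric") -> SurfaceMetric:
    df = pd.read_csv(path, sep="\t")
    return SurfaceMetric(
        values=df["value"].to_numpy(float),
        name=name,
        valid=df["valid"].to_numpy(bool),
    )
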