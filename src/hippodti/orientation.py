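"""Cosine-similarity orientation metrics between V1 and the hippocampal axes.

Each metric is the absolute cosine between the primary diffusion eigenvector
and one axis field: long-axis (AP), tangentiality (PD) and radiality (IO).
The absolute value removes the arbitrary sign of both V1 and the gradient
fields; values lie in [0, 1], 1 meaning diffusion parallel to the axis and 0
perpendicular.  Both inputs are unit-normalised before the dot product, so
the cosine is exactly |H . V1|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dti import TensorVolume
from .errors import DataError
from .laplace import AxisVectorField


@dataclass
class OrientationMetrics:
    long_axis: np.ndarray
    tangentiality: np.ndarray
    radiality: np.ndarray
    valid: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "long_axis": self.long_axis,
            "tangentiality": self.tangentiality,
            "radiality": self.radiality,
        }


def cosine_similarity(
    axis_field: AxisVectorField,
    v1: np.ndarray,
    v1_valid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel |H . V1| with validity propagation.

    Returns ``(values, valid)``; values are zero where invalid.
    """
    v1 = np.asarray(v1, dtype=float)
    if v1.shape != axis_field.vectors.shape:
        raise DataError(
            f"shape mismatch: axis field {axis_field.vectors.shape} vs V1 {v1.shape}"
        )
    if v1_valid is None:
        v1_valid = np.ones(v1.shape[:-1], dtype=bool)
    valid = axis_field.valid & v1_valid
    values = np.zeros(v1.shape[:-1])
    values[valid] = np.abs(np.sum(axis_field.vectors[valid] * v1[valid], axis=-1))
    # guard tiny numerical overshoot of unit-vector products
    np.clip(values, 0.0, 1.0, out=values)
    return values, valid


def orientation_metrics(
    tensor: TensorVolume,
    ap: AxisVectorField,
    pd: AxisVectorField,
    io: AxisVectorField,
) -> OrientationMetrics:
    """Long-axis, tangentiality and radiality volumes from a fitted tensor.

    A voxel is valid only where the tensor fit is valid, V1 is non-degenerate
    and the axis vector is valid.
    """
    for f in (ap, pd, io):
        if f.vectors.shape[:-1] != tensor.v1.shape[:-1]:
            raise DataError("axis fields and tensor volume must share the grid")
    v1_valid = tensor.valid & ~tensor.degenerate
    la, la_ok = cosine_similarity(ap, tensor.v1, v1_valid)
    ta, ta_ok = cosine_similarity(pd, tensor.v1, v1_valid)
    ra, ra_ok = cosine_similarity(io, tensor.v1, v1_valid)
    return OrientationMetrics(
        long_axis=la, tangentiality=ta, radiality=ra, valid=la_ok & ta_ok & ra_ok
    )
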