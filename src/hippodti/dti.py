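"""Diffusion tensor fitting and derived scalars.

The single-tensor model relates the diffusion-weighted signal to a symmetric
3x3 tensor D through ``S = S0 * exp(-<B, D>_F)`` with b-matrix
``B = b * g g^T``, so the exponent reduces to ``-b * g^T D g``.  Units follow
the clinical convention: b in ms/um^2, D in um^2/ms.

Fitting is log-linear least squares per voxel: an ordinary pass on ``log S``
followed (by default) by a weighted pass with weights equal to the squared
predicted signals, the standard two-step WLS estimator.  Eigendecomposition
yields eigenvalues sorted descending, the primary eigenvector V1 (sign
arbitrary; a deterministic sign convention is applied for reproducibility)
and mean diffusivity MD = trace(D)/3.

Tensor components are stored in lower-triangular order
(Dxx, Dxy, Dyy, Dxz, Dyz, Dzz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError

#: index pairs of the lower-triangular component order
_TRI = [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]
#: multiplicity of each component in the quadratic form g^T D g
_TRI_MULT = np.array([1.0, 2.0, 1.0, 2.0, 2.0, 1.0])


@dataclass
class GradientScheme:
    """Diffusion gradient table: b-values (ms/um^2) and unit direction vectors.

    b = 0 entries may carry a zero direction vector.  A fit requires at least
    one b = 0 measurement and at least 6 unique non-zero directions (counted
    up to sign).
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise DataError("bvecs must be (n, 3) matching bvals length")
        nz = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[nz], axis=1)
        if nz.any() and np.any(np.abs(norms - 1.0) > 1e-4):
            raise DataError("non-zero-b directions must be unit norm (+-1e-4)")

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    def n_unique_directions(self, decimals: int = 4) -> int:
        """Distinct non-zero directions, antipodal pairs counted once."""
        g = self.bvecs[self.bvals > 0]
        if g.size == 0:
            return 0
        # canonical sign: first non-zero component positive
        sign = np.sign(g[np.arange(len(g)), np.argmax(np.abs(g) > 1e-12, axis=1)])
        sign[sign == 0] = 1.0
        canon = np.round(g * sign[:, None], decimals)
        return len({tuple(row) for row in canon})

    def validate_for_fit(self):
        if not self.b0_mask.any():
            raise ConfigurationError("scheme has no b=0 measurement")
        if self.n_unique_directions() < 6:
            raise ConfigurationError(
                "tensor fit requires >= 6 unique non-zero gradient directions"
            )

    def design_matrix(self) -> np.ndarray:
        """Rows [1, -b*m_c*q_c] so that X @ [ln S0, D_tri] = ln S."""
        g = self.bvecs
        quad = np.stack([g[:, i] * g[:, j] for i, j in _TRI], axis=1)
        return np.column_stack([np.ones(len(self)), -self.bvals[:, None] * _TRI_MULT * quad])


@dataclass
class DWIVolume:
    """4D diffusion-weighted signals plus scheme and a boolean mask."""

    signals: np.ndarray
    scheme: GradientScheme
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 4 or self.signals.shape[3] != len(self.scheme):
            raise DataError("signals must be 4D with last dim matching the scheme")
        if self.mask is None:
            self.mask = np.ones(self.signals.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.signals.shape[:3]:
                raise DataError("mask shape must match the signal grid")


@dataclass
class TensorVolume:
    """Per-voxel tensor, eigensystem and MD.

    ``valid`` marks voxels with a usable fit; ``non_spd`` flags negative
    eigenvalues (retained, not clamped); ``degenerate`` flags lambda1 ~
    lambda2 voxels whose V1 is unreliable and excluded from orientation
    metrics.
    """

    tensor: np.ndarray            # (..., 6) lower-triangular order
    eigenvalues: np.ndarray       # (..., 3) descending
    v1: np.ndarray                # (..., 3) unit
    md: np.ndarray                # (...)
    s0: np.ndarray                # (...)
    valid: np.ndarray             # (...) bool
    non_spd: np.ndarray = None    # (...) bool
    degenerate: np.ndarray = None # (...) bool
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def tensor_matrices(self) -> np.ndarray:
        return tensor6_to_matrix(self.tensor)


def tensor6_to_matrix(t6: np.ndarray) -> np.ndarray:
    """(..., 6) lower-triangular components -> (..., 3, 3) symmetric matrices."""
    t6 = np.asarray(t6, dtype=float)
    m = np.zeros(t6.shape[:-1] + (3, 3))
    for c, (i, j) in enumerate(_TRI):
        m[..., i, j] = t6[..., c]
        m[..., j, i] = t6[..., c]
    return m


def matrix_to_tensor6(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    return np.stack([m[..., i, j] for i, j in _TRI], axis=-1)


def _eigensystem(t6: np.ndarray, degen_tol: float = 1e-9):
    """Descending eigenvalues, sign-fixed V1, and flags from (..., 6) tensors."""
    mats = tensor6_to_matrix(t6)
    w, v = np.linalg.eigh(mats)          # ascending
    w = w[..., ::-1]
    v1 = v[..., :, -1]
    # deterministic sign: component with the largest magnitude made positive
    lead = np.argmax(np.abs(v1), axis=-1)
    s = np.sign(np.take_along_axis(v1, lead[..., None], axis=-1))
    s[s == 0] = 1.0
    v1 = v1 * s
    non_spd = w[..., 2] < 0
    degenerate = (w[..., 0] - w[..., 1]) < degen_tol
    return w, v1, non_spd, degenerate


def fit_tensor(dwi: DWIVolume, method: str = "wls") -> TensorVolume:
    """Log-linear tensor fit on every masked voxel.

    ``method`` is ``"wls"`` (two-step: OLS then weights = squared predicted
    signals) or ``"ols"``.  Voxels with any non-positive signal are flagged
    invalid and excluded rather than clamped.
    """
    dwi.scheme.validate_for_fit()
    if method not in ("wls", "ols"):
        raise ConfigurationError(f"unknown fit method {method!r}")
    X = dwi.scheme.design_matrix()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ConfigurationError("rank-deficient design: gradient scheme is degenerate")

    shape = dwi.signals.shape[:3]
    S = dwi.signals[dwi.mask]                      # (V, n)
    fit_ok = np.all(S > 0, axis=1)
    logS = np.log(np.where(S > 0, S, 1.0))

    pinv = np.linalg.pinv(X)
    beta = logS @ pinv.T                           # (V, 7) OLS
    if method == "wls":
        w = np.exp(2.0 * (beta @ X.T))             # squared predicted signals
        XtWX = np.einsum("nk,vn,nl->vkl", X, w, X)
        XtWy = np.einsum("nk,vn,vn->vk", X, w, logS)
        beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]

    t6 = beta[:, 1:]
    s0 = np.exp(beta[:, 0])
    w_eig, v1, non_spd, degen = _eigensystem(t6)
    md = np.mean(w_eig, axis=-1)

    def expand(a, fill=0.0):
        out = np.full(shape + a.shape[1:], fill, dtype=a.dtype)
        out[dwi.mask] = a
        return out

    valid = np.zeros(shape, dtype=bool)
    valid[dwi.mask] = fit_ok
    return TensorVolume(
        tensor=expand(t6),
        eigenvalues=expand(w_eig),
        v1=expand(v1),
        md=expand(md),
        s0=expand(s0),
        valid=valid,
        non_spd=expand(non_spd, False) & valid,
        degenerate=expand(degen, False) | ~valid,
    )


def predict_signal(tensor: TensorVolume, scheme: GradientScheme) -> DWIVolume:
    """Forward model ``S = S0 * exp(-b * g^T D g)`` per measurement."""
    X = scheme.design_matrix()
    beta = np.concatenate(
        [np.log(np.where(tensor.s0 > 0, tensor.s0, 1.0))[..., None], tensor.tensor],
        axis=-1,
    )
    S = np.exp(beta @ X.T)
    S[~tensor.valid] = 0.0
    return DWIVolume(signals=S, scheme=scheme, mask=tensor.valid.copy())


def mean_diffusivity(tensor: TensorVolume) -> np.ndarray:
    """MD = (l1 + l2 + l3)/3 = trace(D)/3, um^2/ms."""
    return np.mean(tensor.eigenvalues, axis=-1)


def tensor_from_eigensystem(
    eigenvalues: np.ndarray, v1: np.ndarray, v2: np.ndarray, v3: np.ndarray
) -> np.ndarray:
    """Compose (..., 6) tensors from eigenvalues and an orthonormal frame."""
    lam = np.asarray(eigenvalues, dtype=float)
    R = np.stack([v1, v2, v3], axis=-1)            # columns are eigenvectors
    D = np.einsum("...ik,...k,...jk->...ij", R, lam, R)
    return matrix_to_tensor6(D)
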