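"""Laplace coordinate fields over a labelled grey-matter voxel domain.

The hippocampal grey matter is treated as an irregular voxel domain bounded by
anatomical structures that act as Dirichlet boundaries.  For each of the three
hippocampal axes — anterior-posterior (AP), proximal-distal (PD) and
inner-outer (IO) — a potential ``psi`` is obtained by solving Laplace's
equation ``div(grad(psi)) = 0`` on the domain with ``psi = 0`` on that axis's
source label, ``psi = 1`` on its sink label, and zero-flux (mirror) conditions
along every other domain wall.  The normalised gradient of ``psi`` then yields
a unit vector field pointing along the axis at every grey-matter voxel.

Discretisation is the standard 6-neighbour finite-difference stencil with
per-axis voxel spacing.  Dirichlet values are anchored at labelled voxel
centres, so a slab with source plane ``x = 0`` and sink plane ``x = L``
reproduces ``psi = x / L`` exactly.  Two solvers are provided: red-black
Gauss-Seidel with successive over-relaxation (the default) and a sparse
direct solve of the same linear system.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConfigurationError, ConvergenceError, DataError

logger = logging.getLogger(__name__)

AXES = ("AP", "PD", "IO")

#: label codes: 0 background, 1 grey-matter domain, then (source, sink) per axis.
BACKGROUND = 0
DOMAIN = 1
DEFAULT_BOUNDARY_LABELS: dict[str, tuple[int, int]] = {
    "AP": (2, 3),   # source: anterior / HATA side, sink: posterior / indusium griseum
    "PD": (4, 5),   # source: MTL-cortex side, sink: dentate side
    "IO": (6, 7),   # source: SRLM (inner), sink: pial (outer)
}


@dataclass
class LabeledVolume:
    """Integer label grid with voxel spacing and a voxel-to-world affine.

    ``labels`` uses the coding above (configurable through
    ``boundary_labels``).  The domain is the set of voxels equal to
    :data:`DOMAIN`; labelled boundary voxels are Dirichlet anchors and are not
    solved for.
    """

    labels: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray
    boundary_labels: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDARY_LABELS)
    )

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.labels.ndim != 3:
            raise DataError("labels must be a 3D grid")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise DataError("spacing must be three strictly positive lengths")
        if self.affine.shape != (4, 4):
            raise DataError("affine must be 4x4")

    @property
    def domain_mask(self) -> np.ndarray:
        return self.labels == DOMAIN

    def axis_masks(self, axis: str) -> tuple[np.ndarray, np.ndarray]:
        """Source and sink masks for one axis; raises if the labels are absent."""
        if axis not in self.boundary_labels:
            raise ConfigurationError(f"unknown axis {axis!r}; expected one of {AXES}")
        src_code, snk_code = self.boundary_labels[axis]
        src = self.labels == src_code
        snk = self.labels == snk_code
        if not src.any() or not snk.any():
            raise ConfigurationError(
                f"axis {axis}: source/sink labels ({src_code}, {snk_code}) "
                "must both be nonempty"
            )
        return src, snk


@dataclass
class CoordinateField:
    """A Laplace coordinate ``psi`` in [0, 1] defined on domain + Dirichlet voxels.

    Voxels outside the solve carry NaN.  ``residual`` is the final maximum
    absolute update (SOR) or the maximum stencil residual (direct solve).
    """

    psi: np.ndarray
    axis: str
    residual: float
    n_iter: int = 0


@dataclass
class AxisVectorField:
    """Unit vectors along one hippocampal axis; ``valid`` flags nonzero gradients."""

    vectors: np.ndarray  # (nx, ny, nz, 3), world-oriented, unit where valid
    valid: np.ndarray    # (nx, ny, nz) bool
    axis: str


def _neighbor_shifts():
    return [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]


def _shift(a: np.ndarray, d: tuple[int, int, int], fill):
    """Shift ``a`` by d with constant fill (no wraparound)."""
    out = np.full_like(a, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, s in enumerate(d):
        if s == 1:
            src[ax], dst[ax] = slice(0, -1), slice(1, None)
        elif s == -1:
            src[ax], dst[ax] = slice(1, None), slice(0, -1)
    out[tuple(dst)] = a[tuple(src)]
    return out


def solve_laplace(
    domain: LabeledVolume,
    axis: str,
    tol: float = 1e-6,
    max_iter: int = 50_000,
    omega: float = 1.8,
    method: str = "sor",
) -> CoordinateField:
    """Solve Laplace's equation for one axis on the labelled domain.

    Parameters
    ----------
    domain:
        Labelled volume; the axis's source and sink labels must be nonempty.
    axis:
        One of ``"AP"``, ``"PD"``, ``"IO"``.
    tol:
        SOR convergence threshold on the maximum absolute update per sweep.
    max_iter:
        Maximum SOR sweeps before raising :class:`ConvergenceError`.
    omega:
        Over-relaxation factor in (0, 2).
    method:
        ``"sor"`` (red-black Gauss-Seidel SOR) or ``"direct"`` (sparse LU of
        the identical stencil).

    Returns
    -------
    CoordinateField
        ``psi`` with 0 at source voxels, 1 at sink voxels, NaN elsewhere
        outside the solve.
    """
    if tol <= 0:
        raise ConfigurationError("tol must be positive")
    src, snk = domain.axis_masks(axis)
    dom = domain.domain_mask
    if not dom.any():
        raise ConfigurationError("empty grey-matter domain")

    included = dom | src | snk
    psi = np.zeros(domain.labels.shape, dtype=np.float64)
    psi[snk] = 1.0
    psi[dom] = 0.5

    h2inv = 1.0 / domain.spacing**2
    weights = [h2inv[0], h2inv[0], h2inv[1], h2inv[1], h2inv[2], h2inv[2]]

    if method == "direct":
        psi = _solve_direct(psi, dom, included, weights)
        residual = _stencil_residual(psi, dom, included, weights)
        n_iter = 0
    elif method == "sor":
        psi, residual, n_iter = _solve_sor(
            psi, dom, included, weights, tol, max_iter, omega
        )
    else:
        raise ConfigurationError(f"unknown solver method {method!r}")

    psi[~included] = np.nan
    logger.info(
        "laplace axis=%s method=%s residual=%.3e iters=%d", axis, method, residual, n_iter
    )
    return CoordinateField(psi=psi, axis=axis, residual=residual, n_iter=n_iter)


def _neighbor_sums(psi, included, weights):
    """Weighted neighbour sum and weight total, counting only included voxels."""
    num = np.zeros_like(psi)
    den = np.zeros_like(psi)
    for d, w in zip(_neighbor_shifts(), weights):
        inc = _shift(included, d, False)
        num += w * inc * _shift(psi, d, 0.0)
        den += w * inc
    return num, den


def _solve_sor(psi, dom, included, weights, tol, max_iter, omega):
    ii, jj, kk = np.indices(psi.shape, sparse=True)
    parity = (ii + jj + kk) % 2
    colors = [dom & (parity == c) for c in (0, 1)]
    residual = np.inf
    for it in range(1, max_iter + 1):
        max_delta = 0.0
        for color in colors:
            num, den = _neighbor_sums(psi, included, weights)
            upd = color & (den > 0)
            delta = omega * (num[upd] / den[upd] - psi[upd])
            psi[upd] += delta
            if delta.size:
                max_delta = max(max_delta, float(np.max(np.abs(delta))))
        residual = max_delta
        if residual < tol:
            return psi, residual, it
    raise ConvergenceError(
        f"SOR did not converge in {max_iter} sweeps (final max update {residual:.3e})",
        residual=residual,
    )


def _solve_direct(psi, dom, included, weights):
    shape = psi.shape
    idx = -np.ones(shape, dtype=np.int64)
    idx[dom] = np.arange(int(dom.sum()))
    n = int(dom.sum())
    rows, cols, vals = [], [], []
    b = np.zeros(n)
    diag = np.zeros(n)
    flat_dom = idx[dom]
    for d, w in zip(_neighbor_shifts(), weights):
        inc = _shift(included, d, False)
        ndom = _shift(dom, d, False)
        nval = _shift(psi, d, 0.0)
        nidx = _shift(idx, d, -1)
        sel = inc[dom]
        diag[flat_dom] += w * sel
        interior = ndom[dom]
        rows.append(flat_dom[interior])
        cols.append(nidx[dom][interior])
        vals.append(np.full(int(interior.sum()), -w))
        dirich = sel & ~interior
        b[flat_dom[dirich]] += w * nval[dom][dirich]
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    # isolated voxels (no included neighbour) get psi = current value
    iso = diag == 0
    diag[iso] = 1.0
    b[iso] = psi[dom][iso]
    vals.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    sol = spla.spsolve(A.tocsc(), b)
    out = psi.copy()
    out[dom] = sol
    return out


def _stencil_residual(psi, dom, included, weights):
    num, den = _neighbor_sums(psi, included, weights)
    ok = dom & (den > 0)
    if not ok.any():
        return 0.0
    return float(np.max(np.abs(num[ok] / den[ok] - psi[ok])))


def compute_gradient_field(
    coord: CoordinateField, domain: LabeledVolume, min_norm: float = 1e-8
) -> AxisVectorField:
    """Normalised world-frame gradient of a Laplace coordinate.

    Central differences on the interior, one-sided where only one neighbour
    carries a value (Dirichlet voxels participate, giving correct one-sided
    stencils at the walls).  The voxel-index gradient is mapped to world space
    through the inverse-transpose of the affine's 3x3 block, then normalised.
    Voxels whose gradient magnitude falls below ``min_norm`` are flagged
    invalid and carry a zero vector.
    """
    psi = coord.psi
    dom = domain.domain_mask
    if not np.isfinite(psi[dom]).all():
        raise DataError("psi contains non-finite values on the domain")
    has_val = np.isfinite(psi)
    pz = np.where(has_val, psi, 0.0)

    grad = np.zeros(psi.shape + (3,), dtype=np.float64)
    for ax in range(3):
        d_plus = tuple(1 if a == ax else 0 for a in range(3))
        d_minus = tuple(-1 if a == ax else 0 for a in range(3))
        vp = _shift(pz, d_minus, 0.0)     # value at i+1 brought to i
        hp = _shift(has_val, d_minus, False)
        vm = _shift(pz, d_plus, 0.0)      # value at i-1 brought to i
        hm = _shift(has_val, d_plus, False)
        g = np.zeros_like(psi)
        both = hp & hm
        g[both] = (vp[both] - vm[both]) / 2.0
        fwd = hp & ~hm
        g[fwd] = vp[fwd] - pz[fwd]
        bwd = hm & ~hp
        g[bwd] = pz[bwd] - vm[bwd]
        grad[..., ax] = g

    # voxel-index gradient -> world: g_world = inv(A3).T @ g_index
    A3 = domain.affine[:3, :3]
    M = np.linalg.inv(A3).T
    grad = grad @ M.T

    norm = np.linalg.norm(grad, axis=-1)
    valid = dom & (norm > min_norm)
    vectors = np.zeros_like(grad)
    vectors[valid] = grad[valid] / norm[valid, None]
    return AxisVectorField(vectors=vectors, valid=valid, axis=coord.axis)


def compute_all_axes(
    domain: LabeledVolume,
    tol: float = 1e-6,
    max_iter: int = 50_000,
    omega: float = 1.8,
    method: str = "sor",
) -> dict[str, tuple[CoordinateField, AxisVectorField]]:
    """Solve all three axes and return {axis: (CoordinateField, AxisVectorField)}."""
    out = {}
    for axis in AXES:
        coord = solve_laplace(
            domain, axis, tol=tol, max_iter=max_iter, omega=omega, method=method
        )
        vec = compute_gradient_field(coord, domain)
        n_invalid = int((domain.domain_mask & ~vec.valid).sum())
        logger.info(
            "axis %s: residual %.3e, %d invalid-gradient voxels", axis, coord.residual, n_invalid
        )
        out[axis] = (coord, vec)
    return out


def frame_orthogonality(
    fields: dict[str, tuple[CoordinateField, AxisVectorField]] | dict[str, AxisVectorField],
) -> dict[str, float]:
    """QC: mean absolute pairwise cosine between the three axis fields.

    Solver-derived frames are not exactly orthogonal; this reports, per axis
    pair, the mean |cos| over voxels valid in both fields (0 = orthogonal).
    """
    vecs = {}
    for axis, f in fields.items():
        v = f[1] if isinstance(f, tuple) else f
        vecs[axis] = v
    out = {}
    names = list(vecs)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = vecs[names[i]], vecs[names[j]]
            both = a.valid & b.valid
            dots = np.abs(np.sum(a.vectors[both] * b.vectors[both], axis=-1))
            out[f"{names[i]}-{names[j]}"] = float(dots.mean()) if dots.size else np.nan
    return out
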