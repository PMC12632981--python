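"""Analytic phantoms and synthetic cohorts with known ground truth.

The geometric phantom is a voxelised cylindrical-shell sector standing in for
the hippocampal grey-matter sheet: the anterior-posterior (AP) axis runs
along the cylinder, proximal-distal (PD) around it and inner-outer (IO)
across the shell.  All three Laplace coordinates are then closed-form —
``psi_AP = z/L`` (linear), ``psi_PD = (theta-theta0)/(theta1-theta0)``
(angular) and ``psi_IO = ln(r/r0)/ln(r1/r0)`` (log-radial) — each harmonic,
with mutually orthogonal analytic gradient frames (z-hat, theta-hat, r-hat).
Dirichlet boundary labels are painted on the corresponding walls so the
numerical solver can be validated against the closed forms.  A midthickness
surface at r = sqrt(r0*r1) carries unfolded (u, v) coordinates, five
contiguous subfield bands of deliberately unequal width along PD, and
head/body/tail tertiles along AP.

Synthetic DWI is generated from the forward tensor model with the principal
eigenvector set to a controlled blend of the local axis frame, optionally
degraded with Rician noise at a chosen SNR.  Synthetic cohorts emulate a
three-group cross-sectional study (AD / MCI / CN) with multiplicative group
effects, linear age trends, per-participant offsets and spatially smoothed
vertex noise; every draw is reproducible from (spec, seed) with one RNG
stream per participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .dti import (
    DWIVolume,
    GradientScheme,
    TensorVolume,
    predict_signal,
    tensor_from_eigensystem,
)
from .errors import ConfigurationError, DataError
from .laplace import (
    DEFAULT_BOUNDARY_LABELS,
    AxisVectorField,
    CoordinateField,
    LabeledVolume,
)
from .surface import AP_BINS, SUBFIELDS, HippSurface

#: default PD widths of the five subfield bands (unequal on purpose; CA2 small)
SUBFIELD_PROPORTIONS = (0.28, 0.30, 0.08, 0.12, 0.22)


# ---------------------------------------------------------------------------
# geometric phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    r0: float = 8.0            # inner shell radius, voxels
    r1: float = 14.0           # outer shell radius, voxels
    theta0: float = 0.0        # angular sector, radians
    theta1: float = np.pi
    length: int = 40           # AP extent, voxels
    spacing: float = 1.0       # isotropic voxel size, mm
    pad: int = 3               # in-plane padding beyond r1
    surface_nu: int = 64       # surface grid along AP
    surface_nv: int = 32       # surface grid along PD
    subfield_proportions: tuple = SUBFIELD_PROPORTIONS
    seed: int = 0

    def __post_init__(self):
        if not self.r0 < self.r1:
            raise ConfigurationError("need r0 < r1")
        if not self.theta0 < self.theta1 <= self.theta0 + 2 * np.pi - 1e-6:
            raise ConfigurationError("need theta0 < theta1 with an open sector")
        if self.length < 8:
            raise ConfigurationError("length must be >= 8 voxels")
        if abs(sum(self.subfield_proportions) - 1.0) > 1e-9:
            raise ConfigurationError("subfield proportions must sum to 1")


@dataclass
class Phantom:
    spec: PhantomSpec
    volume: LabeledVolume
    analytic_coords: dict[str, CoordinateField]
    analytic_axes: dict[str, AxisVectorField]
    surface: HippSurface
    interior: np.ndarray = None  # domain voxels >= 3 voxels from any wall


def make_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Voxelise the cylindrical-shell sector and its analytic coordinate frame."""
    spec = spec or PhantomSpec()
    r0, r1, th0, th1, L = spec.r0, spec.r1, spec.theta0, spec.theta1, spec.length
    # even grid: the cylinder axis sits on a voxel corner, never a voxel centre,
    # so no voxel centre can fall exactly on a wall circle (degenerate clamping)
    n_xy = 2 * int(np.ceil(r1 + spec.pad))
    nz = L + 2
    c = (n_xy - 1) / 2.0
    ii, jj, kk = np.meshgrid(
        np.arange(n_xy), np.arange(n_xy), np.arange(nz), indexing="ij"
    )
    x, y = ii - c, jj - c
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)
    # angular offset from theta0, wrapped to [0, 2*pi) so any sector placement works
    delta = np.mod(theta - th0, 2 * np.pi)
    span = th1 - th0

    in_annulus = (r >= r0) & (r <= r1)
    in_sector = delta <= span
    in_z = (kk >= 1) & (kk <= L)
    domain = in_annulus & in_sector & in_z

    labels = np.zeros((n_xy, n_xy, nz), dtype=np.int16)
    labels[domain] = 1
    ap_src, ap_snk = DEFAULT_BOUNDARY_LABELS["AP"]
    pd_src, pd_snk = DEFAULT_BOUNDARY_LABELS["PD"]
    io_src, io_snk = DEFAULT_BOUNDARY_LABELS["IO"]
    cross = in_annulus & in_sector
    labels[cross & (kk == 0)] = ap_src
    labels[cross & (kk == L + 1)] = ap_snk
    # PD walls: thin slabs just outside the angular sector
    below0 = np.mod(th0 - theta, 2 * np.pi)      # angle short of the theta0 wall
    above1 = np.mod(theta - th1, 2 * np.pi)      # angle past the theta1 wall
    d0 = r * np.sin(np.minimum(below0, np.pi / 2))
    d1 = r * np.sin(np.minimum(above1, np.pi / 2))
    free = labels == 0
    outside = ~in_sector
    pd_wall0 = free & in_annulus & in_z & outside & (below0 <= above1) & (d0 <= 1.8)
    pd_wall1 = free & in_annulus & in_z & outside & (above1 < below0) & (d1 <= 1.8)
    labels[pd_wall0] = pd_src
    labels[pd_wall1] = pd_snk
    # IO walls: one-to-two-voxel shells just inside r0 / outside r1
    free = labels == 0
    labels[free & in_sector & in_z & (r < r0) & (r >= r0 - 1.8)] = io_src
    labels[free & in_sector & in_z & (r > r1) & (r <= r1 + 1.8)] = io_snk

    affine = np.diag([spec.spacing] * 3 + [1.0])
    volume = LabeledVolume(labels=labels, spacing=np.full(3, spec.spacing), affine=affine)

    # analytic coordinates (NaN off the solved region)
    included = (labels == 1) | np.isin(labels, [ap_src, ap_snk, pd_src, pd_snk, io_src, io_snk])
    with np.errstate(divide="ignore", invalid="ignore"):
        psi_ap = kk / (L + 1.0)
        psi_pd = delta / span
        psi_pd[outside & (below0 <= above1)] = 0.0   # source side of the sector
        psi_pd[outside & (above1 < below0)] = 1.0    # sink side
        psi_io = np.log(np.where(r > 0, r, 1.0) / r0) / np.log(r1 / r0)
    coords = {}
    for axis, psi in (("AP", psi_ap), ("PD", psi_pd), ("IO", psi_io)):
        p = np.where(included, psi, np.nan)
        coords[axis] = CoordinateField(psi=p, axis=axis, residual=0.0)

    zero = np.zeros_like(r)
    vecs = {
        "AP": np.stack([zero, zero, np.ones_like(r)], axis=-1),
        "PD": np.stack([-np.sin(theta), np.cos(theta), zero], axis=-1),
        "IO": np.stack([np.cos(theta), np.sin(theta), zero], axis=-1),
    }
    axes = {
        axis: AxisVectorField(vectors=np.where(domain[..., None], v, 0.0), valid=domain.copy(), axis=axis)
        for axis, v in vecs.items()
    }

    surface = _make_surface(spec, c)
    interior = _erode(domain, 3)
    return Phantom(
        spec=spec, volume=volume, analytic_coords=coords, analytic_axes=axes,
        surface=surface, interior=interior,
    )


def _erode(mask: np.ndarray, n: int) -> np.ndarray:
    from scipy.ndimage import binary_erosion

    struct = np.zeros((3, 3, 3), dtype=bool)
    struct[1, 1, :] = struct[1, :, 1] = struct[:, 1, 1] = True
    return binary_erosion(mask, structure=struct, iterations=n)


def _make_surface(spec: PhantomSpec, c: float) -> HippSurface:
    nu, nv = spec.surface_nu, spec.surface_nv
    u = (np.arange(nu) + 0.5) / nu
    v = (np.arange(nv) + 0.5) / nv
    uu, vv = np.meshgrid(u, v, indexing="ij")
    r_mid = np.sqrt(spec.r0 * spec.r1)
    theta = spec.theta0 + vv * (spec.theta1 - spec.theta0)
    z = 0.5 + uu * spec.length
    verts = np.stack(
        [c + r_mid * np.cos(theta), c + r_mid * np.sin(theta), z], axis=-1
    ).reshape(-1, 3) * spec.spacing
    uv = np.stack([uu, vv], axis=-1).reshape(-1, 2)

    faces = []
    for i in range(nu - 1):
        for j in range(nv - 1):
            a = i * nv + j
            faces.append([a, a + nv, a + 1])
            faces.append([a + 1, a + nv, a + nv + 1])
    faces = np.asarray(faces, dtype=int)

    edges = np.concatenate([[0.0], np.cumsum(spec.subfield_proportions)])
    sf_idx = np.clip(np.searchsorted(edges, uv[:, 1], side="right") - 1, 0, 4)
    subfield = np.asarray(SUBFIELDS)[sf_idx]
    ap_idx = np.clip((uv[:, 0] * 3).astype(int), 0, 2)
    ap_bin = np.asarray(AP_BINS)[ap_idx]
    thickness = np.full(len(uv), (spec.r1 - spec.r0) * spec.spacing)
    gyr = 1.0 + 0.3 * np.sin(2 * np.pi * uv[:, 0]) * np.cos(np.pi * uv[:, 1])
    return HippSurface(
        vertices=verts, faces=faces, unfolded_uv=uv, subfield=subfield,
        ap_bin=ap_bin, thickness=thickness, gyrification=gyr,
    )


def make_annulus(
    r0: float = 8.0, r1: float = 14.0, n_slices: int = 3, pad: int = 3,
    spacing: float = 1.0,
) -> tuple[LabeledVolume, CoordinateField]:
    """Extruded full annulus with IO walls only, plus the log-radial closed form.

    The inner wall (clamped at psi = 0) is the one-voxel shell strictly inside
    r0 and the outer wall (psi = 1) strictly outside r1, anchoring the
    Dirichlet data at labelled voxel centres.
    """
    n_xy = 2 * int(np.ceil(r1 + pad))   # even: axis on a voxel corner (see make_phantom)
    c = (n_xy - 1) / 2.0
    ii, jj, kk = np.meshgrid(
        np.arange(n_xy), np.arange(n_xy), np.arange(n_slices), indexing="ij"
    )
    r = np.hypot(ii - c, jj - c)
    labels = np.zeros((n_xy, n_xy, n_slices), dtype=np.int16)
    io_src, io_snk = DEFAULT_BOUNDARY_LABELS["IO"]
    labels[(r >= r0) & (r <= r1)] = 1
    labels[(r < r0) & (r >= r0 - 1.8)] = io_src
    labels[(r > r1) & (r <= r1 + 1.8)] = io_snk
    volume = LabeledVolume(
        labels=labels, spacing=np.full(3, spacing),
        affine=np.diag([spacing] * 3 + [1.0]),
    )
    included = labels > 0
    with np.errstate(divide="ignore"):
        psi = np.log(np.where(r > 0, r, 1.0) / r0) / np.log(r1 / r0)
    psi = np.where(included, psi, np.nan)
    return volume, CoordinateField(psi=psi, axis="IO", residual=0.0)


# ---------------------------------------------------------------------------
# synthetic DWI
# ---------------------------------------------------------------------------

def make_gradient_scheme(n_dirs: int = 46, bval: float = 1.0, n_b0: int = 5) -> GradientScheme:
    """Fibonacci-hemisphere direction set with interleaved b = 0 rows."""
    if n_dirs < 6:
        raise ConfigurationError("need at least 6 gradient directions")
    i = np.arange(n_dirs)
    z = (i + 0.5) / n_dirs                     # upper hemisphere: antipodally distinct
    phi = i * np.pi * (3.0 - np.sqrt(5.0))     # golden angle
    rho = np.sqrt(1.0 - z**2)
    dirs = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    n_total = n_dirs + n_b0
    b0_pos = np.linspace(0, n_total - 1, n_b0).round().astype(int) if n_b0 else []
    bvals = np.full(n_total, float(bval))
    bvecs = np.zeros((n_total, 3))
    j = 0
    for k in range(n_total):
        if k in list(b0_pos):
            bvals[k] = 0.0
        else:
            bvecs[k] = dirs[j]
            j += 1
    return GradientScheme(bvals=bvals, bvecs=bvecs)


def make_dwi(
    phantom: Phantom,
    weights: tuple[float, float, float] = (1.0, 0.0, 0.0),
    eigenvalues: tuple[float, float, float] = (1.8, 0.3, 0.3),
    scheme: GradientScheme | None = None,
    snr: float | None = None,
    s0: float = 1000.0,
    seed: int = 0,
) -> tuple[DWIVolume, TensorVolume]:
    """Forward-simulate DWI with V1 a blend of the analytic axis frame.

    ``weights`` are the (AP, PD, IO) blend of the ground-truth principal
    eigenvector; ``eigenvalues`` are the tensor eigenvalues in um^2/ms.
    ``snr`` adds Rician noise of scale sigma = s0/snr to every measurement.
    Returns the noisy DWI volume and the noiseless ground-truth tensor.
    """
    w = np.asarray(weights, dtype=float)
    if np.linalg.norm(w) < 1e-12:
        raise ConfigurationError("zero mixture vector")
    lam = np.asarray(eigenvalues, dtype=float)
    if not (lam[0] >= lam[1] >= lam[2] > 0):
        raise ConfigurationError("eigenvalues must satisfy l1 >= l2 >= l3 > 0")
    dom = phantom.volume.domain_mask
    ap = phantom.analytic_axes["AP"].vectors[dom]
    pd_ = phantom.analytic_axes["PD"].vectors[dom]
    io = phantom.analytic_axes["IO"].vectors[dom]

    v1 = w[0] * ap + w[1] * pd_ + w[2] * io
    v1 /= np.linalg.norm(v1, axis=1, keepdims=True)
    v2 = None
    for cand in (pd_, io, ap):
        t = cand - np.sum(cand * v1, axis=1, keepdims=True) * v1
        n = np.linalg.norm(t, axis=1, keepdims=True)
        if np.all(n > 1e-8):
            v2 = t / n
            break
    if v2 is None:
        raise ConfigurationError("could not complete the eigenframe")
    v3 = np.cross(v1, v2)

    shape = dom.shape
    t6_flat = tensor_from_eigensystem(np.broadcast_to(lam, (len(v1), 3)), v1, v2, v3)
    t6 = np.zeros(shape + (6,))
    t6[dom] = t6_flat
    lam_sorted = np.sort(lam)[::-1]
    eigvals = np.zeros(shape + (3,))
    eigvals[dom] = lam_sorted
    v1_full = np.zeros(shape + (3,))
    v1_full[dom] = v1
    degen = np.zeros(shape, dtype=bool)
    degen[dom] = (lam[0] - lam[1]) < 1e-9
    truth = TensorVolume(
        tensor=t6,
        eigenvalues=eigvals,
        v1=v1_full,
        md=np.where(dom, lam.mean(), 0.0),
        s0=np.where(dom, s0, 0.0),
        valid=dom.copy(),
        non_spd=np.zeros(shape, dtype=bool),
        degenerate=degen | ~dom,
        affine=phantom.volume.affine,
    )
    scheme = scheme or make_gradient_scheme()
    dwi = predict_signal(truth, scheme)
    if snr is not None:
        rng = np.random.default_rng(seed)
        sigma = s0 / snr
        shape4 = dwi.signals.shape
        e1 = rng.normal(0.0, sigma, shape4)
        e2 = rng.normal(0.0, sigma, shape4)
        noisy = np.sqrt((dwi.signals + e1) ** 2 + e2**2)
        noisy[~dom] = 0.0
        dwi = DWIVolume(signals=noisy, scheme=scheme, mask=dom.copy())
    return dwi, truth


# ---------------------------------------------------------------------------
# synthetic cohorts
# ---------------------------------------------------------------------------

@dataclass
class MetricSpec:
    """How one surface metric behaves across the synthetic cohort.

    ``group_scale`` multiplies the baseline map per group; ``age_slope`` is
    an additive change per year of age (centred at the cohort mid-age);
    ``sigma_subject`` is a per-participant offset shared across the surface
    and hemispheres; ``sigma_vertex`` scales spatially smoothed vertex noise.
    """

    baseline: float
    pattern_amp: float = 0.1
    group_scale: dict = field(default_factory=dict)     # e.g. {"AD": 1.15}
    age_slope: dict = field(default_factory=dict)       # per group, units/yr
    sigma_subject: float = 0.0
    sigma_vertex: float = 0.0


#: group effects used by the effectful preset (CN is always the 1.0 baseline)
DEFAULT_METRICS: dict[str, MetricSpec] = {
    "thickness": MetricSpec(2.0, 0.15, {"AD": 0.90, "MCI": 0.96}, {}, 0.08, 0.15),
    "gyrification": MetricSpec(1.2, 0.15, {"AD": 0.94, "MCI": 0.98}, {}, 0.04, 0.08),
    "MD": MetricSpec(0.8, 0.10, {"AD": 1.15, "MCI": 1.07}, {}, 0.03, 0.05),
    "long_axis": MetricSpec(0.55, 0.20, {"AD": 1.08, "MCI": 1.03}, {}, 0.03, 0.06),
    "tangentiality": MetricSpec(0.50, 0.20, {"AD": 0.88, "MCI": 0.95}, {}, 0.03, 0.06),
    "radiality": MetricSpec(0.30, 0.20, {}, {}, 0.03, 0.06),
}


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort."""

    n_per_group: dict = field(
        default_factory=lambda: {"AD": 40, "MCI": 30, "CN": 50}
    )
    age_range: tuple[float, float] = (55.0, 90.0)
    metrics: dict[str, MetricSpec] = field(default_factory=lambda: dict(DEFAULT_METRICS))
    smooth_cells: float = 2.0
    hemispheres: tuple[str, ...] = ("L", "R")
    seed: int = 0

    def __post_init__(self):
        if any(n < 2 for n in self.n_per_group.values()):
            raise ConfigurationError("need n >= 2 per group")
        for name, m in self.metrics.items():
            if m.sigma_subject < 0 or m.sigma_vertex < 0:
                raise ConfigurationError(f"negative noise sigma for {name}")

    @classmethod
    def null(cls, seed: int = 0, **kw) -> "CohortSpec":
        """No group effects and no age trends; noise structure unchanged."""
        metrics = {
            k: replace(m, group_scale={}, age_slope={})
            for k, m in DEFAULT_METRICS.items()
        }
        return cls(metrics=metrics, seed=seed, **kw)

    @classmethod
    def with_effects(cls, seed: int = 0, **kw) -> "CohortSpec":
        """The default multiplicative group shifts (AD strongest, CN baseline)."""
        return cls(seed=seed, **kw)

    @classmethod
    def cn_age_slope(
        cls, metric: str = "MD", slope: float = 0.005, seed: int = 0, **kw
    ) -> "CohortSpec":
        """Null group effects plus a linear age trend in the CN group only."""
        spec = cls.null(seed=seed, **kw)
        spec.metrics[metric] = replace(spec.metrics[metric], age_slope={"CN": slope})
        return spec


@dataclass
class CohortData:
    spec: CohortSpec
    surface: HippSurface
    participants: pd.DataFrame        # participant, group, age, sex
    maps: dict                        # (participant, hemi, metric) -> (V,) array
    truth: dict

    def stacked(self, metric: str, hemi: str = "avg") -> np.ndarray:
        """(P, V) array of one metric; hemi 'L', 'R' or 'avg'."""
        rows = []
        for pid in self.participants["participant"]:
            if hemi == "avg":
                rows.append(
                    0.5 * (self.maps[(pid, "L", metric)] + self.maps[(pid, "R", metric)])
                )
            else:
                rows.append(self.maps[(pid, hemi, metric)])
        return np.stack(rows)

    def parcel_table(self, scheme: str = "subfield") -> pd.DataFrame:
        """Long table (participant, group, age, sex, hemi, metric, parcel, value)."""
        from .surface import SurfaceMetric, parcel_average

        rows = []
        meta = self.participants.set_index("participant")
        for (pid, hemi, metric), vals in self.maps.items():
            pa = parcel_average(
                SurfaceMetric(values=vals, name=metric), self.surface, scheme
            )
            for _, r in pa.iterrows():
                rows.append(
                    {
                        "participant": pid,
                        "group": meta.loc[pid, "group"],
                        "age": meta.loc[pid, "age"],
                        "sex": meta.loc[pid, "sex"],
                        "hemi": hemi,
                        "metric": metric,
                        "parcel": r["parcel"],
                        "value": r["mean"],
                    }
                )
        return pd.DataFrame(rows)


def _smooth_noise(rng, nu, nv, uv, smooth_cells):
    """Unit-variance spatially smoothed noise sampled at vertex uv coords."""
    grid = rng.normal(size=(nu, nv))
    if smooth_cells > 0:
        grid = gaussian_filter(grid, sigma=smooth_cells, mode="reflect")
        sd = grid.std()
        if sd > 0:
            grid = grid / sd
    iu = np.clip((uv[:, 0] * nu).astype(int), 0, nu - 1)
    iv = np.clip((uv[:, 1] * nv).astype(int), 0, nv - 1)
    return grid[iu, iv]


def make_cohort(spec: CohortSpec, surface: HippSurface) -> CohortData:
    """Generate per-participant vertex maps and covariates.

    Each participant draws from an independent RNG stream keyed by
    (spec.seed, participant index), so enlarging the cohort never perturbs
    existing participants.
    """
    uv = surface.unfolded_uv
    age_mid = 0.5 * (spec.age_range[0] + spec.age_range[1])
    nu, nv = 64, 32  # noise raster; coarser than typical vertex spacing

    patterns = {}
    for mi, (metric, ms) in enumerate(spec.metrics.items()):
        phase = 2.0 * np.pi * mi / max(len(spec.metrics), 1)
        patterns[metric] = 1.0 + ms.pattern_amp * np.sin(
            2 * np.pi * uv[:, 0] + phase
        ) * np.cos(np.pi * uv[:, 1])

    rows = []
    maps = {}
    idx = 0
    for group, n in spec.n_per_group.items():
        for i in range(n):
            rng = np.random.default_rng([spec.seed, idx])
            pid = f"sub-{group}{i:03d}"
            age = rng.uniform(*spec.age_range)
            sex = "M" if rng.integers(2) else "F"
            rows.append({"participant": pid, "group": group, "age": age, "sex": sex})
            for metric, ms in spec.metrics.items():
                scale = ms.group_scale.get(group, 1.0)
                slope = ms.age_slope.get(group, 0.0)
                offset = rng.normal(0.0, ms.sigma_subject) if ms.sigma_subject else 0.0
                base = ms.baseline * patterns[metric] * scale + slope * (age - age_mid) + offset
                for hemi in spec.hemispheres:
                    noise = (
                        ms.sigma_vertex
                        * _smooth_noise(rng, nu, nv, uv, spec.smooth_cells)
                        if ms.sigma_vertex
                        else 0.0
                    )
                    maps[(pid, hemi, metric)] = base + noise
            idx += 1

    participants = pd.DataFrame(rows)
    truth = {
        "group_scale": {m: dict(ms.group_scale) for m, ms in spec.metrics.items()},
        "age_slope": {m: dict(ms.age_slope) for m, ms in spec.metrics.items()},
        "baseline": {m: ms.baseline for m, ms in spec.metrics.items()},
    }
    return CohortData(
        spec=spec, surface=surface, participants=participants, maps=maps, truth=truth
    )
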