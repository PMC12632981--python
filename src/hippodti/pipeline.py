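"""Participant- and group-level orchestration with file I/O and provenance.

``run_participant`` chains the volumetric stages — Laplace axis fields,
tensor fit, orientation metrics — then samples everything to the
midthickness surface and writes parcel tables, with a JSON provenance record
(config hash, solver residuals, QC counts).  ``run_group`` applies the
group-level decision logic: per-metric hemisphere x group interaction
screening (hemispheres averaged where the interaction is not significant),
parcel-level Welch ANOVA + Games-Howell with FDR, vertex-wise age and group
contrast maps, and spin-test correlation matrices with Bonferroni families
of 3 (age maps across groups) and 5 (each metric against the other five).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .dti import fit_tensor
from .errors import ConfigurationError, DataError
from .groupstats import (
    age_contrast_maps,
    hemisphere_group_screen,
    subfield_group_analysis,
    vertexwise_contrast,
)
from .laplace import compute_all_axes, frame_orthogonality
from .orientation import orientation_metrics
from .spintest import correlate_map_set, resample_to_grid
from .surface import SurfaceMetric, parcel_average, sample_orientation, sample_scalar

logger = logging.getLogger(__name__)

VOLUME_METRIC_NAMES = ("MD", "long_axis", "tangentiality", "radiality")


@dataclass
class RunConfig:
    labels: str = ""
    dwi: str = ""
    bval: str = ""
    bvec: str = ""
    surface_vertices: str = ""
    surface_faces: str = ""
    out_dir: str = "out"
    solver_tol: float = 1e-6
    solver_max_iter: int = 50_000
    solver_omega: float = 1.8
    solver_method: str = "sor"
    alpha_anova: float = 0.05
    alpha_posthoc: float = 0.01
    n_perm: int = 1000
    spin_grid: tuple[int, int] = (64, 32)
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.alpha_anova < 1 and 0 < self.alpha_posthoc < 1):
            raise ConfigurationError("alpha levels must lie in (0, 1)")
        if self.n_perm < 100:
            raise ConfigurationError("n_perm must be >= 100")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_participant(config: RunConfig) -> dict:
    """Volumetric + surface metric extraction for one participant.

    Writes psi/vector/tensor/orientation NIfTI volumes, per-vertex metric
    TSVs, a parcel table TSV and ``provenance.json``.  Deterministic: a rerun
    with the same config overwrites identical outputs.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    volume = hio.load_labeled_volume(config.labels)
    scheme = hio.read_bvals_bvecs(config.bval, config.bvec)
    signals, dwi_affine = hio.load_nifti(config.dwi)
    surface = hio.read_surface_tsv(config.surface_vertices, config.surface_faces)

    qc = {}
    fields = compute_all_axes(
        volume,
        tol=config.solver_tol,
        max_iter=config.solver_max_iter,
        omega=config.solver_omega,
        method=config.solver_method,
    )
    qc["solver_residuals"] = {a: f[0].residual for a, f in fields.items()}
    qc["invalid_gradient_voxels"] = {
        a: int((volume.domain_mask & ~f[1].valid).sum()) for a, f in fields.items()
    }
    qc["frame_orthogonality_mean_abs_cos"] = frame_orthogonality(fields)
    for axis, (coord, vec) in fields.items():
        hio.save_nifti(np.nan_to_num(coord.psi), volume.affine, out / f"psi_{axis}.nii.gz")
        hio.save_nifti(vec.vectors, volume.affine, out / f"grad_{axis}.nii.gz")

    from .dti import DWIVolume

    dwi = DWIVolume(signals=signals, scheme=scheme, mask=volume.domain_mask)
    tensor = fit_tensor(dwi)
    tensor.affine = volume.affine
    qc["non_spd_voxels"] = int(tensor.non_spd.sum())
    qc["degenerate_voxels"] = int((tensor.degenerate & tensor.valid).sum())
    hio.save_nifti(tensor.md, volume.affine, out / "md.nii.gz")
    hio.save_nifti(tensor.v1, volume.affine, out / "v1.nii.gz")
    hio.save_nifti(tensor.tensor, volume.affine, out / "tensor.nii.gz")

    axes = {a: f[1] for a, f in fields.items()}
    om = orientation_metrics(tensor, axes["AP"], axes["PD"], axes["IO"])
    for name, vol in om.as_dict().items():
        hio.save_nifti(vol, volume.affine, out / f"{name}.nii.gz")

    md_metric = sample_scalar(
        tensor.md, surface, volume.affine,
        valid_mask=tensor.valid & ~tensor.non_spd, name="MD",
    )
    orient_metrics = sample_orientation(tensor, axes, surface, volume.affine)
    vertex_metrics = {"MD": md_metric, **orient_metrics}
    rows = []
    for name, metric in vertex_metrics.items():
        hio.write_metric_tsv(metric, out / f"vertex_{name}.tsv")
        for scheme_name in ("subfield", "ap_bin"):
            pa = parcel_average(metric, surface, scheme=scheme_name)
            for _, r in pa.iterrows():
                rows.append(
                    {"metric": name, "scheme": scheme_name, "parcel": r["parcel"],
                     "n_vertices": r["n_vertices"], "mean": r["mean"]}
                )
    parcels = pd.DataFrame(rows)
    parcels.to_csv(out / "parcels.tsv", sep="\t", index=False, float_format="%.10g")

    provenance = {
        "config_hash": config.digest(),
        "config": {k: str(v) for k, v in config.__dict__.items()},
        "qc": qc,
        "elapsed_s": round(time.time() - t0, 3),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=float))
    return {"parcels": parcels, "vertex_metrics": vertex_metrics, "qc": qc}


def run_group(
    config: RunConfig,
    cohort,
    metrics: list[str] | None = None,
) -> dict:
    """Group-level statistics on a synthetic cohort bundle.

    ``cohort`` is a :class:`hippodti.synthetic.CohortData`.  Stages: Eq-style
    hemisphere x group screening on whole-surface means, hemisphere averaging
    where warranted, parcel ANOVAs (subfields and head/body/tail), per-group
    age-contrast maps with 3-way spin comparisons, and group-contrast maps
    correlated across metrics with a Bonferroni family of 5.
    """
    groups_present = set(cohort.participants["group"])
    if len(groups_present) < 2:
        raise DataError(">=2 groups required")
    metrics = metrics or sorted({k[2] for k in cohort.maps})
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # 1. hemisphere x group interaction screen on whole-surface means
    rows = []
    meta = cohort.participants.set_index("participant")
    for (pid, hemi, metric), vals in cohort.maps.items():
        if metric not in metrics:
            continue
        rows.append(
            {"participant": pid, "group": meta.loc[pid, "group"],
             "age": meta.loc[pid, "age"], "sex": meta.loc[pid, "sex"],
             "hemi": hemi, "metric": metric, "value": float(np.nanmean(vals))}
        )
    hemi_table = pd.DataFrame(rows)
    screen = hemisphere_group_screen(hemi_table, metrics, alpha=config.alpha_anova)
    screen.to_csv(out / "hemisphere_screen.tsv", sep="\t", index=False)

    # 2. parcel-level Welch ANOVA + Games-Howell, per scheme
    parcel_reports = {}
    for scheme_name in ("subfield", "ap_bin"):
        table = cohort.parcel_table(scheme=scheme_name)
        avg_metrics = set(screen.loc[screen["average_hemispheres"], "metric"])
        keep = table["metric"].isin(avg_metrics)
        averaged = (
            table[keep]
            .groupby(["participant", "group", "age", "sex", "metric", "parcel"],
                     as_index=False)["value"].mean()
        )
        averaged["hemi"] = "avg"
        full = pd.concat([averaged, table[~keep]], ignore_index=True)
        reports = []
        for metric in metrics:
            rep = subfield_group_analysis(
                full, metric,
                alpha_anova=config.alpha_anova, alpha_posthoc=config.alpha_posthoc,
            )
            rep.insert(0, "metric", metric)
            reports.append(rep)
        parcel_reports[scheme_name] = pd.concat(reports, ignore_index=True)
        parcel_reports[scheme_name].to_csv(
            out / f"group_stats_{scheme_name}.tsv", sep="\t",
            index=False, float_format="%.8g",
        )

    # 3. vertex-wise contrast maps + spin matrices
    if not any(k[2] == "thickness" for k in cohort.maps):
        raise DataError("cohort must include vertex-wise thickness maps")
    thickness = cohort.stacked("thickness")
    spin_age = {}
    spin_group = {}
    covars = cohort.participants
    group_maps_by_metric = {}
    for metric in metrics:
        maps = cohort.stacked(metric)
        age_maps = age_contrast_maps(maps, covars, thickness)
        rasters = {
            g: resample_to_grid(
                SurfaceMetric(values=cm.t, name=metric, valid=cm.valid),
                cohort.surface, grid=config.spin_grid,
            )
            for g, cm in age_maps.items()
        }
        if len(rasters) >= 2:
            spin_age[metric] = correlate_map_set(
                rasters, n_perm=config.n_perm, seed=config.seed,
                n_comparisons=3,
            )
        gm = {}
        for contrast in ("group:MCI", "group:CN"):
            cm = vertexwise_contrast(maps, covars, thickness, contrast)
            gm[contrast] = cm
        group_maps_by_metric[metric] = gm

    cn_rasters = {
        metric: resample_to_grid(
            SurfaceMetric(values=gm["group:CN"].t, name=metric, valid=gm["group:CN"].valid),
            cohort.surface, grid=config.spin_grid,
        )
        for metric, gm in group_maps_by_metric.items()
    }
    if len(cn_rasters) >= 2:
        spin_group = correlate_map_set(
            cn_rasters, n_perm=config.n_perm, seed=config.seed + 1,
            n_comparisons=max(len(cn_rasters) - 1, 1),
        )
        spin_group["R"].to_csv(out / "spin_group_R.tsv", sep="\t")
        spin_group["p"].to_csv(out / "spin_group_p.tsv", sep="\t")

    meta_json = {
        "seed": config.seed, "n_perm": config.n_perm,
        "grid": list(config.spin_grid), "config_hash": config.digest(),
    }
    (out / "group_run.json").write_text(json.dumps(meta_json, indent=2))
    return {
        "hemisphere_screen": screen,
        "parcel_reports": parcel_reports,
        "spin_age": spin_age,
        "spin_group": spin_group,
        "group_maps": group_maps_by_metric,
    }
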