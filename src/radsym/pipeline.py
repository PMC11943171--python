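"""End-to-end pairwise and atlas analysis runs.

Two studies are orchestrated over a cohort directory of per-subject left and
right meshes with landmarks:

* **pairwise** — per subject: standardise the pair into a common frame
  (mirror, axis-align, crop, landmark-align, decimate), register the mirrored
  right onto the left, take per-vertex signed correspondence distances (whole
  bone and articular subset), then aggregate cohort tables, run kernel PCA on
  the standardised momenta and the group-test cascade.
* **atlas** — standardise every mesh (both sides, right mirrored) into the
  frame of the first subject's right bone, estimate a deterministic atlas
  from that bone as template, average the deformed templates into the mean
  shape, re-register the mean to every mesh, and report signed distances to
  the atlas plus momenta kPCA and group tests.

Every run writes a manifest with the full configuration and seed; rerunning
from the same manifest reproduces the tables byte for byte. Subject failures
are logged and skipped; a run fails only if every subject fails.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .io import read_landmarks, read_mesh, write_landmarks, write_mesh
from .mesh import LandmarkSet, SurfaceMesh
from .phantom import Cohort
from .preprocess import (
    PreprocessConfig,
    _cap_planar_boundary,
    articular_mask,
    crop_by_plane,
    mirror_x,
    preprocess_pair,
    principal_axis_align,
    rigid_align_landmarks,
    shift_lowest_to_origin,
)
from .decimate import decimate
from .registration import DeformationParams, deterministic_atlas, make_control_grid, register
from .stats import (
    boxplot_stats,
    build_mean_shape,
    group_tests,
    kpca_rbf,
    mean_landmarks,
    signed_distance,
    standardize_momenta,
    summarize_group,
    summarize_subject,
)

logger = logging.getLogger("radsym")

__all__ = ["RunConfig", "save_cohort", "load_cohort", "run_pairwise_analysis", "run_atlas_analysis"]


@dataclass
class RunConfig:
    """Configuration of one analysis run; serialised into every manifest."""

    mode: str = "pairwise"
    kernel_width: float = 2.0
    attachment_width: float = 4.0
    noise_std: float = 5e-4
    n_time_points: int = 10
    convergence_tol: float = 1e-4
    max_iterations: int = 80
    control_spacing: Optional[float] = None  # default: kernel width
    control_prune_mm: Optional[float] = None  # default: 2 x spacing
    crop_long_mm: float = 50.0
    crop_final_mm: float = 43.0
    target_vertices: int = 5295
    articular: bool = True
    kpca_components: int = 2
    kpca_gamma: Optional[float] = None
    seed: int = 0

    def deformation_params(self) -> DeformationParams:
        return DeformationParams(
            kernel_width=self.kernel_width,
            attachment_width=self.attachment_width,
            noise_std=self.noise_std,
            n_time_points=self.n_time_points,
            convergence_tol=self.convergence_tol,
            max_iterations=self.max_iterations,
        )

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(
            crop_long_mm=self.crop_long_mm,
            crop_final_mm=self.crop_final_mm,
            target_vertices=self.target_vertices,
        )

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Cohort directory layout
# ---------------------------------------------------------------------------


def save_cohort(cohort: Cohort, out_dir) -> Path:
    """Write a cohort to disk: meshes (VTK), landmarks (CSV), metadata,
    per-vertex ground-truth asymmetry fields, and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        sd = out / f"subject_{s.subject_id:03d}"
        sd.mkdir(exist_ok=True)
        write_mesh(s.pair.left, sd / "left.vtk")
        write_mesh(s.pair.right, sd / "right.vtk")
        write_landmarks(s.pair.left_landmarks, sd / "left_landmarks.csv")
        write_landmarks(s.pair.right_landmarks, sd / "right_landmarks.csv")
        np.savetxt(sd / "ground_truth_displacement.txt", s.pair.ground_truth, fmt="%.10g")
    cohort.metadata.to_csv(out / "metadata.csv", index=False)
    manifest = {
        "params": dataclasses.asdict(cohort.params),
        "n_subjects": len(cohort.subjects),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out


def load_cohort(cohort_dir) -> List[Dict]:
    """Read a cohort directory into per-subject records."""
    root = Path(cohort_dir)
    meta = pd.read_csv(root / "metadata.csv")
    subjects = []
    for _, row in meta.iterrows():
        sd = root / f"subject_{int(row['subject_id']):03d}"
        subjects.append(
            {
                "subject_id": int(row["subject_id"]),
                "group": row["group"],
                "left": read_mesh(sd / "left.vtk"),
                "right": read_mesh(sd / "right.vtk"),
                "left_landmarks": read_landmarks(sd / "left_landmarks.csv"),
                "right_landmarks": read_landmarks(sd / "right_landmarks.csv"),
            }
        )
    return subjects


def _write_manifest(out: Path, config: RunConfig, extra: Dict) -> None:
    manifest = {"config": config.to_dict(), **extra}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))


def _subject_table(per_subject: List[Dict], region: str) -> pd.DataFrame:
    rows = [
        {
            "patient": f"{r['subject_id']:03d}",
            "group": r["group"],
            "mean_mm": r[f"{region}_mean_mm"],
            "sd_mm": r[f"{region}_sd_mm"],
        }
        for r in per_subject
    ]
    return pd.DataFrame(rows)


def _cohort_csvs(per_subject, out, prefix):
    """Cohort CSVs in the reference-table layout: per-subject rows plus
    group aggregation rows."""
    for region in ("whole", "articular"):
        tab = _subject_table(per_subject, region)
        tab.to_csv(out / f"{prefix}_{region}_per_subject.csv", index=False)
        summarize_group(tab).to_csv(out / f"{prefix}_{region}_groups.csv", index=False)


# ---------------------------------------------------------------------------
# Pairwise analysis
# ---------------------------------------------------------------------------


def run_pairwise_analysis(cohort_dir, config: RunConfig, out_dir) -> Path:
    """Intra-individual (left vs mirrored right) symmetry analysis."""
    out = Path(out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    (out / "meshes").mkdir(exist_ok=True)
    (out / "figures").mkdir(exist_ok=True)
    subjects = load_cohort(cohort_dir)
    params = config.deformation_params()
    spacing = config.control_spacing or config.kernel_width
    prune = config.control_prune_mm or 2.0 * spacing

    per_subject, momenta, groups, fields, failures = [], [], [], [], []
    grid = None
    for s in subjects:
        t0 = time.time()
        try:
            L, Llm, R, Rlm = preprocess_pair(
                s["left"], s["left_landmarks"], s["right"], s["right_landmarks"],
                config.preprocess_config(),
            )
            if grid is None:
                # one shared control grid: all subjects live in the same
                # standardised frame, and shared controls make the momenta
                # directly comparable across subjects
                grid = make_control_grid(L, spacing, prune_distance=prune)
            res = register(R, L, params, control_points=grid)
            mask = articular_mask(R, Llm)
            fld = signed_distance(R, res.deformed_source, articular_mask=mask)
            rec = {"subject_id": s["subject_id"], "group": s["group"]}
            for region in ("whole", "articular"):
                stats_r = summarize_subject(fld, region)
                rec.update({f"{region}_{k}": v for k, v in stats_r.items()})
            rec["converged"] = res.converged
            per_subject.append(rec)
            momenta.append(res.state.momenta)
            groups.append(s["group"])
            fields.append((s["subject_id"], fld))
            write_mesh(
                R,
                out / "meshes" / f"subject_{s['subject_id']:03d}_signed_distance.vtk",
                point_scalars={"signed_distance_mm": fld.signed_distance_mm},
            )
            logger.info(
                "pairwise subject %03d done in %.1fs (converged=%s)",
                s["subject_id"], time.time() - t0, res.converged,
            )
        except Exception as exc:  # graceful degradation on cohort jobs
            failures.append({"subject_id": s["subject_id"], "error": str(exc)})
            logger.warning("pairwise subject %03d failed: %s", s["subject_id"], exc)
    if not per_subject:
        raise RuntimeError(f"all {len(subjects)} subjects failed: {failures}")

    _cohort_csvs(per_subject, out / "tables", "pairwise")
    _boxplot_outputs(fields, out, "pairwise")
    test_table = _momenta_tests(momenta, groups, config, out / "tables", "pairwise")
    _write_manifest(
        out, config,
        {"mode": "pairwise", "n_subjects": len(per_subject), "failures": failures},
    )
    return out


def _boxplot_outputs(fields, out: Path, prefix: str) -> None:
    rows = []
    for sid, fld in fields:
        rows.append({"patient": f"{sid:03d}" if isinstance(sid, int) else sid,
                     **boxplot_stats(fld.signed_distance_mm)})
    pd.DataFrame(rows).to_csv(out / "tables" / f"{prefix}_boxplot_data.csv", index=False)
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(max(6, len(fields)), 4))
        ax.boxplot(
            [fld.signed_distance_mm for _, fld in fields],
            tick_labels=[str(sid) for sid, _ in fields],
        )
        ax.set_ylabel("signed distance (mm)")
        ax.set_xlabel("subject")
        ax.axhline(0.0, color="0.6", lw=0.5)
        fig.tight_layout()
        fig.savefig(out / "figures" / f"{prefix}_signed_distance_boxplot.png", dpi=120)
        plt.close(fig)
    except Exception as exc:  # plotting must never sink a cohort run
        logger.warning("figure generation failed: %s", exc)


def _momenta_tests(momenta, groups, config: RunConfig, tables: Path, prefix: str):
    if len(momenta) < 3 or len(set(groups)) < 2:
        return None
    Z, _, _ = standardize_momenta(momenta)
    kp = kpca_rbf(Z, gamma=config.kpca_gamma, n_components=config.kpca_components)
    scores = pd.DataFrame(
        {f"PC{i+1}": kp.scores[:, i] for i in range(kp.scores.shape[1])}
    )
    scores.insert(0, "group", list(groups))
    scores.to_csv(tables / f"{prefix}_kpca_scores.csv", index=False)
    pd.DataFrame({"eigenvalue": kp.eigenvalues}).to_csv(
        tables / f"{prefix}_kpca_eigenvalues.csv", index=False
    )
    counts = pd.Series(groups).value_counts()
    if counts.min() < 3:
        return None
    tests = group_tests(kp.scores, groups)
    tests.to_csv(tables / f"{prefix}_group_tests.csv", index=False)
    return tests


# ---------------------------------------------------------------------------
# Atlas analysis
# ---------------------------------------------------------------------------


def _standardize_to_reference(mesh, lm, ref_mesh, ref_lm, config: RunConfig):
    """Axis-align, crop, then rigidly align onto the reference via
    RS/DSN/DDR + centroid; final crop and decimation in the reference frame.

    As in pairwise preprocessing, the centroid correspondence is refined on
    the final crop: the reference centroid belongs to a 43 mm segment, so
    the subject's centroid is recomputed on its own 43 mm crop and the
    alignment re-estimated until stable.
    """
    mesh, lm, _ = principal_axis_align(mesh, lm)
    mesh, lm = shift_lowest_to_origin(mesh, lm)
    z_max = mesh.vertices[:, 2].max()
    if z_max > config.crop_long_mm:
        mesh = crop_by_plane(mesh, (0, 0, z_max - config.crop_long_mm), (0, 0, 1), "above")
        mesh, lm = shift_lowest_to_origin(mesh, lm)
    names = ["RS", "DSN"] + (["DDR"] if "DDR" in lm and "DDR" in ref_lm else [])
    z_top = ref_mesh.vertices[:, 2].max()
    plane = np.array([0.0, 0.0, z_top - config.crop_final_mm])
    up = np.array([0.0, 0.0, 1.0])
    tgt_lm = ref_lm.as_array(names)
    ref_centroid = ref_mesh.centroid()

    src = np.vstack([lm.as_array(names), mesh.centroid()[None, :]])
    xf = rigid_align_landmarks(src, np.vstack([tgt_lm, ref_centroid[None, :]]))
    mesh0, lm0 = mesh, lm
    for _ in range(3):
        aligned = SurfaceMesh(xf.apply(mesh0.vertices), mesh0.faces)
        aligned_lm = lm0.transformed(xf.apply)
        cropped = crop_by_plane(aligned, plane, up, "above")
        src = np.vstack([aligned_lm.as_array(names), cropped.centroid()[None, :]])
        xf_new = rigid_align_landmarks(src, np.vstack([tgt_lm, ref_centroid[None, :]])).compose(xf)
        delta = np.abs(xf_new.apply(mesh0.centroid()) - xf.apply(mesh0.centroid())).max()
        xf = xf_new
        if delta < 1e-9:
            break
    mesh = SurfaceMesh(xf.apply(mesh0.vertices), mesh0.faces)
    lm = lm0.transformed(xf.apply)
    mesh = crop_by_plane(mesh, plane, up, "above")
    if config.target_vertices and mesh.n_vertices > config.target_vertices:
        mesh = decimate(mesh, config.target_vertices)
    mesh = _cap_planar_boundary(mesh, plane, up, tol=1.0, snap=True)
    return mesh, lm


def run_atlas_analysis(cohort_dir, config: RunConfig, out_dir) -> Path:
    """Inter-individual analysis against the estimated mean shape."""
    out = Path(out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    (out / "meshes").mkdir(exist_ok=True)
    (out / "figures").mkdir(exist_ok=True)
    subjects = load_cohort(cohort_dir)
    params = config.deformation_params()
    spacing = config.control_spacing or config.kernel_width
    prune = config.control_prune_mm or 2.0 * spacing

    # standardise every mesh (right sides mirrored first) into the frame of
    # the first subject's right bone; the reference itself runs through the
    # same standardisation path so a degenerate (identical) cohort stays
    # bitwise consistent
    ref_raw, ref_lm_raw = mirror_x(subjects[0]["right"], subjects[0]["right_landmarks"])
    ref0, ref0_lm, _ = principal_axis_align(ref_raw, ref_lm_raw)
    ref0, ref0_lm = shift_lowest_to_origin(ref0, ref0_lm)
    z_max = ref0.vertices[:, 2].max()
    if z_max > config.crop_long_mm:
        ref0 = crop_by_plane(ref0, (0, 0, z_max - config.crop_long_mm), (0, 0, 1), "above")
        ref0, ref0_lm = shift_lowest_to_origin(ref0, ref0_lm)
    ref, ref_lm = _standardize_to_reference(ref_raw, ref_lm_raw, ref0, ref0_lm, config)

    meshes, lms, labels, groups, failures = [], [], [], [], []
    for s in subjects:
        for side in ("l", "r"):
            try:
                if side == "r":
                    m, lm = mirror_x(s["right"], s["right_landmarks"])
                else:
                    m, lm = s["left"], s["left_landmarks"]
                m, lm = _standardize_to_reference(m, lm, ref, ref_lm, config)
                meshes.append(m)
                lms.append(lm)
                labels.append(f"{s['subject_id']:03d} {side}")
                groups.append(s["group"])
            except Exception as exc:
                failures.append({"subject_id": s["subject_id"], "side": side, "error": str(exc)})
                logger.warning("atlas standardisation failed for %s %s: %s",
                               s["subject_id"], side, exc)
    if not meshes:
        raise RuntimeError(f"all meshes failed standardisation: {failures}")

    # pass 1: deterministic atlas from the subject-1 template
    grid = make_control_grid(ref, spacing, prune_distance=prune)
    _, states, results = deterministic_atlas(ref, meshes, params, control_points=grid)
    mean_shape = build_mean_shape([r.deformed_source for r in results])
    mean_lm = mean_landmarks(lms)
    write_mesh(mean_shape, out / "meshes" / "atlas_mean_shape.vtk")

    # pass 2: register the mean shape to every mesh; distances atlas -> subject
    per_mesh, momenta, fields = [], [], []
    atlas_mask = articular_mask(mean_shape, mean_lm)
    grid2 = make_control_grid(mean_shape, spacing, prune_distance=prune)
    for label, grp, m in zip(labels, groups, meshes):
        t0 = time.time()
        res = register(mean_shape, m, params, control_points=grid2)
        fld = signed_distance(mean_shape, res.deformed_source, articular_mask=atlas_mask)
        sid, side = label.split()
        rec = {"patient": sid, "side": side, "group": grp, "converged": res.converged}
        for region in ("whole", "articular"):
            stats_r = summarize_subject(fld, region)
            rec.update({f"{region}_{k}": v for k, v in stats_r.items()})
        per_mesh.append(rec)
        momenta.append(res.state.momenta)
        fields.append((f"{sid}{side}", fld))
        logger.info("atlas registration %s done in %.1fs", label, time.time() - t0)

    tab_rows = [
        {"patient": r["patient"], "side": r["side"], "group": r["group"],
         "subject_id": int(r["patient"]),
         "whole_mean_mm": r["whole_mean_mm"], "whole_sd_mm": r["whole_sd_mm"],
         "articular_mean_mm": r["articular_mean_mm"], "articular_sd_mm": r["articular_sd_mm"]}
        for r in per_mesh
    ]
    tab = pd.DataFrame(tab_rows)
    tab.to_csv(out / "tables" / "atlas_per_mesh.csv", index=False)
    for region in ("whole", "articular"):
        g = summarize_group(tab.rename(columns={f"{region}_mean_mm": "mean_mm",
                                                f"{region}_sd_mm": "sd_mm"}))
        g.to_csv(out / "tables" / f"atlas_{region}_groups.csv", index=False)
    _boxplot_outputs(fields, out, "atlas")
    _momenta_tests(momenta, groups, config, out / "tables", "atlas")
    _write_manifest(out, config, {"mode": "atlas", "n_meshes": len(per_mesh),
                                  "failures": failures})
    return out
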