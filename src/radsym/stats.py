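"""Correspondence-distance statistics, cohort summaries, and momenta kPCA.

Once registration has put meshes into point-to-point correspondence, the
symmetry statistic is the signed Euclidean distance between corresponded
vertices: magnitude = pairwise distance, sign = direction of the displacement
relative to the source's outward normal (positive = outward). Per-subject and
group summaries are taken over the absolute distances (means in the cohort
tables are magnitudes; the sign lives in maps and boxplots). Group analysis
standardises the flattened momenta, applies RBF-kernel PCA, and runs a
Shapiro–Wilk / Kruskal–Wallis / pairwise Welch cascade on the first
principal-component scores at the 0.05 level with raw (uncorrected)
p-values; a Holm correction is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mesh import LandmarkSet, SurfaceMesh

__all__ = [
    "CorrespondenceField",
    "KpcaResult",
    "build_mean_shape",
    "mean_landmarks",
    "signed_distance",
    "summarize_subject",
    "summarize_group",
    "standardize_momenta",
    "kpca_rbf",
    "group_tests",
    "render_distance_report",
    "boxplot_stats",
]

GROUPS = ("males_under40", "males_over40", "females_under40", "females_over40")


@dataclass
class CorrespondenceField:
    """Per-vertex signed distances (mm) between corresponded meshes."""

    signed_distance_mm: np.ndarray
    source: SurfaceMesh
    articular_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.signed_distance_mm = np.asarray(self.signed_distance_mm, dtype=float).reshape(-1)
        if len(self.signed_distance_mm) != self.source.n_vertices:
            raise ValueError("one signed distance per source vertex required")
        if self.articular_mask is not None:
            self.articular_mask = np.asarray(self.articular_mask, dtype=bool).reshape(-1)
            if len(self.articular_mask) != self.source.n_vertices:
                raise ValueError("articular mask must match vertex count")


@dataclass
class KpcaResult:
    eigenvalues: np.ndarray
    scores: np.ndarray
    gamma: float
    feature_means: np.ndarray
    feature_sds: np.ndarray


# ---------------------------------------------------------------------------
# Mean shapes and signed distances
# ---------------------------------------------------------------------------


def build_mean_shape(meshes: Sequence[SurfaceMesh], template_index: int = 0) -> SurfaceMesh:
    """Vertex-wise arithmetic mean of corresponded meshes; faces come from the
    template."""
    counts = {m.n_vertices for m in meshes}
    if len(counts) != 1:
        raise ValueError(f"meshes are not vertex-corresponded (counts {sorted(counts)})")
    stack = np.stack([m.vertices for m in meshes])
    return SurfaceMesh(stack.mean(axis=0), meshes[template_index].faces.copy())


def mean_landmarks(landmark_sets: Sequence[LandmarkSet]) -> LandmarkSet:
    names = set(landmark_sets[0].names())
    for ls in landmark_sets[1:]:
        if set(ls.names()) != names:
            raise ValueError("landmark sets do not share the same point names")
    return LandmarkSet(
        {n: np.mean([ls[n] for ls in landmark_sets], axis=0) for n in sorted(names)}
    )


def signed_distance(
    source: SurfaceMesh,
    deformed: SurfaceMesh,
    articular_mask: Optional[np.ndarray] = None,
) -> CorrespondenceField:
    """Signed correspondence distance from ``source`` to ``deformed``.

    value_i = sign((deformed_i - source_i) . n_i) * |deformed_i - source_i|
    with n_i the outward unit normal of the source at vertex i. Positive
    means the deformation points outward.
    """
    if source.n_vertices != deformed.n_vertices:
        raise ValueError("meshes are not vertex-corresponded")
    disp = deformed.vertices - source.vertices
    mag = np.linalg.norm(disp, axis=1)
    sign = np.sign(np.einsum("ij,ij->i", disp, source.vertex_normals()))
    sign[sign == 0] = 1.0
    return CorrespondenceField(sign * mag, source, articular_mask)


def summarize_subject(field: CorrespondenceField, mask: str = "whole") -> Dict[str, float]:
    """Mean/SD/max/median of |signed distance| over the whole bone or the
    articular subset."""
    if mask == "whole":
        values = np.abs(field.signed_distance_mm)
    elif mask == "articular":
        if field.articular_mask is None or not field.articular_mask.any():
            raise ValueError("field has no articular mask")
        values = np.abs(field.signed_distance_mm[field.articular_mask])
    else:
        raise ValueError("mask must be 'whole' or 'articular'")
    return {
        "mean_mm": float(values.mean()),
        "sd_mm": float(values.std(ddof=0)),
        "max_mm": float(values.max()),
        "median_mm": float(np.median(values)),
    }


def summarize_group(
    cohort: pd.DataFrame,
    value_col: str = "mean_mm",
    group_col: str = "group",
) -> pd.DataFrame:
    """Group and cohort aggregation of per-subject summaries.

    The group mean is the unweighted mean of per-subject means (and likewise
    for the cohort row labelled ``all``); the dispersion column is the mean
    of the per-subject SDs when present.
    """
    if cohort.empty:
        raise ValueError("empty cohort")
    rows = []
    for grp, sub in cohort.groupby(group_col, sort=False):
        if sub.empty:
            raise ValueError(f"empty group {grp}")
        row = {group_col: grp, "n": len(sub), value_col: sub[value_col].mean()}
        if "sd_mm" in sub:
            row["sd_mm"] = sub["sd_mm"].mean()
        rows.append(row)
    all_row = {group_col: "all", "n": len(cohort), value_col: cohort[value_col].mean()}
    if "sd_mm" in cohort:
        all_row["sd_mm"] = cohort["sd_mm"].mean()
    rows.append(all_row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Momenta kPCA
# ---------------------------------------------------------------------------


def standardize_momenta(momenta: Sequence[np.ndarray]):
    """Flatten per-subject (K, 3) momenta and z-score each column.

    Zero-variance columns are set to 0. Returns (matrix, means, sds).
    """
    if len(momenta) < 2:
        raise ValueError("standardisation needs at least two subjects")
    shapes = {np.asarray(m).shape for m in momenta}
    if len(shapes) != 1:
        raise ValueError("subjects must share one control-point set")
    X = np.stack([np.asarray(m, dtype=float).reshape(-1) for m in momenta])
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    Z = np.zeros_like(X)
    nz = sd > 0
    Z[:, nz] = (X[:, nz] - mu[nz]) / sd[nz]
    return Z, mu, sd


def kpca_rbf(X: np.ndarray, gamma: Optional[float] = None, n_components: int = 2) -> KpcaResult:
    """Kernel PCA with an RBF kernel on a subjects x features matrix.

    Default gamma = 1 / (n_features * Var(X)). Scores follow the
    eigenvector * sqrt(eigenvalue) convention and are centred in feature
    space, so at most n-1 eigenvalues are nonzero.
    """
    from sklearn.decomposition import KernelPCA

    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in kPCA input")
    if len(X) < 3:
        raise ValueError("kPCA needs at least 3 subjects")
    if gamma is None:
        var = X.var()
        gamma = 1.0 / (X.shape[1] * var) if var > 0 else 1.0 / X.shape[1]
    n_components = min(n_components, len(X) - 1)
    kp = KernelPCA(n_components=n_components, kernel="rbf", gamma=gamma)
    scores = kp.fit_transform(X)
    return KpcaResult(
        eigenvalues=np.asarray(kp.eigenvalues_),
        scores=scores,
        gamma=float(gamma),
        feature_means=X.mean(axis=0),
        feature_sds=X.std(axis=0, ddof=0),
    )


def group_tests(
    scores: np.ndarray,
    groups: Sequence[str],
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Shapiro–Wilk, Kruskal–Wallis and all pairwise Welch tests per PC.

    ``scores`` is (n_subjects,) or (n_subjects, n_pcs). Returns a tidy frame
    with one row per test; p-values are raw unless ``holm`` is set, in which
    case Holm-adjusted Welch p-values are appended as ``p_adj``.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] == 1:
        scores = scores.T
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups))
    for g in labels:
        if (groups == g).sum() < 3:
            raise ValueError(f"group {g} has fewer than 3 subjects")
    rows = []
    for pc in range(scores.shape[1]):
        s = scores[:, pc]
        pc_name = f"PC{pc + 1}"
        rows.append(
            {
                "pc": pc_name,
                "test": "shapiro_wilk",
                "group_1": "all",
                "group_2": "",
                "statistic": sps.shapiro(s).statistic,
                "p_value": sps.shapiro(s).pvalue,
            }
        )
        samples = [s[groups == g] for g in labels]
        kw = sps.kruskal(*samples)
        rows.append(
            {
                "pc": pc_name,
                "test": "kruskal_wallis",
                "group_1": "all",
                "group_2": "",
                "statistic": kw.statistic,
                "p_value": kw.pvalue,
            }
        )
        welch_rows = []
        for g1, g2 in combinations(labels, 2):
            a, b = s[groups == g1], s[groups == g2]
            if np.ptp(a) == 0 and np.ptp(b) == 0 and np.allclose(a.mean(), b.mean()):
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_ind(a, b, equal_var=False)
            welch_rows.append(
                {
                    "pc": pc_name,
                    "test": "welch_t",
                    "group_1": g1,
                    "group_2": g2,
                    "statistic": float(t),
                    "p_value": float(p),
                }
            )
        if holm:
            ps = np.array([r["p_value"] for r in welch_rows])
            order = np.argsort(ps)
            adj = np.empty_like(ps)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (len(ps) - rank) * ps[idx])
                adj[idx] = min(1.0, running)
            for r, pa in zip(welch_rows, adj):
                r["p_adj"] = float(pa)
        rows.extend(welch_rows)
    out = pd.DataFrame(rows)
    out["significant"] = out["p_value"] < alpha
    return out


def render_distance_report(fields, out_dir, prefix: str = "distance") -> None:
    """Write the distance visualisation artifacts for a set of subjects.

    ``fields`` is a sequence of (label, CorrespondenceField). Produces a CSV
    of per-subject boxplot statistics (median, quartiles, 99.8th-percentile
    outlier rule), a signed-distance boxplot figure (PNG), and one VTK mesh
    per subject carrying a per-vertex ``signed_distance_mm`` scalar for
    surface colouring (positive = outward, negative = inward).
    """
    import logging
    from pathlib import Path

    from .io import write_mesh

    out = Path(out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    (out / "figures").mkdir(exist_ok=True)
    (out / "meshes").mkdir(exist_ok=True)
    rows = [
        {"patient": str(label), **boxplot_stats(fld.signed_distance_mm)}
        for label, fld in fields
    ]
    pd.DataFrame(rows).to_csv(out / "tables" / f"{prefix}_boxplot_data.csv", index=False)
    for label, fld in fields:
        write_mesh(
            fld.source,
            out / "meshes" / f"{prefix}_{label}_signed_distance.vtk",
            point_scalars={"signed_distance_mm": fld.signed_distance_mm},
        )
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(max(6, len(fields)), 4))
        ax.boxplot(
            [fld.signed_distance_mm for _, fld in fields],
            tick_labels=[str(label) for label, _ in fields],
        )
        ax.set_ylabel("signed distance (mm)")
        ax.set_xlabel("subject")
        ax.axhline(0.0, color="0.6", lw=0.5)
        fig.tight_layout()
        fig.savefig(out / "figures" / f"{prefix}_signed_distance_boxplot.png", dpi=120)
        plt.close(fig)
    except Exception as exc:  # plotting must never sink an analysis run
        logging.getLogger("radsym").warning("figure generation failed: %s", exc)


def boxplot_stats(values: np.ndarray, outlier_percentile: float = 99.8) -> Dict[str, float]:
    """Median, quartiles and the high-tail outlier threshold for one subject's
    signed-distance distribution (outliers = values above the 99.8th
    percentile)."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    thr = np.percentile(v, outlier_percentile)
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "outlier_threshold": float(thr),
        "n_outliers": int((v > thr).sum()),
    }
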