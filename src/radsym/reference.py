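"""Bundled reference cohort tables.

Per-subject summary statistics (mean and SD of corresponded-point distances,
in mm) from a published 40-patient bilateral distal-radius CT study — the
study design this package's synthetic cohorts emulate. Two tables are
bundled: the pairwise table (one row per patient: left-vs-right distance,
whole bone and articular surface) and the atlas table (one row per mesh,
left and right separately: distance of each bone to the cohort mean shape).

These tables are inputs for validating the aggregation rules (group mean =
unweighted mean of per-subject means; cohort mean = unweighted mean over all
subjects); the raw meshes behind them are not publicly deposited.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import summarize_group

__all__ = ["load_reference_pairwise", "load_reference_atlas", "reference_aggregates"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("radsym.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, dtype={"patient": str})


def load_reference_pairwise() -> pd.DataFrame:
    """40 rows: patient, group, whole/articular mean and SD (mm)."""
    return _load("reference_pairwise.csv")


def load_reference_atlas() -> pd.DataFrame:
    """80 rows (40 patients x 2 sides): distances to the cohort mean shape."""
    return _load("reference_atlas.csv")


def reference_aggregates() -> dict:
    """Cohort and group aggregations of the bundled tables.

    Computed with the same :func:`~radsym.stats.summarize_group` rule used for
    synthetic cohorts (unweighted mean of per-subject means).
    """
    pw = load_reference_pairwise()
    at = load_reference_atlas()
    out = {}
    for region in ("whole", "articular"):
        col = f"{region}_mean_mm"
        g = summarize_group(pw.rename(columns={col: "mean_mm"}), value_col="mean_mm")
        g = g.set_index("group")["mean_mm"]
        out[f"pairwise_{region}"] = g.to_dict()
        ga = summarize_group(at.rename(columns={col: "mean_mm"}), value_col="mean_mm")
        out[f"atlas_{region}"] = ga.set_index("group")["mean_mm"].to_dict()
    return out
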