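"""Correspondence statistics, aggregation rules, kPCA, and group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from radsym.mesh import LandmarkSet, SurfaceMesh
from radsym.reference import load_reference_atlas, load_reference_pairwise, reference_aggregates
from radsym.stats import (
    CorrespondenceField,
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


class TestMeanShape:
    def test_identical_inputs(self, sphere10):
        out = build_mean_shape([sphere10, sphere10.copy(), sphere10.copy()])
        assert np.allclose(out.vertices, sphere10.vertices)

    def test_midpoint_of_translates(self, sphere10):
        a = SurfaceMesh(sphere10.vertices + [1, 0, 0], sphere10.faces)
        b = SurfaceMesh(sphere10.vertices - [1, 0, 0], sphere10.faces)
        out = build_mean_shape([a, b])
        assert np.allclose(out.vertices, sphere10.vertices, atol=1e-12)

    def test_elementwise_oracle(self, sphere10, rng):
        variants = [
            SurfaceMesh(sphere10.vertices + 0.3 * rng.normal(size=sphere10.vertices.shape),
                        sphere10.faces)
            for _ in range(10)
        ]
        out = build_mean_shape(variants)
        expected = np.mean([v.vertices for v in variants], axis=0)
        assert np.allclose(out.vertices, expected)

    def test_mismatched_counts_raise(self, sphere10, tetrahedron):
        with pytest.raises(ValueError, match="corresponded"):
            build_mean_shape([sphere10, tetrahedron])


class TestMeanLandmarks:
    def test_midpoint(self):
        a = LandmarkSet({"RS": [0, 0, 40], "DSN": [1, 1, 37]})
        b = LandmarkSet({"RS": [2, 0, 42], "DSN": [1, 1, 39]})
        m = mean_landmarks([a, b])
        assert np.allclose(m["DSN"], [1, 1, 38])
        assert np.allclose(m["RS"], [1, 0, 41])

    def test_elementwise_oracle(self, rng):
        sets = [
            LandmarkSet({"RS": rng.normal(size=3), "DSN": rng.normal(size=3)})
            for _ in range(40)
        ]
        m = mean_landmarks(sets)
        assert np.allclose(m["RS"], np.mean([s["RS"] for s in sets], axis=0))

    def test_missing_name_raises(self):
        a = LandmarkSet({"RS": [0, 0, 0], "DSN": [1, 1, 1], "DDR": [2, 2, 2]})
        b = LandmarkSet({"RS": [0, 0, 0], "DSN": [1, 1, 1]})
        with pytest.raises(ValueError):
            mean_landmarks([a, b])


class TestSignedDistance:
    def test_identity_gives_zeros(self, sphere10):
        fld = signed_distance(sphere10, sphere10)
        assert np.allclose(fld.signed_distance_mm, 0)

    def test_outward_offset_positive(self, sphere10):
        n = sphere10.vertex_normals()
        out = SurfaceMesh(sphere10.vertices + 0.5 * n, sphere10.faces)
        fld = signed_distance(sphere10, out)
        assert np.allclose(fld.signed_distance_mm, 0.5, atol=1e-9)

    def test_inward_offset_negative(self, sphere10):
        n = sphere10.vertex_normals()
        inw = SurfaceMesh(sphere10.vertices - 0.3 * n, sphere10.faces)
        fld = signed_distance(sphere10, inw)
        assert np.allclose(fld.signed_distance_mm, -0.3, atol=1e-9)

    def test_per_vertex_oracle(self, sphere10, rng):
        disp = 0.4 * rng.normal(size=sphere10.vertices.shape)
        moved = SurfaceMesh(sphere10.vertices + disp, sphere10.faces)
        fld = signed_distance(sphere10, moved)
        mags = np.linalg.norm(disp, axis=1)
        assert np.allclose(np.abs(fld.signed_distance_mm), mags, atol=1e-12)
        signs = np.sign(np.einsum("ij,ij->i", disp, sphere10.vertex_normals()))
        nz = signs != 0
        assert np.array_equal(np.sign(fld.signed_distance_mm)[nz], signs[nz])


class TestSummaries:
    def _field(self, sphere10, values, mask=None):
        return CorrespondenceField(values, sphere10, mask)

    def test_constant_field(self, sphere10):
        f = self._field(sphere10, np.full(sphere10.n_vertices, 0.5))
        s = summarize_subject(f, "whole")
        assert s["mean_mm"] == 0.5 and s["sd_mm"] == 0.0

    def test_absolute_value_convention(self, sphere10):
        vals = np.ones(sphere10.n_vertices)
        vals[::2] = -1.0
        s = summarize_subject(self._field(sphere10, vals), "whole")
        assert s["mean_mm"] == pytest.approx(1.0)
        assert s["sd_mm"] == pytest.approx(0.0)

    def test_arithmetic_oracle(self, sphere10, rng):
        vals = rng.normal(size=sphere10.n_vertices)
        s = summarize_subject(self._field(sphere10, vals), "whole")
        assert s["mean_mm"] == pytest.approx(np.abs(vals).mean())
        assert s["max_mm"] == pytest.approx(np.abs(vals).max())
        assert s["median_mm"] == pytest.approx(np.median(np.abs(vals)))

    def test_articular_mask(self, sphere10, rng):
        vals = rng.normal(size=sphere10.n_vertices)
        mask = sphere10.vertices[:, 2] > 5
        s = summarize_subject(self._field(sphere10, vals, mask), "articular")
        assert s["mean_mm"] == pytest.approx(np.abs(vals[mask]).mean())

    def test_empty_articular_mask_raises(self, sphere10):
        f = self._field(sphere10, np.zeros(sphere10.n_vertices),
                        np.zeros(sphere10.n_vertices, bool))
        with pytest.raises(ValueError):
            summarize_subject(f, "articular")


class TestReferenceAggregation:
    """The bundled 40-patient tables reproduce the published aggregations."""

    def test_pairwise_cohort_mean(self):
        agg = reference_aggregates()
        assert round(agg["pairwise_whole"]["all"], 2) == 0.53

    def test_pairwise_group_means(self):
        agg = reference_aggregates()
        assert round(agg["pairwise_whole"]["males_over40"], 2) == 0.57
        assert round(agg["pairwise_whole"]["females_under40"], 2) == 0.45
        assert round(agg["pairwise_articular"]["females_under40"], 2) == 0.40

    def test_atlas_cohort_means(self):
        agg = reference_aggregates()
        assert round(agg["atlas_whole"]["all"], 2) == 0.98
        assert round(agg["atlas_articular"]["all"], 2) == 0.65

    def test_table_shapes(self):
        assert len(load_reference_pairwise()) == 40
        at = load_reference_atlas()
        assert len(at) == 80
        assert set(at["side"]) == {"l", "r"}

    def test_summarize_group_rejects_empty(self):
        with pytest.raises(ValueError):
            summarize_group(pd.DataFrame(columns=["group", "mean_mm"]))


class TestStandardizeMomenta:
    def test_two_subject_sign_pattern(self):
        v = np.array([[1.0, -2.0, 0.5]])
        Z, mu, sd = standardize_momenta([v, -v])
        assert np.allclose(Z[0], -Z[1])
        assert np.allclose(np.abs(Z), 1.0)
        assert np.allclose(mu, 0.0)

    def test_zscore_contract(self, rng):
        moms = [rng.normal(size=(7, 3)) for _ in range(12)]
        Z, _, _ = standardize_momenta(moms)
        assert np.abs(Z.mean(axis=0)).max() < 1e-10
        sds = Z.std(axis=0)
        assert np.all((np.abs(sds - 1) < 1e-10) | (sds == 0))

    def test_columnwise_oracle(self, rng):
        moms = [rng.normal(size=(4, 3)) for _ in range(6)]
        Z, _, _ = standardize_momenta(moms)
        X = np.stack([m.reshape(-1) for m in moms])
        expected = (X - X.mean(0)) / X.std(0)
        assert np.allclose(Z, expected)

    def test_single_subject_raises(self, rng):
        with pytest.raises(ValueError):
            standardize_momenta([rng.normal(size=(4, 3))])


class TestKpca:
    def test_linear_limit_orders_line(self, rng):
        t = np.linspace(0, 1, 12)
        X = np.outer(t, rng.normal(size=8))
        res = kpca_rbf(X, gamma=1e-4, n_components=2)
        pc1 = res.scores[:, 0]
        assert np.all(np.diff(pc1) > 0) or np.all(np.diff(pc1) < 0)

    def test_duplicated_rows_have_identical_scores(self, rng):
        X = rng.normal(size=(8, 5))
        X[3] = X[0]
        res = kpca_rbf(X, n_components=3)
        assert np.allclose(res.scores[3], res.scores[0], atol=1e-8)

    def test_rank_bound_and_centering(self, rng):
        X = rng.normal(size=(10, 6))
        res = kpca_rbf(X, n_components=9)
        assert res.scores.shape[1] <= 9
        assert np.abs(res.scores.mean(axis=0)).max() < 1e-8
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            kpca_rbf(np.array([[np.nan, 1.0], [0.0, 1.0], [2.0, 1.0]]))


class TestGroupTests:
    def _groups(self, n=10):
        return np.repeat(["g1", "g2", "g3", "g4"], n)

    def test_identical_groups_welch_p_one(self):
        vals = np.tile(np.arange(10.0), 4)
        out = group_tests(vals, self._groups())
        welch = out[out.test == "welch_t"]
        assert np.allclose(welch.statistic, 0.0)
        assert np.allclose(welch.p_value, 1.0)

    def test_structure(self, rng):
        out = group_tests(rng.normal(size=(40, 2)), self._groups())
        assert set(out.pc) == {"PC1", "PC2"}
        assert (out.test == "welch_t").sum() == 12  # 6 pairs x 2 PCs
        assert (out.test == "kruskal_wallis").sum() == 2

    def test_small_group_raises(self):
        with pytest.raises(ValueError):
            group_tests(np.arange(4.0), ["a", "a", "b", "b"])

    def test_welch_matches_permutation_oracle(self, rng):
        a = rng.normal(0.0, 1.0, size=10)
        b = rng.normal(0.8, 1.5, size=10)
        out = group_tests(
            np.concatenate([a, b, rng.normal(size=10), rng.normal(size=10)]),
            self._groups(),
        )
        p_welch = float(
            out[(out.test == "welch_t") & (out.group_1 == "g1") & (out.group_2 == "g2")]
            .p_value.iloc[0]
        )
        # permutation distribution of the Welch statistic
        obs = sps.ttest_ind(a, b, equal_var=False).statistic
        pooled = np.concatenate([a, b])
        count = 0
        n_perm = 5000
        r = np.random.default_rng(0)
        for _ in range(n_perm):
            perm = r.permutation(pooled)
            t = sps.ttest_ind(perm[:10], perm[10:], equal_var=False).statistic
            count += abs(t) >= abs(obs)
        assert abs(p_welch - count / n_perm) < 0.02

    def test_holm_adjustment_monotone(self, rng):
        scores = rng.normal(size=40)
        scores[:10] += 2.0
        out = group_tests(scores, self._groups(), holm=True)
        welch = out[out.test == "welch_t"]
        assert np.all(welch.p_adj >= welch.p_value - 1e-12)
        assert welch.p_adj.max() <= 1.0


class TestRenderDistanceReport:
    def test_artifacts_written(self, sphere10, tmp_path, rng):
        from radsym.io import read_vtk_polydata
        from radsym.stats import render_distance_report

        fld = CorrespondenceField(rng.normal(size=sphere10.n_vertices), sphere10)
        render_distance_report([("007", fld)], tmp_path, prefix="pair")
        box = pd.read_csv(tmp_path / "tables" / "pair_boxplot_data.csv")
        assert {"median", "q1", "q3", "outlier_threshold"} <= set(box.columns)
        _, scalars = read_vtk_polydata(tmp_path / "meshes" / "pair_007_signed_distance.vtk")
        assert np.allclose(scalars["signed_distance_mm"], fld.signed_distance_mm)

    def test_constant_field_zero_iqr_row(self, sphere10, tmp_path):
        from radsym.stats import render_distance_report

        fld = CorrespondenceField(np.full(sphere10.n_vertices, 0.4), sphere10)
        render_distance_report([("c", fld)], tmp_path)
        box = pd.read_csv(tmp_path / "tables" / "distance_boxplot_data.csv")
        assert box.loc[0, "q1"] == box.loc[0, "q3"] == pytest.approx(0.4)


class TestBoxplotStats:
    def test_constant_field_zero_iqr(self):
        s = boxplot_stats(np.full(100, 0.3))
        assert s["q1"] == s["q3"] == s["median"] == pytest.approx(0.3)

    def test_outlier_rule(self, rng):
        v = rng.normal(size=5000)
        s = boxplot_stats(v)
        assert s["outlier_threshold"] == pytest.approx(np.percentile(v, 99.8))
        assert s["n_outliers"] == (v > s["outlier_threshold"]).sum()
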