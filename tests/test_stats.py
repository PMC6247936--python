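"""Spread statistics, matrix summaries and the automated report."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from modq.completeness import MCFMatrix
from modq.errors import (
    InsufficientPoints,
    InsufficientRows,
    SingletonGroupWarning,
    UnassignedRow,
)
from modq.stats import (
    build_report,
    column_sd,
    group_mean_mcf,
    grouped_mean_distance,
    mean_euclidean_distance,
    pca_scores,
    zero_variance_modules,
)


def points(*rows, index=None):
    df = pd.DataFrame(list(rows))
    if index:
        df.index = list(index)
    return df


class TestMeanEuclideanDistance:
    def test_identical_points_give_zero(self):
        assert mean_euclidean_distance(points((1, 2), (1, 2))) == 0.0

    def test_three_four_five_triangle(self):
        assert mean_euclidean_distance(points((0, 0), (3, 4))) == 5.0

    def test_unit_equilateral_triangle(self):
        pts = points((0, 0), (1, 0), (0.5, math.sqrt(3) / 2))
        assert mean_euclidean_distance(pts) == pytest.approx(1.0)

    def test_single_point_raises(self):
        with pytest.raises(InsufficientPoints):
            mean_euclidean_distance(points((0, 0)))

    def test_zero_iff_coincident(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pts = rng.normal(size=(5, 3))
            d = mean_euclidean_distance(pts)
            assert (d == 0) == bool((pts == pts[0]).all())

    def test_translation_rotation_invariance_and_scaling(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            pts = rng.normal(size=(6, 2))
            base = mean_euclidean_distance(pts)
            shifted = pts + rng.normal(size=2)
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(theta), -np.sin(theta)],
                            [np.sin(theta), np.cos(theta)]])
            rotated = pts @ rot.T
            scale = rng.uniform(0.1, 5)
            assert mean_euclidean_distance(shifted) == pytest.approx(base)
            assert mean_euclidean_distance(rotated) == pytest.approx(base)
            assert mean_euclidean_distance(pts * scale) == pytest.approx(
                base * scale
            )

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(size=(8, 4))
        n = len(pts)
        acc = [
            float(np.linalg.norm(pts[i] - pts[j]))
            for i in range(n)
            for j in range(i + 1, n)
        ]
        assert mean_euclidean_distance(pts) == pytest.approx(
            sum(acc) / (n * (n - 1) / 2)
        )


class TestGroupedMeanDistance:
    def test_single_group_equals_global(self):
        pts = points((0, 0), (3, 4), (1, 1), index=["a", "b", "c"])
        factor = {"a": "g", "b": "g", "c": "g"}
        out = grouped_mean_distance(pts, factor)
        assert out == {"g": mean_euclidean_distance(pts)}

    def test_two_coincident_groups(self):
        pts = points((1, 1), (1, 1), (5, 5), (5, 5),
                     index=["a", "b", "c", "d"])
        factor = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        assert grouped_mean_distance(pts, factor) == {"g1": 0.0, "g2": 0.0}

    def test_tight_group_smaller_than_loose(self):
        rng = np.random.default_rng(5)
        tight = rng.normal(scale=0.1, size=(5, 2))
        loose = rng.normal(scale=5.0, size=(5, 2))
        pts = pd.DataFrame(
            np.vstack([tight, loose]),
            index=[f"t{i}" for i in range(5)] + [f"l{i}" for i in range(5)],
        )
        factor = {r: ("A" if r.startswith("t") else "B") for r in pts.index}
        out = grouped_mean_distance(pts, factor)
        assert out["A"] < out["B"]

    def test_singleton_group_is_nan_with_warning(self):
        pts = points((0, 0), (1, 1), (2, 2), index=["a", "b", "c"])
        factor = {"a": "g1", "b": "g1", "c": "solo"}
        with pytest.warns(SingletonGroupWarning):
            out = grouped_mean_distance(pts, factor)
        assert math.isnan(out["solo"])

    def test_uncovered_row_raises(self):
        pts = points((0, 0), (1, 1), index=["a", "b"])
        with pytest.raises(UnassignedRow):
            grouped_mean_distance(pts, {"a": "g"})


def matrix(values, rows, cols):
    return MCFMatrix(pd.DataFrame(values, index=rows, columns=cols))


class TestZeroVariance:
    def test_constant_columns_listed(self):
        m = matrix([[1.0, 0.5, 0.5], [1.0, 0.5, 0.6]],
                   ["a", "b"], ["m1", "m2", "m3"])
        assert zero_variance_modules(m) == ["m1", "m2"]

    def test_exact_on_integer_pairs(self):
        # 1/2 and 2/4 are equal as floats but differ as pairs
        sat = pd.DataFrame([[1], [2]], index=["a", "b"], columns=["m"])
        tot = pd.DataFrame([[2], [4]], index=["a", "b"], columns=["m"])
        m = MCFMatrix.from_pairs(sat, tot)
        assert zero_variance_modules(m) == []


class TestColumnSD:
    def test_constant_column_zero(self):
        m = matrix([[0.5], [0.5]], ["a", "b"], ["m"])
        assert column_sd(m)["m"] == 0.0

    def test_sample_denominator(self):
        m = matrix([[0.0], [1.0]], ["a", "b"], ["m"])
        assert column_sd(m)["m"] == pytest.approx(math.sqrt(0.5))

    def test_matches_two_pass_formula(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.uniform(size=(10, 4)),
                          columns=list("abcd"))
        sd = column_sd(df)
        for c in df.columns:
            mu = df[c].mean()
            expect = math.sqrt(((df[c] - mu) ** 2).sum() / (len(df) - 1))
            assert sd[c] == pytest.approx(expect)

    def test_single_row_raises(self):
        with pytest.raises(InsufficientRows):
            column_sd(matrix([[0.5]], ["a"], ["m"]))


class TestGroupMeanMCF:
    def test_singleton_groups_identity(self):
        m = matrix([[0.25, 1.0], [0.5, 0.0]], ["a", "b"], ["m1", "m2"])
        out = group_mean_mcf(m, {"a": "ga", "b": "gb"})
        assert out.loc["ga"].tolist() == [0.25, 1.0]

    def test_mean_of_extremes(self):
        m = matrix([[0.0], [1.0]], ["a", "b"], ["m"])
        out = group_mean_mcf(m, {"a": "g", "b": "g"})
        assert out.loc["g", "m"] == 0.5

    def test_weighted_recombination_recovers_global_mean(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.uniform(size=(6, 3)),
                          index=[f"r{i}" for i in range(6)],
                          columns=["m1", "m2", "m3"])
        factor = {f"r{i}": ("A" if i < 2 else "B") for i in range(6)}
        means = group_mean_mcf(df, factor)
        sizes = pd.Series({"A": 2, "B": 4})
        recombined = (means.mul(sizes, axis=0)).sum() / sizes.sum()
        assert np.allclose(recombined, df.mean())

    def test_first_appearance_row_order(self):
        m = matrix([[0.1], [0.2], [0.3]], ["a", "b", "c"], ["m"])
        out = group_mean_mcf(m, {"a": "z", "b": "y", "c": "z"})
        assert out.index.tolist() == ["z", "y"]


class TestPCA:
    def test_scores_shape_and_variance_order(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.uniform(size=(12, 5)))
        scores, ratio = pca_scores(df)
        assert scores.shape == (12, 5)
        assert all(ratio[i] >= ratio[i + 1] - 1e-12 for i in range(len(ratio) - 1))
        assert np.isclose(ratio.sum(), 1.0)

    def test_n_components_cap(self):
        df = pd.DataFrame(np.random.default_rng(0).uniform(size=(8, 4)))
        scores, _ = pca_scores(df, n_components=2)
        assert scores.shape == (8, 2)


class TestBuildReport:
    def test_full_report_with_factor(self, tmp_path, fixture_set):
        truth = fixture_set["truth"]
        factor = {g.genome_id: g.taxonomy[-1] for g in fixture_set["genomes"]}
        res = build_report(truth, {"genus": factor}, tmp_path / "rep")
        summary = json.loads((tmp_path / "rep" / "summary.json").read_text())
        assert summary["n_genomes"] == truth.shape[0]
        assert summary["n_modules"] == truth.shape[1]
        assert len(res.figures) >= 5
        assert (tmp_path / "rep" / "zero_variance_modules.tsv").exists()
        assert "genus" in summary["group_mean_distance"]
        assert all(summary["sections"].values()), summary["errors"]

    def test_no_factor_skips_grouped_steps(self, tmp_path, fixture_set):
        res = build_report(fixture_set["truth"], None, tmp_path / "rep2")
        summary = res.summary
        assert "skipped" in summary
        assert not any(s.startswith("pc_plot") for s in summary["sections"])
        names = [p.name for p in res.figures]
        assert "heatmap.png" in names and "module_boxplot.png" in names

    def test_zero_variance_module_reported(self, tmp_path):
        m = matrix([[1.0, 0.3], [1.0, 0.7]], ["a", "b"], ["const", "vary"])
        res = build_report(m, None, tmp_path / "rep3")
        assert res.summary["zero_variance_modules"] == ["const"]
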