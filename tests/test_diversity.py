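"""Geometry, outlier rule, per-sample projection, and median split."""

import numpy as np
import pandas as pd
import pytest

from scdiversity.diversity import (
    DiversityConfig,
    assign_groups,
    diversity_score,
    project_sample,
    sample_diversity,
)


class TestDiversityScore:
    def test_identical_cells_score_zero(self):
        coords = np.ones((20, 3))
        score, d, out = diversity_score(coords)
        assert score == 0.0
        assert not out.any()

    def test_two_cell_geometry(self):
        score, d, out = diversity_score(np.array([[0.0, 0.0], [2.0, 0.0]]))
        assert score == pytest.approx(1.0)
        np.testing.assert_allclose(d, [1.0, 1.0])
        assert not out.any()

    def test_single_extreme_cell_excluded(self):
        rng = np.random.default_rng(0)
        n = 500
        theta = rng.uniform(0, 2 * np.pi, n)
        radius = rng.normal(1.0, 0.01, n)
        coords = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
        clean_score, _, _ = diversity_score(coords)
        planted = np.vstack([coords, [10.0, 0.0]])
        score, d, out = diversity_score(planted)
        assert out.sum() == 1 and out[-1]
        assert abs(score - clean_score) / clean_score < 0.01

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(40, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = coords @ q + np.array([5.0, -2.0, 7.0])
        s1, _, _ = diversity_score(coords)
        s2, _, _ = diversity_score(moved)
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_duplicating_cells_leaves_score_unchanged(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(30, 4))
        s1, _, _ = diversity_score(coords)
        s2, _, _ = diversity_score(np.vstack([coords, coords]))
        assert abs(s1 - s2) < 1e-9

    @pytest.mark.parametrize("n", range(2, 11))
    def test_no_outlier_possible_at_small_n(self, n):
        # Samuelson: max |d - mean(d)| / sd(d) <= (n-1)/sqrt(n) < 3 for n <= 10
        rng = np.random.default_rng(100 + n)
        for _ in range(50):
            coords = rng.normal(size=(n, 3)) * rng.lognormal(0, 2)
            _, _, out = diversity_score(coords)
            assert not out.any()

    def test_needs_two_cells(self):
        with pytest.raises(ValueError):
            diversity_score(np.ones((1, 2)))


class TestProjectSample:
    def test_line_gives_one_component(self):
        t = np.linspace(0, 5, 30)
        X = np.column_stack([t, 2 * t, -t])
        coords = project_sample(X, variance_kept=0.8)
        assert coords.shape == (30, 1)

    def test_variance_kept_one_keeps_all(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 4))
        coords = project_sample(X, variance_kept=1.0)
        assert coords.shape[1] == 4

    def test_k_matches_bruteforce_cumulative_scan(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 15)) * np.linspace(3, 0.1, 15)
        coords = project_sample(X, variance_kept=0.8)
        Xc = X - X.mean(0)
        eig = np.sort(np.linalg.eigvalsh(np.cov(Xc, rowvar=False, ddof=1)))[::-1]
        cum = np.cumsum(eig) / eig.sum()
        k_expected = next(i + 1 for i, c in enumerate(cum) if c >= 0.8)
        assert coords.shape[1] == k_expected

    def test_distances_preserved_at_full_variance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(12, 6))
        coords = project_sample(X, variance_kept=1.0)
        d_orig = np.linalg.norm(X - X.mean(0), axis=1)
        d_proj = np.linalg.norm(coords - coords.mean(0), axis=1)
        np.testing.assert_allclose(d_orig, d_proj, atol=1e-9)

    def test_too_few_cells(self):
        with pytest.raises(ValueError, match="3 cells"):
            project_sample(np.ones((2, 4)))


class TestAssignGroups:
    def test_median_split(self):
        groups = assign_groups(pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
        assert groups.to_dict() == {"a": "low", "b": "low", "c": "high", "d": "high"}

    def test_tie_at_median_goes_high(self):
        groups = assign_groups(pd.Series([1.0, 2.0, 3.0]))
        assert list(groups) == ["low", "high", "high"]

    def test_all_equal_warns_single_group(self):
        with pytest.warns(UserWarning, match="equal"):
            groups = assign_groups(pd.Series([2.0, 2.0, 2.0]))
        assert (groups == "high").all()

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            assign_groups(pd.Series([1.0]))


class TestSampleDiversity:
    def test_small_sample_flagged_not_grouped(self):
        rng = np.random.default_rng(6)
        features = rng.normal(size=(30 + 30 + 15, 5))
        samples = np.array(["a"] * 30 + ["b"] * 30 + ["c"] * 15)
        tumor = np.ones(75, dtype=bool)
        cfg = DiversityConfig(min_tumor_cells=20)
        table, _ = sample_diversity(features, samples, tumor, cfg)
        row = table.set_index("sample")
        assert row.loc["a", "included"] and row.loc["b", "included"]
        assert not row.loc["c", "included"]  # 15 <= 20 tumor cells
        assert pd.isna(row.loc["c", "group"])
        assert row.loc[["a", "b"], "group"].notna().all()

    def test_cnv_style_input_column_permutation_invariant(self):
        rng = np.random.default_rng(7)
        profile = rng.normal(size=(40, 50))
        samples = np.array(["s"] * 40)
        tumor = np.ones(40, dtype=bool)
        t1, _ = sample_diversity(profile, samples, tumor, assign=False)
        t2, _ = sample_diversity(
            profile[:, rng.permutation(50)], samples, tumor, assign=False
        )
        assert t1.loc[0, "score"] == pytest.approx(t2.loc[0, "score"], abs=1e-9)

    def test_identical_profiles_score_zero(self):
        profile = np.tile(np.arange(10.0), (25, 1))
        table, _ = sample_diversity(
            profile, np.array(["s"] * 25), np.ones(25, bool), assign=False
        )
        assert table.loc[0, "score"] == pytest.approx(0.0, abs=1e-12)


def test_cnv_subclones_raise_cnv_diversity():
    """A tumor whose subclones carry private dosage segments scores higher
    CNV-profile diversity than a clonal control."""
    import scdiversity as sd
    from scdiversity.qc import QCConfig, filter_cells, filter_genes, normalize_total

    def cnv_score(extra):
        cfg = sd.SimConfig(
            n_samples=1,
            cells_per_type={"CAF": 40, "TEC": 40, "TAM": 40, "malignant": 120},
            n_subclones=2,
            subclone_divergence=0.0,
            subclone_extra_segments=extra,
            seed=21,
        )
        raw, ann, truth = sd.simulate_dataset(cfg)
        qc = QCConfig()
        filtered, report = filter_cells(filter_genes(raw, qc), qc)
        norm = normalize_total(filtered, qc)
        kept = report["kept"].to_numpy()
        ref = np.isin(truth.cell_type[kept], ["TEC", "CAF", "TAM"])
        profile = sd.infer_cnv_profile(norm, ann, np.flatnonzero(ref))
        table, _ = sample_diversity(
            profile.values, norm.sample_of_cell, truth.is_malignant[kept], assign=False
        )
        return table.loc[0, "score"]

    two_subclones = cnv_score(
        [(0, "chr6", 0, 300, 1.5), (1, "chr8", 0, 300, 0.5)]
    )
    clonal = cnv_score([])
    assert two_subclones > clonal * 1.1
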