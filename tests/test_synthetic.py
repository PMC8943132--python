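"""Generator contracts: determinism, planted structure, and ground truth."""

import numpy as np
import pandas as pd
import pytest

from scdiversity.synthetic import (
    CELL_TYPES,
    ConfigurationError,
    SimConfig,
    generate_gene_annotation,
    simulate_dataset,
    simulate_qc_fixture,
)


def _tiny_config(**kw):
    defaults = dict(
        n_samples=1,
        cells_per_type={"T": 40, "CAF": 30, "malignant": 60},
        n_chromosomes=4,
        genes_per_chromosome=50,
        cnv_segments=[("chr1", 0, 50, 1.5)],
        seed=0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestGeneAnnotation:
    def test_counts_and_strict_ordering(self):
        ann = generate_gene_annotation(_tiny_config(n_chromosomes=2))
        auto = ann[ann["chrom"] != "chrM"]
        assert len(auto) == 100
        assert auto.groupby("chrom").size().eq(50).all()
        for _, sub in auto.groupby("chrom"):
            assert sub["start"].is_monotonic_increasing
            assert sub["start"].is_unique

    def test_deterministic(self):
        a = generate_gene_annotation(_tiny_config())
        b = generate_gene_annotation(_tiny_config())
        pd.testing.assert_frame_equal(a, b)

    def test_mito_genes_on_their_own_contig(self):
        ann = generate_gene_annotation(_tiny_config())
        mito = ann[ann["gene_id"].str.startswith("MT-")]
        assert set(mito["chrom"]) == {"chrM"}
        assert len(mito) == 13

    def test_degenerate_config_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_gene_annotation(_tiny_config(genes_per_chromosome=0))


class TestSimConfigValidation:
    def test_empty_cells_per_type(self):
        with pytest.raises(ConfigurationError, match="empty"):
            simulate_dataset(_tiny_config(cells_per_type={}))

    def test_unknown_cell_type(self):
        with pytest.raises(ConfigurationError, match="unknown cell type"):
            _tiny_config(cells_per_type={"weird": 5}).validate()

    @pytest.mark.parametrize(
        "segments,msg",
        [
            ([("chr9", 0, 10, 1.5)], "unknown chromosome"),
            ([("chr1", 0, 10, -2.0)], "dosage"),
            ([("chr1", 0, 60, 1.5)], "bounds"),
            ([("chr1", 0, 30, 1.5), ("chr1", 20, 40, 0.5)], "overlap"),
        ],
    )
    def test_bad_segments(self, segments, msg):
        with pytest.raises(ConfigurationError, match=msg):
            _tiny_config(cnv_segments=segments).validate()

    def test_lr_types_from_vocabulary(self):
        with pytest.raises(ConfigurationError, match="CELL_TYPES"):
            _tiny_config(lr_planted=[("A", "B", "nope", "malignant", 2.0)]).validate()

    def test_per_sample_divergence_length(self):
        with pytest.raises(ConfigurationError, match="n_samples"):
            _tiny_config(n_samples=2, subclone_divergence=[0.1]).validate()


class TestSimulateDataset:
    def test_same_seed_bitwise_identical(self):
        a, _, _ = simulate_dataset(_tiny_config())
        b, _, _ = simulate_dataset(_tiny_config())
        assert (a.counts != b.counts).nnz == 0
        assert list(a.barcodes) == list(b.barcodes)

    def test_ground_truth_invariants(self):
        raw, ann, truth = simulate_dataset(_tiny_config())
        non_mal = ~truth.is_malignant
        assert (truth.cnv_dosage[non_mal] == 1.0).all()
        assert all(s is None for s in truth.subclone_id[non_mal])
        assert all(s is not None for s in truth.subclone_id[truth.is_malignant])
        assert set(truth.cell_type) <= set(CELL_TYPES)

    def test_no_divergence_single_subclone_is_exchangeable(self):
        raw, ann, truth = simulate_dataset(
            _tiny_config(subclone_divergence=0.0, n_subclones=1)
        )
        mal = truth.is_malignant
        assert len(set(truth.subclone_id[mal])) == 1

    def test_planted_gain_ratio_at_500_cells(self):
        cfg = _tiny_config(
            cells_per_type={"CAF": 500, "malignant": 500},
            subclone_divergence=0.0,
            mito_fraction_target=0.0,
            type_program_size=0,  # isolate the dosage effect
        )
        raw, ann, truth = simulate_dataset(cfg)
        seg_genes = ann.index[(ann["chrom"] == "chr1")].to_numpy()
        C = raw.counts.toarray()
        mal_mean = C[np.ix_(seg_genes, np.flatnonzero(truth.is_malignant))].mean()
        ref_mean = C[np.ix_(seg_genes, np.flatnonzero(~truth.is_malignant))].mean()
        assert mal_mean / ref_mean == pytest.approx(1.5, rel=0.05)

    def test_marker_fold_recovered_at_1000_cells(self):
        cfg = _tiny_config(
            cells_per_type={"T": 1000, "B": 1000},
            subclone_divergence=0.0,
        )
        raw, ann, truth = simulate_dataset(cfg)
        genes = list(raw.gene_ids)
        t_markers = [genes.index(g) for g in ("CD3D", "CD3E", "CD8A")]
        C = raw.counts.toarray().astype(float)
        t_cells = truth.cell_type == "T"
        ratio = C[np.ix_(t_markers, np.flatnonzero(t_cells))].mean() / C[
            np.ix_(t_markers, np.flatnonzero(~t_cells))
        ].mean()
        assert ratio == pytest.approx(cfg.marker_fold, rel=0.10)

    def test_mito_fraction_near_target(self):
        cfg = _tiny_config(mito_fraction_target=0.08)
        raw, ann, truth = simulate_dataset(cfg)
        mito = np.array([g.startswith("MT-") for g in raw.gene_ids])
        totals = np.asarray(raw.counts.sum(axis=0)).ravel()
        mito_frac = np.asarray(raw.counts[mito].sum(axis=0)).ravel() / totals
        assert mito_frac.mean() == pytest.approx(0.08, rel=0.10)
        assert np.quantile(mito_frac, 0.95) < 0.16

    def test_planted_lr_fold_in_sender_and_receiver(self):
        cfg = _tiny_config(
            cells_per_type={"CAF": 400, "T": 400, "malignant": 400},
            lr_planted=[("COL1A1", "ITGA2", "CAF", "malignant", 4.0)],
            subclone_divergence=0.0,
        )
        raw, ann, truth = simulate_dataset(cfg)
        genes = list(raw.gene_ids)
        C = raw.counts.toarray().astype(float)
        lig = C[genes.index("COL1A1")]
        caf, t = truth.cell_type == "CAF", truth.cell_type == "T"
        assert lig[caf].mean() / lig[t].mean() == pytest.approx(4.0, rel=0.15)


class TestQCFixture:
    def test_counts_are_as_planted(self):
        raw, truth = simulate_qc_fixture(seed=1)
        n_genes_per_cell = np.asarray((raw.counts > 0).sum(axis=0)).ravel()
        low = n_genes_per_cell < 500
        assert low.sum() == truth["k_low_gene"]
        detected_cells = np.asarray((raw.counts > 0).sum(axis=1)).ravel()
        rare = {g for g, d in zip(raw.gene_ids, detected_cells) if d < 3}
        assert rare == truth["rare_genes"]

    def test_violation_sets_disjoint(self):
        raw, truth = simulate_qc_fixture(seed=2)
        assert not truth["low_gene_barcodes"] & truth["high_mito_barcodes"]
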