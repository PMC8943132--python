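"""CNV inference, the signal/correlation scores, and the malignancy call."""

import numpy as np
import pandas as pd
import pytest

from scdiversity.cnv import (
    CNVProfile,
    classify_malignant,
    cnv_correlation,
    cnv_signal,
    infer_cnv_profile,
    read_gene_annotation,
    write_gene_annotation,
)
from scdiversity.qc import QCConfig, filter_cells, filter_genes, normalize_total
from scdiversity.synthetic import SimConfig, simulate_dataset

from conftest import make_norm


def _profile(values, samples=None):
    values = np.asarray(values, dtype=float)
    n_cells, n_genes = values.shape
    return CNVProfile(
        values=values,
        gene_ids=np.array([f"g{i}" for i in range(n_genes)], dtype=object),
        chromosomes=np.array(["chr1"] * n_genes, dtype=object),
        barcodes=np.array([f"c{i}" for i in range(n_cells)], dtype=object),
        sample_of_cell=np.array(
            samples if samples is not None else ["s"] * n_cells, dtype=object
        ),
        reference_mask=np.zeros(n_cells, dtype=bool),
        window=3,
    )


class TestCnvSignal:
    def test_simple_values(self):
        assert cnv_signal(_profile([[0.0, 0.0]]))[0] == 0.0
        assert cnv_signal(_profile([[0.2, -0.2]]))[0] == pytest.approx(0.04)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(100, 500))
        fast = cnv_signal(_profile(values))
        for i in range(100):
            acc = 0.0
            for v in values[i]:
                acc += v * v
            assert abs(fast[i] - acc / 500) < 1e-12

    def test_gene_permutation_invariant(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(10, 60))
        np.testing.assert_allclose(
            cnv_signal(_profile(values)),
            cnv_signal(_profile(values[:, rng.permutation(60)])),
            atol=1e-14,
        )


class TestCnvCorrelation:
    def test_single_top_cell_correlates_perfectly_with_itself(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=30)
        values = np.vstack([base * 3] + [rng.normal(0, 0.01, 30) for _ in range(9)])
        corr = cnv_correlation(_profile(values), top_fraction=0.05)
        assert corr[0] == pytest.approx(1.0)

    def test_zero_variance_row_is_zero_with_warning(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(10, 20))
        values[4] = 1.5  # flat row
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = cnv_correlation(_profile(values))
        assert corr[4] == 0.0

    def test_top_cells_use_leave_one_out(self):
        # two strong aneuploid cells sharing a profile + quiet cells:
        # each top cell must be correlated against the *other* one
        rng = np.random.default_rng(4)
        base = rng.normal(size=40)
        values = np.vstack(
            [base * 2, base * 2 + rng.normal(0, 0.1, 40)]
            + [rng.normal(0, 0.01, 40) for _ in range(38)]
        )
        corr = cnv_correlation(_profile(values), top_fraction=0.05)
        assert corr[0] > 0.9 and corr[1] > 0.9


class TestClassifyMalignant:
    @pytest.mark.parametrize(
        "signal,corr,expected",
        [
            (0.06, 0.6, True),
            (0.05, 0.9, False),  # threshold itself is not "above"
            (0.2, 0.3, False),  # conjunction required
            (0.04, 0.9, False),
        ],
    )
    def test_strict_conjunction(self, signal, corr, expected):
        call = classify_malignant(np.array([signal]), np.array([corr]))
        assert bool(call["is_malignant"][0]) is expected


class TestInferCnvProfile:
    @staticmethod
    def _toy_annotation(gene_ids, genes_per_chrom=10):
        rows = []
        for i, g in enumerate(gene_ids):
            chrom = f"chr{i // genes_per_chrom + 1}"
            rows.append((g, chrom, (i % genes_per_chrom) * 100, (i % genes_per_chrom) * 100 + 50))
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])

    def test_reference_cells_center_at_zero(self):
        rng = np.random.default_rng(5)
        values = np.log1p(rng.gamma(2.0, 1.0, size=(30, 40)))
        norm = make_norm(values)
        ann = self._toy_annotation(norm.gene_ids)
        prof = infer_cnv_profile(norm, ann, np.arange(15), window=5)
        ref_mean = prof.values[prof.reference_mask].mean(axis=0)
        np.testing.assert_allclose(ref_mean, 0, atol=1e-10)

    def test_window_larger_than_chromosome_shrinks(self):
        rng = np.random.default_rng(6)
        values = np.log1p(rng.gamma(2.0, 1.0, size=(20, 25)))
        norm = make_norm(values)
        ann = self._toy_annotation(norm.gene_ids, genes_per_chrom=5)
        prof = infer_cnv_profile(norm, ann, np.arange(12), window=101)
        assert prof.values.shape == (25, 20)

    def test_even_window_rejected(self):
        norm = make_norm(np.ones((5, 12)))
        ann = self._toy_annotation(norm.gene_ids)
        with pytest.raises(ValueError, match="odd"):
            infer_cnv_profile(norm, ann, np.arange(12), window=10)

    def test_requires_reference_cells(self):
        norm = make_norm(np.ones((5, 12)))
        ann = self._toy_annotation(norm.gene_ids)
        with pytest.raises(ValueError, match="reference"):
            infer_cnv_profile(norm, ann, np.array([], dtype=int), window=5)

    def test_planted_gain_elevated_over_flanks(self, small_normalized):
        norm, ann, truth, kept = small_normalized
        mal = truth.is_malignant[kept]
        ref = np.isin(truth.cell_type[kept], ["TEC", "CAF", "TAM"])
        prof = infer_cnv_profile(norm, ann, np.flatnonzero(ref))
        gain = prof.chromosomes == "chr1"  # planted 1.5x gain
        neutral = prof.chromosomes == "chr7"  # no planted segment
        gain_mean = prof.values[mal][:, gain].mean()
        flank_mean = prof.values[mal][:, neutral].mean()
        assert gain_mean > 0
        assert gain_mean > flank_mean + 0.1

    def test_loss_depressed(self, small_normalized):
        norm, ann, truth, kept = small_normalized
        mal = truth.is_malignant[kept]
        ref = np.isin(truth.cell_type[kept], ["TEC", "CAF", "TAM"])
        prof = infer_cnv_profile(norm, ann, np.flatnonzero(ref))
        loss = prof.chromosomes == "chr2"  # planted 0.5x loss
        assert prof.values[mal][:, loss].mean() < -0.1


def test_doubling_dosage_amplitude_never_decreases_signal():
    medians = []
    for gain in (1.25, 1.5, 2.0):
        cfg = SimConfig(
            n_samples=1,
            cells_per_type={"CAF": 40, "TEC": 40, "TAM": 40, "malignant": 80},
            cnv_segments=[("chr1", 0, 300, gain), ("chr3", 0, 300, gain)],
            seed=7,
        )
        raw, ann, truth = simulate_dataset(cfg)
        qc = QCConfig()
        filtered, report = filter_cells(filter_genes(raw, qc), qc)
        norm = normalize_total(filtered, qc)
        kept = report["kept"].to_numpy()
        ref = np.isin(truth.cell_type[kept], ["TEC", "CAF", "TAM"])
        prof = infer_cnv_profile(norm, ann, np.flatnonzero(ref))
        medians.append(np.median(cnv_signal(prof)[truth.is_malignant[kept]]))
    assert medians[0] <= medians[1] <= medians[2]


def test_gene_annotation_round_trip(tmp_path):
    ann = pd.DataFrame(
        {"gene_id": ["a", "b"], "chrom": ["chr1", "chr1"], "start": [0, 100], "end": [50, 150]}
    )
    write_gene_annotation(ann, tmp_path / "genes.bed")
    back = read_gene_annotation(tmp_path / "genes.bed")
    pd.testing.assert_frame_equal(ann, back)
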