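"""Synthetic scRNA-seq data with known ground truth.

Generates multi-sample UMI count matrices with the structure the pipeline
assumes: discrete non-malignant cell types carrying marker-gene programs,
malignant cells with chromosome-segment dosage changes and tunable subclonal
divergence (the ground-truth knob behind the diversity score), mitochondrial
content, and planted ligand-receptor enrichment between a fibroblast-like
sender and the malignant population.

Counts follow a negative-binomial model: per-gene base means drawn from a
log-normal, a shared dispersion, per-cell log-normal library-size factors.
CNV dosage, marker folds, subclone log-fold offsets and L-R folds all act
multiplicatively on the NB mean. Mitochondrial genes live on their own
contig ("chrM"), outside any CNV segment, and are scaled per cell group so
the expected mitochondrial UMI fraction matches ``mito_fraction_target``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .annotation import DEFAULT_MARKER_PANEL
from .matrix import RawCountMatrix

__all__ = [
    "CELL_TYPES",
    "SimConfig",
    "GroundTruth",
    "generate_gene_annotation",
    "simulate_dataset",
    "simulate_qc_fixture",
]

CELL_TYPES: tuple[str, ...] = ("B", "CAF", "HPC-like", "T", "TAM", "TEC", "malignant")

# Genes carrying planted ligand-receptor / stemness structure, in addition
# to the marker panel; all named genes are placed on the last autosome.
_EXTRA_NAMED_GENES: tuple[str, ...] = (
    "COL1A1", "COL4A1", "COL4A2", "COL6A2", "FN1", "ITGA2", "ITGAV",
    "ICAM1", "SOX4", "BMI1", "SOX9", "SMAD2", "MYC",
)


class ConfigurationError(ValueError):
    pass


def _named_genes() -> list[str]:
    seen: dict[str, None] = {}
    for genes in DEFAULT_MARKER_PANEL.values():
        for g in genes:
            seen.setdefault(g)
    for g in _EXTRA_NAMED_GENES:
        seen.setdefault(g)
    return list(seen)


@dataclass
class SimConfig:
    """Generator parameters; defaults give a 4-sample, ~600-cell-per-sample
    cohort with a quarter of the autosomal genome under dosage change."""

    n_samples: int = 4
    cells_per_type: Mapping[str, int] = field(
        default_factory=lambda: {
            "T": 100,
            "B": 50,
            "TEC": 70,
            "CAF": 70,
            "TAM": 60,
            "HPC-like": 50,
            "malignant": 200,
        }
    )
    n_chromosomes: int = 20
    genes_per_chromosome: int = 300
    n_mito_genes: int = 13
    baseline_mean: float = 8.0
    nb_dispersion: float = 0.2
    marker_fold: float = 4.0
    mito_fraction_target: float = 0.05
    # a quarter of the autosomal genome under dosage change (gains and a loss)
    cnv_segments: Sequence[tuple[str, int, int, float]] = field(
        default_factory=lambda: [
            ("chr1", 0, 300, 1.5),
            ("chr2", 0, 300, 0.5),
            ("chr3", 0, 300, 1.5),
            ("chr4", 0, 300, 0.5),
            ("chr5", 0, 300, 1.5),
        ]
    )
    n_subclones: int = 4
    subclone_divergence: float | Sequence[float] = 0.5
    program_fraction: float = 0.10
    # each cell type carries a broad lineage program on top of its canonical
    # markers, as real lineages do; without it types differ in too few genes
    # for graph clustering to resolve them
    type_program_size: int = 100
    type_program_fold: float = 3.0
    lr_planted: Sequence[tuple[str, str, str, str, float]] = field(
        default_factory=lambda: [("COL1A1", "ITGA2", "CAF", "malignant", 4.0)]
    )
    # extra dosage segments private to one subclone:
    # (subclone index, chromosome, start gene, end gene, dosage)
    subclone_extra_segments: Sequence[tuple[int, str, int, int, float]] = field(
        default_factory=list
    )
    library_size_sigma: float = 0.25
    gene_scale_sigma: float = 0.5
    seed: int = 0

    @property
    def n_genes(self) -> int:
        """Autosomal gene count (mitochondrial genes are extra, on chrM)."""
        return self.n_chromosomes * self.genes_per_chromosome

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def divergence_of_sample(self, s: int) -> float:
        if isinstance(self.subclone_divergence, (int, float)):
            return float(self.subclone_divergence)
        return float(self.subclone_divergence[s])

    def validate(self) -> None:
        if self.n_chromosomes <= 0 or self.genes_per_chromosome <= 0:
            raise ConfigurationError("n_chromosomes and genes_per_chromosome must be > 0")
        if self.n_samples <= 0:
            raise ConfigurationError("n_samples must be > 0")
        if not self.cells_per_type:
            raise ConfigurationError("cells_per_type is empty")
        for t in self.cells_per_type:
            if t not in CELL_TYPES:
                raise ConfigurationError(f"unknown cell type {t!r}; allowed: {CELL_TYPES}")
        if not 0 <= self.mito_fraction_target < 1:
            raise ConfigurationError("mito_fraction_target must be in [0, 1)")
        if self.marker_fold <= 0 or self.baseline_mean <= 0 or self.nb_dispersion < 0:
            raise ConfigurationError("scale parameters must be positive")
        chroms = set(self.chromosomes)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, dosage in self.cnv_segments:
            if chrom not in chroms:
                raise ConfigurationError(f"CNV segment on unknown chromosome {chrom!r}")
            if dosage <= 0:
                raise ConfigurationError("dosage multipliers must be > 0")
            if not 0 <= start < end <= self.genes_per_chromosome:
                raise ConfigurationError(
                    f"segment [{start}, {end}) outside chromosome bounds "
                    f"[0, {self.genes_per_chromosome})"
                )
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, segs in by_chrom.items():
            segs = sorted(segs)
            for (s1, e1), (s2, _) in zip(segs, segs[1:]):
                if s2 < e1:
                    raise ConfigurationError(f"overlapping CNV segments on {chrom}")
        for lig, rec, sender, receiver, fold in self.lr_planted:
            if sender not in CELL_TYPES or receiver not in CELL_TYPES:
                raise ConfigurationError("lr_planted types must come from CELL_TYPES")
            if fold <= 0:
                raise ConfigurationError("lr_planted folds must be > 0")
        for ci, chrom, start, end, mult in self.subclone_extra_segments:
            if not 0 <= ci < self.n_subclones:
                raise ConfigurationError("subclone index out of range")
            if chrom not in chroms:
                raise ConfigurationError(f"subclone segment on unknown chromosome {chrom!r}")
            if mult <= 0:
                raise ConfigurationError("dosage multipliers must be > 0")
            if not 0 <= start < end <= self.genes_per_chromosome:
                raise ConfigurationError("subclone segment outside chromosome bounds")
        if isinstance(self.subclone_divergence, Sequence) and not isinstance(
            self.subclone_divergence, (str, bytes)
        ):
            if len(self.subclone_divergence) != self.n_samples:
                raise ConfigurationError(
                    "per-sample subclone_divergence must have n_samples entries"
                )
        named = _named_genes()
        if len(named) > self.genes_per_chromosome:
            raise ConfigurationError(
                f"genes_per_chromosome must be >= {len(named)} to host the named genes"
            )
        if min(self.divergence_of_sample(s) for s in range(self.n_samples)) < 0:
            raise ConfigurationError("subclone_divergence must be non-negative")
        if self.n_subclones <= 0:
            raise ConfigurationError("n_subclones must be > 0")

    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, Mapping):
                return dict(v)
            if isinstance(v, (list, tuple)):
                return [plain(x) for x in v]
            if isinstance(v, np.generic):
                return v.item()
            return v

        return {k: plain(v) for k, v in self.__dict__.items()}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline must recover."""

    cell_type: np.ndarray  # per cell
    is_malignant: np.ndarray  # per cell, bool
    subclone_id: np.ndarray  # per cell; None for non-malignant
    cnv_dosage: np.ndarray  # cells x genes multiplier; 1 everywhere for non-malignant
    divergence: dict[str, float]  # per sample
    sample_of_cell: np.ndarray
    lr_planted: list[tuple[str, str, str, str, float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_type": self.cell_type,
                "is_malignant": self.is_malignant,
                "subclone_id": [s if s is not None else "" for s in self.subclone_id],
                "sample": self.sample_of_cell,
            }
        )


def gene_names(config: SimConfig) -> list[str]:
    """Deterministic gene naming: generic ids, with the named marker /
    ligand-receptor genes occupying the head of the last autosome and
    ``MT-``-prefixed genes on chrM."""
    names = [f"G{i:05d}" for i in range(config.n_genes)]
    named = _named_genes()
    offset = (config.n_chromosomes - 1) * config.genes_per_chromosome
    for j, g in enumerate(named):
        names[offset + j] = g
    names += [f"MT-{j + 1}" for j in range(config.n_mito_genes)]
    return names


def generate_gene_annotation(config: SimConfig) -> pd.DataFrame:
    """BED-like gene table (gene_id, chrom, start, end; 0-based half-open).

    Gene starts increase strictly within each chromosome; mitochondrial
    genes sit on "chrM" so they never intersect a CNV segment. Deterministic
    given the config.
    """
    config.validate()
    names = gene_names(config)
    rows = []
    i = 0
    for chrom in config.chromosomes:
        for j in range(config.genes_per_chromosome):
            start = 10_000 * (j + 1)
            rows.append((names[i], chrom, start, start + 1_000))
            i += 1
    for j in range(config.n_mito_genes):
        start = 1_000 * (j + 1)
        rows.append((names[i], "chrM", start, start + 500))
        i += 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def _dosage_vector(config: SimConfig) -> np.ndarray:
    """Per-gene dosage multiplier from the planted segments (autosomes + chrM)."""
    dosage = np.ones(config.n_genes + config.n_mito_genes)
    chrom_offset = {c: i * config.genes_per_chromosome for i, c in enumerate(config.chromosomes)}
    for chrom, start, end, mult in config.cnv_segments:
        o = chrom_offset[chrom]
        dosage[o + start : o + end] = mult
    return dosage


def _subclone_dosages(config: SimConfig) -> list[np.ndarray]:
    """One dosage vector per subclone: shared trunk segments plus any
    subclone-private segments."""
    chrom_offset = {c: i * config.genes_per_chromosome for i, c in enumerate(config.chromosomes)}
    base = _dosage_vector(config)
    vectors = [base.copy() for _ in range(config.n_subclones)]
    for ci, chrom, start, end, mult in config.subclone_extra_segments:
        o = chrom_offset[chrom]
        vectors[ci][o + start : o + end] *= mult
    return vectors


def simulate_dataset(
    config: SimConfig,
) -> tuple[RawCountMatrix, pd.DataFrame, GroundTruth]:
    """Draw a multi-sample count matrix plus annotation and ground truth.

    Reproducible: the same config (including seed) yields a bitwise-identical
    matrix.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_auto, n_mito = config.n_genes, config.n_mito_genes
    n_total = n_auto + n_mito
    names = gene_names(config)
    name_idx = {g: i for i, g in enumerate(names)}
    annotation = generate_gene_annotation(config)

    # gene base expression scales
    scale = config.baseline_mean * rng.lognormal(0.0, config.gene_scale_sigma, n_total)
    mito_weights = rng.lognormal(0.0, 0.25, n_mito)
    mito_weights /= mito_weights.sum()

    # per-type multiplier vectors (markers + planted L-R genes)
    type_mult = {t: np.ones(n_total) for t in CELL_TYPES}
    for cell_type, markers in DEFAULT_MARKER_PANEL.items():
        for g in markers:
            type_mult[cell_type][name_idx[g]] *= config.marker_fold
    for lig, rec, sender, receiver, fold in config.lr_planted:
        type_mult[sender][name_idx[lig]] *= fold
        type_mult[receiver][name_idx[rec]] *= fold
    # broad lineage programs (generic genes only, so planted markers and
    # L-R genes keep their configured folds)
    named_idx = {name_idx[g] for g in _named_genes()}
    eligible = np.array([i for i in range(n_auto) if i not in named_idx])
    for cell_type in CELL_TYPES:
        if config.type_program_size > 0:
            program = rng.choice(eligible, size=min(config.type_program_size, len(eligible)), replace=False)
            type_mult[cell_type][program] *= config.type_program_fold

    subclone_dosage = _subclone_dosages(config)
    # one fixed program panel; each (sample, subclone) draws its own
    # i.i.d. log-fold offsets on it. Programs live on expressed genes
    # (upper half of base expression): perturbing near-silent genes has no
    # biological meaning and no expression footprint.
    program_size = max(1, int(round(config.program_fraction * n_auto)))
    generic = np.array([i for i in range(n_auto) if i not in named_idx])
    expressed = generic[scale[generic] >= np.median(scale[generic])]
    program_size = min(program_size, len(expressed))
    program_panel = rng.choice(expressed, size=program_size, replace=False)

    barcodes: list[str] = []
    sample_of_cell: list[str] = []
    cell_type_of: list[str] = []
    malignant_of: list[bool] = []
    subclone_of: list[str | None] = []
    blocks: list[np.ndarray] = []
    dosage_rows: list[np.ndarray] = []
    divergence: dict[str, float] = {}

    types_in_order = sorted(config.cells_per_type)
    cell_counter = 0
    for s in range(config.n_samples):
        sample = f"sample{s + 1}"
        sigma_d = config.divergence_of_sample(s)
        divergence[sample] = sigma_d
        # per-subclone multiplicative programs
        subclone_mult = []
        for c in range(config.n_subclones):
            offsets = rng.normal(0.0, sigma_d, program_size) if sigma_d > 0 else np.zeros(program_size)
            mult = np.ones(n_total)
            mult[program_panel] = np.exp(offsets)
            subclone_mult.append(mult)
        for cell_type in types_in_order:
            n_cells_t = int(config.cells_per_type[cell_type])
            if n_cells_t == 0:
                continue
            malignant = cell_type == "malignant"
            if malignant:
                subclones = rng.integers(0, config.n_subclones, n_cells_t)
            else:
                subclones = np.full(n_cells_t, -1)
            lib = rng.lognormal(0.0, config.library_size_sigma, n_cells_t)
            for c in np.unique(subclones):
                cells = np.flatnonzero(subclones == c)
                mean_g = scale * type_mult[cell_type]
                if malignant:
                    mean_g = mean_g * subclone_dosage[int(c)] * subclone_mult[int(c)]
                # mitochondrial means: expected mito share == target per group
                auto_sum = mean_g[:n_auto].sum()
                tgt = config.mito_fraction_target
                mean_g = mean_g.copy()
                mean_g[n_auto:] = (
                    mito_weights * (tgt / (1 - tgt)) * auto_sum if tgt > 0 else 0.0
                )
                mu = mean_g[:, None] * lib[cells][None, :]
                if config.nb_dispersion > 0:
                    nb_n = 1.0 / config.nb_dispersion
                    nb_p = nb_n / (nb_n + mu)
                    counts = rng.negative_binomial(nb_n, nb_p)
                else:
                    counts = rng.poisson(mu)
                blocks.append(counts)
                for cell in cells:
                    barcodes.append(f"{sample}-C{cell_counter + cell:05d}")
                row_dosage = subclone_dosage[int(c)] if malignant else np.ones(n_total)
                dosage_rows.extend([row_dosage] * len(cells))
                sample_of_cell.extend([sample] * len(cells))
                cell_type_of.extend([cell_type] * len(cells))
                malignant_of.extend([malignant] * len(cells))
                subclone_of.extend(
                    [f"{sample}.subclone{int(c)}" if malignant else None] * len(cells)
                )
            cell_counter += n_cells_t

    counts = sp.csr_matrix(np.concatenate(blocks, axis=1).astype(np.int64))
    raw = RawCountMatrix(
        counts=counts,
        gene_ids=np.array(names, dtype=object),
        barcodes=np.array(barcodes, dtype=object),
        sample_of_cell=np.array(sample_of_cell, dtype=object),
    )
    truth = GroundTruth(
        cell_type=np.array(cell_type_of, dtype=object),
        is_malignant=np.array(malignant_of, dtype=bool),
        subclone_id=np.array(subclone_of, dtype=object),
        cnv_dosage=np.vstack(dosage_rows),
        divergence=divergence,
        sample_of_cell=np.array(sample_of_cell, dtype=object),
        lr_planted=[tuple(x) for x in config.lr_planted],
    )
    return raw, annotation, truth


def write_dataset(
    raw: RawCountMatrix,
    annotation: pd.DataFrame,
    truth: GroundTruth,
    config: SimConfig,
    outdir,
) -> None:
    """Write the 10x triplet, BED-like annotation, ground-truth TSV and config."""
    from .cnv import write_gene_annotation
    from .matrix import write_counts

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts(raw, outdir)
    write_gene_annotation(annotation, outdir / "genes.bed")
    truth.to_frame().to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    config.to_yaml(outdir / "sim_config.yaml")


def simulate_qc_fixture(
    n_genes: int = 620,
    n_mito_genes: int = 13,
    n_cells: int = 60,
    k_low_gene: int = 5,
    k_high_mito: int = 4,
    k_rare_gene: int = 7,
    min_genes_per_cell: int = 500,
    seed: int = 0,
) -> tuple[RawCountMatrix, dict]:
    """A QC fixture with exactly countable planted violations.

    Normal cells express every non-rare gene (so no accidental failures);
    ``k_low_gene`` cells express exactly ``min_genes_per_cell`` - 1 genes
    with no mitochondrial reads; ``k_high_mito`` cells carry ~40%
    mitochondrial UMIs but plenty of genes; ``k_rare_gene`` genes are
    detected in exactly 2 cells. The violation sets are disjoint, so QC
    removal counts must equal the planted counts exactly.
    """
    if n_genes - k_rare_gene < min_genes_per_cell - 1:
        raise ConfigurationError("not enough non-rare genes for the low-gene cells")
    n_normal = n_cells - k_low_gene - k_high_mito
    if n_normal < 3:
        raise ConfigurationError("need at least 3 normal cells")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)] + [
        f"MT-{j + 1}" for j in range(n_mito_genes)
    ]
    rare = np.arange(n_genes - k_rare_gene, n_genes)
    nonrare = np.arange(n_genes - k_rare_gene)
    mito = np.arange(n_genes, n_genes + n_mito_genes)
    X = np.zeros((n_genes + n_mito_genes, n_cells), dtype=np.int64)

    col = 0
    normal_cols = range(col, col + n_normal)
    for c in normal_cols:
        X[nonrare, c] = rng.poisson(2.0, len(nonrare)) + 1
        auto_total = X[nonrare, c].sum()
        mito_total = int(round(0.05 / 0.95 * auto_total))
        X[mito, c] = rng.multinomial(mito_total, np.ones(n_mito_genes) / n_mito_genes)
    col += n_normal
    for g in rare:  # detected in exactly 2 normal cells
        cells = rng.choice(n_normal, size=2, replace=False)
        X[g, cells] = 1
    low_cols = range(col, col + k_low_gene)
    for c in low_cols:
        expressed = rng.choice(nonrare, size=min_genes_per_cell - 1, replace=False)
        X[expressed, c] = 1
    col += k_low_gene
    high_cols = range(col, col + k_high_mito)
    for c in high_cols:
        X[nonrare, c] = 1
        mito_total = int(round(0.4 / 0.6 * len(nonrare)))
        X[mito, c] = rng.multinomial(mito_total, np.ones(n_mito_genes) / n_mito_genes)

    barcodes = np.array([f"cell{c:04d}" for c in range(n_cells)], dtype=object)
    raw = RawCountMatrix(
        counts=sp.csr_matrix(X),
        gene_ids=np.array(gene_ids, dtype=object),
        barcodes=barcodes,
    )
    truth = {
        "k_low_gene": k_low_gene,
        "k_high_mito": k_high_mito,
        "k_rare_gene": k_rare_gene,
        "low_gene_barcodes": set(barcodes[list(low_cols)]),
        "high_mito_barcodes": set(barcodes[list(high_cols)]),
        "rare_genes": {gene_ids[g] for g in rare},
    }
    return raw, truth
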