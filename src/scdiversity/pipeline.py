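"""End-to-end orchestration: QC -> features -> annotation -> CNV ->
diversity -> differential expression -> crosstalk.

Every stage writes its table to the output directory as it completes, a
manifest records input hashes, the full config and the seed, and all
randomness derives from one global seed, so a rerun with identical inputs
reproduces identical outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import DEFAULT_MARKER_PANEL, annotate_cells
from .cnv import (
    classify_malignant,
    cnv_correlation,
    cnv_signal,
    infer_cnv_profile,
)
from .crosstalk import DEFAULT_LR_PAIRS, permutation_test, read_lr_pairs
from .diversity import DiversityConfig, sample_diversity
from .downstream import STEMNESS_GENES, group_de, signature_score
from .features import HVGConfig, run_pca, run_tsne, scale_matrix, select_hvg
from .matrix import RawCountMatrix, read_counts
from .qc import QCConfig, filter_cells, filter_genes, normalize_total

logger = logging.getLogger("scdiversity")

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class FeatureStageConfig:
    n_pcs: int = 20
    run_tsne: bool = False
    tsne_perplexity: float = 30.0


@dataclass
class AnnotationStageConfig:
    resolution: float = 1.0
    n_neighbors: int = 15


@dataclass
class CNVStageConfig:
    window: int = 101
    clip: float = 3.0
    signal_min: float = 0.05
    corr_min: float = 0.5
    top_fraction: float = 0.05
    reference_types: tuple[str, ...] = ("TEC", "CAF", "TAM")


@dataclass
class CrosstalkStageConfig:
    sender: str = "CAF"
    receiver: str = "malignant"
    n_permutations: int = 1000
    min_fraction: float = 0.10
    pairs_path: str | None = None


@dataclass
class PipelineConfig:
    """Single source of truth for every stage threshold plus the global seed."""

    qc: QCConfig = field(default_factory=QCConfig)
    hvg: HVGConfig = field(default_factory=HVGConfig)
    features: FeatureStageConfig = field(default_factory=FeatureStageConfig)
    annotation: AnnotationStageConfig = field(default_factory=AnnotationStageConfig)
    cnv: CNVStageConfig = field(default_factory=CNVStageConfig)
    diversity: DiversityConfig = field(default_factory=DiversityConfig)
    crosstalk: CrosstalkStageConfig = field(default_factory=CrosstalkStageConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cnv"]["reference_types"] = list(d["cnv"]["reference_types"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sub = {
            "qc": QCConfig,
            "hvg": HVGConfig,
            "features": FeatureStageConfig,
            "annotation": AnnotationStageConfig,
            "cnv": CNVStageConfig,
            "diversity": DiversityConfig,
            "crosstalk": CrosstalkStageConfig,
        }
        kwargs = {}
        for key, klass in sub.items():
            if key in d:
                payload = dict(d.pop(key))
                if key == "cnv" and "reference_types" in payload:
                    payload["reference_types"] = tuple(payload["reference_types"])
                kwargs[key] = klass(**payload)
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineResult:
    cells: pd.DataFrame
    diversity: pd.DataFrame
    cell_distances: pd.DataFrame
    de: pd.DataFrame | None
    interactions: pd.DataFrame | None
    hvg: pd.DataFrame
    manifest: dict


def _sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, outdir: Path, name: str) -> None:
    df.to_csv(outdir / name, sep="\t", index=False, float_format="%.10g")
    logger.info("wrote %s (%d rows)", name, len(df))


def run_pipeline(
    raw: RawCountMatrix | dict,
    gene_annotation: pd.DataFrame,
    config: PipelineConfig | None = None,
    outdir=None,
    input_paths: dict | None = None,
) -> PipelineResult:
    """Run all stages on a count matrix and write stage outputs + manifest.

    ``raw`` may be an in-memory RawCountMatrix or a dict of 10x paths
    (mtx/features/barcodes[/samples]). A stage failure raises
    PipelineStageError naming the stage; outputs of completed stages remain
    on disk.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    if isinstance(raw, dict):
        input_paths = dict(raw)
        raw = read_counts(
            raw["mtx"], raw["features"], raw["barcodes"], raw.get("samples")
        )

    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": [],
    }
    if input_paths:
        manifest["input_hashes"] = {
            k: _sha256_file(v) for k, v in input_paths.items() if v is not None
        }

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"].append(name)

    try:
        stage("qc")
        raw_f = filter_genes(raw, config.qc)
        raw_f, qc_report = filter_cells(raw_f, config.qc)
        norm = normalize_total(raw_f, config.qc)
        if outdir is not None:
            _write(qc_report, outdir, "qc_report.tsv")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("qc", e) from e

    try:
        stage("features")
        hvg_genes, hvg_stats = select_hvg(norm, config.hvg)
        scaled, kept_genes = scale_matrix(norm, hvg_genes)
        k = min(config.features.n_pcs, scaled.shape[0], norm.n_cells - 1)
        pcs = run_pca(scaled, k)
        tsne_coords = None
        if config.features.run_tsne:
            perplexity = min(
                config.features.tsne_perplexity, max(2.0, (norm.n_cells - 1) / 4)
            )
            tsne_coords = run_tsne(
                pcs, n_pcs=min(config.features.n_pcs, pcs.n_components),
                seed=config.seed, perplexity=perplexity,
            )
        if outdir is not None:
            _write(hvg_stats, outdir, "hvg.tsv")
            pd.DataFrame(
                {"component": np.arange(1, k + 1), "eigenvalue": pcs.eigenvalues}
            ).to_csv(outdir / "eigenvalues.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("features", e) from e

    try:
        stage("annotation")
        ann_table = annotate_cells(
            norm,
            pcs,
            DEFAULT_MARKER_PANEL,
            resolution=config.annotation.resolution,
            seed=config.seed,
            n_neighbors=config.annotation.n_neighbors,
        )
        if outdir is not None:
            _write(ann_table, outdir, "annotation.tsv")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("annotation", e) from e

    try:
        stage("cnv")
        reference = np.isin(ann_table["type"].to_numpy(), config.cnv.reference_types)
        profile = infer_cnv_profile(
            norm,
            gene_annotation,
            np.flatnonzero(reference),
            window=config.cnv.window,
            clip=config.cnv.clip,
        )
        signal = cnv_signal(profile)
        corr = cnv_correlation(profile, config.cnv.top_fraction)
        calls = classify_malignant(
            signal, corr, config.cnv.signal_min, config.cnv.corr_min
        )
        if outdir is not None:
            _write(
                pd.concat(
                    [pd.DataFrame({"barcode": norm.barcodes}), calls], axis=1
                ),
                outdir,
                "malignancy.tsv",
            )
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("cnv", e) from e

    try:
        stage("diversity")
        tumor_mask = calls["is_malignant"].to_numpy()
        expr_div, expr_cells = sample_diversity(
            scaled.T, norm.sample_of_cell, tumor_mask, config.diversity
        )
        cnv_div, _ = sample_diversity(
            profile.values, norm.sample_of_cell, tumor_mask, config.diversity,
            assign=False,
        )
        diversity_table = expr_div.rename(columns={"score": "score_expression"}).merge(
            cnv_div[["sample", "score"]].rename(columns={"score": "score_cnv"}),
            on="sample",
            how="left",
        )
        excluded = diversity_table.loc[~diversity_table["included"], "sample"].tolist()
        for s in excluded:
            logger.info(
                "sample %s excluded from grouping: <= %d tumor cells",
                s, config.diversity.min_tumor_cells,
            )
        expr_cells = expr_cells.assign(
            barcode=norm.barcodes[expr_cells["cell_index"].to_numpy()]
        )
        if outdir is not None:
            _write(diversity_table, outdir, "diversity.tsv")
            _write(
                expr_cells[["barcode", "sample", "distance", "outlier"]],
                outdir,
                "cell_distances.tsv",
            )
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("diversity", e) from e

    de = None
    try:
        stage("downstream")
        group_of_sample = dict(
            zip(diversity_table["sample"], diversity_table["group"])
        )
        tumor_groups = np.array(
            [
                group_of_sample.get(s) if m else None
                for s, m in zip(norm.sample_of_cell, tumor_mask)
            ],
            dtype=object,
        )
        has_both = {"high", "low"} <= set(
            g for g in tumor_groups if isinstance(g, str)
        )
        if has_both:
            tumor_norm = norm.subset_cells(tumor_mask)
            de = group_de(tumor_norm, tumor_groups[tumor_mask])
            stem = signature_score(norm, [g for g in STEMNESS_GENES if g in set(norm.gene_ids)])
            if outdir is not None:
                _write(de, outdir, "de_results.tsv")
                _write(
                    stem.rename("stemness_score").reset_index(), outdir,
                    "signature_scores.tsv",
                )
        else:
            logger.warning("skipping DE: need tumor cells in both diversity groups")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("downstream", e) from e

    interactions = None
    try:
        stage("crosstalk")
        types = ann_table["type"].to_numpy(dtype=object).copy()
        types[tumor_mask] = "malignant"  # malignancy call takes precedence
        pairs = (
            read_lr_pairs(config.crosstalk.pairs_path)
            if config.crosstalk.pairs_path
            else DEFAULT_LR_PAIRS
        )
        interactions = permutation_test(
            norm,
            types,
            pairs,
            sender_receiver=[(config.crosstalk.sender, config.crosstalk.receiver)],
            n_permutations=config.crosstalk.n_permutations,
            seed=config.seed,
            min_fraction=config.crosstalk.min_fraction,
        )
        if outdir is not None:
            _write(interactions, outdir, "interactions.tsv")
    except Exception as e:  # noqa: BLE001
        raise PipelineStageError("crosstalk", e) from e

    cells = qc_report[qc_report["kept"]].reset_index(drop=True).copy()
    cells["cluster"] = ann_table["cluster"].to_numpy()
    cells["type"] = ann_table["type"].to_numpy()
    cells["cnv_signal"] = calls["cnv_signal"].to_numpy()
    cells["cnv_correlation"] = calls["cnv_correlation"].to_numpy()
    cells["is_malignant"] = calls["is_malignant"].to_numpy()
    cells["pc1"] = pcs.coordinates[:, 0]
    cells["pc2"] = pcs.coordinates[:, 1] if pcs.n_components > 1 else np.nan
    if tsne_coords is not None:
        cells["tsne1"], cells["tsne2"] = tsne_coords[:, 0], tsne_coords[:, 1]
    dist_of = dict(zip(expr_cells["barcode"], expr_cells["distance"]))
    out_of = dict(zip(expr_cells["barcode"], expr_cells["outlier"]))
    cells["distance"] = [dist_of.get(b, np.nan) for b in cells["barcode"]]
    cells["outlier"] = [bool(out_of.get(b, False)) for b in cells["barcode"]]

    if outdir is not None:
        _write(cells, outdir, "cells.tsv")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        cells=cells,
        diversity=diversity_table,
        cell_distances=expr_cells,
        de=de,
        interactions=interactions,
        hvg=hvg_stats,
        manifest=manifest,
    )
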