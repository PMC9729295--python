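"""End-to-end orchestration: diff -> KSEA -> (IHC) -> (pull-down).

`run_screen` executes the requested stages from a single
:class:`PipelineConfig`, writes per-stage TSVs (plus volcano and barcode
coordinate files) into the output directory, and emits a JSON manifest with
the config hash, seed, package version and per-stage row counts.  Identical
config + seed produces byte-identical outputs.  The global seed is fanned out
to named substreams so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, PhosphoscreenError
from .io import (align_annotations, read_annotation_table, read_intensity_table,
                 write_results_table)
from . import differential, ihc, ksea, pulldown

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All inputs, thresholds and the mandatory global seed for one run."""

    matrix_path: str
    annotations_path: str
    out_dir: str
    seed: int
    arm: str = "all"
    motifs_path: str | None = None  # enables the KSEA stage
    ihc_path: str | None = None  # enables the IHC stage (tidy cohort CSV/TSV)
    ihc_markers: tuple[str, ...] = ()
    pulldown_path: str | None = None  # enables the pull-down stage
    n_perm_mww: int = differential.DEFAULT_N_PERM
    n_perm_ksea: int = ksea.DEFAULT_N_PERM
    fc_threshold_log2: float = differential.DEFAULT_FC_THRESHOLD_LOG2
    p_threshold: float = differential.DEFAULT_P_THRESHOLD
    peptide_fdr_threshold: float = differential.DEFAULT_FDR_THRESHOLD
    ksea_fdr_threshold: float = ksea.DEFAULT_FDR_THRESHOLD
    pulldown_log2_threshold: float = pulldown.DEFAULT_LOG2_THRESHOLD
    bonferroni_m: int = ihc.DEFAULT_BONFERRONI_M

    def validate(self) -> None:
        for name in ("fc_threshold_log2", "p_threshold", "peptide_fdr_threshold",
                     "ksea_fdr_threshold", "pulldown_log2_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_perm_mww < 1 or self.n_perm_ksea < 1:
            raise ConfigError("permutation counts must be >= 1")
        if self.arm not in ("all", "standard", "experimental"):
            raise ConfigError(f"arm must be all/standard/experimental, got {self.arm!r}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "seed" not in raw:
        raise ConfigError("config must set a global seed (stochastic stages)")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    if "ihc_markers" in raw:
        raw["ihc_markers"] = tuple(raw["ihc_markers"])
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_screen(config: PipelineConfig) -> dict:
    """Run the configured stages; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seed_diff, seed_ksea = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2))
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    matrix = read_intensity_table(config.matrix_path)
    annotations = read_annotation_table(config.annotations_path)
    matrix, annotations = align_annotations(matrix, annotations)
    logger.info("loaded %d peptides x %d samples", *matrix.shape)

    # --- differential phosphopeptide stage ---------------------------------
    stage = "diff"
    try:
        res = differential.run_differential(
            matrix, annotations, arm=config.arm, n_perm=config.n_perm_mww,
            seed=seed_diff, fc_threshold_log2=config.fc_threshold_log2,
            p_threshold=config.p_threshold,
            fdr_threshold=config.peptide_fdr_threshold)
        write_results_table(res, out / "differential.tsv")
        write_results_table(res[["peptide_id", "volcano_x", "volcano_y", "cloud", "is_hit"]],
                            out / "volcano_coordinates.tsv")
        manifest["stages"][stage] = {"rows": len(res), "hits": int(res["is_hit"].sum())}
    except PhosphoscreenError as exc:
        _fail(out, manifest, stage, exc)

    # --- KSEA stage ---------------------------------------------------------
    if config.motifs_path is not None:
        stage = "ksea"
        try:
            patterns = ksea.read_motif_library(config.motifs_path)
            arm_anns = (annotations if config.arm == "all"
                        else [a for a in annotations if a.arm == config.arm])
            arm_matrix = matrix.restrict_samples([a.sample_id for a in arm_anns])
            results = ksea.ksea_run(
                arm_matrix, arm_anns, patterns, n_perm=config.n_perm_ksea,
                seed=seed_ksea, fdr_threshold=config.ksea_fdr_threshold)
            write_results_table(results, out / "ksea.tsv")
            sets = ksea.build_kinase_sets(arm_matrix, patterns)
            barcode = pd.DataFrame(
                [(s.kinase_id, pos)
                 for s in sets
                 for pos in ksea.barcode_positions(arm_matrix, arm_anns, s)],
                columns=["kinase_id", "rank_position"])
            write_results_table(barcode, out / "ksea_barcode_coordinates.tsv")
            manifest["stages"][stage] = {
                "rows": len(results),
                "significant": sum(r.significant for r in results)}
        except PhosphoscreenError as exc:
            _fail(out, manifest, stage, exc)

    # --- IHC stage ----------------------------------------------------------
    if config.ihc_path is not None:
        stage = "ihc"
        try:
            sep = "," if str(config.ihc_path).endswith(".csv") else "\t"
            cohort = pd.read_csv(config.ihc_path, sep=sep)
            markers = list(config.ihc_markers) or sorted(cohort["marker"].unique())
            assocs = [ihc.association_test(cohort[cohort["marker"] == m],
                                           m_comparisons=config.bonferroni_m)
                      for m in markers]
            write_results_table(assocs, out / "ihc_associations.tsv")
            manifest["stages"][stage] = {"rows": len(assocs)}
            if len(markers) >= 2:
                combined = ihc.combined_marker_rate(cohort, markers[0], markers[1])
                write_results_table([combined], out / "ihc_combined.tsv")
                manifest["stages"][stage]["combined_pair"] = markers[:2]
        except PhosphoscreenError as exc:
            _fail(out, manifest, stage, exc)

    # --- pull-down stage ----------------------------------------------------
    if config.pulldown_path is not None:
        stage = "pulldown"
        try:
            table = pulldown.read_pulldown_table(config.pulldown_path)
            points = pulldown.score_and_filter(
                pulldown.prepare(table),
                log2_threshold=config.pulldown_log2_threshold)
            write_results_table(points, out / "pulldown_points.tsv")
            manifest["stages"][stage] = {
                "rows": len(points),
                "candidates": sum(p.is_candidate for p in points)}
        except PhosphoscreenError as exc:
            _fail(out, manifest, stage, exc)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _fail(out: Path, manifest: dict, stage: str, exc: Exception) -> None:
    partial = out / "manifest.json.partial"
    manifest["stages"][stage] = {"error": str(exc)}
    partial.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    raise PhosphoscreenError(f"stage {stage!r} failed: {exc}") from exc
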