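"""End-to-end orchestration: simulate/extract → count → test → report.

``run_pipeline`` executes the full analysis on either simulated reads or
user-supplied FASTA/FASTQ files, writes every intermediate artifact as
TSV under an output directory, and records a JSON manifest with the
seed, per-stage record counts and SHA-256 digests of all outputs, so a
rerun with the same configuration is bit-identical and the read → ditag
→ tag → UniTag accounting can be audited after the fact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import de as de_mod
from . import expression as expr
from . import extraction as extr
from . import synthetic as syn

logger = logging.getLogger("supersage")


def configure_logging(level: str = "INFO") -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML/JSON."""

    out_dir: Union[str, Path] = "supersage_out"
    reads: list[str] = field(default_factory=list)
    references: str | None = None
    reference_labels: str | None = None
    sim: syn.SimConfig | None = None
    thresholds: de_mod.Thresholds = field(default_factory=de_mod.Thresholds)
    max_mismatch: int = 3
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.reads and self.sim is None:
            # default to a simulation seeded by the pipeline seed
            self.sim = syn.SimConfig(seed=self.seed)
        for path in list(self.reads) + [self.references, self.reference_labels]:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured input does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if "sim" in data and data["sim"] is not None:
            data["sim"] = syn.SimConfig.from_mapping(data["sim"])
        if "thresholds" in data and data["thresholds"] is not None:
            data["thresholds"] = de_mod.Thresholds(**data["thresholds"])
        return cls(**data)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclass
class PipelineBundle:
    """Paths of all artifacts of one run plus the in-memory results."""

    out_dir: Path
    table: pd.DataFrame
    results: pd.DataFrame
    candidates: pd.DataFrame
    summary: expr.LibrarySummary
    annotation: pd.DataFrame | None
    manifest: dict


def run_pipeline(config: PipelineConfig) -> PipelineBundle:
    """Execute extract → count → classify → normalize → test → annotate
    → select → report and write the artifact bundle."""
    configure_logging(config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "digests": {}}

    stage = "simulate/parse"
    try:
        if config.reads:
            reads = [r for path in config.reads for r in extr.parse_reads(path)]
            truth = None
        else:
            assert config.sim is not None
            transcripts = syn.generate_transcriptome(
                config.sim.n_transcripts,
                config.sim.length_range,
                seed=config.sim.seed,
            )
            truth = syn.assign_expression(transcripts, config.sim)
            simulated = syn.simulate_reads(truth, config.sim)
            syn.write_truth(truth, out_dir / "truth.tsv")
            reads = [r for lib in ("W", "F") for r in simulated.reads[lib]]
            manifest["stages"]["simulated_draws"] = simulated.draw_totals()
        manifest["stages"]["reads"] = len(reads)
        logger.info("%s: %d reads", stage, len(reads))

        stage = "extract"
        extraction = extr.extract_tags(reads)
        extr.tags_to_tsv(extraction, out_dir / "tags.tsv")
        extr.rejections_to_tsv(extraction.rejections, out_dir / "rejections.tsv")
        manifest["stages"]["retained_ditags"] = extraction.n_retained
        manifest["stages"]["rejections"] = extraction.rejection_counts()
        manifest["stages"]["tags"] = {
            lib: len(t) for lib, t in extraction.tags.items()
        }
        logger.info(
            "%s: %d ditags retained, %d rejections",
            stage,
            extraction.n_retained,
            len(extraction.rejections),
        )

        stage = "count/classify/normalize"
        table = expr.normalize(expr.classify_unitags(expr.count_tags(extraction.tags)))
        expr.write_table(table, out_dir / "count_table.tsv")
        summary = expr.summarize_library(table)
        summary.to_frame().to_csv(out_dir / "library_features.tsv", sep="\t", index=False)
        manifest["stages"]["unique_tags"] = len(table)
        manifest["stages"]["unitags"] = summary.unitags["total"]
        manifest["stages"]["singletons"] = summary.singletons["total"]
        logger.info(
            "%s: %d unique tags (%d unitags, %d singletons)",
            stage,
            len(table),
            summary.unitags["total"],
            summary.singletons["total"],
        )

        stage = "test"
        results = de_mod.de_test(table, thresholds=config.thresholds)
        de_mod.write_results(results, out_dir / "de_results.tsv")
        volcano = de_mod.volcano_table(results, table)
        de_mod.write_results(volcano, out_dir / "volcano.tsv")
        n_called = int(results["direction"].isin(["up", "down"]).sum())
        manifest["stages"]["tested_unitags"] = len(results)
        manifest["stages"]["de_calls"] = n_called
        logger.info("%s: %d unitags tested, %d called", stage, len(results), n_called)

        stage = "annotate"
        annotation_df = None
        regulatory: dict[str, bool] = {}
        if config.references:
            refs = ann.ReferenceSet.from_fasta(config.references)
            if config.reference_labels:
                refs.load_labels(config.reference_labels)
            annotation_df, tier_summary = ann.annotate_table(
                table, refs, max_mismatch=config.max_mismatch
            )
            ann.write_annotation(annotation_df, out_dir / "annotation.tsv")
            tier_summary.to_csv(out_dir / "annotation_tiers.tsv", sep="\t")
            regulatory = ann.regulatory_flags(annotation_df, refs)
            manifest["stages"]["annotated"] = int(
                (annotation_df["tier"] != ann.NO_HIT).sum()
            )
            logger.info("%s: %d/%d tags annotated", stage,
                        manifest["stages"]["annotated"], len(annotation_df))

        stage = "select"
        candidates = de_mod.select_candidates(
            results, table, regulatory, thresholds=config.thresholds
        )
        de_mod.write_results(candidates, out_dir / "candidates.tsv")
        manifest["stages"]["candidates"] = int(candidates["candidate"].sum())

        stage = "report"
        render_reports(table, results, candidates, summary, out_dir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for path in sorted(out_dir.glob("*.tsv")):
        manifest["digests"][path.name] = _sha256(path)
    with open(out_dir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return PipelineBundle(
        out_dir, table, results, candidates, summary, annotation_df, manifest
    )


def fc_histogram(results: pd.DataFrame, n_bins: int = 16) -> pd.DataFrame:
    """Fold-change distribution of the called (up/down) tags.

    Bins are regular on the log2 scale over the observed range; counts
    sum to the number of called tags.
    """
    called = results[results["direction"].isin(["up", "down"])]
    if len(called) == 0:
        return pd.DataFrame(columns=["bin_low", "bin_high", "count"])
    log_fc = np.log2(called["fc"].to_numpy())
    edges = np.linspace(log_fc.min(), log_fc.max(), n_bins + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)
    counts, _ = np.histogram(log_fc, bins=edges)
    return pd.DataFrame(
        {
            "bin_low": 2.0 ** edges[:-1],
            "bin_high": 2.0 ** edges[1:],
            "count": counts,
        }
    )


def render_reports(
    table: pd.DataFrame,
    results: pd.DataFrame,
    candidates: pd.DataFrame,
    summary: expr.LibrarySummary,
    out_dir: Union[str, Path],
) -> dict[str, Path]:
    """Write the human-readable report tables.

    library features (depth/diversity/abundance classes), the candidate
    list sorted by fold change, the fold-change histogram of called tags,
    and the abundance-vs-fold-change table of all tested tags.
    """
    out_dir = Path(out_dir)
    paths: dict[str, Path] = {}
    paths["library_features"] = out_dir / "library_features.tsv"
    summary.to_frame().to_csv(paths["library_features"], sep="\t", index=False)

    paths["candidate_list"] = out_dir / "candidate_list.tsv"
    cand = candidates[candidates["candidate"]].sort_values(
        "fc", ascending=False, kind="mergesort"
    )
    cand.to_csv(paths["candidate_list"], sep="\t", index=False)

    paths["fc_histogram"] = out_dir / "fc_histogram.tsv"
    fc_histogram(results).to_csv(paths["fc_histogram"], sep="\t", index=False)

    paths["abundance_vs_fc"] = out_dir / "abundance_vs_fc.tsv"
    volcano = de_mod.volcano_table(results, table)
    volcano[["tag", "log2_fc", "cpm"]].assign(
        log10_cpm=np.log10(volcano["cpm"].to_numpy())
    ).to_csv(paths["abundance_vs_fc"], sep="\t", index=False)
    return paths
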