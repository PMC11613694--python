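"""End-to-end discovery workflow: normalize -> call -> control frequencies ->
trio 0-1-1 -> frequency filter -> merge -> size filter -> annotate.

The core path is deterministic: two runs on identical inputs produce identical
primary outputs. Every filter stage records its in/out counts in the run log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import caller, events as ev_mod, frequency, trio as trio_mod
from .caller import CNMatrix
from .depth import DepthMatrix
from .events import DeletionEvent
from .formats import (
    AnnotationTables,
    RegionSet,
    TrioSet,
    read_gene_flags,
    read_interval_bed,
    read_pedigree,
    read_region_table,
    read_roh_bed,
    write_event_table,
)
from .frequency import FdelTable
from .trio import TrioCall

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class Thresholds:
    max_fdel: float = frequency.DEFAULT_MAX_FDEL
    min_size: int = ev_mod.DEFAULT_MIN_SIZE
    max_gap: int = ev_mod.DEFAULT_MAX_GAP
    min_region_median: float = caller.DEFAULT_MIN_REGION_MEDIAN
    cn_max: int = caller.DEFAULT_CN_MAX
    roh_min: int = ev_mod.DEFAULT_ROH_MIN


@dataclass
class PipelineConfig:
    regions_path: str
    pedigree_path: str
    case_depth_path: str
    control_depth_path: str
    output_dir: str
    regions_format: str = "tsv"
    gene_flags_path: str | None = None
    segdup_path: str | None = None
    roh_path: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0  # unused by the deterministic core path; reserved

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        thr = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=thr, **raw)


@dataclass
class DiscoveryResult:
    events: list[DeletionEvent]
    de_novo: list[TrioCall]
    fdel_table: FdelTable
    passing_loci: list[str]  # region ids backing the final events (singleton-screen targets)
    stage_counts: dict[str, tuple[int, int]]  # stage -> (in, out)
    cn_cases: CNMatrix
    cn_controls: CNMatrix


def discover_events(
    case_depths: DepthMatrix,
    control_depths: DepthMatrix,
    trios: TrioSet,
    regions: RegionSet,
    annot: AnnotationTables | None = None,
    thresholds: Thresholds | None = None,
) -> DiscoveryResult:
    """Run the full trio discovery workflow in memory.

    Filter order is frequency -> merge -> size: fdel is a per-region quantity
    so it must be applied before region-level calls are merged, and size is a
    per-event quantity so it must follow merging.
    """
    thr = thresholds or Thresholds()
    counts: dict[str, tuple[int, int]] = {}

    def stage(name, func, *args, **kwargs):
        try:
            return func(*args, **kwargs)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, exc) from exc

    case_samples = set(case_depths.sample_ids)
    missing = [s for s in trios.all_sample_ids if s not in case_samples]
    if missing:
        raise StageError("input_check", ValueError(
            f"pedigree sample(s) absent from case depth matrix: {missing[:5]}"))

    ratios_cases = stage("normalize_cases", caller.normalize_depth_matrix,
                         case_depths, min_region_median=thr.min_region_median)
    cn_cases = stage("call_cases", caller.call_copy_numbers, ratios_cases, cn_max=thr.cn_max)
    ratios_ctrl = stage("normalize_controls", caller.normalize_depth_matrix,
                        control_depths, min_region_median=thr.min_region_median)
    cn_ctrl = stage("call_controls", caller.call_copy_numbers, ratios_ctrl, cn_max=thr.cn_max)

    fdel = stage("control_frequency", frequency.heterozygous_deletion_frequency, cn_ctrl)

    calls = stage("trio_genotyping", trio_mod.find_inherited_biallelic, cn_cases, trios)
    de_novo = stage("de_novo_flagging", trio_mod.flag_de_novo_candidates, cn_cases, trios)

    filtered = stage("frequency_filter", frequency.apply_frequency_filter,
                     calls, fdel, max_fdel=thr.max_fdel)
    counts["frequency_filter"] = (len(calls), len(filtered))

    merged = stage("merge", ev_mod.merge_contiguous_calls, filtered, regions,
                   max_gap=thr.max_gap, region_mask=cn_cases.region_mask, fdel=fdel)
    counts["merge"] = (len(filtered), len(merged))

    sized = stage("size_filter", ev_mod.apply_size_filter, merged, min_size=thr.min_size)
    counts["size_filter"] = (len(merged), len(sized))

    if annot is not None:
        sized = stage("annotate", ev_mod.annotate_events, sized, annot, regions,
                      roh_min=thr.roh_min)

    passing_loci = sorted({rid for ev in sized for rid in ev.region_ids},
                          key=regions.index_of)
    for name, (n_in, n_out) in counts.items():
        logger.info("stage %s: %d in, %d retained, %d removed", name, n_in, n_out, n_in - n_out)
    return DiscoveryResult(
        events=sized,
        de_novo=de_novo,
        fdel_table=fdel,
        passing_loci=passing_loci,
        stage_counts=counts,
        cn_cases=cn_cases,
        cn_controls=cn_ctrl,
    )


def run_ar_discovery(config: PipelineConfig) -> DiscoveryResult:
    """File-driven front end of :func:`discover_events`.

    Writes the event TSV/BED, fdel table, de novo candidate list, the passing
    loci for the targeted singleton screen, and a run log with per-stage
    counts into ``config.output_dir``.
    """

    def load(name, func, *args, **kwargs):
        try:
            return func(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc

    regions = load("read_regions", read_region_table, config.regions_path, config.regions_format)
    trios = load("read_pedigree", read_pedigree, config.pedigree_path)
    case_depths = load("read_case_depths", DepthMatrix.from_tsv, config.case_depth_path)
    control_depths = load("read_control_depths", DepthMatrix.from_tsv, config.control_depth_path)

    annot = None
    if config.gene_flags_path or config.segdup_path or config.roh_path:
        annot = AnnotationTables(
            gene_flags=load("read_gene_flags", read_gene_flags, config.gene_flags_path)
            if config.gene_flags_path else {},
            segdups=load("read_segdups", read_interval_bed, config.segdup_path)
            if config.segdup_path else [],
            roh=load("read_roh", read_roh_bed, config.roh_path) if config.roh_path else {},
        )

    result = discover_events(case_depths, control_depths, trios, regions,
                             annot=annot, thresholds=config.thresholds)

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_event_table(result.events, outdir / "events.tsv", format="tsv")
    write_event_table(result.events, outdir / "events.bed", format="bed")
    result.fdel_table.to_tsv(outdir / "fdel.tsv")
    trio_mod.write_trio_calls(result.de_novo, outdir / "de_novo_candidates.tsv")
    (outdir / "target_loci.txt").write_text("".join(f"{r}\n" for r in result.passing_loci))
    with (outdir / "run_log.txt").open("w") as fh:
        for name, (n_in, n_out) in result.stage_counts.items():
            fh.write(f"{name}\tin={n_in}\tretained={n_out}\tremoved={n_in - n_out}\n")
        fh.write(f"events_final\t{len(result.events)}\n")
    return result
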