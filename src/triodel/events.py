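"""Merging region-level CN0 calls into distinct deletion events, size
filtering, annotation, and morbid-gene enrichment summaries.

Calls for one sample are chained across regions that are consecutive in
RegionSet order, lie within ``max_gap`` of each other, and have no intervening
un-called unmasked region. Events from different samples with identical spans
are consolidated into one event listing all supporting samples — this is the
operational definition of a "distinct" deletion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .formats import AnnotationTables, RegionSet, chrom_sort_key
from .frequency import FdelTable
from .trio import Call, SingletonCall, TrioCall, PATTERN_SINGLETON

DEFAULT_MAX_GAP = 100_000
DEFAULT_MIN_SIZE = 8_000
DEFAULT_ROH_MIN = 2_000_000


@dataclass(frozen=True)
class DeletionEvent:
    """A merged multi-region homozygous deletion with supporting samples.

    ``start``/``end`` are the union span of the member regions (0-based
    half-open); ``size`` is the genomic span, not the sum of member lengths.
    Annotation fields are None until :func:`annotate_events` fills them
    (``roh_overlap`` stays None when ROH data is missing for every supporting
    sample — unknown, not false).
    """

    chrom: str
    start: int
    end: int
    region_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    pattern: str
    fdel_max: float | None = None
    genes: tuple[str, ...] = ()
    omim_morbid: bool | None = None
    omim_ar: bool | None = None
    segdup_overlap: bool | None = None
    roh_overlap: bool | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("event end must exceed start")
        if not self.region_ids:
            raise ValueError("event must have at least one member region")

    @property
    def size(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[int, int, int, tuple[str, ...]]:
        return (chrom_sort_key(self.chrom), self.start, self.end, self.region_ids)


def _call_key(call: Call) -> str:
    return call.trio.proband_id if isinstance(call, TrioCall) else call.sample_id


def _call_pattern(call: Call) -> str:
    return call.pattern if isinstance(call, TrioCall) else PATTERN_SINGLETON


def merge_contiguous_calls(
    calls: Sequence[Call],
    regions: RegionSet,
    max_gap: int = DEFAULT_MAX_GAP,
    region_mask: Sequence[bool] | None = None,
    fdel: FdelTable | None = None,
) -> list[DeletionEvent]:
    """Chain each sample's called regions into events and consolidate
    identical spans across samples.

    ``region_mask`` (aligned with ``regions``) marks uninformative regions that
    may be skipped over when chaining; an unmasked un-called region between two
    calls breaks the chain regardless of gap size. ``fdel`` supplies the
    per-region frequencies from which each event's ``fdel_max`` is taken.
    """
    if region_mask is None:
        region_mask = np.zeros(len(regions), dtype=bool)
    else:
        region_mask = np.asarray(region_mask, dtype=bool)
        if region_mask.shape != (len(regions),):
            raise ValueError("region_mask length must match the RegionSet")

    # (sample key, pattern) -> sorted region indices
    by_sample: dict[tuple[str, str], list[int]] = {}
    for call in calls:
        idx = regions.index_of(call.region_id)  # raises on unknown region
        by_sample.setdefault((_call_key(call), _call_pattern(call)), []).append(idx)

    raw: dict[tuple, dict] = {}
    for (sample, pattern), idxs in by_sample.items():
        idxs = sorted(set(idxs))
        called = set(idxs)
        chains: list[list[int]] = [[idxs[0]]]
        for prev, cur in zip(idxs, idxs[1:]):
            if _chainable(prev, cur, regions, called, region_mask, max_gap):
                chains[-1].append(cur)
            else:
                chains.append([cur])
        for chain in chains:
            members = [regions[i] for i in chain]
            span = (
                members[0].chrom,
                min(r.start for r in members),
                max(r.end for r in members),
                tuple(r.region_id for r in members),
                pattern,
            )
            rec = raw.setdefault(span, {"samples": set()})
            rec["samples"].add(sample)

    events: list[DeletionEvent] = []
    for (chrom, start, end, region_ids, pattern), rec in raw.items():
        fdel_max: float | None = None
        if fdel is not None:
            known = [fdel.fdel(r) for r in region_ids if r in fdel]
            fdel_max = max(known) if known else None
        events.append(
            DeletionEvent(
                chrom=chrom,
                start=start,
                end=end,
                region_ids=region_ids,
                sample_ids=tuple(sorted(rec["samples"])),
                pattern=pattern,
                fdel_max=fdel_max,
            )
        )
    events.sort(key=DeletionEvent.sort_key)
    return events


def _chainable(
    prev: int,
    cur: int,
    regions: RegionSet,
    called: set[int],
    region_mask: np.ndarray,
    max_gap: int,
) -> bool:
    a, b = regions[prev], regions[cur]
    if a.chrom != b.chrom:
        return False
    if b.start - a.end > max_gap:  # overlapping regions give a negative gap
        return False
    for k in range(prev + 1, cur):
        if regions[k].chrom != a.chrom:
            continue
        if k not in called and not region_mask[k]:
            return False
    return True


def apply_size_filter(
    events: Sequence[DeletionEvent], min_size: int = DEFAULT_MIN_SIZE
) -> list[DeletionEvent]:
    """Retain events of at least ``min_size`` base pairs (inclusive)."""
    if min_size <= 0:
        raise ValueError(f"min_size must be positive, got {min_size}")
    return [ev for ev in events if ev.size >= min_size]


def annotate_events(
    events: Sequence[DeletionEvent],
    annot: AnnotationTables,
    regions: RegionSet,
    roh_min: int = DEFAULT_ROH_MIN,
) -> list[DeletionEvent]:
    """Attach gene symbols, OMIM flags, segdup overlap and autozygosity evidence.

    Segdup overlap is any >= 1 bp half-open intersection with the event span.
    Autozygosity requires the event to be fully contained in an ROH run of at
    least ``roh_min`` bp for a supporting sample: true if any supporting sample
    shows containment, false if all samples have ROH data and none does, and
    None (unknown) when data is missing and no containment was seen.
    """
    out: list[DeletionEvent] = []
    for ev in events:
        genes: list[str] = []
        for rid in ev.region_ids:
            g = regions.get(rid).gene_symbol
            if g and g not in genes:
                genes.append(g)
        flags = [annot.gene_flags.get(g) for g in genes]
        omim_morbid = any(f.omim_morbid for f in flags if f is not None)
        omim_ar = any(f.omim_ar for f in flags if f is not None)

        segdup = any(
            c == ev.chrom and s < ev.end and ev.start < e for c, s, e in annot.segdups
        )

        roh: bool | None
        statuses: list[bool | None] = []
        for sample in ev.sample_ids:
            runs = annot.roh.get(sample)
            if runs is None:
                statuses.append(None)
                continue
            statuses.append(
                any(
                    c == ev.chrom and e - s >= roh_min and s <= ev.start and ev.end <= e
                    for c, s, e in runs
                )
            )
        if any(s is True for s in statuses):
            roh = True
        elif statuses and all(s is False for s in statuses):
            roh = False
        else:
            roh = None

        out.append(
            replace(
                ev,
                genes=tuple(genes),
                omim_morbid=omim_morbid,
                omim_ar=omim_ar,
                segdup_overlap=segdup,
                roh_overlap=roh,
            )
        )
    return out


@dataclass(frozen=True)
class GeneDeletionRecord:
    """One gene's deletion observation: control frequency and event size."""

    gene_symbol: str
    fdel: float
    size: int


def morbid_enrichment(
    records: Sequence[GeneDeletionRecord],
    annot: AnnotationTables,
    fdel_bins: Sequence[float],
    size_bins: Sequence[float],
) -> pd.DataFrame:
    """Stratify gene-deletion records by (fdel bin x size bin) and tabulate the
    proportion involving OMIM-morbid genes.

    Bins are half-open ``[edge_i, edge_{i+1})``. Empty cells report counts of
    zero and an undefined (NaN) proportion.
    """
    fdel_edges = np.asarray(fdel_bins, dtype=float)
    size_edges = np.asarray(size_bins, dtype=float)
    for edges, name in ((fdel_edges, "fdel_bins"), (size_edges, "size_bins")):
        if edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError(f"{name} must be >= 2 strictly increasing edges")

    fdel_iv = pd.IntervalIndex.from_breaks(fdel_edges, closed="left")
    size_iv = pd.IntervalIndex.from_breaks(size_edges, closed="left")
    index = pd.MultiIndex.from_product([fdel_iv, size_iv], names=["fdel_bin", "size_bin"])
    table = pd.DataFrame(
        {"n_morbid": 0, "n_non_morbid": 0}, index=index, dtype=int
    )

    for rec in records:
        fi = fdel_iv.get_indexer([rec.fdel])[0]
        si = size_iv.get_indexer([rec.size])[0]
        if fi < 0 or si < 0:  # outside the binned range
            continue
        flags = annot.gene_flags.get(rec.gene_symbol)
        col = "n_morbid" if (flags is not None and flags.omim_morbid) else "n_non_morbid"
        table.loc[(fdel_iv[fi], size_iv[si]), col] += 1

    total = table["n_morbid"] + table["n_non_morbid"]
    with np.errstate(invalid="ignore"):
        table["proportion_morbid"] = np.where(
            total > 0, table["n_morbid"] / total.replace(0, np.nan), np.nan
        )
    return table
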