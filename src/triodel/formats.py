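"""On-disk formats: region tables, pedigrees, annotation tables and event reports.

All coordinates are 0-based half-open (BED convention). Chromosome labels are
normalized by stripping a leading ``chr``; only autosomes ``1``..``22`` are
retained anywhere in the pipeline.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

AUTOSOMES = tuple(str(i) for i in range(1, 23))
_AUTOSOME_SET = frozenset(AUTOSOMES)

_MISSING = "0"  # PED missing-parent sentinel


class ParseError(ValueError):
    """Malformed record in an input file; message carries the line number."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix (case-insensitive) from a chromosome label."""
    if chrom.lower().startswith("chr"):
        return chrom[3:]
    return chrom


def is_autosome(chrom: str) -> bool:
    return normalize_chrom(chrom) in _AUTOSOME_SET


def chrom_sort_key(chrom: str) -> int:
    """Numeric sort key for an autosome label."""
    return int(normalize_chrom(chrom))


@dataclass(frozen=True, order=False)
class Region:
    """A genomic interval with identifier and optional gene symbol.

    The atomic unit of depth measurement and copy-number calling.
    """

    region_id: str
    chrom: str
    start: int
    end: int
    gene_symbol: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not self.region_id:
            raise ValueError("region_id must be non-empty")
        if self.chrom not in _AUTOSOME_SET:
            raise ValueError(f"region {self.region_id!r}: chrom {self.chrom!r} is not an autosome")
        if self.start < 0:
            raise ValueError(f"region {self.region_id!r}: negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"region {self.region_id!r}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[int, int, int, str]:
        return (chrom_sort_key(self.chrom), self.start, self.end, self.region_id)


class RegionSet:
    """Ordered collection of :class:`Region`, sorted by (chrom, start).

    Regions may overlap (gene spans can), but region_ids are unique and the
    sort order is total.
    """

    def __init__(self, regions: Iterable[Region]):
        self._regions: list[Region] = sorted(regions, key=Region.sort_key)
        self._by_id: dict[str, Region] = {}
        self._index: dict[str, int] = {}
        for i, r in enumerate(self._regions):
            if r.region_id in self._by_id:
                raise ValueError(f"duplicate region_id {r.region_id!r}")
            self._by_id[r.region_id] = r
            self._index[r.region_id] = i

    def __len__(self) -> int:
        return len(self._regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self._regions)

    def __getitem__(self, i: int) -> Region:
        return self._regions[i]

    def __contains__(self, region_id: str) -> bool:
        return region_id in self._by_id

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RegionSet) and self._regions == other._regions

    def get(self, region_id: str) -> Region:
        try:
            return self._by_id[region_id]
        except KeyError:
            raise KeyError(f"unknown region_id {region_id!r}") from None

    def index_of(self, region_id: str) -> int:
        try:
            return self._index[region_id]
        except KeyError:
            raise KeyError(f"unknown region_id {region_id!r}") from None

    @property
    def region_ids(self) -> list[str]:
        return [r.region_id for r in self._regions]


@dataclass(frozen=True)
class Trio:
    """Proband with both parents."""

    proband_id: str
    father_id: str
    mother_id: str

    def __post_init__(self) -> None:
        ids = (self.proband_id, self.father_id, self.mother_id)
        if not all(ids):
            raise ValueError("trio member ids must be non-empty")
        if len(set(ids)) != 3:
            raise ValueError(f"trio member ids must be distinct: {ids}")

    @property
    def member_ids(self) -> tuple[str, str, str]:
        return (self.proband_id, self.father_id, self.mother_id)


@dataclass
class TrioSet:
    """Trios plus singleton probands lacking sequenced parents."""

    trios: list[Trio] = field(default_factory=list)
    singletons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        probands = [t.proband_id for t in self.trios]
        if len(set(probands)) != len(probands):
            raise ValueError("a sample appears as proband in two trios")

    @property
    def all_sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trios:
            for s in t.member_ids:
                seen.setdefault(s)
        for s in self.singletons:
            seen.setdefault(s)
        return list(seen)


@dataclass(frozen=True)
class GeneFlags:
    omim_morbid: bool = False
    omim_ar: bool = False


@dataclass
class AnnotationTables:
    """Gene disease flags, segmental-duplication intervals and per-sample ROH runs.

    Intervals are 0-based half-open tuples ``(chrom, start, end)``.
    """

    gene_flags: dict[str, GeneFlags] = field(default_factory=dict)
    segdups: list[tuple[str, int, int]] = field(default_factory=list)
    roh: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, start, end in self.segdups:
            if end <= start:
                raise ValueError(f"segdup interval ({chrom}:{start}-{end}) has end <= start")
        for sample, runs in self.roh.items():
            for chrom, start, end in runs:
                if end <= start:
                    raise ValueError(
                        f"ROH interval for {sample!r} ({chrom}:{start}-{end}) has end <= start"
                    )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_region_table(path: str | Path, format: str = "tsv") -> RegionSet:
    """Read a region table from BED (``chrom start end [name]``) or TSV
    (header ``region_id chrom start end [gene_symbol]``).

    Non-autosomal records are dropped with a logged count. Malformed
    coordinates raise :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    if format not in ("bed", "tsv"):
        raise ValueError(f"unknown region table format {format!r}")
    regions: list[Region] = []
    n_dropped = 0
    with path.open() as fh:
        header: list[str] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if format == "tsv" and header is None:
                header = fields
                _require_columns(header, ("region_id", "chrom", "start", "end"), path)
                continue
            try:
                if format == "bed":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    name = fields[3] if len(fields) > 3 else f"{normalize_chrom(chrom)}:{start}-{end}"
                    gene: str | None = None
                else:
                    row = dict(zip(header, fields))  # type: ignore[arg-type]
                    chrom = row["chrom"]
                    start, end = int(row["start"]), int(row["end"])
                    name = row["region_id"]
                    gene = row.get("gene_symbol") or None
            except (IndexError, KeyError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed record: {exc}") from exc
            if not is_autosome(chrom):
                n_dropped += 1
                continue
            try:
                regions.append(Region(name, chrom, start, end, gene))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if n_dropped:
        logger.warning("dropped %d non-autosomal record(s) from %s", n_dropped, path)
    return RegionSet(regions)


def write_region_table(regions: RegionSet, path: str | Path) -> None:
    """Write a TSV region table (inverse of ``read_region_table(format='tsv')``)."""
    with Path(path).open("w") as fh:
        fh.write("region_id\tchrom\tstart\tend\tgene_symbol\n")
        for r in regions:
            fh.write(f"{r.region_id}\t{r.chrom}\t{r.start}\t{r.end}\t{r.gene_symbol or ''}\n")


def read_pedigree(path: str | Path) -> TrioSet:
    """Read a 6-column PED file into trios and singleton probands.

    An individual with both parents present in the file forms a trio. An
    individual with at least one missing/absent parent who is not themself a
    parent of anyone in the file is a singleton proband. ``0`` denotes a
    missing parent; family_id is carried but unused.
    """
    path = Path(path)
    rows: list[tuple[str, str, str]] = []  # (individual, father, mother)
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 PED columns, got {len(fields)}")
            _, iid, fid, mid = fields[0], fields[1], fields[2], fields[3]
            if iid in seen:
                raise ParseError(f"{path}:{lineno}: duplicate individual_id {iid!r}")
            if fid != _MISSING and fid == mid:
                raise ParseError(f"{path}:{lineno}: father_id == mother_id ({fid!r})")
            seen.add(iid)
            rows.append((iid, fid, mid))

    parents = {fid for _, fid, _ in rows if fid != _MISSING}
    parents |= {mid for _, _, mid in rows if mid != _MISSING}
    trios: list[Trio] = []
    singletons: list[str] = []
    for iid, fid, mid in rows:
        has_father = fid != _MISSING and fid in seen
        has_mother = mid != _MISSING and mid in seen
        if has_father and has_mother:
            trios.append(Trio(iid, fid, mid))
        elif iid not in parents:
            singletons.append(iid)
    return TrioSet(trios=trios, singletons=singletons)


def write_pedigree(trios: TrioSet, path: str | Path) -> None:
    """Write a TrioSet as a PED file (one family per trio / singleton)."""
    with Path(path).open("w") as fh:
        for i, t in enumerate(trios.trios, start=1):
            fam = f"FAM{i:05d}"
            fh.write(f"{fam}\t{t.father_id}\t0\t0\t1\t1\n")
            fh.write(f"{fam}\t{t.mother_id}\t0\t0\t2\t1\n")
            fh.write(f"{fam}\t{t.proband_id}\t{t.father_id}\t{t.mother_id}\t0\t2\n")
        for j, s in enumerate(trios.singletons, start=1):
            fh.write(f"SGL{j:05d}\t{s}\t0\t0\t0\t2\n")


def read_gene_flags(path: str | Path) -> dict[str, GeneFlags]:
    """Read a gene annotation TSV with header ``gene_symbol omim_morbid omim_ar``."""
    path = Path(path)
    flags: dict[str, GeneFlags] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        _require_columns(header, ("gene_symbol", "omim_morbid", "omim_ar"), path)
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            row = dict(zip(header, raw.rstrip("\n").split("\t")))
            try:
                flags[row["gene_symbol"]] = GeneFlags(
                    omim_morbid=_parse_bool(row["omim_morbid"]),
                    omim_ar=_parse_bool(row["omim_ar"]),
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return flags


def read_interval_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a 3+-column BED of plain intervals (e.g. segmental duplications)."""
    out: list[tuple[str, int, int]] = []
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            try:
                out.append((normalize_chrom(fields[0]), int(fields[1]), int(fields[2])))
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed BED record: {exc}") from exc
    return out


def read_roh_bed(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """Read a 4-column BED of per-sample ROH runs; column 4 is the sample id."""
    runs: dict[str, list[tuple[str, int, int]]] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: ROH BED needs 4 columns (chrom start end sample)")
            try:
                chrom, start, end = normalize_chrom(fields[0]), int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed BED record: {exc}") from exc
            runs.setdefault(fields[3], []).append((chrom, start, end))
    return runs


# ---------------------------------------------------------------------------
# event report writer / reader
# ---------------------------------------------------------------------------

EVENT_COLUMNS = (
    "chrom",
    "start",
    "end",
    "size",
    "region_ids",
    "pattern",
    "fdel",
    "genes",
    "omim_morbid",
    "omim_ar",
    "segdup_overlap",
    "roh_overlap",
    "sample_ids",
)

_NA = "NA"


def write_event_table(events: Sequence, path: str | Path, format: str = "tsv") -> None:
    """Write deletion events as TSV (full report) or BED (coordinates + ids).

    The TSV round-trips exactly through :func:`read_event_table`.
    """
    path = Path(path)
    if format == "tsv":
        with path.open("w") as fh:
            fh.write("\t".join(EVENT_COLUMNS) + "\n")
            for ev in events:
                fh.write(
                    "\t".join(
                        (
                            ev.chrom,
                            str(ev.start),
                            str(ev.end),
                            str(ev.size),
                            ",".join(ev.region_ids),
                            ev.pattern,
                            _NA if ev.fdel_max is None else repr(float(ev.fdel_max)),
                            ",".join(ev.genes),
                            _fmt_bool(ev.omim_morbid),
                            _fmt_bool(ev.omim_ar),
                            _fmt_bool(ev.segdup_overlap),
                            _fmt_bool(ev.roh_overlap),
                            ",".join(ev.sample_ids),
                        )
                    )
                    + "\n"
                )
    elif format == "bed":
        with path.open("w") as fh:
            for ev in events:
                name = ";".join(ev.region_ids)
                fh.write(f"{ev.chrom}\t{ev.start}\t{ev.end}\t{name}\t{len(ev.sample_ids)}\n")
    else:
        raise ValueError(f"unknown event table format {format!r}")


def read_event_table(path: str | Path) -> list:
    """Read back the TSV written by :func:`write_event_table`."""
    from .events import DeletionEvent  # deferred: avoids an import cycle

    path = Path(path)
    events: list[DeletionEvent] = []
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        _require_columns(header, EVENT_COLUMNS, path)
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            row = dict(zip(header, raw.rstrip("\n").split("\t")))
            try:
                events.append(
                    DeletionEvent(
                        chrom=row["chrom"],
                        start=int(row["start"]),
                        end=int(row["end"]),
                        region_ids=_split_list(row["region_ids"]),
                        sample_ids=_split_list(row["sample_ids"]),
                        pattern=row["pattern"],
                        fdel_max=None if row["fdel"] == _NA else float(row["fdel"]),
                        genes=_split_list(row["genes"]),
                        omim_morbid=_parse_opt_bool(row["omim_morbid"]),
                        omim_ar=_parse_opt_bool(row["omim_ar"]),
                        segdup_overlap=_parse_opt_bool(row["segdup_overlap"]),
                        roh_overlap=_parse_opt_bool(row["roh_overlap"]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return events


def _require_columns(header: Sequence[str], required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")


def _split_list(value: str) -> tuple[str, ...]:
    return tuple(value.split(",")) if value else ()


def _fmt_bool(value: bool | None) -> str:
    if value is None:
        return _NA
    return "true" if value else "false"


def _parse_bool(value: str) -> bool:
    v = value.strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def _parse_opt_bool(value: str) -> bool | None:
    if value == _NA:
        return None
    return _parse_bool(value)
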