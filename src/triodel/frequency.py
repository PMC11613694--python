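"""Per-region heterozygous-deletion frequency in a control cohort, and the
rarity filter applied to candidate calls.

The frequency ("fdel") counts control individuals at copy number exactly 1;
homozygous control deletions are tallied separately and reported, not folded
into fdel. Calls at regions with no control data fail closed (dropped with a
warning) since rarity cannot be asserted without controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, TypeVar

import numpy as np

from .caller import CNMatrix
from .trio import Call

logger = logging.getLogger(__name__)

DEFAULT_MAX_FDEL = 0.005

C = TypeVar("C", bound=Call)


@dataclass(frozen=True)
class FdelEntry:
    fdel: float
    n_het: int
    n_hom: int
    n_controls: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_het + self.n_hom <= self.n_controls):
            raise ValueError("het + hom counts exceed control cohort size")
        if not np.isclose(self.fdel, self.n_het / self.n_controls):
            raise ValueError("fdel inconsistent with n_het / n_controls")


@dataclass
class FdelTable:
    """region_id -> heterozygous-deletion frequency among controls."""

    entries: dict[str, FdelEntry]

    def __contains__(self, region_id: str) -> bool:
        return region_id in self.entries

    def __getitem__(self, region_id: str) -> FdelEntry:
        return self.entries[region_id]

    def fdel(self, region_id: str) -> float:
        return self.entries[region_id].fdel

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("region_id\tfdel\tn_het\tn_hom\tn_controls\n")
            for rid, e in self.entries.items():
                fh.write(f"{rid}\t{float(e.fdel)!r}\t{e.n_het}\t{e.n_hom}\t{e.n_controls}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FdelTable":
        entries: dict[str, FdelEntry] = {}
        with Path(path).open() as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for raw in fh:
                if not raw.strip():
                    continue
                row = dict(zip(header, raw.rstrip("\n").split("\t")))
                entries[row["region_id"]] = FdelEntry(
                    fdel=float(row["fdel"]),
                    n_het=int(row["n_het"]),
                    n_hom=int(row["n_hom"]),
                    n_controls=int(row["n_controls"]),
                )
        return cls(entries)


def heterozygous_deletion_frequency(cn_controls: CNMatrix) -> FdelTable:
    """Tally CN 1 (het) and CN 0 (hom) carriers per region among controls.

    fdel = n_het / n_controls. Masked regions yield no entry.
    """
    n = cn_controls.n_samples
    if n == 0:
        raise ValueError("control cohort is empty")
    entries: dict[str, FdelEntry] = {}
    n_het = (cn_controls.values == 1).sum(axis=0)
    n_hom = (cn_controls.values == 0).sum(axis=0)
    for j, rid in enumerate(cn_controls.region_ids):
        if cn_controls.region_mask[j]:
            continue
        entries[rid] = FdelEntry(
            fdel=float(n_het[j]) / n, n_het=int(n_het[j]), n_hom=int(n_hom[j]), n_controls=n
        )
    return FdelTable(entries)


def apply_frequency_filter(
    calls: Sequence[C], fdel: FdelTable, max_fdel: float = DEFAULT_MAX_FDEL
) -> list[C]:
    """Retain calls whose region fdel is strictly below ``max_fdel``.

    Calls at regions absent from the table are dropped with a warning.
    """
    if not (0 < max_fdel <= 1):
        raise ValueError(f"max_fdel must be in (0, 1], got {max_fdel}")
    kept: list[C] = []
    n_unknown = 0
    for call in calls:
        if call.region_id not in fdel:
            n_unknown += 1
            continue
        if fdel.fdel(call.region_id) < max_fdel:
            kept.append(call)
    if n_unknown:
        logger.warning(
            "dropped %d call(s) at regions with no control frequency data", n_unknown
        )
    return kept
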