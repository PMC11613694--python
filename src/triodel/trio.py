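"""Inheritance-pattern filters over the copy-number matrix.

Regions in a CN matrix are assumed to follow RegionSet order (chrom, start),
so sorting call lists by region index yields genomic order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .caller import CNMatrix
from .formats import Trio, TrioSet

logger = logging.getLogger(__name__)

PATTERN_INHERITED = "inherited_biallelic"
PATTERN_DE_NOVO = "de_novo_candidate"
PATTERN_SINGLETON = "singleton"


@dataclass(frozen=True)
class TrioCall:
    """A CN pattern at one region for one trio."""

    trio: Trio
    region_id: str
    proband_cn: int
    father_cn: int
    mother_cn: int
    pattern: str

    def __post_init__(self) -> None:
        if self.pattern == PATTERN_INHERITED:
            if (self.proband_cn, self.father_cn, self.mother_cn) != (0, 1, 1):
                raise ValueError("inherited_biallelic requires CN pattern (0, 1, 1)")
        elif self.pattern == PATTERN_DE_NOVO:
            parents = (self.father_cn, self.mother_cn)
            ok = self.proband_cn == 0 and sum(p >= 2 for p in parents) == 1 and min(parents) <= 1
            if not ok:
                raise ValueError(
                    "de_novo_candidate requires proband CN 0 with exactly one parent CN >= 2"
                )
        else:
            raise ValueError(f"unknown trio call pattern {self.pattern!r}")


@dataclass(frozen=True)
class SingletonCall:
    """A homozygous-deletion hit at a target region for a singleton proband."""

    sample_id: str
    region_id: str
    cn: int = 0


Call = TrioCall | SingletonCall


def _trio_cn_rows(cn: CNMatrix, trios: Sequence[Trio]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    p = np.array([cn.sample_index(t.proband_id) for t in trios], dtype=int)
    f = np.array([cn.sample_index(t.father_id) for t in trios], dtype=int)
    m = np.array([cn.sample_index(t.mother_id) for t in trios], dtype=int)
    return cn.values[p, :], cn.values[f, :], cn.values[m, :]


def _collect_calls(
    cn: CNMatrix, trios: Sequence[Trio], hit: np.ndarray, pattern: str,
    pcn: np.ndarray, fcn: np.ndarray, mcn: np.ndarray,
) -> list[TrioCall]:
    # sorted by (region index, proband) == (chrom, start, proband_id)
    tri_idx, reg_idx = np.nonzero(hit)
    order = np.lexsort(([trios[i].proband_id for i in tri_idx], reg_idx))
    return [
        TrioCall(
            trio=trios[tri_idx[k]],
            region_id=cn.region_ids[reg_idx[k]],
            proband_cn=int(pcn[tri_idx[k], reg_idx[k]]),
            father_cn=int(fcn[tri_idx[k], reg_idx[k]]),
            mother_cn=int(mcn[tri_idx[k], reg_idx[k]]),
            pattern=pattern,
        )
        for k in order
    ]


def find_inherited_biallelic(cn: CNMatrix, trios: TrioSet) -> list[TrioCall]:
    """All (trio, region) pairs with proband CN 0 and both parents CN 1.

    Output is sorted by (chrom, start, proband_id). Masked regions never call.
    """
    if not trios.trios:
        return []
    pcn, fcn, mcn = _trio_cn_rows(cn, trios.trios)
    hit = (pcn == 0) & (fcn == 1) & (mcn == 1) & ~cn.region_mask[None, :]
    return _collect_calls(cn, trios.trios, hit, PATTERN_INHERITED, pcn, fcn, mcn)


def flag_de_novo_candidates(cn: CNMatrix, trios: TrioSet) -> list[TrioCall]:
    """Proband CN 0 with exactly one parent CN >= 2 and the other CN <= 1.

    Requiring the non-transmitting parent at CN >= 2 (not merely != 1) keeps
    single-copy gains from mimicking de novo loss. Probands at CN 0 with both
    parents CN >= 2 imply two independent events and are logged, not called.
    """
    if not trios.trios:
        return []
    pcn, fcn, mcn = _trio_cn_rows(cn, trios.trios)
    unmasked = ~cn.region_mask[None, :]
    father_hi, mother_hi = fcn >= 2, mcn >= 2
    # exactly one parent >= 2 implies the other is <= 1 (integer CN)
    hit = (pcn == 0) & (father_hi ^ mother_hi) & unmasked
    double = (pcn == 0) & father_hi & mother_hi & unmasked
    n_double = int(double.sum())
    if n_double:
        logger.info(
            "%d proband CN0 site(s) with both parents CN>=2 (possible double de novo) not called",
            n_double,
        )
    return _collect_calls(cn, trios.trios, hit, PATTERN_DE_NOVO, pcn, fcn, mcn)


def targeted_singleton_screen(
    cn: CNMatrix, singles: Sequence[str], targets: Sequence[str]
) -> list[SingletonCall]:
    """All (singleton, target region) pairs at CN 0.

    No frequency filter is re-applied: targets have already passed it in the
    trio discovery phase.
    """
    target_idx = [cn.region_index(r) for r in targets]  # raises on unknown target
    hits: list[tuple[int, str]] = []
    for j in target_idx:
        if cn.region_mask[j]:
            continue
        for s in singles:
            if cn.values[cn.sample_index(s), j] == 0:
                hits.append((j, s))
    hits.sort()
    return [SingletonCall(sample_id=s, region_id=cn.region_ids[j], cn=0) for j, s in hits]


# ---------------------------------------------------------------------------
# TSV io for call lists (CLI plumbing)
# ---------------------------------------------------------------------------

TRIO_CALL_COLUMNS = ("proband_id", "father_id", "mother_id", "region_id",
                     "proband_cn", "father_cn", "mother_cn", "pattern")


def write_trio_calls(calls: Sequence[TrioCall], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(TRIO_CALL_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.trio.proband_id}\t{c.trio.father_id}\t{c.trio.mother_id}\t{c.region_id}\t"
                f"{c.proband_cn}\t{c.father_cn}\t{c.mother_cn}\t{c.pattern}\n"
            )


def read_trio_calls(path: str | Path) -> list[TrioCall]:
    calls: list[TrioCall] = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for raw in fh:
            if not raw.strip():
                continue
            row = dict(zip(header, raw.rstrip("\n").split("\t")))
            calls.append(
                TrioCall(
                    trio=Trio(row["proband_id"], row["father_id"], row["mother_id"]),
                    region_id=row["region_id"],
                    proband_cn=int(row["proband_cn"]),
                    father_cn=int(row["father_cn"]),
                    mother_cn=int(row["mother_cn"]),
                    pattern=row["pattern"],
                )
            )
    return calls


def write_singleton_calls(calls: Sequence[SingletonCall], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_id\tregion_id\tcn\n")
        for c in calls:
            fh.write(f"{c.sample_id}\t{c.region_id}\t{c.cn}\n")
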