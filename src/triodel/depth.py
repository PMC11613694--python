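"""Mean per-region coverage: the samples x regions depth matrix.

The primary input contract is per-base coverage (any object with a
``depth_array(chrom, start, end)`` method); direct alignment-file reading is an
optional adapter behind the same contract.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .formats import Region, RegionSet, normalize_chrom


@runtime_checkable
class CoverageSource(Protocol):
    """Per-base coverage provider for one sample."""

    def depth_array(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base depths over ``[start, end)``; absent bases read as 0."""
        ...


class ArrayCoverage:
    """Coverage backed by in-memory per-chromosome depth vectors.

    Positions beyond the stored vector read as 0; a chromosome absent from the
    source raises ``KeyError``.
    """

    def __init__(self, per_chrom: dict[str, np.ndarray]):
        self._per_chrom = {normalize_chrom(c): np.asarray(v, dtype=float) for c, v in per_chrom.items()}

    @classmethod
    def from_depth_text(cls, path: str | Path) -> "ArrayCoverage":
        """Build from the text output of a depth utility: ``chrom pos depth``
        with 1-based positions (the ``samtools depth`` dialect)."""
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "pos", "depth"],
                         dtype={"chrom": str})
        per_chrom: dict[str, np.ndarray] = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            arr = np.zeros(int(grp["pos"].max()), dtype=float)
            arr[grp["pos"].to_numpy() - 1] = grp["depth"].to_numpy()
            per_chrom[str(chrom)] = arr
        return cls(per_chrom)

    def depth_array(self, chrom: str, start: int, end: int) -> np.ndarray:
        chrom = normalize_chrom(chrom)
        if chrom not in self._per_chrom:
            raise KeyError(f"chromosome {chrom!r} not present in coverage source")
        arr = self._per_chrom[chrom]
        out = np.zeros(end - start, dtype=float)
        lo, hi = max(start, 0), min(end, arr.size)
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out


class BamCoverage:
    """Optional adapter computing per-base coverage from an indexed BAM/CRAM.

    Reads below ``min_mapq`` (default 20) and duplicate-marked reads are
    excluded. Requires :mod:`pysam`.
    """

    def __init__(self, path: str | Path, min_mapq: int = 20):
        import pysam  # deferred: optional dependency

        self._af = pysam.AlignmentFile(str(path))
        self._min_mapq = min_mapq
        self._chroms = {normalize_chrom(r): r for r in self._af.references}

    def depth_array(self, chrom: str, start: int, end: int) -> np.ndarray:
        chrom = normalize_chrom(chrom)
        if chrom not in self._chroms:
            raise KeyError(f"chromosome {chrom!r} not present in alignment file")
        min_mapq = self._min_mapq

        def _keep(read) -> bool:
            return not read.is_duplicate and read.mapping_quality >= min_mapq

        counts = self._af.count_coverage(
            self._chroms[chrom], start, end, quality_threshold=0, read_callback=_keep
        )
        return np.asarray(counts, dtype=float).sum(axis=0)


@dataclass
class DepthMatrix:
    """Samples x regions matrix of mean per-base coverage."""

    sample_ids: list[str]
    region_ids: list[str]
    values: np.ndarray  # shape (n_samples, n_regions), float, >= 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.region_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.region_ids)} regions"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_id in depth matrix")
        if len(set(self.region_ids)) != len(self.region_ids):
            raise ValueError("duplicate region_id in depth matrix")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("depth matrix values must be finite and non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in depth matrix") from None

    def to_tsv(self, path: str | Path) -> None:
        """Rows = regions, first column ``region_id``, one column per sample."""
        df = pd.DataFrame(self.values.T, index=self.region_ids, columns=self.sample_ids)
        df.index.name = "region_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DepthMatrix":
        df = pd.read_csv(path, sep="\t", index_col="region_id")
        return cls(
            sample_ids=[str(c) for c in df.columns],
            region_ids=[str(i) for i in df.index],
            values=df.to_numpy(dtype=float).T,
        )


def mean_region_depth(coverage: CoverageSource, region: Region) -> float:
    """Mean per-base depth over a region.

    The denominator is always the region length: uncovered bases contribute 0,
    so deleted regions yield depressed means.
    """
    arr = coverage.depth_array(region.chrom, region.start, region.end)
    return float(np.sum(arr)) / region.length


def build_depth_matrix(
    samples: Iterable[tuple[str, CoverageSource]], regions: RegionSet
) -> DepthMatrix:
    """Mean region depth for every (sample, region) pair."""
    samples = list(samples)
    sample_ids = [sid for sid, _ in samples]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_id in coverage inputs")
    values = np.empty((len(samples), len(regions)), dtype=float)
    for i, (_, cov) in enumerate(samples):
        for j, region in enumerate(regions):
            values[i, j] = mean_region_depth(cov, region)
    return DepthMatrix(sample_ids=sample_ids, region_ids=regions.region_ids, values=values)
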