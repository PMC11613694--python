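"""Diploid-scaled normalization of the depth matrix and integer copy-number calls.

Two-stage median normalization: a per-sample scale (median over regions)
removes library-size effects, then a per-region baseline (median of the scaled
values across a reference cohort) removes region mappability/length effects.
Medians are robust to the rare deletion carriers the method targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .depth import DepthMatrix

DEFAULT_CN_MAX = 4
DEFAULT_MIN_REGION_MEDIAN = 0.1

MASKED_CN = -1  # sentinel value in CNMatrix.values for masked regions


def default_bins(cn_max: int = DEFAULT_CN_MAX) -> np.ndarray:
    """Half-integer bin edges: CN 0 iff d < 0.5; CN k iff k-0.5 <= d < k+0.5."""
    return np.arange(0.5, cn_max, 1.0)


@dataclass
class RatioMatrix:
    """Diploid-scaled dosage d (d ~ 2 means two copies) with a per-region mask."""

    sample_ids: list[str]
    region_ids: list[str]
    values: np.ndarray  # (n_samples, n_regions); NaN where masked
    region_mask: np.ndarray  # (n_regions,) bool; True = uninformative

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_mask = np.asarray(self.region_mask, dtype=bool)
        if self.values.shape != (len(self.sample_ids), len(self.region_ids)):
            raise ValueError("ratio matrix shape mismatch")
        if self.region_mask.shape != (len(self.region_ids),):
            raise ValueError("region mask shape mismatch")
        unmasked = self.values[:, ~self.region_mask]
        if unmasked.size and (not np.all(np.isfinite(unmasked)) or np.any(unmasked < 0)):
            raise ValueError("unmasked ratio values must be finite and non-negative")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values.T, index=self.region_ids, columns=self.sample_ids)
        df.index.name = "region_id"
        df.insert(0, "masked", self.region_mask.astype(int))
        df.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class CNMatrix:
    """Integer copy-number calls per sample per region; masked regions carry none.

    ``qual`` optionally records |d - CN| per call for triage.
    """

    sample_ids: list[str]
    region_ids: list[str]
    values: np.ndarray  # (n_samples, n_regions) int; MASKED_CN where masked
    region_mask: np.ndarray  # (n_regions,) bool
    qual: np.ndarray | None = None  # |d - CN| per cell, NaN where masked

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        self.region_mask = np.asarray(self.region_mask, dtype=bool)
        if self.values.shape != (len(self.sample_ids), len(self.region_ids)):
            raise ValueError("CN matrix shape mismatch")
        if self.region_mask.shape != (len(self.region_ids),):
            raise ValueError("region mask shape mismatch")
        unmasked = self.values[:, ~self.region_mask]
        if unmasked.size and np.any(unmasked < 0):
            raise ValueError("unmasked copy numbers must be >= 0")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in CN matrix") from None

    def region_index(self, region_id: str) -> int:
        try:
            return self.region_ids.index(region_id)
        except ValueError:
            raise KeyError(f"region {region_id!r} not in CN matrix") from None

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values.T, index=self.region_ids, columns=self.sample_ids)
        df.index.name = "region_id"
        df.insert(0, "masked", self.region_mask.astype(int))
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CNMatrix":
        df = pd.read_csv(path, sep="\t", index_col="region_id")
        mask = df.pop("masked").to_numpy(dtype=bool)
        return cls(
            sample_ids=[str(c) for c in df.columns],
            region_ids=[str(i) for i in df.index],
            values=df.to_numpy(dtype=int).T,
            region_mask=mask,
        )


def normalize_depth_matrix(
    depths: DepthMatrix,
    reference_samples: Sequence[str] | None = None,
    min_region_median: float = DEFAULT_MIN_REGION_MEDIAN,
) -> RatioMatrix:
    """Two-stage median normalization to diploid-scaled dosage.

    Stage 1: each sample's depths are divided by that sample's median over
    regions (library-size removal). Stage 2: each region's stage-1 values are
    divided by the region's median across ``reference_samples`` (default: all
    samples) and doubled, so two copies sit at d = 2. Regions whose reference
    median falls below ``min_region_median`` are masked as uninformative.
    """
    if depths.n_samples < 2 or depths.n_regions < 2:
        raise ValueError("normalization needs at least 2 samples and 2 regions")
    sample_medians = np.median(depths.values, axis=1)
    zero = np.flatnonzero(sample_medians == 0)
    if zero.size:
        raise ValueError(
            f"sample {depths.sample_ids[zero[0]]!r} has zero median depth (no usable coverage)"
        )
    r1 = depths.values / sample_medians[:, None]

    if reference_samples is None:
        ref_idx = np.arange(depths.n_samples)
    else:
        ref_idx = np.array([depths.sample_index(s) for s in reference_samples])
        if ref_idx.size == 0:
            raise ValueError("reference_samples must be non-empty")
    region_medians = np.median(r1[ref_idx, :], axis=0)

    mask = region_medians < min_region_median
    values = np.full_like(r1, np.nan)
    values[:, ~mask] = 2.0 * r1[:, ~mask] / region_medians[~mask]
    return RatioMatrix(
        sample_ids=list(depths.sample_ids),
        region_ids=list(depths.region_ids),
        values=values,
        region_mask=mask,
    )


def call_copy_numbers(
    ratios: RatioMatrix,
    bins: Sequence[float] | None = None,
    cn_max: int = DEFAULT_CN_MAX,
) -> CNMatrix:
    """Bin diploid-scaled dosage into integer copy numbers.

    Default edges sit at half-integers so d rounds to the nearest integer CN,
    with values exactly on an edge assigned upward (d = 0.5 calls CN 1).
    Calls are capped at ``cn_max``; masked regions propagate.
    """
    edges = default_bins(cn_max) if bins is None else np.asarray(bins, dtype=float)
    if edges.ndim != 1 or edges.size == 0 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be a strictly increasing 1-D sequence")
    unmasked_cols = ~ratios.region_mask
    if not np.all(np.isfinite(ratios.values[:, unmasked_cols])):
        raise ValueError("non-finite ratio at an unmasked region")

    cn = np.full(ratios.values.shape, MASKED_CN, dtype=int)
    d = ratios.values[:, unmasked_cols]
    # side='right' puts d == edge into the upper bin (upward tie-break)
    cn[:, unmasked_cols] = np.minimum(np.searchsorted(edges, d.ravel(), side="right"), cn_max).reshape(d.shape)

    qual = np.full(ratios.values.shape, np.nan)
    qual[:, unmasked_cols] = np.abs(d - cn[:, unmasked_cols])
    return CNMatrix(
        sample_ids=list(ratios.sample_ids),
        region_ids=list(ratios.region_ids),
        values=cn,
        region_mask=ratios.region_mask.copy(),
        qual=qual,
    )
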