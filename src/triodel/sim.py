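"""Synthetic depth-matrix cohorts with known deletion genotypes.

Deletion alleles segregate at specified frequencies under Hardy-Weinberg in
founders and Mendelian transmission in trios. Expected depth factorizes as
mean_depth x lognormal sample effect x lognormal region effect x (CN / 2);
homozygous-deleted cells receive a small background floor standing in for
mismapped reads at segmental duplications. Count noise is drawn at a
per-region resolution of roughly one unit per read length, mimicking the
sampling error of a mean-coverage estimate over a region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .depth import DepthMatrix
from .formats import Region, RegionSet, Trio, TrioSet

NOISE_MODELS = ("none", "poisson", "negbin")


@dataclass(frozen=True)
class SpikedEvent:
    """A deletion allele spanning 1..k contiguous regions at frequency p.

    ``force_parent_het`` makes every simulated parent a carrier (useful for
    Mendelian segregation checks); ``n_forced_trios`` restricts the forcing to
    the first N trios so a rare deletion can be made to segregate in a handful
    of families without biasing the cohort-median normalization.
    """

    region_ids: tuple[str, ...]
    allele_freq: float
    force_parent_het: bool = False
    n_forced_trios: int | None = None

    def __post_init__(self) -> None:
        if not self.region_ids:
            raise ValueError("spiked event needs at least one region")
        if not (0 <= self.allele_freq < 1):
            raise ValueError(f"allele frequency must be in [0, 1), got {self.allele_freq}")
        if self.n_forced_trios is not None and self.n_forced_trios < 0:
            raise ValueError("n_forced_trios must be >= 0")


@dataclass
class SimConfig:
    seed: int
    n_controls: int = 0
    n_trios: int = 0
    regions: RegionSet | None = None
    # auto-generated region grid when `regions` is None:
    n_regions: int = 100
    region_length: int = 10_000
    region_spacing: int = 5_000
    spiked_events: list[SpikedEvent] = field(default_factory=list)
    mean_depth: float = 30.0
    noise: str = "none"
    negbin_dispersion: float = 200.0  # gamma-Poisson; relative extra-Poisson sd = 1/sqrt(r)
    read_length: int = 150  # count-noise resolution: ~1 unit per read length
    region_effect_sd: float = 0.0
    sample_effect_sd: float = 0.0
    background_floor_frac: float = 0.01  # CN0 depth as a fraction of diploid expectation
    de_novo_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError(f"mean_depth must be positive, got {self.mean_depth}")
        if self.noise not in NOISE_MODELS:
            raise ValueError(f"noise must be one of {NOISE_MODELS}, got {self.noise!r}")
        if self.negbin_dispersion <= 0:
            raise ValueError("negbin_dispersion must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")

    def resolve_regions(self) -> RegionSet:
        return self.regions if self.regions is not None else make_regions(
            self.n_regions, self.region_length, self.region_spacing
        )


@dataclass(frozen=True)
class TrueEvent:
    chrom: str
    start: int
    end: int
    region_ids: tuple[str, ...]
    allele_freq: float


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated depth matrix."""

    sample_ids: list[str]
    events: list[TrueEvent]
    genotypes: np.ndarray  # (n_samples, n_events) copies retained in {0,1,2}
    realized_fdel: list[float]  # per event: fraction of founders with exactly 1 copy
    trios: list[Trio] = field(default_factory=list)
    inherited_biallelic: list[tuple[str, int]] = field(default_factory=list)  # (proband, event idx)
    de_novo: list[tuple[str, int]] = field(default_factory=list)  # detectable (0, parent>=2) patterns
    injected_de_novo: list[tuple[str, int]] = field(default_factory=list)  # all injected losses

    def true_cn_matrix(self, regions: RegionSet) -> np.ndarray:
        """Integer CN per (sample, region): 2 everywhere except spiked spans."""
        cn = np.full((len(self.sample_ids), len(regions)), 2, dtype=int)
        for e, ev in enumerate(self.events):
            cols = [regions.index_of(r) for r in ev.region_ids]
            for c in cols:
                cn[:, c] = self.genotypes[:, e]
        return cn


def make_regions(
    n_regions: int, region_length: int = 10_000, region_spacing: int = 5_000
) -> RegionSet:
    """A deterministic grid of gene-like regions spread over autosomes 1..22."""
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    # at least 10 regions per chromosome so contiguous multi-region spans exist
    per_chrom = max(10, math.ceil(n_regions / 22))
    regions = []
    for i in range(n_regions):
        chrom = str(i // per_chrom + 1)
        k = i % per_chrom
        start = 10_000 + k * (region_length + region_spacing)
        regions.append(
            Region(
                region_id=f"R{i:05d}",
                chrom=chrom,
                start=start,
                end=start + region_length,
                gene_symbol=f"GENE{i:05d}",
            )
        )
    return RegionSet(regions)


def _event_columns(events: list[SpikedEvent], regions: RegionSet) -> list[list[int]]:
    cols: list[list[int]] = []
    for ev in events:
        idxs = [regions.index_of(r) for r in ev.region_ids]
        if idxs != list(range(idxs[0], idxs[0] + len(idxs))):
            raise ValueError(f"spiked event regions {ev.region_ids} are not contiguous")
        chroms = {regions[i].chrom for i in idxs}
        if len(chroms) != 1:
            raise ValueError(f"spiked event regions {ev.region_ids} span multiple chromosomes")
        cols.append(idxs)
    return cols


def _true_events(config: SimConfig, regions: RegionSet) -> list[TrueEvent]:
    out = []
    for ev in config.spiked_events:
        members = [regions.get(r) for r in ev.region_ids]
        out.append(
            TrueEvent(
                chrom=members[0].chrom,
                start=min(r.start for r in members),
                end=max(r.end for r in members),
                region_ids=tuple(ev.region_ids),
                allele_freq=ev.allele_freq,
            )
        )
    return out


def _observe_depth(
    cn: np.ndarray, config: SimConfig, regions: RegionSet, rng: np.random.Generator
) -> np.ndarray:
    n_samples, n_regions = cn.shape
    g = rng.lognormal(0.0, config.sample_effect_sd, size=n_samples) if config.sample_effect_sd > 0 else np.ones(n_samples)
    e = rng.lognormal(0.0, config.region_effect_sd, size=n_regions) if config.region_effect_sd > 0 else np.ones(n_regions)
    diploid = config.mean_depth * np.outer(g, e)
    expected = diploid * (cn / 2.0)
    floor = config.background_floor_frac * diploid
    expected = np.where(cn == 0, floor, expected)

    if config.noise == "none":
        return expected
    # count-noise resolution: one unit per read length of region span
    m = np.array([max(1, r.length // config.read_length) for r in regions], dtype=float)
    mean_counts = expected * m[None, :]
    if config.noise == "poisson":
        counts = rng.poisson(mean_counts)
    else:  # negbin via gamma-poisson mixture
        r = config.negbin_dispersion
        lam = rng.gamma(shape=r, scale=mean_counts / r)
        counts = rng.poisson(lam)
    return counts / m[None, :]


def _founder_copies(
    n: int, events: list[SpikedEvent], rng: np.random.Generator
) -> np.ndarray:
    """Copies retained per (sample, event) under Hardy-Weinberg."""
    geno = np.full((n, len(events)), 2, dtype=int)
    for e, ev in enumerate(events):
        geno[:, e] = 2 - rng.binomial(2, ev.allele_freq, size=n)
    return geno


def simulate_cohort(config: SimConfig) -> tuple[DepthMatrix, SimTruth]:
    """Simulate an unrelated cohort (``n_controls`` founders)."""
    if config.n_controls < 1:
        raise ValueError("n_controls must be >= 1 for simulate_cohort")
    rng = np.random.default_rng([config.seed, 0])
    regions = config.resolve_regions()
    cols = _event_columns(config.spiked_events, regions)

    sample_ids = [f"C{i:05d}" for i in range(config.n_controls)]
    geno = _founder_copies(config.n_controls, config.spiked_events, rng)
    cn = np.full((config.n_controls, len(regions)), 2, dtype=int)
    for e, idxs in enumerate(cols):
        for c in idxs:
            cn[:, c] = geno[:, e]
    depths = _observe_depth(cn, config, regions, rng)
    truth = SimTruth(
        sample_ids=sample_ids,
        events=_true_events(config, regions),
        genotypes=geno,
        realized_fdel=[float(np.mean(geno[:, e] == 1)) for e in range(geno.shape[1])],
    )
    return (
        DepthMatrix(sample_ids=sample_ids, region_ids=regions.region_ids, values=depths),
        truth,
    )


def simulate_trios(config: SimConfig) -> tuple[DepthMatrix, SimTruth]:
    """Simulate ``n_trios`` parent-child trios (3 samples each).

    Parents are Hardy-Weinberg founders; each child inherits one allele from
    each parent uniformly at random. With ``de_novo_rate`` > 0 a child loses
    one retained copy independently of the parents at that rate.
    """
    if config.n_trios < 1:
        raise ValueError("n_trios must be >= 1 for simulate_trios")
    rng = np.random.default_rng([config.seed, 1])
    regions = config.resolve_regions()
    cols = _event_columns(config.spiked_events, regions)
    n, n_events = config.n_trios, len(config.spiked_events)

    trios = [Trio(f"P{i:05d}", f"F{i:05d}", f"M{i:05d}") for i in range(n)]
    fat = _founder_copies(n, config.spiked_events, rng)
    mot = _founder_copies(n, config.spiked_events, rng)
    for e, ev in enumerate(config.spiked_events):
        if ev.force_parent_het:
            k = n if ev.n_forced_trios is None else min(ev.n_forced_trios, n)
            fat[:k, e] = 1
            mot[:k, e] = 1
    # transmit a deleted allele with probability (2 - copies) / 2
    child = np.full((n, n_events), 2, dtype=int)
    injected: list[tuple[str, int]] = []
    if n_events:
        del_from_f = rng.random((n, n_events)) < (2 - fat) / 2.0
        del_from_m = rng.random((n, n_events)) < (2 - mot) / 2.0
        child = 2 - del_from_f.astype(int) - del_from_m.astype(int)
        if config.de_novo_rate > 0:
            lose = (rng.random((n, n_events)) < config.de_novo_rate) & (child > 0)
            child = child - lose.astype(int)
            injected = [(trios[i].proband_id, int(e)) for i, e in zip(*np.nonzero(lose))]

    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    for i, t in enumerate(trios):
        sample_ids += [t.father_id, t.mother_id, t.proband_id]
        rows += [fat[i], mot[i], child[i]]
    geno = np.array(rows, dtype=int) if rows else np.zeros((0, n_events), dtype=int)

    cn = np.full((3 * n, len(regions)), 2, dtype=int)
    for e, idxs in enumerate(cols):
        for c in idxs:
            cn[:, c] = geno[:, e]
    depths = _observe_depth(cn, config, regions, rng)

    inherited = [
        (trios[i].proband_id, int(e))
        for i in range(n)
        for e in range(n_events)
        if (child[i, e], fat[i, e], mot[i, e]) == (0, 1, 1)
    ]
    de_novo = [
        (trios[i].proband_id, int(e))
        for i in range(n)
        for e in range(n_events)
        if child[i, e] == 0 and (fat[i, e] >= 2) ^ (mot[i, e] >= 2)
    ]
    founders = np.concatenate([fat, mot], axis=0) if n_events else np.zeros((0, 0))
    truth = SimTruth(
        sample_ids=sample_ids,
        events=_true_events(config, regions),
        genotypes=geno,
        realized_fdel=[float(np.mean(founders[:, e] == 1)) for e in range(n_events)],
        trios=trios,
        inherited_biallelic=inherited,
        de_novo=de_novo,
        injected_de_novo=injected,
    )
    return (
        DepthMatrix(sample_ids=sample_ids, region_ids=regions.region_ids, values=depths),
        truth,
    )


def trio_set(truth: SimTruth) -> TrioSet:
    return TrioSet(trios=list(truth.trios))


def write_truth_tsv(truth: SimTruth, path: str | Path) -> None:
    """Genotype table: one row per (sample, event) with copies retained."""
    with Path(path).open("w") as fh:
        fh.write("sample_id\tevent_index\tchrom\tstart\tend\tcopies\n")
        for e, ev in enumerate(truth.events):
            for i, sid in enumerate(truth.sample_ids):
                fh.write(f"{sid}\t{e}\t{ev.chrom}\t{ev.start}\t{ev.end}\t{truth.genotypes[i, e]}\n")
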