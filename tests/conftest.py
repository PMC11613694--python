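import numpy as np
import pytest

from triodel import CNMatrix, Region, RegionSet, Trio, TrioSet


@pytest.fixture
def simple_regions() -> RegionSet:
    """Five regions on chrom 1 (adjacent-ish) and one on chrom 2."""
    return RegionSet(
        [
            Region("rA", "1", 1000, 10000, "GENEA"),
            Region("rB", "1", 12000, 20000, "GENEB"),
            Region("rC", "1", 23000, 30000, "GENEC"),
            Region("rD", "1", 700000, 710000, "GENED"),
            Region("rE", "1", 712000, 720000, None),
            Region("rF", "2", 5000, 15000, "GENEF"),
        ]
    )


def make_cn(values, sample_ids=None, region_ids=None, mask=None) -> CNMatrix:
    """Build a CNMatrix from a 2-D list/array with defaulted axis labels."""
    values = np.asarray(values, dtype=int)
    n_samples, n_regions = values.shape
    return CNMatrix(
        sample_ids=sample_ids or [f"S{i}" for i in range(n_samples)],
        region_ids=region_ids or [f"R{j}" for j in range(n_regions)],
        values=values,
        region_mask=np.zeros(n_regions, dtype=bool) if mask is None else np.asarray(mask, bool),
    )


def make_trioset(n: int) -> TrioSet:
    return TrioSet(trios=[Trio(f"P{i}", f"F{i}", f"M{i}") for i in range(n)])


def trio_sample_ids(trios: TrioSet) -> list[str]:
    out = []
    for t in trios.trios:
        out += [t.proband_id, t.father_id, t.mother_id]
    return out
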