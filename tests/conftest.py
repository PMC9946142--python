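from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from introscan.io_formats import WindowCountTable
from introscan.simulate import ExpressionParams, PlantedEvent, SimConfig


def make_track(deviations, chrom="chr1A", width=1_000_000, start=0) -> pd.DataFrame:
    """Deviation track from a plain list (NaN allowed) on a uniform grid."""
    starts = start + width * np.arange(len(deviations))
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + width,
            "deviation": np.asarray(deviations, dtype=float),
        }
    )


def make_counts(counts, chrom="chr1A", width=1_000_000, total=None) -> WindowCountTable:
    counts = np.asarray(counts, dtype=np.int64)
    starts = width * np.arange(len(counts))
    frame = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + width, "count": counts}
    )
    return WindowCountTable(frame, int(counts.sum()) if total is None else total)


@pytest.fixture
def small_sim_config() -> SimConfig:
    """A fast 3 x 10 Mbp genome with one event of each class."""
    return SimConfig(
        chrom_lengths={"chr1A": 10_000_000, "chr1B": 10_000_000, "chr1D": 10_000_000},
        donor_snp_rate=1e-3,
        parent_snp_rate=2e-4,
        events=(
            PlantedEvent("chr1D", 2_000_000, 6_000_000, "introgression", "hom"),
            PlantedEvent("chr1A", 3_000_000, 6_000_000, "deletion", "hom"),
            PlantedEvent("chr1B", 4_000_000, 7_000_000, "duplication", "hom"),
        ),
        expression=ExpressionParams(n_triads=120, gene_offset=500_000, gene_spacing=20_000),
        seed=11,
    )
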