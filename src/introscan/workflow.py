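"""In-memory orchestration of the genomic detection stages.

Convenience layer over karyotype, snp_profile and segments for datasets held
in memory (typically simulated ones); the file-based equivalent lives in
:func:`introscan.cli.run_pipeline`.
"""

from __future__ import annotations

import pandas as pd

from .config import Thresholds, DEFAULT
from .karyotype import coverage_deviation
from .segments import SegmentBlock, detect_segments
from .simulate import LineDataset
from .snp_profile import (
    assign_line_snps_frame,
    bin_snps,
    derive_donor_specific_frames,
)


def deviation_tracks(ds: LineDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coarse and fine coverage-deviation tracks for the dataset's line."""
    cfg = ds.config
    parents = {p: ds.counts[p] for p in cfg.parents}
    parents_fine = {p: ds.counts_fine[p] for p in cfg.parents}
    track = coverage_deviation(ds.counts[cfg.line], parents)
    fine = coverage_deviation(ds.counts_fine[cfg.line], parents_fine)
    return track, fine


def snp_window_profile(ds: LineDataset, thresholds: Thresholds = DEFAULT) -> pd.DataFrame:
    """Donor-specific SNP window profile (hom/het counts) for the line."""
    cfg = ds.config
    from .snp_profile import _donor_specific_frame

    donor = _donor_specific_frame(ds.snps[cfg.donor], {p: ds.snps[p] for p in cfg.parents})
    donor_index = pd.MultiIndex.from_frame(donor[["chrom", "pos", "alt"]])
    matched = assign_line_snps_frame(
        ds.snps[cfg.line], donor_index, cfg.depth, thresholds.snp_max_depth_factor
    )
    return bin_snps(matched, ds.counts[cfg.line].grid())


def detect_line(
    ds: LineDataset,
    thresholds: Thresholds = DEFAULT,
    use_snps: bool = True,
) -> list[SegmentBlock]:
    """Run karyotyping, SNP profiling and segment calling on a dataset.

    With ``use_snps`` off (or when the dataset carries no SNPs, as in
    coverage-only downsampling analyses) blocks are called and refined from
    the deviation tracks alone and left origin-unassigned.
    """
    track, fine = deviation_tracks(ds)
    profile = snp_window_profile(ds, thresholds) if use_snps and ds.snps else None
    return detect_segments(track, fine, profile, thresholds)
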