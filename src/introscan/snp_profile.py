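"""Donor-specific SNP derivation, matching and per-window binning.

A donor-specific SNP is an alternate allele called in the donor accession
against the wheat reference and absent from every wheat parent of the cross.
Introgression-line SNPs matching the donor set in position and allele mark
introgressed intervals: homozygous matches indicate the introgressed site
itself, while heterozygous matches arise where donor-derived reads aberrantly
map onto wheat background, so the homozygous:heterozygous ratio separates
real introgressions from mapping artefacts.  Sites above 3x the sample's
mean coverage are removed as collapsed repeat expansions before binning
matches into windows.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT
from .io_formats import SnpRecord

log = logging.getLogger(__name__)

DonorSnpSet = set[tuple[str, int, str]]


def derive_donor_specific(
    donor_snps: Iterable[SnpRecord],
    other_parent_snps: Mapping[str, Iterable[SnpRecord]],
    include_het_donor: bool = False,
    strict_position_exclusion: bool = False,
) -> DonorSnpSet:
    """Donor SNPs absent from all non-donor parents.

    Only homozygous donor calls seed the set by default — the donor accession
    is a single diploid individual, so heterozygous donor calls are ambiguous
    evidence of a species-specific allele (``include_het_donor`` admits
    them).  Exclusion against the wheat parents is allele-specific: a parent
    variant at the same position with a different alternate allele does not
    remove the donor allele, unless ``strict_position_exclusion`` is set.
    """
    donor: DonorSnpSet = {
        (r.chrom, r.pos, r.alt)
        for r in donor_snps
        if include_het_donor or r.genotype == "hom_alt"
    }
    if strict_position_exclusion:
        excluded_pos = {
            (r.chrom, r.pos)
            for records in other_parent_snps.values()
            for r in records
        }
        result = {s for s in donor if (s[0], s[1]) not in excluded_pos}
    else:
        excluded = {
            (r.chrom, r.pos, r.alt)
            for records in other_parent_snps.values()
            for r in records
        }
        result = donor - excluded
    log.info(
        "derive_donor_specific: %d donor alleles, %d donor-specific",
        len(donor), len(result),
    )
    return result


def assign_line_snps(
    line_snps: Iterable[SnpRecord],
    donor_set: DonorSnpSet,
    mean_depth: float | None = None,
    max_depth_factor: float = DEFAULT.snp_max_depth_factor,
) -> list[SnpRecord]:
    """Line SNPs matching the donor-specific set in position and allele.

    When ``mean_depth`` is given, matched sites with depth above
    ``max_depth_factor`` times the mean are dropped (collapsed repeats);
    records lacking depth then raise ``ValueError``.
    """
    matched: list[SnpRecord] = []
    n_depth_dropped = 0
    for r in line_snps:
        if (r.chrom, r.pos, r.alt) not in donor_set:
            continue
        if mean_depth is not None:
            if mean_depth <= 0:
                raise ValueError("mean_depth must be positive")
            if r.depth is None:
                raise ValueError(
                    f"SNP {r.chrom}:{r.pos} lacks depth; required for the "
                    f"{max_depth_factor}x coverage filter"
                )
            if r.depth > max_depth_factor * mean_depth:
                n_depth_dropped += 1
                continue
        matched.append(r)
    log.info(
        "assign_line_snps: %d matched, %d dropped by depth filter",
        len(matched), n_depth_dropped,
    )
    return matched


def derive_donor_specific_frames(
    donor_snps: pd.DataFrame,
    other_parent_snps: Mapping[str, pd.DataFrame],
    include_het_donor: bool = False,
    strict_position_exclusion: bool = False,
) -> DonorSnpSet:
    """Vectorized :func:`derive_donor_specific` over SNP frames
    (columns chrom, pos, alt, genotype); same contract."""
    kept = _donor_specific_frame(
        donor_snps, other_parent_snps, include_het_donor, strict_position_exclusion
    )
    result = set(zip(kept["chrom"], kept["pos"].astype(int), kept["alt"]))
    log.info("derive_donor_specific: %d donor-specific alleles", len(result))
    return result


def _donor_specific_frame(
    donor_snps: pd.DataFrame,
    other_parent_snps: Mapping[str, pd.DataFrame],
    include_het_donor: bool = False,
    strict_position_exclusion: bool = False,
) -> pd.DataFrame:
    d = donor_snps if include_het_donor else donor_snps[donor_snps["genotype"] == "hom_alt"]
    cols = ["chrom", "pos"] if strict_position_exclusion else ["chrom", "pos", "alt"]
    keys = pd.MultiIndex.from_frame(d[cols])
    keep = np.ones(len(d), dtype=bool)
    for frame in other_parent_snps.values():
        keep &= ~keys.isin(pd.MultiIndex.from_frame(frame[cols]))
    return d[keep]


def assign_line_snps_frame(
    line_snps: pd.DataFrame,
    donor_set: DonorSnpSet | pd.MultiIndex,
    mean_depth: float | None = None,
    max_depth_factor: float = DEFAULT.snp_max_depth_factor,
) -> pd.DataFrame:
    """Vectorized :func:`assign_line_snps` over a SNP frame; same contract.
    ``donor_set`` may be the tuple set or a (chrom, pos, alt) MultiIndex."""
    keys = pd.MultiIndex.from_frame(line_snps[["chrom", "pos", "alt"]])
    if isinstance(donor_set, pd.MultiIndex):
        donor_index = donor_set
    elif donor_set:
        donor_index = pd.MultiIndex.from_tuples(sorted(donor_set), names=["chrom", "pos", "alt"])
    else:
        donor_index = pd.MultiIndex.from_arrays([[], [], []])
    matched = line_snps[keys.isin(donor_index)]
    if mean_depth is not None:
        if mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if matched["depth"].isna().any():
            raise ValueError("matched SNPs lack depth; required for the coverage filter")
        matched = matched[matched["depth"] <= max_depth_factor * mean_depth]
    return matched.reset_index(drop=True)


def bin_snps(
    matched: Sequence[SnpRecord] | pd.DataFrame,
    windows: pd.DataFrame,
) -> pd.DataFrame:
    """Bin matched SNPs into windows, split by genotype class.

    VCF positions are 1-based, windows half-open 0-based: position ``pos``
    falls in the window with ``start <= pos - 1 < end``.  SNPs outside every
    window are logged and skipped.  Returns the window grid with added
    ``hom`` and ``het`` count columns.
    """
    out = windows[["chrom", "start", "end"]].copy().reset_index(drop=True)
    hom = np.zeros(len(out), dtype=np.int64)
    het = np.zeros(len(out), dtype=np.int64)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in out.groupby("chrom"):
        order = grp.sort_values("start")
        by_chrom[str(chrom)] = (
            order["start"].to_numpy(np.int64),
            order["end"].to_numpy(np.int64),
            order.index.to_numpy(np.int64),
        )
    if isinstance(matched, pd.DataFrame):
        triples = zip(matched["chrom"], matched["pos"].astype(int), matched["genotype"])
    else:
        triples = ((r.chrom, r.pos, r.genotype) for r in matched)
    n_skipped = 0
    for chrom, pos, genotype in triples:
        loc = by_chrom.get(chrom)
        pos0 = pos - 1
        if loc is None:
            n_skipped += 1
            continue
        starts, ends, idx = loc
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        if i < 0 or pos0 >= ends[i]:
            n_skipped += 1
            continue
        if genotype == "hom_alt":
            hom[idx[i]] += 1
        else:
            het[idx[i]] += 1
    if n_skipped:
        log.info("bin_snps: %d SNPs outside all windows skipped", n_skipped)
    out["hom"] = hom
    out["het"] = het
    return out
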