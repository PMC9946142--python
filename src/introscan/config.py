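"""Threshold configuration shared across the pipeline.

All filter thresholds used by the workflow live in one dataclass so a run can
be audited or re-parameterized from a single YAML block.  Defaults are the
values used throughout the analysis: the 0.8-1.2 normal coverage band, the
0.7 block threshold with 5 Mbp merging and the 80% constituent-window rule,
the 3x SNP-site depth cap, the 0.6x gene depth factor, TPM > 1.0 for
expression, |log2FC| >= 1 with adjusted p < 0.05 for differential expression,
and the 90/85/80% protein-identity cut-offs.  The donor-SNP block-assignment
thresholds (hom density, window fraction, hom:het ratio) are calibration
defaults exposed here because no published values exist for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import yaml


@dataclass(frozen=True)
class Thresholds:
    # in-silico karyotyping
    normal_band: tuple[float, float] = (0.8, 1.2)
    block_threshold: float = 0.7
    merge_gap: int = 5_000_000
    min_block_fraction: float = 0.8
    dup_threshold: float = 1.8
    het_band: tuple[float, float] = (0.4, 0.6)
    # a reduced block whose mean deviation is below this is called homozygous
    hom_zygosity_max_dev: float = 0.3
    # donor-specific SNP handling
    snp_max_depth_factor: float = 3.0
    min_hom_density: float = 5.0          # hom donor SNPs per Mbp
    min_window_fraction: float = 0.5
    min_hom_het_ratio: float = 2.0
    het_min_density: float = 50.0         # donor SNPs per Mbp for het blocks
    # gene classification
    gene_depth_factor: float = 0.6
    resistance_min_depth: float = 2.0
    # orthology
    rbh_min_identity: float = 90.0
    rbh_min_query_coverage: float = 0.8
    novelty_domain_identity: float = 85.0
    novelty_protein_identity: float = 80.0
    # expression
    tpm_expressed: float = 1.0
    lfc_min: float = 1.0
    padj_max: float = 0.05
    min_norm_count: float = 1.0
    pseudocount: float = 0.5
    lfc_window: int = 10_000_000

    def updated(self, **kwargs: Any) -> "Thresholds":
        return replace(self, **kwargs)


def load_thresholds(path: str | Path | None, **overrides: Any) -> Thresholds:
    """Load thresholds from a YAML file (top-level or under a ``thresholds``
    key), applying keyword overrides last.  Unknown keys raise ``KeyError``."""
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        data = raw.get("thresholds", raw)
    data.update(overrides)
    known = {f.name for f in fields(Thresholds)}
    unknown = set(data) - known
    if unknown:
        raise KeyError(f"unknown threshold keys: {sorted(unknown)}")
    for key in ("normal_band", "het_band"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return Thresholds(**data)


DEFAULT = Thresholds()
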