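"""Shared analysis thresholds and their on-disk configuration format.

Every stage of the pipeline reads its cut-offs from a single
:class:`Thresholds` object so that window conventions (1-based, inclusive,
absolute base-pair distance) and significance levels are defined exactly
once.  The defaults are the values used throughout large-scale plasma pQTL
studies: genome-wide significance 1.8e-9, candidate threshold 5e-6 for the
stepwise conditional analysis, a 1 Mb cis window around the target gene's
transcription start site, 2 Mb region merging, a 5 Mb cross-platform locus
window, and the strict r^2 > 0.8 high-LD rule.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Tuple

import yaml

__all__ = ["Thresholds", "load_config", "save_config"]


@dataclass
class Thresholds:
    """Analysis-wide significance thresholds and genomic window sizes.

    Attributes
    ----------
    genomewide_p
        Genome-wide significance threshold for pQTL discovery.
    candidate_p
        Inclusion threshold for the stepwise conditional candidate set.
    ld_high_r2
        High-LD rule; comparisons are strict (``r2 > ld_high_r2``).
    cis_window_bp
        A signal is *cis* iff on the target gene's chromosome and within
        this distance of its TSS (inclusive boundary).
    region_merge_bp
        Single-linkage chaining distance when merging signals into regions
        (inclusive boundary).
    xplat_window_bp
        Locus window when searching for a corresponding signal on the
        other platform.
    replication_p
        Nominal threshold for same-direction replication.
    fwer
        Family-wise error rate for the Bonferroni-controlled
        protein-phenotype scan.
    maf_min, info_min
        Variant inclusion filters (MAF > 0.01% and imputation info > 0.9).
    nonspecific_protein_count
        A variant associated with strictly more proteins than this is
        flagged non-specific.
    pleiotropic_protein_count
        Strictly-greater rule for the pleiotropic flag.
    mhc_interval
        Optional ``(chrom, start, end)``; any variant inside joins a
        single MHC region regardless of distance chaining.
    """

    genomewide_p: float = 1.8e-9
    candidate_p: float = 5e-6
    ld_high_r2: float = 0.8
    cis_window_bp: int = 1_000_000
    region_merge_bp: int = 2_000_000
    xplat_window_bp: int = 5_000_000
    replication_p: float = 0.05
    fwer: float = 0.05
    maf_min: float = 1e-4
    info_min: float = 0.9
    nonspecific_protein_count: int = 10
    pleiotropic_protein_count: int = 50
    mhc_interval: Optional[Tuple[str, int, int]] = ("chr6", 25_500_000, 34_000_000)

    def __post_init__(self) -> None:
        for name in ("genomewide_p", "candidate_p", "replication_p", "fwer"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0,1), got {v}")
        for name in ("cis_window_bp", "region_merge_bp", "xplat_window_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.ld_high_r2 < 1.0):
            raise ValueError("ld_high_r2 must lie in (0,1)")
        if self.mhc_interval is not None:
            chrom, start, end = self.mhc_interval
            if start > end:
                raise ValueError("mhc_interval start > end")
            self.mhc_interval = (str(chrom), int(start), int(end))


def load_config(path) -> Thresholds:
    """Read a nested key-value (YAML) config file into :class:`Thresholds`.

    Unknown keys raise; absent keys keep their defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    section = raw.get("thresholds", raw)
    known = {f.name for f in dataclasses.fields(Thresholds)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "mhc_interval" in section and section["mhc_interval"] is not None:
        section["mhc_interval"] = tuple(section["mhc_interval"])
    return Thresholds(**section)


def save_config(thresholds: Thresholds, path) -> None:
    d = dataclasses.asdict(thresholds)
    if d["mhc_interval"] is not None:
        d["mhc_interval"] = list(d["mhc_interval"])
    with open(path, "w") as fh:
        yaml.safe_dump({"thresholds": d}, fh, sort_keys=False)
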