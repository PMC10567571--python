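"""Cross-platform assay matching and inter-platform level concordance.

Assays on the two platforms are matched by shared target identifier
(full cross-product per target, so a target with one assay on platform A
and two on platform B contributes two pairs).  Concordance is the Spearman
rank correlation of levels over donors measured on both platforms, using
the first measurement per donor; ranks make the log transform irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssayPair",
    "match_assays",
    "first_measurements",
    "pair_correlations",
    "stratified_summary",
    "random_pair_baseline",
]


@dataclass
class AssayPair:
    target_id: str
    assay_id_a: str
    assay_id_b: str
    spearman_r: Optional[float] = None
    n_overlap: int = 0


def match_assays(panel_a: pd.DataFrame, panel_b: pd.DataFrame) -> List[AssayPair]:
    """All (platform A assay, platform B assay) pairs sharing a target."""
    by_target_b = panel_b.groupby("target_id")["assay_id"]
    pairs = []
    for _, row in panel_a.sort_values("assay_id").iterrows():
        target = row["target_id"]
        if target not in by_target_b.groups:
            continue
        for b_assay in sorted(by_target_b.get_group(target)):
            pairs.append(AssayPair(target_id=target,
                                   assay_id_a=row["assay_id"],
                                   assay_id_b=b_assay))
    return pairs


def first_measurements(matrix: pd.DataFrame) -> pd.DataFrame:
    """One level per (donor, assay): the first measurement by measurement id."""
    ordered = matrix.sort_values("measurement_id", kind="mergesort")
    return ordered.drop_duplicates(["donor_id", "assay_id"], keep="first")


def _wide(matrix: pd.DataFrame) -> pd.DataFrame:
    firsts = first_measurements(matrix)
    return firsts.pivot(index="donor_id", columns="assay_id", values="level")


def pair_correlations(pairs: List[AssayPair], matrix_a: pd.DataFrame,
                      matrix_b: pd.DataFrame) -> List[AssayPair]:
    """Fill in Spearman r (ties by average rank) over overlapping donors."""
    wide_a, wide_b = _wide(matrix_a), _wide(matrix_b)
    overlap = wide_a.index.intersection(wide_b.index)
    for pair in pairs:
        a = wide_a.loc[overlap, pair.assay_id_a]
        b = wide_b.loc[overlap, pair.assay_id_b]
        ok = a.notna() & b.notna()
        pair.n_overlap = int(ok.sum())
        if pair.n_overlap < 2:
            pair.spearman_r = None
            continue
        r = stats.spearmanr(a[ok], b[ok]).statistic
        pair.spearman_r = float(r)
    return pairs


def pairs_frame(pairs: List[AssayPair]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in pairs])


def random_pair_baseline(matrix_a: pd.DataFrame, matrix_b: pd.DataFrame,
                         panel_a: pd.DataFrame, panel_b: pd.DataFrame,
                         n_pairs: int = 200, seed: int = 0) -> float:
    """Median Spearman r over random cross-platform assay pairs (any
    targets) — the null baseline for the matched-pair correlations."""
    rng = np.random.default_rng(seed)
    wide_a, wide_b = _wide(matrix_a), _wide(matrix_b)
    overlap = wide_a.index.intersection(wide_b.index)
    assays_a = sorted(panel_a["assay_id"])
    assays_b = sorted(panel_b["assay_id"])
    rs = []
    for _ in range(n_pairs):
        a = wide_a.loc[overlap, assays_a[rng.integers(len(assays_a))]]
        b = wide_b.loc[overlap, assays_b[rng.integers(len(assays_b))]]
        ok = a.notna() & b.notna()
        if ok.sum() < 2:
            continue
        rs.append(stats.spearmanr(a[ok], b[ok]).statistic)
    return float(np.median(rs)) if rs else np.nan


def stratified_summary(pairs: List[AssayPair], panel: pd.DataFrame) -> pd.DataFrame:
    """Median correlation by dilution group, subcellular class and (for
    platform A assays) panel set; empty strata are omitted."""
    frame = pairs_frame(pairs).dropna(subset=["spearman_r"])
    if frame.empty:
        return pd.DataFrame(columns=["stratum", "value", "median_r", "n_pairs"])
    annot = panel.set_index("assay_id")
    frame = frame.assign(
        dilution_group=frame["assay_id_a"].map(annot["dilution_group"]),
        subcellular_class=frame["assay_id_a"].map(annot["subcellular_class"]),
        panel_set=frame["assay_id_a"].map(annot["panel_set"]),
    )
    rows = [{"stratum": "overall", "value": "all",
             "median_r": float(frame["spearman_r"].median()),
             "n_pairs": len(frame)}]
    for stratum in ("dilution_group", "subcellular_class", "panel_set"):
        for value, group in frame.groupby(stratum):
            if len(group) == 0 or value == "":
                continue
            rows.append({"stratum": stratum, "value": value,
                         "median_r": float(group["spearman_r"].median()),
                         "n_pairs": len(group)})
    return pd.DataFrame(rows)
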