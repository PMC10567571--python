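"""Assay precision and QC statistics under a log-normal level model.

Protein levels ``x`` are taken as log-normal: on the log scale with mean mu
and variance sigma^2, the level mean is ``exp(mu + sigma^2/2)`` and the
coefficient of variation (s.d./mean) is ``sqrt(exp(sigma^2) - 1)``,
independent of mu.  The log-scale s.d. of repeated measurements is
estimated with the robust median-absolute-deviation estimator (normal
consistency constant 1.4826); the s.d. of a single measurement is the
paired-difference s.d. divided by sqrt(2).

Also here: the random-pair CV (duplicates replaced by random donor pairs,
so biological variance enters), the batch-susceptibility ratio of
same-plate to across-plate control CVs, per-sample median (SMP)
normalization within dilution groups, and below-LOD statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .io import DILUTION_GROUPS, InsufficientDataError, ValidationError

__all__ = [
    "MAD_CONSTANT",
    "PrecisionRecord",
    "cv_lognormal",
    "estimate_cv_duplicates",
    "estimate_cv_random_pairs",
    "duplicate_pairs",
    "cohort_precision",
    "batch_susceptibility",
    "smp_normalize",
    "lod_stats",
]

MAD_CONSTANT = 1.4826  # MAD -> s.d. under normality


@dataclass
class PrecisionRecord:
    assay_id: str
    mode: str  # "duplicate" or "random_pair"
    n_pairs: int
    sigma_log: float
    cv: float


def cv_lognormal(sigma_log: float) -> float:
    """CV of a log-normal with log-scale s.d. ``sigma_log``:
    ``sqrt(exp(sigma^2) - 1)``."""
    sigma_log = float(sigma_log)
    if sigma_log < 0:
        raise ValueError("sigma_log must be non-negative")
    return float(np.sqrt(np.expm1(sigma_log ** 2)))


def _sigma_from_pairs(x1: np.ndarray, x2: np.ndarray) -> float:
    """Log-scale s.d. of one measurement from paired levels via MAD."""
    if np.any(x1 <= 0) or np.any(x2 <= 0):
        raise ValueError("levels must be positive")
    d = np.log(x1) - np.log(x2)
    mad = float(np.median(np.abs(d - np.median(d))))
    sigma_d = MAD_CONSTANT * mad
    return sigma_d / np.sqrt(2.0)


def estimate_cv_duplicates(x1, x2, assay_id: str = "") -> PrecisionRecord:
    """Duplicate-pair CV: each pair is two measurements of the same sample,
    so only technical variance enters."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("paired arrays must have equal length")
    if len(x1) < 3:
        raise InsufficientDataError("need at least 3 duplicate pairs")
    sigma = _sigma_from_pairs(x1, x2)
    return PrecisionRecord(assay_id=assay_id, mode="duplicate",
                           n_pairs=len(x1), sigma_log=sigma,
                           cv=cv_lognormal(sigma))


def estimate_cv_random_pairs(levels, n_pairs: int = 1000,
                             seed: int = 0,
                             assay_id: str = "") -> PrecisionRecord:
    """Random-pair CV: pairs of distinct donors drawn uniformly (seeded),
    so biological variance enters the estimate as well."""
    levels = np.asarray(levels, dtype=float)
    if len(levels) < 2:
        raise InsufficientDataError("need at least 2 donors")
    rng = np.random.default_rng(seed)
    first = rng.integers(0, len(levels), size=n_pairs)
    offset = rng.integers(1, len(levels), size=n_pairs)
    second = (first + offset) % len(levels)  # without replacement within pair
    sigma = _sigma_from_pairs(levels[first], levels[second])
    return PrecisionRecord(assay_id=assay_id, mode="random_pair",
                           n_pairs=n_pairs, sigma_log=sigma,
                           cv=cv_lognormal(sigma))


def duplicate_pairs(matrix: pd.DataFrame) -> pd.DataFrame:
    """Extract one row per duplicate pair (level_1, level_2) per assay."""
    linked = matrix.dropna(subset=["is_duplicate_of"])
    by_id = matrix.set_index("measurement_id")["level"]
    rows = []
    seen = set()
    for _, row in linked.iterrows():
        key = frozenset((row["measurement_id"], row["is_duplicate_of"]))
        if key in seen:
            continue
        seen.add(key)
        rows.append({
            "assay_id": row["assay_id"], "donor_id": row["donor_id"],
            "level_1": row["level"],
            "level_2": by_id.loc[row["is_duplicate_of"]],
        })
    return pd.DataFrame(rows, columns=["assay_id", "donor_id",
                                       "level_1", "level_2"])


def cohort_precision(matrix: pd.DataFrame, n_random_pairs: int = 1000,
                     seed: int = 0) -> pd.DataFrame:
    """Per-assay duplicate and random-pair CVs for a protein matrix."""
    pairs = duplicate_pairs(matrix)
    firsts = matrix[matrix["is_duplicate_of"].isna()]
    records = []
    for assay_id, group in pairs.groupby("assay_id"):
        if len(group) < 3:
            continue
        rec = estimate_cv_duplicates(group["level_1"], group["level_2"],
                                     assay_id=assay_id)
        records.append(rec)
    for assay_id, group in firsts.groupby("assay_id"):
        rec = estimate_cv_random_pairs(group["level"].to_numpy(),
                                       n_pairs=n_random_pairs, seed=seed,
                                       assay_id=assay_id)
        records.append(rec)
    return pd.DataFrame([vars(r) for r in records])


def batch_susceptibility(cv_same_plate: float, cv_across_plate: float) -> float:
    """Ratio of same-plate to across-plate control CV, clipped to [0, 1].

    Values near one indicate little susceptibility to batch (plate)
    effects; values near zero indicate strong susceptibility.
    """
    if cv_across_plate <= 0:
        raise ZeroDivisionError("across-plate CV must be positive")
    if cv_same_plate < 0:
        raise ValueError("CVs must be non-negative")
    return float(np.clip(cv_same_plate / cv_across_plate, 0.0, 1.0))


def smp_normalize(matrix: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Per-sample median normalization within dilution groups.

    Within each dilution group, each sample's levels are divided by that
    sample's median ratio to the per-assay cohort-median reference, so every
    sample's median ratio becomes 1 per dilution group.  Idempotent.
    """
    out = matrix.copy()
    dilution = panel.set_index("assay_id")["dilution_group"]
    groups = out["assay_id"].map(dilution)
    for group in DILUTION_GROUPS:
        mask = (groups == group).to_numpy()
        if not mask.any():
            warnings.warn(f"dilution group {group!r} has no assays; skipped")
            continue
        sub = out.loc[mask]
        firsts = sub[sub["is_duplicate_of"].isna()] \
            .sort_values("measurement_id", kind="mergesort")
        wide = firsts.pivot_table(index="donor_id", columns="assay_id",
                                  values="level", aggfunc="first")
        total = pd.Series(1.0, index=wide.index)
        # alternate reference / per-sample factor updates to a fixed point,
        # so re-normalizing already-normalized data is a no-op
        for _ in range(200):
            reference = wide.median(axis=0)
            factor = (wide / reference).median(axis=1)
            wide = wide.div(factor, axis=0)
            total *= factor
            if (factor - 1.0).abs().max() < 1e-12:
                break
        scaled = sub["level"] / sub["donor_id"].map(total).to_numpy()
        out.loc[mask, "level"] = scaled.to_numpy()
    return out


def lod_stats(matrix: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Per-assay fraction of measurements below the LOD and whether the
    median level is above it; assays without a LOD are skipped with a note."""
    lod_of = panel.set_index("assay_id")["lod"]
    rows = []
    for assay_id, group in matrix.groupby("assay_id"):
        if len(group) == 0:
            raise ValidationError(f"assay {assay_id!r} has no measurements")
        lod = lod_of.get(assay_id, np.nan)
        if pd.isna(lod):
            rows.append({"assay_id": assay_id, "fraction_below_lod": np.nan,
                         "median_above_lod": pd.NA, "note": "no LOD"})
            continue
        frac = float((group["level"] < lod).mean())
        rows.append({
            "assay_id": assay_id, "fraction_below_lod": frac,
            "median_above_lod": bool(group["level"].median() > lod),
            "note": "",
        })
    return pd.DataFrame(rows)
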