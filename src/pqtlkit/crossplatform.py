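"""Cross-platform pQTL correspondence, replication, power and tiers.

A sentinel signal detected on one platform *corresponds* to the other
platform when any signal (sentinel or secondary) for a same-target assay
within 5 Mb is in high LD (r2 > 0.8, strict) with it, with LD computed in
one designated reference genotype panel.  Replication of a single
association requires nominal significance (P < 0.05) in the other cohort
with the same effect direction after allele alignment.

Power for a 1-df association test at threshold P, sample size N, per-allele
effect beta (phenotype-s.d. units) and allele frequency f is
``1 - F(X^-1(1 - P), 2 N beta^2 f (1 - f))`` with ``F`` the noncentral
chi-squared CDF (1 df) and ``X^-1`` the central chi-squared quantile.

Targets are organized into confidence tiers: tier 1 = cis pQTL on both
platforms and strong inter-platform correlation; tier 2 = cis pQTL on at
least one platform but missing the other condition; tier 3 = cis pQTL on
neither platform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import Thresholds
from .gwas import ld_r2
from .io import GenotypeMatrix

__all__ = [
    "CorrespondenceRecord",
    "PowerParams",
    "TierAssignment",
    "correspond",
    "correspondence_fraction",
    "replicate",
    "power",
    "tier_classify",
]


@dataclass
class CorrespondenceRecord:
    platform: str
    assay_id: str
    variant_id: str
    cis_trans: str
    matched: bool
    matched_variant_id: Optional[str] = None
    matched_assay_id: Optional[str] = None
    matched_rank: str = "none"  # sentinel / secondary / none
    r2: Optional[float] = None
    distance_bp: Optional[int] = None
    reason: str = ""


@dataclass
class PowerParams:
    p_threshold: float
    n: int
    beta: float
    f: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must lie in (0,1)")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 < self.f < 1.0):
            raise ValueError("f must lie in (0,1)")

    @property
    def ncp(self) -> float:
        return 2.0 * self.n * self.beta ** 2 * self.f * (1.0 - self.f)


@dataclass
class TierAssignment:
    target_id: str
    tier: int
    cis_on_a: bool
    cis_on_b: bool
    max_pair_correlation: Optional[float]


def correspond(query_sentinels: pd.DataFrame, other_signals: pd.DataFrame,
               genotypes: GenotypeMatrix, thresholds: Thresholds,
               platform: str = "") -> List[CorrespondenceRecord]:
    """Match each query sentinel against the other platform's signals.

    ``query_sentinels`` and ``other_signals`` are signal tables (as produced
    by the pQTL engine) with target_id, variant_id, chrom, pos, rank and
    cis_trans columns.  A match requires a same-target assay signal within
    the cross-platform window whose variant has r2 above the high-LD rule
    (strict) in the reference genotypes.  ``matched_rank`` records whether
    the best match is the sentinel at its locus.
    """
    records: List[CorrespondenceRecord] = []
    by_target = dict(tuple(other_signals.groupby("target_id"))) \
        if len(other_signals) else {}
    for _, q in query_sentinels.iterrows():
        rec = CorrespondenceRecord(
            platform=platform, assay_id=q["assay_id"],
            variant_id=q["variant_id"], cis_trans=q.get("cis_trans", ""),
            matched=False)
        pool = by_target.get(q["target_id"])
        if pool is None or not len(pool):
            rec.reason = "no same-target signals on other platform"
            records.append(rec)
            continue
        near = pool[(pool["chrom"] == q["chrom"]) &
                    ((pool["pos"] - q["pos"]).abs() <=
                     thresholds.xplat_window_bp)]
        if not len(near):
            rec.reason = "no signal within locus window"
            records.append(rec)
            continue
        if q["variant_id"] not in genotypes:
            rec.reason = "query variant absent from reference genotypes"
            records.append(rec)
            continue
        qdose = genotypes.dosage(q["variant_id"])
        best = None
        for _, s in near.sort_values(["rank", "p_marginal"]).iterrows():
            if s["variant_id"] not in genotypes:
                continue
            try:
                r2 = ld_r2(qdose, genotypes.dosage(s["variant_id"]))
            except ValueError:
                continue
            if r2 > thresholds.ld_high_r2:
                best = (s, r2)
                break
        if best is None:
            rec.reason = "no high-LD signal at locus"
        else:
            s, r2 = best
            rec.matched = True
            rec.matched_variant_id = s["variant_id"]
            rec.matched_assay_id = s["assay_id"]
            rec.matched_rank = "sentinel" if s["rank"] == 1 else "secondary"
            rec.r2 = r2
            rec.distance_bp = int(abs(s["pos"] - q["pos"]))
        records.append(rec)
    return records


def correspondence_fraction(n_matched: int, n_total: int,
                            as_percent: bool = True) -> float:
    """Fraction (or percent) of query sentinels with a corresponding
    signal on the other platform."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_matched <= n_total):
        raise ValueError("n_matched must lie in [0, n_total]")
    frac = n_matched / n_total
    return 100.0 * frac if as_percent else frac


def replicate(beta_disc: float, beta_repl: float, p_repl: float,
              thresholds: Optional[Thresholds] = None,
              alleles_flipped: bool = False) -> bool:
    """Same-direction nominal replication; flip the replication beta first
    when the effect alleles are swapped between cohorts."""
    thresholds = thresholds or Thresholds()
    if alleles_flipped:
        beta_repl = -beta_repl
    return bool(p_repl < thresholds.replication_p and
                np.sign(beta_repl) == np.sign(beta_disc) and
                beta_disc != 0)


def power(params: PowerParams) -> float:
    """Probability of rejecting no-association at the given threshold."""
    crit = stats.chi2.isf(params.p_threshold, df=1)
    if params.ncp == 0:
        # central case: exactly the threshold
        return float(params.p_threshold)
    return float(stats.ncx2.sf(crit, df=1, nc=params.ncp))


def tier_classify(targets: Sequence[str], signals_a: pd.DataFrame,
                  signals_b: pd.DataFrame, pair_correlations: pd.DataFrame,
                  correlation_cutoff: float = 0.5) -> List[TierAssignment]:
    """Confidence tiers from cis pQTL presence and level concordance.

    ``pair_correlations`` has target_id and spearman_r columns (one row per
    cross-platform assay pair); the maximum over a target's pairs is
    compared with the cutoff.  Targets with no assays on either platform
    should not be passed.
    """
    def cis_targets(signals: pd.DataFrame) -> set:
        if not len(signals):
            return set()
        return set(signals.loc[signals["cis_trans"] == "cis", "target_id"])

    cis_a, cis_b = cis_targets(signals_a), cis_targets(signals_b)
    max_r: Dict[str, float] = {}
    if len(pair_correlations):
        max_r = pair_correlations.dropna(subset=["spearman_r"]) \
            .groupby("target_id")["spearman_r"].max().to_dict()
    out = []
    for target in targets:
        on_a, on_b = target in cis_a, target in cis_b
        r = max_r.get(target)
        if not on_a and not on_b:
            tier = 3
        elif on_a and on_b and r is not None and r >= correlation_cutoff:
            tier = 1
        else:
            tier = 2
        out.append(TierAssignment(target_id=target, tier=tier,
                                  cis_on_a=on_a, cis_on_b=on_b,
                                  max_pair_correlation=r))
    return out
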