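"""Single-causal fine-mapping and colocalization from summary statistics.

Per-variant evidence is the Wakefield approximate Bayes factor computed
from z = beta/se with shrinkage r = W / (W + se^2):

    ABF = sqrt(1 - r) * exp(z^2 * r / 2)

with prior effect variance W (default 0.04, i.e. a prior s.d. of 0.2 on
the standardized scale).  Under a flat prior over the variants of a locus,
posterior inclusion probabilities are proportional to the ABFs and the 95%
credible set is the minimal prefix of variants (sorted by decreasing
posterior) whose cumulative mass reaches 0.95.

Colocalization of two traits over a shared variant list follows the
enumeration of five hypotheses (no signal / trait-1 only / trait-2 only /
two distinct signals / one shared signal) with per-hypothesis sums of ABF
products weighted by the priors p1 = p2 = 1e-4 and p12 = 1e-5; all sums are
accumulated in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .config import Thresholds
from .gwas import ld_r2
from .io import GenotypeMatrix

__all__ = [
    "DEFAULT_W",
    "CredibleSet",
    "ColocResult",
    "log_abf",
    "credible_set",
    "trait_overlap",
    "coloc",
]

DEFAULT_W = 0.04  # prior effect variance; s.d. 0.2 on the standardized scale


@dataclass
class CredibleSet:
    variant_ids: List[str]
    posteriors: List[float]
    mass: float
    w: float
    all_posteriors: Dict[str, float] = field(default_factory=dict)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in set(self.variant_ids)

    @property
    def size(self) -> int:
        return len(self.variant_ids)


@dataclass
class ColocResult:
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    p1: float
    p2: float
    p12: float
    n_variants: int

    def as_array(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])


def log_abf(beta, se, w: float = DEFAULT_W) -> np.ndarray:
    """Log Wakefield approximate Bayes factor (association vs null)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    z2 = (beta / se) ** 2
    r = w / (w + se ** 2)
    return 0.5 * (np.log1p(-r) + z2 * r)


def credible_set(variant_ids: Sequence[str], beta, se,
                 w: float = DEFAULT_W, mass: float = 0.95) -> CredibleSet:
    """Minimal 95% credible set under a flat single-causal prior.

    Posterior inclusion probabilities are ABFs normalized over the locus;
    the set is the shortest prefix of variants in decreasing-posterior
    order (ties by variant id for determinism) reaching the target mass.
    """
    variant_ids = list(variant_ids)
    la = log_abf(beta, se, w)
    post = np.exp(la - logsumexp(la))
    order = sorted(range(len(variant_ids)),
                   key=lambda i: (-post[i], variant_ids[i]))
    cumulative, members, probs = 0.0, [], []
    for i in order:
        members.append(variant_ids[i])
        probs.append(float(post[i]))
        cumulative += post[i]
        if cumulative >= mass - 1e-12:
            break
    return CredibleSet(variant_ids=members, posteriors=probs,
                       mass=float(cumulative), w=w,
                       all_posteriors=dict(zip(variant_ids, map(float, post))))


def trait_overlap(signal_variant: str, credset: CredibleSet,
                  trait_hits: pd.DataFrame, genotypes: GenotypeMatrix,
                  thresholds: Optional[Thresholds] = None) -> pd.DataFrame:
    """Relate a pQTL signal to catalogued trait-associated variants.

    A (trait, signal) pair qualifies iff the trait variant is in high LD
    (strict r2 rule) with the signal variant AND is a member of the
    signal's credible set; both conditions are reported separately.  Trait
    variants absent from the reference genotypes are skipped with a reason.
    """
    thresholds = thresholds or Thresholds()
    if signal_variant not in genotypes:
        raise KeyError(f"signal variant {signal_variant!r} not in genotypes")
    sdose = genotypes.dosage(signal_variant)
    rows = []
    for _, hit in trait_hits.iterrows():
        vid = hit["variant_id"]
        row = {"trait_id": hit["trait_id"], "variant_id": vid,
               "signal_variant": signal_variant, "r2": np.nan,
               "high_ld": False, "in_credible_set": False,
               "qualifies": False, "reason": ""}
        if vid not in genotypes:
            row["reason"] = "trait variant absent from genotypes"
            rows.append(row)
            continue
        try:
            r2 = ld_r2(sdose, genotypes.dosage(vid))
        except ValueError:
            row["reason"] = "LD undefined (zero variance)"
            rows.append(row)
            continue
        row["r2"] = r2
        row["high_ld"] = r2 > thresholds.ld_high_r2
        row["in_credible_set"] = vid in credset
        row["qualifies"] = row["high_ld"] and row["in_credible_set"]
        rows.append(row)
    return pd.DataFrame(rows)


def coloc(beta_a, se_a, beta_b, se_b,
          variant_ids: Optional[Sequence[str]] = None,
          p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5,
          w_a: float = DEFAULT_W, w_b: float = DEFAULT_W) -> ColocResult:
    """Colocalization posteriors for two traits over one variant list.

    Hypothesis sums (log space): H0 = 1; H1 = p1 * sum(BF_A);
    H2 = p2 * sum(BF_B); H3 = p1*p2 * (sum BF_A * sum BF_B
    - sum BF_A*BF_B); H4 = p12 * sum(BF_A*BF_B); normalized to posteriors.
    """
    beta_a = np.asarray(beta_a, dtype=float)
    beta_b = np.asarray(beta_b, dtype=float)
    se_a = np.asarray(se_a, dtype=float)
    se_b = np.asarray(se_b, dtype=float)
    if not (len(beta_a) == len(beta_b) == len(se_a) == len(se_b)):
        raise ValueError("trait A and B variant lists are misaligned")
    m = len(beta_a)
    if m == 0:
        raise ValueError("empty locus")
    la = log_abf(beta_a, se_a, w_a)
    lb = log_abf(beta_b, se_b, w_b)
    lsum_a = logsumexp(la)
    lsum_b = logsumexp(lb)
    lsum_ab = logsumexp(la + lb)
    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(p1) + lsum_a
    lh[2] = np.log(p2) + lsum_b
    # sum_{i != j} BF_A,i BF_B,j = sumA*sumB - sum(BF_A BF_B), in log space
    cross = lsum_a + lsum_b
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = cross + np.log1p(-np.exp(np.minimum(lsum_ab - cross, 0.0)))
    if m == 1 or not np.isfinite(diff):
        lh[3] = -np.inf
    else:
        lh[3] = np.log(p1) + np.log(p2) + diff
    lh[4] = (np.log(p12) + lsum_ab) if p12 > 0 else -np.inf
    post = np.exp(lh - logsumexp(lh))
    post = post / post.sum()
    return ColocResult(pp0=float(post[0]), pp1=float(post[1]),
                       pp2=float(post[2]), pp3=float(post[3]),
                       pp4=float(post[4]), p1=p1, p2=p2, p12=p12,
                       n_variants=m)
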