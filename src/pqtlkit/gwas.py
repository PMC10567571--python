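"""pQTL mapping: phenotype preparation, association testing, recursive
stepwise conditional analysis, region merging and LD clumping.

The association engine is ordinary least squares on unrelated individuals:
protein levels are rank-inverse-normal transformed (Blom scores),
residualized on age, sex and sample age, transformed again, and regressed
on alternate-allele dosage, optionally conditional on previously selected
variants.  P values come from the nested-model likelihood-ratio test
(chi-squared, 1 df), and effects are in phenotype-s.d. units per
alternate-allele copy.

Discovery follows the recursive conditional scheme: restrict to candidates
with marginal P below the candidate threshold, repeatedly select the
variant with the smallest conditional P while it stays below genome-wide
significance, then refit a joint model of all selected variants.  Signals
are merged into regions by 2 Mb single-linkage chaining (the MHC interval
is one region), classified cis/trans against the target TSS, and clumped
across assays by high LD to count per-variant protein specificity.

The model-object surface is :class:`ProteinGwas` (built from a simulated
or loaded cohort) whose :meth:`ProteinGwas.fit` returns
:class:`PqtlResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import Thresholds
from .io import GenotypeMatrix, InsufficientDataError

__all__ = [
    "DegenerateInputError",
    "RankDeficiencyError",
    "AssocResult",
    "rint",
    "prepare_phenotype",
    "assoc_test",
    "gwas_scan",
    "stepwise_conditional",
    "joint_model",
    "ld_r2",
    "merge_regions",
    "classify_cis_trans",
    "clump_pqtls",
    "ProteinGwas",
    "PqtlResults",
    "map_platform_pqtls",
]


class DegenerateInputError(ValueError):
    """All values identical or otherwise untransformable."""


class RankDeficiencyError(ValueError):
    """Collinear design; the message names the offending variants."""


@dataclass
class AssocResult:
    assay_id: str
    variant_id: str
    effect_allele: str
    beta: float
    se: float
    p: float
    n: int
    conditioning_set: Tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# phenotype preparation


def rint(values) -> np.ndarray:
    """Rank-inverse-normal (Blom) scores: Phi^-1((r - 3/8) / (n + 1/4)),
    ties by average rank."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise InsufficientDataError("need at least 2 values")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values")
    if np.ptp(values) == 0:
        raise DegenerateInputError("all values identical")
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf((ranks - 0.375) / (len(values) + 0.25))


def _encode_covariates(samples: pd.DataFrame,
                       use_sample_age: bool = True) -> pd.DataFrame:
    cov = pd.DataFrame(index=samples["donor_id"])
    cov["age"] = samples["age"].to_numpy(dtype=float)
    cov["sex"] = pd.Categorical(samples["sex"]).codes.astype(float)
    if use_sample_age and "sample_age" in samples:
        cov["sample_age"] = samples["sample_age"].to_numpy(dtype=float)
    return cov


def prepare_phenotype(levels: pd.Series, samples: pd.DataFrame,
                      use_sample_age: bool = True) -> pd.Series:
    """RINT -> residualize on age, sex (and sample age) -> RINT again.

    ``levels`` is donor-indexed (first measurement per donor); donors with
    missing covariates are dropped with a warning.
    """
    cov = _encode_covariates(samples, use_sample_age)
    cov = cov.loc[cov.index.intersection(levels.index)]
    complete = cov.dropna()
    dropped = len(cov) - len(complete)
    if dropped:
        warnings.warn(f"dropped {dropped} donors with missing covariates")
    levels = levels.loc[complete.index]
    y = rint(levels.to_numpy())
    x = np.column_stack([np.ones(len(complete)), complete.to_numpy()])
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return pd.Series(rint(resid), index=complete.index, name=levels.name)


# ---------------------------------------------------------------------------
# association tests


def _lrt_p(n: int, rss0: float, rss1: float) -> float:
    if rss1 <= 0:
        return 0.0
    chi2 = n * np.log(max(rss0, rss1) / rss1)
    return float(stats.chi2.sf(chi2, df=1))


def assoc_test(phenotype: np.ndarray, dosage: np.ndarray,
               conditioning: Optional[np.ndarray] = None,
               assay_id: str = "", variant_id: str = "",
               effect_allele: str = "alt",
               conditioning_ids: Sequence[str] = ()) -> AssocResult:
    """Least-squares association of phenotype on dosage, optionally
    conditional on other dosages; P from the likelihood-ratio chi2(1)."""
    y = np.asarray(phenotype, dtype=float)
    g = np.asarray(dosage, dtype=float)
    n = len(y)
    if conditioning is None:
        conditioning = np.empty((n, 0))
    z = np.atleast_2d(np.asarray(conditioning, dtype=float))
    if z.shape[0] != n:
        z = z.T
    k = z.shape[1]
    if n <= k + 2:
        raise InsufficientDataError("n must exceed #conditioning + 2")
    x0 = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(x0) < x0.shape[1]:
        names = ", ".join(conditioning_ids) or "conditioning set"
        raise RankDeficiencyError(f"collinear conditioning set: {names}")
    x1 = np.column_stack([x0, g])
    if np.linalg.matrix_rank(x1) < x1.shape[1]:
        raise RankDeficiencyError(
            f"dosage {variant_id!r} collinear with conditioning set")
    coef0, res0, *_ = np.linalg.lstsq(x0, y, rcond=None)
    rss0 = float(np.sum((y - x0 @ coef0) ** 2))
    coef1, *_ = np.linalg.lstsq(x1, y, rcond=None)
    resid = y - x1 @ coef1
    rss1 = float(resid @ resid)
    dof = n - x1.shape[1]
    sigma2 = rss1 / dof
    xtx_inv = np.linalg.inv(x1.T @ x1)
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    return AssocResult(
        assay_id=assay_id, variant_id=variant_id,
        effect_allele=effect_allele, beta=float(coef1[-1]), se=se,
        p=_lrt_p(n, rss0, rss1), n=n,
        conditioning_set=tuple(conditioning_ids))


def gwas_scan(phenotype: pd.Series, genotypes: GenotypeMatrix,
              thresholds: Thresholds, assay_id: str = "") -> pd.DataFrame:
    """Marginal association of one prepared phenotype with every variant.

    Vectorized simple regression with intercept; returns a long DataFrame
    (one row per variant with non-zero dosage variance) with a boolean
    ``significant`` column at the genome-wide threshold.
    """
    donors = list(phenotype.index)
    sub = genotypes.subset_donors(donors)
    y = phenotype.to_numpy(dtype=float)
    n = len(y)
    yc = y - y.mean()
    tss = float(yc @ yc)
    g = sub.dosages
    gc = g - g.mean(axis=0)
    gg = np.einsum("ij,ij->j", gc, gc)
    keep = gg > 0
    gy = yc @ gc
    beta = np.where(keep, gy / np.where(keep, gg, 1.0), np.nan)
    rss1 = tss - np.where(keep, beta ** 2 * gg, 0.0)
    rss1 = np.maximum(rss1, 1e-300)
    chi2 = n * np.log(np.maximum(tss / rss1, 1.0))
    p = stats.chi2.sf(chi2, df=1)
    se = np.sqrt(rss1 / (n - 2) / np.where(keep, gg, 1.0))
    frame = pd.DataFrame({
        "assay_id": assay_id,
        "variant_id": sub.variant_ids,
        "effect_allele": "alt",
        "beta": beta, "se": se, "p": p, "n": n,
    })
    frame = frame.loc[keep].reset_index(drop=True)
    frame["significant"] = frame["p"] < thresholds.genomewide_p
    return frame


def _tie_order(variant_ids: Iterable[str], variants: pd.DataFrame):
    pos = variants.set_index("variant_id")["pos"]
    return sorted(variant_ids, key=lambda v: (int(pos[v]), v))


def stepwise_conditional(phenotype: pd.Series, genotypes: GenotypeMatrix,
                         candidates: Sequence[str], variants: pd.DataFrame,
                         thresholds: Thresholds,
                         assay_id: str = "") -> List[AssocResult]:
    """Greedy forward selection with the two-threshold recursive rule.

    ``candidates`` is the per-chromosome set of variants with marginal
    P below the candidate threshold.  At each step the variant with the
    smallest conditional P (ties: smaller position, then variant id) is
    selected if that P is below genome-wide significance; its conditional
    statistics at the selection step are recorded.  Stops when no candidate
    passes, or errors if selection exceeds n/2 variants.
    """
    donors = list(phenotype.index)
    sub = genotypes.subset_donors(donors)
    y = phenotype.to_numpy(dtype=float)
    remaining = _tie_order(dict.fromkeys(candidates), variants)
    selected: List[AssocResult] = []
    selected_ids: List[str] = []
    while remaining:
        if len(selected) > len(y) / 2:
            raise RuntimeError("stepwise selection exceeded n/2 variants")
        cond = (np.column_stack([sub.dosage(v) for v in selected_ids])
                if selected_ids else None)
        best: Optional[AssocResult] = None
        for vid in remaining:  # remaining is already in tie-break order
            try:
                res = assoc_test(y, sub.dosage(vid), cond,
                                 assay_id=assay_id, variant_id=vid,
                                 conditioning_ids=tuple(selected_ids))
            except RankDeficiencyError:
                continue  # candidate collinear with selected set
            if best is None or res.p < best.p:
                best = res
        if best is None or not (best.p < thresholds.genomewide_p):
            break
        selected.append(best)
        selected_ids.append(best.variant_id)
        remaining = [v for v in remaining if v != best.variant_id]
    return selected


def joint_model(phenotype: pd.Series, genotypes: GenotypeMatrix,
                selected: Sequence[str],
                thresholds: Thresholds,
                assay_id: str = "") -> pd.DataFrame:
    """Joint multiple-regression fit of all selected variants.

    Per-variant joint beta/se and a drop-one likelihood-ratio P; flags
    variants that lose genome-wide significance jointly.
    """
    ids = list(selected)
    if not ids:
        raise InsufficientDataError("need at least one selected variant")
    if len(set(ids)) != len(ids):
        raise RankDeficiencyError("duplicated variants in joint model")
    donors = list(phenotype.index)
    sub = genotypes.subset_donors(donors)
    y = phenotype.to_numpy(dtype=float)
    n = len(y)
    g = np.column_stack([sub.dosage(v) for v in ids])
    x = np.column_stack([np.ones(n), g])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise RankDeficiencyError(f"collinear joint model: {', '.join(ids)}")
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    rss_full = float(resid @ resid)
    sigma2 = rss_full / (n - x.shape[1])
    xtx_inv = np.linalg.inv(x.T @ x)
    rows = []
    for j, vid in enumerate(ids):
        drop = np.delete(x, j + 1, axis=1)
        coef0, *_ = np.linalg.lstsq(drop, y, rcond=None)
        rss0 = float(np.sum((y - drop @ coef0) ** 2))
        p = _lrt_p(n, rss0, rss_full)
        rows.append({
            "assay_id": assay_id, "variant_id": vid,
            "beta_joint": float(coef[j + 1]),
            "se_joint": float(np.sqrt(sigma2 * xtx_inv[j + 1, j + 1])),
            "p_joint": p,
            "joint_significant": p < thresholds.genomewide_p,
        })
    return pd.DataFrame(rows)


def ld_r2(dosage_1, dosage_2) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    a = np.asarray(dosage_1, dtype=float)
    b = np.asarray(dosage_2, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("LD undefined for zero-variance dosage")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# regions, classification, clumping


def _in_mhc(chrom: str, pos: int, thresholds: Thresholds) -> bool:
    if thresholds.mhc_interval is None:
        return False
    mchrom, start, end = thresholds.mhc_interval
    return chrom == mchrom and start <= pos <= end


def merge_regions(signals: pd.DataFrame,
                  thresholds: Thresholds) -> pd.DataFrame:
    """Assign region ids to one assay's signals by single-linkage chaining.

    Signals within ``region_merge_bp`` (inclusive) on the same chromosome
    chain transitively into one region; any signal inside the MHC interval
    joins the single MHC region regardless of chaining.  The signal with
    the smallest marginal P in each region becomes the sentinel (rank 1);
    other signals keep their discovery-order ranks (2, 3, ...).  Ties in
    the sentinel choice break by position, then variant id.
    """
    out = signals.copy().reset_index(drop=True)
    region_of = np.full(len(out), -1, dtype=int)
    next_region = 0
    mhc_region: Optional[int] = None
    for chrom, group in out.groupby("chrom", sort=True):
        order = group.sort_values(["pos", "variant_id"]).index
        prev_pos = None
        current = None
        for idx in order:
            pos = int(out.at[idx, "pos"])
            if _in_mhc(str(chrom), pos, thresholds):
                if mhc_region is None:
                    mhc_region = next_region
                    next_region += 1
                region_of[idx] = mhc_region
                # MHC breaks the distance chain on either side
                prev_pos, current = None, None
                continue
            if current is None or prev_pos is None or \
                    pos - prev_pos > thresholds.region_merge_bp:
                current = next_region
                next_region += 1
            region_of[idx] = current
            prev_pos = pos
    out["region_id"] = region_of
    # sentinel per region: smallest marginal p, ties by position then id
    ranks = np.zeros(len(out), dtype=int)
    for _, group in out.groupby("region_id"):
        ordered = group.sort_values(["p_marginal", "pos", "variant_id"])
        sentinel_idx = ordered.index[0]
        ranks[sentinel_idx] = 1
        rest = group.drop(index=sentinel_idx)
        if "discovery_order" in group:
            rest = rest.sort_values("discovery_order")
        for r, idx in enumerate(rest.index, start=2):
            ranks[idx] = r
    out["rank"] = ranks
    return out


def classify_cis_trans(chrom: str, pos: int, target_chrom: Optional[str],
                       target_tss: Optional[int],
                       thresholds: Thresholds) -> str:
    """cis iff on the target chromosome within the cis window (inclusive)
    of the TSS; 'unclassifiable' when the TSS is unknown."""
    if target_chrom is None or target_tss is None or \
            (isinstance(target_tss, float) and np.isnan(target_tss)):
        return "unclassifiable"
    if str(chrom) != str(target_chrom):
        return "trans"
    return "cis" if abs(int(pos) - int(target_tss)) <= \
        thresholds.cis_window_bp else "trans"


def clump_pqtls(signals: pd.DataFrame, genotypes: GenotypeMatrix,
                thresholds: Thresholds) -> pd.DataFrame:
    """Cluster signals across assays into pQTLs by high LD to a seed.

    Greedy: the most significant unclustered signal seeds a cluster and
    absorbs every unclustered signal whose variant has r2 > 0.8 with the
    seed variant.  Adds per-cluster distinct-protein counts and the
    non-specific (> 10 proteins) and pleiotropic (> 50 proteins) flags,
    plus a per-signal flag for proteins whose every pQTL is a
    non-specific trans signal.
    """
    out = signals.copy().reset_index(drop=True)
    order = out.sort_values(["p_marginal", "pos", "variant_id"]).index
    cluster = np.full(len(out), -1, dtype=int)
    seeds: Dict[int, str] = {}
    next_cluster = 0
    dosage_cache: Dict[str, np.ndarray] = {}

    def dose(vid: str) -> np.ndarray:
        if vid not in dosage_cache:
            dosage_cache[vid] = genotypes.dosage(vid)
        return dosage_cache[vid]

    for idx in order:
        if cluster[idx] >= 0:
            continue
        seed_vid = out.at[idx, "variant_id"]
        cid = next_cluster
        next_cluster += 1
        seeds[cid] = seed_vid
        cluster[idx] = cid
        for jdx in order:
            if cluster[jdx] >= 0:
                continue
            vid = out.at[jdx, "variant_id"]
            if vid == seed_vid:
                cluster[jdx] = cid
                continue
            try:
                if ld_r2(dose(seed_vid), dose(vid)) > thresholds.ld_high_r2:
                    cluster[jdx] = cid
            except ValueError:
                continue
    out["cluster_id"] = cluster
    out["cluster_seed"] = out["cluster_id"].map(seeds)
    counts = out.groupby("cluster_id")["target_id"].nunique()
    out["cluster_protein_count"] = out["cluster_id"].map(counts)
    out["non_specific"] = out["cluster_protein_count"] > \
        thresholds.nonspecific_protein_count
    out["pleiotropic"] = out["cluster_protein_count"] > \
        thresholds.pleiotropic_protein_count
    # proteins whose only pQTLs are non-specific trans signals
    is_ns_trans = out["non_specific"] & (out["cis_trans"] == "trans")
    only_ns = out.groupby("target_id").apply(
        lambda g: bool(is_ns_trans.loc[g.index].all()),
        include_groups=False)
    out["protein_only_nonspecific_trans"] = out["target_id"].map(only_ns)
    return out


# ---------------------------------------------------------------------------
# model objects


class ProteinGwas:
    """pQTL model for one assay: prepared phenotype vs genotype dosages.

    Parameters
    ----------
    levels : pd.Series
        Donor-indexed raw levels (first measurement per donor).
    genotypes : GenotypeMatrix
    variants : pd.DataFrame
        Variant table for the genotype matrix.
    samples : pd.DataFrame
        Covariate table (age, sex, sample_age).
    thresholds : Thresholds
    assay_id, target_chrom, target_tss
        Assay identity and target annotation for cis/trans classification.
    """

    def __init__(self, levels: pd.Series, genotypes: GenotypeMatrix,
                 variants: pd.DataFrame, samples: pd.DataFrame,
                 thresholds: Optional[Thresholds] = None,
                 assay_id: str = "", target_id: str = "",
                 target_chrom: Optional[str] = None,
                 target_tss: Optional[int] = None):
        self.thresholds = thresholds or Thresholds()
        self.genotypes = genotypes
        self.variants = variants
        self.assay_id = assay_id
        self.target_id = target_id
        self.target_chrom = target_chrom
        self.target_tss = target_tss
        self.phenotype = prepare_phenotype(levels, samples)

    @classmethod
    def from_cohort(cls, cohort, assay_id: str,
                    thresholds: Optional[Thresholds] = None) -> "ProteinGwas":
        from .concordance import first_measurements

        panel = cohort.panel.set_index("assay_id")
        row = panel.loc[assay_id]
        matrix = cohort.protein_matrices[row["platform"]]
        firsts = first_measurements(matrix[matrix["assay_id"] == assay_id])
        levels = firsts.set_index("donor_id")["level"]
        return cls(levels, cohort.genotypes, cohort.variants, cohort.samples,
                   thresholds, assay_id=assay_id,
                   target_id=row["target_id"],
                   target_chrom=row["target_chrom"],
                   target_tss=int(row["target_tss"]))

    def fit(self) -> "PqtlResults":
        th = self.thresholds
        marginal = gwas_scan(self.phenotype, self.genotypes, th,
                             assay_id=self.assay_id)
        marginal = marginal.merge(
            self.variants[["variant_id", "chrom", "pos"]], on="variant_id")
        candidates = marginal[marginal["p"] < th.candidate_p]
        signal_rows = []
        for chrom, group in candidates.groupby("chrom"):
            chain = stepwise_conditional(
                self.phenotype, self.genotypes,
                list(group["variant_id"]), self.variants, th,
                assay_id=self.assay_id)
            if not chain:
                continue
            joint = joint_model(self.phenotype, self.genotypes,
                                [r.variant_id for r in chain], th,
                                assay_id=self.assay_id) \
                .set_index("variant_id")
            marg = marginal.set_index("variant_id")
            for order, res in enumerate(chain):
                m = marg.loc[res.variant_id]
                j = joint.loc[res.variant_id]
                signal_rows.append({
                    "assay_id": self.assay_id, "target_id": self.target_id,
                    "variant_id": res.variant_id, "chrom": chrom,
                    "pos": int(m["pos"]),
                    "discovery_order": order,
                    "beta_marginal": float(m["beta"]),
                    "se_marginal": float(m["se"]),
                    "p_marginal": float(m["p"]),
                    "beta_cond": res.beta, "se_cond": res.se,
                    "p_cond": res.p,
                    "beta_joint": float(j["beta_joint"]),
                    "se_joint": float(j["se_joint"]),
                    "p_joint": float(j["p_joint"]),
                    "joint_significant": bool(j["joint_significant"]),
                    "n": res.n,
                })
        signals = pd.DataFrame(signal_rows)
        if len(signals):
            signals = merge_regions(signals, th)
            signals["cis_trans"] = [
                classify_cis_trans(c, p, self.target_chrom, self.target_tss,
                                   th)
                for c, p in zip(signals["chrom"], signals["pos"])]
        else:
            signals = pd.DataFrame(columns=[
                "assay_id", "target_id", "variant_id", "chrom", "pos",
                "discovery_order", "beta_marginal", "se_marginal",
                "p_marginal", "beta_cond", "se_cond", "p_cond", "beta_joint",
                "se_joint", "p_joint", "joint_significant", "n", "region_id",
                "rank", "cis_trans"])
        return PqtlResults(model=self, marginal=marginal, signals=signals)


@dataclass
class PqtlResults:
    """Fitted pQTL results for one assay.

    ``marginal`` holds the genome-wide scan; ``signals`` the conditionally
    independent signals with marginal, conditional-at-selection and joint
    statistics, region ids, sentinel/secondary ranks and cis/trans class.
    """

    model: ProteinGwas
    marginal: pd.DataFrame
    signals: pd.DataFrame

    @property
    def sentinels(self) -> pd.DataFrame:
        return self.signals[self.signals["rank"] == 1]

    @property
    def n_signals(self) -> int:
        return len(self.signals)

    def summary(self) -> str:
        th = self.model.thresholds
        lines = [
            f"pQTL scan: assay {self.model.assay_id} "
            f"(target {self.model.target_id})",
            f"  donors: {len(self.model.phenotype)}   variants tested: "
            f"{len(self.marginal)}",
            f"  genome-wide threshold: {th.genomewide_p:g}   "
            f"candidate threshold: {th.candidate_p:g}",
            f"  signals: {self.n_signals} "
            f"({(self.signals['cis_trans'] == 'cis').sum()} cis, "
            f"{(self.signals['cis_trans'] == 'trans').sum()} trans)",
        ]
        if self.n_signals:
            cols = ["variant_id", "chrom", "pos", "rank", "cis_trans",
                    "beta_joint", "se_joint", "p_joint"]
            lines.append(self.signals[cols].to_string(index=False))
        return "\n".join(lines)


def map_platform_pqtls(cohort, platform: str,
                       thresholds: Optional[Thresholds] = None,
                       assay_ids: Optional[Sequence[str]] = None
                       ) -> pd.DataFrame:
    """Fit :class:`ProteinGwas` for every assay on a platform and stack
    the signal tables (adds the platform column)."""
    thresholds = thresholds or Thresholds()
    panel = cohort.panel[cohort.panel["platform"] == platform]
    if assay_ids is not None:
        panel = panel[panel["assay_id"].isin(assay_ids)]
    tables = []
    for assay_id in panel["assay_id"]:
        res = ProteinGwas.from_cohort(cohort, assay_id, thresholds).fit()
        if len(res.signals):
            tables.append(res.signals)
    if not tables:
        return pd.DataFrame()
    out = pd.concat(tables, ignore_index=True)
    out["platform"] = platform
    return out
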