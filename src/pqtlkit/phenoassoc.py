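"""Protein-phenotype association scans with Bonferroni control.

Binary phenotypes are fitted by logistic regression (effect reported as an
odds ratio per s.d. of RINT-standardized protein level) and quantitative
traits by linear regression after inverse-normal transforming the outcome;
both adjust for sex and age (sample age optionally).  Significance is
controlled family-wise by Bonferroni over the number of assays on the
platform.  Binary phenotypes require more than 50 diagnosed individuals to
enter the scan; logistic fits that fail to converge or separate are
returned as flagged records rather than raising.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .concordance import first_measurements
from .gwas import rint

__all__ = [
    "MIN_CASES",
    "bonferroni_threshold",
    "protein_pheno_scan",
]

MIN_CASES = 50


def bonferroni_threshold(fwer: float, n_assays: int) -> float:
    """Per-test threshold controlling the family-wise error over assays."""
    if not (0.0 < fwer < 1.0):
        raise ValueError("fwer must lie in (0,1)")
    if n_assays < 1:
        raise ValueError("n_assays must be >= 1")
    return fwer / n_assays


def _is_binary(values: pd.Series) -> bool:
    uniq = set(pd.unique(values.dropna()))
    return uniq <= {0, 1, 0.0, 1.0, True, False}


def _fit_binary(y: np.ndarray, x: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, x)
        try:
            fit = model.fit(disp=0, maxiter=100)
        except Exception as exc:  # separation raises in some versions
            return None, f"logistic fit failed: {type(exc).__name__}"
    fitted = fit.predict(x)
    if np.any(fitted < 1e-10) or np.any(fitted > 1 - 1e-10):
        return None, "separation (fitted probabilities pinned to 0/1)"
    if not fit.mle_retvals.get("converged", True):
        return None, "logistic fit did not converge"
    return fit, ""


def protein_pheno_scan(matrix: pd.DataFrame, phenotypes: pd.DataFrame,
                       samples: pd.DataFrame,
                       fwer: float = 0.05,
                       n_assays: Optional[int] = None,
                       use_sample_age: bool = False) -> pd.DataFrame:
    """Scan every (assay, phenotype) pair.

    ``matrix`` is a long protein matrix for one platform; ``phenotypes``
    has donor_id plus one column per phenotype (binary 0/1 or
    quantitative).  Returns one record per tested pair with estimate
    (odds ratio per s.d. for binary, beta per s.d. for quantitative), se on
    the log-odds/beta scale, p, n (and case count), a Bonferroni
    significance flag, and a reason string for skipped or failed fits.
    """
    firsts = first_measurements(matrix)
    wide = firsts.pivot(index="donor_id", columns="assay_id", values="level")
    assay_ids = list(wide.columns)
    if n_assays is None:
        n_assays = len(assay_ids)
    threshold = bonferroni_threshold(fwer, n_assays)

    cov = samples.set_index("donor_id")
    cov_frame = pd.DataFrame({
        "age": cov["age"].astype(float),
        "sex": pd.Categorical(cov["sex"]).codes.astype(float),
    }, index=cov.index)
    if use_sample_age and "sample_age" in cov:
        cov_frame["sample_age"] = cov["sample_age"].astype(float)

    pheno = phenotypes.set_index("donor_id")
    records = []
    for pheno_name in pheno.columns:
        y_all = pheno[pheno_name]
        binary = _is_binary(y_all)
        if binary and int(y_all.sum()) <= MIN_CASES:
            records.append({
                "assay_id": pd.NA, "phenotype": pheno_name,
                "type": "binary", "estimate": np.nan, "se": np.nan,
                "p": np.nan, "n": 0, "n_cases": int(y_all.sum()),
                "significant": False,
                "reason": f"fewer than {MIN_CASES + 1} cases; excluded",
            })
            continue
        for assay_id in assay_ids:
            levels = wide[assay_id]
            donors = levels.dropna().index \
                .intersection(y_all.dropna().index) \
                .intersection(cov_frame.dropna().index)
            y = y_all.loc[donors].to_numpy(dtype=float)
            z = rint(levels.loc[donors].to_numpy())
            z = z / z.std(ddof=0)  # unit s.d. by construction
            x = np.column_stack([np.ones(len(donors)), z,
                                 cov_frame.loc[donors].to_numpy()])
            record = {
                "assay_id": assay_id, "phenotype": pheno_name,
                "type": "binary" if binary else "quantitative",
                "n": len(donors),
                "n_cases": int(y.sum()) if binary else pd.NA,
                "reason": "",
            }
            if binary:
                fit, reason = _fit_binary(y, x)
                if fit is None:
                    record.update(estimate=np.nan, se=np.nan, p=np.nan,
                                  significant=False, reason=reason)
                    records.append(record)
                    continue
                record.update(
                    estimate=float(np.exp(fit.params[1])),  # OR per s.d.
                    se=float(fit.bse[1]), p=float(fit.pvalues[1]))
            else:
                fit = sm.OLS(rint(y), x).fit()
                record.update(estimate=float(fit.params[1]),
                              se=float(fit.bse[1]),
                              p=float(fit.pvalues[1]))
            record["significant"] = bool(record["p"] < threshold)
            records.append(record)
    return pd.DataFrame(records)
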