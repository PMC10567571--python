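"""Independent reference implementations used only to check the package.

Each oracle is written as plainly as possible (explicit loops, statsmodels
fits) and shares no code with the implementation it verifies.
"""

import numpy as np
import statsmodels.api as sm
from scipy import stats


def forward_selection_oracle(y, dosages, variant_ids, positions,
                             candidate_p, genomewide_p):
    """Brute-force greedy forward selection with the two-threshold rule.

    At each round, fit one OLS per remaining candidate conditional on the
    selected set, take the smallest likelihood-ratio p (ties: position,
    then id) and select it iff p < genomewide_p.  Returns the ordered list
    of (variant_id, beta, se, p).
    """
    y = np.asarray(y, float)
    n = len(y)
    order = sorted(range(len(variant_ids)),
                   key=lambda i: (positions[i], variant_ids[i]))
    # the marginal filter defines the candidate set
    candidates = []
    for i in order:
        x = sm.add_constant(dosages[:, i])
        fit = sm.OLS(y, x).fit()
        rss1 = float(fit.ssr)
        rss0 = float(np.sum((y - y.mean()) ** 2))
        p = stats.chi2.sf(n * np.log(rss0 / rss1), 1) if rss1 > 0 else 0.0
        if p < candidate_p:
            candidates.append(i)

    selected = []
    while candidates:
        best = None
        for i in candidates:
            cols = [dosages[:, j] for _, j in selected] + [dosages[:, i]]
            x1 = sm.add_constant(np.column_stack(cols))
            if np.linalg.matrix_rank(x1) < x1.shape[1]:
                continue
            fit1 = sm.OLS(y, x1).fit()
            if selected:
                x0 = sm.add_constant(
                    np.column_stack([dosages[:, j] for _, j in selected]))
                rss0 = float(sm.OLS(y, x0).fit().ssr)
            else:
                rss0 = float(np.sum((y - y.mean()) ** 2))
            rss1 = float(fit1.ssr)
            p = stats.chi2.sf(n * np.log(max(rss0, rss1) / rss1), 1) \
                if rss1 > 0 else 0.0
            if best is None or p < best[0]:
                best = (p, i, float(fit1.params[-1]), float(fit1.bse[-1]))
        if best is None or not (best[0] < genomewide_p):
            break
        p, i, beta, se = best
        selected.append(((variant_ids[i], beta, se, p), i))
        candidates = [c for c in candidates if c != i]
    return [rec for rec, _ in selected]


def single_linkage_regions_oracle(positions, max_gap):
    """Brute-force transitive closure of |pos_i - pos_j| <= max_gap."""
    m = len(positions)
    parent = list(range(m))

    def find(a):
        while parent[a] != a:
            a = parent[a]
        return a

    for i in range(m):
        for j in range(i + 1, m):
            if abs(positions[i] - positions[j]) <= max_gap:
                parent[find(i)] = find(j)
    labels = [find(i) for i in range(m)]
    relabel = {}
    return [relabel.setdefault(l, len(relabel)) for l in labels]


def ld_closure_clusters_oracle(dosages, r2_cut):
    """Transitive closure of pairwise r^2 > r2_cut over signal dosages."""
    m = dosages.shape[1]
    parent = list(range(m))

    def find(a):
        while parent[a] != a:
            a = parent[a]
        return a

    for i in range(m):
        for j in range(i + 1, m):
            r = np.corrcoef(dosages[:, i], dosages[:, j])[0, 1]
            if r * r > r2_cut:
                parent[find(i)] = find(j)
    labels = [find(i) for i in range(m)]
    relabel = {}
    return [relabel.setdefault(l, len(relabel)) for l in labels]
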