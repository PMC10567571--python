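"""Published summary counts from large-scale two-platform plasma pQTL
studies, used as arithmetic cross-checks.

These are inputs, not results: each entry is a (numerator, denominator)
count pair whose printed percentage the package's fraction arithmetic must
reproduce, plus the platform assay totals behind the published Bonferroni
thresholds.  Platform "A" denotes the antibody-based platform, "B" the
aptamer-based platform.
"""

from __future__ import annotations

__all__ = [
    "ASSAY_COUNTS",
    "CORRESPONDENCE_COUNTS",
    "SECONDARY_SIGNAL_COUNTS",
    "POWER_EXAMPLE",
]

# assays per platform entering the Bonferroni adjustment
ASSAY_COUNTS = {"A": 2941, "B": 4907}

# sentinel signals on one platform with a corresponding (r2 > 0.8, within
# 5 Mb, same target) signal on the other: (matched, total, printed %)
CORRESPONDENCE_COUNTS = {
    "cis_a_to_b": (581, 1468, 40),
    "cis_a_to_b_sentinel": (434, 1468, 30),
    "cis_b_to_a": (559, 1164, 48),
    "cis_b_to_a_sentinel": (449, 1164, 39),
    "trans_a_to_b": (1855, 18578, 10),
    "trans_b_to_a": (1918, 10352, 19),
}

# sentinel signals with at least one secondary signal: (with, total, %)
SECONDARY_SIGNAL_COUNTS = {
    "cis_a": (1702, 2102, 81),
    "cis_b": (1594, 2120, 75),
    "trans_a": (3340, 24824, 13),
    "trans_b": (4065, 22616, 18),
}

# a representative large-cohort power evaluation point
POWER_EXAMPLE = {"p_threshold": 1.8e-9, "n": 35_000, "beta": 0.1, "f": 0.3}
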