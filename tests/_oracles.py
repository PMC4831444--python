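"""Independent oracles used by the test suite.

The Weir-Cockerham oracle below goes through the classical nested-ANOVA
mean-squares route (sums of squares over allele indicators -> MSP/MSI/MSG
-> moment estimators of the variance components), a different derivation
path from the package's direct component formulas, so agreement between the
two is a genuine cross-check.
"""
from __future__ import annotations

import numpy as np

MISSING = -1


def wc_fst_anova_oracle(dosages_by_group: list[list[int]]) -> tuple[float, float, float, float]:
    """Brute-force W&C variance components for one biallelic locus.

    Parameters: per-group lists of diploid dosages (0/1/2, no missing).
    Returns (sigma2_P, sigma2_I, sigma2_G, theta); theta is NaN when the
    total variance is zero.
    """
    groups = [np.asarray(g, dtype=float) for g in dosages_by_group if len(g) >= 2]
    r = len(groups)
    if r < 2:
        return (np.nan,) * 4
    n_g = np.array([len(g) for g in groups], dtype=float)
    n_tot = n_g.sum()
    p_g = np.array([g.sum() / (2 * len(g)) for g in groups])
    p_bar = (n_g * p_g).sum() / n_tot

    # sums of squares over the 2*n allele indicators, nested: alleles within
    # individuals within groups
    ss_within_ind = sum(float((g == 1).sum()) * 0.5 for g in groups)
    ss_ind = sum(
        float((2 * (g / 2 - p) ** 2).sum()) for g, p in zip(groups, p_g)
    )
    ss_group = float((2 * n_g * (p_g - p_bar) ** 2).sum())

    msg = ss_within_ind / n_tot                     # df = n (one per individual)
    msi = ss_ind / (n_tot - r)
    msp = ss_group / (r - 1)
    nc = (n_tot - (n_g ** 2).sum() / n_tot) / (r - 1)

    s2_g = msg
    s2_i = (msi - msg) / 2.0
    s2_p = (msp - msi) / (2.0 * nc)
    tot = s2_p + s2_i + s2_g
    theta = s2_p / tot if tot != 0 else np.nan
    return s2_p, s2_i, s2_g, theta


def enumerate_two_group_configs(max_n: int = 6):
    """Yield every 2-group dosage configuration with 2..max_n individuals
    total and >= 2 per group (genotypes exhaustive over {0,1,2})."""
    import itertools

    for n in range(4, max_n + 1):
        for n1 in range(2, n - 1):
            n2 = n - n1
            for geno in itertools.product((0, 1, 2), repeat=n):
                yield list(geno[:n1]), list(geno[n1:n1 + n2])


def additive_four_taxon_matrix(
    a: float, b: float, c: float, d: float, internal: float
) -> np.ndarray:
    """Distances for the unrooted tree ((A:a,B:b):internal,(C:c,D:d))."""
    return np.array(
        [
            [0, a + b, a + internal + c, a + internal + d],
            [a + b, 0, b + internal + c, b + internal + d],
            [a + internal + c, b + internal + c, 0, c + d],
            [a + internal + d, b + internal + d, c + d, 0],
        ],
        dtype=float,
    )
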