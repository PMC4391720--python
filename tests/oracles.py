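"""Independent brute-force oracles used to validate the implementation.

These are deliberately written as direct, slow translations of the
published definitions (explicit loops, exact integer arithmetic where
possible) and share no code with the package.
"""

from __future__ import annotations

import itertools
import math


def pairwise_diff(seq_a: str, seq_b: str) -> int:
    """Differences over sites where both residues are A/C/G/T."""
    valid = set("ACGT")
    return sum(
        1
        for x, y in zip(seq_a, seq_b)
        if x in valid and y in valid and x != y
    )


def pi_locus_oracle(seqs: list[str]) -> float:
    n = len(seqs)
    total = sum(
        pairwise_diff(seqs[i], seqs[j])
        for i in range(n - 1)
        for j in range(i + 1, n)
    )
    return total / (n * (n - 1) / 2)


def segregating_sites_oracle(seqs: list[str]) -> int:
    valid = set("ACGT")
    S = 0
    for col in zip(*seqs):
        states = {c for c in col if c in valid}
        if len(states) > 1:
            S += 1
    return S


def tajimas_d_oracle(seqs: list[str]) -> float:
    """Direct-formula Tajima's D (published 1989 constants, written out)."""
    n = len(seqs)
    S = segregating_sites_oracle(seqs)
    if S == 0:
        return math.nan
    pi = pi_locus_oracle(seqs)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def stirling_unsigned(n: int, k: int) -> int:
    """Exact unsigned Stirling numbers of the first kind (integer recurrence)."""
    if n == 0:
        return 1 if k == 0 else 0
    if k == 0:
        return 0
    return (n - 1) * stirling_unsigned(n - 1, k) + stirling_unsigned(n - 1, k - 1)


def fus_fs_oracle(seqs: list[str]) -> float:
    """Exact Ewens-formula Fu's Fs using integer Stirling numbers (n <= 8)."""
    n = len(seqs)
    assert n <= 8, "exact oracle is for small n"
    theta = pi_locus_oracle(seqs)
    if theta <= 0:
        return math.nan
    k_obs = len(set(seqs))
    denom = 1.0
    for i in range(n):
        denom *= theta + i
    probs = [stirling_unsigned(n, k) * theta**k / denom for k in range(1, n + 1)]
    s_prime = sum(probs[k_obs - 1 :])
    s_minus = sum(probs[: k_obs - 1])
    if s_minus <= 0:
        return math.nan
    return math.log(s_prime / s_minus)


def phist_oracle(seqs_a: list[str], seqs_b: list[str]) -> float:
    """One-level AMOVA ΦST for two populations, from sums of squares."""
    seqs = seqs_a + seqs_b
    na, nb = len(seqs_a), len(seqs_b)
    N = na + nb

    def ssd(index_groups):
        out = 0.0
        for grp in index_groups:
            sub = 0.0
            for i, gi in enumerate(grp):
                for gj in grp[i + 1 :]:
                    sub += pairwise_diff(seqs[gi], seqs[gj])
            out += sub / len(grp)
        return out

    ssd_total = ssd([list(range(N))])
    ssd_wp = ssd([list(range(na)), list(range(na, N))])
    ssd_ap = ssd_total - ssd_wp
    sigma_w = ssd_wp / (N - 2)
    n_c = (N - (na**2 + nb**2) / N) / 1
    sigma_a = (ssd_ap / 1 - sigma_w) / n_c
    if sigma_a + sigma_w == 0:
        return math.nan
    return sigma_a / (sigma_a + sigma_w)


def amova_oracle(
    seqs: list[str], pops: list[str], regions_of: dict[str, str]
) -> dict[str, float]:
    """Three-level AMOVA variance fractions from sums-of-squares definitions."""
    N = len(seqs)
    pop_labels = sorted(set(pops))
    region_labels = sorted({regions_of[p] for p in pop_labels})
    pop_idx = {p: [i for i, q in enumerate(pops) if q == p] for p in pop_labels}
    reg_idx = {
        r: [i for i, q in enumerate(pops) if regions_of[q] == r]
        for r in region_labels
    }

    def ssd(groups):
        out = 0.0
        for grp in groups:
            sub = 0.0
            for a, i in enumerate(grp):
                for j in grp[a + 1 :]:
                    sub += pairwise_diff(seqs[i], seqs[j])
            out += sub / len(grp)
        return out

    ssd_total = ssd([list(range(N))])
    ssd_wp = ssd(list(pop_idx.values()))
    ssd_wg = ssd(list(reg_idx.values()))
    ssd_ap = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg

    P, G = len(pop_labels), len(region_labels)
    df_wp, df_ap, df_ag = N - P, P - G, G - 1
    msd_wp = ssd_wp / df_wp
    msd_ap = ssd_ap / df_ap
    msd_ag = ssd_ag / df_ag

    sum_n2_over_ng = sum(
        sum(len(pop_idx[p]) ** 2 for p in pop_labels if regions_of[p] == r)
        / len(reg_idx[r])
        for r in region_labels
    )
    sum_n2_over_n = sum(len(v) ** 2 for v in pop_idx.values()) / N
    n_coef = (N - sum_n2_over_ng) / df_ap
    np_coef = (sum_n2_over_ng - sum_n2_over_n) / df_ag
    npp_coef = (N - sum(len(v) ** 2 for v in reg_idx.values()) / N) / df_ag

    sigma_c = msd_wp
    sigma_b = (msd_ap - sigma_c) / n_coef
    sigma_a = (msd_ag - sigma_c - np_coef * sigma_b) / npp_coef
    total = sigma_a + sigma_b + sigma_c
    return {
        "among_regions": sigma_a / total,
        "among_populations_within_regions": sigma_b / total,
        "within_populations": sigma_c / total,
    }


def mantel_exact_p(mat_a, mat_b) -> float:
    """Exact Mantel p by enumerating every permutation (small orders only)."""
    import numpy as np

    A = np.asarray(mat_a, float)
    B = np.asarray(mat_b, float)
    k = A.shape[0]
    iu = [(i, j) for i in range(k - 1) for j in range(i + 1, k)]

    def corr(perm):
        a = [A[i, j] for i, j in iu]
        b = [B[perm[i], perm[j]] for i, j in iu]
        return np.corrcoef(a, b)[0, 1]

    r_obs = corr(tuple(range(k)))
    hits = 0
    total = 0
    for perm in itertools.permutations(range(k)):
        total += 1
        if corr(perm) >= r_obs - 1e-12:
            hits += 1
    return hits / total
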