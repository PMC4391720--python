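"""Sequence-based population-genetic statistics.

Diversity indices (S, H, Hd, π), neutrality tests (Tajima's D, Fu's Fs),
mismatch distributions with Harpending's raggedness, pairwise ΦST and
hierarchical AMOVA (Excoffier-style variance components on pairwise
nucleotide distances), Nei's net divergence D_A, and Mantel matrix
correlation.

Missing data rule: sites with ``N`` or ``-`` in either member of a pair are
excluded from that pair's distance (complete-pair deletion per site pair).
Undefined statistics (e.g. Tajima's D with no segregating sites) are
returned as ``nan`` rather than raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Alignment, PopulationMap, collapse_haplotypes

__all__ = [
    "DiversityStats",
    "NeutralityStats",
    "MismatchResult",
    "StructureResult",
    "pairwise_differences",
    "diversity",
    "tajimas_d",
    "tajimas_d_from_counts",
    "fus_fs",
    "fus_fs_from_counts",
    "mismatch",
    "raggedness",
    "pairwise_phist",
    "amova",
    "nei_da",
    "mantel",
    "population_summary",
]

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 255, "N": 255}


def _encode(aln: Alignment) -> np.ndarray:
    """(n, L) uint8 matrix; 255 marks missing (N or gap)."""
    lut = np.full(128, 255, dtype=np.uint8)
    for base, code in _ENC.items():
        lut[ord(base)] = code
    rows = [
        lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        for _, seq in aln.sequences
    ]
    return np.vstack(rows)


def pairwise_differences(aln: Alignment) -> np.ndarray:
    """Symmetric (n, n) matrix of pairwise nucleotide differences.

    Sites missing (N/gap) in either sequence of a pair are skipped for that
    pair.
    """
    X = _encode(aln)
    valid = X != 255
    n = X.shape[0]
    D = np.zeros((n, n), dtype=float)
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        diff = (X[i] != X[i + 1 :]) & both
        d = diff.sum(axis=1).astype(float)
        D[i, i + 1 :] = d
        D[i + 1 :, i] = d
    return D


def _segregating_sites(aln: Alignment) -> int:
    X = _encode(aln)
    S = 0
    for j in range(X.shape[1]):
        col = X[:, j]
        states = set(col[col != 255].tolist())
        if len(states) > 1:
            S += 1
    return S


@dataclass
class DiversityStats:
    n: int
    S: int
    H: int
    Hd: float
    pi_site: float
    pi_locus: float


@dataclass
class NeutralityStats:
    tajima_D: float  # nan when undefined (S = 0)
    fu_Fs: float  # nan when undefined (no pairwise differences)


@dataclass
class MismatchResult:
    counts: np.ndarray  # frequency of difference classes 0..d
    raggedness_r: float


@dataclass
class StructureResult:
    labels: list[str] = field(default_factory=list)
    phi_st_matrix: np.ndarray | None = None
    p_values: np.ndarray | None = None
    amova_components: dict[str, float] | None = None
    amova_table: pd.DataFrame | None = None
    d_a_matrix: np.ndarray | None = None


def diversity(aln: Alignment, popmap: PopulationMap | None = None) -> DiversityStats:
    """Diversity indices: segregating sites, haplotypes, Hd, π.

    ``pi_locus`` is the mean number of pairwise differences; ``pi_site``
    divides by the alignment length.  ``Hd = n/(n−1)·(1 − Σ p_k²)``.
    """
    n = aln.n
    if n < 2:
        raise ValueError("diversity requires at least 2 sequences")
    if popmap is None:
        popmap = PopulationMap({sid: ("all", "all") for sid in aln.sample_ids})
    table = collapse_haplotypes(aln, popmap)
    freqs = table.frequencies()
    hd = n / (n - 1) * (1.0 - sum(p * p for p in freqs))
    D = pairwise_differences(aln)
    iu = np.triu_indices(n, k=1)
    pi_locus = float(D[iu].mean())
    return DiversityStats(
        n=n,
        S=_segregating_sites(aln),
        H=table.n_haplotypes,
        Hd=hd,
        pi_site=pi_locus / aln.length,
        pi_locus=pi_locus,
    )


def _tajima_constants(n: int) -> tuple[float, float]:
    """(a1, denominator pieces e1, e2) per Tajima 1989."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / (i * i) for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return a1, e1, e2


def tajimas_d_from_counts(n: int, S: int, pi_locus: float) -> float:
    """Tajima's D from sample size, segregating sites and mean differences.

    Returns ``nan`` when S = 0 (the statistic is undefined).
    """
    if n < 2:
        raise ValueError("Tajima's D requires n >= 2")
    if S == 0:
        return math.nan
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    return (pi_locus - S / a1) / math.sqrt(var)


def tajimas_d(aln: Alignment) -> float:
    """Tajima's D for one alignment (nan when no segregating sites)."""
    n = aln.n
    S = _segregating_sites(aln)
    if S == 0:
        return math.nan
    D = pairwise_differences(aln)
    iu = np.triu_indices(n, k=1)
    return tajimas_d_from_counts(n, S, float(D[iu].mean()))


def _log_stirling_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned first-kind Stirling numbers).

    Log-space recurrence |s(n+1,k)| = n·|s(n,k)| + |s(n,k−1)|; stable for
    n well beyond the sample sizes used here (overflow-free where integer
    arithmetic fails above n ≈ 130).
    """
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |s(0,0)| = 1
    for m in range(n):
        new = np.full(n + 1, -np.inf)
        # |s(m+1,k)| = m*|s(m,k)| + |s(m,k-1)|
        with np.errstate(invalid="ignore"):
            shifted = np.concatenate(([-np.inf], row[:-1]))
            grown = row + (math.log(m) if m > 0 else -np.inf)
            new = np.logaddexp(grown, shifted)
        row = new
    return row


def fus_fs_from_counts(n: int, k_obs: int, theta: float) -> float:
    """Fu's Fs from sample size, haplotype count and θ̂ (mean differences).

    ``S' = Pr(K ≥ k_obs)`` under the Ewens sampling formula with θ̂;
    ``Fs = ln(S'/(1−S'))``.  Returns ``nan`` when θ̂ = 0 or when S' is
    numerically 0 or 1.
    """
    if n < 2:
        raise ValueError("Fu's Fs requires n >= 2")
    if theta <= 0.0:
        return math.nan
    log_s = _log_stirling_row(n)
    log_theta = math.log(theta)
    log_denom = sum(math.log(theta + i) for i in range(n))
    log_pk = log_s[1 : n + 1] + np.arange(1, n + 1) * log_theta - log_denom
    # normalise defensively against rounding
    log_pk -= _logsumexp(log_pk)
    log_sp = _logsumexp(log_pk[k_obs - 1 :])  # Pr(K >= k_obs)
    log_sm = _logsumexp(log_pk[: k_obs - 1]) if k_obs > 1 else -np.inf
    if not np.isfinite(log_sm):  # S' = 1: K >= 1 always
        return math.nan
    return float(log_sp - log_sm)


def _logsumexp(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    m = np.max(x)
    if not np.isfinite(m):
        return float(m)
    return float(m + math.log(np.exp(x - m).sum()))


def fus_fs(aln: Alignment) -> float:
    """Fu's Fs for one alignment (nan when all sequences are identical)."""
    n = aln.n
    D = pairwise_differences(aln)
    iu = np.triu_indices(n, k=1)
    theta = float(D[iu].mean())
    popmap = PopulationMap({sid: ("all", "all") for sid in aln.sample_ids})
    k_obs = collapse_haplotypes(aln, popmap).n_haplotypes
    return fus_fs_from_counts(n, k_obs, theta)


def raggedness(counts: np.ndarray) -> float:
    """Harpending's raggedness r = Σ_{i=1}^{d+1} (x_i − x_{i−1})².

    ``counts`` are frequencies of difference classes 0..d; x are relative
    frequencies with x_{d+1} = 0.
    """
    counts = np.asarray(counts, dtype=float)
    x = counts / counts.sum()
    x = np.concatenate([x, [0.0]])
    return float(np.sum(np.diff(x) ** 2))


def mismatch(aln: Alignment) -> MismatchResult:
    """Mismatch distribution: histogram of pairwise differences + raggedness."""
    D = pairwise_differences(aln)
    iu = np.triu_indices(aln.n, k=1)
    diffs = np.rint(D[iu]).astype(int)
    d_max = int(diffs.max()) if diffs.size else 0
    counts = np.bincount(diffs, minlength=d_max + 1)
    return MismatchResult(counts=counts, raggedness_r=raggedness(counts))


# ---------------------------------------------------------------------------
# AMOVA machinery (Excoffier, Smouse & Quattro 1992 sums of squares)
# ---------------------------------------------------------------------------


def _ssd_within(D: np.ndarray, groups: list[np.ndarray]) -> float:
    """Σ over groups of (1/n_g)·Σ_{i<j in g} d_ij."""
    total = 0.0
    for idx in groups:
        if len(idx) < 2:
            continue
        sub = D[np.ix_(idx, idx)]
        total += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return total


def _ssd_total(D: np.ndarray) -> float:
    n = D.shape[0]
    return D[np.triu_indices(n, k=1)].sum() / n


def _one_level_components(
    D: np.ndarray, groups: list[np.ndarray]
) -> tuple[float, float]:
    """(σ_a², σ_w²) for a one-level AMOVA over the given groups.

    Only samples inside ``groups`` enter the analysis (the distance matrix
    may cover more samples, e.g. other populations in a pairwise ΦST).
    """
    sizes = np.array([len(g) for g in groups], dtype=float)
    N = sizes.sum()
    P = len(groups)
    pooled = np.concatenate([np.asarray(g) for g in groups])
    ssd_wp = _ssd_within(D, groups)
    ssd_ap = _ssd_total(D[np.ix_(pooled, pooled)]) - ssd_wp
    df_wp = N - P
    df_ap = P - 1
    sigma_w = ssd_wp / df_wp if df_wp > 0 else math.nan
    n_c = (N - (sizes**2).sum() / N) / df_ap
    msd_ap = ssd_ap / df_ap
    sigma_a = (msd_ap - sigma_w) / n_c
    return sigma_a, sigma_w


def _phist_from_groups(D: np.ndarray, groups: list[np.ndarray]) -> float:
    sigma_a, sigma_w = _one_level_components(D, groups)
    denom = sigma_a + sigma_w
    if denom == 0.0:
        return math.nan
    return sigma_a / denom


def pairwise_phist(
    aln: Alignment,
    popmap: PopulationMap,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    level: str = "population",
) -> StructureResult:
    """Pairwise ΦST with permutation p-values.

    For each population pair a one-level AMOVA on pairwise nucleotide
    distances gives ΦST = σ_a²/(σ_a²+σ_w²); p is the fraction of label
    permutations with ΦST at least as large as observed.  Negative ΦST
    values are reported as computed.  Pairs where either population has
    fewer than 2 sequences are ``nan``.
    """
    if rng is None:
        rng = np.random.default_rng()
    popmap.check_covers(aln)
    D = pairwise_differences(aln)
    groups = popmap.grouped(aln, level)
    labels = [lab for lab in groups if groups[lab]]
    id_index = {sid: i for i, sid in enumerate(aln.sample_ids)}
    idx = {lab: np.array([id_index[s] for s in groups[lab]]) for lab in labels}
    P = len(labels)
    phi = np.zeros((P, P))
    pvals = np.full((P, P), math.nan)
    np.fill_diagonal(pvals, math.nan)
    for a in range(P - 1):
        for b in range(a + 1, P):
            ia, ib = idx[labels[a]], idx[labels[b]]
            if len(ia) < 2 or len(ib) < 2:
                phi[a, b] = phi[b, a] = math.nan
                continue
            obs = _phist_from_groups(D, [ia, ib])
            phi[a, b] = phi[b, a] = obs
            pooled = np.concatenate([ia, ib])
            hits = 1  # observed counts as one permutation
            for _ in range(n_perm):
                perm = rng.permutation(pooled)
                pa, pb = perm[: len(ia)], perm[len(ia) :]
                val = _phist_from_groups(D, [pa, pb])
                if not math.isnan(val) and val >= obs - 1e-12:
                    hits += 1
            p = hits / (n_perm + 1)
            pvals[a, b] = pvals[b, a] = p
    return StructureResult(labels=labels, phi_st_matrix=phi, p_values=pvals)


def amova(aln: Alignment, popmap: PopulationMap) -> StructureResult:
    """Hierarchical AMOVA: among regions / among populations within regions /
    within populations.

    Returns variance components, fixation indices and percentage-of-variation
    fractions (summing to 1).  With a single region the analysis reduces to a
    one-level AMOVA over populations.
    """
    popmap.check_covers(aln)
    D = pairwise_differences(aln)
    id_index = {sid: i for i, sid in enumerate(aln.sample_ids)}
    pops = popmap.grouped(aln, "population")
    pop_labels = [p for p in pops if pops[p]]
    pop_idx = [np.array([id_index[s] for s in pops[p]]) for p in pop_labels]
    region_of_pop = {p: popmap.population_to_region[p] for p in pop_labels}
    region_labels = [r for r in popmap.regions if any(region_of_pop[p] == r for p in pop_labels)]

    if len(region_labels) < 2:
        sigma_a, sigma_w = _one_level_components(D, pop_idx)
        total = sigma_a + sigma_w
        comps = {
            "among_regions": 0.0,
            "among_populations_within_regions": sigma_a / total,
            "within_populations": sigma_w / total,
        }
        return StructureResult(labels=pop_labels, amova_components=comps)

    sizes = np.array([len(g) for g in pop_idx], dtype=float)
    N = sizes.sum()
    P = len(pop_idx)
    G = len(region_labels)
    region_groups = {
        r: np.concatenate(
            [pop_idx[i] for i, p in enumerate(pop_labels) if region_of_pop[p] == r]
        )
        for r in region_labels
    }
    Ng = {r: float(len(region_groups[r])) for r in region_labels}

    ssd_total = _ssd_total(D)
    ssd_wp = _ssd_within(D, pop_idx)
    ssd_wg = _ssd_within(D, list(region_groups.values()))
    ssd_ap_wg = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg

    df_wp = N - P
    df_ap = P - G
    df_ag = G - 1
    msd_wp = ssd_wp / df_wp
    msd_ap = ssd_ap_wg / df_ap if df_ap > 0 else 0.0
    msd_ag = ssd_ag / df_ag

    sum_n2_over_Ng = sum(
        sum(len(pop_idx[i]) ** 2 for i, p in enumerate(pop_labels) if region_of_pop[p] == r)
        / Ng[r]
        for r in region_labels
    )
    sum_n2_over_N = (sizes**2).sum() / N
    n_coef = (N - sum_n2_over_Ng) / df_ap if df_ap > 0 else 0.0
    np_coef = (sum_n2_over_Ng - sum_n2_over_N) / df_ag
    npp_coef = (N - sum(Ng[r] ** 2 for r in region_labels) / N) / df_ag

    sigma_c = msd_wp
    sigma_b = (msd_ap - sigma_c) / n_coef if n_coef > 0 else 0.0
    sigma_a = (msd_ag - sigma_c - np_coef * sigma_b) / npp_coef
    total = sigma_a + sigma_b + sigma_c

    comps = {
        "among_regions": sigma_a / total,
        "among_populations_within_regions": sigma_b / total,
        "within_populations": sigma_c / total,
    }
    table = pd.DataFrame(
        {
            "source": [
                "among_regions",
                "among_populations_within_regions",
                "within_populations",
            ],
            "df": [df_ag, df_ap, df_wp],
            "ssd": [ssd_ag, ssd_ap_wg, ssd_wp],
            "variance": [sigma_a, sigma_b, sigma_c],
            "pct_variation": [
                100 * sigma_a / total,
                100 * sigma_b / total,
                100 * sigma_c / total,
            ],
        }
    )
    phi_st = (sigma_a + sigma_b) / total
    phi_ct = sigma_a / total
    phi_sc = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else math.nan
    comps_full = dict(comps)
    comps_full.update({"phi_ST": phi_st, "phi_CT": phi_ct, "phi_SC": phi_sc})
    return StructureResult(
        labels=pop_labels, amova_components=comps_full, amova_table=table
    )


def nei_da(
    aln: Alignment, popmap: PopulationMap, level: str = "population"
) -> tuple[list[str], np.ndarray]:
    """Nei's net divergence D_A(x,y) = π_xy − (π_x + π_y)/2 per locus."""
    popmap.check_covers(aln)
    D = pairwise_differences(aln)
    groups = popmap.grouped(aln, level)
    labels = [lab for lab in groups if groups[lab]]
    id_index = {sid: i for i, sid in enumerate(aln.sample_ids)}
    idx = {lab: np.array([id_index[s] for s in groups[lab]]) for lab in labels}

    def pi_within(ix: np.ndarray) -> float:
        if len(ix) < 2:
            return 0.0
        sub = D[np.ix_(ix, ix)]
        return float(sub[np.triu_indices(len(ix), k=1)].mean())

    def pi_between(ix: np.ndarray, iy: np.ndarray) -> float:
        return float(D[np.ix_(ix, iy)].mean())

    P = len(labels)
    out = np.zeros((P, P))
    for a in range(P - 1):
        for b in range(a + 1, P):
            ia, ib = idx[labels[a]], idx[labels[b]]
            da = pi_between(ia, ib) - (pi_within(ia) + pi_within(ib)) / 2.0
            out[a, b] = out[b, a] = da
    return labels, out


def mantel(
    mat_a: np.ndarray,
    mat_b: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the upper triangles; p is obtained by
    simultaneous row/column permutation of the second matrix (one-sided,
    r_perm ≥ r_obs).  Returns (nan, nan) if either triangle has zero
    variance.
    """
    A = np.asarray(mat_a, dtype=float)
    B = np.asarray(mat_b, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal order")
    if A.shape[0] < 4:
        raise ValueError("Mantel test requires order >= 4")
    if rng is None:
        rng = np.random.default_rng()
    iu = np.triu_indices(A.shape[0], k=1)
    a, b = A[iu], B[iu]
    if a.std() == 0 or b.std() == 0:
        return math.nan, math.nan
    r_obs = float(np.corrcoef(a, b)[0, 1])
    hits = 1
    for _ in range(n_perm):
        perm = rng.permutation(A.shape[0])
        bp = B[np.ix_(perm, perm)][iu]
        if np.corrcoef(a, bp)[0, 1] >= r_obs - 1e-12:
            hits += 1
    return r_obs, hits / (n_perm + 1)


def population_summary(
    aln: Alignment,
    popmap: PopulationMap,
) -> pd.DataFrame:
    """Per-population, per-region and total diversity/neutrality table.

    Columns: N, S, H, Hd, pi_site, pi_locus, tajima_D, fu_Fs, raggedness_r —
    one row per population, per region, plus a pooled total row.
    """
    popmap.check_covers(aln)
    rows = []

    def one(label: str, level: str, ids: list[str]) -> None:
        if len(ids) < 2:
            rows.append(
                {"label": label, "level": level, "N": len(ids)}
            )
            return
        sub = aln.subset(ids)
        div = diversity(sub, popmap)
        mm = mismatch(sub)
        rows.append(
            {
                "label": label,
                "level": level,
                "N": div.n,
                "S": div.S,
                "H": div.H,
                "Hd": div.Hd,
                "pi_site": div.pi_site,
                "pi_locus": div.pi_locus,
                "tajima_D": tajimas_d(sub),
                "fu_Fs": fus_fs(sub),
                "raggedness_r": mm.raggedness_r,
            }
        )

    for pop, ids in popmap.grouped(aln, "population").items():
        if ids:
            one(pop, "population", ids)
    for reg, ids in popmap.grouped(aln, "region").items():
        if ids:
            one(reg, "region", ids)
    one("total", "total", aln.sample_ids)
    return pd.DataFrame(rows)
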