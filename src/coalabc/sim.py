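"""Structured-coalescent simulation with splits, island migration and growth.

Single-locus genealogies are simulated backward in time without
recombination under any of the demographic models in :mod:`coalabc.models`:

* within-deme coalescence at rate k(k−1)/2 divided by the deme's current
  relative size;
* symmetric island migration at per-lineage rate m/(n_demes−1) toward each
  other coexisting deme (when the model has migration);
* deterministic lineage relocation at split times (backward merges);
* exponential growth handled exactly by inverse-CDF time rescaling of the
  coalescence waiting times — a deme founded (backward: merging) at time τ
  has relative size exp(−α·t) for t < τ and exp(−α·τ) earlier.

Mutations follow the infinite-sites model: Poisson with mean (θ/2)·T_total
placed uniformly on branches, each creating a new segregating column.
Times are in 4Ne-generation units for both loci; the mitochondrial locus
differs only through its θ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import Alignment
from .models import THETA_RATIO_ITS2_OVER_COI, DemographicModel

__all__ = [
    "SampleConfig",
    "SimResult",
    "simulate",
    "render_sequences",
    "simulate_two_locus_dataset",
    "to_ms_text",
    "matrix_summaries",
]

_BASES = "ACGT"


@dataclass
class SampleConfig:
    """Per-region sample counts and locus lengths for a two-locus design."""

    coi_counts: tuple[int, ...] = (37, 30, 21, 42)
    its2_counts: tuple[int, ...] = (78, 56, 42, 74)
    coi_length: int = 668
    its2_length: int = 274

    def __post_init__(self) -> None:
        if len(self.coi_counts) != len(self.its2_counts):
            raise ValueError("locus sample configurations must cover the same regions")
        if any(c <= 0 for c in self.coi_counts + tuple(self.its2_counts)):
            raise ValueError("sample counts must be positive")

    @property
    def n_regions(self) -> int:
        return len(self.coi_counts)


@dataclass
class SimResult:
    """Binary segregating-site matrix plus genealogy metadata.

    ``matrix`` is (n_samples, S) over {0,1} with every column polymorphic;
    ``groups`` gives the region index of each sample row.
    """

    matrix: np.ndarray
    groups: np.ndarray
    tree_length: float
    n_groups: int

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def S(self) -> int:
        return self.matrix.shape[1]


class _Lineage:
    __slots__ = ("deme", "samples", "start")

    def __init__(self, deme: int, samples: list[int], start: float):
        self.deme = deme
        self.samples = samples
        self.start = start


def _resolve_splits(
    model: DemographicModel, params: dict[str, float]
) -> list[tuple[float, int, int]]:
    """(time, source, dest) split events with numeric times, sorted."""
    events = []
    for ev in model.split_events:
        events.append((params[ev.time_symbol], ev.source, ev.dest))
    events.sort(key=lambda e: e[0])
    return events


def _growth_anchors(
    model: DemographicModel, params: dict[str, float]
) -> dict[int, float]:
    """Backward founding time (growth anchor) per deme, for growth models.

    A deme grows from its merge-into-parent time; the root deme (and the
    single deme of the panmictic growth model) anchors at τ1.
    """
    if not model.has_growth:
        return {}
    anchors: dict[int, float] = {}
    for ev in model.split_events:
        anchors[ev.source] = params[ev.time_symbol]
    tau1 = params.get("tau1")
    if tau1 is None:
        raise ValueError("growth models require tau1")
    for deme in range(model.n_demes):
        anchors.setdefault(deme, tau1)
    return anchors


def simulate(
    model: DemographicModel,
    params: dict[str, float],
    sample_counts: tuple[int, ...],
    theta: float,
    rng: np.random.Generator,
) -> SimResult:
    """Simulate one locus under ``model`` and drop infinite-sites mutations.

    ``sample_counts`` gives samples per region group; for single-deme models
    all groups are placed in the one deme but keep their region labels.
    """
    n_groups = len(sample_counts)
    n = int(sum(sample_counts))
    if n < 2:
        raise ValueError("need at least 2 samples")
    groups = np.repeat(np.arange(n_groups), sample_counts)
    alpha = params.get("alpha", 0.0) if model.has_growth else 0.0
    m_total = params.get("m", 0.0) if model.has_migration else 0.0
    # per-lineage, per-target-deme migration rate
    mig_pair = m_total / (model.n_demes - 1) if model.n_demes > 1 else 0.0

    splits = _resolve_splits(model, params)
    anchors = _growth_anchors(model, params)
    boundaries = sorted({t for t, _, _ in splits} | set(anchors.values()))

    lineages: list[_Lineage] = []
    idx = 0
    for g, cnt in enumerate(sample_counts):
        deme = g if model.n_demes > 1 else 0
        for _ in range(cnt):
            lineages.append(_Lineage(deme, [idx], 0.0))
            idx += 1

    branches: list[tuple[list[int], float]] = []
    existing = set(range(model.n_demes))
    t = 0.0
    split_ptr = 0
    bound_ptr = 0
    exp = math.exp
    log = math.log

    while len(lineages) > 1:
        while bound_ptr < len(boundaries) and boundaries[bound_ptr] <= t:
            bound_ptr += 1
        boundary = boundaries[bound_ptr] if bound_ptr < len(boundaries) else math.inf

        # per-deme lineage partition
        by_deme: dict[int, list[_Lineage]] = {}
        for lin in lineages:
            by_deme.setdefault(lin.deme, []).append(lin)

        # candidate coalescence per deme
        w_min = math.inf
        ev_deme = -1
        for deme, lins in by_deme.items():
            k = len(lins)
            if k < 2:
                continue
            k2 = k * (k - 1) / 2.0
            anchor = anchors.get(deme)
            if anchor is not None and t < anchor:
                # growing regime: rate(t) = k2 * exp(alpha * t)
                e = rng.exponential()
                w = log(exp(alpha * t) + e * alpha / k2) / alpha - t
            else:
                size = exp(-alpha * anchor) if anchor is not None else 1.0
                w = rng.exponential() * size / k2
            if w < w_min:
                w_min = w
                ev_deme = deme

        # migration
        w_mig = math.inf
        if mig_pair > 0.0 and len(existing) > 1:
            rate = len(lineages) * (len(existing) - 1) * mig_pair
            w_mig = rng.exponential() / rate

        w_next = min(w_min, w_mig)
        if t + w_next >= boundary:
            # advance to the boundary and apply any splits scheduled there
            t = boundary
            while split_ptr < len(splits) and splits[split_ptr][0] <= t + 1e-15:
                _, src, dst = splits[split_ptr]
                for lin in lineages:
                    if lin.deme == src:
                        lin.deme = dst
                existing.discard(src)
                split_ptr += 1
            continue

        t += w_next
        if w_mig < w_min:
            lin = lineages[rng.integers(len(lineages))]
            targets = [d for d in existing if d != lin.deme]
            lin.deme = targets[rng.integers(len(targets))] if targets else lin.deme
        else:
            lins = by_deme[ev_deme]
            i, j = rng.choice(len(lins), size=2, replace=False)
            a, b = lins[i], lins[j]
            branches.append((a.samples, t - a.start))
            branches.append((b.samples, t - b.start))
            lineages.remove(a)
            lineages.remove(b)
            lineages.append(_Lineage(ev_deme, a.samples + b.samples, t))

    total_len = sum(length for _, length in branches)
    n_mut = rng.poisson(theta / 2.0 * total_len) if theta > 0 else 0
    if n_mut == 0 or total_len == 0.0:
        return SimResult(np.zeros((n, 0), dtype=np.uint8), groups, total_len, n_groups)
    lengths = np.array([length for _, length in branches])
    which = rng.choice(len(branches), size=n_mut, p=lengths / total_len)
    matrix = np.zeros((n, n_mut), dtype=np.uint8)
    for col, bi in enumerate(which):
        matrix[branches[bi][0], col] = 1
    return SimResult(matrix, groups, total_len, n_groups)


def render_sequences(
    sim_result: SimResult,
    length: int,
    rng: np.random.Generator,
    sample_ids: list[str] | None = None,
    locus_name: str = "locus",
    ploidy: str = "haploid",
) -> Alignment:
    """Render a binary segregating-site matrix as nucleotide sequences.

    Each segregating column is placed at a distinct random position with a
    random ancestral/derived base pair; monomorphic positions are filled
    with a random reference base.
    """
    n, S = sim_result.matrix.shape
    if S > length:
        raise ValueError(f"{S} segregating sites exceed locus length {length}")
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    ref = rng.integers(0, 4, size=length)
    positions = rng.choice(length, size=S, replace=False)
    derived = np.array(
        [(ref[p] + rng.integers(1, 4)) % 4 for p in positions], dtype=int
    )
    seq_codes = np.tile(ref, (n, 1))
    for col in range(S):
        carriers = sim_result.matrix[:, col] == 1
        seq_codes[carriers, positions[col]] = derived[col]
    base = np.array(list(_BASES))
    seqs = ["".join(base[row]) for row in seq_codes]
    return Alignment(locus_name, list(zip(sample_ids, seqs)), ploidy)


def simulate_two_locus_dataset(
    model: DemographicModel,
    params: dict[str, float],
    sample_config: SampleConfig,
    rng: np.random.Generator,
) -> tuple[SimResult, SimResult]:
    """Independent genealogies for the two unlinked loci.

    The loci share all demographic parameters; θ for the nuclear locus is
    tied to the mitochondrial θ by the fixed 1:4 ratio.
    """
    theta_coi = params["theta_coi"]
    theta_its2 = params.get(
        "theta_its2", THETA_RATIO_ITS2_OVER_COI * theta_coi
    )
    res_coi = simulate(model, params, tuple(sample_config.coi_counts), theta_coi, rng)
    res_its2 = simulate(
        model, params, tuple(sample_config.its2_counts), theta_its2, rng
    )
    return res_coi, res_its2


def to_ms_text(results: list[SimResult], rng: np.random.Generator) -> str:
    """Render replicates in ms-like text (``//`` blocks, segsites, 0/1 rows)."""
    chunks = []
    for res in results:
        pos = np.sort(rng.uniform(size=res.S))
        lines = ["//", f"segsites: {res.S}"]
        if res.S:
            lines.append("positions: " + " ".join(f"{p:.5f}" for p in pos))
            lines.extend("".join(map(str, row)) for row in res.matrix)
        chunks.append("\n".join(lines))
    return "\n".join(chunks) + "\n"


def matrix_summaries(res: SimResult) -> dict[str, float]:
    """Summary statistics from the binary matrix.

    Returns total π (mean pairwise differences per locus), segregating
    sites, Tajima's D (0 when undefined at S=0, flagged by ``d_defined``),
    mean within-region π and mean between-region π over region pairs.
    """
    from .stats import tajimas_d_from_counts

    n = res.n
    c = res.matrix.sum(axis=0).astype(float)
    pairs = n * (n - 1) / 2.0
    pi = float((c * (n - c)).sum() / pairs)
    S = res.S
    if S > 0:
        d = tajimas_d_from_counts(n, S, pi)
        d_defined = 1.0
    else:
        d, d_defined = 0.0, 0.0

    group_counts = []
    group_sizes = []
    for g in range(res.n_groups):
        mask = res.groups == g
        ng = int(mask.sum())
        if ng == 0:
            continue
        group_sizes.append(ng)
        group_counts.append(res.matrix[mask].sum(axis=0).astype(float))

    pi_w_vals = []
    for ng, cg in zip(group_sizes, group_counts):
        if ng >= 2:
            pi_w_vals.append(float((cg * (ng - cg)).sum() / (ng * (ng - 1) / 2.0)))
    pi_w = float(np.mean(pi_w_vals)) if pi_w_vals else 0.0

    pi_b_vals = []
    for a in range(len(group_sizes) - 1):
        for b in range(a + 1, len(group_sizes)):
            na, nb = group_sizes[a], group_sizes[b]
            ca, cb = group_counts[a], group_counts[b]
            between = (ca * (nb - cb) + (na - ca) * cb).sum()
            pi_b_vals.append(float(between / (na * nb)))
    pi_b = float(np.mean(pi_b_vals)) if pi_b_vals else 0.0

    return {
        "pi": pi,
        "ss": float(S),
        "d": d,
        "d_defined": d_defined,
        "pi_w": pi_w,
        "pi_b": pi_b,
    }
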