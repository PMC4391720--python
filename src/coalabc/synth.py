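"""Study-shaped synthetic datasets with known ground truth.

Generates complete two-locus datasets (mitochondrial + phased nuclear) under
any demographic model, laid out like the target field-sampling design:
eight populations nested in four geographical regions, fixed per-population
sample sizes (130 mitochondrial sequences, 250 phased nuclear gene copies)
and locus lengths (668 and 274 bp).  The simulated demes are
the four regions; populations within a region subdivide that region's
samples, so population labels within a region carry no extra structure.

A reduced layout (6 mitochondrial sequences and 8 nuclear copies per
population) is provided for fast exercises of the full pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import Alignment, PopulationMap, write_fasta, write_popmap
from .models import DemographicModel, enumerate_models
from .sim import SampleConfig, render_sequences, simulate_two_locus_dataset

__all__ = [
    "StudyLayout",
    "STUDY_LAYOUT",
    "REDUCED_LAYOUT",
    "generate_dataset",
    "generate_fixture_suite",
]


@dataclass(frozen=True)
class StudyLayout:
    """Sampling design: populations, their regions and per-population counts."""

    populations: tuple[str, ...]
    regions: tuple[str, ...]  # region label per population
    coi_counts: tuple[int, ...]
    its2_counts: tuple[int, ...]  # phased gene copies (2 per individual)
    coi_length: int = 668
    its2_length: int = 274

    def __post_init__(self) -> None:
        k = len(self.populations)
        if not (len(self.regions) == len(self.coi_counts) == len(self.its2_counts) == k):
            raise ValueError("per-population fields must have equal length")
        if any(c % 2 for c in self.its2_counts):
            raise ValueError("phased nuclear copy counts must be even")

    @property
    def region_labels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.regions:
            if r not in seen:
                seen.append(r)
        return tuple(seen)

    def region_totals(self, counts: tuple[int, ...]) -> tuple[int, ...]:
        totals = {r: 0 for r in self.region_labels}
        for r, c in zip(self.regions, counts):
            totals[r] += c
        return tuple(totals[r] for r in self.region_labels)

    def sample_config(self) -> SampleConfig:
        return SampleConfig(
            coi_counts=self.region_totals(self.coi_counts),
            its2_counts=self.region_totals(self.its2_counts),
            coi_length=self.coi_length,
            its2_length=self.its2_length,
        )


STUDY_LAYOUT = StudyLayout(
    populations=(
        "Centenário do Sul",
        "Florestópolis",
        "Teodoro Sampaio",
        "Campinas",
        "Jundiaí",
        "Ibirama",
        "Gramado",
        "Sapiranga",
    ),
    regions=("1", "1", "1", "2", "2", "3", "4", "4"),
    coi_counts=(13, 9, 15, 11, 19, 21, 9, 33),
    its2_counts=(28, 20, 30, 20, 36, 42, 18, 56),
)

REDUCED_LAYOUT = StudyLayout(
    populations=STUDY_LAYOUT.populations,
    regions=STUDY_LAYOUT.regions,
    coi_counts=(6,) * 8,
    its2_counts=(8,) * 8,
    coi_length=668,
    its2_length=274,
)

_SLUGS = {
    "Centenário do Sul": "CSU",
    "Florestópolis": "FLO",
    "Teodoro Sampaio": "TSA",
    "Campinas": "CAM",
    "Jundiaí": "JUN",
    "Ibirama": "IBI",
    "Gramado": "GRA",
    "Sapiranga": "SAP",
}


def _slug(pop: str) -> str:
    return _SLUGS.get(pop, "".join(ch for ch in pop if ch.isalnum())[:6].upper())


def generate_dataset(
    model: DemographicModel,
    params: dict[str, float],
    layout: StudyLayout = STUDY_LAYOUT,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[Alignment, Alignment, PopulationMap, dict]:
    """Simulate one study-shaped dataset with a recorded truth record.

    Region-level simulated samples are distributed to populations in layout
    order; nuclear copies are emitted as ``/1``/``/2`` pairs per individual.
    With ``out_dir`` the FASTA files, popmap and truth record are written;
    the same seed reproduces byte-identical files.
    """
    if model.n_demes not in (1, len(layout.region_labels)):
        raise ValueError(
            f"model has {model.n_demes} demes; layout has "
            f"{len(layout.region_labels)} regions"
        )
    rng = np.random.default_rng(seed)
    cfg = layout.sample_config()
    res_coi, res_its2 = simulate_two_locus_dataset(model, params, cfg, rng)

    coi_ids: list[str] = []
    its2_ids: list[str] = []
    assignments: dict[str, tuple[str, str]] = {}
    for pop, reg, c_coi, c_its2 in zip(
        layout.populations, layout.regions, layout.coi_counts, layout.its2_counts
    ):
        slug = _slug(pop)
        for i in range(c_coi):
            sid = f"{slug}_c{i + 1:02d}"
            coi_ids.append(sid)
            assignments[sid] = (pop, reg)
        for j in range(c_its2 // 2):
            for phase in (1, 2):
                sid = f"{slug}_n{j + 1:02d}/{phase}"
                its2_ids.append(sid)
                assignments[sid] = (pop, reg)

    aln_coi = render_sequences(
        res_coi, layout.coi_length, rng, coi_ids, "COI", "haploid"
    )
    aln_its2 = render_sequences(
        res_its2, layout.its2_length, rng, its2_ids, "ITS2", "diploid-phased"
    )
    popmap = PopulationMap(
        assignments, list(layout.populations), list(layout.region_labels)
    )
    truth = {
        "model_id": model.model_id,
        "scenario": model.scenario,
        "seed": seed,
        "params": {k: float(v) for k, v in params.items()},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(aln_coi, out / "coi.fasta")
        write_fasta(aln_its2, out / "its2.fasta")
        write_popmap(popmap, out / "popmap.tsv")
        (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return aln_coi, aln_its2, popmap, truth


def _fixed_haplotype_alignment(
    n_per_pop: int, n_diff_sites: int, length: int = 40
) -> tuple[Alignment, PopulationMap]:
    """Two populations each fixed for one haplotype, k sites apart."""
    base = "A" * length
    other = "T" * n_diff_sites + "A" * (length - n_diff_sites)
    seqs = [(f"p1_{i}", base) for i in range(n_per_pop)] + [
        (f"p2_{i}", other) for i in range(n_per_pop)
    ]
    aln = Alignment("fixed_pair", seqs)
    popmap = PopulationMap(
        {sid: ("pop1" if sid.startswith("p1") else "pop2",) * 2 for sid, _ in seqs}
    )
    return aln, popmap


def _starburst_alignment(n: int = 12, length: int = 40) -> Alignment:
    """One common central haplotype plus singleton one-step derivatives."""
    center = "A" * length
    seqs = [(f"c{i}", center) for i in range(n // 2)]
    for j in range(n - n // 2):
        seq = list(center)
        seq[j] = "G"
        seqs.append((f"d{j}", "".join(seq)))
    return Alignment("starburst", seqs)


def generate_fixture_suite(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write the small named fixtures every pipeline stage is tested against.

    Includes an all-identical alignment, a two-population fixed-haplotype
    alignment (ΦST = 1), a star-burst alignment (many singleton haplotypes)
    and a reduced-layout panmictic dataset, plus a manifest of the files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ident = Alignment("identical", [(f"s{i}", "ACGTACGT") for i in range(6)])
    paths["identical"] = out / "identical.fasta"
    write_fasta(ident, paths["identical"])
    ident_map = PopulationMap({f"s{i}": ("pop1", "r1") for i in range(6)})
    paths["identical_popmap"] = out / "identical.popmap.tsv"
    write_popmap(ident_map, paths["identical_popmap"])

    fixed_aln, fixed_map = _fixed_haplotype_alignment(n_per_pop=5, n_diff_sites=4)
    paths["two_pops_fixed"] = out / "two_pops_fixed.fasta"
    write_fasta(fixed_aln, paths["two_pops_fixed"])
    paths["two_pops_fixed_popmap"] = out / "two_pops_fixed.popmap.tsv"
    write_popmap(fixed_map, paths["two_pops_fixed_popmap"])

    star = _starburst_alignment()
    paths["starburst"] = out / "starburst.fasta"
    write_fasta(star, paths["starburst"])

    model1 = enumerate_models()[0]
    sub = out / "reduced_panmictic"
    generate_dataset(
        model1, {"theta_coi": 3.0, "theta_its2": 12.0}, REDUCED_LAYOUT, seed, sub
    )
    paths["reduced_panmictic"] = sub

    manifest = {name: str(p.relative_to(out)) for name, p in paths.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths
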