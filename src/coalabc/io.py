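"""Sequence alignments, population maps and haplotype tables.

The in-memory dataset object shared by every downstream stage is the
:class:`Alignment` (equal-length sequences with sample labels) plus a
:class:`PopulationMap` assigning each sample to a population nested in a
geographical region.  Phased diploid loci are represented as two haploid
entries per individual, suffixed ``/1`` and ``/2``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_RESIDUES = frozenset("ACGT-N")

__all__ = [
    "Alignment",
    "PopulationMap",
    "HaplotypeTable",
    "AlignmentShapeError",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_popmap",
    "write_popmap",
    "collapse_haplotypes",
]


class AlignmentShapeError(ValueError):
    """Sequences in one locus do not share a common length."""


class FormatError(ValueError):
    """Malformed FASTA/popmap content (illegal residue, duplicate sample...)."""


@dataclass
class Alignment:
    """Aligned sequences for one locus.

    Parameters
    ----------
    locus_name : str
        Label for the locus (e.g. ``"COI"``).
    sequences : list of (str, str)
        ``(sample_id, residues)`` pairs; residues over ``{A,C,G,T,-,N}``.
    ploidy : {"haploid", "diploid-phased"}
        Phased diploid loci carry two entries per individual.
    """

    locus_name: str
    sequences: list[tuple[str, str]]
    ploidy: str = "haploid"

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentShapeError(f"{self.locus_name}: empty alignment")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"{self.locus_name}: unequal sequence lengths {sorted(lengths)}"
            )
        if next(iter(lengths)) == 0:
            raise AlignmentShapeError(f"{self.locus_name}: zero-length sequences")
        ids = [sid for sid, _ in self.sequences]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"{self.locus_name}: duplicate sample ids {dup}")
        for sid, seq in self.sequences:
            bad = set(seq) - VALID_RESIDUES
            if bad:
                raise FormatError(
                    f"{self.locus_name}/{sid}: illegal residues {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        """Number of aligned sites."""
        return len(self.sequences[0][1])

    @property
    def n(self) -> int:
        """Number of sequences."""
        return len(self.sequences)

    @property
    def sample_ids(self) -> list[str]:
        return [sid for sid, _ in self.sequences]

    def subset(self, sample_ids: list[str]) -> "Alignment":
        """Alignment restricted to the given samples, in the given order."""
        by_id = dict(self.sequences)
        missing = [s for s in sample_ids if s not in by_id]
        if missing:
            raise KeyError(f"samples not in alignment: {missing}")
        return Alignment(
            self.locus_name, [(s, by_id[s]) for s in sample_ids], self.ploidy
        )


@dataclass
class PopulationMap:
    """sample → (population, region) assignment with ordered levels."""

    assignments: dict[str, tuple[str, str]]
    populations: list[str] = field(default_factory=list)
    regions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.populations:
            seen: list[str] = []
            for pop, _ in self.assignments.values():
                if pop not in seen:
                    seen.append(pop)
            self.populations = seen
        if not self.regions:
            seen = []
            for _, reg in self.assignments.values():
                if reg not in seen:
                    seen.append(reg)
            self.regions = seen
        pop2reg: dict[str, str] = {}
        for sid, (pop, reg) in self.assignments.items():
            if pop in pop2reg and pop2reg[pop] != reg:
                raise FormatError(
                    f"population {pop!r} mapped to regions "
                    f"{pop2reg[pop]!r} and {reg!r}"
                )
            pop2reg[pop] = reg
        self.population_to_region = pop2reg

    def population_of(self, sample_id: str) -> str:
        return self.assignments[sample_id][0]

    def region_of(self, sample_id: str) -> str:
        return self.assignments[sample_id][1]

    def check_covers(self, aln: Alignment) -> None:
        """Raise listing any alignment sample without an assignment."""
        missing = [s for s in aln.sample_ids if s not in self.assignments]
        if missing:
            raise FormatError(
                f"{aln.locus_name}: {len(missing)} samples missing from popmap: "
                f"{missing[:10]}"
            )

    def grouped(self, aln: Alignment, level: str = "population") -> dict[str, list[str]]:
        """Sample ids of ``aln`` grouped by population or region, level order."""
        key = self.population_of if level == "population" else self.region_of
        labels = self.populations if level == "population" else self.regions
        groups: dict[str, list[str]] = {lab: [] for lab in labels}
        for sid in aln.sample_ids:
            groups[key(sid)].append(sid)
        return groups


@dataclass
class HaplotypeTable:
    """Distinct sequences with per-population counts."""

    haplotypes: list[str]
    counts: dict[str, list[int]]  # population -> count per haplotype

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def total(self) -> int:
        return sum(sum(v) for v in self.counts.values())

    def frequencies(self) -> list[float]:
        """Pooled relative frequency of each haplotype."""
        tot = self.total()
        pooled = [
            sum(self.counts[p][k] for p in self.counts)
            for k in range(self.n_haplotypes)
        ]
        return [c / tot for c in pooled]


def read_fasta(path: str | Path, locus_name: str, ploidy: str = "haploid") -> Alignment:
    """Read an aligned multi-FASTA file into an :class:`Alignment`.

    Residues are upper-cased; record order is preserved.  Unequal record
    lengths raise :class:`AlignmentShapeError`; residues outside
    ``{A,C,G,T,-,N}`` raise :class:`FormatError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    seqs = [(rec.id, str(rec.seq).upper()) for rec in records]
    return Alignment(locus_name, seqs, ploidy)


def write_fasta(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as FASTA wrapped at 70 columns."""
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln.sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(records)


def read_popmap(path: str | Path) -> PopulationMap:
    """Read a tab-separated sample/population(/region) map.

    A header line ``sample<TAB>population[<TAB>region]`` is skipped if
    present.  With two columns the region defaults to the population.
    """
    assignments: dict[str, tuple[str, str]] = {}
    populations: list[str] = []
    regions: list[str] = []
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and any(r)]
    if not rows:
        raise FormatError(f"{path}: empty popmap")
    if rows[0][0].lower() == "sample":
        rows = rows[1:]
    if not rows:
        raise FormatError(f"{path}: popmap has a header but no data rows")
    for row in rows:
        if len(row) < 2:
            raise FormatError(f"{path}: popmap row with <2 columns: {row}")
        sid, pop = row[0], row[1]
        reg = row[2] if len(row) >= 3 and row[2] else pop
        if sid in assignments:
            raise FormatError(f"{path}: duplicate sample {sid!r}")
        assignments[sid] = (pop, reg)
        if pop not in populations:
            populations.append(pop)
        if reg not in regions:
            regions.append(reg)
    return PopulationMap(assignments, populations, regions)


def write_popmap(popmap: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\tregion\n")
        for sid, (pop, reg) in popmap.assignments.items():
            fh.write(f"{sid}\t{pop}\t{reg}\n")


def collapse_haplotypes(aln: Alignment, popmap: PopulationMap) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes with per-population counts.

    Sites containing ``N`` or ``-`` are compared literally (treated as
    ordinary states for haplotype identity).
    """
    popmap.check_covers(aln)
    haplotypes: list[str] = []
    index: dict[str, int] = {}
    for _, seq in aln.sequences:
        if seq not in index:
            index[seq] = len(haplotypes)
            haplotypes.append(seq)
    counts = {pop: [0] * len(haplotypes) for pop in popmap.populations}
    for sid, seq in aln.sequences:
        counts[popmap.population_of(sid)][index[seq]] += 1
    return HaplotypeTable(haplotypes, counts)
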