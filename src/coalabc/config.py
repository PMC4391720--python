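"""Pipeline configuration: priors, model set, simulation counts, tolerances,
candidate summary vectors and seeds, serialized as YAML."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import yaml

from .abc import STAT_NAMES
from .models import Priors

__all__ = ["PipelineConfig", "default_candidate_vectors"]


def default_candidate_vectors() -> list[tuple[str, ...]]:
    """All non-empty subsets of the five candidate statistics."""
    out: list[tuple[str, ...]] = []
    for k in range(1, len(STAT_NAMES) + 1):
        out.extend(combinations(STAT_NAMES, k))
    return out


@dataclass
class PipelineConfig:
    """Settings for a full run; defaults mirror the full-scale design.

    ``n_sims_per_model`` defaults to the full-scale 100 000; desk-scale runs
    override it (the ``reduced`` profile uses 2000).
    """

    coi_fasta: str = ""
    its2_fasta: str = ""
    popmap: str = ""
    out_dir: str = "results"
    priors: Priors = field(default_factory=Priors)
    model_ids: list[int] = field(default_factory=lambda: list(range(1, 15)))
    n_sims_per_model: int = 100_000
    tolerances: tuple[float, float] = (0.001, 0.01)
    pods_per_model: int = 10
    candidate_vectors: list[tuple[str, ...]] = field(
        default_factory=default_candidate_vectors
    )
    choice_methods: list[str] = field(
        default_factory=lambda: ["rejection", "mnlogistic", "neuralnet"]
    )
    final_method: str = "rejection"
    final_tolerance: float = 0.001
    estimation_tolerance: float = 0.01
    n_permutations: int = 1000
    seed: int = 1
    layout: str = "study"  # "study" | "reduced"

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "priors" in data:
            pr = data["priors"]
            for key in ("theta_coi", "tau1", "m", "alpha"):
                if key in pr:
                    pr[key] = tuple(pr[key])
            data["priors"] = Priors(**pr)
        if "candidate_vectors" in data:
            data["candidate_vectors"] = [tuple(v) for v in data["candidate_vectors"]]
        if "tolerances" in data:
            data["tolerances"] = tuple(data["tolerances"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["priors"] = {
            "theta_coi": list(self.priors.theta_coi),
            "tau1": list(self.priors.tau1),
            "tau23_low": self.priors.tau23_low,
            "m": list(self.priors.m),
            "alpha": list(self.priors.alpha),
        }
        data["candidate_vectors"] = [list(v) for v in self.candidate_vectors]
        data["tolerances"] = list(self.tolerances)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
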