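"""Structured run configuration with YAML round-trip.

A :class:`RunConfig` bundles every knob of a full pipeline replay — genome
spec, annotation geometry, population mixture, optional spike-ins and
extraction, treatment list, library prep, size classes and analysis options —
so that one config file plus one seed reproduces a study arm end to end.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .fixtures import AnnotationParams, GenomeModel
from .simulate import ExtractionModel, PopulationConfig
from .treatments import LibraryPrep, TreatmentSpec
from .analysis import SizeClassConfig

__all__ = ["RunConfig", "AnalysisOptions"]


@dataclass
class AnalysisOptions:
    bin_size: int = 100
    periodicity_window: tuple[int, int] = (100, 160)
    smoothing_half_width: int = 5
    trace_kernel_sigma: float = 5.0
    trace_region_a: tuple[int, int] = (180, 250)
    trace_region_b: tuple[int, int] = (251, 350)


def _tupleize(obj: Any) -> Any:
    """YAML has no tuples; convert lists back for dataclass fields that use them."""
    if isinstance(obj, list):
        return tuple(_tupleize(x) for x in obj)
    return obj


def _listify(obj: Any) -> Any:
    if isinstance(obj, tuple):
        return [_listify(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_listify(x) for x in obj]
    return obj


def _from_dict(cls, data: dict) -> Any:
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            value = data[f.name]
            if isinstance(value, list):
                value = _tupleize(value)
            if isinstance(value, dict):
                # nested plain dicts keep inner tuples as tuples where needed
                value = {k: _tupleize(v) if isinstance(v, list) else v for k, v in value.items()}
            kwargs[f.name] = value
    return cls(**kwargs)


@dataclass
class RunConfig:
    seed: int = 0
    genome: GenomeModel = field(default_factory=GenomeModel)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    extraction: ExtractionModel | None = None
    spikein_copies_per_size: int = 0
    treatments: list[TreatmentSpec] = field(default_factory=list)
    library: LibraryPrep = field(default_factory=LibraryPrep)
    size_classes: SizeClassConfig = field(default_factory=SizeClassConfig)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "genome": {
                "contigs": [[n, l] for n, l in self.genome.contigs],
                "mito_name": self.genome.mito_name,
            },
            "annotation": _listify(dataclasses.asdict(self.annotation)),
            "population": _listify(dataclasses.asdict(self.population)),
            "extraction": None
            if self.extraction is None
            else _listify(dataclasses.asdict(self.extraction)),
            "spikein_copies_per_size": self.spikein_copies_per_size,
            "treatments": [_listify(dataclasses.asdict(t)) for t in self.treatments],
            "library": _listify(dataclasses.asdict(self.library)),
            "size_classes": _listify(dataclasses.asdict(self.size_classes)),
            "analysis": _listify(dataclasses.asdict(self.analysis)),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        genome_d = data.get("genome", {})
        genome = GenomeModel(
            contigs=tuple((str(n), int(l)) for n, l in genome_d.get("contigs", GenomeModel().contigs)),
            mito_name=genome_d.get("mito_name", "chrM"),
        )
        extraction_d = data.get("extraction")
        return cls(
            seed=int(data.get("seed", 0)),
            genome=genome,
            annotation=_from_dict(AnnotationParams, data.get("annotation", {})),
            population=_from_dict(PopulationConfig, data.get("population", {})),
            extraction=None if extraction_d is None else _from_dict(ExtractionModel, extraction_d),
            spikein_copies_per_size=int(data.get("spikein_copies_per_size", 0)),
            treatments=[_from_dict(TreatmentSpec, t) for t in data.get("treatments", [])],
            library=_from_dict(LibraryPrep, data.get("library", {})),
            size_classes=_from_dict(SizeClassConfig, data.get("size_classes", {})),
            analysis=_from_dict(AnalysisOptions, data.get("analysis", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
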