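"""Run configuration: schema, validation, YAML round-trip, presets.

A run is described by one structured config with four sections
(generator, model, evolution, analysis).  Two presets matter in
practice: ``desk`` -- the scaled-down study conditions used by the test
suite and the acceptance script (4 loci x 2 kb, 30 nuclei, 50
individuals, 300 generations, mu = 0.001); ``paper`` -- full, publication-scale
conditions (18 kb loci, 100 individuals, 3,350 generations),
expressible but slow.  ``smoke`` is a minimal end-to-end
configuration for pipeline checks.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class GeneratorConfig:
    genes: list[str] = field(default_factory=lambda: ["hb", "Kr", "gt", "kni"])
    locus_length: int = 2000
    n_planted: int = 15
    accessible_fraction: float = 1.0
    gc: float = 0.5
    n_nuclei: int = 30
    scan_pvalue: float = 5e-3
    high_pvalue: float = 1.5e-3

    def validate(self):
        if self.locus_length < 100:
            raise ValueError("generator.locus_length: must be >= 100")
        if not 0 <= self.accessible_fraction <= 1:
            raise ValueError("generator.accessible_fraction: must be in [0, 1]")
        if not 0 < self.gc < 1:
            raise ValueError("generator.gc: must be in (0, 1)")
        if self.n_nuclei < 4:
            raise ValueError("generator.n_nuclei: must be >= 4")
        if not 0 < self.high_pvalue <= self.scan_pvalue:
            raise ValueError(
                "generator.high_pvalue: must be in (0, scan_pvalue]"
            )


@dataclass
class ModelConfig:
    t_end: float = 6.0
    dt: float = 0.04
    omega: float = 0.5
    coop_range: int = 50
    beta: float = 0.35
    weight: float = 0.9
    theta: float = -1.5

    def validate(self):
        if self.dt <= 0 or self.dt > self.t_end:
            raise ValueError("model.dt: must be in (0, t_end]")
        if self.omega < 0:
            raise ValueError("model.omega: must be >= 0")
        if self.coop_range < 0:
            raise ValueError("model.coop_range: must be >= 0")


@dataclass
class EvolutionConfig:
    population_size: int = 50
    mu: float = 0.001
    generations: int = 300
    elite_size: int = 10

    def validate(self):
        if self.elite_size > self.population_size or self.elite_size < 1:
            raise ValueError(
                "evolution.elite_size: must be in [1, population_size]"
            )
        if not 0 <= self.mu <= 1:
            raise ValueError("evolution.mu: must be in [0, 1]")
        if self.generations < 1:
            raise ValueError("evolution.generations: must be >= 1")


@dataclass
class AnalysisConfig:
    bin_width: int = 180
    n_affinity_sets: int = 35
    low_high_threshold: float = 4.0
    burn_in: int = 100
    n_boot: int = 499

    def validate(self):
        if self.bin_width < 1:
            raise ValueError("analysis.bin_width: must be >= 1")
        if self.n_affinity_sets < 1:
            raise ValueError("analysis.n_affinity_sets: must be >= 1")


@dataclass
class RunConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def validate(self) -> "RunConfig":
        self.generator.validate()
        self.model.validate()
        self.evolution.validate()
        self.analysis.validate()
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        sections = {
            "generator": GeneratorConfig,
            "model": ModelConfig,
            "evolution": EvolutionConfig,
            "analysis": AnalysisConfig,
        }
        for section, payload in d.items():
            if section not in sections:
                raise ValueError(f"unknown config section {section!r}")
            klass = sections[section]
            known = {f for f in klass.__dataclass_fields__}
            for key in payload:
                if key not in known:
                    raise ValueError(
                        f"unknown field {section}.{key} (known: {sorted(known)})"
                    )
            setattr(cfg, section, klass(**payload))
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "preset" in data:
            cfg = preset(data.pop("preset")).to_dict()
            for section, payload in data.items():
                cfg.setdefault(section, {}).update(payload or {})
            return cls.from_dict(cfg)
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def preset(name: str) -> RunConfig:
    """Named presets: desk (default), paper, smoke."""
    if name == "desk":
        return RunConfig().validate()
    if name == "paper":
        return RunConfig(
            generator=GeneratorConfig(locus_length=18_000, n_planted=120),
            evolution=EvolutionConfig(
                population_size=100, generations=3_350, elite_size=20
            ),
        ).validate()
    if name == "smoke":
        return RunConfig(
            generator=GeneratorConfig(
                genes=["hb", "Kr"], locus_length=800, n_planted=8, n_nuclei=12
            ),
            evolution=EvolutionConfig(
                population_size=20, generations=30, elite_size=5
            ),
        ).validate()
    raise ValueError(f"unknown preset {name!r} (desk, paper, smoke)")
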