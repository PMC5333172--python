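"""Seeded orchestration: generate -> evolve -> track -> analyze.

One global seed derives all stage seeds through
``numpy.random.SeedSequence(seed).spawn(...)`` in a fixed order
(pwms, genotype, evolution, analysis); no stage draws from an unseeded
source, so a run is bit-reproducible from (config, seed) and the
manifest records checksums to prove it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, analysis, expression, io, synthetic, tracking
from .config import RunConfig
from .evolution import EvoConfig, evolve
from .expression import ModelParams, TimeGrid
from .synthetic import LocusSpec, default_tf_specs, make_genotype, make_pwms, make_tf_profiles, make_wildtype

STAGES = ("generate", "evolve", "track", "analyze")


@dataclass
class RunManifest:
    config: dict
    seed: int
    stage_seeds: dict
    version: str = __version__
    status: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("pwms", "genotype", "evolution", "analysis")
    return {
        name: int(child.generate_state(1)[0] & 0x7FFFFFFF)
        for name, child in zip(names, children)
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRun:
    """In-memory pipeline state; stages can be run individually."""

    def __init__(self, config: RunConfig, seed: int):
        self.config = config.validate()
        self.seed = seed
        self.stage_seeds = _stage_seeds(seed)
        self.tf_specs = None
        self.pwms = None
        self.genotype = None
        self.profiles = None
        self.params = None
        self.grid = None
        self.U = None
        self.founder_annotation = None
        self.records = None
        self.trajectories = None

    # -- stages -----------------------------------------------------------

    def generate(self):
        g = self.config.generator
        m = self.config.model
        self.tf_specs = default_tf_specs(g.genes)
        for spec in self.tf_specs:
            spec.validate_roles(g.genes)
        self.pwms = make_pwms(
            self.tf_specs, self.stage_seeds["pwms"], g.scan_pvalue, g.high_pvalue
        )
        loci = [
            LocusSpec(
                gene=gene,
                length=g.locus_length,
                accessible_fraction=g.accessible_fraction,
                n_planted=g.n_planted,
            )
            for gene in g.genes
        ]
        self.genotype = make_genotype(
            loci, self.pwms, self.stage_seeds["genotype"], gc=g.gc
        )
        self.profiles = make_tf_profiles(g.n_nuclei)
        self.params = ModelParams.default(
            genes=g.genes,
            tf_specs=self.tf_specs,
            weight=m.weight,
            theta=np.full(len(g.genes), m.theta),
            omega=m.omega,
            coop_range=m.coop_range,
            beta=m.beta,
        ).set_reference_energies(self.pwms)
        self.grid = TimeGrid(t_end=m.t_end, dt=m.dt)
        self.U, self.founder_annotation = make_wildtype(
            self.genotype, self.params, self.pwms, self.profiles, self.grid
        )
        return self

    def evolve(self, progress: bool = False):
        if self.U is None:
            self.generate()
        e = self.config.evolution
        cfg = EvoConfig(
            population_size=e.population_size,
            mu=e.mu,
            generations=e.generations,
            elite_size=e.elite_size,
            rng_seed=self.stage_seeds["evolution"],
        )
        self.records = evolve(
            cfg,
            self.genotype,
            self.pwms,
            self.params,
            self.profiles,
            self.U,
            self.grid,
            progress=progress,
        )
        return self

    def track(self):
        if self.records is None:
            self.evolve()
        self.trajectories = tracking.track_individuals(
            [rec.tracked_sites for rec in self.records]
        )
        return self

    def analyze(self):
        if self.trajectories is None:
            self.track()
        a = self.config.analysis
        G = self.config.evolution.generations
        lengths = self.genotype.locus_lengths
        out = {}
        out["site_counts"] = analysis.site_count_dynamics(self.records)
        out["energy_all"] = analysis.energy_dynamics(self.records, "all")
        out["energy_new"] = analysis.energy_dynamics(self.records, "new")
        out["energy_tracked"] = analysis.energy_dynamics(
            self.records, "tracked-initial", self.trajectories
        )
        out["bin_profile"] = analysis.bin_energy_dynamics(
            self.records, lengths, a.bin_width
        )
        out["generation_correlation"] = analysis.generation_correlation(
            out["bin_profile"]
        )
        out["affinity_sets"] = analysis.affinity_set_correlation(
            self.trajectories, G, n_sets=min(
                a.n_affinity_sets,
                sum(1 for t in self.trajectories if t.origin == "initial"),
            )
        )
        out["low_high_ratio"] = analysis.low_high_ratio(
            [[s.E for s in rec.tracked_sites] for rec in self.records],
            a.low_high_threshold,
        )
        out["rms_energy"] = analysis.rms_energy_correlation(self.records, "all")
        groups = analysis.site_groups_from_tracking(
            self.trajectories, G, self.config.model.coop_range
        )
        rng = np.random.default_rng(self.stage_seeds["analysis"])
        samples, ks_table = analysis.knockout_score_distributions(
            self.founder_annotation,
            self.params,
            self.U,
            self.profiles,
            groups,
            self.grid,
            n_boot=a.n_boot,
            rng=rng,
        )
        out["knockout_samples"] = samples
        out["knockout_ks"] = ks_table
        out["trajectory_table"] = tracking.trajectory_table(
            self.trajectories, G, self.config.model.coop_range
        )
        self.analysis_outputs = out
        return self


def run_pipeline(
    config: RunConfig, seed: int, outdir, stages=STAGES, progress: bool = False
) -> RunManifest:
    """Execute the pipeline and write all outputs plus a manifest.

    On a stage failure, outputs written so far stay on disk and the
    manifest marks the failing stage before the exception propagates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run = PipelineRun(config, seed)
    manifest = RunManifest(
        config=config.to_dict(), seed=seed, stage_seeds=run.stage_seeds
    )
    mpath = outdir / "manifest.json"
    try:
        for stage in stages:
            getattr(run, stage)() if stage != "evolve" else run.evolve(progress)
            _write_stage_outputs(run, stage, outdir)
            manifest.status[stage] = "ok"
    except Exception:
        for stage in stages:
            manifest.status.setdefault(stage, "failed")
        manifest.checksums = {
            p.name: _sha256(p) for p in sorted(outdir.iterdir()) if p.is_file()
        }
        manifest.write(mpath)
        raise
    manifest.checksums = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest.write(mpath)
    return manifest


def _write_stage_outputs(run: PipelineRun, stage: str, outdir: Path) -> None:
    if stage == "generate":
        io.write_fasta(run.genotype.loci, outdir / "loci.fasta")
        io.intervals_to_bed(run.genotype.accessibility, outdir / "accessibility.bed")
        io.intervals_to_bed(run.genotype.crms, outdir / "crms.bed")
        io.intervals_to_bed(run.genotype.footprints, outdir / "footprints.bed")
        io.write_bed(
            outdir / "planted_sites.bed",
            [
                (p.locus, p.position, p.position + _pwm_len(run, p.tf), p.tf, 0, p.strand)
                for p in run.genotype.planted
            ],
        )
        for pwm in run.pwms:
            io.write_pwm(pwm, outdir / f"pwm_{pwm.tf}.txt")
        io.sites_to_bed(run.founder_annotation, outdir / "founder_sites.bed")
        io.expression_to_table(run.U, outdir / "wildtype_expression.tsv")
    elif stage == "evolve":
        import pandas as pd

        rows = [
            {
                "generation": rec.generation,
                "F_min": float(rec.F_all[0]),
                "F_mean": float(rec.F_all.mean()),
                "F_elite_mean": float(rec.elite_F.mean()),
                "elite_mean_sites": float(
                    np.mean([len(s) for s in rec.elite_sites])
                ),
            }
            for rec in run.records
        ]
        io.write_table(pd.DataFrame(rows), outdir / "fitness.tsv")
        io.sites_to_bed(run.records[-1].elite_sites[0], outdir / "final_best_sites.bed")
    elif stage == "track":
        G = run.config.evolution.generations
        io.write_table(
            tracking.trajectory_table(
                run.trajectories, G, run.config.model.coop_range
            ),
            outdir / "trajectories.tsv",
        )
    elif stage == "analyze":
        out = run.analysis_outputs
        io.write_table(out["site_counts"], outdir / "site_counts.tsv")
        io.write_table(out["energy_all"], outdir / "energy_all.tsv")
        io.write_table(out["energy_new"], outdir / "energy_new.tsv")
        io.write_table(out["energy_tracked"], outdir / "energy_tracked.tsv")
        io.write_table(out["rms_energy"], outdir / "rms_energy_correlation.tsv")
        io.write_table(out["knockout_ks"], outdir / "knockout_ks.tsv")
        import pandas as pd

        cm = out["affinity_sets"]
        io.write_table(
            pd.DataFrame(cm.matrix, columns=[f"set_{l}" for l in cm.labels]),
            outdir / "affinity_set_correlation.tsv",
        )
        io.write_table(
            pd.DataFrame(
                {
                    "generation": range(len(out["low_high_ratio"])),
                    "low_high_ratio": out["low_high_ratio"],
                }
            ),
            outdir / "low_high_ratio.tsv",
        )


def _pwm_len(run: PipelineRun, tf: str) -> int:
    return next(p.length for p in run.pwms if p.tf == tf)
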