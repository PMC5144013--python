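"""End-to-end pipeline: simulate/ingest -> rarefy -> beta diversity ->
screen -> index validation -> source tracking.

A single :class:`PipelineConfig` (usually a TOML file) drives the run.
All randomness derives from one global seed via fixed per-stage
offsets, so any stage can be rerun in isolation; a :class:`RunManifest`
records the config, per-stage wall time, output checksums and warnings,
and is written (possibly partial) even when a stage fails.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import tables as tio
from .simulate import SyntheticConfig, simulate_tree, simulate_two_group_tables, \
    simulate_fmt_sinks
from .diversity import rarefy, unweighted_unifrac, bray_curtis, pcoa, permanova
from .screen import effect_size, select_signature
from .index import index_report
from .sourcetracking import fit_sources, track_all, summarize_by_population

logger = logging.getLogger("microsig")

STAGE_SEED_OFFSETS = {
    "simulate": 0, "rarefy": 1, "permanova": 2,
    "screen": 3, "sinks": 4, "track": 5,
}


class ConfigError(ValueError):
    """The pipeline configuration is invalid."""


class StageError(RuntimeError):
    """A pipeline stage failed; downstream stages were not run."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "microsig_out"
    seed: int = 0
    # either simulate (dict of SyntheticConfig fields) or inputs
    # (dict with table/metadata/tree paths) must be provided
    simulate: dict | None = None
    inputs: dict | None = None
    rarefy_depth: int = 2000
    permanova_n_perm: int = 999
    screen: dict = field(default_factory=dict)       # alpha, threshold, n_boot, ...
    index: dict = field(default_factory=dict)        # objective, positive_group
    sinks: dict = field(default_factory=dict)        # n_per_arm, depth, mixing_*
    track: dict = field(default_factory=dict)        # chain parameters

    def __post_init__(self):
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError("exactly one of [simulate] or [inputs] must be given")
        if self.inputs is not None:
            for key in ("table", "metadata", "tree"):
                if key not in self.inputs:
                    raise ConfigError(f"[inputs] must name a {key!r} path")
                if not Path(self.inputs[key]).exists():
                    raise ConfigError(f"input path does not exist: {self.inputs[key]}")

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        try:
            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        except (OSError, tomllib.TOMLDecodeError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunManifest:
    version: str
    config: dict
    stages: dict = field(default_factory=dict)       # stage -> wall seconds
    outputs: dict = field(default_factory=dict)      # relpath -> sha256
    warnings: list = field(default_factory=list)
    error: str | None = None

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    return (config.seed + STAGE_SEED_OFFSETS[stage]) % (2**31)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage in dependency order, writing outputs to ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, config=asdict(config))
    caught: list[warnings.WarningMessage] = []

    def register(name: str) -> Path:
        path = outdir / name
        manifest.outputs[name] = None  # filled after the stage completes
        return path

    def finish_stage(stage: str, started: float):
        manifest.stages[stage] = round(time.perf_counter() - started, 4)
        for name, digest in list(manifest.outputs.items()):
            if digest is None:
                manifest.outputs[name] = _sha256(outdir / name)
        for w in caught:
            msg = f"{stage}: {w.message}"
            if msg not in manifest.warnings:
                manifest.warnings.append(msg)
        caught.clear()
        logger.info("stage %s done in %.2fs", stage, manifest.stages[stage])

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            _run_stages(config, outdir, manifest, register, finish_stage)
    except StageError as exc:
        manifest.error = str(exc)
        manifest.outputs = {k: v for k, v in manifest.outputs.items() if v is not None}
        manifest.write(outdir / "manifest.json")
        raise
    manifest.write(outdir / "manifest.json")
    return manifest


def _run_stages(config, outdir, manifest, register, finish_stage):
    # --- simulate or ingest -------------------------------------------------
    t0 = time.perf_counter()
    try:
        if config.simulate is not None:
            sim_params = {k: v for k, v in config.simulate.items() if k != "seed"}
            sim = SyntheticConfig(seed=_stage_seed(config, "simulate"),
                                  **sim_params)
            table, meta, truth = simulate_two_group_tables(sim)
            tree = simulate_tree(sim.n_taxa, seed=_stage_seed(config, "simulate"))
            with open(register("truth.json"), "w") as fh:
                json.dump({"signature_taxa": list(truth.signature_taxa),
                           "directions": truth.directions}, fh, indent=2,
                          sort_keys=True)
        else:
            table = tio.read_taxon_table(config.inputs["table"])
            meta = tio.read_sample_metadata(config.inputs["metadata"])
            tree = tio.read_tree(config.inputs["tree"])
        tio.write_taxon_table(table, register("table.tsv"))
        tio.write_sample_metadata(meta, register("metadata.tsv"))
        tio.write_tree(tree, register("tree.nwk"))
    except (ValueError, OSError) as exc:
        raise StageError("simulate", str(exc)) from exc
    finish_stage("simulate", t0)
    group_labels = list(pd.unique(meta["group"]))

    # --- rarefy -------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        rare = rarefy(table, config.rarefy_depth, seed=_stage_seed(config, "rarefy"))
        tio.write_taxon_table(rare, register("rarefied.tsv"))
        rel = rare.to_relative()
    except ValueError as exc:
        raise StageError("rarefy", str(exc)) from exc
    finish_stage("rarefy", t0)

    # --- beta diversity -----------------------------------------------------
    t0 = time.perf_counter()
    try:
        uf = unweighted_unifrac(tree, rare)
        bc = bray_curtis(rel)
        tio.write_distance_matrix(uf, register("unifrac.tsv"))
        tio.write_distance_matrix(bc, register("braycurtis.tsv"))
        ord_res = pcoa(uf)
        ord_res.samples.to_csv(register("pcoa_coords.tsv"), sep="\t")
        pd.DataFrame({"eigenvalue": ord_res.eigvals}).to_csv(
            register("pcoa_eigenvalues.tsv"), sep="\t", index_label="axis")
        perm = permanova(uf, meta.loc[rare.sample_ids, "group"],
                         n_perm=config.permanova_n_perm,
                         seed=_stage_seed(config, "permanova"))
        with open(register("permanova.json"), "w") as fh:
            json.dump({"pseudo_f": perm.pseudo_f, "p_value": perm.p_value,
                       "n_permutations": perm.n_permutations, "seed": perm.seed},
                      fh, indent=2, sort_keys=True)
    except ValueError as exc:
        raise StageError("beta_diversity", str(exc)) from exc
    finish_stage("beta_diversity", t0)

    # --- screen -------------------------------------------------------------
    t0 = time.perf_counter()
    try:
        res = effect_size(rel, meta.loc[rare.sample_ids, "group"],
                          seed=_stage_seed(config, "screen"), **config.screen)
        res.frame.to_csv(register("screen.tsv"), sep="\t", index_label="taxon")
        enriched_counts = res.frame.loc[res.frame["passed"], "enriched_group"] \
            .value_counts()
        target_group = (config.index.get("positive_group")
                        or (enriched_counts.index[0] if len(enriched_counts)
                            else group_labels[-1]))
        panel = select_signature(res, group=target_group)
        panel.save(register("panel.txt"))
    except ValueError as exc:
        raise StageError("screen", str(exc)) from exc
    finish_stage("screen", t0)

    # --- index --------------------------------------------------------------
    t0 = time.perf_counter()
    if len(panel) == 0:
        raise StageError("index", "signature panel is empty; cannot build an index")
    try:
        report = index_report(rel, panel, meta.loc[rare.sample_ids, "group"],
                              positive_group=config.index.get("positive_group"),
                              objective=config.index.get("objective", "accuracy"))
        report.index.to_csv(register("index.tsv"), sep="\t", index_label="sample_id")
        report.roc_points.to_csv(register("roc.tsv"), sep="\t", index=False)
        with open(register("index_report.json"), "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    except ValueError as exc:
        raise StageError("index", str(exc)) from exc
    finish_stage("index", t0)

    # --- FMT sinks + source tracking ----------------------------------------
    t0 = time.perf_counter()
    try:
        sinks_cfg = dict(config.sinks)
        n_per_arm = int(sinks_cfg.get("n_per_arm", 5))
        sink_depth = int(sinks_cfg.get("depth", 20000))
        mix_donor = float(sinks_cfg.get("mixing_donor", 0.7))
        mix_recipient = float(sinks_cfg.get("mixing_recipient", 0.2))
        mix_unknown = float(sinks_cfg.get("mixing_unknown", 0.1))
        profiles = rel.fractions.groupby(meta.loc[rare.sample_ids, "group"]).mean()
        profiles = profiles.div(profiles.sum(axis=1), axis=0)
        rng = np.random.default_rng(_stage_seed(config, "sinks"))
        unk = rng.lognormal(0.0, 1.5, size=profiles.shape[1])
        unknown_profile = pd.Series(unk / unk.sum(), index=profiles.columns)
        a, b = profiles.index[0], profiles.index[1]
        sink_tables, truths, arm_of = [], [], {}
        for donor, recipient in ((a, b), (b, a)):
            mixing = {donor: mix_donor, recipient: mix_recipient}
            vec = [mixing[src] for src in profiles.index] + [mix_unknown]
            arm = f"{donor}_to_{recipient}"
            t_arm, truth_arm = simulate_fmt_sinks(
                profiles, vec, unknown_profile, depth=sink_depth,
                n_sinks=n_per_arm, seed=_stage_seed(config, "sinks"),
                sink_prefix=arm)
            sink_tables.append(t_arm.counts)
            truths.append(truth_arm.mixing)
            arm_of.update({s: arm for s in t_arm.sample_ids})
        sinks = tio.TaxonTable(pd.concat(sink_tables))
        tio.write_taxon_table(sinks, register("sinks.tsv"))
        pd.concat(truths).to_csv(register("sink_truth.tsv"), sep="\t",
                                 index_label="sample_id")

        model = fit_sources(rare, meta.loc[rare.sample_ids, "group"],
                            source_groups=list(profiles.index))
        track_kwargs = dict(config.track)
        if track_kwargs.get("rarefy_depth") == 0:  # TOML has no null
            track_kwargs["rarefy_depth"] = None
        props = track_all(sinks, model, seed=_stage_seed(config, "track"),
                          **track_kwargs)
        props.to_csv(register("sink_proportions.tsv"), sep="\t",
                     index_label="sample_id")
        summary = summarize_by_population(props, pd.Series(arm_of))
        summary.to_csv(register("arm_summary.tsv"), sep="\t", index_label="arm")
    except ValueError as exc:
        raise StageError("source_tracking", str(exc)) from exc
    finish_stage("source_tracking", t0)
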