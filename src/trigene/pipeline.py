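"""Config-driven orchestration of the full analysis pipeline.

A run is described by a single YAML/dict config (:class:`RunConfig`): either
a simulation block (demography preset + sample sizes) or input paths (VCF,
popmap, optional genetic map and gene BED), the population roles for each
stage, thresholds, seeds and an output directory.  ``run_pipeline`` executes
the requested stages in dependency order, writes every artifact as TSV/VCF/
Newick alongside a manifest (inputs, seeds, package version, parameter
hash), and keeps going when an optional stage fails (the failure is recorded
in the manifest and reflected in the exit status).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io as tio
from .datatypes import GeneIntervals, GenotypeMatrix, PopulationMap
from .demography import DemographyModel, pbs_null_model, yunnan_model
from .fstats import gene_flow_scan
from .lddemog import binned_r2, ne_trajectory, trajectory_frame
from .popdiff import fst_nj_tree, pairwise_fst_matrix, nucleotide_diversity
from .roh import roh_call, roh_classify_totals, segments_frame
from .selection import build_null, gene_pbs_scan, pbs_pvalues, site_filter_pbs
from .simdata import default_popmap, emit_dataset, genes_from_regions, simulate_neutral
from .varclass import exclude_singletons, flag_novel, novelty_counts

log = logging.getLogger("trigene.pipeline")

_MODEL_PRESETS = {"yunnan": yunnan_model, "pbs_null": pbs_null_model}

DEFAULT_THRESHOLDS = {
    "alpha_extreme": 0.01,
    "alpha_strong": 0.05,
    "pbs_variant_threshold": 0.1,
    "min_depth": 50.0,
    "max_missing": 0.05,
    "roh_gt_error_phred": 30.0,
    "ld_max_cm": 0.25,
    "z_threshold": 3.0,
}


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: ["simulate"])
    simulate: dict | None = None
    inputs: dict | None = None
    roles: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    VALID_STAGES = (
        "simulate", "filter", "diversity", "fst", "fstats", "pbs", "ldne",
        "roh", "varclass",
    )

    def __post_init__(self) -> None:
        errors = []
        for s in self.stages:
            if s not in self.VALID_STAGES:
                errors.append(f"unknown stage {s!r}")
        if self.simulate is None and self.inputs is None:
            errors.append("config needs either a 'simulate' block or 'inputs' paths")
        merged = dict(DEFAULT_THRESHOLDS)
        for k, v in self.thresholds.items():
            if k not in DEFAULT_THRESHOLDS:
                errors.append(f"unknown threshold {k!r}")
            else:
                merged[k] = v
        self.thresholds = merged
        if not (0 < self.thresholds["alpha_extreme"] <= self.thresholds["alpha_strong"] < 1):
            errors.append("alpha thresholds must satisfy 0 < extreme <= strong < 1")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir,
            "seed": self.seed,
            "stages": list(self.stages),
            "simulate": self.simulate,
            "inputs": self.inputs,
            "roles": self.roles,
            "thresholds": self.thresholds,
        }


def _load_or_simulate(cfg: RunConfig, rng_seed: np.random.SeedSequence):
    if cfg.simulate is not None:
        sim = dict(cfg.simulate)
        preset = sim.pop("model", "yunnan")
        model_kwargs = sim.pop("model_kwargs", {})
        if preset not in _MODEL_PRESETS:
            raise ValueError(f"unknown demography preset {preset!r}")
        model: DemographyModel = _MODEL_PRESETS[preset](**model_kwargs)
        n_samples = sim.pop("n_samples")
        geno = simulate_neutral(model, n_samples, seed=rng_seed, **sim)
        popmap = default_popmap(n_samples)
        genes = genes_from_regions(geno)
        return geno, popmap, genes
    paths = cfg.inputs
    geno = tio.read_vcf(paths["vcf"])
    popmap = tio.read_popmap(paths["popmap"])
    if paths.get("map"):
        geno = tio.attach_genetic_map(geno, tio.read_plink_map(paths["map"]))
    genes = tio.read_bed(paths["bed"]) if paths.get("bed") else None
    return geno, popmap, genes


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: s for name, s in zip(
        ["simulate", "pbs_null"], ss.spawn(2)
    )}
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha1(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12],
        "stages": {},
        "artifacts": {},
        "failures": {},
    }
    th = config.thresholds
    t0 = time.time()
    geno, popmap, genes = _load_or_simulate(config, seeds["simulate"])
    if "simulate" in config.stages:
        paths = emit_dataset(geno, popmap, genes, outdir / "dataset")
        manifest["artifacts"].update(paths)
        manifest["stages"]["simulate"] = {"n_variants": geno.n_variants,
                                          "n_samples": geno.n_samples}
    if "filter" in config.stages:
        try:
            geno = site_filter_pbs(geno, th["min_depth"], th["max_missing"])
        except ValueError:
            geno = site_filter_pbs(geno, None, th["max_missing"])
        manifest["stages"]["filter"] = {"n_variants": geno.n_variants}

    def _stage(name, fn):
        if name not in config.stages:
            return
        t = time.time()
        try:
            fn()
            manifest["stages"].setdefault(name, {})["seconds"] = round(time.time() - t, 2)
            log.info("stage %s done in %.1fs", name, time.time() - t)
        except Exception as exc:  # optional stage failure must not abort the run
            log.error("stage %s failed: %s", name, exc)
            manifest["failures"][name] = str(exc)

    def do_diversity():
        rows = [{"population": p, "pi": nucleotide_diversity(geno, popmap, p)}
                for p in popmap.populations]
        import pandas as pd

        path = outdir / "diversity.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        manifest["artifacts"]["diversity"] = str(path)

    def do_fst():
        fstm = pairwise_fst_matrix(geno, popmap)
        path = outdir / "fst_matrix.tsv"
        fstm.to_frame().to_csv(path, sep="\t")
        manifest["artifacts"]["fst_matrix"] = str(path)
        if len(fstm.labels) >= 3:
            tree = fst_nj_tree(fstm)
            tpath = outdir / "fst_nj.nwk"
            tpath.write_text(tree + "\n")
            manifest["artifacts"]["fst_nj_tree"] = str(tpath)

    def do_fstats():
        roles = config.roles
        scan = gene_flow_scan(
            geno, popmap,
            [tuple(p) for p in roles["pairs"]], roles["donors"], roles["outgroup"],
            z_threshold=th["z_threshold"],
        )
        path = outdir / "gene_flow_scan.tsv"
        scan.to_csv(path, sep="\t", index=False)
        manifest["artifacts"]["gene_flow_scan"] = str(path)

    def do_pbs():
        roles = config.roles
        triple = tuple(roles["pbs_triple"])
        table = gene_pbs_scan(geno, popmap, genes, triple)
        pbs_cfg = roles.get("pbs_null", {})
        if pbs_cfg:
            model = _MODEL_PRESETS[pbs_cfg.get("model", "pbs_null")](
                **pbs_cfg.get("model_kwargs", {})
            )
            null = build_null(
                model, tuple(pbs_cfg.get("triple", triple)),
                bins=sorted(table["n_snps"].map(lambda c: min(int(c), 100)).unique()),
                n_sim=pbs_cfg.get("n_sim", 1000),
                seed=int(seeds["pbs_null"].generate_state(1)[0] % (2**31)),
                gene_length=pbs_cfg.get("gene_length"),
                n_samples=pbs_cfg.get("n_samples"),
                burnin=pbs_cfg.get("burnin"),
            )
            table = pbs_pvalues(table, null)
            null_path = outdir / "pbs_null.json"
            null.to_json(null_path)
            manifest["artifacts"]["pbs_null"] = str(null_path)
        path = outdir / "pbs_scan.tsv"
        table.to_csv(path, sep="\t", index=False)
        manifest["artifacts"]["pbs_scan"] = str(path)

    def do_ldne():
        import pandas as pd

        frames = []
        for pop in config.roles.get("ldne_pops", popmap.populations):
            df = trajectory_frame(
                ne_trajectory(binned_r2(geno, popmap, pop, max_cm=th["ld_max_cm"]))
            )
            df.insert(0, "population", pop)
            frames.append(df)
        path = outdir / "ld_ne_trajectories.tsv"
        pd.concat(frames).to_csv(path, sep="\t", index=False)
        manifest["artifacts"]["ld_ne"] = str(path)

    def do_roh():
        segs = []
        for s in config.roles.get("roh_samples", geno.samples):
            segs.extend(roh_call(geno, s, gt_error_phred=th["roh_gt_error_phred"]))
        spath = outdir / "roh_segments.tsv"
        segments_frame(segs).to_csv(spath, sep="\t", index=False)
        tpath = outdir / "roh_totals.tsv"
        roh_classify_totals(segs).to_csv(tpath, sep="\t")
        manifest["artifacts"]["roh_segments"] = str(spath)
        manifest["artifacts"]["roh_totals"] = str(tpath)

    def do_varclass():
        catalogs = [
            tio.read_catalog(p) for p in config.roles.get("catalog_paths", [])
        ]
        novel = flag_novel(geno, catalogs)
        keep = exclude_singletons(geno, popmap, scope="cohort")
        tables = novelty_counts(geno, popmap, novel, keep)
        ppath = outdir / "novel_by_population.tsv"
        ipath = outdir / "novel_by_individual.tsv"
        tables["population"].to_csv(ppath, sep="\t", index=False)
        tables["individual"].to_csv(ipath, sep="\t", index=False)
        manifest["artifacts"]["novel_by_population"] = str(ppath)
        manifest["artifacts"]["novel_by_individual"] = str(ipath)

    _stage("diversity", do_diversity)
    _stage("fst", do_fst)
    _stage("fstats", do_fstats)
    _stage("pbs", do_pbs)
    _stage("ldne", do_ldne)
    _stage("roh", do_roh)
    _stage("varclass", do_varclass)

    manifest["seconds_total"] = round(time.time() - t0, 2)
    manifest["ok"] = not manifest["failures"]
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
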