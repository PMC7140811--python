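"""Orchestration: filter -> stats -> SFS -> fit as a configured pipeline.

A :class:`PipelineConfig` (loadable from YAML) names the inputs and per-stage
parameters; :func:`run_pipeline` executes the stages in order, writes
per-stage artifacts (filtered VCF, statistics tables, SFS text files, fit
JSON) into the output directory and returns a machine-readable report.
Every stage logs dropped-site counts; a stage failure raises with the stage
name, keeping earlier artifacts on disk.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import PopulationMap
from .filtering import FilterSpec, filter_sites, polarize
from .inference import DivergenceModel, OptimizerSchedule, delta_aic
from .sfs import build_projected_sfs
from .stats import (bootstrap_pi_ci, clinal_regression, amova,
                    geographic_distance_matrix, mantel_test, per_site_pi,
                    weir_cockerham)
from .vcfio import read_vcf, write_vcf

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str
    popmap: str
    coords: str | None = None
    outgroups: str | None = None          # file with one sample id per line
    out_dir: str = "helipop_out"
    seed: int = 1
    # filter stage
    min_sample_coverage: float = 0.5
    maf: float | None = None
    mac: int | None = 2
    thin_bp: int | None = 1000
    # stats stage
    n_boot: int = 1000
    mantel_perms: int = 10_000
    amova_perms: int = 1000
    clusters: dict = field(default_factory=dict)   # population -> cluster
    # sfs / fit stage
    wild_pops: list = field(default_factory=list)
    cult_pops: list = field(default_factory=list)
    projection: tuple = (30, 24)
    models: tuple = ("A", "B", "C")
    grids: tuple = (40, 50, 60)
    dt_fac: float = 5e-3
    schedule: dict = field(default_factory=dict)
    mu: float = 6.1e-9
    L: float = 11.7e6
    gen_time: float = 1.0
    run_stats: bool = True
    run_fit: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def validate(self):
        for name in ("vcf", "popmap"):
            p = getattr(self, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"{name} path missing: {p}")
        for name in ("coords", "outgroups"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path missing: {p}")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") \
                    from e
        return wrapper
    return deco


@_stage("filter")
def _run_filter(cfg: PipelineConfig, out: Path):
    table = read_vcf(cfg.vcf)
    popmap = PopulationMap.read(cfg.popmap, cfg.coords)
    n_raw = table.n_sites
    spec = FilterSpec(min_sample_coverage=cfg.min_sample_coverage,
                      maf_threshold=cfg.maf, mac_threshold=cfg.mac,
                      thin_bp=cfg.thin_bp)
    table = filter_sites(table, spec)
    n_filtered = table.n_sites
    polarized = None
    if cfg.outgroups:
        outgroups = [ln.strip() for ln in Path(cfg.outgroups).read_text()
                     .splitlines() if ln.strip()]
        polarized = polarize(table, outgroups)
        write_vcf(polarized, out / "polarized.vcf")
    if table.n_sites:
        write_vcf(table, out / "filtered.vcf")
    report = {"sites_input": n_raw, "sites_filtered": n_filtered,
              "sites_polarized": None if polarized is None
              else polarized.n_sites}
    return table, polarized, popmap, report


@_stage("stats")
def _run_stats(cfg: PipelineConfig, table, popmap: PopulationMap, out: Path):
    ingroup = {s: p for s, p in popmap.assignments.items()
               if p != "outgroup" and s in table.samples}
    pm = PopulationMap(ingroup, popmap.coords)
    sub = table.take_samples(list(ingroup))
    report = {}
    rows = []
    for pop in pm.populations:
        pis = per_site_pi(sub, pm.sample_indices(sub, pop))
        est = bootstrap_pi_ci(pis, n_boot=cfg.n_boot, seed=cfg.seed)
        rows.append((pop, est.mean_pi, est.ci_low, est.ci_high, est.n_sites))
    with open(out / "pi_per_population.tsv", "w") as fh:
        fh.write("population\tmean_pi\tci_low\tci_high\tn_sites\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
    report["pi"] = {r[0]: r[1] for r in rows}

    fs = weir_cockerham(sub, pm)
    report["fst_global"] = fs.fst_global
    report["fis_global"] = fs.fis_global
    np.savetxt(out / "fst_pairwise.tsv", fs.fst_pairwise, delimiter="\t",
               header="\t".join(fs.populations))

    if pm.coords:
        geo = geographic_distance_matrix(pm)
        mr = mantel_test(geo, fs.fst_pairwise, n_perm=cfg.mantel_perms,
                         seed=cfg.seed)
        report["mantel"] = {"r": mr.r, "p": mr.p, "n_perm": mr.n_perm}
        lats = [pm.coords[p][0] for p in pm.populations]
        reg = clinal_regression([report["pi"][p] for p in pm.populations],
                                lats)
        report["cline_latitude"] = {"slope": reg.slope, "r": reg.r,
                                    "F": reg.F, "p": reg.p}
    if cfg.clusters:
        am = amova(sub, pm, cfg.clusters, n_perm=cfg.amova_perms,
                   seed=cfg.seed)
        report["amova"] = {"percentages": am.percentages,
                           "p_values": am.p_values}
    with open(out / "stats.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


@_stage("sfs")
def _run_sfs(cfg: PipelineConfig, polarized, popmap, out: Path):
    if polarized is None:
        raise ValueError("SFS stage needs polarized sites (set outgroups)")
    assign = {}
    for s, p in popmap.assignments.items():
        if p in cfg.wild_pops:
            assign[s] = "wild"
        elif p in cfg.cult_pops:
            assign[s] = "cultivated"
    pm = PopulationMap(assign)
    sfs = build_projected_sfs(polarized, pm, ("wild", "cultivated"),
                              tuple(cfg.projection))
    sfs.to_file(out / "joint_sfs.txt")
    return sfs


@_stage("fit")
def _run_fit(cfg: PipelineConfig, sfs, out: Path):
    schedule = OptimizerSchedule(**cfg.schedule) if cfg.schedule \
        else OptimizerSchedule.reduced()
    fits = {}
    for model in cfg.models:
        dm = DivergenceModel(sfs, model=model, grids=tuple(cfg.grids),
                             dt_fac=cfg.dt_fac)
        fit = dm.fit(schedule=schedule, seed=cfg.seed)
        fit.convert(cfg.mu, cfg.L, cfg.gen_time)
        fits[model] = fit
    aics = {m: f.aic for m, f in fits.items()}
    deltas = dict(zip(aics, delta_aic(list(aics.values()))))
    report = {}
    for m, f in fits.items():
        report[m] = {
            "ll": f.log_likelihood, "aic": f.aic, "delta_aic": deltas[m],
            "theta_hat": f.theta_hat,
            "params": {n: getattr(f.params, n)
                       for n in f.params.free_param_names(m)},
            "sd": f.sd, "converted": f.converted,
        }
    report["best_model"] = min(aics, key=aics.get)
    with open(out / "fits.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all configured stages; returns the machine-readable report."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=logging.INFO,
        handlers=[logging.StreamHandler(),
                  logging.FileHandler(out / "pipeline.log")],
        force=False)
    report = {"version": __version__, "seed": cfg.seed,
              "config": {k: v for k, v in vars(cfg).items()}}
    table, polarized, popmap, filt_report = _run_filter(cfg, out)
    report["filter"] = filt_report
    if cfg.run_stats:
        report["stats"] = _run_stats(cfg, table, popmap, out)
    if cfg.run_fit and cfg.wild_pops and cfg.cult_pops:
        sfs = _run_sfs(cfg, polarized, popmap, out)
        report["fit"] = _run_fit(cfg, sfs, out)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
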