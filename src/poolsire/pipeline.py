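"""End-to-end orchestration: simulate -> build-grm -> regress -> gblup -> report.

A run is driven by a :class:`RunConfig` (usually loaded from YAML) naming
either a simulation config or a set of input files — never both — plus stage
toggles and module flags.  Every artifact lands in the output directory and
a manifest records versions, seeds, input hashes and per-stage timings, so a
run can be reproduced from the manifest alone.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import FlockConfig
from .errors import AnalysisError, ConfigError
from .flock import simulate_flock
from .gblup import fit_gblup, slope_gebv_concordance
from .grm import build_hgrm
from .io import (
    align_loci,
    read_pool_table,
    read_sire_table,
    write_grm,
    write_pool_table,
    write_sire_table,
)
from .regression import DEFAULT_LEVELS, fit_sire_slopes, summarize_significance

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "build-grm", "regress", "gblup", "report")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (simulation XOR file inputs)."""

    outdir: Path
    simulation: FlockConfig | None = None
    sire_table: Path | None = None
    pool_table: Path | None = None
    pool_meta: Path | None = None
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    dosage_input: bool = False
    freq_source: str = "all"
    weight_freq_by_members: bool = False
    use_h: bool = True
    weight_by_members: bool = False
    n_perm: int = 100
    n_sim: int = 2000
    levels: tuple[float, ...] = DEFAULT_LEVELS
    gzip_grm: bool = False

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        from_files = self.sire_table is not None or self.pool_table is not None
        if self.simulation is not None and from_files:
            raise ConfigError("give a simulation config or input files, not both")
        if self.simulation is None and not from_files and "simulate" in self.stages:
            raise ConfigError("no input source: need simulation or sire/pool tables")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = FlockConfig(**sim)
        stages = tuple(raw.pop("stages", ALL_STAGES))
        levels = tuple(raw.pop("levels", DEFAULT_LEVELS))
        return cls(simulation=sim, stages=stages, levels=levels, **raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns (and writes) the manifest."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logging.getLogger("poolsire").addHandler(fh)
    manifest: dict = {
        "poolsire_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "inputs": {},
        "timings_s": {},
        "artifacts": {},
    }
    try:
        _run_stages(config, out, manifest)
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        logging.getLogger("poolsire").removeHandler(fh)
        fh.close()
    return manifest


def _run_stages(config: RunConfig, out: Path, manifest: dict) -> None:
    sires = pools = None
    truth = None

    if "simulate" in config.stages:
        t0 = time.perf_counter()
        if config.simulation is None:
            raise AnalysisError("simulate stage enabled but no simulation config")
        flock = simulate_flock(config.simulation)
        sires, pools, truth = flock.sires, flock.pools, flock.sire_truth
        write_sire_table(sires, out / "sires.tsv")
        write_pool_table(pools, out / "pools.tsv", out / "pool_meta.csv")
        truth.to_csv(out / "sire_truth.csv")
        manifest["inputs"]["simulation"] = config.simulation.to_dict()
        manifest["artifacts"]["sires"] = str(out / "sires.tsv")
        manifest["artifacts"]["pools"] = str(out / "pools.tsv")
        manifest["timings_s"]["simulate"] = round(time.perf_counter() - t0, 3)
    elif config.sire_table is not None:
        sires = read_sire_table(config.sire_table, dosage=config.dosage_input)
        pools = read_pool_table(config.pool_table, meta_path=config.pool_meta)
        for key in ("sire_table", "pool_table", "pool_meta"):
            p = getattr(config, key)
            if p is not None:
                manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(Path(p))}
        n_before = len(sires.loci) + len(pools.loci)
        sires, pools = align_loci(sires, pools)
        manifest["inputs"]["dropped_loci"] = n_before - 2 * len(sires.loci)

    grm = None
    if "build-grm" in config.stages:
        if sires is None or pools is None:
            raise AnalysisError("build-grm stage needs sire and pool tables upstream")
        t0 = time.perf_counter()
        grm = build_hgrm(
            sires, pools,
            freq_source=config.freq_source,
            weight_freq_by_members=config.weight_freq_by_members,
        )
        write_grm(grm.gstar, grm.roles, out / "gstar", grm.pair_counts, config.gzip_grm)
        write_grm(grm.h, grm.roles, out / "hgrm", grm.pair_counts, config.gzip_grm)
        (out / "grm_info.json").write_text(json.dumps({
            "denominator": grm.denominator,
            "n_loci": grm.n_loci,
            "n_sires": int((grm.roles == "sire").sum()),
            "n_pools": int((grm.roles == "pool").sum()),
        }, indent=2))
        manifest["artifacts"]["hgrm"] = str(out / "hgrm.grm")
        manifest["timings_s"]["build-grm"] = round(time.perf_counter() - t0, 3)

    slopes = None
    if "regress" in config.stages:
        if grm is None:
            raise AnalysisError("regress stage needs the h-GRM upstream")
        t0 = time.perf_counter()
        slopes = fit_sire_slopes(grm, pools.meta, use_h=config.use_h)
        ranked = slopes.assign(rank=slopes["beta2"].rank().astype(int))
        ranked.to_csv(out / "sire_slopes.tsv", sep="\t", float_format="%.10g")
        summary = summarize_significance(
            grm, pools.meta, n_perm=config.n_perm, n_sim=config.n_sim,
            seed=config.seed, levels=config.levels, use_h=config.use_h,
        )
        (out / "significance.json").write_text(json.dumps({
            "levels": list(summary.levels),
            "observed": summary.observed_proportions.tolist(),
            "permuted": summary.permuted_proportions.tolist(),
            "n_perm": summary.n_perm,
            "n_sires": summary.n_sires,
            "chisq_p": summary.chisq_p,
        }, indent=2))
        manifest["artifacts"]["sire_slopes"] = str(out / "sire_slopes.tsv")
        manifest["timings_s"]["regress"] = round(time.perf_counter() - t0, 3)

    fit = None
    if "gblup" in config.stages:
        if grm is None:
            raise AnalysisError("gblup stage needs the h-GRM upstream")
        t0 = time.perf_counter()
        fit = fit_gblup(grm, pools.meta, use_h=config.use_h,
                        weight_by_members=config.weight_by_members)
        sire_ids = grm.roles.index[grm.roles == "sire"]
        gebv = fit.gebv.loc[sire_ids]
        gebv.to_frame().assign(rank=gebv.rank().astype(int)).to_csv(
            out / "sire_gebv.tsv", sep="\t", float_format="%.10g")
        (out / "gblup.json").write_text(json.dumps({
            "sigma_g2": fit.sigma_g2,
            "sigma_e2": fit.sigma_e2,
            "fixed_effects": fit.fixed_effects.to_dict(),
            "log_reml": fit.log_reml,
            "converged": fit.converged,
            "boundary": fit.boundary,
        }, indent=2))
        manifest["artifacts"]["sire_gebv"] = str(out / "sire_gebv.tsv")
        manifest["timings_s"]["gblup"] = round(time.perf_counter() - t0, 3)

    if "report" in config.stages:
        if fit is None:
            raise AnalysisError("report stage needs the gblup stage upstream")
        t0 = time.perf_counter()
        sire_ids = grm.roles.index[grm.roles == "sire"]
        report = pd.DataFrame({"gebv": fit.gebv.loc[sire_ids]})
        if slopes is not None:
            report["beta2"] = slopes["beta2"]
            report["p_value"] = slopes["p_value"]
            conc = slope_gebv_concordance(slopes["beta2"], fit.gebv.loc[sire_ids])
            manifest["concordance"] = conc
        else:
            log.warning("regress stage disabled; slope-GEBV concordance skipped")
        if truth is not None:
            report["true_bv"] = truth.reindex(sire_ids)
        report.assign(rank=report["gebv"].rank().astype(int)).sort_values(
            "gebv").to_csv(out / "sire_report.tsv", sep="\t", float_format="%.10g")
        manifest["artifacts"]["sire_report"] = str(out / "sire_report.tsv")
        manifest["timings_s"]["report"] = round(time.perf_counter() - t0, 3)
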