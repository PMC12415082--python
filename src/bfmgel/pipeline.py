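"""End-to-end pipeline: assemble -> equilibrate -> crosslink -> network
metrics -> BMC extraction -> deswell -> virtual TEM -> quantification ->
scattering, over an ensemble of seeds.

Results are returned as plain dicts (and optionally written to an output
directory together with a manifest of config, seeds and file checksums).
Ensemble means and standard errors are reported over the seed replicates;
the full-scale protocol uses >= 20 starting conformations, the scaled
default is 5.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .builders import SolutionSpec, assemble_solution
from .crosslink import crosslink_until, extent_of_reaction
from .deswell import (aggregate_and_void_stats, deswell_run, extract_bmc,
                      relocate_cluster)
from .imaging import quantify, virtual_tem
from .lattice import EnergyModel, audit, write_state
from .netgraph import biggest_molecule_cluster, bmc_metrics, molecule_graph
from .scatter import intensity_profile, powerlaw_slope, write_profile
from .builders import LATTICE_UNIT_NM
from .lattice import SPECIES_CODES


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage, message):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Scaled-default configuration of the simulation-to-analysis chain."""

    gamma: float = 0.4
    c_hep_mM: float = 1.5
    box_edge: int = 128
    equilibration_mcs: int = 20_000
    p_target: float = 0.90
    crosslink_max_mcs: int = 2_000_000
    capture: str = "face"
    p_react: float = 0.05
    deswell_epsilon: float = -0.30
    deswell_mcs: int = 100_000
    deswell_relocate: bool = False
    slab_thickness_nm: float = 70.0
    pixel_size_nm: float = 0.5
    tem_noise_level: float = 0.03
    scatter_q_min: float = 0.3
    scatter_q_max: float = 4.0
    scatter_q_points: int = 60
    scatter_subsample: int = 1500
    n_seeds: int = 5
    base_seed: int = 1

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_seed(cfg: PipelineConfig, seed: int, outdir: Path | None = None):
    """Run the full chain for one starting conformation."""
    result = {"seed": seed}
    files = []

    def _stage(name):
        result["stage"] = name

    try:
        _stage("assemble")
        spec = SolutionSpec(gamma=cfg.gamma, c_hep_mM=cfg.c_hep_mM,
                            box_edge=cfg.box_edge,
                            equilibration_mcs=cfg.equilibration_mcs,
                            seed=seed)
        state = assemble_solution(spec)
        initial = state.copy()
        audit(state)
        result["n_monomers"] = state.n_monomers
        result["volume_fraction"] = state.volume_fraction()

        _stage("crosslink")
        state, log = crosslink_until(
            state, p_target=cfg.p_target, max_mcs=cfg.crosslink_max_mcs,
            rng=np.random.default_rng(seed + 7_000_003),
            capture=cfg.capture, p_react=cfg.p_react)
        audit(state, reference=initial)
        result["p"] = extent_of_reaction(state)
        result["crosslink_completed"] = bool(log.completed)
        result["crosslink_mcs"] = float(log.p_trajectory[-1, 0])

        _stage("extract_bmc")
        if state.crosslink_count() == 0:
            raise ValueError("no crosslinks formed; BMC is empty")
        graph = molecule_graph(state)
        bmc = biggest_molecule_cluster(graph)
        metrics = bmc_metrics(graph, bmc, state=state)
        result["metrics"] = metrics.to_dict()
        bmc_state = extract_bmc(state)
        if cfg.deswell_relocate:
            bmc_state = relocate_cluster(bmc_state, 2 * cfg.box_edge)

        _stage("deswell")
        energy = EnergyModel(epsilon_pp=cfg.deswell_epsilon)
        pre_stats = aggregate_and_void_stats(bmc_state, energy,
                                             rng=seed + 11)
        bmc_state, traj = deswell_run(
            bmc_state, n_mcs=cfg.deswell_mcs, energy=energy,
            rng=np.random.default_rng(seed + 13_000_017))
        audit(bmc_state)
        post_stats = aggregate_and_void_stats(bmc_state, energy,
                                              rng=seed + 11)
        result["void_radius_pre"] = pre_stats.mean_void_radius
        result["void_radius_post"] = post_stats.mean_void_radius
        result["void_radius_post_nm"] = post_stats.mean_void_radius \
            * LATTICE_UNIT_NM
        result["peg_cluster_max_pre"] = int(
            pre_stats.peg_cluster_sizes.max()) \
            if len(pre_stats.peg_cluster_sizes) else 0
        result["peg_cluster_max_post"] = int(
            post_stats.peg_cluster_sizes.max()) \
            if len(post_stats.peg_cluster_sizes) else 0
        result["contact_energy_trajectory"] = \
            traj["energy_trajectory"].tolist()

        _stage("virtual_tem")
        slab_nm = min(cfg.slab_thickness_nm,
                      bmc_state.box_edge * LATTICE_UNIT_NM)
        image = virtual_tem(bmc_state, slab_origin=0,
                            slab_thickness_nm=slab_nm,
                            pixel_size_nm=cfg.pixel_size_nm,
                            noise_level=cfg.tem_noise_level,
                            seed=seed + 17)

        _stage("quantify")
        quant = quantify(image)
        result["quant"] = quant.to_dict()

        _stage("scatter")
        hep = bmc_state.positions[bmc_state.species
                                  == SPECIES_CODES["HEP"]]
        q = np.linspace(cfg.scatter_q_min, cfg.scatter_q_max,
                        cfg.scatter_q_points)
        profile = intensity_profile(hep * LATTICE_UNIT_NM, q,
                                    n_subsample=cfg.scatter_subsample,
                                    seed=seed + 19, label=f"seed{seed}")
        try:
            slope, err = powerlaw_slope(profile, 1.0, cfg.scatter_q_max)
            result["powerlaw_slope"] = slope
            result["powerlaw_stderr"] = err
        except ValueError:
            result["powerlaw_slope"] = None

        if outdir is not None:
            outdir.mkdir(parents=True, exist_ok=True)
            sd = outdir / f"seed_{seed}"
            sd.mkdir(exist_ok=True)
            write_state(bmc_state, sd / "bmc_deswollen.txt")
            log.trajectory_to_csv(sd / "p_trajectory.csv")
            log.events_to_csv(sd / "reaction_events.csv")
            image.save(sd / "virtual_tem.tif")
            write_profile(profile, sd / "scattering.txt")
            (sd / "metrics.json").write_text(
                json.dumps(_jsonable(result), indent=2))
            files = [sd / n for n in ("bmc_deswollen.txt",
                                      "p_trajectory.csv",
                                      "reaction_events.csv",
                                      "virtual_tem.tif",
                                      "scattering.txt", "metrics.json")]
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(result.get("stage", "unknown"), str(exc)) \
            from exc
    result.pop("stage", None)
    return result, files


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _ensemble_summary(per_seed):
    keys = ["p", "void_radius_post", "powerlaw_slope"]
    metric_keys = ["gamma_bmc", "f_hep_bmc", "incorporation_peg",
                   "incorporation_hep", "zeta_per_strand",
                   "bmc_mass_fraction"]
    summary = {}
    for k in keys:
        vals = [r[k] for r in per_seed if r.get(k) is not None]
        if vals:
            summary[k] = {"mean": float(np.mean(vals)),
                          "sem": float(np.std(vals) / max(1, np.sqrt(
                              len(vals))))}
    for k in metric_keys:
        vals = [r["metrics"][k] for r in per_seed if "metrics" in r]
        if vals:
            summary[k] = {"mean": float(np.mean(vals)),
                          "sem": float(np.std(vals) / max(1, np.sqrt(
                              len(vals))))}
    return summary


def run_pipeline(cfg: PipelineConfig, outdir=None) -> dict:
    """Run the chain over ``cfg.n_seeds`` replicates.

    Returns ``{"config", "per_seed", "ensemble", "manifest"}``; with
    ``outdir`` all per-stage outputs plus ``manifest.json`` (config,
    seeds, version, file checksums) are written.
    """
    outdir = Path(outdir) if outdir is not None else None
    seeds = [cfg.base_seed + k for k in range(cfg.n_seeds)]
    per_seed = []
    all_files = []
    for seed in seeds:
        res, files = run_seed(cfg, seed, outdir)
        per_seed.append(res)
        all_files.extend(files)
    out = {"config": dataclasses.asdict(cfg), "per_seed": per_seed,
           "ensemble": _ensemble_summary(per_seed)}
    if outdir is not None:
        manifest = {
            "version": __version__, "seeds": seeds,
            "config": dataclasses.asdict(cfg),
            "files": {str(p.relative_to(outdir)): _sha256(p)
                      for p in all_files},
        }
        (outdir / "manifest.json").write_text(
            json.dumps(_jsonable(manifest), indent=2))
        (outdir / "results.json").write_text(
            json.dumps(_jsonable(out), indent=2))
        out["manifest"] = manifest
    return out
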