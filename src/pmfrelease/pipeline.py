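"""End-to-end demo pipeline: planted barriers -> umbrella sampling -> WHAM ->
barrier ranking -> rate ratios -> release-curve fits -> cluster analysis.

The demo reproduces the logic of the full free-energy release study on
synthetic data: each named compound gets a planted translocation well depth;
umbrella windows are simulated over the matrix->water coordinate; WHAM with
bootstrap errors recovers the profile and barrier; compounds are ranked and
compared by relative rates; illustrative power-law release curves are fitted;
and a planted aggregation configuration is cluster-analysed.  Every stage
writes its outputs under the run directory and every seed is recorded, so
each number in the final report is traceable to a stage file and a rerun with
the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import yaml

from . import io as pio
from .aggregation import cluster_trace, find_clusters
from .constants import DEFAULT_TEMPERATURE
from .release_kinetics import (
    barrier_relative_difference,
    fit_peppas,
    rank_compounds,
    relative_rate,
)
from .toy_sim import (
    LangevinConfig,
    generate_particle_config,
    generate_release_curve,
    generate_umbrella_dataset,
    make_translocation_potential,
)
from .umbrella_wham import bootstrap_pmf_error, extract_barrier

log = logging.getLogger("pmfrelease")

__all__ = ["PipelineConfig", "PipelineStageError", "run_demo"]

#: Planted translocation well depths, kJ/mol (drug and prodrug series).
DEFAULT_COMPOUNDS = {
    "DTXL": -69.8,
    "OA-DTXL": -75.3,
    "PEG10-DTXL": -76.9,
    "PEG25-DTXL": -90.7,
}

#: Illustrative power-law release parameters per compound for the demo's
#: curve-fitting stage (K in h^-n, Fickian-like exponents).
DEFAULT_RELEASE_PARAMS = {
    "DTXL": (0.30, 0.45),
    "OA-DTXL": (0.26, 0.45),
    "PEG10-DTXL": (0.24, 0.46),
    "PEG25-DTXL": (0.17, 0.48),
}


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; partial outputs remain on disk."""

    def __init__(self, stage, original):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """Declarative configuration of the demo run.

    Umbrella geometry defaults follow the standard pulling protocol
    (60 windows, 0.2 nm spacing, 1000 kJ mol^-1 nm^-2 spring, 310 K); the
    sampling sizes are demo-scale and freely overridable.
    """

    master_seed: int = 2024
    temperature: float = DEFAULT_TEMPERATURE
    compounds: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COMPOUNDS))
    # umbrella geometry
    n_windows: int = 60
    window_spacing: float = 0.2
    spring: float = 1000.0
    window_start: float = 0.0
    # planted-profile geometry (nm)
    well_center: float = 3.0
    interface_center: float = 7.0
    interface_width: float = 1.0
    # sampling
    n_samples_per_window: int = 2000
    sample_stride: int = 1000
    equilibration_steps: int = 5000
    diffusion_coeff: float = 0.004
    timestep: float = 0.002
    # WHAM
    bin_width: float = 0.05
    wham_tol: float = 1e-8
    n_boot: int = 16
    # release-curve demo
    release_params: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RELEASE_PARAMS)
    )
    release_noise_sigma: float = 0.02
    release_n_points: int = 20
    release_t_max: float = 4.5
    # aggregation demo
    cluster_sizes: List[int] = field(default_factory=lambda: [5, 4] + [1] * 18)
    cluster_cutoff: float = 0.6
    cluster_intra_spacing: float = 0.45
    cluster_inter_separation: float = 3.0
    box_edge: float = 15.0
    n_cluster_frames: int = 5

    def to_yaml(self, path):
        payload = dataclasses.asdict(self)
        payload["release_params"] = {k: list(v) for k, v in self.release_params.items()}
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path):
        payload = yaml.safe_load(Path(path).read_text())
        if "release_params" in payload:
            payload["release_params"] = {
                k: tuple(v) for k, v in payload["release_params"].items()
            }
        return cls(**payload)

    def override(self, **kwargs):
        """New config with the given fields replaced (CLI flags beat file values)."""
        return dataclasses.replace(self, **{k: v for k, v in kwargs.items() if v is not None})


def _seed_for(master: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    import zlib

    ss = np.random.SeedSequence(master, spawn_key=(zlib.crc32(stage.encode()), index))
    return int(ss.generate_state(1)[0] % (2**31))


def run_demo(config: PipelineConfig, out_dir) -> dict:
    """Run the full demo pipeline; returns (and writes) the structured report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report: dict = {"master_seed": config.master_seed, "stages": {}, "seeds": {}}

    # ---- stage 1: umbrella sampling + WHAM per compound ------------------- #
    stage = "umbrella_wham"
    barriers: Dict[str, float] = {}
    stderrs: Dict[str, float] = {}
    try:
        centers = config.window_start + config.window_spacing * np.arange(config.n_windows)
        for i, (name, depth) in enumerate(sorted(config.compounds.items())):
            seed = _seed_for(config.master_seed, "umbrella", i)
            boot_seed = _seed_for(config.master_seed, "bootstrap", i)
            report["seeds"][f"umbrella:{name}"] = seed
            report["seeds"][f"bootstrap:{name}"] = boot_seed
            log.info("[%s] %s: planted depth %.1f kJ/mol, seed %d", stage, name, depth, seed)
            pot = make_translocation_potential(
                depth,
                well_center=config.well_center,
                interface_center=config.interface_center,
                interface_width=config.interface_width,
            )
            cfg = LangevinConfig(
                n_steps=config.n_samples_per_window * config.sample_stride,
                seed=seed,
                temperature=config.temperature,
                diffusion_coeff=config.diffusion_coeff,
                timestep=config.timestep,
            )
            ws = generate_umbrella_dataset(
                pot,
                centers,
                config.spring,
                cfg,
                equilibration_steps=config.equilibration_steps,
                sample_stride=config.sample_stride,
            )
            prof = bootstrap_pmf_error(
                ws,
                n_boot=config.n_boot,
                seed=boot_seed,
                bin_width=config.bin_width,
                tol=config.wham_tol,
            )
            bar = extract_barrier(prof)
            barriers[name] = bar.delta_g
            stderrs[name] = bar.stderr if bar.stderr is not None else float("nan")
            pio.write_pmf(out / f"pmf_{name}.tsv", prof)
            log.info(
                "[%s] %s: recovered %.2f +- %.2f kJ/mol (planted %.1f)",
                stage, name, bar.delta_g, stderrs[name], depth,
            )
        report["stages"][stage] = {
            "barriers_kJ_per_mol": barriers,
            "barrier_stderr_kJ_per_mol": stderrs,
            "planted_depths_kJ_per_mol": dict(config.compounds),
        }
    except Exception as err:  # noqa: BLE001
        _persist(report, out)
        raise PipelineStageError(stage, err) from err

    # ---- stage 2: ranking, rate ratios, relative differences -------------- #
    stage = "ranking"
    try:
        rank = rank_compounds(barriers)
        names = rank.order
        ratios = {}
        rel_diffs = {}
        if len(names) > 1:
            for a in names:
                for b in names:
                    if a != b:
                        ratios[f"{a}/{b}"] = relative_rate(
                            min(barriers[a], 0.0), min(barriers[b], 0.0), config.temperature
                        )
                        rel_diffs[f"{a} vs {b}"] = barrier_relative_difference(
                            barriers[a], barriers[b]
                        )
        report["stages"][stage] = {
            "order_fastest_to_slowest": names,
            "ties": rank.ties,
            "rate_ratios": ratios,
            "barrier_relative_differences_pct": rel_diffs,
        }
        log.info("[%s] order fastest->slowest: %s", stage, names)
    except Exception as err:  # noqa: BLE001
        _persist(report, out)
        raise PipelineStageError(stage, err) from err

    # ---- stage 3: release curves + power-law fits ------------------------- #
    stage = "release_kinetics"
    try:
        fits = {}
        times = np.linspace(
            config.release_t_max / config.release_n_points,
            config.release_t_max,
            config.release_n_points,
        )
        for i, name in enumerate(sorted(config.compounds)):
            K, n = config.release_params.get(name, (0.3, 0.45))
            seed = _seed_for(config.master_seed, "release", i)
            report["seeds"][f"release:{name}"] = seed
            curve = generate_release_curve(K, n, times, config.release_noise_sigma, seed)
            pio.write_release_curve(out / f"release_{name}.csv", curve)
            fit = fit_peppas(curve)
            fits[name] = {
                "K": fit.K, "n": fit.n,
                "true_K": K, "true_n": n,
                "n_points_fitted": fit.n_points,
            }
            log.info("[%s] %s: K=%.3f n=%.3f (true %.2f/%.2f)", stage, name, fit.K, fit.n, K, n)
        report["stages"][stage] = fits
    except Exception as err:  # noqa: BLE001
        _persist(report, out)
        raise PipelineStageError(stage, err) from err

    # ---- stage 4: aggregation --------------------------------------------- #
    stage = "aggregation"
    try:
        frames = []
        for i in range(config.n_cluster_frames):
            seed = _seed_for(config.master_seed, "clusters", i)
            report["seeds"][f"clusters:frame{i}"] = seed
            planted = generate_particle_config(
                config.cluster_sizes,
                intra_spacing=config.cluster_intra_spacing,
                inter_separation=config.cluster_inter_separation,
                box=[config.box_edge] * 3,
                seed=seed,
            )
            frames.append(planted.configuration)
        pio.write_xyz(out / "cluster_frames.xyz", frames)
        trace = cluster_trace(frames, cutoff=config.cluster_cutoff)
        part = find_clusters(frames[0], config.cluster_cutoff)
        report["stages"][stage] = {
            "planted_sizes": sorted(config.cluster_sizes, reverse=True),
            "frame0_sizes": list(part.sizes),
            "number_average": trace.number_average.tolist(),
            "mass_average": trace.mass_average.tolist(),
        }
        log.info("[%s] frame-0 sizes %s", stage, part.sizes)
    except Exception as err:  # noqa: BLE001
        _persist(report, out)
        raise PipelineStageError(stage, err) from err

    _persist(report, out)
    _write_summary_tsv(report, out)
    return report


def _persist(report, out: Path):
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def _write_summary_tsv(report, out: Path):
    stage = report["stages"].get("umbrella_wham")
    if not stage:
        return
    lines = ["compound\tplanted_kJ_per_mol\trecovered_kJ_per_mol\tstderr_kJ_per_mol"]
    for name in sorted(stage["barriers_kJ_per_mol"]):
        lines.append(
            f"{name}\t{stage['planted_depths_kJ_per_mol'][name]!r}"
            f"\t{stage['barriers_kJ_per_mol'][name]!r}"
            f"\t{stage['barrier_stderr_kJ_per_mol'][name]!r}"
        )
    (out / "barriers.tsv").write_text("\n".join(lines) + "\n")
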