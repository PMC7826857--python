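"""Codon-profile presets, scenario bundles and end-to-end experiment drivers.

The named presets cover the standard study conditions: a uniformly
efficient construct, a single strongly slow codon (0.5% relative
efficiency at footprint 26 of 30) that maximises queue formation near
the 3' end, milder and 5'-placed variants, and a double-length (60 Rf)
transcript.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import analysis as an
from .engine import simulate_to_steady_state
from .params import Config, ConstructDesign, test_scale_config


def build_codon_profile(L: int, slow_positions: Iterable[int] = (),
                        slow_efficiency: float = 1.0) -> np.ndarray:
    """A relative-efficiency vector: ones, with ``slow_efficiency`` at the
    listed 1-based footprint positions."""
    if L < 1:
        raise ValueError("transcript length must be >= 1")
    if not (0 < slow_efficiency <= 1):
        raise ValueError("slow_efficiency must lie in (0, 1]")
    profile = np.ones(int(L), dtype=float)
    for pos in slow_positions:
        if not (1 <= pos <= L):
            raise ValueError(f"slow-codon position {pos} outside 1..{L}")
        profile[pos - 1] = slow_efficiency
    return profile


def profile_to_csv(profile: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"site": np.arange(1, profile.size + 1),
                  "efficiency": profile}).to_csv(path, index=False)


def profile_from_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df.sort_values("site")["efficiency"].to_numpy(dtype=float)


@dataclass
class ScenarioPreset:
    """A named construct scenario: codon profile plus design defaults."""

    name: str
    design: ConstructDesign
    description: str
    param_overrides: dict = field(default_factory=dict)


def _presets() -> dict[str, ScenarioPreset]:
    mk = build_codon_profile
    return {
        "uniform": ScenarioPreset(
            "uniform", ConstructDesign(codon_profile=mk(30)),
            "30 Rf construct, all codons equally efficient"),
        "slow-codon": ScenarioPreset(
            "slow-codon",
            ConstructDesign(codon_profile=mk(30, (26,), 0.005)),
            "one slow codon (0.5% efficiency) at footprint 26 of 30 — the "
            "core queue-forming scenario"),
        "slow-codon-3pct": ScenarioPreset(
            "slow-codon-3pct",
            ConstructDesign(codon_profile=mk(30, (26,), 0.03)),
            "milder slow codon (3% efficiency) at footprint 26 of 30"),
        "slow-codon-5prime": ScenarioPreset(
            "slow-codon-5prime",
            ConstructDesign(codon_profile=mk(30, (2,), 0.005)),
            "slow codon near the 5' end (footprint 2): a minimal 'ramp' "
            "that staggers initiation instead of queuing late"),
        "uniform-60": ScenarioPreset(
            "uniform-60", ConstructDesign(codon_profile=mk(60)),
            "double-length (60 Rf) uniform construct",
            param_overrides={"length": {"H": 60}}),
        "slow-codon-60": ScenarioPreset(
            "slow-codon-60",
            ConstructDesign(codon_profile=mk(60, (52,), 0.03)),
            "double-length construct with a 3% slow codon at footprint 52",
            param_overrides={"length": {"H": 60}}),
    }


def list_presets() -> list[str]:
    return sorted(_presets())


def get_preset(name: str) -> ScenarioPreset:
    presets = _presets()
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(presets))}")
    return presets[name]


def apply_preset(cfg: Config, preset: ScenarioPreset) -> Config:
    """Return a config with the preset's design and parameter overrides."""
    params = cfg.parameters
    for key, val in preset.param_overrides.items():
        current = getattr(params, key)
        if isinstance(current, dict):
            merged = dict(current)
            merged.update(val)
            params = params.replace(**{key: merged})
        else:
            params = params.replace(**{key: val})
    design = preset.design.replace(promH=cfg.construct.promH,
                                   RBSH=cfg.construct.RBSH)
    return Config(parameters=params, construct=design,
                  simulation=cfg.simulation, analysis=cfg.analysis)


# ----------------------------------------------------------------------
# One-command experiment reproduction
# ----------------------------------------------------------------------

EXPERIMENTS = (
    "monod", "schaechter", "hfrac-linearity", "design-grid-uniform",
    "design-grid-slow", "density-profile", "yield-heatmaps",
    "construct-score",
)

#: nutrient-quality scan used by the endogenous growth-law experiments
N_SCAN = (10.0, 30.0, 55.0, 85.0, 120.0, 160.0, 210.0)


def _grid(cfg: Config, scenario: str, seeds) -> an.DesignGrid:
    preset = get_preset("uniform" if scenario == "uniform" else "slow-codon")
    c = apply_preset(cfg, preset)
    return an.simulate_design_grid(
        c.parameters, c.construct, c.simulation,
        cfg.analysis.prom_values, cfg.analysis.rbs_values,
        seeds=seeds, scenario=scenario)


def reproduce(experiment: str, seed: int, out_dir: str | Path,
              config: Optional[Config] = None, n_replicates: int = 1) -> dict:
    """Run one named experiment end to end and write its tables.

    Returns a dict of the main numeric outputs; CSV/JSON artifacts are
    written under ``out_dir``.  The default configuration is the reduced
    test-scale cell, so every experiment finishes in minutes.
    """
    if experiment not in EXPERIMENTS:
        raise KeyError(
            f"unknown experiment {experiment!r}; available: "
            f"{', '.join(EXPERIMENTS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or test_scale_config()
    seeds = [seed + k for k in range(n_replicates)]
    result: dict = {"experiment": experiment, "seed": seed}

    if experiment in ("monod", "schaechter"):
        report = an.run_growth_law_suite(
            cfg.parameters, cfg.construct, cfg.simulation, list(N_SCAN),
            seeds=seeds, run_burden_scan=False)
        df = pd.DataFrame({"n": sorted(N_SCAN),
                           "grate_per_h": report["monod"]["grate_per_h"],
                           "mrna_protein_ratio":
                               report["schaechter"]["mrna_protein_ratio"]})
        df.to_csv(out / "growth_laws.csv", index=False)
        result.update(monod=report["monod"], schaechter=report["schaechter"])
    elif experiment == "hfrac-linearity":
        report = an.run_growth_law_suite(
            cfg.parameters, cfg.construct, cfg.simulation, list(N_SCAN),
            seeds=seeds, run_burden_scan=True)
        pd.DataFrame(report["burden"]).to_csv(out / "hfrac_vs_grate.csv",
                                              index=False)
        result.update(burden=report["burden"])
    elif experiment in ("design-grid-uniform", "design-grid-slow"):
        scenario = "uniform" if experiment.endswith("uniform") else "slow"
        grid = _grid(cfg, scenario, seeds)
        grid.to_frame().to_csv(out / f"design_grid_{scenario}.csv", index=False)
        result.update(grate=grid.grate.tolist(), hrate=grid.hrate.tolist())
    elif experiment == "density-profile":
        rows = []
        for scenario in ("uniform", "slow"):
            preset = get_preset("uniform" if scenario == "uniform"
                                else "slow-codon")
            c = apply_preset(cfg, preset)
            design = c.construct.replace(promH=1 / 3, RBSH=3.0)
            _, summ = simulate_to_steady_state(c.parameters, design,
                                               c.simulation, seed)
            dens = an.density_profile(summ)
            for site, prop in enumerate(dens, start=1):
                rows.append({"scenario": scenario, "site": site,
                             "proportion": prop})
            result[f"argmax_{scenario}"] = int(np.argmax(dens)) + 1
        pd.DataFrame(rows).to_csv(out / "density_profile.csv", index=False)
    elif experiment in ("yield-heatmaps", "construct-score"):
        times = cfg.analysis.time_points_h
        frames = []
        for scenario in ("uniform", "slow"):
            grid = _grid(cfg, scenario, seeds)
            for mode, N in (("exponential", 1.0),
                            ("turbidostat", cfg.analysis.turbidostat_N)):
                if experiment == "yield-heatmaps":
                    surf = an.compute_yield_surface(
                        grid, times, mode, N, cfg.analysis.t_zero_interval_h)
                    for k, t in enumerate(surf.times_h):
                        for i, r in enumerate(grid.rbs_values):
                            for j, p in enumerate(grid.prom_values):
                                frames.append({
                                    "scenario": scenario, "mode": mode,
                                    "time_h": t, "RBSH": r, "promH": p,
                                    "H": surf.H[k, i, j],
                                    "H_norm": surf.H_norm[k, i, j]})
                else:
                    df = an.score_timecourse(
                        grid, times, mode, N, cfg.analysis.t_zero_interval_h)
                    df["codon_scenario"] = scenario
                    frames.append(df)
                    result[f"score_{scenario}_{mode}"] = df["score"].tolist()
        if experiment == "yield-heatmaps":
            pd.DataFrame(frames).to_csv(out / "yield_heatmaps.csv", index=False)
        else:
            pd.concat(frames).to_csv(out / "construct_score.csv", index=False)
    (out / f"{experiment}_result.json").write_text(
        json.dumps(result, indent=2, default=float) + "\n")
    _maybe_plot(experiment, out)
    return result


def _maybe_plot(experiment: str, out: Path) -> None:
    """Convenience figures when matplotlib is available; tables are the
    primary artifacts and figures add no information."""
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # pragma: no cover
        return
    if experiment in ("monod", "schaechter"):
        df = pd.read_csv(out / "growth_laws.csv")
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
        axes[0].plot(df["n"], df["grate_per_h"], "o-")
        axes[0].set(xlabel="nutrient quality n", ylabel="Grate (1/h)")
        axes[1].plot(df["grate_per_h"], df["mrna_protein_ratio"], "o")
        axes[1].set(xlabel="Grate (1/h)", ylabel="mRNA:protein mass ratio")
        fig.tight_layout()
        fig.savefig(out / "growth_laws.png", dpi=120)
        plt.close(fig)
    elif experiment == "density-profile":
        df = pd.read_csv(out / "density_profile.csv")
        fig, ax = plt.subplots(figsize=(5, 3.2))
        for scen, sub in df.groupby("scenario"):
            ax.plot(sub["site"], sub["proportion"], label=scen)
        ax.set(xlabel="footprint position", ylabel="proportion of ribosomes")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "density_profile.png", dpi=120)
        plt.close(fig)
    elif experiment == "construct-score":
        df = pd.read_csv(out / "construct_score.csv")
        fig, ax = plt.subplots(figsize=(5, 3.2))
        for (scen, mode), sub in df.groupby(["codon_scenario", "scenario"]):
            style = "--" if mode == "turbidostat" else "-"
            ax.plot(sub["time_h"], sub["score"], style,
                    label=f"{scen} / {mode}")
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set(xlabel="time (h)", ylabel="Construct Score")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "construct_score.png", dpi=120)
        plt.close(fig)
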