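"""From steady-state summaries to design conclusions.

Per-cell steady-state rates feed population-level yield formulas.  With
``Hrate`` (proteins/cell/h) and ``Grate`` (1/h) constant at steady state,
the population yield is the integral of ``Hrate * N(T)``:

* uncapped exponential growth from one cell, ``N(t) = 2**(Grate*t)``:
  ``H_exp(t) = Hrate/(Grate*ln 2) * (2**(Grate*t) - 1)``;
* a turbidostat holding the population at ``N`` cells:
  ``H_tur(t) = Hrate * N * t`` (time-invariant dynamics).

Yields over a promoter-strength x RBS-strength grid are normalised per
time slice (max cell = 1) and condensed into the Construct Score
``Y - X``, where ``X`` weights the normalised grid by promoter strength
and ``Y`` by RBS strength: a positive score says raising the RBS is the
more efficient knob, a negative score favours the promoter, and zero
means perfect symmetry about the promH = RBSH diagonal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import SteadyStateSummary, simulate_to_steady_state
from .params import AnalysisSettings, ConstructDesign, ModelParameters, SimulationSettings


def yield_exponential(hrate: float, grate: float, t: float) -> float:
    """Population protein yield after ``t`` hours of uncapped exponential growth.

    ``Hrate/(Grate*ln2) * (2**(Grate*t) - 1)``; the ``Grate -> 0`` limit
    ``Hrate*t`` is substituted when ``Grate*t`` underflows the expansion.
    """
    if hrate < 0 or grate < 0 or t < 0:
        raise ValueError("hrate, grate and t must be non-negative")
    x = grate * t
    if x < 1e-8:
        return hrate * t
    return hrate / (grate * math.log(2.0)) * (2.0 ** x - 1.0)


def yield_turbidostat(hrate: float, N: float, t: float) -> float:
    """Population protein yield after ``t`` hours in a turbidostat of ``N`` cells."""
    if hrate < 0 or N < 0 or t < 0:
        raise ValueError("hrate, N and t must be non-negative")
    return hrate * N * t


def normalize_grid(values: np.ndarray) -> np.ndarray:
    """Divide one time slice by its maximum (max cell becomes 1)."""
    values = np.asarray(values, dtype=float)
    vmax = values.max()
    if vmax <= 0:
        raise ValueError("cannot normalise an all-zero yield slice")
    return values / vmax


def construct_score(norm_slice: np.ndarray, prom_values: Sequence[float],
                    rbs_values: Sequence[float]) -> float:
    """Construct Score ``Y - X`` of one normalised yield slice.

    Rows index RBS strength ``i``, columns promoter strength ``j``; the
    weights are the strengths themselves.  ``X = sum_ij j * H[i, j]``,
    ``Y = sum_ij i * H[i, j]``.
    """
    H = np.asarray(norm_slice, dtype=float)
    prom = np.asarray(prom_values, dtype=float)
    rbs = np.asarray(rbs_values, dtype=float)
    if H.shape != (rbs.size, prom.size):
        raise ValueError(
            f"slice shape {H.shape} does not match (len(rbs), len(prom)) = "
            f"({rbs.size}, {prom.size})")
    X = float(np.sum(H * prom[None, :]))
    Y = float(np.sum(H * rbs[:, None]))
    return Y - X


@dataclass
class DesignGrid:
    """Steady-state (Grate, Hrate) over a promoter x RBS strength grid.

    ``grate`` and ``hrate`` are (len(rbs_values), len(prom_values)) arrays
    in 1/h and proteins/cell/h; rows index RBS strength, columns promoter
    strength.
    """

    prom_values: np.ndarray
    rbs_values: np.ndarray
    grate: np.ndarray
    hrate: np.ndarray
    scenario: str = "uniform"
    seeds: list[int] = field(default_factory=list)
    summaries: Optional[list] = None

    def __post_init__(self) -> None:
        self.prom_values = np.asarray(self.prom_values, dtype=float)
        self.rbs_values = np.asarray(self.rbs_values, dtype=float)
        self.grate = np.asarray(self.grate, dtype=float)
        self.hrate = np.asarray(self.hrate, dtype=float)
        shape = (self.rbs_values.size, self.prom_values.size)
        if self.grate.shape != shape or self.hrate.shape != shape:
            raise ValueError("grate/hrate shape must be (len(rbs), len(prom))")
        if np.any(self.prom_values <= 0) or np.any(self.rbs_values <= 0):
            raise ValueError("strengths must be positive")
        if np.any(~np.isfinite(self.grate)) or np.any(~np.isfinite(self.hrate)):
            raise ValueError("grid has missing cells")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.rbs_values):
            for j, p in enumerate(self.prom_values):
                rows.append({"RBSH": r, "promH": p,
                             "grate_per_h": self.grate[i, j],
                             "hrate_per_h": self.hrate[i, j],
                             "scenario": self.scenario})
        return pd.DataFrame(rows)


@dataclass
class YieldSurface:
    """H(t) and its per-slice normalisation over the design grid."""

    times_h: np.ndarray
    H: np.ndarray          # (n_times, n_rbs, n_prom)
    H_norm: np.ndarray
    scenario: str          # "exponential" | "turbidostat"
    N: Optional[float]
    prom_values: np.ndarray
    rbs_values: np.ndarray


def compute_yield_surface(grid: DesignGrid, times_h: Sequence[float],
                          scenario: str, N: float = 1.0,
                          t_zero_interval_h: float = 1e-12) -> YieldSurface:
    """Evaluate H(t) per grid cell and normalise each time slice.

    A requested time of exactly zero is evaluated over the small interval
    ``t_zero_interval_h`` so that the t=0 slice reflects the relative
    production rates rather than degenerating to all zeros.
    """
    times = np.asarray(list(times_h), dtype=float)
    if times.size == 0:
        raise ValueError("empty time vector")
    nr, np_ = grid.rbs_values.size, grid.prom_values.size
    H = np.zeros((times.size, nr, np_))
    for k, t in enumerate(times):
        t_eff = max(float(t), t_zero_interval_h)
        for i in range(nr):
            for j in range(np_):
                if scenario == "exponential":
                    H[k, i, j] = yield_exponential(grid.hrate[i, j],
                                                   grid.grate[i, j], t_eff)
                elif scenario == "turbidostat":
                    H[k, i, j] = yield_turbidostat(grid.hrate[i, j], N, t_eff)
                else:
                    raise ValueError(f"unknown scenario {scenario!r}")
    H_norm = np.stack([normalize_grid(H[k]) for k in range(times.size)])
    return YieldSurface(times_h=times, H=H, H_norm=H_norm, scenario=scenario,
                        N=N if scenario == "turbidostat" else None,
                        prom_values=grid.prom_values, rbs_values=grid.rbs_values)


def score_timecourse(grid: DesignGrid, times_h: Sequence[float],
                     scenario: str, N: float = 1.0,
                     t_zero_interval_h: float = 1e-12) -> pd.DataFrame:
    """Construct Score at each time point for one growth scenario.

    Turbidostat scores are constant in time (and independent of ``N``,
    which cancels in the normalisation).
    """
    surf = compute_yield_surface(grid, times_h, scenario, N, t_zero_interval_h)
    scores = [construct_score(surf.H_norm[k], grid.prom_values, grid.rbs_values)
              for k in range(surf.times_h.size)]
    return pd.DataFrame({"time_h": surf.times_h, "score": scores,
                         "scenario": scenario})


def density_profile(summary: SteadyStateSummary) -> np.ndarray:
    """Proportion of mRNA_H-bound ribosomes per footprint site (sums to 1)."""
    if summary.h_density is None:
        raise ValueError("no ribosomes were ever observed on H transcripts")
    return summary.h_density


# ----------------------------------------------------------------------
# Experiment drivers
# ----------------------------------------------------------------------

def simulate_design_grid(params: ModelParameters, design: ConstructDesign,
                         sim: SimulationSettings,
                         prom_values: Sequence[float],
                         rbs_values: Sequence[float],
                         seeds: Sequence[int] = (0,),
                         scenario: str = "uniform",
                         ) -> DesignGrid:
    """Simulate every promoter x RBS combination to steady state.

    Each cell averages the steady-state rates over the given seeds;
    ``design`` supplies the codon profile (its promH/RBSH are overridden
    cell by cell).
    """
    prom_values = list(prom_values)
    rbs_values = list(rbs_values)
    grate = np.zeros((len(rbs_values), len(prom_values)))
    hrate = np.zeros_like(grate)
    summaries = []
    for i, rbs in enumerate(rbs_values):
        for j, prom in enumerate(prom_values):
            cell = design.replace(promH=prom, RBSH=rbs)
            gs, hs = [], []
            for seed in seeds:
                _, summ = simulate_to_steady_state(params, cell, sim, seed)
                gs.append(summ.grate)
                hs.append(summ.hrate)
                summaries.append(summ)
            grate[i, j] = float(np.mean(gs))
            hrate[i, j] = float(np.mean(hs))
    return DesignGrid(prom_values=np.array(prom_values),
                      rbs_values=np.array(rbs_values),
                      grate=grate, hrate=hrate, scenario=scenario,
                      seeds=list(seeds), summaries=summaries)


def _endogenous(params: ModelParameters) -> ModelParameters:
    """Switch the construct off (no H transcription)."""
    w = dict(params.w)
    w["H"] = 0.0
    return params.replace(w=w)


def run_growth_law_suite(params: ModelParameters, design: ConstructDesign,
                         sim: SimulationSettings,
                         n_values: Sequence[float],
                         seeds: Sequence[int] = (0,),
                         burden_grid: Optional[DesignGrid] = None,
                         burden_hfrac: Optional[np.ndarray] = None,
                         run_burden_scan: bool = True,
                         analysis: Optional[AnalysisSettings] = None,
                         ) -> dict:
    """Growth-law validation report.

    Three checks against classic bacterial growth phenomenology:

    * Monod: steady-state growth rate vs nutrient quality ``n`` is
      non-decreasing and saturating (construct switched off);
    * Schaechter: mRNA:protein mass ratio vs growth rate over the same
      ``n`` scan is linear with positive slope;
    * burden: over the 3x3 promoter/RBS grid at fixed ``n``, the
      heterologous mass fraction Hfrac vs growth rate is linear with
      negative slope.

    Least-squares fits are ordinary unweighted regressions; only slope
    sign and R-squared are meaningful at stochastic test scales.
    """
    n_values = list(n_values)
    if len(set(n_values)) < 5:
        raise ValueError("need at least 5 distinct nutrient-quality values")
    analysis = analysis or AnalysisSettings()
    endo = _endogenous(params)
    report: dict = {"n_values": n_values, "flags": []}
    grates, ratios = [], []
    for n in sorted(n_values):
        gs, rs = [], []
        for seed in seeds:
            _, summ = simulate_to_steady_state(endo.replace(n=n),
                                               design, sim, seed)
            if not summ.converged:
                report["flags"].append(f"n={n} seed={seed} did not converge")
            gs.append(summ.grate)
            rs.append(summ.mrna_protein_ratio)
        grates.append(float(np.mean(gs)))
        ratios.append(float(np.mean(rs)))
    grates_arr = np.array(grates)
    incr = np.diff(grates_arr)
    report["monod"] = {
        "grate_per_h": grates,
        "non_decreasing": bool(np.all(incr >= -1e-12)),
        "first_increment": float(incr[0]),
        "last_increment": float(incr[-1]),
        "saturating": bool(incr[-1] < 0.5 * incr[0]),
    }
    sch = stats.linregress(grates, ratios)
    report["schaechter"] = {
        "mrna_protein_ratio": ratios,
        "slope": float(sch.slope),
        "r_squared": float(sch.rvalue ** 2),
    }
    if run_burden_scan or burden_grid is not None:
        if burden_grid is None:
            burden_grid = simulate_design_grid(
                params, design, sim, analysis.prom_values,
                analysis.rbs_values, seeds, scenario="uniform")
            burden_hfrac = np.array(
                [s.hfrac for s in burden_grid.summaries]).reshape(
                    len(analysis.rbs_values), len(analysis.prom_values),
                    len(seeds)).mean(axis=2)
            for s in burden_grid.summaries:
                if not s.converged:
                    report["flags"].append(
                        f"grid cell seed={s.seed} did not converge")
        hfr = np.asarray(burden_hfrac).ravel()
        gr = burden_grid.grate.ravel()
        fit = stats.linregress(hfr, gr)
        report["burden"] = {
            "hfrac": hfr.tolist(),
            "grate_per_h": gr.tolist(),
            "slope": float(fit.slope),
            "r_squared": float(fit.rvalue ** 2),
        }
    return report
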