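"""Model parameters, construct designs, and configuration I/O.

The cell's proteome is coarse-grained into five functional classes:

``R``
    ribosomal proteins (the ribosome itself; long transcripts),
``ET`` / ``EM``
    the enzymatic class, split into nutrient transporters and metabolic
    enzymes with identical expression parameters (reported aggregated as
    ``E = ET + EM``),
``Q``
    house-keeping proteins under negative autoregulation,
``H``
    the heterologous (synthetic construct) protein.

Transcript lengths are measured in ribosomal footprints (Rf); 1 Rf covers
30 nucleotides, i.e. 10 amino acids.  All rates are per minute.  The
resource-allocation structure and default rate constants follow the
mechanistic growth model of Weisse et al. (PNAS 2015), with translation
replaced here by an explicit per-footprint elongation lattice.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

#: Gene-class labels, in canonical index order.
CLASSES: tuple[str, ...] = ("R", "ET", "EM", "Q", "H")

#: nucleotides per ribosomal footprint
NT_PER_RF = 30
#: amino acids per ribosomal footprint
AA_PER_RF = 10


@dataclass
class ModelParameters:
    """All rate constants and geometry of the whole-cell model.

    Attributes
    ----------
    n:
        Nutrient quality: energy units produced per internal nutrient
        molecule.  Acts as the proxy for external nutrient concentration.
    s_ext:
        Fixed external nutrient level (boundary species, count).
    w:
        Maximal transcription rate per class (transcripts/min).
    theta:
        Transcription energy threshold per class (energy count).
    b:
        Ribosome-mRNA binding rate constant per class (1/(molecule*min)).
    length:
        Transcript length per class in Rf sites.
    K_q, h_q:
        Threshold (protein count) and Hill exponent of house-keeping
        transcription autoinhibition.
    d_m:
        mRNA degradation rate (1/min), acting on ribosome-free mRNAs only.
    gamma_max, K_gamma:
        Maximal per-site elongation hop rate (sites/min) and the energy
        half-saturation constant of the hop rate.
    v_t, K_t:
        Per-transporter nutrient import turnover (1/min) and its
        half-saturation w.r.t. external nutrient.
    v_m, K_m:
        Per-enzyme catabolism turnover (1/min) and its half-saturation
        w.r.t. internal nutrient.
    M:
        Total protein mass budget in Rf units (divide amino acids by 10).
    mass_per_nt, mass_per_aa:
        Average masses (Da) used only for the mRNA:protein mass ratio.
    """

    n: float = 100.0
    s_ext: float = 1.0e4
    w: dict[str, float] = field(
        default_factory=lambda: {"R": 930.0, "ET": 4.14, "EM": 4.14, "Q": 948.9, "H": 4.14}
    )
    theta: dict[str, float] = field(
        default_factory=lambda: {"R": 426.87, "ET": 4.38, "EM": 4.38, "Q": 4.38, "H": 4.38}
    )
    b: dict[str, float] = field(
        default_factory=lambda: {c: 0.0095 for c in CLASSES}
    )
    length: dict[str, int] = field(
        default_factory=lambda: {"R": 750, "ET": 30, "EM": 30, "Q": 30, "H": 30}
    )
    K_q: float = 152219.0
    h_q: float = 4.0
    d_m: float = 0.1
    gamma_max: float = 126.0
    K_gamma: float = 7.0
    v_t: float = 726.0
    K_t: float = 1000.0
    v_m: float = 5800.0
    K_m: float = 1000.0
    M: float = 1.0e7
    mass_per_nt: float = 330.0
    mass_per_aa: float = 110.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError(f"nutrient quality n must be >= 1, got {self.n}")
        if self.h_q < 1:
            raise ValueError(f"Hill exponent h_q must be >= 1, got {self.h_q}")
        if self.M <= 0:
            raise ValueError("protein mass budget M must be positive")
        for name in ("s_ext", "K_q", "d_m", "gamma_max", "K_gamma",
                     "v_t", "K_t", "v_m", "K_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be non-negative")
        for d, label in ((self.w, "w"), (self.theta, "theta"), (self.b, "b")):
            missing = set(CLASSES) - set(d)
            if missing:
                raise ValueError(f"{label} missing classes: {sorted(missing)}")
            for c in CLASSES:
                if d[c] < 0:
                    raise ValueError(f"{label}[{c}] must be non-negative")
        for c in CLASSES:
            if self.length[c] < 1:
                raise ValueError(f"length[{c}] must be >= 1")

    # -- convenience -------------------------------------------------
    def lengths_array(self) -> np.ndarray:
        return np.array([self.length[c] for c in CLASSES], dtype=np.int64)

    def replace(self, **kwargs) -> "ModelParameters":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**d)


@dataclass
class ConstructDesign:
    """Design of the heterologous construct.

    ``promH`` multiplies the maximal transcription rate of the H gene and
    ``RBSH`` multiplies its ribosome binding rate; both are relative
    strengths (1 = the endogenous enzymatic baseline).  ``codon_profile``
    holds one relative elongation efficiency in (0, 1] per footprint site
    of the H transcript; endogenous transcripts are uniformly efficient.
    """

    promH: float = 1.0
    RBSH: float = 1.0
    codon_profile: np.ndarray = field(
        default_factory=lambda: np.ones(30, dtype=float)
    )

    def __post_init__(self) -> None:
        self.codon_profile = np.asarray(self.codon_profile, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.promH <= 0:
            raise ValueError("promH must be positive")
        if self.RBSH <= 0:
            raise ValueError("RBSH must be positive")
        prof = self.codon_profile
        if prof.ndim != 1 or prof.size < 1:
            raise ValueError("codon_profile must be a non-empty 1-D vector")
        if np.any(prof <= 0) or np.any(prof > 1):
            raise ValueError("codon efficiencies must lie in (0, 1]")

    def check_against(self, params: ModelParameters) -> None:
        if self.codon_profile.size != params.length["H"]:
            raise ValueError(
                f"codon profile length {self.codon_profile.size} != "
                f"H transcript length {params.length['H']}"
            )

    def replace(self, **kwargs) -> "ConstructDesign":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "promH": self.promH,
            "RBSH": self.RBSH,
            "codon_profile": self.codon_profile.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConstructDesign":
        return cls(
            promH=d.get("promH", 1.0),
            RBSH=d.get("RBSH", 1.0),
            codon_profile=np.asarray(d.get("codon_profile", np.ones(30))),
        )


@dataclass
class SimulationSettings:
    """Stochastic-simulation control knobs.

    The run extends on a doubling time grid until the steady-state rule
    holds (the monitored protein count stays within ``ss_tol`` of its mean
    over the trailing ``ss_window_frac`` of simulated time) or
    ``max_time`` is reached.
    """

    seed: int = 0
    t_initial: float = 60.0       # min: first convergence check
    max_time: float = 1920.0      # min: hard cap
    sample_dt: float = 0.1        # min: observable sampling grid
    ss_window_frac: float = 0.10
    ss_tol: float = 0.01
    init_on_occupied: bool = True  # ribosomes may initiate on occupied mRNAs

    def validate(self) -> None:
        if not (0 < self.ss_window_frac <= 1):
            raise ValueError("ss_window_frac must be in (0, 1]")
        if self.ss_tol <= 0 or self.sample_dt <= 0 or self.max_time <= 0:
            raise ValueError("ss_tol, sample_dt and max_time must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSettings":
        return cls(**d)


@dataclass
class AnalysisSettings:
    """Settings for the yield/design analysis layer."""

    time_points_h: list[float] = field(default_factory=lambda: [0.0, 4.0, 8.0, 24.0])
    turbidostat_N: float = 1.0e9
    prom_values: list[float] = field(default_factory=lambda: [1 / 3, 1.0, 3.0])
    rbs_values: list[float] = field(default_factory=lambda: [1 / 3, 1.0, 3.0])
    n_replicates: int = 3
    t_zero_interval_h: float = 1e-12  # "t=0" evaluated on this small interval

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisSettings":
        return cls(**d)


@dataclass
class Config:
    """Full configuration: [parameters], [construct], [simulation], [analysis]."""

    parameters: ModelParameters = field(default_factory=ModelParameters)
    construct: ConstructDesign = field(default_factory=ConstructDesign)
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)

    def validate(self) -> None:
        self.parameters.validate()
        self.construct.validate()
        self.construct.check_against(self.parameters)
        self.simulation.validate()

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters.to_dict(),
            "construct": self.construct.to_dict(),
            "simulation": self.simulation.to_dict(),
            "analysis": self.analysis.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        cfg = cls(
            parameters=ModelParameters.from_dict(d.get("parameters", {})),
            construct=ConstructDesign.from_dict(d.get("construct", {})),
            simulation=SimulationSettings.from_dict(d.get("simulation", {})),
            analysis=AnalysisSettings.from_dict(d.get("analysis", {})),
        )
        cfg.validate()
        return cfg

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> Config:
    """Load a JSON (or TOML) configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".toml", ".tml"):
        import tomllib

        d = tomllib.loads(text)
    else:
        d = json.loads(text)
    return Config.from_dict(d)


def save_config(cfg: Config, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2) + "\n")


def default_config() -> Config:
    """The packaged full-scale default configuration."""
    text = resources.files("stocellator.data").joinpath("default_config.json").read_text()
    return Config.from_dict(json.loads(text))


def test_scale_config() -> Config:
    """A reduced-size cell for fast simulation.

    Shrinks the protein mass budget, transcript pool and ribosome lattice
    for the R class (75 Rf instead of 750), with transcription and
    metabolic capacity rescaled in proportion, so that steady states are
    reached within minutes of CPU time while the growth laws, burden
    response and queue phenomenology are preserved.
    """
    text = resources.files("stocellator.data").joinpath("test_scale_config.json").read_text()
    return Config.from_dict(json.loads(text))
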