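"""Species, state and reaction propensities of the resource-limited cell.

Every cellular process — nutrient import, catabolism, transcription,
ribosome binding, elongation, mRNA decay and growth dilution — is a
discrete reaction channel with a state-dependent propensity; there are no
deterministic rate equations.  Shared resources (energy ``a``, free
ribosomes, the finite proteome budget ``M``) couple heterologous
expression to growth: the growth rate is proportional to the total
translational flux, ``Grate = gamma(a) * B / M`` with ``B`` the number of
bound (translating) ribosomes, and every species is diluted at that rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import CLASSES, AA_PER_RF, NT_PER_RF, ConstructDesign, ModelParameters
from .tasep import TranscriptLattice, gamma_rate


@dataclass
class CellState:
    """Instantaneous state of the single simulated cell.

    ``m_free`` counts ribosome-free mRNAs per class (degradable);
    ``lattices`` holds every mRNA carrying at least one ribosome.
    ``p['R']`` is the ribosome count; the invariant
    ``r_free + bound == p['R']`` holds because ribosomes are either free
    or translating.
    """

    t: float = 0.0
    s_i: int = 0
    a: int = 0
    r_free: int = 0
    m_free: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CLASSES})
    lattices: list[TranscriptLattice] = field(default_factory=list)
    p: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CLASSES})

    @property
    def bound_ribosomes(self) -> int:
        return sum(lat.n_ribosomes for lat in self.lattices)

    def validate(self) -> None:
        if self.s_i < 0 or self.a < 0 or self.r_free < 0:
            raise ValueError("counts must be non-negative")
        if any(v < 0 for v in self.m_free.values()):
            raise ValueError("mRNA counts must be non-negative")
        if any(v < 0 for v in self.p.values()):
            raise ValueError("protein counts must be non-negative")
        if self.r_free + self.bound_ribosomes > self.p["R"]:
            raise ValueError("free + bound ribosomes exceed the ribosome count")
        for lat in self.lattices:
            lat.validate()
            if lat.n_ribosomes == 0:
                raise ValueError("empty lattice must be a free mRNA instead")


def transcription_propensity(class_x: str, state: CellState,
                             params: ModelParameters,
                             design: ConstructDesign) -> float:
    """Energy-gated transcription rate of one gene class.

    ``w_x * a/(theta_x + a)``, scaled by ``promH`` for the construct and
    by the autoinhibition factor ``1/(1 + (p_Q/K_q)**h_q)`` for the
    house-keeping class.
    """
    if class_x not in params.w:
        raise ValueError(f"unknown gene class {class_x!r}")
    if state.a < 0:
        raise ValueError("negative energy count")
    a = state.a
    rate = params.w[class_x] * a / (params.theta[class_x] + a)
    if class_x == "H":
        rate *= design.promH
    elif class_x == "Q":
        rate *= 1.0 / (1.0 + (state.p["Q"] / params.K_q) ** params.h_q)
    return rate


def metabolism_propensities(state: CellState, params: ModelParameters
                            ) -> tuple[float, float]:
    """(import, catabolism) propensities.

    Import brings one external nutrient inside per firing
    (``p_ET * v_t * s_ext/(K_t + s_ext)``); catabolism converts one
    internal nutrient into ``n`` energy units
    (``p_EM * v_m * s_i/(K_m + s_i)``).
    """
    imp = state.p["ET"] * params.v_t * params.s_ext / (params.K_t + params.s_ext)
    cat = state.p["EM"] * params.v_m * state.s_i / (params.K_m + state.s_i)
    return imp, cat


def growth_rate(state: CellState, params: ModelParameters) -> float:
    """Grate = gamma(a) * B / M  (1/min), B = bound ribosomes."""
    if params.M <= 0:
        raise ValueError("protein mass budget M must be positive")
    return gamma_rate(state.a, params) * state.bound_ribosomes / params.M


def dilution_propensities(state: CellState, params: ModelParameters
                          ) -> dict[str, float]:
    """Per-target removal propensities at the current growth rate.

    Every free molecule is removed at rate ``Grate`` each; an occupied
    lattice is removed whole (its bound ribosomes are lost with it,
    modelling partitioning at division).  The ribosome protein count is
    implicit (``p_R = r_free + bound``), so ribosomes are diluted through
    the ``r_free`` and lattice channels, never double-counted.
    """
    g = growth_rate(state, params)
    props: dict[str, float] = {
        "s_i": g * state.s_i,
        "a": g * state.a,
        "r_free": g * state.r_free,
    }
    for c in CLASSES:
        props[f"m_free_{c}"] = g * state.m_free[c]
    for c in CLASSES:
        if c != "R":
            props[f"p_{c}"] = g * state.p[c]
    props["lattice"] = g * len(state.lattices)
    return props


def mass_fractions(state: CellState, params: ModelParameters) -> dict[str, float]:
    """Proteome mass fractions; mass of class x is ``p_x * len_x`` (Rf)."""
    masses = {c: state.p[c] * params.length[c] for c in CLASSES}
    total = sum(masses.values())
    if total <= 0:
        raise ValueError("mass fractions undefined for an empty proteome")
    return {c: masses[c] / total for c in CLASSES}


def heterologous_mass_fraction(state: CellState, params: ModelParameters) -> float:
    """Hfrac, the construct's share of total proteome mass."""
    return mass_fractions(state, params)["H"]


def mrna_protein_mass_ratio(state: CellState, params: ModelParameters) -> float:
    """Total mRNA mass over total protein mass.

    mRNA mass counts free and ribosome-occupied transcripts alike
    (``len_x`` Rf = ``30*len_x`` nt); protein mass uses ``10*len_x`` aa.
    The average masses per nt and per aa are configurable constants.
    """
    n_mrna = dict(state.m_free)
    for lat in state.lattices:
        n_mrna[lat.class_x] += 1
    mrna_mass = sum(
        n_mrna[c] * params.length[c] * NT_PER_RF * params.mass_per_nt
        for c in CLASSES
    )
    prot_mass = sum(
        state.p[c] * params.length[c] * AA_PER_RF * params.mass_per_aa
        for c in CLASSES
    )
    if prot_mass <= 0:
        raise ValueError("mRNA:protein ratio undefined for an empty proteome")
    return mrna_mass / prot_mass
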