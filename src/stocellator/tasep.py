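"""Codon-resolution translation: a modified TASEP on each mRNA.

Each ribosome-bearing transcript is a lattice of ``L`` footprint sites
with hard-core exclusion (one ribosome per site, nearest-neighbour
blocking).  Ribosomes hop strictly forward; a hop from site ``j`` carries
propensity ``gamma(a) * eff[j]`` where ``gamma(a)`` is the shared,
energy-dependent elongation rate and ``eff[j]`` the relative efficiency
of the codon(s) at that site.  The modification relative to a classic
TASEP is that blocked ("queuing") ribosomes carry zero propensity in the
transition vector and can never be selected — which leaves the
continuous-time law unchanged while avoiding wasted event draws.

A ribosome on the last site terminates with one further hop, releasing
itself and one finished protein; an mRNA left empty becomes degradable
again ("ribosome protection").

``stationary_oracle`` solves the exact master equation of a single
open-boundary lattice over all 2**L occupancy configurations, and
``simulate_single_lattice`` runs the event-level dynamics for the same
system; their agreement on densities and current validates the modified
transition scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .model_core import CellState
    from .params import ConstructDesign, ModelParameters


@dataclass
class TranscriptLattice:
    """One mRNA carrying at least one ribosome.

    ``positions`` are 1-based site indices, strictly increasing; site 1 is
    the initiation (5') site, site ``L`` the termination site.  ``eff``
    holds the per-site relative efficiency (all ones for endogenous
    classes).
    """

    class_x: str
    L: int
    positions: list[int] = field(default_factory=list)
    eff: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.eff is None:
            self.eff = np.ones(self.L, dtype=float)
        else:
            self.eff = np.asarray(self.eff, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.eff.size != self.L:
            raise ValueError("efficiency vector length must equal L")
        pos = self.positions
        if any(p < 1 or p > self.L for p in pos):
            raise ValueError("ribosome positions must lie in 1..L")
        if any(pos[i + 1] <= pos[i] for i in range(len(pos) - 1)):
            raise ValueError("positions must be strictly increasing (exclusion)")

    @property
    def n_ribosomes(self) -> int:
        return len(self.positions)

    def occupancy(self) -> np.ndarray:
        occ = np.zeros(self.L, dtype=np.int8)
        for p in self.positions:
            occ[p - 1] = 1
        return occ


def gamma_rate(a: float, params: "ModelParameters") -> float:
    """Energy-dependent elongation hop rate gamma(a) = gamma_max*a/(K_gamma+a)."""
    if a < 0:
        raise ValueError("energy count must be non-negative")
    return params.gamma_max * a / (params.K_gamma + a)


def transition_vector(lattice: TranscriptLattice, a: float,
                      params: "ModelParameters") -> np.ndarray:
    """Per-ribosome forward-hop propensities.

    Entry ``k`` corresponds to ``lattice.positions[k]``: zero iff the next
    site is occupied, else ``gamma(a)`` times the efficiency of the codon
    the ribosome is decoding — the site it is about to move into
    (``eff[j+1]``), so a slow codon throttles entry into its own position
    and the queue builds strictly upstream of it.  The ribosome on the
    last site always gets the termination propensity ``gamma(a)*eff[L]``.
    """
    g = gamma_rate(a, params)
    pos = lattice.positions
    occupied = set(pos)
    tv = np.zeros(len(pos), dtype=float)
    for k, j in enumerate(pos):
        if j == lattice.L or (j + 1) not in occupied:
            tv[k] = g * lattice.eff[min(j, lattice.L - 1)]
    return tv


def hop_out_rates(profile: np.ndarray, gamma: float = 1.0) -> np.ndarray:
    """Per-site departure rates implied by a codon-efficiency profile.

    Under the entry-gating convention the hop out of site ``j`` carries the
    efficiency of site ``j+1`` (termination out of ``L`` carries
    ``eff[L]``); this helper expresses that as explicit out-rates for the
    open-lattice oracle.
    """
    profile = np.asarray(profile, dtype=float)
    L = profile.size
    out = np.empty(L)
    out[:-1] = gamma * profile[1:]
    out[-1] = gamma * profile[-1]
    return out


def apply_move(lattice: TranscriptLattice, ribosome_index: int
               ) -> tuple[TranscriptLattice, Optional[str]]:
    """Advance one unblocked ribosome by a single site, in place.

    Returns ``(lattice, released_class)`` where ``released_class`` is the
    lattice's gene class if the move was a termination (ribosome left the
    lattice, one protein made) and ``None`` otherwise.  Selecting a
    blocked ribosome is a programming error and raises.
    """
    pos = lattice.positions
    j = pos[ribosome_index]
    if j < lattice.L and (j + 1) in pos:
        raise ValueError(f"ribosome at site {j} is blocked; not selectable")
    if j == lattice.L:
        pos.pop(ribosome_index)
        return lattice, lattice.class_x
    pos[ribosome_index] = j + 1
    return lattice, None


def initiation_propensity(class_x: str, state: "CellState",
                          params: "ModelParameters",
                          design: "ConstructDesign") -> float:
    """Ribosome-binding propensity for class ``class_x``.

    ``b_x * RBSH?(x) * r_free * (free mRNAs + occupied mRNAs with site 1
    free)``; firing places a ribosome on site 1 of a target drawn
    uniformly from those eligible.
    """
    if class_x not in params.b:
        raise ValueError(f"unknown gene class {class_x!r}")
    rbs = design.RBSH if class_x == "H" else 1.0
    n_targets = state.m_free[class_x] + sum(
        1 for lat in state.lattices
        if lat.class_x == class_x and 1 not in lat.positions
    )
    return params.b[class_x] * rbs * state.r_free * n_targets


def degradation_propensity(class_x: str, state: "CellState",
                           params: "ModelParameters") -> float:
    """mRNA decay acts on ribosome-free transcripts only (ribosome protection)."""
    if class_x not in params.b:
        raise ValueError(f"unknown gene class {class_x!r}")
    return params.d_m * state.m_free[class_x]


# ----------------------------------------------------------------------
# Exact oracle and event-level simulator for one open-boundary lattice
# ----------------------------------------------------------------------

def _configs(L: int) -> np.ndarray:
    """All 2**L occupancy configurations as rows (site 1 = column 0)."""
    idx = np.arange(2 ** L, dtype=np.int64)
    return (idx[:, None] >> np.arange(L)) & 1


def stationary_oracle(L: int, entry_rate: float, hop_rates: np.ndarray,
                      exit_rate: float) -> tuple[np.ndarray, float]:
    """Exact stationary density and current of one open TASEP lattice.

    Builds the generator over all ``2**L`` occupancy configurations with
    the same blocking rule as the simulator (entry requires site 1 empty;
    the hop from interior site ``j`` requires site ``j+1`` empty; the exit
    hop from site ``L`` is always allowed) and solves ``Q^T pi = 0``.

    Parameters
    ----------
    L:
        Lattice length; limited to 12 to bound the state space.
    entry_rate:
        Initiation propensity onto an empty site 1.
    hop_rates:
        Length-``L`` vector; entry ``j-1`` is the full hop propensity out
        of site ``j`` (i.e. ``gamma * eff[j]``) for interior sites.
    exit_rate:
        Termination propensity out of site ``L`` (overrides
        ``hop_rates[-1]``).

    Returns
    -------
    (density, current):
        Mean stationary occupancy per site, and the steady-state protein
        output flux (= entry flux).
    """
    if L > 12:
        raise ValueError("oracle limited to L <= 12 (state space 2**L)")
    hop_rates = np.asarray(hop_rates, dtype=float)
    if hop_rates.size != L:
        raise ValueError("hop_rates must have length L")
    n = 2 ** L
    Q = np.zeros((n, n))
    for s in range(n):
        occ = [(s >> j) & 1 for j in range(L)]
        if occ[0] == 0:
            t = s | 1
            Q[s, t] += entry_rate
        for j in range(L - 1):
            if occ[j] and not occ[j + 1]:
                t = (s & ~(1 << j)) | (1 << (j + 1))
                Q[s, t] += hop_rates[j]
        if occ[L - 1]:
            t = s & ~(1 << (L - 1))
            Q[s, t] += exit_rate
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    # stationary distribution: pi Q = 0, sum pi = 1
    A = np.vstack([Q.T, np.ones(n)])
    rhs = np.zeros(n + 1)
    rhs[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    cfg = _configs(L)
    density = pi @ cfg
    current = float(entry_rate * pi[cfg[:, 0] == 0].sum())
    return density, current


def simulate_single_lattice(L: int, entry_rate: float, profile: np.ndarray,
                            t_max: float, rng: np.random.Generator,
                            t_burn: float = 0.0
                            ) -> tuple[np.ndarray, float, float]:
    """Event-level simulation of one open lattice with unit ``gamma``.

    Uses the package's transition-vector rule (blocked ribosomes carry
    zero propensity) via :func:`transition_vector` / :func:`apply_move`;
    ``profile`` is the codon-efficiency vector.  Returns time-averaged
    per-site density over ``(t_burn, t_max]``, the exit current
    (terminations per unit time), and the total averaging time.
    """

    class _P:  # minimal parameter shim: gamma(a) == 1 for any a > 0
        gamma_max = 2.0
        K_gamma = 1.0

    eff = np.asarray(profile, dtype=float)
    lat = TranscriptLattice(class_x="X", L=L, positions=[], eff=eff)
    t = 0.0
    occ_time = np.zeros(L)
    n_exit = 0
    while t < t_max:
        tv = transition_vector(lat, 1.0, _P)
        props = list(tv)
        if 1 not in lat.positions:
            props.append(entry_rate)
        total = float(np.sum(props))
        if total <= 0:
            break
        dt = rng.exponential(1.0 / total)
        t_new = min(t + dt, t_max)
        if t >= t_burn:
            occ_time += lat.occupancy() * (t_new - t)
        elif t_new > t_burn:
            occ_time += lat.occupancy() * (t_new - t_burn)
        if t + dt > t_max:
            t = t_max
            break
        t = t_new
        k = rng.choice(len(props), p=np.asarray(props) / total)
        if k < len(tv):
            _, released = apply_move(lat, k)
            if released is not None and t >= t_burn:
                n_exit += 1
        else:
            lat.positions.insert(0, 1)
            lat.validate()
    t_avg = max(t_max - t_burn, 1e-12)
    density = occ_time / t_avg
    current = n_exit / t_avg
    return density, current, t_avg
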