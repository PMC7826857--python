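# Methods

## Model overview

StoCellAtor is a stochastic, resource-limited whole-cell model of a
growing bacterium in which translation is resolved to the level of
individual ribosome movements on every mRNA. The cell's proteome is
coarse-grained into five classes: ribosomal (R), enzymatic — split into
nutrient transporters (ET) and metabolic enzymes (EM) — house-keeping
(Q), and a heterologous construct protein (H). The resource-allocation
backbone (nutrient import, catabolism to a shared energy currency,
energy-gated transcription, growth dilution) follows the mechanistic
growth model of Weisse et al. (PNAS 2015); the one-step translation
reaction of that model is replaced by a totally asymmetric simple
exclusion process (TASEP) per transcript.

All processes are reaction channels of a single exact stochastic
simulation (Gillespie direct method); there are no differential
equations. Time is in minutes. Transcript lengths are measured in
ribosomal footprints (Rf): 1 Rf = 30 nt = 10 aa, one ribosome occupies
exactly one site. R transcripts are 750 Rf (22,500 nt) and all other
classes 30 Rf (900 nt) at full scale.

### Reaction channels

With `a` the energy count, `s_i` internal nutrient, `r` free ribosomes,
`m_x` free mRNAs, and `p_x` proteins:

| process | propensity | effect |
| --- | --- | --- |
| transcription of x | `w_x a/(theta_x + a)`, times `promH` for H, times `1/(1+(p_Q/K_q)^h_q)` for Q | `m_x += 1` |
| mRNA decay | `d_m m_x` (ribosome-free mRNAs only) | `m_x -= 1` |
| initiation | `b_x RBSH?(x) r (m_x + occupied mRNAs with site 1 free)` | ribosome onto site 1 |
| elongation hop | `gamma(a) eff_j` per unblocked ribosome | advance 1 site, `a -= 1` |
| import | `p_ET v_t s/(K_t + s)` (s external, fixed) | `s_i += 1` |
| catabolism | `p_EM v_m s_i/(K_m + s_i)` | `s_i -= 1`, `a += n` |
| dilution | `Grate` per free molecule / per occupied mRNA | removal |

`gamma(a) = gamma_max a/(K_gamma + a)` is the shared elongation rate and
`Grate = gamma(a) B / M` the instantaneous growth rate, with `B` the
number of bound (translating) ribosomes and `M` the protein mass budget
in Rf units. Because each hop deposits one Rf of protein mass, the total
mass flux equals `Grate * M` identically and the steady-state proteome
mass relaxes to `M`. Nutrient quality `n` — energy molecules per
catabolised nutrient — is the proxy for external nutrient concentration
and the knob scanned in the Monod experiment. One energy unit is spent
per Rf hop (a lumped 10-aa elongation cost), so a full-length protein of
`len_x` Rf costs `len_x` units.

Ribosome bookkeeping: the ribosome count is `p_R = r + B` by
construction. A finished R protein immediately joins the free ribosome
pool. Dilution removes free molecules individually; an occupied mRNA is
removed whole, losing its bound ribosomes (partitioning at division).
Ribosome-free mRNAs are the only degradable ones ("ribosome
protection").

### The modified TASEP

Each occupied transcript is a lattice with hard-core exclusion. Only
*authorised* transitions enter the transition vector: a ribosome directly
behind another carries propensity zero and can never be selected, which
leaves the continuous-time law identical to the classic
select-and-reject scheme (verified against the exact stationary master
equation, see below) while avoiding wasted event draws.

**Efficiency convention.** The hop of the ribosome at site `j` carries
the efficiency of the codon it is decoding, i.e. the site it is about to
enter: `gamma(a) * eff[j+1]`; the ribosome on the last site terminates
with `gamma(a) * eff[L]`. This entry-gating convention makes a slow
codon throttle entry into its own position, so the ribosome density
peaks immediately *upstream* of the slow site and drops at and beyond
it — the queue phenomenology the framework is built to capture. (Under
the alternative, departure-gating convention the exact stationary
solution puts the density maximum at the slow site itself; the two
conventions are otherwise equivalent relabelings of the rate profile.)

Initiation requires only site 1 to be free and may target both free
mRNAs and occupied ones with a free initiation site (a config switch can
restrict it to free mRNAs). Backward hops and drop-off are neglected.

### Steady-state rule

A run extends on a doubling time grid until the monitored variable stays
within a tolerance band of its trailing-window mean: at full scale,
within 1% over the last 10% of simulated time, evaluated over the whole
run with no explicit burn-in. Heterologous runs monitor the construct
protein count `p_H`; endogenous runs monitor total proteome mass, which
is pinned to `M` by the mass-flux identity and therefore usable even
when individual protein counts are noisy. Non-converged runs (cap
`max_time` reached) are flagged in the summary, never silently returned.
Steady-state outputs are time averages over the trailing window: growth
rate `Grate` (reported per hour), production rate `Hrate` (H proteins
per cell per hour, from the slope of the cumulative production counter),
the heterologous mass fraction `Hfrac`, the mRNA:protein mass ratio
(330 Da/nt and 110 Da/aa by default; only the linearity of its relation
to `Grate` is ever asserted, which is scale-free), and the per-site
ribosome density on H transcripts.

## Population yield and design scores

With per-cell steady-state rates constant, the population protein yield
is `H(t) = integral of Hrate * N(T) dT`. Two growth scenarios:

- uncapped exponential growth from one cell, `N(t) = 2^(Grate t)`:
  `H_exp(t) = Hrate/(Grate ln 2) (2^(Grate t) - 1)` (series limit
  `Hrate t` as `Grate t -> 0`);
- turbidostat at fixed `N`: `H_tur(t) = Hrate N t`, whose dynamics are
  time-invariant.

Yields over the 3x3 grid of promoter strengths `promH` and RBS strengths
`RBSH` (relative values 1/3, 1, 3, spanning the ~9x range of typical
part libraries) are normalised per time slice by the slice maximum.
The Construct Score of a slice is `Y - X`, where
`X = sum_ij promH_j H_norm[i,j]` and `Y = sum_ij RBSH_i H_norm[i,j]`
(rows index RBS strength, columns promoter strength; the *strengths*,
not the indices, are the weights). Positive scores mean the RBS is the
more efficient knob to raise yield, negative scores favour the promoter,
zero indicates symmetry about the `promH = RBSH` diagonal. The "t = 0"
slice is evaluated over a 1e-12 h interval, which makes it proportional
to the `Hrate` grid. In the turbidostat, `N` and `t` cancel in the
normalisation, so the score is constant in time and independent of the
population size.

## Parameters

Full-scale defaults (`data/default_config.json`) are the fitted values
of Weisse et al. converted to Rf units: `gamma_max = 126` sites/min
(1260 aa/min), `K_gamma = 7`, `M = 1e7` Rf (1e8 aa), `d_m = 0.1`/min,
`b_x = 0.0095`/(molecule min), `w_R = 930`, `w_Q = 948.9`,
`w_ET = w_EM = 4.14` transcripts/min, `theta_R = 426.87`,
`theta_nonR = 4.38`, `K_q = 152219`, `h_q = 4`, `v_t = 726`,
`K_t = 1000`, `v_m = 5800`, `K_m = 1000`, `s_ext = 1e4`. They define a
cell of realistic size (~1e4 ribosomes) that is far too expensive for
routine exact-SSA studies; they are configuration, not assertions.

All shipped experiments run on the **test-scale cell**
(`data/test_scale_config.json`), a self-consistent miniature chosen once
from endogenous diagnostics:

- `M = 2.5e5` Rf, `len_R = 75` (other lengths unchanged), giving
  ~100-400 ribosomes, ~10^2 mRNAs and event rates ~10^4/min;
- `w_R = 1.2`, `w_Q = 15`, `w_ET = w_EM = 1.25`, `w_H = 1` (times
  `promH`), `K_q = 4600`: proteome shares near 5% R / 15% E / 55% Q with
  an R-mRNA pool of >= 5 copies — below that, ribosome-production noise
  dominates the growth rate;
- a single transcription threshold `theta = 427` for every class: with
  the full-scale split thresholds, total mRNA is insensitive to energy
  over the accessible range and the mRNA:protein ratio *falls* with
  growth rate (ribosome protection holds transcripts longer at slow
  elongation), inverting the Schaechter trend; a common threshold
  restores mRNA scaling with energy;
- `v_t = 0.38`, `v_m = 0.3`, `K_m = 100`, `K_gamma = 300`: the energy
  supply/demand crossover sits near `n ~ 60`, so the scan
  `n = 10 ... 210` traverses the hyperbolic rise and the saturated
  plateau of the growth rate; design-grid experiments use the fixed
  `n = 100`;
- convergence guard: `t_initial = 720` min, window 1/3, tolerance 0.75,
  `max_time = 1440` min. At a few hundred copies with 3-4 bursty
  construct mRNAs, `p_H` shows slow +-50-70% excursions, so the 1% rule
  has no useful analogue at this scale; the guard only intercepts
  unfinished transients, and precision comes from the 240-min (or
  longer) averaging window. The relaxation time of every slow pool is
  <= 1/Grate ~ 30 min, an order of magnitude below the first checkpoint.

What the miniature preserves: resource competition between construct and
host expression, energy limitation and Monod saturation, mRNA-protein
scaling, ribosome sequestration by queues and its growth cost. What it
does not: absolute copy numbers and rates (its growth rates, ~0.3-5/h,
are faster than a real cell at the same nominal `n`), the smallness of
relative fluctuations of a full-size cell, and any quantitative
correspondence to measured E. coli parameters. Conclusions drawn from
the shipped experiments are therefore about trends, orderings and fitted
shapes, never absolute values.

## Numerical choices

- Exact direct-method SSA; all propensities are recomputed each event
  from O(1) scalars plus per-lattice hop weights maintained
  incrementally (the global weight is refreshed exactly every 2^16
  events to cancel float drift).
- The production engine is a numba kernel operating on a flat occupancy
  matrix (capacity 8192 lattices; exceeding it is a hard error, not a
  silent truncation). A pure-Python reference SSA implements the same
  reaction set on transparent objects; the test suite drives both and
  cross-checks the lattice law against an exact 2^L master-equation
  oracle.
- Observables are sampled on a fixed 0.2-min grid (0.1 at full scale);
  the H-transcript occupancy histogram is accumulated per sample and
  averaged over the steady window.
- Randomness: one integer seed per run; segment streams are derived via
  `numpy.random.SeedSequence`, making (seed, config) -> trajectory
  bit-reproducible.
- Grid cells average >= 1 replicate seeds (default 3 in the analysis
  layer); seeds are recorded in the grid object.
- Degenerate inputs: zero-energy states have zero transcription and
  elongation propensity (energy can never go negative); an all-zero
  yield slice, an empty proteome and an empty steady window raise
  errors rather than returning NaNs.

## Design choices where the design was open

- The enzymatic class is split into ET/EM with identical expression
  parameters, preserving the import/catabolism structure of the
  backbone model; reports aggregate E = ET + EM.
- `p_R` is implicit (`r + B`): ribosomes are diluted through the free
  pool and through lattice loss, avoiding double counting.
- Bound ribosomes are lost when their lattice is diluted (partitioning)
  rather than returned to the free pool.
- Initiation on occupied transcripts is allowed by default
  (`init_on_occupied`), since nothing physically distinguishes an
  occupied mRNA with a free initiation site from a free one.
- The energy dependence `gamma(a)` multiplies every hop uniformly;
  codon efficiency is a static per-site factor.

## Known limitations

- No tRNA-pool dynamics, nucleotide-level sequence, cotranslational
  folding, toxicity or metabolic burden beyond resource competition; no
  mutation dynamics or population structure — single-cell steady states
  feed closed-form population formulas instead.
- The chemostat is not modelled (only exponential and turbidostat
  scenarios).
- The exact SSA limits practical cell sizes; tau-leaping or hybrid
  schemes would be needed for the full-scale default parameters.
- The steady-state detector is a pragmatic rule, not an ergodicity
  test: for strongly bursty low-copy regimes it degenerates into a
  transient guard (see above), and window averages carry the residual
  slow-mode noise visible in replicate scatter.
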