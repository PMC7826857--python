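# stocellator

**StoCellAtor** — a stochastic, resource-limited whole-cell model of a
bacterium with codon-resolution translation, for predicting how the
design of a synthetic gene construct (promoter strength, ribosome
binding site strength, codon composition) trades off heterologous
protein yield against growth, per cell and across a growing population.

It is aimed at synthetic biologists and modellers who want to reason
about **gene expression burden** and **ribosomal queues**: slow codons
stall ribosomes, stalled ribosomes sequester a shared, finite
translation capacity, and that sequestration feeds back on growth rate
and therefore on population-level yield in continuous culture.

## The model in brief

A single cell carries five proteome classes — ribosomal (R), enzymatic
(split into transporters ET and metabolic enzymes EM), house-keeping
(Q), heterologous (H). Every process is a reaction channel of one exact
stochastic simulation (Gillespie direct method):

- metabolism: import `p_ET·v_t·s/(K_t+s)`, catabolism
  `p_EM·v_m·s_i/(K_m+s_i)` yielding `n` energy units per nutrient
  (`n` is the nutrient-quality knob);
- transcription: `w_x·a/(θ_x+a)`, scaled by `promH` for the construct
  and autoinhibited for Q;
- translation: each mRNA is a TASEP lattice of 30-nt ribosomal
  footprints. A ribosome at site `j` hops forward with propensity
  `γ(a)·eff[j+1]` — blocked ribosomes carry zero propensity and are
  never selected (the "transition vector" scheme). Termination releases
  one protein; ribosome-free mRNAs (and only those) decay at `d_m`;
- growth: `Grate = γ(a)·B/M` with `B` the bound-ribosome count, and
  every species is diluted at `Grate`.

From per-cell steady states `(Grate, Hrate)` the package computes
population yields

- exponential growth: `H_exp(t) = Hrate/(Grate·ln2)·(2^(Grate·t) − 1)`,
- turbidostat (fixed `N` cells): `H_tur(t) = Hrate·N·t`,

normalises them over a 3×3 grid of promoter/RBS strengths (1/3, 1, 3)
and condenses each time slice into the **Construct Score** `Y − X`
(RBS-weighted minus promoter-weighted sum of the normalised grid):
positive ⇒ a stronger RBS buys more yield, negative ⇒ a stronger
promoter does, zero ⇒ symmetric.

See `docs/methods.md` for assumptions, parameters, units, and the
reduced "test-scale" cell that all shipped experiments run on.

## Worked example

Simulate the core queue-forming scenario — a construct with one slow
codon (0.5% relative efficiency) at footprint 26 of 30, weak promoter
(`promH = 1/3`) and strong RBS (`RBSH = 3`) — against the same design
with uniform codons:

```python
import numpy as np
from stocellator import test_scale_config, simulate_to_steady_state
from stocellator.presets import get_preset

cfg = test_scale_config()
for name in ("uniform", "slow-codon"):
    design = get_preset(name).design.replace(promH=1/3, RBSH=3.0)
    _, s = simulate_to_steady_state(cfg.parameters, design,
                                    cfg.simulation, seed=11)
    peak = int(np.argmax(s.h_density)) + 1
    print(f"{name:10s}  Grate={s.grate:5.2f}/h  Hrate={s.hrate:6.1f}/h  "
          f"density peak at footprint {peak}")
```

prints

```
uniform     Grate= 3.59/h  Hrate=2064.2/h  density peak at footprint 10
slow-codon  Grate= 1.79/h  Hrate= 185.9/h  density peak at footprint 25
```

The slow codon halves the growth rate and collapses production by ~90%:
ribosomes queue upstream of footprint 26 (the density histogram peaks at
25, against a roughly flat profile for uniform codons), sequestering
translation capacity the rest of the cell needs. The same comparison
over the full design grid shows the headline design principle: with
queues present, raising the promoter beats raising the RBS
(Construct Score ≈ −1.4 in a turbidostat, vs ≈ +0.07 without queues).

Command-line equivalents:

```bash
stocellator presets                      # available codon scenarios
stocellator simulate --test-scale --seed 11 --out run/
stocellator scan --test-scale --scenario slow --seed 1 --out grid.csv
stocellator yield --grid-results grid.csv --mode tur --times 0,4,8,24 \
    --N 1000000000 --out yield.csv       # + yield.scores.csv
stocellator growth-laws --test-scale --seed 1 --out laws.json
stocellator reproduce construct-score --seed 1 --out results/
```

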