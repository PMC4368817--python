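# epperm

Quantification of electroporation-induced microvascular permeability from
intravital fluorescence microscopy time series.

## The problem

Electroporation (EP) — trains of short high-voltage pulses — transiently
permeabilizes not only cell membranes but also the walls of skin
microvessels, letting macromolecules (antibody- and plasmid-sized dextrans
of 70 and 2000 kDa) leak from blood into the interstitium. In a dorsal
window chamber, the mean fluorescence F(t) of a region of interest
containing only microvessels rises when a labelled dextran bolus is
injected (intravascular signal), then decays with renal clearance, and —
after the pulses — rises again as tracer accumulates in the tissue. This
package turns such traces into a physical transport coefficient: the
**apparent wall diffusion coefficient** `D_wall` (μm²/s) of the
permeabilized microvessel wall, and the derived **apparent permeability**
`P_wall = D_wall / d_wall` (cm/s, with `d_wall` the ~1 μm wall thickness).
"Apparent" because any convective leakage is lumped into the coefficient.

## The model

Two interconnected models are fitted in sequence:

1. **Pharmacokinetics.** The bolus enters the blood from the orbital sinus
   with first-order rate `k_a` and is cleared with rate `k_e`, giving the
   Bateman intravascular amount
   `m_iv(τ) = dose·k_a/(k_e−k_a)·(e^(−k_a τ) − e^(−k_e τ))` and the
   capillary concentration `c_iv(t)` that drives transport. The rates are
   fitted to the pre-pulse trace (Phase II), where the signal is purely
   intravascular.

2. **Transport.** Capillaries are long parallel tubes on an
   equilateral-triangle lattice (radius 3.5 μm, wall 1 μm, spacing 60 μm,
   four layers centred in a 300 μm skin slab), so Fick's second law
   `∂c/∂t = ∇·(D(x,t)∇c)` is solved on a 2-D unit cell with symmetry side
   walls. The wall coefficient is a delayed ramp `D_wall(t)`: zero until
   `T_del`, linear to its saturated value `D_wall` at `T_sat`, constant
   after. The lumen is held at `c_iv(t)`; tissue has constant `D_tiss`
   (30 μm²/s for 70 kDa, 5 for 2000 kDa). The solver is a conservative
   finite-volume scheme with Peaceman–Rachford ADI time stepping.

The three ramp parameters `(D_wall, T_del−T_EP, T_sat−T_del)` are
estimated by a seeded genetic algorithm (with Nelder–Mead polish)
minimizing the squared residuals between the normalized model signal
`m_iv(t)` (+`m_ev(t)` after the pulses) and the normalized trace.

## Worked example

Everything is testable without data: the `synthetic` module generates
traces from known ground truth. Here a noiseless EP experiment with true
`D_wall = 0.008 μm²/s`, onset delay 60 s and ramp 300 s is generated and
re-analysed:

```python
from epperm import GAConfig, MicrovascularPermeabilityModel, default_truth, make_schedule, simulate_trace

schedule = make_schedule()                       # the A–E acquisition protocol
truth = default_truth(schedule, d_sat=0.008, noise_cv=0.0)
dataset = simulate_trace(schedule, truth)

model = MicrovascularPermeabilityModel(dataset.trace, d_tiss=30.0)
results = model.fit(GAConfig(population=12, max_generations=8, seed=3))
print(results.summary())
```

```
Microvascular permeability estimate (apparent wall coefficient)
================================================================
samples (phase II/III)                    99
tissue coefficient D_tiss                 30  um^2/s
uptake rate k_a                         0.02  1/s
clearance rate k_e                    0.0005  1/s
----------------------------------------------------------------
wall coefficient D_wall                0.008  um^2/s
permeability P_wall                    8e-07  cm/s
onset delay T_del - T_EP                  60  s
ramp duration T_sat - T_del              300  s
----------------------------------------------------------------
objective (SSR)                    7.416e-14
GA generations                             8
converged                               True
phase III linearity R^2               0.9851
================================================================
```

The fit recovers the generating parameters to a fraction of a percent:
`D_wall = 0.008 μm²/s` maps to `P_wall = 8×10⁻⁷ cm/s` over the 1 μm wall,
and the post-pulse accumulation is nearly linear (R² = 0.985), as expected
once the ramp saturates. `results.sensitivity()` refits over a `D_tiss`
grid, and `results.plot_fit()` overlays data and model.

A thin CLI covers the same pipeline from the shell:
`epperm simulate | mask | fit | sweep | report` (see `epperm <cmd> -h`).

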