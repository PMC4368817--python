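# Methods

This note records the modelling choices, numerical schemes, defaults and
known limitations of `epperm`. Units throughout: lengths in μm, times in
s, diffusion coefficients in μm²/s, permeability in cm/s; amounts are
per unit capillary length (area integrals of concentration over the 2-D
cross-section).

## Signal model and preprocessing

The measured trace is modelled as `F(t) = background + κ·m(t)`, where
`m(t)` is the dextran amount in the imaged region: intravascular only
(`m_iv`) before pulse delivery, intravascular plus extravascular
(`m_iv + m_ev`) after. Fluorescence is taken proportional to the amount
of tracer in view; the gain κ and the effective blood volume are
therefore unidentifiable and are removed by preprocessing: the mean of
the pre-injection (Phase I) samples is subtracted from every sample, and
the trace is divided by its maximum over the pre-pulse Phase II window.
Every downstream quantity is invariant to rescaling the raw intensities
by any positive constant; this is enforced by tests.

Phases use a half-open convention: a sample at exactly the injection
time belongs to Phase II, one at exactly the pulse time to Phase III.

## Acquisition schedule

The default schedule reproduces the experimental protocol: interval A
(300 s at one frame per 20 s; injection at its end), B (120 s at 5 s,
starting after a 10 s acquisition restart gap), C (600 s at 20 s; pulses
at its end), D (600 s at 20 s), E (1800 s at 120 s). Frames sit at
interval starts plus integer multiples of the period, strictly inside
each interval. With the 10 s gap the pulse lands 730 s after the
injection; the commonly quoted "12 minutes" is the rounded version of
the same arithmetic. Frame timestamps are interval-start aligned — the
alignment within a frame period is not observable at the fitted
timescales.

## Pharmacokinetics

Uptake from the orbital sinus into blood and clearance from blood are
first order (a standard absorption–elimination cascade), giving the
Bateman form for `m_iv(τ)` with the confluent limit
`dose·k_a·τ·e^(−k_a τ)` used when `|k_a − k_e| < 1e-9·k_a` to avoid
catastrophic cancellation. Defaults `k_a = 0.02 /s`, `k_e = 5e-4 /s`
place the intravascular peak ~3 min after injection with visible decay
within 10 min, matching the qualitative time course of the experiments;
`dose` and `v_blood` are fixed to 1 (unidentifiable under
normalization).

`fit_pk` estimates the rates from the Phase II samples only — before the
pulses the signal is purely intravascular, since 70 kDa and larger
dextrans do not extravasate from homeostatic skin on this timescale. The
fit is least squares in log-parameter space with a free amplitude.
The amplitude could in principle be pinned by the normalization (the
model maximum mapped to the data maximum), but the sample maximum of a
noisy trace is biased upward and that bias propagates into the rates;
with a free amplitude the estimator is unbiased in practice and
identical on noiseless data. Preconditions: at least 6 samples spanning
the rise and 3 past the empirical peak. A small multistart guards
against the (mild) k_a/k_e exchange ambiguity.

## Transport model

Geometry: capillaries of radius r = 3.5 μm with a w = 1 μm wall, centres
on an equilateral-triangle lattice with spacing a = 60 μm, four
horizontal layers starting h = 72 μm below each surface of an H = 300 μm
slab (layers at 72, ~124, ~176, ~228 μm; the packing consistency check
verifies h + (n_layers−1)·a·√3/2 ≈ H − h within 5% of H). Because the
tubes are long and parallel, transport is 2-D; by periodicity the domain
is a half-spacing unit cell [0, a/2]×[0, H] with zero-flux (symmetry)
side walls, on which capillaries appear as half cross-sections.

Discretization: conservative finite volume on a square grid (default
resolution 1 μm — the coarsest that resolves the wall). Face
diffusivities are exact line integrals of 1/D along the segment joining
the two adjacent cell centres, evaluated from the analytic circles:
lumen portions contribute no resistance (well-mixed plasma), wall
portions resistance `L_wall/D_wall(t)`, tissue portions
`L_tiss/D_tiss`. This honours the wall's diffusive resistance
(w/D_wall) independently of how the thin ring rasterizes; with plain
per-cell harmonic averaging the wall conductance changed by ~10% on grid
halving, with path integrals the change is ~0.1%.

Boundary conditions: Dirichlet `c = c_iv(t)` on lumen cells (no
diffusive resistance inside the well-mixed plasma), zero flux at the
outer surfaces z = 0 and z = H (glass cover and intact epidermis) and at
the symmetry side walls. Initial tissue concentration is zero. The
wall–tissue partition coefficient is 1 (no partitioning is modelled).

Time stepping: Peaceman–Rachford ADI (alternating implicit x/z sweeps
with Thomas solves), unconditionally stable and second order in time;
`D_wall` is evaluated at the half step. Default step 10 s (halving it
changes `m_ev` by ~2e-5 relative). With a sealed lumen the scheme
conserves the wall+tissue amount to machine precision per step, which
the tests assert at 1e-10. Because `D_wall(t) = 0` before `T_del` and
the tissue starts empty, the field is identically zero until the delay;
integration therefore starts at `T_del`. The kernel is numba-compiled;
one forward solve of the default unit cell over a full experiment takes
~60 ms.

`m_iv(t)` is `c_iv(t)` times the rasterized lumen area, `m_ev(t)` the
area integral of concentration over tissue cells (the thin wall ring's
content, <1% of the tissue signal at these parameters, is not counted as
extravascular). The model trace normalizes `m_iv + m_ev` by its maximum
over the pre-pulse samples, mirroring the data normalization exactly.

Validation is two-fold and part of the test suite: (i) an independent
brute-force explicit (FTCS) solver with its own rasterization and
numerically sampled path integrals, run at 4× finer resolution, agrees
with the production scheme within 1% on a one-capillary cell; (ii) grid
halving on the production unit cell changes `m_ev` at the end of the
experiment by ~0.1%.

## Wall permeabilization ramp

The apparent wall coefficient is zero before the pulses, stays zero for
a delay `T_del − T_EP` (attributed to transient vasoconstriction of
afferent vessels), rises linearly to its saturated value `D_wall`
between `T_del` and `T_sat`, and stays constant to the end of
observation. The model deliberately excludes the eventual resealing of
the wall (reported at 30–60 min post-pulse) — it describes early times
only. A control experiment is the same model with `D_wall = 0`.

## Inverse problem

The three ramp parameters are estimated by minimizing the sum of squared
residuals between normalized model and normalized trace over Phases II
and III (equal per-sample weights). The landscape has a curved
delay/ramp trade-off valley, so a global stochastic search is used:
a genetic algorithm with tournament selection (size 3), blend (BLX-0.5)
crossover at rate 0.7, Gaussian mutation (σ = 0.1 of the normalized gene
range) at rate 0.2, one elite, all driven by a single seeded generator —
identical seeds give identical results. `d_sat` is searched in log10
space over [1e-4, 0.1] μm²/s; delay over [0, 600] s; ramp over
[10, 1800] s. These bounds comfortably contain physiological
permeabilizations without encoding any particular outcome. The GA run is
followed by a Nelder–Mead polish of the best individual (default on);
the GA locates the basin and the polish closes the last 2–3 orders of
magnitude of the objective far more cheaply than additional generations
would. Defaults (population 24, ≤60 generations with early stopping,
polish ≤300 evaluations) converge on traces of this length; the tests
and the acceptance script use a reduced budget (population 12, 8
generations) that the polish compensates for. Forward solutions are
cached per candidate, which matters because elites are re-evaluated
every generation. A forward-solver failure maps to a large finite
penalty (1e6) and is logged rather than raised.

Fitting is two-stage — pharmacokinetics first on the pre-pulse window,
wall parameters second with the rates held fixed — mirroring the
two-interconnected-models structure; this keeps the wall search
three-dimensional and the PK estimate independent of the
permeabilization model.

Group analysis (`fit_group`) fits each trace independently and reports
the median `d_sat`; the median of an even count is the mean of the two
middle values. Medians are used instead of means because group sizes are
small (n = 3) and outliers occur (a poorly coupled pulse application
shows up as a shallow accumulation slope); no outlier rejection is
applied.

## Synthetic data

The generator is the package's study-condition definition, not a test
dial. Defaults: Bateman kinetics as above; wall ramp with saturated
coefficient 0.008 μm²/s reached 60 s + 300 s after the pulses (the scale
of the measured permeabilizations); `D_tiss` 30 μm²/s; constant
background 100 a.u.; gain 1 (recorded in the truth for oracle tests —
the pipeline is invariant to it); multiplicative Gaussian noise
`F·(1 + cv·ε)` with cv = 3% (measurement noise summaries are reported as
standard errors in this kind of experiment but no noise model is
identified; multiplicative Gaussian is the simplest defensible choice,
and the Phase I residual CV converges to the nominal cv, which is
tested). One seed governs a whole dataset; identical inputs are
bitwise reproducible.

Rendered image stacks place wide vertical "large-vessel" stripes
(tracking `c_iv(t)`) on a diffuse microvascular field (tracking the
region-of-interest mean) with Gaussian or Poisson pixel noise, and emit
the ground-truth mask alongside. What the generator does **not**
emulate: vasoconstriction dynamics of large vessels, photobleaching,
animal motion/registration error, spatial heterogeneity of the
microvascular field, or tracer polydispersity. Passing the recovery
tests therefore demonstrates correctness of the inference machinery
under the model's own assumptions, not robustness to those effects in
real data.

## Image analysis

The vessel mask is built from the last pre-pulse frame: subtract a
Gaussian low-pass (default σ = 6 px — well above the ~1 px capillary
scale at 3.4 μm/px, well below typical large-vessel widths) from the
original, threshold the high-pass residue (Otsu's rule by default, with
a manual override), then morphologically close (3×3) and drop components
under 32 px. A constant frame with the automatic threshold returns an
explicit "no vessels detected" empty mask. Raising the threshold never
adds pixels (closing and small-object removal are inclusion-monotone).
The published analysis additionally corrected masks manually and
registered frames in external software; both are out of scope here and
frames are assumed aligned. The trace is the per-frame mean over
unmasked pixels.

## Sensitivity analysis

`D_tiss` is a literature value, so the full inverse problem is repeated
over a grid (default {2, 5, 10, 30, 50, 70} μm²/s — six points spanning
the published range at desk-scale runtime). Because the fitted wall
coefficients sit three orders of magnitude below `D_tiss`, the wall is
the rate-limiting resistance and the fitted `d_sat` barely moves: on
synthetic data the spread over a 14× `D_tiss` range is a few percent
(the acceptance check bounds it by 2×, a deliberately loose ceiling
fixed by the recovery simulation).

## Derived quantities

`P_wall = D_wall/d_wall` with `d_wall` defaulting to the geometric wall
thickness w = 1 μm, converted μm/s → cm/s (×1e-4); on the customary
1e-7 cm/s scale, P over a 1 μm wall is numerically 1000·D. The expected
free-diffusion ratio between the two tracer sizes follows Stokes–
Einstein from their hydrodynamic radii (6.49 nm for 70 kDa, 26.89 nm for
2000 kDa — literature constants, not recomputed from temperature and
viscosity). The post-pulse linearity diagnostic is the R² of an ordinary
least-squares line through Phase III, defined as 0 for a zero-variance
trace. The electrode gap (6 mm) is carried as config metadata only
(e.g. 1300 V/cm × 0.6 cm = 780 V as a consistency check); no electric
field is computed spatially.

## Problem sizes and numerical defaults

Default analyses use the 30×300-cell unit cell (1 μm resolution), 10 s
ADI steps, GA population 12–24 with ≤8–60 generations plus polish; the
noisy-recovery study uses 20 replicate seeds; the solver oracle runs a
20×20 μm one-capillary cell at 0.25 μm/explicit vs 1 μm/implicit. These
sizes keep a full test-plus-acceptance cycle within minutes on one CPU
while every reported tolerance retains a comfortable margin.

## Known limitations

- Convection through the permeabilized wall is not modelled separately;
  the fitted coefficient is *apparent* and absorbs it.
- The wall coefficient does not reseal; estimates are meaningful only
  for the first ~40 min after the pulses.
- Large-vessel permeability, vasoconstriction and vessel-size dependence
  are excluded by design (masked out of the data, absent from the model).
- `m_iv` uses the rasterized lumen area of the unit cell; an independent
  measurement of the intravascular volume fraction would replace it.
- Per-trace pharmacokinetic fitting uses the pre-pulse window only; with
  control experiments available, pooling Phase III control data would
  tighten `k_e`. An option to pool is provided at the API level
  (`fit_pk` accepts any sample set), but the default mirrors the
  two-stage, pre-pulse-only protocol.
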