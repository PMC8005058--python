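# Methods

This note documents the physical model behind `amzi-twin`, the parameters
that matter, the numerical choices, and what the simulation does and does
not capture about a real aMZI biosensor instrument.

## Interferometer model

Each sensor element is a two-beam interferometer with transmission
`T = ½(1 + cos Δφ)`.  The phase difference is modelled as

    Δφ = (2π/λ) · OPD,     OPD = n_g · ΔL_asym + Δn_eff · L,

combining a static geometric asymmetry (which sets the free spectral range)
with the analyte-induced effective-index change over the sensing arm of
length `L`.  The published transfer-function and FSR expressions each show
only one of these two terms; a working twin needs both simultaneously — an
interferometer that is asymmetric (so it has fringes to track) *and*
analyte-sensitive.  The group index is used in the static term because group
delay, not phase index, sets the fringe spacing of a dispersive
interferometer.

Sign convention: an index increase in the sensing window lengthens the OPD
and red-shifts the fringes; the demodulator reports red shifts as positive
pm.  (The underlying data sheets never state a sign; this is our choice,
applied consistently.)

### Two sensitivity scales

The closed-form fringe sensitivity `S = L·FSR/λ` for the default geometry
(L = 12.5 mm, FSR = 1500 pm, λ = 850 nm) evaluates to ≈22 059 nm per unit of
*effective-index* change.  The headline bulk sensitivity of such sensors is
quoted as up to 5000 nm/RIU of *cladding-index* change; the two differ by
the mode-confinement factor ∂n_eff/∂n_bulk, which is not published for this
stack and which we deliberately do not guess.  `AMZIDesign` therefore
exposes both: the closed form, and a `sensitivity_override` that pins the
bulk value.  All default configurations pin 5000 nm/RIU, and bulk-index
inputs are interpreted on that pinned scale.

## Instrument and noise model

The reader sweeps a VCSEL with a 10 Hz sawtooth, sampling 8 photodiodes at
1000 samples per cycle (10 kHz each).  The sweep is modelled as linear in
wavelength over a span of two FSRs (3000 pm) centred at 850 nm.  Real
current-tuned VCSELs are linear in current, not wavelength; since
demodulation is per cycle and relative, residual ramp nonlinearity is a
common-mode effect we neglect.  The span itself is not a published quantity;
two FSRs keeps ≥2 full fringes per record so the Fourier phase estimate is
well conditioned, and an integer number of FSRs places the fringe exactly on
a DFT bin (hence no window function by default).

The measurement-noise budget is specified directly in wavelength-equivalent
pm per component so the quadrature law `3σ = 3√(σ_a² + σ_s² + σ_t²)`
composes them; conversions from physical units (RIN, kelvin) are out of
scope.  Components are injected where they physically act:

* **amplitude** — white intensity noise per sample, per channel,
  independent across channels.  Its standard deviation is calibrated
  analytically from the DFT phase-estimator statistics
  (`σ_φ = σ_I·√(2/N)/A` for a fringe of amplitude `A` in `N` samples) so
  that the *demodulated position* noise equals `σ_ampl`;
* **spectral** — per-cycle jitter of the whole wavelength ramp, common to
  all channels, white across cycles;
* **temperature** — common-mode OPD drift, a stationary AR(1) process with
  a 5-cycle correlation time and wavelength-equivalent stationary sigma
  `σ_temp`.

Because each component carries its exact wavelength-equivalent sigma, the
demodulated baseline 3σ converges to the composed budget; the quadrature
law is verified by simulation, not assumed by the demodulator.  Defaults
use three equal components composing to 3σ = 0.8 pm, the instrument's
measured noise floor, which with the pinned sensitivity gives the reference
LoD of 1.6 × 10⁻⁷ RIU.

## Assay model

Six sensing aMZIs carry an antibody-spotted (or deliberately unspotted,
BSA-blocked) sensing arm and a mouse-IgG-spotted reference arm; the channel
signal is the difference of its two arms.  Surface binding follows 1:1
Langmuir kinetics, solved in closed form per fluidic step (concentration is
piecewise constant, so each step is an exponential relaxation to its own
equilibrium).  Defaults: k_on = 1×10⁵ M⁻¹s⁻¹, k_off = 1×10⁻⁴ s⁻¹
(K_D = 1 nM, typical of a good monoclonal), capacities of 2500 pm (TGFBI,
68 kDa) and 4000 pm (POSTN, 90 kDa) chosen so saturated serum-level
responses land in the low thousands of pm.  No kinetic constants are
published for these assays; these are defaults to be overridden per use.
They make a 10 ng/mL sample resolvable well above the 0.8 pm floor within
minutes, consistent with the reported assay sensitivity.

Phenomenological background terms:

* nonspecific adsorption on every protein-coated arm, proportional to
  analyte concentration — it largely cancels within a balanced channel,
  which is the point of the mIgG reference arm;
* cross-reactive adsorption on non-cognate antibody arms above a
  concentration threshold (default 1 µg/mL, matching the observed POSTN
  cross-reactivity onset), linear in the excess concentration;
* a signed control drift on unspotted channels during serum exposure
  (default −1 pm/s at 10 % serum, scaling linearly with serum fraction).
  Real control channels reproducibly drift opposite to the binding signal;
  the mechanism is debated (surface rearrangement, reversible adsorption),
  so the twin models the phenomenon without asserting a mechanism.

Bulk refractive-index changes pass through a transport lag (default 15 s —
the observed delay between switching pumps and the signal responding) and a
first-order mixing transient (default τ = 5 s).  The NaCl refractive-index
increment is 0.0102 RIU per mol/L, so the 40 mM salt step is −4.08 × 10⁻⁴
RIU, which the pinned 5000 nm/RIU sensing channels read as ≈2040 pm.

## Demodulation and analysis

Per cycle and channel: rFFT, dominant non-DC bin (ties toward lower
frequency), phase = argument at that bin in (−π, π]; flat traces are
flagged low-contrast instead of raising.  Across cycles: nearest-multiple-
of-2π unwrapping, valid while the shift rate stays below FSR/2 per cycle
(steps above 0.9π are recorded as warnings); conversion to pm via FSR/2π;
baseline zeroing over a configurable window (default the first 10 s).
Differential referencing subtracts the nearest control channel pointwise.

Resolution is 3× the sample standard deviation of the baseline position
(window must hold ≥30 cycles and no programmed step); LoD divides by the
pinned sensitivity.  Step analysis takes plateaus as the mean of the last
40 % of each step and detects transitions at 5× the previous plateau's
noise; neither fraction nor threshold is published, both are configurable.
The bulk and internal-reference outputs serve as run-validity monitors: a
QC flag is raised if they drift beyond a configurable bound (relaxed for
the salt-step fixture, where the bulk monitor is *supposed* to respond).

Known numerical limitation: the interferogram phase 2π·OPD/λ is not exactly
linear across the sweep (a ~0.01 rad chirp at the default span), which
biases absolute extracted phases slightly; the bias is common mode and
cancels to first order in baseline-zeroed sensorgrams, leaving ≈0.01 %
error on large shifts (e.g. 0.4 pm on a 3000 pm ramp).

## Fixtures, problem sizes, and what passing means

The three fixtures mirror the instrument's validation experiments at desk
scale: a TGFBI-then-POSTN titration (100–2500 ng/mL, 120 s per step), a
10 % serum incubation (600 s) with unspotted controls on aMZIs 2 and 4, and
alternating PBS / reduced-NaCl steps (60 µL per phase at 48 µL/min, hence
75 s, validated by the program's volume bookkeeping).  Long programs are
simulated at a reduced record rate (every 5th–10th sweep cycle) — the
per-cycle physics is unchanged, only the sensorgram sampling density —
and baseline noise runs use 250–500 full-rate cycles.

The generator emulates the *structure* of real experiments: specific and
cross-reactive binding, serum background with opposite-signed controls,
bulk steps with fluidic lag, a calibrated noise floor.  It does not emulate
mass-transport depletion, flow-cell dispersion beyond first order,
chip-to-chip spotting variability, or patient-serum matrix effects; serum
response magnitudes are therefore qualitative (signs and orderings are
meaningful, absolute pm values are not), and passing tests demonstrate the
correctness and internal consistency of the processing chain, not clinical
performance.

Degenerate inputs (zero lengths, zero sensitivity, non-finite phases,
mismatched volumes, unknown analytes, 7-output layouts) are rejected with
explicit domain/configuration errors rather than propagating infinities.
All stochastic stages draw from per-purpose generators spawned
deterministically from a single seed; identical config + seed reproduces
every output byte for byte.
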