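# amzi-twin

A digital twin of a multiplexed **asymmetric Mach–Zehnder interferometer
(aMZI) photonic biosensor** for blood-borne protein biomarkers.  It simulates
the full measurement chain of an evanescent-field refractometric immunosensor
— analyte binding on antibody-spotted sensing windows, the resulting
effective-index change, swept-wavelength interferogram acquisition with a
three-component noise budget, Fourier phase demodulation, differential
referencing — and computes the standard performance figures of such a sensor.

It is aimed at people developing or characterising integrated photonic
biosensors who want a controllable, reproducible software stand-in for the
instrument: for prototyping demodulation and referencing algorithms, for
budgeting noise against a target limit of detection, and for generating
realistic sensorgrams without a wet lab.

## The model

An aMZI splits guided light into two arms of unequal optical path and
recombines them; the transmitted power is

    T(Δφ) = ½ (1 + cos Δφ),      Δφ = 2π · OPD / λ,

so transmission is periodic in wavelength with free spectral range

    FSR = λ₀² / (n_g · ΔL),      n_g = n_eff − λ₀ · dn_eff/dλ,

where ΔL is the arm asymmetry and n_g the group index.  Analyte binding in
the exposed sensing window raises the mode's effective index and red-shifts
the fringes with sensitivity

    S = Δλ / Δn = L · FSR / λ_res   [nm/RIU],

with L the sensing-arm length.  The resolution R is taken as 3× the standard
deviation of the measured fringe position, composed from amplitude, spectral
and temperature noise in quadrature,

    3σ_meas = 3 √(σ_ampl² + σ_spect² + σ_temp²),

and the limit of detection is **LoD = R / S**.  The default design (FSR =
1500 pm, L = 12.5 mm at λ = 850 nm, pinned bulk sensitivity 5000 nm/RIU,
3σ = 0.8 pm) gives LoD = 1.6 × 10⁻⁷ RIU.

The simulated instrument is an 8-output chip (6 antibody-spotted sensing
aMZIs, 1 low-sensitivity bulk monitor, 1 unexposed internal reference) read
out by a current-swept VCSEL: a 10 Hz sawtooth sweeps the wavelength while
each photodiode is sampled 1000 times per cycle (10 kHz).  Each cycle's
sine-like interferogram is demodulated by taking the phase of the dominant
non-DC Fourier bin; phases are unwrapped across cycles and converted to pm
via FSR/2π.  Surface binding follows 1:1 Langmuir kinetics driven by a timed
fluidic program; bulk refractive-index steps pass through a transport lag
and first-order mixing.

## Worked example

```bash
amzi-twin describe
```

```json
{
  "fsr_pm": 1500.0,
  "group_index": 2.0,
  "sensitivity_nm_per_riu": 5000.0,
  "fringe_sensitivity_nm_per_riu": 22058.823529411766,
  "noise_3sigma_pm": 0.8,
  "lod_riu": 1.6e-07,
  "sample_rate_hz": 10000.0
}
```

`fsr_pm` is the fringe spacing of the default interferometer;
`sensitivity_nm_per_riu` is the pinned bulk-cladding sensitivity while
`fringe_sensitivity_nm_per_riu` is the closed-form effective-index
sensitivity L·FSR/λ (larger, because it does not include the
evanescent-field confinement of the mode); `lod_riu` is the smallest
reliably detectable index change for the 0.8 pm noise budget.

A full stochastic run — simulate 250 noisy baseline sweep cycles,
demodulate, and estimate resolution and LoD from the data:

```bash
amzi-twin lod --seed 1 --cycles 250
```

```json
{
  "cycles": 250,
  "estimated_resolution_pm": 0.8174402285249713,
  "sensitivity_nm_per_riu": 5000.0,
  "estimated_lod_riu": 1.6348804570499425e-07
}
```

The estimated 3σ resolution lands on the injected 0.8 pm budget and the
measured LoD on 1.6 × 10⁻⁷ RIU, showing the noise injection, demodulation
and the quadrature budget are mutually consistent.

Canned desk-scale experiments (a two-analyte spiked-buffer titration of
TGFBI and POSTN, a 10 % serum incubation with unspotted control channels,
and alternating PBS / reduced-NaCl bulk steps) are available as fixtures:

```bash
amzi-twin fixture salt_steps --out salt.yaml
amzi-twin run --config salt.yaml --seed 7 --out results_salt/
amzi-twin steps --config salt.yaml --seed 7
```

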