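"""Swept-wavelength acquisition chain of the eight-channel aMZI reader.

A current-tuned VCSEL is driven with a 10 Hz sawtooth; every cycle sweeps the
emission wavelength linearly across a span around 850 nm while eight
photodiodes sample the aMZI outputs 1000 times per cycle (10 kHz per diode).
Each record therefore holds a sine-like interferogram per channel whose
fringe phase encodes the optical path difference of that interferometer at
that moment.

Noise is injected per the three-component wavelength-equivalent budget:

* amplitude noise — white intensity noise per sample, with its standard
  deviation calibrated analytically so the demodulated fringe-position noise
  equals ``sigma_ampl`` (for a discrete Fourier phase estimate of a sinusoid
  of amplitude A in N samples, ``sigma_phase = sigma_I * sqrt(2/N) / A``);
* spectral noise — per-cycle jitter of the whole wavelength ramp, common to
  all channels, sigma = ``sigma_spect``;
* temperature noise — slow common-mode drift of the optical path difference,
  modelled as a stationary AR(1) process whose wavelength-equivalent sigma is
  ``sigma_temp``.

Because each component is injected with its exact wavelength-equivalent
sigma, the demodulated baseline 3-sigma converges to the composed budget
``3*sqrt(sa**2 + ss**2 + st**2)`` — the quadrature law is then a property of
the simulated physics, verified downstream rather than assumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .optics import (
    AMZIDesign,
    ModeDispersion,
    NoiseBudget,
    OpticsDomainError,
    optical_path_difference,
    transfer_wavelength,
)
from .assay import AnalyteState

__all__ = [
    "SweepConfig",
    "ChannelRole",
    "ChipLayout",
    "RawSweepRecord",
    "wavelength_ramp",
    "simulate_cycles",
    "default_chip_layout",
    "default_mode_dispersion",
    "records_to_frame",
    "write_raw_csv",
    "read_raw_csv",
]

PM_PER_NM = 1.0e3


@dataclass(frozen=True)
class SweepConfig:
    """One sawtooth sweep of the VCSEL.

    Defaults follow the reader electronics: 10 Hz sweep rate, 1000 samples
    per cycle (10 kHz per photodiode).  The sweep span defaults to two free
    spectral ranges (3000 pm) so every record holds at least two full
    fringes, which keeps the Fourier phase estimate well-conditioned.
    """

    sweep_rate_hz: float = 10.0
    samples_per_cycle: int = 1000
    sweep_span_pm: float = 3000.0
    center_wavelength_nm: float = 850.0
    detector_gain: float = 1.0
    detector_offset: float = 0.1

    def __post_init__(self) -> None:
        if self.samples_per_cycle < 16:
            raise OpticsDomainError("samples_per_cycle must be >= 16")
        if not (self.sweep_span_pm > 0.0 and self.sweep_rate_hz > 0.0):
            raise OpticsDomainError("sweep span and rate must be positive")
        if not (self.center_wavelength_nm > 0.0):
            raise OpticsDomainError("center wavelength must be positive")

    @property
    def sample_rate_hz(self) -> float:
        """Per-photodiode sampling rate: sweep_rate x samples_per_cycle."""
        return self.sweep_rate_hz * self.samples_per_cycle


class ChannelRole:
    SENSING = "sensing"
    BULK = "bulk_low_sensitivity"
    REFERENCE = "internal_reference"


@dataclass(frozen=True)
class ChipLayout:
    """Eight aMZI outputs: six sensing, one low-sensitivity bulk monitor,
    one unexposed internal reference, sharing one guided-mode dispersion."""

    mode: ModeDispersion
    roles: tuple[str, ...]
    designs: tuple[AMZIDesign, ...]

    def __post_init__(self) -> None:
        if len(self.roles) != 8 or len(self.designs) != 8:
            raise OpticsDomainError("chip layout must define exactly 8 outputs")
        if sum(r == ChannelRole.SENSING for r in self.roles) != 6:
            raise OpticsDomainError("chip layout must have exactly 6 sensing channels")

    @property
    def n_outputs(self) -> int:
        return 8

    def fsr_pm(self, channel: int) -> float:
        return self.designs[channel].fsr_pm(self.mode)

    def sensitivity_nm_per_riu(self, channel: int) -> float:
        return self.designs[channel].sensitivity_nm_per_riu(self.mode)

    def sensing_channels(self) -> list[int]:
        return [i for i, r in enumerate(self.roles) if r == ChannelRole.SENSING]

    def amzi_index(self, channel: int) -> int | None:
        """1-based sensing aMZI index for a channel, or None if not sensing."""
        sensing = self.sensing_channels()
        return sensing.index(channel) + 1 if channel in sensing else None


@dataclass
class RawSweepRecord:
    """Interferogram samples of one sweep cycle: shape (8, samples_per_cycle)."""

    cycle_index: int
    timestamp_s: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise OpticsDomainError("record intensities must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]


def default_mode_dispersion() -> ModeDispersion:
    """Single-mode TriPleX-like dispersion at 850 nm with group index 2.0."""
    n_eff, n_g, lambda0 = 1.52, 2.0, 850.0
    return ModeDispersion(n_eff=n_eff, dneff_dlambda=(n_eff - n_g) / lambda0, lambda0=lambda0)


def default_chip_layout(
    sensitivity_override: float = 5000.0,
    bulk_channel_sensitivity: float = 500.0,
) -> ChipLayout:
    """Layout with FSR = 1500 pm and 12.5 mm sensing arms on every channel.

    The asymmetry length is chosen so the FSR is exactly 1500 pm for the
    default mode; sensing channels pin the bulk sensitivity at
    5000 nm/RIU, the bulk monitor at a deliberately low 500 nm/RIU.
    """
    mode = default_mode_dispersion()
    lambda0 = mode.lambda0
    fsr_pm = 1500.0
    asym_mm = lambda0**2 / (mode.group_index * (fsr_pm / PM_PER_NM)) / 1.0e6
    sensing = AMZIDesign(12.5, asym_mm, lambda0, sensitivity_override=sensitivity_override)
    bulk = AMZIDesign(12.5, asym_mm, lambda0, sensitivity_override=bulk_channel_sensitivity)
    ref = AMZIDesign(12.5, asym_mm, lambda0, sensitivity_override=sensitivity_override)
    return ChipLayout(
        mode=mode,
        roles=tuple([ChannelRole.SENSING] * 6 + [ChannelRole.BULK, ChannelRole.REFERENCE]),
        designs=tuple([sensing] * 6 + [bulk, ref]),
    )


def wavelength_ramp(cfg: SweepConfig) -> np.ndarray:
    """Linear wavelength ramp of one sawtooth cycle, in nm, strictly increasing.

    Endpoints are center +/- span/2 inclusive.
    """
    half_nm = cfg.sweep_span_pm / PM_PER_NM / 2.0
    return np.linspace(
        cfg.center_wavelength_nm - half_nm,
        cfg.center_wavelength_nm + half_nm,
        cfg.samples_per_cycle,
    )


def _response_shift_pm(layout: ChipLayout, channel: int, surface_pm: np.ndarray, bulk_riu: float) -> float:
    """Wavelength-equivalent response of one channel to the analyte state, pm."""
    role = layout.roles[channel]
    if role == ChannelRole.REFERENCE:
        return 0.0
    shift = layout.sensitivity_nm_per_riu(channel) * bulk_riu * PM_PER_NM
    amzi = layout.amzi_index(channel)
    if amzi is not None:
        shift += float(surface_pm[amzi - 1])
    return shift


def simulate_cycles(
    layout: ChipLayout,
    state: AnalyteState | None,
    cfg: SweepConfig,
    noise: NoiseBudget,
    n_cycles: int,
    seed: int,
    start_time_s: float = 0.0,
    cycle_stride: int = 1,
    temp_corr_cycles: float = 5.0,
) -> Iterator[RawSweepRecord]:
    """Yield interferogram records for ``n_cycles`` sweep cycles.

    ``state`` may be None for a static (baseline) chip.  ``cycle_stride``
    subsamples the 10 Hz cycle train (every stride-th cycle is synthesized)
    so long fluidic programs can be simulated at reduced record rate without
    changing the per-cycle physics.  The stream is reproducible bit-for-bit
    for a given seed.
    """
    if n_cycles <= 0:
        raise OpticsDomainError("n_cycles must be positive")
    if cycle_stride < 1:
        raise OpticsDomainError("cycle_stride must be >= 1")
    ss = np.random.SeedSequence(seed)
    rng_amp, rng_spect, rng_temp = (np.random.default_rng(s) for s in ss.spawn(3))

    ramp = wavelength_ramp(cfg)
    n_ch, n_s = layout.n_outputs, cfg.samples_per_cycle
    lam_res = np.array([d.lambda_res for d in layout.designs])
    fsr = np.array([layout.fsr_pm(c) for c in range(n_ch)])
    opd0 = np.array(
        [optical_path_difference(layout.mode, layout.designs[c]) for c in range(n_ch)]
    )
    # amplitude-noise sigma calibrated so demodulated position noise = sigma_ampl
    amp_fringe = cfg.detector_gain * 0.5
    sigma_int = (
        (2.0 * np.pi * noise.sigma_ampl / fsr) * amp_fringe * math.sqrt(n_s / 2.0)
    )
    rho = math.exp(-1.0 / temp_corr_cycles) if temp_corr_cycles > 0 else 0.0
    z_temp = rng_temp.standard_normal()  # stationary start

    for k in range(n_cycles):
        t = start_time_s + k * cycle_stride / cfg.sweep_rate_hz
        if state is not None:
            surface_pm, bulk_riu = state.at_time(t)
        else:
            surface_pm, bulk_riu = np.zeros(6), 0.0
        if k > 0:
            z_temp = rho * z_temp + math.sqrt(1.0 - rho**2) * rng_temp.standard_normal()
        d_lambda_spect = rng_spect.normal(0.0, noise.sigma_spect) if noise.sigma_spect else 0.0

        samples = np.empty((n_ch, n_s))
        for c in range(n_ch):
            shift_pm = _response_shift_pm(layout, c, surface_pm, bulk_riu)
            shift_pm += z_temp * noise.sigma_temp  # common-mode thermal drift
            opd = opd0[c] + shift_pm * lam_res[c] / fsr[c]  # pm shift -> nm of opd
            lam = ramp + d_lambda_spect / PM_PER_NM
            samples[c] = cfg.detector_gain * transfer_wavelength(lam, opd) + cfg.detector_offset
        if noise.sigma_ampl:
            samples += sigma_int[:, None] * rng_amp.standard_normal((n_ch, n_s))
        yield RawSweepRecord(cycle_index=k, timestamp_s=t, samples=samples)


# ---------------------------------------------------------------------------
# Raw-record I/O (tidy long-format CSV)
# ---------------------------------------------------------------------------


def records_to_frame(records: Iterable[RawSweepRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        n_ch, n_s = rec.samples.shape
        rows.append(
            pd.DataFrame(
                {
                    "cycle": rec.cycle_index,
                    "timestamp_s": rec.timestamp_s,
                    "channel": np.repeat(np.arange(n_ch), n_s),
                    "sample_index": np.tile(np.arange(n_s), n_ch),
                    "intensity": rec.samples.ravel(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_raw_csv(records: Iterable[RawSweepRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_raw_csv(path) -> list[RawSweepRecord]:
    df = pd.read_csv(path)
    out = []
    for cycle, grp in df.groupby("cycle", sort=True):
        n_ch = grp["channel"].nunique()
        n_s = grp["sample_index"].nunique()
        samples = (
            grp.sort_values(["channel", "sample_index"])["intensity"].to_numpy().reshape(n_ch, n_s)
        )
        out.append(
            RawSweepRecord(
                cycle_index=int(cycle),
                timestamp_s=float(grp["timestamp_s"].iloc[0]),
                samples=samples,
            )
        )
    return out
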