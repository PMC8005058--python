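"""Fourier phase demodulation of swept-wavelength interferograms.

Each sweep cycle yields, per channel, a sine-like interferogram whose fringe
phase encodes the interferometer's optical path difference at that instant.
The analysis chain implemented here:

1. ``extract_phase`` — discrete Fourier transform of the per-cycle trace;
   the dominant non-DC bin carries the fringe, and its argument is the
   fringe phase.  With the default sweep span equal to an integer number of
   free spectral ranges the fringe falls exactly on a bin, so no window
   function is applied by default.
2. ``track_sensorgram`` — unwrap the per-cycle phases over time (nearest
   multiple of 2*pi between consecutive cycles; valid while the shift rate
   stays below half an FSR per cycle) and convert to a wavelength shift in
   pm via ``FSR / (2*pi)``, baseline-zeroed over a reference window.
3. ``differential_signal`` — subtract a reference channel from a signal
   channel to cancel bulk and background common modes.
4. ``estimate_resolution`` / ``estimate_lod`` — resolution as 3x the sample
   standard deviation of the baseline position, LoD as resolution over
   sensitivity.
5. ``analyze_steps`` — plateau levels, level differences and threshold-
   crossing response delays for programmed fluidic steps.

Sign convention: the sweep ramps from short to long wavelength, so a red
shift of the fringes (opd increase) delays the fringe within the sweep and
lowers the extracted sample-index phase; the tracker flips the sign so that
a red shift reads as a positive pm shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .assay import FlowStep
from .instrument import ChipLayout, ChannelRole, RawSweepRecord, SweepConfig

__all__ = [
    "PhaseExtraction",
    "Sensorgram",
    "StepAnalysis",
    "extract_phase",
    "track_sensorgram",
    "differential_signal",
    "estimate_resolution",
    "estimate_lod",
    "analyze_steps",
    "qc_reference_channels",
]


class DemodError(ValueError):
    """Raised for invalid demodulation inputs."""


class AlignmentError(DemodError):
    """Raised when two time series do not share a time grid."""


class PreconditionError(DemodError):
    """Raised when a statistical estimate's preconditions are not met."""


#: red fringe shift (opd increase) lowers the sample-index phase of an
#: increasing-wavelength sweep; flip so red shifts are positive pm
SWEEP_PHASE_SIGN = -1.0

#: fringe amplitude below this fraction of the DC level flags low contrast
DEFAULT_CONTRAST_FLOOR = 0.05


# ---------------------------------------------------------------------------
# Phase extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseExtraction:
    """Per-channel result of one cycle's Fourier demodulation."""

    phase_rad: np.ndarray  # in (-pi, pi]
    amplitude: np.ndarray  # fringe amplitude, intensity units
    contrast: np.ndarray  # fringe amplitude / DC level
    dominant_bin: np.ndarray
    low_contrast: np.ndarray  # flagged flat/degenerate traces


def extract_phase(
    record: RawSweepRecord,
    cfg: SweepConfig | None = None,
    contrast_floor: float = DEFAULT_CONTRAST_FLOOR,
) -> PhaseExtraction:
    """Fourier fringe phase, amplitude and contrast of each channel's trace.

    The dominant non-DC rFFT bin is selected (ties break toward lower
    frequency); the returned phase is its argument.  A trace whose fringe
    amplitude falls below ``contrast_floor`` times the DC level is flagged
    low-contrast rather than raising — its phase is meaningless but finite.
    """
    samples = np.atleast_2d(record.samples)
    n_s = samples.shape[1]
    if n_s < 16:
        raise DemodError(f"record must hold >= 16 samples per trace, got {n_s}")
    spectrum = np.fft.rfft(samples, axis=1)
    mag = np.abs(spectrum)
    dominant = 1 + np.argmax(mag[:, 1:], axis=1)  # argmax is first-of-ties: lower bin
    rows = np.arange(samples.shape[0])
    peak = spectrum[rows, dominant]
    phase = np.angle(peak)
    # map -pi to +pi so the range is (-pi, pi]
    phase = np.where(np.isclose(phase, -np.pi), np.pi, phase)
    amplitude = 2.0 * np.abs(peak) / n_s
    dc = np.abs(spectrum[:, 0]) / n_s
    with np.errstate(divide="ignore", invalid="ignore"):
        contrast = np.where(dc > 0, amplitude / np.where(dc > 0, dc, 1.0), np.inf)
    low = amplitude < contrast_floor * np.maximum(dc, np.finfo(float).tiny)
    return PhaseExtraction(
        phase_rad=phase,
        amplitude=amplitude,
        contrast=contrast,
        dominant_bin=dominant,
        low_contrast=low,
    )


# ---------------------------------------------------------------------------
# Sensorgram tracking
# ---------------------------------------------------------------------------


@dataclass
class Sensorgram:
    """Per-channel fringe-shift time series in pm, with referencing metadata."""

    time_s: np.ndarray
    shift_pm: np.ndarray  # (n_channels, n_times)
    fsr_pm: np.ndarray  # per channel
    channels: list[int]
    metadata: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.shift_pm = np.atleast_2d(np.asarray(self.shift_pm, dtype=float))
        self.fsr_pm = np.atleast_1d(np.asarray(self.fsr_pm, dtype=float))
        if np.any(np.diff(self.time_s) <= 0):
            raise DemodError("sensorgram time grid must be strictly increasing")
        if not np.all(np.isfinite(self.shift_pm)):
            raise DemodError("sensorgram shifts must be finite")

    def channel_trace(self, channel: int) -> np.ndarray:
        return self.shift_pm[self.channels.index(channel)]

    def phase_rad(self, channel: int) -> np.ndarray:
        """Equivalent phase trace: shift * 2*pi / FSR."""
        i = self.channels.index(channel)
        return self.shift_pm[i] * 2.0 * np.pi / self.fsr_pm[i]

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame(
                {"time_s": self.time_s, "channel": ch, "shift_pm": self.shift_pm[i]}
            )
            for i, ch in enumerate(self.channels)
        ]
        return pd.concat(frames, ignore_index=True)

    def _single_channel(self, channel: int | None) -> int:
        if channel is not None:
            return self.channels.index(channel)
        if len(self.channels) == 1:
            return 0
        raise DemodError("multi-channel sensorgram: a channel must be specified")


def track_sensorgram(
    records: Iterable[RawSweepRecord],
    cfg: SweepConfig,
    layout: ChipLayout,
    baseline_window_s: tuple[float, float] = (0.0, 10.0),
) -> Sensorgram:
    """Unwrap per-cycle fringe phases into a pm sensorgram for all channels.

    Phases are unwrapped with the nearest-multiple-of-2*pi rule between
    consecutive cycles (assumes < FSR/2 shift per cycle); near-ambiguous
    steps (> 0.9*pi) are recorded as warnings.  Traces are zeroed on the
    mean within ``baseline_window_s`` (falling back to the first cycle if
    the window is empty).
    """
    records = list(records)
    if not records:
        raise DemodError("no records to track")
    times = np.array([r.timestamp_s for r in records])
    phases = np.stack([extract_phase(r, cfg).phase_rad for r in records], axis=1)
    n_ch = phases.shape[0]
    fsr = np.array([layout.fsr_pm(c) for c in range(n_ch)])

    warnings: list[str] = []
    steps = np.diff(phases, axis=1)
    wrapped = (steps + np.pi) % (2.0 * np.pi) - np.pi
    for c in range(n_ch):
        worst = np.max(np.abs(wrapped[c])) if wrapped.shape[1] else 0.0
        if worst > 0.9 * np.pi:
            warnings.append(
                f"channel {c}: inter-cycle phase step of {worst:.3f} rad is near the "
                "unwrap ambiguity limit (pi)"
            )
    unwrapped = np.concatenate(
        [phases[:, :1], phases[:, :1] + np.cumsum(wrapped, axis=1)], axis=1
    )
    shift = SWEEP_PHASE_SIGN * (unwrapped - unwrapped[:, :1]) * fsr[:, None] / (2.0 * np.pi)

    lo, hi = baseline_window_s
    in_win = (times >= lo) & (times <= hi)
    baseline = shift[:, in_win].mean(axis=1, keepdims=True) if np.any(in_win) else shift[:, :1]
    shift = shift - baseline

    return Sensorgram(
        time_s=times,
        shift_pm=shift,
        fsr_pm=fsr,
        channels=list(range(n_ch)),
        metadata={"baseline_window_s": baseline_window_s, "referencing": "none"},
        warnings=warnings,
    )


def differential_signal(
    sensorgram: Sensorgram, signal_channel: int, reference_channel: int
) -> Sensorgram:
    """Signal-channel trace minus reference-channel trace.

    Common-mode terms (bulk index, temperature drift, shared background)
    cancel pointwise; the pairing is recorded in the metadata.
    """
    for ch in (signal_channel, reference_channel):
        if ch not in sensorgram.channels:
            raise AlignmentError(f"channel {ch} not present in sensorgram")
    i = sensorgram.channels.index(signal_channel)
    j = sensorgram.channels.index(reference_channel)
    diff = sensorgram.shift_pm[i] - sensorgram.shift_pm[j]
    return Sensorgram(
        time_s=sensorgram.time_s.copy(),
        shift_pm=diff[None, :],
        fsr_pm=sensorgram.fsr_pm[[i]],
        channels=[signal_channel],
        metadata={
            **sensorgram.metadata,
            "referencing": {"signal": signal_channel, "reference": reference_channel},
        },
        warnings=list(sensorgram.warnings),
    )


# ---------------------------------------------------------------------------
# Resolution / LoD
# ---------------------------------------------------------------------------


def _window_samples(
    sensorgram: Sensorgram,
    baseline_window_s: tuple[float, float],
    channel: int | None,
    program: Sequence[FlowStep] | None,
    min_cycles: int = 30,
) -> np.ndarray:
    lo, hi = baseline_window_s
    if program is not None:
        edges = np.cumsum([s.duration_s for s in program])[:-1]
        inside = [e for e in edges if lo < e < hi]
        if inside:
            raise PreconditionError(
                f"baseline window ({lo}, {hi}) s spans programmed step change(s) at {inside} s"
            )
    mask = (sensorgram.time_s >= lo) & (sensorgram.time_s <= hi)
    if int(mask.sum()) < min_cycles:
        raise PreconditionError(
            f"baseline window holds {int(mask.sum())} cycles; >= {min_cycles} required"
        )
    idx = sensorgram._single_channel(channel)
    return sensorgram.shift_pm[idx, mask]


def estimate_resolution(
    sensorgram: Sensorgram,
    baseline_window_s: tuple[float, float],
    channel: int | None = None,
    program: Sequence[FlowStep] | None = None,
) -> float:
    """Resolution in pm: 3x the sample std of the baseline fringe position."""
    x = _window_samples(sensorgram, baseline_window_s, channel, program)
    return 3.0 * float(np.std(x, ddof=1))


def estimate_lod(
    sensorgram: Sensorgram,
    baseline_window_s: tuple[float, float],
    sensitivity_nm_per_riu: float,
    channel: int | None = None,
    program: Sequence[FlowStep] | None = None,
) -> float:
    """Limit of detection in RIU: estimated resolution over sensitivity."""
    if not (sensitivity_nm_per_riu > 0.0):
        raise DemodError("sensitivity must be positive")
    r_pm = estimate_resolution(sensorgram, baseline_window_s, channel, program)
    return (r_pm / 1000.0) / sensitivity_nm_per_riu


# ---------------------------------------------------------------------------
# Step analysis
# ---------------------------------------------------------------------------


@dataclass
class StepAnalysis:
    """Plateau levels and threshold-crossing timing of a stepped sensorgram."""

    step_labels: list[str]
    step_edges_s: np.ndarray  # program boundaries, length n_steps + 1
    plateau_levels: np.ndarray  # mean over the final plateau fraction of each step
    plateau_sigmas: np.ndarray
    level_differences: np.ndarray  # successive plateau differences
    transition_times_s: list[float | None]  # detected change time per transition
    response_delays_s: list[float | None]
    unsettled: list[bool]  # steps too short for the settling guard


def analyze_steps(
    sensorgram: Sensorgram,
    program: Sequence[FlowStep],
    channel: int | None = None,
    plateau_fraction: float = 0.4,
    threshold_sigma: float = 5.0,
    settle_guard_s: float = 30.0,
    program_start_s: float = 0.0,
) -> StepAnalysis:
    """Quantify programmed fluidic steps on one channel's sensorgram.

    Plateaus are the mean over the final ``plateau_fraction`` of each step
    (samples outside transition windows); a transition is detected at the
    first crossing of ``threshold_sigma`` times the previous plateau's noise
    after the programmed change.  Steps shorter than ``settle_guard_s`` are
    flagged unsettled.
    """
    if not program:
        raise DemodError("empty step program")
    idx = sensorgram._single_channel(channel)
    x = sensorgram.shift_pm[idx]
    t = sensorgram.time_s
    edges = program_start_s + np.concatenate([[0.0], np.cumsum([s.duration_s for s in program])])

    levels, sigmas, unsettled = [], [], []
    for si, step in enumerate(program):
        t0, t1 = edges[si], edges[si + 1]
        # half-open on the right so a sample exactly at the change belongs
        # to the next step
        last = si == len(program) - 1
        mask = (t >= t1 - plateau_fraction * step.duration_s) & ((t <= t1) if last else (t < t1))
        if not np.any(mask):
            raise PreconditionError(f"no sensorgram samples in plateau of step '{step.label}'")
        levels.append(float(np.mean(x[mask])))
        sigmas.append(float(np.std(x[mask], ddof=1)) if mask.sum() > 1 else 0.0)
        unsettled.append(step.duration_s < settle_guard_s)

    transitions: list[float | None] = []
    delays: list[float | None] = []
    for si in range(1, len(program)):
        edge = edges[si]
        prev_level, prev_sigma = levels[si - 1], sigmas[si - 1]
        thresh = max(threshold_sigma * prev_sigma, 1e-9)
        mask = (t >= edge) & (t < edges[si + 1] if si + 1 < len(program) else t <= edges[si + 1])
        crossing = np.nonzero(np.abs(x[mask] - prev_level) > thresh)[0]
        if crossing.size:
            t_det = float(t[mask][crossing[0]])
            transitions.append(t_det)
            delays.append(t_det - float(edge))
        else:
            transitions.append(None)
            delays.append(None)

    return StepAnalysis(
        step_labels=[s.label for s in program],
        step_edges_s=edges,
        plateau_levels=np.array(levels),
        plateau_sigmas=np.array(sigmas),
        level_differences=np.diff(np.array(levels)),
        transition_times_s=transitions,
        response_delays_s=delays,
        unsettled=unsettled,
    )


# ---------------------------------------------------------------------------
# Run-validity checks
# ---------------------------------------------------------------------------


def qc_reference_channels(
    sensorgram: Sensorgram,
    layout: ChipLayout,
    max_drift_pm: float = 50.0,
) -> dict[int, bool]:
    """Flag the bulk and internal-reference channels if they drift.

    On a functional chip with a stable buffer these monitor channels stay
    flat; drift beyond ``max_drift_pm`` marks the run suspect.  Returns
    {channel: flagged} for each monitor channel present.
    """
    flags: dict[int, bool] = {}
    for c, role in enumerate(layout.roles):
        if role in (ChannelRole.BULK, ChannelRole.REFERENCE) and c in sensorgram.channels:
            trace = sensorgram.channel_trace(c)
            flags[c] = bool(np.max(np.abs(trace - trace[0])) > max_drift_pm)
    return flags
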