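"""Synthetic nanopore current traces with known ground truth.

This module emulates the acquisition chain of a solid-state nanopore
recording of DNA NanoLock translocations: a baseline open-pore current,
rectangular conductance blockades for each translocating molecule, additive
Gaussian input noise, and a low-pass Bessel filter cascade (hardware
analog stage followed, at analysis time, by a software digital stage).

Three translocation geometries are modelled:

* ``single_file_only`` -- a linear duplex (e.g. the 400 bp molecular
  ruler) that always passes end-first: one blockade segment at the 1x
  dsDNA level for the full dwell.
* ``circular`` -- a closed (circularized) NanoLock: two strands occupy
  the pore simultaneously over half the contour, giving one segment at
  the 2x level lasting half the single-file dwell.
* ``foldable_linear`` -- an open NanoLock.  With probability
  ``end_capture_weight`` it is captured by an end (single-file).
  Otherwise it is captured at a uniform fractional position ``p`` along
  its contour and translocates folded: a 2x segment over the doubled
  portion ``m = min(p, 1 - p)`` of the dwell, followed by a 1x segment
  over the remainder.  A capture close to the midpoint leaves a tail too
  short to resolve and mimics a circular event (the false-positive
  mechanism of the digital scheme).

The event charge deficit (blockade area) is identical across all three
realizations for the same dwell draw, which is asserted exactly by the
test suite on ground-truth segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "AcquisitionConfig",
    "PoreModel",
    "SpeciesModel",
    "MixSpec",
    "GroundTruthEvent",
    "SyntheticTrace",
    "bessel_sos",
    "apply_bessel_filter",
    "filter_rise_time",
    "equivalent_noise_bandwidth",
    "sample_event_waveform",
    "simulate_trace",
    "simulate_event_stream",
    "ruler_species",
    "open_nanolock_species",
    "closed_nanolock_species",
]

GEOMETRIES = ("single_file_only", "foldable_linear", "circular")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition settings of the recording chain.

    Defaults mirror a high-bandwidth amplifier sampling at 4.17 MHz with
    a 1 MHz analog bandwidth; analysis applies a 200 kHz software
    low-pass Bessel filter.  ``voltage_mv`` is the applied bias.
    """

    sampling_rate: float = 4.17e6
    analog_bandwidth: float = 1e6
    digital_filter_cutoff: float = 2e5
    filter_poles: int = 4
    voltage_mv: float = 150.0
    duration_s: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.digital_filter_cutoff <= self.analog_bandwidth):
            raise ValueError("need 0 < digital_filter_cutoff <= analog_bandwidth")
        if self.analog_bandwidth > self.sampling_rate / 2:
            raise ValueError("analog_bandwidth must not exceed Nyquist")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.voltage_mv == 0:
            raise ValueError("voltage_mv must be nonzero")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate))

    @property
    def rise_time_s(self) -> float:
        """10-90% rise time of the analysis (digital) filter stage."""
        return filter_rise_time(self.digital_filter_cutoff, self.filter_poles)


@dataclass(frozen=True)
class PoreModel:
    """Electrical model of one pore.

    ``blockade_1x_ns`` is the conductance blockade of a single duplex in
    the pore (~5 nS for dsDNA in 3.2 M LiCl); two duplexes side by side
    block twice that by construction.  ``noise_rms_pa`` is the RMS
    current noise measured at the digital analysis bandwidth.
    """

    open_pore_conductance_ns: float = 40.0
    blockade_1x_ns: float = 5.0
    noise_rms_pa: float = 60.0
    baseline_drift_pa_per_s: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_rms_pa < 0:
            raise ValueError("noise_rms_pa must be >= 0")
        if self.blockade_1x_ns <= 0:
            raise ValueError("blockade_1x_ns must be positive")
        if 2 * self.blockade_1x_ns >= self.open_pore_conductance_ns:
            raise ValueError("pore too small: 2x blockade exceeds open-pore conductance")

    @property
    def blockade_2x_ns(self) -> float:
        return 2.0 * self.blockade_1x_ns

    def open_current_pa(self, voltage_mv: float) -> float:
        # nS * mV = pA
        return self.open_pore_conductance_ns * voltage_mv


@dataclass(frozen=True)
class SpeciesModel:
    """One molecular species and its capture/dwell statistics.

    Dwell times of a single-file passage are log-normal with the given
    median and shape; the capture rate is proportional to concentration
    (``capture_rate_per_nm`` in Hz/nM).  ``end_capture_weight`` is the
    probability that a foldable molecule is captured by an end and
    passes single file (persistence-length argument: a 400 bp molecule
    of ~150 bp persistence length is most often captured by an end).
    """

    name: str
    geometry: str
    dwell_median_s: float = 100e-6
    dwell_sigma: float = 0.4
    capture_rate_per_nm: float = 0.0157
    end_capture_weight: float = 0.75

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(
                f"unknown geometry {self.geometry!r}; expected one of {GEOMETRIES}"
            )
        if self.dwell_median_s <= 0 or self.dwell_sigma <= 0:
            raise ValueError("dwell parameters must be positive")
        if not 0 <= self.end_capture_weight <= 1:
            raise ValueError("end_capture_weight must be in [0, 1]")
        if self.capture_rate_per_nm < 0:
            raise ValueError("capture_rate_per_nm must be >= 0")


def ruler_species(**kw) -> SpeciesModel:
    """400 bp dsDNA molecular-ruler control (always single file)."""
    return SpeciesModel(name="ruler_400bp", geometry="single_file_only", **kw)


def open_nanolock_species(**kw) -> SpeciesModel:
    """Open (linear) NanoLock probe; may translocate folded."""
    return SpeciesModel(name="nanolock_open", geometry="foldable_linear", **kw)


def closed_nanolock_species(**kw) -> SpeciesModel:
    """Closed (circularized) NanoLock probe."""
    return SpeciesModel(name="nanolock_closed", geometry="circular", **kw)


@dataclass(frozen=True)
class MixSpec:
    """A mixture of species at given concentrations (nM)."""

    components: tuple = ()

    def __post_init__(self) -> None:
        for _, conc in self.components:
            if conc < 0:
                raise ValueError("concentrations must be >= 0")

    @classmethod
    def from_closed_fraction(
        cls, closed_fraction: float, probe_conc_nm: float = 30.0, **species_kw
    ) -> "MixSpec":
        """Open/closed NanoLock mix at total probe concentration with a
        given closed fraction ``f`` (e.g. from the binding model)."""
        if not 0 <= closed_fraction <= 1:
            raise ValueError("closed_fraction must be in [0, 1]")
        return cls(
            components=(
                (open_nanolock_species(**species_kw), probe_conc_nm * (1 - closed_fraction)),
                (closed_nanolock_species(**species_kw), probe_conc_nm * closed_fraction),
            )
        )


@dataclass
class GroundTruthEvent:
    """Ground truth for one simulated translocation."""

    species: str
    start_s: float
    p: float  # fractional capture position; NaN unless foldable mid-capture
    true_bit: int
    segments: list  # [(blockade_ns, duration_s), ...]

    @property
    def duration_s(self) -> float:
        return float(sum(d for _, d in self.segments))

    @property
    def area_ns_s(self) -> float:
        """Unfiltered blockade area in conductance units (nS*s)."""
        return float(sum(g * d for g, d in self.segments))


@dataclass
class SyntheticTrace:
    """Current samples (pA, after the analog hardware stage) plus metadata
    and the ground-truth event log."""

    samples: np.ndarray
    acq: AcquisitionConfig
    pore: PoreModel
    events: pd.DataFrame


# ---------------------------------------------------------------------------
# Filters


def bessel_sos(cutoff_hz: float, fs: float, poles: int = 4) -> np.ndarray:
    """Low-pass Bessel filter (magnitude -3 dB at ``cutoff_hz``) as SOS."""
    if cutoff_hz >= fs / 2:
        raise ValueError("filter cutoff must be below Nyquist")
    return signal.bessel(poles, cutoff_hz, btype="low", norm="mag", fs=fs, output="sos")


def apply_bessel_filter(
    samples: np.ndarray, acq: AcquisitionConfig, cutoff_hz: float | None = None
) -> np.ndarray:
    """Causal low-pass Bessel filtering, as applied by acquisition
    hardware or analysis software.  Unit DC gain preserves event area."""
    if cutoff_hz is None:
        cutoff_hz = acq.digital_filter_cutoff
    sos = bessel_sos(cutoff_hz, acq.sampling_rate, acq.filter_poles)
    zi = signal.sosfilt_zi(sos) * samples[0]
    out, _ = signal.sosfilt(sos, samples, zi=zi)
    return out


def filter_rise_time(cutoff_hz: float, poles: int = 4) -> float:
    """Approximate 10-90% step-response rise time of a low-pass Bessel
    filter (~0.34/f_c for 4 poles)."""
    return 0.34 / cutoff_hz * (poles / 4) ** 0.5


def _analog_stage_applies(acq: AcquisitionConfig) -> bool:
    # The analog stage cannot be designed at/near Nyquist; when the
    # sampling rate barely exceeds twice the analog bandwidth the signal
    # is already band-limited and the stage is skipped.
    return acq.analog_bandwidth < 0.45 * acq.sampling_rate


def equivalent_noise_bandwidth(acq: AcquisitionConfig) -> float:
    """Equivalent noise bandwidth (Hz) of the full filter cascade
    (analog stage if applicable, then the digital analysis stage)."""
    n = 4096
    f = np.linspace(0, acq.sampling_rate / 2, n)
    h = np.ones_like(f)
    if _analog_stage_applies(acq):
        sos = bessel_sos(acq.analog_bandwidth, acq.sampling_rate, acq.filter_poles)
        _, ha = signal.sosfreqz(sos, worN=f, fs=acq.sampling_rate)
        h = h * np.abs(ha)
    sos = bessel_sos(acq.digital_filter_cutoff, acq.sampling_rate, acq.filter_poles)
    _, hd = signal.sosfreqz(sos, worN=f, fs=acq.sampling_rate)
    h = h * np.abs(hd)
    return float(np.trapezoid(h**2, f) / h[0] ** 2)


def white_noise_sigma(acq: AcquisitionConfig, pore: PoreModel) -> float:
    """Per-sample white-noise sigma such that the filtered trace has RMS
    ``pore.noise_rms_pa`` at the digital analysis bandwidth."""
    if pore.noise_rms_pa == 0:
        return 0.0
    enbw = equivalent_noise_bandwidth(acq)
    return pore.noise_rms_pa * math.sqrt(acq.sampling_rate / (2.0 * enbw))


# ---------------------------------------------------------------------------
# Event waveforms


def sample_event_waveform(
    species: SpeciesModel,
    pore: PoreModel,
    rng: np.random.Generator,
) -> GroundTruthEvent:
    """Draw one translocation: piecewise-constant blockade segments.

    Let tau be the log-normal single-file dwell draw.  The blockade area
    ``blockade_1x * tau`` is conserved across geometries: the circular
    event blocks at 2x for tau/2; a folded event blocks 2x over the
    doubled fraction and 1x over the rest.
    """
    tau = float(rng.lognormal(math.log(species.dwell_median_s), species.dwell_sigma))
    g1, g2 = pore.blockade_1x_ns, pore.blockade_2x_ns
    if species.geometry == "single_file_only":
        return GroundTruthEvent(species.name, math.nan, math.nan, 0, [(g1, tau)])
    if species.geometry == "circular":
        return GroundTruthEvent(species.name, math.nan, math.nan, 1, [(g2, tau / 2)])
    if species.geometry == "foldable_linear":
        if rng.random() < species.end_capture_weight:
            return GroundTruthEvent(species.name, math.nan, math.nan, 0, [(g1, tau)])
        p = float(rng.uniform(0.0, 1.0))
        m = min(p, 1.0 - p)
        segments = [(g2, m * tau)]
        if (1.0 - 2.0 * m) * tau > 0:
            segments.append((g1, (1.0 - 2.0 * m) * tau))
        return GroundTruthEvent(species.name, math.nan, p, 0, segments)
    raise ValueError(f"unknown geometry {species.geometry!r}")


def _events_to_frame(events: list[GroundTruthEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append(
            {
                "start_s": ev.start_s,
                "species": ev.species,
                "p": ev.p,
                "true_bit": ev.true_bit,
                "duration_s": ev.duration_s,
                "n_segments": len(ev.segments),
                "segments": ";".join(f"{g:.6g}@{d:.9g}" for g, d in ev.segments),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["start_s", "species", "p", "true_bit", "duration_s", "n_segments", "segments"],
    )
    return frame.sort_values("start_s", ignore_index=True) if len(frame) else frame


def parse_segments(text: str) -> list[tuple[float, float]]:
    """Inverse of the ``segments`` column encoding."""
    out = []
    for part in str(text).split(";"):
        g, d = part.split("@")
        out.append((float(g), float(d)))
    return out


# ---------------------------------------------------------------------------
# Trace simulation


def _draw_event_times(
    rng: np.random.Generator,
    durations: np.ndarray,
    trace_duration: float,
    guard_s: float,
    max_retries: int = 100,
) -> np.ndarray:
    """Uniform start times for a Poisson batch; overlapping events are
    re-drawn (later start moved) up to ``max_retries`` times each."""
    n = len(durations)
    starts = rng.uniform(0.0, trace_duration, size=n)
    order = np.argsort(starts)
    starts, durations = starts[order], durations[order]
    placed_start: list[float] = []
    placed_end: list[float] = []
    out = np.empty(n)
    for i in range(n):
        s, d = starts[i], durations[i]
        for attempt in range(max_retries + 1):
            lo, hi = s - guard_s, s + d + guard_s
            ok = all(hi <= ps or lo >= pe for ps, pe in zip(placed_start, placed_end))
            if ok and 0.0 <= s and s + d <= trace_duration:
                break
            if attempt == max_retries:
                raise RuntimeError(
                    "event pile-up beyond retry budget; lower the concentration, "
                    "shorten dwell times, or lengthen the trace"
                )
            s = rng.uniform(0.0, max(trace_duration - d, 1e-12))
        placed_start.append(s)
        placed_end.append(s + d)
        out[i] = s
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    return out[inv]


def simulate_trace(
    acq: AcquisitionConfig,
    pore: PoreModel,
    mix: MixSpec,
    rng: np.random.Generator | int | None = None,
) -> SyntheticTrace:
    """Simulate one recording.

    Capture events arrive as independent Poisson processes per species
    with rate ``capture_rate_per_nm * concentration``.  Identical seed
    and configuration give a bit-identical trace.
    """
    if rng is None:
        rng = np.random.default_rng(acq.rng_seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    fs = acq.sampling_rate
    n = acq.n_samples
    duration = n / fs
    guard = 4.0 * acq.rise_time_s

    events: list[GroundTruthEvent] = []
    all_durations: list[float] = []
    for species, conc in mix.components:
        rate = species.capture_rate_per_nm * conc
        if rate <= 0:
            continue
        count = rng.poisson(rate * duration)
        for _ in range(count):
            ev = sample_event_waveform(species, pore, rng)
            events.append(ev)
            all_durations.append(ev.duration_s)
    if events:
        starts = _draw_event_times(rng, np.asarray(all_durations), duration, guard)
        for ev, s in zip(events, starts):
            ev.start_s = float(s)

    baseline = pore.open_current_pa(acq.voltage_mv)
    current = np.full(n, baseline, dtype=np.float64)
    if pore.baseline_drift_pa_per_s != 0.0:
        current += pore.baseline_drift_pa_per_s * (np.arange(n) / fs)
    v = acq.voltage_mv
    for ev in events:
        t = ev.start_s
        for g, d in ev.segments:
            i0 = int(round(t * fs))
            i1 = int(round((t + d) * fs))
            current[i0 : max(i1, i0 + 1)] -= g * v
            t += d
    sigma_in = white_noise_sigma(acq, pore)
    if sigma_in > 0:
        current += rng.normal(0.0, sigma_in, size=n)
    if _analog_stage_applies(acq):
        current = apply_bessel_filter(current, acq, acq.analog_bandwidth)
    return SyntheticTrace(current, acq, pore, _events_to_frame(events))


def simulate_event_stream(
    mix: MixSpec,
    duration_s: float,
    pore: PoreModel | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Ground-truth event log only, without waveform rendering.

    The fast path for count-level studies (standard curves, running
    fractions): the same Poisson capture statistics and per-event
    geometry draws as :func:`simulate_trace`, returned as the
    ground-truth table.  Waveform-level effects (noise, filtering,
    detection losses) are not emulated.
    """
    pore = pore or PoreModel()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    events: list[GroundTruthEvent] = []
    for species, conc in mix.components:
        rate = species.capture_rate_per_nm * conc
        if rate <= 0:
            continue
        count = rng.poisson(rate * duration_s)
        starts = rng.uniform(0.0, duration_s, size=count)
        for s in starts:
            ev = sample_event_waveform(species, pore, rng)
            ev.start_s = float(s)
            events.append(ev)
    return _events_to_frame(events)
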