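"""Reproducible simulation studies over the full pipeline.

These functions package the desk-scale computational experiments that
characterize the assay: the classifier false-positive rate on open-only
runs, recovery of the 1x/2x blockade levels through detection, and the
paired digital-vs-analog limit-of-detection comparison under run-to-run
capture-rate variability.

Trace-level studies run at a 1 MHz sampling rate with the 200 kHz
analysis filter: the filter, not the sampler, limits time resolution,
so this preserves the physics of the default acquisition chain while
keeping multi-thousand-event runs tractable.  Event capture is made
denser than in a real recording (50 Hz vs ~0.5 Hz) purely to shorten
the simulated recording; events remain far sparser than their duration,
so pile-up stays negligible.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from .classify import NanoLockClassifier, calibrate_ruler, false_positive_rate
from .detect import CusumEventDetector, match_events_to_truth
from .kinetics import KineticsConfig, dose_response, fast_closure, observed_fraction
from .quantify import build_standard_curve
from .synth import (
    AcquisitionConfig,
    MixSpec,
    PoreModel,
    SpeciesModel,
    closed_nanolock_species,
    open_nanolock_species,
    ruler_species,
    simulate_trace,
)

__all__ = [
    "study_acquisition",
    "simulate_species_events",
    "classifier_false_positive_study",
    "blockade_recovery_study",
    "paired_lod_study",
]


def study_acquisition(duration_s: float = 10.0, voltage_mv: float = 150.0, seed: int = 0) -> AcquisitionConfig:
    """Acquisition settings for desk-scale studies (1 MHz sampling,
    200 kHz analysis filter; the analog stage is already band-limited)."""
    return AcquisitionConfig(
        sampling_rate=1e6,
        analog_bandwidth=5e5,
        digital_filter_cutoff=2e5,
        voltage_mv=voltage_mv,
        duration_s=duration_s,
        rng_seed=seed,
    )


def _dense(species: SpeciesModel, rate_hz: float, conc_nm: float = 30.0) -> SpeciesModel:
    return replace(species, capture_rate_per_nm=rate_hz / conc_nm)


def simulate_species_events(
    species: SpeciesModel,
    n_events: int,
    seed: int,
    pore: PoreModel | None = None,
    voltage_mv: float = 150.0,
    rate_hz: float = 50.0,
    chunk_s: float = 10.0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate, detect and truth-match ~``n_events`` events of a single
    species, in independent trace chunks.

    Returns the truth-matched detected-events table and summary stats
    (including ground-truth counts and detector rejections).
    """
    pore = pore or PoreModel()
    detector = CusumEventDetector(expected_blockade_1x_ns=pore.blockade_1x_ns)
    mix = MixSpec(components=((_dense(species, rate_hz), 30.0),))
    frames: list[pd.DataFrame] = []
    stats = {"n_truth": 0, "missed": 0, "spurious": 0}
    got = 0
    chunk = 0
    while got < n_events:
        acq = study_acquisition(chunk_s, voltage_mv, seed=seed + chunk)
        trace = simulate_trace(acq, pore, mix, rng=np.random.default_rng(seed + chunk))
        events = detector.transform(trace)
        matched = match_events_to_truth(events, trace.events)
        stats["n_truth"] += len(trace.events)
        stats["missed"] += matched.attrs["missed"]
        stats["spurious"] += matched.attrs["spurious"]
        frames.append(matched)
        got += len(matched)
        chunk += 1
        if chunk > 10 * max(1, math.ceil(n_events / (rate_hz * chunk_s))):
            raise RuntimeError("event budget not reached; check detection settings")
    out = pd.concat(frames, ignore_index=True)
    out["event_id"] = np.arange(len(out))
    return out, stats


def _calibrated_classifier(
    seed: int, pore: PoreModel, voltage_mv: float, n_ruler: int = 400
) -> NanoLockClassifier:
    ruler_events, _ = simulate_species_events(
        ruler_species(), n_ruler, seed=seed + 90_000, pore=pore, voltage_mv=voltage_mv
    )
    clf = NanoLockClassifier()
    clf.set_calibration(calibrate_ruler(ruler_events, source=f"ruler_seed{seed}"))
    return clf


def classifier_false_positive_study(
    n_events: int = 20000,
    seed: int = 0,
    pore: PoreModel | None = None,
    voltage_mv: float = 150.0,
) -> dict:
    """False-positive rate of the digital classifier on open-only runs.

    Simulates traces containing only open NanoLocks at the default
    capture-position mixture (75% end capture, uniform fold position
    otherwise) and noise, runs detection and ruler-calibrated
    classification, and reports the fraction of counted events labelled
    circular with its exact binomial interval.
    """
    pore = pore or PoreModel()
    clf = _calibrated_classifier(seed, pore, voltage_mv)
    events, stats = simulate_species_events(
        open_nanolock_species(), n_events, seed=seed, pore=pore, voltage_mv=voltage_mv
    )
    classified = clf.predict(events)
    known = classified[classified["true_bit"].notna()]
    rate, ci = false_positive_rate(known)
    counted = known[known["digital_bit"] != "excluded"]
    return {
        "fp_rate": rate,
        "fp_percent": 100.0 * rate,
        "ci_low": ci[0],
        "ci_high": ci[1],
        "n_counted": int(len(counted)),
        "n_circular": int((counted["digital_bit"] == 1).sum()),
        "n_reject": int((classified["digital_bit"] == "excluded").sum()),
        "delta_g_1x_ns": clf.delta_g_1x_,
        **stats,
    }


def blockade_recovery_study(
    geometry: str = "circular",
    n_events: int = 600,
    seed: int = 0,
    pore: PoreModel | None = None,
    voltage_mv: float = 150.0,
) -> dict:
    """Median detected maximum-blockage conductance for one geometry.

    ``circular`` events should recover the 2x level (~10 nS with the
    default pore), ``single_file`` the 1x level (~5 nS).
    """
    pore = pore or PoreModel()
    species = {
        "circular": closed_nanolock_species(),
        "single_file": ruler_species(),
    }[geometry]
    events, stats = simulate_species_events(
        species, n_events, seed=seed, pore=pore, voltage_mv=voltage_mv
    )
    g = events["max_blockage_nS"].to_numpy()
    return {
        "median_max_blockage_ns": float(np.median(g)),
        "iqr_ns": tuple(np.percentile(g, [25, 75])),
        "n_events": int(len(g)),
        **stats,
    }


# ---------------------------------------------------------------------------
# Paired digital/analog LoD study


def simulate_run_counts(
    x: float,
    rng: np.random.Generator,
    f_model: float,
    events_nominal: int = 14000,
    duration_s: float = 600.0,
    rate_cv: float = 0.5,
    floor: float = 0.008,
    ceiling: float = 0.95,
) -> dict:
    """Counted events of one run at reporter:probe ratio ``x``.

    A log-normal run-specific multiplier (coefficient of variation
    ``rate_cv``) scales the capture rate; the total event count is
    Poisson and the bit-1 count binomial at the observed closed
    fraction.  The closed fraction is multiplier-invariant by
    construction; the bit-1 capture rate is not.
    """
    sig = math.sqrt(math.log(1.0 + rate_cv**2))
    mult = float(rng.lognormal(-0.5 * sig * sig, sig))
    n_total = int(rng.poisson(events_nominal * mult))
    f_obs = float(observed_fraction(f_model, floor, ceiling))
    n_1 = int(rng.binomial(n_total, f_obs)) if n_total > 0 else 0
    return {
        "x": x,
        "multiplier": mult,
        "n_total": n_total,
        "n_1": n_1,
        "duration_s": duration_s,
        "digital": n_1 / n_total if n_total else 0.0,
        "analog_hz": n_1 / duration_s,
    }


def paired_lod_study(
    seed: int = 0,
    n_replicates: int = 101,
    concentrations_nm: np.ndarray | None = None,
    probe_conc_nm: float = 30.0,
    events_nominal: int = 14000,
    duration_s: float = 600.0,
    rate_cv: float = 0.5,
    n_blanks: int = 3,
    kinetics: KineticsConfig | None = None,
) -> dict:
    """Digital vs analog LoD on paired simulated standard curves.

    Both readouts are computed from the *same* simulated event sets:
    the digital response is the closed fraction, the analog response the
    bit-1 capture rate.  Each run carries an independent log-normal
    capture-rate multiplier (CV ``rate_cv``), emulating pore-to-pore and
    run-to-run variability.  Standard curves are fitted on the
    monotonic branch (reporter <= probe) and LoDs evaluated at 2.5
    blank SD above blank; the study reports the median LoDs and their
    median ratio over ``n_replicates`` independent curve pairs.
    """
    if concentrations_nm is None:
        concentrations_nm = np.array([0.03, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0])
    concentrations_nm = np.asarray(concentrations_nm, dtype=float)
    x_grid = concentrations_nm / probe_conc_nm
    kin = kinetics or fast_closure(KineticsConfig())
    f_map = dict(
        zip(x_grid, dose_response(kin, x_grid)["f_model"].to_numpy())
    )
    rng = np.random.default_rng(seed)
    ratios, lods_d, lods_a = [], [], []
    failures = 0
    for _ in range(n_replicates):
        blanks = [
            simulate_run_counts(0.0, rng, 0.0, events_nominal, duration_s, rate_cv)
            for _ in range(n_blanks)
        ]
        runs = [
            simulate_run_counts(x, rng, f_map[x], events_nominal, duration_s, rate_cv)
            for x in x_grid
        ]
        try:
            dig = build_standard_curve(
                concentrations_nm,
                [r["digital"] for r in runs],
                [b["digital"] for b in blanks],
            )
            ana = build_standard_curve(
                concentrations_nm,
                [r["analog_hz"] for r in runs],
                [b["analog_hz"] for b in blanks],
            )
        except (RuntimeError, ValueError):
            failures += 1
            continue
        if dig.lod is None or ana.lod is None:
            failures += 1
            continue
        lods_d.append(dig.lod)
        lods_a.append(ana.lod)
        ratios.append(ana.lod / dig.lod)
    if not ratios:
        raise RuntimeError("no replicate produced a defined LoD pair")
    return {
        "lod_digital_nm": float(np.median(lods_d)),
        "lod_analog_nm": float(np.median(lods_a)),
        "lod_ratio": float(np.median(ratios)),
        "ratios": np.asarray(ratios),
        "n_replicates": len(ratios),
        "n_failures": failures,
    }
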