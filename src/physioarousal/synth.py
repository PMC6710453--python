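"""Synthetic study generator with known ground truth.

Two levels of synthesis are provided:

* :func:`synth_recording` / :func:`synth_study` build full multi-channel raw
  recordings (ECG, dZ/dt, Z0, two respiration belts, EDA) from a
  :class:`GroundTruth`, so the entire signal-derivation chain can be tested
  against known beat times, B/Z/X latencies, respiration rates and injected
  skin-conductance responses.
* :func:`synth_segment_study` draws the participants x segments x parameters
  analysis table directly from the same population model.  This fast path is
  the workhorse for statistical simulation studies (imputation calibration,
  null-effect replication), where re-deriving every value from raw signals
  would add nothing but runtime.

Waveform templates are parameterized canonical shapes: a Gaussian QRS complex
with smaller Q/S/T deflections, a squared-sine (raised-cosine) dZ/dt ejection
wave with an explicit X-notch, a quasi-sinusoidal respiration belt signal and
kinked linear-rise/quadratic-recovery skin conductance responses on a slowly
declining tonic level.

Randomness uses numpy ``default_rng`` with per-participant substreams spawned
from a single master seed, so a study is reproducible from ``(config, seed)``
and any single participant can be regenerated in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (
    ANALYSIS_SEGMENTS,
    CONDITIONS,
    EventTimeline,
    MAP_SEGMENTS,
    PARAMETERS,
    POST_SEGMENTS,
    analysis_cells,
)

__all__ = [
    "GroundTruth", "Recording", "Channel", "StudySim", "EventTimeline",
    "make_beat_times", "synth_recording", "synth_study", "synth_segment_study",
    "DEFAULT_REACTIVITY", "SEGMENT_NOISE_SD", "BASELINE_MEAN", "BASELINE_SD",
]


# ---------------------------------------------------------------------------
# ground truth

@dataclass
class GroundTruth:
    """Physiological truth for one synthetic participant.

    Times are seconds unless noted; ``hp_mean`` and modulation amplitudes are
    milliseconds; impedance quantities follow the Kubicek convention.
    ``segment_effects`` maps ``(parameter, analysis_segment)`` to an additive
    shift in the parameter's own units, applied on top of the participant's
    level (used both for question reactivity and condition effects).
    """

    hp_mean: float = 800.0          # mean heart period, ms
    lf_amp: float = 25.0            # low-frequency IBI modulation amplitude, ms
    hf_amp: float = 20.0            # high-frequency IBI modulation amplitude, ms
    f_lf: float = 0.10              # Hz, must lie in [0.07, 0.14)
    f_hf: float = 0.25              # Hz, must lie in [0.14, 0.4]
    ibi_noise: float = 2.0          # white IBI noise SD, ms
    pep: float = 100.0              # pre-ejection period (Q at R-20 ms), ms
    lvet: float = 280.0             # left-ventricular ejection time (B to X), ms
    zb_delay: float = 60.0          # Z latency after B, ms
    dzdt_max: float = 0.8           # peak dZ/dt, Ohm/s
    z0: float = 30.0                # basal thoracic impedance, Ohm
    electrode_distance: float = 48.28  # measuring-electrode spacing L, cm
    resp_rate: float = 15.0         # cycles/min
    scr_rate: float = 4.0           # nonspecific SCR rate, events/min
    scr_events: list[tuple[float, float]] | None = None  # (onset s, amp uS)
    eda_level: float = 5.0          # tonic skin conductance, uS
    eda_slope: float = -0.001       # tonic drift, uS/s
    bp: tuple[tuple[float, float], ...] = ((120.0, 80.0),) * 3  # (sys, dia) per slot
    condition: str = "MS"
    segment_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    ecg_noise: float = 0.01         # mV
    dzdt_noise: float = 0.005       # Ohm/s
    resp_noise: float = 0.02        # arbitrary belt units
    eda_noise: float = 0.0005       # uS

    def __post_init__(self) -> None:
        if self.hp_mean <= 0:
            raise ValueError("hp_mean must be positive")
        if not (0.07 <= self.f_lf < 0.14):
            raise ValueError("f_lf outside the low-frequency band [0.07, 0.14)")
        if not (0.14 <= self.f_hf <= 0.4):
            raise ValueError("f_hf outside the high-frequency band [0.14, 0.4]")
        if self.pep <= 20:
            raise ValueError("pep must exceed 20 ms (Q precedes B)")
        if self.lvet <= 2 * self.zb_delay + 40:
            raise ValueError("lvet too short for the ejection template")
        for name in ("lf_amp", "hf_amp", "dzdt_max", "z0", "electrode_distance",
                     "resp_rate", "scr_rate", "eda_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")

    def noise_free(self) -> "GroundTruth":
        """Copy with every stochastic signal component switched off."""
        return replace(self, ibi_noise=0.0, ecg_noise=0.0, dzdt_noise=0.0,
                       resp_noise=0.0, eda_noise=0.0)

    def effect(self, parameter: str, segment: str) -> float:
        return self.segment_effects.get((parameter, segment), 0.0)


@dataclass
class Channel:
    samples: np.ndarray
    rate: float
    units: str


@dataclass
class Recording:
    """One participant's multi-channel recording plus protocol metadata."""

    channels: dict[str, Channel]
    events: EventTimeline
    bp_readings: tuple  # 3 x (sys, dia) mmHg, entries may be None
    participant_id: str
    condition: str
    electrode_distance: float = 48.28
    truth: GroundTruth | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.bp_readings) != 3:
            raise ValueError("exactly 3 blood pressure readings expected")
        dur = self.events.duration
        for name, ch in self.channels.items():
            if ch.rate <= 0:
                raise ValueError(f"channel {name}: non-positive rate")
            if abs(len(ch.samples) / ch.rate - dur) > 2.0:
                raise ValueError(f"channel {name}: length inconsistent with timeline")

    # -- serialization: one directory per participant, CSV arrays + JSON sidecar
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        sidecar = {
            "participant_id": self.participant_id,
            "condition": self.condition,
            "electrode_distance": self.electrode_distance,
            "bp_readings": [list(r) if r is not None else None for r in self.bp_readings],
            "events": [list(s) for s in self.events.segments],
            "channels": {n: {"rate": c.rate, "units": c.units} for n, c in self.channels.items()},
            "meta": self.meta,
        }
        (directory / "recording.json").write_text(json.dumps(sidecar, indent=1))
        for name, ch in self.channels.items():
            np.savetxt(directory / f"{name}.csv", ch.samples, fmt="%.6g")

    @classmethod
    def load(cls, directory: str | Path) -> "Recording":
        directory = Path(directory)
        sidecar = json.loads((directory / "recording.json").read_text())
        channels = {
            name: Channel(np.loadtxt(directory / f"{name}.csv"), info["rate"], info["units"])
            for name, info in sidecar["channels"].items()
        }
        return cls(
            channels=channels,
            events=EventTimeline([tuple(s) for s in sidecar["events"]]),
            bp_readings=tuple(tuple(r) if r is not None else None
                              for r in sidecar["bp_readings"]),
            participant_id=sidecar["participant_id"],
            condition=sidecar["condition"],
            electrode_distance=sidecar["electrode_distance"],
            meta=sidecar.get("meta", {}),
        )


# ---------------------------------------------------------------------------
# beat train

def make_beat_times(truth: GroundTruth, duration: float,
                    seed: int | np.random.Generator = 0,
                    hr_offset=None) -> np.ndarray:
    """R-wave times over ``[0, duration]`` seconds.

    Successive inter-beat intervals equal ``hp_mean`` plus sinusoidal LF/HF
    modulation plus white noise.  ``hr_offset`` (optional, callable t -> bpm)
    shifts the instantaneous heart rate, used to realize per-segment effects.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = [0.0]
    t = 0.0
    while True:
        hp = truth.hp_mean
        if hr_offset is not None:
            hr = 60000.0 / truth.hp_mean + hr_offset(t)
            hp = 60000.0 / max(hr, 20.0)
        ibi = (hp
               + truth.lf_amp * np.sin(2 * np.pi * truth.f_lf * t)
               + truth.hf_amp * np.sin(2 * np.pi * truth.f_hf * t))
        if truth.ibi_noise > 0:
            ibi += truth.ibi_noise * rng.standard_normal()
        ibi = max(ibi, 200.0)  # refractory floor
        t += ibi / 1000.0
        if t > duration + 1e-9:
            break
        times.append(t)
    return np.asarray(times)


# ---------------------------------------------------------------------------
# waveform synthesis helpers

def _add_template(signal_out: np.ndarray, rate: float, t0: float,
                  rel_t: np.ndarray, template: np.ndarray) -> None:
    """Add ``template`` (sampled at ``rel_t`` seconds around t0) in place."""
    idx = np.round((t0 + rel_t) * rate).astype(int)
    ok = (idx >= 0) & (idx < len(signal_out))
    signal_out[idx[ok]] += template[ok]


def _segment_lookup(timeline: EventTimeline):
    """Map a time to its analysis segment label (BL minutes pooled)."""
    edges = [(lab if not lab.startswith("BL") else "BL", s, e)
             for lab, s, e in timeline.segments]

    def lookup(t: float) -> str | None:
        for lab, s, e in edges:
            if s <= t < e:
                return lab
        return edges[-1][0] if edges and t >= edges[-1][2] else None

    return lookup


SCR_RISE_S = 5.0    # onset-to-peak time, inside the 3.5-12 s counting window
SCR_DECAY_S = 7.0   # peak-to-baseline recovery time
SCR_MIN_GAP_S = SCR_RISE_S + SCR_DECAY_S + 1.0


def _scr_kernel(rel_t: np.ndarray, rise: float = SCR_RISE_S,
                decay: float = SCR_DECAY_S) -> np.ndarray:
    """Canonical SCR with unit peak: linear rise, quadratic recovery.

    The kinks at onset and peak keep the qualifying local minimum and local
    maximum pinned to the injected latencies even when an event rides on a
    drifting tonic level or a neighbor's tail; the compact support (the
    kernel is exactly zero beyond ``rise + decay`` seconds) is what makes
    superposed trains individuable by the onset-to-peak counting rule.
    """
    up = rel_t / rise
    down = 1.0 - (rel_t - rise) / decay
    return np.where((rel_t >= 0) & (rel_t <= rise), up,
                    np.where((rel_t > rise) & (rel_t <= rise + decay),
                             down ** 2, 0.0))


def _draw_scr_events(truth: GroundTruth, timeline: EventTimeline,
                     rng: np.random.Generator, min_gap: float = SCR_MIN_GAP_S,
                     amp_range: tuple[float, float] = (0.05, 0.3)):
    """Poisson-like SCR onsets per analysis segment, thinned to ``min_gap``.

    Superposed SCRs closer than one kernel footprint cannot be individuated
    by any onset-to-peak counting rule, so the generator enforces a minimum
    onset separation (which caps the realizable rate at ~60/min_gap); the
    realized events are the injected ground truth.
    """
    events: list[tuple[float, float]] = []
    last = -np.inf
    latest = timeline.duration - SCR_RISE_S - 2.0
    for lab, start, end in timeline.segments:
        seg = "BL" if lab.startswith("BL") else lab
        rate = max(truth.scr_rate + truth.effect("NSFR", seg), 0.0)  # events/min
        n = rng.poisson(rate * (end - start) / 60.0)
        onsets = np.sort(rng.uniform(start, end - 1.0, size=n))
        for onset in onsets:
            # skip the first second (an onset needs a preceding local minimum)
            if onset - last >= min_gap and 1.0 <= onset <= latest:
                events.append((float(onset), float(rng.uniform(*amp_range))))
                last = onset
    return events


# ---------------------------------------------------------------------------
# full recording

def synth_recording(truth: GroundTruth, timeline: EventTimeline | None = None,
                    seed: int | np.random.Generator = 0,
                    participant_id: str = "p000") -> Recording:
    """Render one participant's raw multi-channel recording.

    Channel layout (name: native rate): ``ecg`` 500 Hz (mV), ``dzdt`` 500 Hz
    (Ohm/s), ``z0`` 25 Hz (Ohm), ``resp_thorax``/``resp_abdomen`` 100 Hz
    (a.u.), ``eda`` 25 Hz (uS).  The dZ/dt B point is placed at
    R + (pep - 20) ms, the maximum slope ``dzdt_max`` at B + ``zb_delay``,
    and the X notch at B + ``lvet``.  Reproducible given the seed.
    """
    timeline = timeline or EventTimeline.standard()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    duration = timeline.duration
    seg_of = _segment_lookup(timeline)

    def seg_effect(parameter: str, t: float) -> float:
        seg = seg_of(t)
        return truth.effect(parameter, seg) if seg else 0.0

    # --- beat train with per-segment HR shifts
    has_hr_fx = any(p == "HR" for p, _ in truth.segment_effects)
    beats = make_beat_times(truth, duration, rng,
                            hr_offset=(lambda t: seg_effect("HR", t)) if has_hr_fx else None)

    # --- ECG (500 Hz)
    fs_ecg = 500.0
    n_ecg = int(round(duration * fs_ecg)) + 1
    ecg = np.zeros(n_ecg)
    rel = np.arange(-0.06, 0.45, 1 / fs_ecg)
    qrs_t = (1.00 * np.exp(-0.5 * (rel / 0.008) ** 2)          # R
             - 0.15 * np.exp(-0.5 * ((rel + 0.025) / 0.010) ** 2)  # Q
             - 0.12 * np.exp(-0.5 * ((rel - 0.030) / 0.010) ** 2)  # S
             + 0.25 * np.exp(-0.5 * ((rel - 0.250) / 0.050) ** 2))  # T
    for b in beats:
        _add_template(ecg, fs_ecg, b, rel, qrs_t)
    if truth.ecg_noise > 0:
        ecg += truth.ecg_noise * rng.standard_normal(n_ecg)

    # --- dZ/dt (500 Hz): squared-sine ejection wave + X notch
    fs_dz = 500.0
    n_dz = int(round(duration * fs_dz)) + 1
    dzdt = np.zeros(n_dz)
    rel_dz = np.arange(0.0, 0.62, 1 / fs_dz)
    for b in beats:
        pep_b = truth.pep + seg_effect("PEP", b)
        amp_b = truth.dzdt_max * max(1.0 + seg_effect("CO", b) / 5.0, 0.05)
        b_lat = (pep_b - 20.0) / 1000.0
        width = 2 * truth.zb_delay / 1000.0
        x_lat = b_lat + truth.lvet / 1000.0
        tau = rel_dz - b_lat
        # half-sine ejection wave: abrupt upstroke at B (as in real dZ/dt),
        # peak dzdt_max at B + zb_delay, return to baseline at B + 2*zb_delay
        wave = np.where((tau >= 0) & (tau <= width),
                        amp_b * np.sin(np.pi * tau / width), 0.0)
        notch_w = 0.08
        tau_x = rel_dz - x_lat
        wave -= np.where(np.abs(tau_x) <= notch_w / 2,
                         0.3 * amp_b * np.cos(np.pi * tau_x / notch_w) ** 2, 0.0)
        _add_template(dzdt, fs_dz, b, rel_dz, wave)
    if truth.dzdt_noise > 0:
        dzdt += truth.dzdt_noise * rng.standard_normal(n_dz)

    # --- respiration (100 Hz), instantaneous rate per segment
    fs_rsp = 100.0
    t_rsp = np.arange(0.0, duration + 1 / fs_rsp, 1 / fs_rsp)
    rr_inst = np.array([max(truth.resp_rate + seg_effect("RR", t), 2.0) for t in t_rsp]) / 60.0
    phase = 2 * np.pi * np.cumsum(rr_inst) / fs_rsp
    thorax = np.sin(phase)
    abdomen = 0.85 * np.sin(phase - 0.3)
    if truth.resp_noise > 0:
        thorax = thorax + truth.resp_noise * rng.standard_normal(len(t_rsp))
        abdomen = abdomen + truth.resp_noise * rng.standard_normal(len(t_rsp))

    # --- Z0 (25 Hz): basal impedance with mild respiratory coupling
    fs_z0 = 25.0
    t_z0 = np.arange(0.0, duration + 1 / fs_z0, 1 / fs_z0)
    z0_sig = truth.z0 + 0.05 * np.sin(2 * np.pi * truth.resp_rate / 60.0 * t_z0)
    z0_sig = z0_sig + 0.005 * rng.standard_normal(len(t_z0))

    # --- EDA (25 Hz): declining tonic level + superposed SCRs
    fs_eda = 25.0
    t_eda = np.arange(0.0, duration + 1 / fs_eda, 1 / fs_eda)
    eda = truth.eda_level + truth.eda_slope * t_eda
    scr_events = truth.scr_events
    if scr_events is None:
        scr_events = _draw_scr_events(truth, timeline, rng)
    for onset, amp in scr_events:
        eda = eda + amp * _scr_kernel(t_eda - onset)
    if truth.eda_noise > 0:
        # skin conductance noise is slow: band-limit white noise (~1 s kernel)
        kernel = np.hanning(int(fs_eda) + 2)[1:-1]
        smooth = np.convolve(rng.standard_normal(len(t_eda)), kernel / kernel.sum(),
                             mode="same")
        eda = eda + truth.eda_noise * smooth / max(np.std(smooth), 1e-12)

    # --- spot blood pressure with per-slot MAP effects
    slot_seg = ("BL", "R1", "R2f")
    bp_readings = tuple(
        (sys + truth.effect("MAP", slot_seg[i]), dia + truth.effect("MAP", slot_seg[i]))
        for i, (sys, dia) in enumerate(truth.bp)
    )

    realized = replace(truth, scr_events=list(scr_events))
    return Recording(
        channels={
            "ecg": Channel(ecg, fs_ecg, "mV"),
            "dzdt": Channel(dzdt, fs_dz, "Ohm/s"),
            "z0": Channel(z0_sig, fs_z0, "Ohm"),
            "resp_thorax": Channel(thorax, fs_rsp, "a.u."),
            "resp_abdomen": Channel(abdomen, fs_rsp, "a.u."),
            "eda": Channel(eda, fs_eda, "uS"),
        },
        events=timeline,
        bp_readings=bp_readings,
        participant_id=participant_id,
        condition=truth.condition,
        electrode_distance=truth.electrode_distance,
        truth=realized,
        meta={"beat_times": beats.tolist(), "scr_events": list(map(list, scr_events))},
    )


# ---------------------------------------------------------------------------
# population model

#: Population means of participant baseline levels, per parameter.
BASELINE_MEAN = {"HR": 75.0, "MAP": 93.3, "lnHF": 6.0, "lnLF": 6.5, "RR": 15.0,
                 "NSFR": 6.0, "PEP": 100.0, "CO": 5.5, "TPR": 17.0}

#: Between-participant SDs of those levels.
BASELINE_SD = {"HR": 8.0, "MAP": 8.0, "lnHF": 1.0, "lnLF": 1.0, "RR": 2.5,
               "NSFR": 2.0, "PEP": 10.0, "CO": 1.0, "TPR": 3.5}

#: Within-participant segment-to-segment noise SD, calibrated so that the
#: dispersion of baseline-change scores at n = 108 matches the standard
#: errors this study design reports (SD_change ~= SE * sqrt(108), with
#: sigma_segment = SD_change / sqrt(2) for independent segment noise).
SEGMENT_NOISE_SD = {"HR": 2.05, "MAP": 4.1, "lnHF": 0.88, "lnLF": 0.95,
                    "RR": 5.7, "NSFR": 6.0, "PEP": 16.7, "CO": 3.45, "TPR": 1.25}

#: Question-related within-subject reactivity shared by both conditions,
#: mirroring the canonical arousal response to effortful typed answering:
#: heart rate, respiration rate and electrodermal fluctuation rate rise while
#: answering, vagally mediated HF-HRV falls, and heart rate dips below
#: baseline in the first post-question minute.
DEFAULT_REACTIVITY = {
    ("HR", "Q1"): 3.5, ("HR", "R1"): -1.2, ("HR", "Q2"): 2.8,
    ("HR", "R2a"): -0.9, ("HR", "R2f"): 0.9,
    ("lnHF", "Q1"): -0.8, ("lnHF", "Q2"): -0.9,
    ("RR", "Q1"): 3.7, ("RR", "Q2"): 3.7,
    ("NSFR", "Q1"): 5.8, ("NSFR", "Q2"): 6.3,
    ("PEP", "Q1"): -3.1, ("PEP", "Q2"): -3.4,
}

#: Fraction of analysis cells missing, matching the study design emulated.
DEFAULT_MISS_RATE = 0.1392


def _draw_truth(rng: np.random.Generator, condition: str,
                effects: dict[tuple[str, str], float],
                reactivity: dict[tuple[str, str], float],
                noise_free: bool = False) -> GroundTruth:
    """One participant's truth drawn around the population means."""
    hr = max(rng.normal(BASELINE_MEAN["HR"], BASELINE_SD["HR"]), 45.0)
    seg_fx = dict(reactivity)
    if condition == "MS":
        for key, shift in effects.items():
            seg_fx[key] = seg_fx.get(key, 0.0) + shift
    sys = rng.normal(120.0, 10.0)
    dia = min(rng.normal(80.0, 8.0), sys - 5.0)
    truth = GroundTruth(
        hp_mean=60000.0 / hr,
        lf_amp=max(rng.normal(25.0, 8.0), 2.0),
        hf_amp=max(rng.normal(20.0, 7.0), 2.0),
        f_lf=rng.uniform(0.08, 0.12),
        f_hf=rng.uniform(0.2, 0.3),
        pep=max(rng.normal(BASELINE_MEAN["PEP"], BASELINE_SD["PEP"]), 60.0),
        lvet=max(rng.normal(280.0, 20.0), 200.0),
        dzdt_max=max(rng.normal(0.8, 0.12), 0.3),
        z0=max(rng.normal(30.0, 3.0), 20.0),
        electrode_distance=max(rng.normal(48.28, 5.80), 30.0),
        resp_rate=max(rng.normal(BASELINE_MEAN["RR"], BASELINE_SD["RR"]), 8.0),
        scr_rate=max(rng.normal(4.0, 1.5), 0.5),
        eda_level=max(rng.normal(5.0, 1.5), 1.0),
        bp=tuple((sys + rng.normal(0, 2.0), dia + rng.normal(0, 2.0)) for _ in range(3)),
        condition=condition,
        segment_effects=seg_fx,
    )
    return truth.noise_free() if noise_free else truth


@dataclass
class StudySim:
    """A simulated two-condition study: recordings (or none), truths, mask."""

    recordings: list[Recording]
    truths: list[GroundTruth]
    conditions: pd.Series
    mask: pd.DataFrame  # boolean, participants x change-score cells
    seed: int


def _mcar_mask(participants, miss_rate: float, rng: np.random.Generator) -> pd.DataFrame:
    cols = [f"{p}:{s}" for p, s in analysis_cells()]
    if not 0 <= miss_rate < 1:
        raise ValueError("miss_rate must lie in [0, 1)")
    mask = rng.random((len(participants), len(cols))) < miss_rate
    return pd.DataFrame(mask, index=participants, columns=cols)


def synth_study(n_ms: int = 53, n_dps: int = 55,
                effects: dict[tuple[str, str], float] | None = None,
                miss_rate: float = DEFAULT_MISS_RATE,
                seed: int = 0, noise_free: bool = False,
                timeline: EventTimeline | None = None) -> StudySim:
    """Full-recording study: per-participant truths, raw recordings, MCAR mask.

    ``effects`` are additive condition effects (applied to the MS group only)
    per ``(parameter, segment)``; the default of no effects reproduces the
    null between-group design.  Missingness is completely at random over the
    downstream change-score cells, the level at which imputation operates.
    """
    if n_ms <= 0 or n_dps <= 0:
        raise ValueError("group sizes must be positive")
    effects = effects or {}
    master = np.random.SeedSequence(seed)
    streams = master.spawn(n_ms + n_dps + 1)
    mask_rng = np.random.default_rng(streams[-1])
    recordings, truths, conditions, ids = [], [], [], []
    for i in range(n_ms + n_dps):
        rng = np.random.default_rng(streams[i])
        cond = "MS" if i < n_ms else "DPS"
        truth = _draw_truth(rng, cond, effects, DEFAULT_REACTIVITY, noise_free)
        tl = timeline or EventTimeline.standard(
            q1_duration=float(np.clip(rng.normal(79.9, 42.0), 30.0, 240.0)),
            q2_duration=float(np.clip(rng.normal(79.0, 38.0), 30.0, 240.0)),
        )
        pid = f"p{i:03d}"
        recordings.append(synth_recording(truth, tl, rng, participant_id=pid))
        truths.append(recordings[-1].truth)
        conditions.append(cond)
        ids.append(pid)
    return StudySim(
        recordings=recordings,
        truths=truths,
        conditions=pd.Series(conditions, index=ids, name="condition"),
        mask=_mcar_mask(ids, miss_rate, mask_rng),
        seed=seed,
    )


def synth_segment_study(n_ms: int = 53, n_dps: int = 55,
                        effects: dict[tuple[str, str], float] | None = None,
                        miss_rate: float = DEFAULT_MISS_RATE,
                        seed: int = 0,
                        reactivity: dict[tuple[str, str], float] | None = None):
    """Draw the analysis table directly from the population model.

    Returns a :class:`physioarousal.protocol.SegmentTable`.  Each cell is
    participant level + within-subject reactivity + condition effect (MS only)
    + independent segment noise.  Cross-parameter identities of the raw
    pipeline (e.g. TPR = MAP/CO) are not enforced on this path; every
    parameter is generated directly on its own scale.
    """
    from .protocol import SegmentTable

    if n_ms <= 0 or n_dps <= 0:
        raise ValueError("group sizes must be positive")
    effects = effects or {}
    reactivity = DEFAULT_REACTIVITY if reactivity is None else reactivity
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = n_ms + n_dps
    ids = [f"p{i:03d}" for i in range(n)]
    conditions = pd.Series(["MS"] * n_ms + ["DPS"] * n_dps, index=ids, name="condition")

    columns = []
    for p in PARAMETERS:
        segs = MAP_SEGMENTS if p == "MAP" else ANALYSIS_SEGMENTS
        columns.extend((p, s) for s in segs)
    values = pd.DataFrame(index=ids,
                          columns=pd.MultiIndex.from_tuples(columns), dtype=float)
    for p in PARAMETERS:
        level = rng.normal(BASELINE_MEAN[p], BASELINE_SD[p], size=n)
        segs = MAP_SEGMENTS if p == "MAP" else ANALYSIS_SEGMENTS
        for s in segs:
            shift = np.full(n, reactivity.get((p, s), 0.0))
            if (p, s) in effects:
                shift = shift + np.where(conditions.values == "MS", effects[(p, s)], 0.0)
            cell = level + shift + rng.normal(0.0, SEGMENT_NOISE_SD[p], size=n)
            if p in ("NSFR", "RR", "CO", "TPR"):
                cell = np.maximum(cell, 0.0)
            values[(p, s)] = cell
    mask = _mcar_mask(ids, miss_rate, rng)
    return SegmentTable(values=values, condition=conditions, mask=mask)
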