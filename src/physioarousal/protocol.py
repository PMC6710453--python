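"""Map derived signals onto the protocol timeline; build the analysis table.

The unit of statistical analysis is the participants x segments x parameters
table: nine physiological parameters (HR, MAP, lnHF, lnLF, RR, NSFR, PEP,
CO, TPR) over ten analysis segments (pooled baseline BL, Q1, R1, Q2,
R2a-R2f), with MAP restricted to its BP-backed points (BL, R1, R2f).
Change scores are each post-baseline cell minus the participant's baseline,
yielding 74 analysis cells and hence 74 within- plus 74 between-subject
comparisons (148 in total) on a complete design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cardiac, hemodynamics, resp_eda
from .design import (
    ANALYSIS_SEGMENTS,
    MAP_SEGMENTS,
    PARAMETERS,
    POST_SEGMENTS,
    analysis_cells,
)

__all__ = ["SegmentTable", "baseline_value", "process_recording",
           "build_segment_table", "change_scores", "comparison_counts",
           "MIN_QUESTION_SPAN_S"]

#: Question segments shorter than this are treated as missing.
MIN_QUESTION_SPAN_S = 30.0


def baseline_value(minute_values) -> float:
    """Pooled baseline: mean of the available 1-min baseline values.

    Requires at least two usable minutes (of the four recorded: two eyes
    open, two eyes closed); otherwise missing.
    """
    vals = np.asarray([v for v in minute_values if v is not None and np.isfinite(v)],
                      dtype=float)
    return float(np.mean(vals)) if vals.size >= 2 else np.nan


def _window_value(values_per_window) -> float:
    """Combine per-window values of one analysis segment (BL pools minutes)."""
    if len(values_per_window) == 1:
        return values_per_window[0]
    return baseline_value(values_per_window)


def process_recording(rec) -> dict[tuple[str, str], float]:
    """Derive all nine parameters per analysis segment from one recording.

    Returns ``{(parameter, segment): value}`` with nan for missing cells.
    Question segments shorter than :data:`MIN_QUESTION_SPAN_S` are missing.
    """
    windows = rec.events.analysis_windows()
    out: dict[tuple[str, str], float] = {}

    # --- cardiac chain
    ecg = cardiac.preprocess_ecg(rec.channels["ecg"].samples, rec.channels["ecg"].rate)
    beats = cardiac.detect_r_waves(ecg)

    # --- impedance chain
    dzdt = hemodynamics.preprocess_dzdt(rec.channels["dzdt"].samples,
                                        rec.channels["dzdt"].rate)
    z0_sig = rec.channels["z0"]

    # --- respiration chain (two belts)
    breath_series = []
    for name in ("resp_thorax", "resp_abdomen"):
        if name in rec.channels:
            x = resp_eda.preprocess_resp(rec.channels[name].samples,
                                         rec.channels[name].rate)
            breath_series.append(resp_eda.detect_breaths(x, belt=name))

    # --- electrodermal chain
    eda_ch = rec.channels["eda"]
    eda = (eda_ch.samples if eda_ch.rate == resp_eda.EDA_RATE_HZ
           else resp_eda.preprocess_resp(eda_ch.samples, eda_ch.rate))

    # --- spot blood pressure
    seg_map = hemodynamics.assign_bp_slots(rec.bp_readings)

    for seg in ANALYSIS_SEGMENTS:
        wins = windows.get(seg, [])
        usable = [w for w in wins
                  if seg not in ("Q1", "Q2") or (w[1] - w[0]) >= MIN_QUESTION_SPAN_S]
        if not usable:
            for p in PARAMETERS:
                out[(p, seg)] = np.nan
            continue

        hr_vals, hp_vals, hf_vals, lf_vals, rr_vals, nsfr_vals = [], [], [], [], [], []
        pep_vals, co_vals = [], []
        for win in usable:
            hp, hr = cardiac.heart_period(beats, win)
            hp_vals.append(hp); hr_vals.append(hr)
            if win[1] - win[0] >= 60.0:
                hrv = cardiac.hrv_band_power(beats, win)
                hf_vals.append(hrv.ln_hf); lf_vals.append(hrv.ln_lf)
            else:  # too short for spectral estimation -> missing
                hf_vals.append(np.nan); lf_vals.append(np.nan)
            rr_vals.append(resp_eda.resp_rate(breath_series, win))
            nsfr_vals.append(resp_eda.detect_nsf(eda, win)[1])

            ens = hemodynamics.ensemble_average(dzdt, beats, win)
            pep = sv = np.nan
            if ens is not None:
                i0 = int(win[0] * z0_sig.rate)
                i1 = max(int(win[1] * z0_sig.rate), i0 + 1)
                z0_mean = float(np.mean(z0_sig.samples[i0:i1]))
                pts = hemodynamics.detect_bzx(ens)
                if pts.valid:
                    pep = hemodynamics.pep_from_b(pts.b)
                    lvet_s = (pts.x - pts.b) / 1000.0
                    dzdt_max = float(ens.waveform[np.searchsorted(ens.time_ms, pts.z)])
                    sv = hemodynamics.stroke_volume_kubicek(
                        z0_mean, rec.electrode_distance, lvet_s, dzdt_max)
            pep_vals.append(pep)
            co_vals.append(hemodynamics.cardiac_output(sv, hr)
                           if np.isfinite(sv) and np.isfinite(hr) else np.nan)

        out[("HR", seg)] = _window_value(hr_vals)
        out[("lnHF", seg)] = _window_value(hf_vals)
        out[("lnLF", seg)] = _window_value(lf_vals)
        out[("RR", seg)] = _window_value(rr_vals)
        out[("NSFR", seg)] = _window_value(nsfr_vals)
        out[("PEP", seg)] = _window_value(pep_vals)
        out[("CO", seg)] = _window_value(co_vals)

        map_val = seg_map.get(seg)
        out[("MAP", seg)] = (float(map_val)
                             if map_val is not None and seg in MAP_SEGMENTS else np.nan)
        co = out[("CO", seg)]
        if map_val is not None and np.isfinite(co) and co > 0:
            out[("TPR", seg)] = hemodynamics.total_peripheral_resistance(map_val, co)
        else:
            out[("TPR", seg)] = np.nan
    return out


@dataclass
class SegmentTable:
    """Participants x (parameter, segment) analysis table.

    ``values`` is a wide DataFrame with a (parameter, segment) column
    MultiIndex containing only valid cells (MAP restricted to BL/R1/R2f);
    ``condition`` labels each participant MS or DPS; ``mask`` (optional,
    boolean, columns named ``PARAM:SEG``) marks change-score cells missing.
    """

    values: pd.DataFrame
    condition: pd.Series
    mask: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.condition.index):
            raise ValueError("values and condition must share the participant index")
        self.values.index.name = "participant"
        self.values.columns.names = ["parameter", "segment"]
        self.condition.index.name = "participant"

    def to_tidy(self) -> pd.DataFrame:
        """Tidy CSV-ready frame: participant, condition, parameter, segment, value."""
        long = self.values.stack([0, 1], future_stack=True).rename("value").reset_index()
        long.columns = ["participant", "parameter", "segment", "value"]
        long.insert(1, "condition", long["participant"].map(self.condition))
        return long

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame, mask: pd.DataFrame | None = None) -> "SegmentTable":
        values = tidy.pivot_table(index="participant", values="value",
                                  columns=["parameter", "segment"], dropna=False)
        cols = [(p, s) for p in PARAMETERS
                for s in (MAP_SEGMENTS if p == "MAP" else ANALYSIS_SEGMENTS)
                if (p, s) in values.columns]
        condition = tidy.drop_duplicates("participant").set_index("participant")["condition"]
        return cls(values[cols], condition.loc[values.index], mask=mask)


def build_segment_table(derived: list[dict], conditions, participants=None,
                        mask: pd.DataFrame | None = None) -> SegmentTable:
    """Assemble per-participant ``process_recording`` outputs into a table."""
    participants = list(participants) if participants is not None else [
        f"p{i:03d}" for i in range(len(derived))]
    cols = [(p, s) for p in PARAMETERS
            for s in (MAP_SEGMENTS if p == "MAP" else ANALYSIS_SEGMENTS)]
    values = pd.DataFrame(
        [[d.get(c, np.nan) for c in cols] for d in derived],
        index=participants, columns=pd.MultiIndex.from_tuples(cols), dtype=float)
    condition = pd.Series(list(conditions), index=participants, name="condition")
    return SegmentTable(values, condition, mask=mask)


def change_scores(table: SegmentTable) -> pd.DataFrame:
    """Baseline-change matrix: post-baseline cell minus BL, flattened columns.

    Columns are named ``PARAM:SEG`` over the 74 analysis cells; the BL column
    is dropped.  A change score is defined only when both terms are present.
    The table's missingness mask, when given, is applied here (cells set to
    NaN), since imputation operates on change scores.
    """
    cols = [f"{p}:{s}" for p, s in analysis_cells()]
    out = pd.DataFrame(index=table.values.index, columns=cols, dtype=float)
    for p, s in analysis_cells():
        if (p, s) not in table.values.columns or (p, "BL") not in table.values.columns:
            continue
        out[f"{p}:{s}"] = table.values[(p, s)] - table.values[(p, "BL")]
    if table.mask is not None:
        shared = [c for c in cols if c in table.mask.columns]
        out = out.mask(table.mask[shared].reindex(columns=cols, fill_value=False))
    return out


def comparison_counts(scores: pd.DataFrame) -> tuple[int, int]:
    """(within, between) test counts: cells with any data in each family."""
    has_data = scores.notna().any(axis=0)
    n = int(has_data.sum())
    return n, n
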