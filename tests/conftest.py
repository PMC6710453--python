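"""Shared fixtures: synthetic recordings and the reference evidence table."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from physioarousal import synth
from physioarousal.design import EventTimeline

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def reference_table() -> pd.DataFrame:
    """The published 148-comparison evidence table (means, SEs, Bayes factors).

    ``bf_censored`` marks cells printed as an exceedance bound (>1000), stored
    at the bound.
    """
    return pd.read_csv(DATA_DIR / "reference_evidence_table.csv")


@pytest.fixture(scope="session")
def clean_truth() -> synth.GroundTruth:
    return synth.GroundTruth().noise_free()


@pytest.fixture(scope="session")
def std_timeline() -> EventTimeline:
    return EventTimeline.standard()


@pytest.fixture(scope="session")
def clean_recording(clean_truth, std_timeline) -> synth.Recording:
    """One noise-free participant over the standard protocol."""
    return synth.synth_recording(clean_truth, std_timeline, seed=7)


@pytest.fixture(scope="session")
def clean_beats(clean_recording):
    from physioarousal import cardiac

    ecg = cardiac.preprocess_ecg(clean_recording.channels["ecg"].samples,
                                 clean_recording.channels["ecg"].rate)
    return cardiac.detect_r_waves(ecg)


@pytest.fixture(scope="session")
def segment_study():
    """Small fast-path study with defaults-scale missingness."""
    return synth.synth_segment_study(12, 12, seed=99)
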