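"""Experimental protocol layout.

The design is a two-condition between-subjects protocol: a mortality-salience
(MS) group and a dental-pain-salience (DPS) control group each answer two
open-ended questions by typing, embedded in a fixed timeline of resting
recordings:

* four 1-min baseline recordings (two eyes open, two eyes closed),
* question 1 (variable duration, typically ~80 s),
* a 1-min rest (R1),
* question 2 (variable duration),
* a 6-min rest, subdivided for analysis into six 1-min intervals (R2a-R2f).

Spot blood pressure is taken three times: mid-baseline, after R1, and after
the 6-min rest, so mean arterial pressure exists only at BP-backed analysis
points.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Recording-level segment labels in protocol order.
SEGMENT_LABELS = (
    "BL1", "BL2", "BL3", "BL4",
    "Q1", "R1", "Q2",
    "R2a", "R2b", "R2c", "R2d", "R2e", "R2f",
)

#: Segments entering the statistical analysis (baseline minutes pooled).
ANALYSIS_SEGMENTS = ("BL", "Q1", "R1", "Q2", "R2a", "R2b", "R2c", "R2d", "R2e", "R2f")

#: Post-baseline analysis segments (change scores are defined on these).
POST_SEGMENTS = ANALYSIS_SEGMENTS[1:]

#: The nine physiological parameters under analysis.
PARAMETERS = ("HR", "MAP", "lnHF", "lnLF", "RR", "NSFR", "PEP", "CO", "TPR")

#: Analysis points at which MAP exists. Within each BP slot the reading is a
#: single constant, so each distinct post-baseline MAP value is analyzed once
#: (at R1 for the second reading, at R2f for the third).
MAP_SEGMENTS = ("BL", "R1", "R2f")

#: BP slot assignment: analysis segment -> index of the spot reading (0-2).
BP_SLOT_OF_SEGMENT = {
    "BL": 0,
    "Q1": 1, "R1": 1,
    "Q2": 2, "R2a": 2, "R2b": 2, "R2c": 2, "R2d": 2, "R2e": 2, "R2f": 2,
}

CONDITIONS = ("MS", "DPS")


def analysis_cells() -> list[tuple[str, str]]:
    """All (parameter, post-baseline segment) pairs with data.

    Eight parameters exist at all nine post-baseline segments (TPR varies
    through CO even where MAP is shared across a BP slot); MAP exists only at
    its two distinct post-baseline BP points. 8*9 + 2 = 74 cells, i.e. 74
    within- plus 74 between-subject tests, 148 comparisons in total.
    """
    cells = []
    for p in PARAMETERS:
        segs = ("R1", "R2f") if p == "MAP" else POST_SEGMENTS
        cells.extend((p, s) for s in segs)
    return cells


@dataclass
class EventTimeline:
    """Ordered, non-overlapping protocol segments.

    ``segments`` maps recording-level labels to half-open ``[start, end)``
    windows in seconds from recording onset.
    """

    segments: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = 0.0
        for label, start, end in self.segments:
            if end <= start:
                raise ValueError(f"segment {label} has non-positive duration")
            if start < prev_end - 1e-9:
                raise ValueError(f"segment {label} overlaps its predecessor")
            prev_end = end
        labels = [s[0] for s in self.segments]
        if labels and labels != [l for l in SEGMENT_LABELS if l in labels]:
            raise ValueError("segments out of protocol order")

    @property
    def duration(self) -> float:
        return self.segments[-1][2] if self.segments else 0.0

    def window(self, label: str) -> tuple[float, float]:
        for lab, start, end in self.segments:
            if lab == label:
                return (start, end)
        raise KeyError(label)

    def analysis_windows(self) -> dict[str, list[tuple[float, float]]]:
        """Windows per analysis segment; BL pools the four baseline minutes."""
        out: dict[str, list[tuple[float, float]]] = {}
        for lab, start, end in self.segments:
            key = "BL" if lab.startswith("BL") else lab
            out.setdefault(key, []).append((start, end))
        return out

    @classmethod
    def standard(cls, q1_duration: float = 79.9, q2_duration: float = 79.0,
                 minute: float = 60.0) -> "EventTimeline":
        """The canonical protocol with configurable question durations."""
        if q1_duration <= 0 or q2_duration <= 0:
            raise ValueError("question durations must be positive")
        segs = []
        t = 0.0
        for lab in ("BL1", "BL2", "BL3", "BL4"):
            segs.append((lab, t, t + minute)); t += minute
        segs.append(("Q1", t, t + q1_duration)); t += q1_duration
        segs.append(("R1", t, t + minute)); t += minute
        segs.append(("Q2", t, t + q2_duration)); t += q2_duration
        for lab in ("R2a", "R2b", "R2c", "R2d", "R2e", "R2f"):
            segs.append((lab, t, t + minute)); t += minute
        return cls(segs)
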