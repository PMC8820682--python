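"""Study design of the ethanol / liver-regeneration miRNA time course.

The default design mirrors the animal study being emulated: two diets
(chronic-ethanol EtOH vs. pair-fed carbohydrate CHO), liver sampled at
baseline and 6/24/72 h after 70% partial hepatectomy, n = 3 animals per
condition, and anti-miR-21 (AM21) or saline treatment arms collected at
baseline and 24 h only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import validate_sample_table

UNTREATED = "untreated"


@dataclass(frozen=True)
class StudyDesign:
    diets: tuple[str, ...] = ("CHO", "EtOH")
    times_h: tuple[float, ...] = (0, 6, 24, 72)
    treatments: tuple[str, ...] = (UNTREATED, "saline", "AM21")
    treatment_times_h: tuple[float, ...] = (0, 24)
    n_reps: int = 3
    panel_size: int = 420

    def __post_init__(self) -> None:
        if not self.diets:
            raise ValueError("diets is empty")
        if not self.times_h:
            raise ValueError("times_h is empty")
        if list(self.times_h) != sorted(set(self.times_h)):
            raise ValueError("times_h must be strictly increasing")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if not set(self.treatment_times_h) <= set(self.times_h):
            raise ValueError("treatment_times_h must be a subset of times_h")
        if UNTREATED not in self.treatments:
            raise ValueError(f"treatments must include {UNTREATED!r}")

    @property
    def baseline_time(self) -> float:
        return self.times_h[0]


def generate_design(design: StudyDesign) -> pd.DataFrame:
    """Expand a :class:`StudyDesign` into one sample row per animal.

    Untreated samples exist at every time point; treated samples only at the
    treatment collection times.
    """
    rows = []
    for diet in design.diets:
        for treatment in design.treatments:
            times = design.times_h if treatment == UNTREATED else design.treatment_times_h
            for t in times:
                for rep in range(1, design.n_reps + 1):
                    sid = f"{diet}_t{t:g}_{treatment}_r{rep}"
                    rows.append((sid, diet, t, treatment, rep))
    table = pd.DataFrame(rows, columns=["sample_id", "diet", "time_h", "treatment", "replicate"])
    return validate_sample_table(table)
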