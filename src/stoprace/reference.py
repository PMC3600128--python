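"""Reference predicted-value grid for stop-task outcomes.

Model-predicted SSRT, GoRT and GoRTSD (ms, with 95% confidence intervals) by
sex, age extreme (6 / 18 years) and ADHD-trait extreme (reversed SWAN -54 /
+54), from the large community study whose design this package emulates.
The grid serves two purposes: worked-example arithmetic on cell differences,
and calibration targets for the synthetic cohort's trait-to-race-parameter
maps.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["published_grid"]

# (response, sex, age, trait) -> (predicted, ci_low, ci_high), all ms.
_GRID = {
    ("ssrt", "female", 6, -54): (398, 385, 412),
    ("ssrt", "female", 18, -54): (177, 170, 183),
    ("ssrt", "male", 6, -54): (371, 359, 384),
    ("ssrt", "male", 18, -54): (177, 170, 185),
    ("ssrt", "female", 6, 54): (536, 516, 557),
    ("ssrt", "female", 18, 54): (238, 229, 247),
    ("ssrt", "male", 6, 54): (500, 483, 518),
    ("ssrt", "male", 18, 54): (239, 228, 249),
    ("gort", "female", 6, -54): (735, 723, 747),
    ("gort", "female", 18, -54): (521, 512, 530),
    ("gort", "male", 6, -54): (693, 682, 705),
    ("gort", "male", 18, -54): (528, 517, 539),
    ("gort", "female", 6, 54): (765, 752, 779),
    ("gort", "female", 18, 54): (542, 532, 552),
    ("gort", "male", 6, 54): (722, 710, 734),
    ("gort", "male", 18, 54): (549, 537, 561),
    ("gortsd", "female", 6, -54): (205, 200, 210),
    ("gortsd", "female", 18, -54): (118, 115, 121),
    ("gortsd", "male", 6, -54): (188, 183, 193),
    ("gortsd", "male", 18, -54): (119, 115, 122),
    ("gortsd", "female", 6, 54): (256, 249, 264),
    ("gortsd", "female", 18, 54): (147, 143, 152),
    ("gortsd", "male", 6, 54): (235, 229, 241),
    ("gortsd", "male", 18, 54): (148, 143, 153),
}


def published_grid(response: str | None = None) -> pd.DataFrame:
    """The reference grid as a tidy frame (optionally one response only)."""
    rows = [
        {
            "response": resp,
            "sex": sex,
            "age": age,
            "trait": trait,
            "predicted": pred,
            "ci_low": lo,
            "ci_high": hi,
        }
        for (resp, sex, age, trait), (pred, lo, hi) in _GRID.items()
    ]
    frame = pd.DataFrame(rows)
    if response is not None:
        frame = frame[frame["response"] == response].reset_index(drop=True)
    return frame
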