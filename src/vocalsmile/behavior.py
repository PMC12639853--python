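"""Behavioral layer of the main task: rating collapse, perceptual accuracy,
chance-level tests, and covariate correlations.

Each sentence carries an acoustic manipulation label, the Filter
(Smiling-F vs. Unsmiling-F), and the participant's 4-key rating, which is
collapsed post hoc to a binary Choice (Smile-C vs. Unsmile-C). Perceptual
accuracy is the proportion of filter-congruent choices:

    accuracy = (n_SmilingF&SmileC + n_UnsmilingF&UnsmileC)
               / (n_SmilingF + n_UnsmilingF)

Trials with a missing rating (no response inside the rating window) are
excluded from both the numerator and the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from . import stats as vstats

__all__ = [
    "SMILING_F",
    "UNSMILING_F",
    "SMILE_C",
    "UNSMILE_C",
    "BehavioralTrial",
    "BehavioralSummary",
    "collapse_rating",
    "perceptual_accuracy",
    "test_above_chance",
    "correlate",
]

SMILING_F = "Smiling-F"
UNSMILING_F = "Unsmiling-F"
SMILE_C = "Smile-C"
UNSMILE_C = "Unsmile-C"

# 4-key pad: two left keys = unsmile intensities, two right keys = smile
_KEY_TO_CHOICE = {1: UNSMILE_C, 2: UNSMILE_C, 3: SMILE_C, 4: SMILE_C}


@dataclass(frozen=True)
class BehavioralTrial:
    sentence_id: int
    filter: str
    rating: int | None

    @property
    def choice(self) -> str | None:
        return None if self.rating is None else collapse_rating(self.rating)

    @property
    def correct(self) -> bool | None:
        c = self.choice
        if c is None:
            return None
        return (self.filter == SMILING_F) == (c == SMILE_C)


@dataclass(frozen=True)
class BehavioralSummary:
    n_smileF_smileC: int
    n_unsmileF_unsmileC: int
    n_smileF: int
    n_unsmileF: int

    @property
    def accuracy(self) -> float:
        total = self.n_smileF + self.n_unsmileF
        if total == 0:
            raise ValueError("no rated trials")
        return (self.n_smileF_smileC + self.n_unsmileF_unsmileC) / total


def collapse_rating(rating: int) -> str:
    """Map a 4-key rating to the binary choice (keys 1-2 unsmile, 3-4 smile)."""
    try:
        return _KEY_TO_CHOICE[int(rating)]
    except (KeyError, TypeError, ValueError):
        raise ValueError(f"invalid rating key: {rating!r}") from None


def _to_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        df = trials.copy()
    else:
        trials = list(trials)
        if not trials:
            raise ValueError("no trials")
        df = pd.DataFrame(
            {
                "sentence_id": [t.sentence_id for t in trials],
                "filter": [t.filter for t in trials],
                "rating": [t.rating for t in trials],
            }
        )
    if df.empty:
        raise ValueError("no trials")
    return df


def perceptual_accuracy(trials: Iterable[BehavioralTrial] | pd.DataFrame) -> BehavioralSummary:
    """Count filter-congruent binary choices and form the accuracy summary."""
    df = _to_frame(trials)
    rated = df[df["rating"].notna()]
    if rated.empty:
        raise ValueError("no rated trials")
    choice = rated["rating"].map(collapse_rating)
    smile_f = rated["filter"] == SMILING_F
    unsmile_f = rated["filter"] == UNSMILING_F
    return BehavioralSummary(
        n_smileF_smileC=int((smile_f & (choice == SMILE_C)).sum()),
        n_unsmileF_unsmileC=int((unsmile_f & (choice == UNSMILE_C)).sum()),
        n_smileF=int(smile_f.sum()),
        n_unsmileF=int(unsmile_f.sum()),
    )


def test_above_chance(accuracies, chance: float = 0.5) -> vstats.TTestResult:
    """One-sample t of per-participant accuracies against chance (0.5)."""
    return vstats.one_sample_t(np.asarray(accuracies, dtype=float), chance)


def correlate(x, y) -> vstats.PearsonResult:
    """Pearson correlation reported with r, df, t, and p."""
    return vstats.pearson(x, y)
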