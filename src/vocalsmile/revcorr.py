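"""Reverse-correlation kernels (classification images) for vocal smile.

A participant's kernel is, per frequency band, the mean gain of trials
they classified as smiling minus the mean gain of trials classified as
unsmiling. Group kernels are per-band averages over participants; groups
are compared band-wise with independent-samples t-tests (no multiplicity
correction). The Kernel Distance summarizes how far an individual kernel
sits from the combined-group reference kernel: the mean over bands of the
per-band absolute difference (an RMS variant is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import stats as vstats
from .stimgen import FrequencyGrid, GainProfile

__all__ = [
    "Kernel",
    "BandComparison",
    "estimate_kernel",
    "group_kernel",
    "compare_bands",
    "kernel_distance",
]

SMILE = "smile"
UNSMILE = "unsmile"


@dataclass(frozen=True)
class Kernel:
    """Per-band classification-image values in dB."""

    grid: FrequencyGrid
    values: np.ndarray
    n_smile: int
    n_unsmile: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != self.grid.bands.shape:
            raise ValueError("kernel needs one value per band")


@dataclass(frozen=True)
class BandComparison:
    band_hz: float
    t: float
    df: int
    p: float
    significant: bool


def _gains_choices(trials) -> tuple[FrequencyGrid, np.ndarray, np.ndarray]:
    """Accept a (gains, choices, grid) session object or an iterable of
    (GainProfile, choice) pairs."""
    if hasattr(trials, "gains") and hasattr(trials, "choices"):
        return trials.grid, np.asarray(trials.gains, float), np.asarray(trials.choices)
    profiles, choices = [], []
    grid = None
    for profile, choice in trials:
        if not isinstance(profile, GainProfile):
            raise TypeError("expected (GainProfile, choice) pairs")
        if grid is None:
            grid = profile.grid
        elif profile.grid != grid:
            raise ValueError("mixed frequency grids in one session")
        profiles.append(profile.gains)
        choices.append(choice)
    if grid is None:
        raise ValueError("no trials")
    return grid, np.vstack(profiles), np.asarray(choices)


def estimate_kernel(trials) -> Kernel:
    """First-order classification image: mean gain of smile-chosen trials
    minus mean gain of unsmile-chosen trials, per band."""
    grid, gains, choices = _gains_choices(trials)
    smile_mask = choices == SMILE
    unsmile_mask = choices == UNSMILE
    n_s, n_u = int(smile_mask.sum()), int(unsmile_mask.sum())
    if n_s == 0 or n_u == 0:
        raise ValueError("kernel estimation needs trials of both choices")
    values = gains[smile_mask].mean(axis=0) - gains[unsmile_mask].mean(axis=0)
    return Kernel(grid, values, n_s, n_u)


def _check_same_grid(kernels: Sequence[Kernel]) -> FrequencyGrid:
    grid = kernels[0].grid
    for k in kernels[1:]:
        if k.grid != grid:
            raise ValueError("kernels on different frequency grids")
    return grid


def group_kernel(kernels: Sequence[Kernel]) -> Kernel:
    """Per-band arithmetic mean over individual kernels."""
    if not kernels:
        raise ValueError("no kernels")
    grid = _check_same_grid(kernels)
    values = np.vstack([k.values for k in kernels]).mean(axis=0)
    return Kernel(grid, values,
                  sum(k.n_smile for k in kernels),
                  sum(k.n_unsmile for k in kernels))


def compare_bands(group_a: Sequence[Kernel], group_b: Sequence[Kernel],
                  alpha: float = 0.05) -> list[BandComparison]:
    """Independent-samples t-test per band on individual kernel values.

    No multiple-comparison correction is applied across bands.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 kernels per group")
    grid = _check_same_grid(list(group_a) + list(group_b))
    a = np.vstack([k.values for k in group_a])
    b = np.vstack([k.values for k in group_b])
    out = []
    for j, f in enumerate(grid.bands):
        res = vstats.two_sample_t(a[:, j], b[:, j])
        out.append(BandComparison(float(f), res.t, res.df, res.p,
                                  res.p < alpha))
    return out


def kernel_distance(individual: Kernel, reference: Kernel,
                    method: str = "mean_abs") -> float:
    """Scalar dissimilarity between an individual kernel and the reference
    (combined-group) kernel: the mean over bands of the per-band absolute
    difference, or the RMS of differences with method='rms'."""
    if individual.grid != reference.grid:
        raise ValueError("kernels on different frequency grids")
    diff = individual.values - reference.values
    if method == "mean_abs":
        return float(np.mean(np.abs(diff)))
    if method == "rms":
        return float(np.sqrt(np.mean(diff**2)))
    raise ValueError(f"unknown method: {method!r}")


def kernels_to_frame(kernels: dict[str, Kernel]) -> pd.DataFrame:
    """Long table (participant_id, band_hz, value_db) for serialization."""
    rows = []
    for pid, k in kernels.items():
        for f, v in zip(k.grid.bands, k.values):
            rows.append({"participant_id": pid, "band_hz": f, "value_db": v})
    return pd.DataFrame(rows)
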