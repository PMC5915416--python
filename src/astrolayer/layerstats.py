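"""Cortical-depth binning and nuclear marker-intensity quantification.

Astrocyte position is expressed as relative distance from the corpus
callosum (0) to the pia (1) and assigned to four depth bins:

    bin1 [0.9, 1.0]   (layer I)
    bin2 [0.65, 0.9)  (≈ layers II/III)
    bin3 [0.25, 0.65) (≈ layers IV–V)
    bin4 [0, 0.25)    (≈ layer VI)

Nuclear-ROI median intensities of a marker (e.g. Lef1, Id1) are rescaled
per image to a 0–100 scale; per-bin positive-cell fractions are compared
across bins by one-way ANOVA with Bonferroni-corrected pairwise tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_BINS",
    "BinScheme",
    "assign_bin",
    "scale_intensities",
    "positivity_threshold",
    "positive_fraction",
]


@dataclass(frozen=True)
class BinScheme:
    """Ordered depth bins.  ``edges[i] <= bin_{i} < edges[i+1]`` scanned
    from the deepest bin upward; the listed order is bin1 (most
    superficial) first to match figure conventions."""

    names: tuple[str, ...]
    lower: tuple[float, ...]  # inclusive
    upper: tuple[float, ...]  # exclusive except the topmost bin

    def assign(self, relative_depth: float) -> str:
        if not 0.0 <= relative_depth <= 1.0:
            raise ValueError(f"relative depth {relative_depth} outside [0, 1]")
        for name, lo, hi in zip(self.names, self.lower, self.upper):
            if hi >= 1.0:  # topmost bin includes its upper boundary
                if lo <= relative_depth <= hi:
                    return name
            elif lo <= relative_depth < hi:
                return name
        raise ValueError(f"no bin covers depth {relative_depth}")


DEFAULT_BINS = BinScheme(
    names=("bin1", "bin2", "bin3", "bin4"),
    lower=(0.9, 0.65, 0.25, 0.0),
    upper=(1.0, 0.9, 0.65, 0.25),
)


def assign_bin(relative_depth: float, scheme: BinScheme = DEFAULT_BINS) -> str:
    """Depth bin of a cell; boundaries belong to the upper (more
    superficial) bin, and 1.0 belongs to bin1."""
    return scheme.assign(float(relative_depth))


def scale_intensities(raw, *, constant_value: float = 50.0) -> np.ndarray:
    """Min–max rescale one image group's raw medians to 0–100.

    A constant group cannot be rescaled; all its values map to
    ``constant_value`` with a warning.
    """
    x = np.asarray(raw, dtype=float)
    if len(x) < 2:
        raise ValueError("scaling requires >= 2 values per image")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        logger.warning("constant intensity group: mapping all values to %.0f", constant_value)
        return np.full_like(x, constant_value)
    return 100.0 * (x - lo) / (hi - lo)


def positivity_threshold(scaled, rule: str | float = "otsu") -> float:
    """Cutoff on the 0–100 scale above which a cell counts as positive.

    ``rule`` is either "otsu" (threshold of the scaled distribution) or
    a fixed numeric cutoff.
    """
    if isinstance(rule, (int, float)):
        return float(rule)
    if rule == "otsu":
        return float(threshold_otsu(np.asarray(scaled, dtype=float)))
    raise ValueError(f"unknown positivity rule {rule!r}")


def positive_fraction(
    cells: pd.DataFrame,
    threshold_rule: str | float = "otsu",
    bin_col: str = "bin",
    intensity_col: str = "scaled_intensity",
    animal_col: str = "animal",
    perivascular_col: str = "perivascular",
) -> dict:
    """Per-bin positive-cell fractions with an across-bin ANOVA.

    ``cells`` has one row per cell with at least a bin and a scaled
    intensity; perivascular-flagged cells are excluded.  Fractions are
    computed per animal (when an animal column is present) and per bin;
    the bin effect is tested by one-way ANOVA on per-animal fractions
    followed by Bonferroni-corrected pairwise Welch tests.  The applied
    positivity threshold is surfaced in the output.
    """
    df = cells.copy()
    if perivascular_col in df.columns:
        df = df[~df[perivascular_col].astype(bool)]
    if df.empty:
        raise ValueError("no cells left after exclusions")
    cutoff = positivity_threshold(df[intensity_col].to_numpy(), threshold_rule)
    df = df.assign(positive=df[intensity_col] > cutoff)
    group_cols = [bin_col] + ([animal_col] if animal_col in df.columns else [])
    per_animal = df.groupby(group_cols, observed=True)["positive"].mean().rename("fraction")
    per_bin = df.groupby(bin_col, observed=True)["positive"].mean().rename("fraction")

    anova_p = np.nan
    pairwise: dict[tuple[str, str], float] = {}
    if animal_col in df.columns:
        groups = {
            b: g.to_numpy() for b, g in per_animal.groupby(level=bin_col, observed=True)
        }
        usable = {b: v for b, v in groups.items() if len(v) >= 2}
        if len(usable) >= 2:
            if all(np.ptp(v) == 0 for v in usable.values()):
                # no within-group variability: degenerate ANOVA
                means = [v[0] for v in usable.values()]
                anova_p = 1.0 if np.ptp(means) == 0 else 0.0
            else:
                _, anova_p = stats.f_oneway(*usable.values())
            pairs = list(itertools.combinations(sorted(usable), 2))
            for b1, b2 in pairs:
                _, p = stats.ttest_ind(usable[b1], usable[b2], equal_var=False)
                pairwise[(b1, b2)] = min(1.0, float(p) * len(pairs))
    return {
        "threshold": cutoff,
        "threshold_rule": threshold_rule,
        "per_bin": per_bin,
        "per_animal": per_animal,
        "anova_p": float(anova_p),
        "pairwise_bonferroni": pairwise,
        "n_cells": int(len(df)),
    }
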