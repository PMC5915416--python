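"""Per-cell nuclear marker-intensity generator with planted bin effects.

Emulates marker immunostaining quantification (e.g. Lef1, Id1): each
depth bin has a planted positive-cell proportion and separate raw
intensity distributions for positive and negative nuclei.  Cells get a
relative depth drawn uniformly inside their bin, an animal assignment,
and a truth positivity flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..layerstats import DEFAULT_BINS, BinScheme
from ._seeds import child_rng

__all__ = ["BinEffect", "simulate_intensity_cells"]


@dataclass(frozen=True)
class BinEffect:
    """Planted intensity model for one bin."""

    positive_proportion: float
    positive_mean: float = 180.0
    negative_mean: float = 60.0
    sd: float = 20.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_proportion <= 1.0:
            raise ValueError(
                f"positive proportion must be in [0, 1], got {self.positive_proportion}"
            )


def simulate_intensity_cells(
    bin_effects: dict[str, BinEffect],
    n_per_bin: int = 100,
    seed: int = 0,
    n_animals: int = 3,
    scheme: BinScheme = DEFAULT_BINS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-cell intensity records and their truth table.

    Returns ``(cells, truth)``; ``cells`` has columns cell_id, animal,
    relative_depth, bin, raw_intensity, perivascular (always False
    here), and ``truth`` carries the planted positivity flags.
    """
    rng = child_rng(seed, "intensity")
    rows, truth_rows = [], []
    idx = 0
    for name, effect in bin_effects.items():
        i = scheme.names.index(name)
        lo, hi = scheme.lower[i], scheme.upper[i]
        for _ in range(n_per_bin):
            depth = float(rng.uniform(lo, hi))
            positive = bool(rng.random() < effect.positive_proportion)
            mean = effect.positive_mean if positive else effect.negative_mean
            raw = float(rng.normal(mean, effect.sd))
            rows.append(
                {
                    "cell_id": f"cell{idx:05d}",
                    "animal": f"animal{1 + idx % n_animals}",
                    "relative_depth": depth,
                    "bin": name,
                    "raw_intensity": raw,
                    "perivascular": False,
                }
            )
            truth_rows.append({"cell_id": f"cell{idx:05d}", "positive": positive})
            idx += 1
    cells = pd.DataFrame(rows).set_index("cell_id")
    truth = pd.DataFrame(truth_rows).set_index("cell_id")
    return cells, truth
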