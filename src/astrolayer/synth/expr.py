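"""Paired upper/deep expression generator with planted fold changes.

Counts are drawn log-normally around planted per-gene means with a
shared within-animal factor (which makes the paired design informative)
and rounded to integers; a subset of genes carries planted upper/deep
fold changes.  Gene lengths are assigned uniformly in a realistic bp
range so the RPKM conversion is exercised.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..expression import ExpressionMatrix
from ._seeds import child_rng

__all__ = ["simulate_expression"]


def simulate_expression(
    n_genes: int = 2000,
    n_pairs: int = 3,
    de_spec: dict[int, float] | None = None,
    seed: int = 0,
    noise_sd: float = 0.15,
    animal_sd: float = 0.1,
    base_log_mean: float = 4.5,
    base_log_sd: float = 1.5,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate a paired count matrix and its truth table.

    ``de_spec`` maps gene index → planted fold change (upper/deep,
    must be > 0); all other genes have fold change 1.  ``noise_sd`` and
    ``animal_sd`` are standard deviations on the natural-log scale for
    the residual and shared-pair components.  Returns
    ``(ExpressionMatrix, truth)`` where truth carries each gene's
    planted fold change and DE flag.
    """
    if n_pairs < 2:
        raise ValueError("need n_pairs >= 2")
    de_spec = dict(de_spec or {})
    for g, f in de_spec.items():
        if f <= 0:
            raise ValueError(f"fold change must be > 0, got {f} for gene {g}")
        if not 0 <= g < n_genes:
            raise ValueError(f"gene index {g} out of range")
    rng = child_rng(seed, "expression")

    genes = [f"gene{g:05d}" for g in range(n_genes)]
    log_mu = rng.normal(base_log_mean, base_log_sd, size=n_genes)
    log_fc = np.zeros(n_genes)
    for g, f in de_spec.items():
        log_fc[g] = np.log(f)
    lengths = pd.Series(
        rng.integers(500, 5001, size=n_genes).astype(float), index=genes, name="length_bp"
    )

    cols, data, design_rows = [], [], []
    for a in range(n_pairs):
        animal = f"animal{a + 1}"
        pair_eff = rng.normal(0.0, animal_sd, size=n_genes)
        for comp, shift in (("deep", 0.0), ("upper", 1.0)):
            eps = rng.normal(0.0, noise_sd, size=n_genes)
            counts = np.rint(np.exp(log_mu + pair_eff + shift * log_fc + eps))
            cols.append(f"{animal}_{comp}")
            data.append(np.maximum(counts, 0.0))
            design_rows.append((f"{animal}_{comp}", animal, comp))

    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    design = pd.DataFrame(
        design_rows, columns=["sample", "animal", "compartment"]
    ).set_index("sample")
    truth = pd.DataFrame(
        {
            "fold_change": np.exp(log_fc),
            "is_de": [g in de_spec for g in range(n_genes)],
        },
        index=genes,
    )
    return ExpressionMatrix(counts=counts, gene_lengths=lengths, design=design), truth
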