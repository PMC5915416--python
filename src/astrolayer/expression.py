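"""Paired upper-vs-deep astrocyte expression contrast.

Takes a gene × sample count matrix with gene lengths and a paired design
(each animal contributes one upper-layer and one deep-layer sample),
converts counts to RPKM (reads per kilobase per million mapped reads),
and reports per-gene fold changes with paired two-tailed t-test
p-values, plus sorted tables of upper- and deep-enriched genes.

The headline fold change is the mean over animals of the per-animal
RPKM ratios (upper/deep), not the ratio of mean RPKMs — the two differ
strongly for genes with variable expression, and the per-pair estimator
respects the paired design.  Both estimators are emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "rpkm",
    "paired_contrast",
    "enriched_tables",
]


@dataclass
class ExpressionMatrix:
    """Paired gene × sample counts.

    ``counts``: DataFrame genes × samples; ``gene_lengths``: bp per gene
    (aligned index); ``design``: DataFrame indexed by sample with
    columns ``animal`` and ``compartment`` ("upper" / "deep").
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any() or (self.gene_lengths <= 0).any():
            raise ValueError("every gene needs a positive length")
        d = self.design
        if not set(d.index) >= set(self.counts.columns):
            raise ValueError("design must cover all samples")
        per_animal = d.loc[list(self.counts.columns)].groupby("animal")["compartment"]
        for animal, comps in per_animal:
            if sorted(comps) != ["deep", "upper"]:
                raise ValueError(
                    f"animal {animal!r} must have exactly one upper and one deep sample"
                )

    @property
    def animals(self) -> list:
        return sorted(self.design.loc[list(self.counts.columns), "animal"].unique())

    def sample_of(self, animal, compartment: str) -> str:
        d = self.design.loc[list(self.counts.columns)]
        sel = d[(d["animal"] == animal) & (d["compartment"] == compartment)]
        return sel.index[0]


def rpkm(counts: pd.DataFrame, gene_lengths: pd.Series, library_sizes=None) -> pd.DataFrame:
    """RPKM = counts × 10⁹ / (library size × gene length in bp).

    ``library_sizes`` defaults to the column sums of ``counts``.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("gene lengths must be positive for all genes")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    library_sizes = pd.Series(library_sizes, index=counts.columns).astype(float)
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be > 0")
    return counts.div(library_sizes, axis=1).div(lengths, axis=0) * 1e9


def paired_contrast(
    matrix: ExpressionMatrix,
    library_sizes=None,
    ratio_mean: str = "arithmetic",
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-gene upper-vs-deep contrast on RPKM values.

    Returns a DataFrame with mean RPKM per compartment, both fold-change
    estimators (per-pair ratio mean as ``fold_change``, ratio of means
    as ``fold_change_of_means``), the number of usable pairs, the paired
    two-tailed t-test p on per-animal RPKM values, and a direction flag.
    Pairs whose deep-compartment RPKM is zero contribute no ratio; genes
    with fewer than 2 usable pairs are flagged (``fold_change`` NaN).
    """
    if ratio_mean not in ("arithmetic", "geometric"):
        raise ValueError("ratio_mean must be 'arithmetic' or 'geometric'")
    animals = matrix.animals
    if len(animals) < 2:
        raise ValueError("paired contrast requires >= 2 complete pairs")
    expr = rpkm(matrix.counts, matrix.gene_lengths, library_sizes)
    upper = expr[[matrix.sample_of(a, "upper") for a in animals]].to_numpy()
    deep = expr[[matrix.sample_of(a, "deep") for a in animals]].to_numpy()

    def _ratio_fc(num, den):
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        n_ok = np.sum(np.isfinite(r), axis=1)
        with warnings_suppressed():
            if ratio_mean == "arithmetic":
                f = np.nanmean(r, axis=1)
            else:
                f = np.exp(np.nanmean(np.log(r), axis=1))
        return np.where(n_ok >= 2, f, np.nan), n_ok

    fc, n_pairs = _ratio_fc(upper, deep)
    fc_deep, _ = _ratio_fc(deep, upper)

    mean_upper, mean_deep = upper.mean(axis=1), deep.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc_of_means = np.where(mean_deep > 0, mean_upper / mean_deep, np.nan)

    t, p = stats.ttest_rel(upper, deep, axis=1)
    out = pd.DataFrame(
        {
            "mean_rpkm_upper": mean_upper,
            "mean_rpkm_deep": mean_deep,
            "fold_change": fc,
            "fold_change_deep": fc_deep,
            "fold_change_of_means": fc_of_means,
            "n_pairs": n_pairs,
            "t": t,
            "p": p,
            "direction": np.where(mean_upper >= mean_deep, "upper", "deep"),
        },
        index=matrix.counts.index,
    )
    if fdr:
        from statsmodels.stats.multitest import multipletests

        ok = np.isfinite(out["p"])
        q = np.full(len(out), np.nan)
        if ok.any():
            q[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
        out["q_fdr"] = q
    return out


class warnings_suppressed:
    """Context silencing numpy's all-NaN slice warnings."""

    def __enter__(self):
        import warnings as _w

        self._cm = _w.catch_warnings()
        self._cm.__enter__()
        _w.simplefilter("ignore", RuntimeWarning)
        return self

    def __exit__(self, *exc):
        return self._cm.__exit__(*exc)


def enriched_tables(
    contrast: pd.DataFrame, p_cutoff: float = 0.05, fc_cutoff: float = 1.2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the contrast into upper- and deep-enriched gene tables.

    Upper-enriched: fold change (upper/deep) >= ``fc_cutoff`` and
    p < ``p_cutoff``; deep-enriched analogously on the inverted ratio.
    Both tables are sorted by their enrichment fold change, descending;
    a gene can appear in at most one table.
    """
    fc = contrast["fold_change"]
    sig = contrast["p"] < p_cutoff
    upper = contrast[sig & (fc >= fc_cutoff) & (contrast["direction"] == "upper")].copy()
    upper = upper.sort_values("fold_change", ascending=False)
    deep = contrast[
        sig & (contrast["fold_change_deep"] >= fc_cutoff) & (contrast["direction"] == "deep")
    ].copy()
    deep = deep.sort_values("fold_change_deep", ascending=False)
    return upper, deep
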