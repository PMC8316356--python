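"""Gene-level tissue atlas summaries.

Classifies tissues into four TP73/TP63 expression groups at a mean-TPM
threshold (default 2 TPM), computes the cross-gene Spearman rank
correlation over tissues, and provides the log2(TPM + 0.1) transform
used for scatter displays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "TissueSummary",
    "TissueGrouper",
    "group_tissues",
    "spearman",
    "plot_transform_tpm",
    "plot_atlas",
    "GROUP_LABELS",
]

GROUP_LABELS = ("p73High_p63High", "p73High", "p63High", "LowLow")


@dataclass
class TissueSummary:
    tissue: str
    mean_tpm: dict[str, float]
    group: str


def _classify(tp73: float, tp63: float, threshold: float) -> str:
    """Mean TPM >= threshold counts as High (closed upper category)."""
    hi73, hi63 = tp73 >= threshold, tp63 >= threshold
    if hi73 and hi63:
        return "p73High_p63High"
    if hi73:
        return "p73High"
    if hi63:
        return "p63High"
    return "LowLow"


class TissueGrouper(TransformerMixin, BaseEstimator):
    """Assign four-group expression labels to a tissue × gene TPM matrix.

    ``transform`` takes a DataFrame indexed by tissue with one column per
    gene (mean TPM) and returns it with an added ``group`` column.
    """

    def __init__(self, threshold_tpm: float = 2.0, genes=("TP73", "TP63")):
        self.threshold_tpm = threshold_tpm
        self.genes = genes

    def fit(self, X=None, y=None) -> "TissueGrouper":
        self.genes_ = tuple(self.genes)
        if len(self.genes_) != 2:
            raise ValueError("TissueGrouper expects exactly two genes")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "genes_"):
            self.fit()
        missing = [g for g in self.genes_ if g not in X.columns]
        if missing:
            raise ValueError(f"TPM matrix missing gene columns: {missing}")
        g73, g63 = self.genes_
        out = X.copy()
        out["group"] = [
            _classify(row[g73], row[g63], self.threshold_tpm)
            for _, row in X.iterrows()
        ]
        return out


def group_tissues(
    tpm_table: pd.DataFrame,
    annotation: Mapping[str, str],
    threshold_tpm: float = 2.0,
    genes=("TP73", "TP63"),
) -> list[TissueSummary]:
    """Per-tissue mean TPM and four-group classification.

    ``tpm_table`` is gene × sample (as read by
    :func:`junctiso.junction_io.read_tpm`); every sample column must be
    annotated with a tissue.  Grouping uses per-tissue means, so it is
    invariant to sample order and to duplicating samples.
    """
    for gene in genes:
        if gene not in tpm_table.index:
            raise ValueError(f"TPM table missing gene row {gene!r}")
    missing = sorted(set(map(str, tpm_table.columns)) - set(annotation))
    if missing:
        raise KeyError(f"samples missing from annotation: {missing}")
    sub = tpm_table.loc[list(genes)].T  # samples × genes
    sub.index = [annotation[str(s)] for s in sub.index]
    means = sub.groupby(level=0).mean()
    grouper = TissueGrouper(threshold_tpm=threshold_tpm, genes=genes).fit()
    labelled = grouper.transform(means)
    return [
        TissueSummary(
            tissue=str(t),
            mean_tpm={g: float(labelled.at[t, g]) for g in genes},
            group=str(labelled.at[t, "group"]),
        )
        for t in labelled.index
    ]


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with two-sided t-approximation p-value.

    Ties receive average ranks.  Returns (nan, nan) with a warning when
    either vector is constant (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined", stacklevel=2)
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def plot_transform_tpm(tpm):
    """log2(TPM + 0.1), the scatter-axis transform."""
    return np.log2(np.asarray(tpm, dtype=float) + 0.1)


_GROUP_COLORS = {
    "p73High_p63High": "#e6c229",
    "p73High": "#8a4f9e",
    "p63High": "#4f9e57",
    "LowLow": "#9b9b9b",
}


def plot_atlas(summaries: Sequence[TissueSummary], path, genes=("TP73", "TP63")):
    """Scatter of per-tissue log2(TPM + 0.1), colored by expression group."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gx, gy = genes
    fig, ax = plt.subplots(figsize=(6, 6))
    for s in summaries:
        ax.scatter(
            plot_transform_tpm(s.mean_tpm[gx]),
            plot_transform_tpm(s.mean_tpm[gy]),
            color=_GROUP_COLORS.get(s.group, "black"),
            s=30,
        )
        ax.annotate(s.tissue, (
            plot_transform_tpm(s.mean_tpm[gx]),
            plot_transform_tpm(s.mean_tpm[gy]),
        ), fontsize=6, alpha=0.7)
    thr = plot_transform_tpm(2.0)
    ax.axvline(thr, ls="--", lw=0.8, color="gray")
    ax.axhline(thr, ls="--", lw=0.8, color="gray")
    ax.set_xlabel(f"{gx} log2(mean TPM + 0.1)")
    ax.set_ylabel(f"{gy} log2(mean TPM + 0.1)")
    x = [s.mean_tpm[gx] for s in summaries]
    y = [s.mean_tpm[gy] for s in summaries]
    if len(summaries) >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
        r, p = spearman(x, y)
        ax.set_title(f"r_s = {r:.2f}, p = {p:.2g}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
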