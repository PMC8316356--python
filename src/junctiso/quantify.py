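"""Hierarchical competing-junction isoform quantification.

The core operation converts one sample's (depth-normalized) junction
counts into leaf isoform percentages by walking a cascade: at the root
level each competing junction takes a share of 100% proportional to its
count; each subsequent level splits its *parent* label's percentage in
proportion to its own competing counts.  Because each level is a ratio of
counts within one sample, the result is invariant to any overall scaling
of the counts — CPM normalization matters only for cross-sample displays.

NA semantics: if the root level has zero total count the whole terminus
is undefined (all leaves NA).  If a deeper level has zero total count
while its parent still carries mass, only that subtree is NA and the row
is flagged *partial* (its non-NA leaves no longer sum to 100).

The class :class:`CascadeQuantifier` presents the operation as a
scikit-learn transformer over a samples × junction-uid count matrix;
:func:`cascade_fractions` and friends are thin functional wrappers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .gene_models import CascadeSpec, GeneModel, resolve_model
from .junction_io import JunctionCounts

__all__ = [
    "FractionTable",
    "CascadeQuantifier",
    "cascade_fractions",
    "nterm_fractions",
    "cterm_fractions",
    "e8_variant_fractions",
    "quantify_samples",
    "aggregate_by_tissue",
]

NA = float("nan")


@dataclass
class FractionTable:
    """Long-format isoform percentages per sample or per tissue.

    ``data`` columns: unit_id, terminus, isoform, pct, partial, n_samples.
    ``pct`` is in [0, 100] or NaN; ``partial`` marks rows whose terminus
    had a zero denominator below the root (non-NA leaves < 100%);
    ``n_samples`` is 1 at sample level and the number of non-NA samples
    averaged at tissue level.
    """

    unit: str  # "sample" | "tissue"
    data: pd.DataFrame

    def pivot(self, terminus: str) -> pd.DataFrame:
        """Wide view (unit_id × isoform) for one terminus."""
        sub = self.data[self.data["terminus"] == terminus]
        return sub.pivot(index="unit_id", columns="isoform", values="pct")


def _cascade_percentages(
    counts: Mapping[str, float], cascade: CascadeSpec
) -> dict[str, float]:
    """Propagate count mass down the cascade; return label -> percentage."""
    pct: dict[str, float] = {"ALL": 100.0}
    for level in cascade.levels:
        parent_pct = pct[level.parent]
        branch = level.branch_map()
        total = sum(counts.get(uid, 0.0) for uid in branch)
        for uid, child in branch.items():
            if math.isnan(parent_pct):
                pct[child] = NA
            elif total == 0.0:
                # no reads to apportion: children undefined unless the
                # parent itself carries no mass
                pct[child] = 0.0 if parent_pct == 0.0 else NA
            else:
                pct[child] = parent_pct * counts.get(uid, 0.0) / total
    return {leaf: pct[leaf] for leaf in cascade.leaf_labels()}


def _as_counts_mapping(nj) -> Mapping[str, float]:
    if isinstance(nj, JunctionCounts):
        return nj.normalized
    if isinstance(nj, pd.Series):
        return nj.to_dict()
    return nj


def cascade_fractions(nj, cascade: CascadeSpec) -> dict[str, float]:
    """Leaf percentages for one sample under one cascade.

    ``nj`` maps junction uid to a (normalized) count, or is a
    :class:`JunctionCounts`.  Junctions absent from ``nj`` count as zero.
    """
    return _cascade_percentages(_as_counts_mapping(nj), cascade)


def nterm_fractions(nj, model: GeneModel) -> dict[str, float]:
    """N-terminal promoter-usage split (TA vs dN, plus I3a for TP73)."""
    return cascade_fractions(nj, model.cascade("N"))


def cterm_fractions(nj, model: GeneModel) -> dict[str, float]:
    """C-terminal splicing split (alpha/beta/... leaves)."""
    return cascade_fractions(nj, model.cascade("C"))


def e8_variant_fractions(nj, model: GeneModel) -> dict[str, float]:
    """Full-length E8 vs shortened-donor E8s split (TP63)."""
    return cascade_fractions(nj, model.cascade("E8variant"))


class CascadeQuantifier(TransformerMixin, BaseEstimator):
    """Transform a junction-count matrix into leaf isoform percentages.

    Parameters
    ----------
    model : GeneModel, "TP73", "TP63", or path to a model config
    terminus : which cascade to apply ("N", "C", or "E8variant")

    ``transform`` accepts a DataFrame whose columns are junction uids
    (extra columns are ignored; missing cascade junctions count as zero)
    and returns a DataFrame (same index) with one column per leaf label.
    NaN encodes an undefined percentage; a row with some but not all
    leaves NaN had a zero denominator below the cascade root.
    """

    def __init__(self, model="TP73", terminus: str = "C"):
        self.model = model
        self.terminus = terminus

    def fit(self, X=None, y=None) -> "CascadeQuantifier":
        model = resolve_model(self.model)
        cascade = model.cascade(self.terminus)
        known = {j.uid for j in model.junctions}
        for level in cascade.levels:
            for uid, _ in level.branches:
                if uid not in known:
                    raise ValueError(
                        f"{model.symbol} {self.terminus} cascade references "
                        f"junction {uid!r} absent from the model"
                    )
        self.model_ = model
        self.cascade_ = cascade
        self.leaves_ = list(cascade.leaf_labels())
        self.junction_uids_ = sorted(
            {uid for lv in cascade.levels for uid, _ in lv.branches}
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "cascade_"):
            self.fit()
        if isinstance(X, pd.Series):
            X = X.to_frame().T
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame of junction counts")
        if (X.reindex(columns=self.junction_uids_).fillna(0.0).to_numpy() < 0).any():
            raise ValueError("junction counts must be non-negative")
        rows = []
        for _, row in X.iterrows():
            rows.append(_cascade_percentages(row.to_dict(), self.cascade_))
        return pd.DataFrame(rows, index=X.index, columns=self.leaves_)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.leaves_, dtype=object)


def quantify_samples(
    counts: Sequence[JunctionCounts],
    model: GeneModel,
    termini: Optional[Sequence[str]] = None,
) -> FractionTable:
    """Per-sample leaf percentages for every cascade the model defines."""
    termini = list(termini) if termini else [c.terminus for c in model.cascades]
    records = []
    for jc in counts:
        nj = jc.normalized
        for terminus in termini:
            leaf_pct = cascade_fractions(nj, model.cascade(terminus))
            vals = list(leaf_pct.values())
            n_na = sum(math.isnan(v) for v in vals)
            partial = 0 < n_na < len(vals)
            for isoform, pct in leaf_pct.items():
                records.append(
                    {
                        "unit_id": jc.sample_id,
                        "terminus": terminus,
                        "isoform": isoform,
                        "pct": pct,
                        "partial": partial,
                        "n_samples": 1,
                    }
                )
    return FractionTable(unit="sample", data=pd.DataFrame(records))


def aggregate_by_tissue(
    per_sample: FractionTable, annotation: Mapping[str, str]
) -> FractionTable:
    """Mean leaf percentage per tissue, complete-case over samples.

    Samples with NA for a leaf are skipped for that leaf (``n_samples``
    reports how many contributed); a tissue is NA only when every sample
    is.  Every sample must appear in ``annotation``.
    """
    if per_sample.unit != "sample":
        raise ValueError("aggregate_by_tissue expects a sample-level table")
    df = per_sample.data.copy()
    missing = sorted(set(df["unit_id"]) - set(annotation))
    if missing:
        raise KeyError(f"samples missing from annotation: {missing}")
    df["tissue"] = df["unit_id"].map(annotation)
    records = []
    for (tissue, terminus, isoform), grp in df.groupby(
        ["tissue", "terminus", "isoform"], sort=True
    ):
        vals = grp["pct"].dropna()
        records.append(
            {
                "unit_id": tissue,
                "terminus": terminus,
                "isoform": isoform,
                "pct": vals.mean() if len(vals) else NA,
                "partial": bool(grp["partial"].any()),
                "n_samples": int(len(vals)),
            }
        )
    return FractionTable(unit="tissue", data=pd.DataFrame(records))
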