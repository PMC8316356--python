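"""Readers and writers for junction, exon, TPM and annotation tables.

Supported inputs:

- STAR ``SJ.out.tab`` files (9-column TSV; intron coordinates 1-based
  inclusive) — one sample per file.
- junction×sample count matrices (rows labelled ``chrom_start_end``) in
  the style of the GTEx junction quantifications.
- exon×sample raw-count TSVs, gene×sample TPM TSVs, and a two-column
  sample→tissue annotation TSV.

Junctions are matched to a :class:`~junctiso.gene_models.GeneModel` by
exact ``(chromosome, intron_start, intron_end)``; rows matching no model
junction are skipped (a count is logged).  Depth normalization is counts
per million: ``raw / total_aligned_reads * 1e6``.  Exon counts are
normalized per kilobase of exon per million aligned reads; the constant
factors cancel in every downstream ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .gene_models import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "JunctionCounts",
    "ExonCounts",
    "read_star_junctions",
    "read_junction_matrix",
    "read_exon_counts",
    "read_depths",
    "read_annotation",
    "read_tpm",
    "write_fraction_table",
    "read_fraction_table",
    "write_ratio_table",
    "junction_frame",
]

PathLike = Union[str, Path]


@dataclass
class JunctionCounts:
    """Raw and CPM-normalized junction-spanning read counts for one sample.

    ``raw`` maps junction uid (see :meth:`JunctionKey.uid`) to the number
    of uniquely-mapping reads spanning that junction; junctions absent
    from the mapping count as zero.
    """

    sample_id: str
    total_aligned_reads: int
    raw: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_aligned_reads <= 0:
            raise ValueError(
                f"sample {self.sample_id}: total_aligned_reads must be positive"
            )

    @property
    def normalized(self) -> dict[str, float]:
        """Counts per million aligned reads."""
        scale = 1e6 / self.total_aligned_reads
        return {uid: c * scale for uid, c in self.raw.items()}

    def get(self, uid: str) -> float:
        return self.raw.get(uid, 0.0)


@dataclass
class ExonCounts:
    """Raw and length/depth-normalized exon read counts for one sample.

    ``normalized[e] = raw[e] / (length_bp[e]/1000) / (total/1e6)`` —
    reads per kilobase of exon per million aligned reads.
    """

    sample_id: str
    total_aligned_reads: int
    raw: dict[str, float] = field(default_factory=dict)
    lengths_bp: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_aligned_reads <= 0:
            raise ValueError(
                f"sample {self.sample_id}: total_aligned_reads must be positive"
            )

    @property
    def normalized(self) -> dict[str, float]:
        out = {}
        depth_m = self.total_aligned_reads / 1e6
        for label, c in self.raw.items():
            kb = self.lengths_bp[label] / 1000.0
            out[label] = c / kb / depth_m
        return out


# ---------------------------------------------------------------------------
# readers


def read_star_junctions(
    path: PathLike,
    model: GeneModel,
    total_aligned_reads: int,
    sample_id: Optional[str] = None,
) -> JunctionCounts:
    """Read one STAR ``SJ.out.tab`` file into model junction counts.

    Columns: chrom, intron start, intron end (1-based inclusive), strand
    code, motif, annotated flag, unique-read count, multi-read count, max
    overhang.  Only uniquely-mapping reads (column 7) are used.  Rows
    whose intron coordinates match no model junction are ignored (their
    number is logged); model junctions absent from the file get count 0.
    """
    if total_aligned_reads <= 0:
        raise ValueError("total_aligned_reads must be positive")
    path = Path(path)
    by_coords = model.junction_by_coords()
    raw: dict[str, float] = {j.uid: 0.0 for j in model.junctions}
    unmatched = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                istart, iend = int(fields[1]), int(fields[2])
                unique = int(fields[6])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from exc
            key = by_coords.get((chrom, istart, iend))
            if key is None:
                unmatched += 1
                continue
            raw[key.uid] = float(unique)
    if unmatched:
        logger.info("%s: %d junction rows matched no model junction", path, unmatched)
    return JunctionCounts(
        sample_id=sample_id or path.stem.split(".")[0],
        total_aligned_reads=int(total_aligned_reads),
        raw=raw,
    )


def read_junction_matrix(
    path: PathLike, model: GeneModel, depths: Mapping[str, int]
) -> list[JunctionCounts]:
    """Read a junction×sample count matrix (rows ``chrom_start_end``)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [s for s in df.columns if s not in depths]
    if missing:
        raise ValueError(f"{path}: samples missing from depths: {missing}")
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate junction rows: {dupes}")
    by_coords = model.junction_by_coords()
    uid_rows: dict[str, str] = {}
    unmatched = 0
    for jid in df.index:
        try:
            chrom, istart, iend = str(jid).rsplit("_", 2)
            key = by_coords.get((chrom, int(istart), int(iend)))
        except ValueError:
            key = None
        if key is None:
            unmatched += 1
            continue
        uid_rows[key.uid] = jid
    if unmatched:
        logger.info("%s: %d matrix rows matched no model junction", path, unmatched)
    out = []
    for sample in df.columns:
        raw = {j.uid: 0.0 for j in model.junctions}
        for uid, jid in uid_rows.items():
            raw[uid] = float(df.at[jid, sample])
        out.append(
            JunctionCounts(
                sample_id=str(sample),
                total_aligned_reads=int(depths[sample]),
                raw=raw,
            )
        )
    return out


def read_exon_counts(
    path: PathLike, model: GeneModel, depths: Mapping[str, int]
) -> list[ExonCounts]:
    """Read an exon×sample raw-count TSV (rows = exon labels)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    known = {e.label for e in model.exons}
    unknown = [str(x) for x in df.index if str(x) not in known]
    if unknown:
        raise ValueError(f"{path}: unknown exon labels: {unknown}")
    missing = [s for s in df.columns if s not in depths]
    if missing:
        raise ValueError(f"{path}: samples missing from depths: {missing}")
    lengths = {e.label: e.length_bp for e in model.exons}
    out = []
    for sample in df.columns:
        raw = {str(label): float(df.at[label, sample]) for label in df.index}
        out.append(
            ExonCounts(
                sample_id=str(sample),
                total_aligned_reads=int(depths[sample]),
                raw=raw,
                lengths_bp=lengths,
            )
        )
    return out


def read_depths(path: PathLike) -> dict[str, int]:
    """Two-column TSV: sample_id, total_aligned_reads."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip() for c in df.columns]
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int)))


def read_annotation(path: PathLike) -> dict[str, str]:
    """Two-column TSV: sample_id, tissue."""
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_tpm(path: PathLike) -> pd.DataFrame:
    """Gene×sample TPM TSV; returns a DataFrame indexed by gene symbol."""
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# writers


def write_fraction_table(fractions, path: PathLike) -> None:
    """Write isoform percentages as long-format TSV.

    Columns: unit_id, terminus, isoform, pct (2 decimals, NA for missing),
    partial, n_samples.  Rows sorted (unit_id, terminus, isoform).
    Accepts a :class:`~junctiso.quantify.FractionTable` or its DataFrame.
    """
    df = getattr(fractions, "data", fractions).copy()
    df = df.sort_values(["unit_id", "terminus", "isoform"], kind="mergesort")
    df["pct"] = df["pct"].round(2)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_fraction_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df["unit_id"] = df["unit_id"].astype(str)
    return df


def write_ratio_table(ratios: Sequence, path: PathLike) -> None:
    """Write 5'-junction depletion ratios as TSV.

    Columns: unit_id, gene, numerator, denominator, ratio_pct, excluded,
    reason, flag.  ``ratios`` is a sequence of RatioResult.
    """
    rows = []
    for r in ratios:
        rows.append(
            {
                "unit_id": r.unit_id,
                "gene": r.gene,
                "numerator": round(r.numerator, 6),
                "denominator": round(r.denominator, 6),
                "ratio_pct": (
                    float("nan") if r.ratio_pct is None or math.isnan(r.ratio_pct)
                    else round(r.ratio_pct, 2)
                ),
                "excluded": r.excluded,
                "reason": r.reason or "",
                "flag": getattr(r, "flag", "") or "",
            }
        )
    df = pd.DataFrame(rows).sort_values(["unit_id", "gene"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# conversion helpers


def junction_frame(
    counts: Sequence[JunctionCounts], model: GeneModel, normalized: bool = True
) -> pd.DataFrame:
    """Stack per-sample counts into a samples × junction-uid DataFrame."""
    uids = [j.uid for j in model.junctions]
    rows = []
    for jc in counts:
        source = jc.normalized if normalized else jc.raw
        rows.append([source.get(uid, 0.0) for uid in uids])
    return pd.DataFrame(rows, index=[jc.sample_id for jc in counts], columns=uids)
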