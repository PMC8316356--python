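"""Synthetic junction/exon count generator with a built-in analytic oracle.

Emulates the statistical structure the quantification assumes: a known
mixture of full-length transcripts, Poisson (optionally negative
binomial) counting noise at a chosen junction-read depth, a tunable
single-exponential 3' coverage bias in transcript coordinates (the
shape of poly-A-capture depletion toward 5' ends, steepened by RNA
degradation), and optional internally-initiated transcripts such as the
putative E4-proximal TP73 product.

Two oracle routes are exposed for testing the quantifier against ground
truth:

- :func:`expected_junction_intensity` — noise-free expected counts per
  junction (transcript-path bookkeeping with bias weights), scaled to
  the configured depth.
- :func:`truth_fractions` — the leaf percentages each cascade *should*
  report, obtained by walking every transcript down the cascade levels
  (pure per-transcript bookkeeping, no count arithmetic shared with the
  quantifier).

What the generator does not emulate: fragment-length effects, GC bias,
mappability, multi-mapping at paralogous loci, and library-specific
junction-overhang filters.  Passing recovery tests therefore show
correctness of the count-to-fraction algebra under the stated noise
model, not robustness to every artifact of real libraries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .gene_models import GeneModel, JunctionKey, resolve_model
from .junction_io import ExonCounts, JunctionCounts

__all__ = [
    "SimulationConfig",
    "SyntheticSample",
    "expected_junction_intensity",
    "expected_exon_intensity",
    "truth_fractions",
    "simulate",
    "write_simulation",
]

NA = float("nan")


@dataclass
class SimulationConfig:
    """Ground-truth description of one simulated condition.

    Parameters
    ----------
    model : GeneModel, "TP73", "TP63", or config path
    mixture : full-transcript name -> weight (sums to 1).  Names are
        either hyphenated N/C combinations ("dN-alpha") or complete
        transcripts ("I3a", "E4p73").
    depth : expected total junction-spanning reads for the gene.
    bias_decay_bp : 3'-bias length scale; junction weight is
        exp(-d / bias_decay_bp) with d the transcript-coordinate distance
        to the 3' end.  None (or inf) disables bias.
    e8s_share : for genes with a shortened-donor E8 variant, the fraction
        of E8->E9 mass routed through E8s (default 0.30, the split
        observed across tissues); ignored where no variant exists.
    nb_dispersion : if set, counts are negative binomial with this
        dispersion (variance = mu + dispersion * mu^2) instead of Poisson.
    total_aligned_reads : library size used for CPM bookkeeping.
    tpm : optional gene TPM emitted alongside the counts.
    """

    model: Union[GeneModel, str] = "TP73"
    mixture: dict[str, float] = field(default_factory=lambda: {"dN-alpha": 1.0})
    depth: float = 1e5
    bias_decay_bp: Optional[float] = None
    n_samples: int = 1
    seed: int = 0
    total_aligned_reads: int = 50_000_000
    tpm: Optional[float] = None
    e8s_share: float = 0.30
    nb_dispersion: Optional[float] = None

    def resolved_model(self) -> GeneModel:
        return resolve_model(self.model)

    def validate(self) -> GeneModel:
        model = self.resolved_model()
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.total_aligned_reads <= 0:
            raise ValueError("total_aligned_reads must be positive")
        if not 0.0 <= self.e8s_share <= 1.0:
            raise ValueError("e8s_share must lie in [0, 1]")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights sum to {total}, expected 1")
        if any(w < 0 for w in self.mixture.values()):
            raise ValueError("mixture weights must be non-negative")
        for name in self.mixture:
            model.transcript_path(name)  # raises KeyError for unknown names
        return model


@dataclass
class SyntheticSample:
    """One simulated sample plus the ground truth that generated it."""

    junction_counts: JunctionCounts
    exon_counts: ExonCounts
    truth: dict[str, dict[str, float]]  # terminus -> leaf -> expected pct
    mixture: dict[str, float]


# ---------------------------------------------------------------------------
# transcript expansion and expected intensities


def _expanded_transcripts(
    cfg: SimulationConfig, model: GeneModel
) -> list[tuple[str, bool, float]]:
    """(name, uses_e8s, weight) triples; E8-variant split applied."""
    trim = model.e8s_trim_bp()
    out = []
    for name, w in cfg.mixture.items():
        if w == 0:
            continue
        path = model.transcript_path(name)
        crosses_e8 = trim > 0 and any(
            (d, a) == ("E8", "E9") for d, a in zip(path, path[1:])
        )
        if crosses_e8 and cfg.e8s_share > 0:
            if cfg.e8s_share < 1:
                out.append((name, False, w * (1 - cfg.e8s_share)))
            out.append((name, True, w * cfg.e8s_share))
        else:
            out.append((name, False, w))
    return out


def _junction_distances(
    model: GeneModel, name: str, e8s: bool
) -> list[tuple[JunctionKey, float]]:
    """Each junction on the transcript with its distance to the 3' end."""
    path = model.transcript_path(name)
    lengths = [model.effective_exon_length(lab, e8s=e8s) for lab in path]
    juncs = model.transcript_junctions(name, e8s=e8s)
    out = []
    tail = float(sum(lengths))
    for i, j in enumerate(juncs):
        tail -= lengths[i]
        out.append((j, tail))  # bases downstream of the junction
    return out


def _bias_weight(distance: float, decay: Optional[float]) -> float:
    if decay is None or math.isinf(decay):
        return 1.0
    return math.exp(-distance / decay)


def expected_junction_intensity(cfg: SimulationConfig) -> dict[str, float]:
    """Expected raw junction counts, scaled to sum to ``cfg.depth``.

    Each transcript of weight w contributes w * bias_weight(d_j) to every
    junction j on its path, d_j being the transcript-coordinate distance
    from j to the 3' end; the total over all junctions is then rescaled
    to the configured depth.
    """
    model = cfg.validate()
    raw: dict[str, float] = {j.uid: 0.0 for j in model.junctions}
    for name, e8s, w in _expanded_transcripts(cfg, model):
        for j, dist in _junction_distances(model, name, e8s):
            raw[j.uid] += w * _bias_weight(dist, cfg.bias_decay_bp)
    total = sum(raw.values())
    if total == 0:
        return raw
    scale = cfg.depth / total
    return {uid: v * scale for uid, v in raw.items()}


def expected_exon_intensity(cfg: SimulationConfig) -> dict[str, float]:
    """Expected raw exon counts (per-base coverage aggregated per exon).

    Without bias each exon's weight is its (effective) length, so the
    per-kilobase-normalized profile is flat; with bias the per-base
    exponential is integrated analytically over the exon's transcript
    interval.  Scaled to sum to ``cfg.depth``.
    """
    model = cfg.validate()
    raw: dict[str, float] = {e.label: 0.0 for e in model.exons}
    decay = cfg.bias_decay_bp
    for name, e8s, w in _expanded_transcripts(cfg, model):
        path = model.transcript_path(name)
        lengths = [model.effective_exon_length(lab, e8s=e8s) for lab in path]
        tail = float(sum(lengths))
        for lab, length in zip(path, lengths):
            b = tail  # distance of the exon's 5'-most base to the 3' end
            a = tail - length
            if decay is None or math.isinf(decay):
                weight = float(length)
            else:
                weight = decay * (math.exp(-a / decay) - math.exp(-b / decay))
            raw[lab] += w * weight
            tail = a
    total = sum(raw.values())
    if total == 0:
        return raw
    scale = cfg.depth / total
    return {lab: v * scale for lab, v in raw.items()}


# ---------------------------------------------------------------------------
# ground-truth fractions (independent per-transcript bookkeeping)


def truth_fractions(cfg: SimulationConfig) -> dict[str, dict[str, float]]:
    """Leaf percentages implied by the mixture, per cascade terminus.

    Each transcript is walked down the cascade: starting at the root it
    takes whichever branch junction its junction path contains, level by
    level, until it lands on a leaf or fails to match (transcripts
    lacking the root junctions — e.g. E4p73 at the N terminus — carry no
    information for that terminus and are excluded from its
    normalization).  All leaves are NA when no transcript reaches the
    cascade at all.
    """
    model = cfg.validate()
    transcripts = [
        (frozenset(j.uid for j in model.transcript_junctions(n, e8s=e)), w)
        for n, e, w in _expanded_transcripts(cfg, model)
    ]
    out: dict[str, dict[str, float]] = {}
    for cascade in model.cascades:
        leaf_mass = {leaf: 0.0 for leaf in cascade.leaf_labels()}
        for junc_set, w in transcripts:
            label = "ALL"
            for level in cascade.levels:
                if label != level.parent:
                    continue
                matches = [child for uid, child in level.branches if uid in junc_set]
                if len(matches) != 1:
                    label = None
                    break
                label = matches[0]
            if label in leaf_mass:
                leaf_mass[label] += w
        total = sum(leaf_mass.values())
        if total == 0:
            out[cascade.terminus] = {leaf: NA for leaf in leaf_mass}
        else:
            out[cascade.terminus] = {
                leaf: 100.0 * m / total for leaf, m in leaf_mass.items()
            }
    return out


# ---------------------------------------------------------------------------
# sampling


def simulate(cfg: SimulationConfig) -> list[SyntheticSample]:
    """Draw ``cfg.n_samples`` noisy samples from the configured condition.

    Junction and exon raw counts are independent Poisson draws around the
    expected intensities (negative binomial when ``nb_dispersion`` is
    set).  Fully reproducible from ``cfg.seed``.
    """
    model = cfg.validate()
    j_int = expected_junction_intensity(cfg)
    e_int = expected_exon_intensity(cfg)
    truth = truth_fractions(cfg)
    lengths = {e.label: e.length_bp for e in model.exons}
    j_uids = list(j_int)
    e_labels = list(e_int)
    j_mu = np.array([j_int[u] for u in j_uids])
    e_mu = np.array([e_int[lab] for lab in e_labels])
    rng = np.random.default_rng(cfg.seed)

    def draw(mu: np.ndarray) -> np.ndarray:
        if cfg.nb_dispersion:
            shape = 1.0 / cfg.nb_dispersion
            lam = rng.gamma(shape, 1.0, size=mu.shape) / shape * mu
            return rng.poisson(lam)
        return rng.poisson(mu)

    samples = []
    for i in range(cfg.n_samples):
        sid = f"{model.symbol.lower()}_sim{i:04d}"
        j_raw = draw(j_mu)
        e_raw = draw(e_mu)
        samples.append(
            SyntheticSample(
                junction_counts=JunctionCounts(
                    sample_id=sid,
                    total_aligned_reads=cfg.total_aligned_reads,
                    raw={u: float(c) for u, c in zip(j_uids, j_raw)},
                ),
                exon_counts=ExonCounts(
                    sample_id=sid,
                    total_aligned_reads=cfg.total_aligned_reads,
                    raw={lab: float(c) for lab, c in zip(e_labels, e_raw)},
                    lengths_bp=lengths,
                ),
                truth=truth,
                mixture=dict(cfg.mixture),
            )
        )
    return samples


def write_simulation(
    samples: Sequence[SyntheticSample],
    model: Union[GeneModel, str],
    outdir: Union[str, Path],
    tissue: str = "synthetic",
    tpm: Optional[float] = None,
) -> None:
    """Write a simulated cohort in the formats the readers consume.

    Emits one STAR-style ``<sample>.sj.tab`` per sample, plus
    ``exon_counts.tsv``, ``depths.tsv``, ``annotation.tsv``,
    ``truth.tsv`` and (when ``tpm`` is given) ``tpm.tsv``.
    """
    model = resolve_model(model)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    strand_code = 1 if model.strand == "+" else 2
    for s in samples:
        jc = s.junction_counts
        lines = []
        for j in model.junctions:
            lines.append(
                "\t".join(
                    map(
                        str,
                        [
                            model.chromosome,
                            j.intron_start,
                            j.intron_end,
                            strand_code,
                            0,
                            1,
                            int(jc.raw.get(j.uid, 0)),
                            0,
                            50,
                        ],
                    )
                )
            )
        (outdir / f"{jc.sample_id}.sj.tab").write_text("\n".join(lines) + "\n")

    exon_df = pd.DataFrame(
        {s.exon_counts.sample_id: s.exon_counts.raw for s in samples}
    )
    exon_df.index.name = "exon"
    exon_df.to_csv(outdir / "exon_counts.tsv", sep="\t")

    depths = pd.DataFrame(
        {
            "sample_id": [s.junction_counts.sample_id for s in samples],
            "total_aligned_reads": [
                s.junction_counts.total_aligned_reads for s in samples
            ],
        }
    )
    depths.to_csv(outdir / "depths.tsv", sep="\t", index=False)

    annot = pd.DataFrame(
        {
            "sample_id": [s.junction_counts.sample_id for s in samples],
            "tissue": tissue,
        }
    )
    annot.to_csv(outdir / "annotation.tsv", sep="\t", index=False)

    truth_rows = []
    for s in samples:
        for terminus, leaves in s.truth.items():
            for leaf, pct in leaves.items():
                truth_rows.append(
                    {
                        "sample_id": s.junction_counts.sample_id,
                        "terminus": terminus,
                        "isoform": leaf,
                        "expected_pct": round(pct, 6) if not math.isnan(pct) else pct,
                    }
                )
    pd.DataFrame(truth_rows).to_csv(
        outdir / "truth.tsv", sep="\t", index=False, na_rep="NA"
    )

    if tpm is not None:
        tpm_df = pd.DataFrame(
            {s.junction_counts.sample_id: [tpm] for s in samples},
            index=[model.symbol],
        )
        tpm_df.index.name = "gene"
        tpm_df.to_csv(outdir / "tpm.tsv", sep="\t")
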