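"""Declarative gene models for junction-based isoform quantification.

A :class:`GeneModel` describes one gene as a set of exons, the splice
junctions connecting them, the terminal isoform segments those junctions
evidence, and one or more *cascades*: ordered levels of competing junctions
whose relative read share, multiplied down the hierarchy, yields leaf
isoform percentages.  The two shipped models encode the TP73 and TP63
loci (p53-family transcription factors with alternative promoters P1-TA
and P2-dN and extensive C-terminal alternative splicing), but the
quantification machinery is generic over any model expressible in this
vocabulary.

Coordinates are 1-based inclusive.  The shipped models use schematic
genomic coordinates with realistic exon lengths: every downstream
computation depends only on junction identity (which exons a read
connects) and on exon length, never on absolute genomic position, so the
models remain valid without transcribing annotation-exact boundaries.
The alternative first exon written E3' in the literature is spelled
``E3p`` in machine-readable labels (ASCII-safe keys).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml

__all__ = [
    "ExonDef",
    "JunctionKey",
    "IsoformDef",
    "CascadeLevel",
    "CascadeSpec",
    "GeneModel",
    "build_tp73_model",
    "build_tp63_model",
    "validate_model",
    "resolve_model",
]

#: parent label of the root cascade level (subdivides all junction mass)
ROOT = "ALL"


@dataclass(frozen=True)
class ExonDef:
    """One exon: label plus 1-based inclusive genomic boundaries."""

    label: str
    start: int
    end: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class JunctionKey:
    """One splice junction, identified by its donor/acceptor exons.

    ``variant`` distinguishes alternate donor or acceptor sites within the
    same exon pair (e.g. the shortened TP63 exon-8 donor ``E8s``).
    ``intron_start``/``intron_end`` are the first and last intronic bases,
    1-based inclusive — the convention STAR's SJ.out.tab uses.
    """

    donor_exon: str
    acceptor_exon: str
    intron_start: int
    intron_end: int
    variant: Optional[str] = None

    @property
    def uid(self) -> str:
        """Stable string id, e.g. ``"E10-E11"`` or ``"E8-E9:E8s"``."""
        base = f"{self.donor_exon}-{self.acceptor_exon}"
        return f"{base}:{self.variant}" if self.variant else base


@dataclass(frozen=True)
class IsoformDef:
    """A terminal isoform segment (or a complete transcript).

    ``kind`` says how the segment composes into full transcripts:

    - ``"n_prefix"``  — N-terminal choice; ``exon_path`` ends at the first
      shared body exon's predecessor (E4).
    - ``"c_suffix"``  — C-terminal choice; ``exon_path`` starts with the
      exon spliced onto E10.
    - ``"complete"``  — a self-contained transcript (e.g. the
      testis-specific I3a product, or the putative E4-initiated E4p73).
    """

    name: str
    exon_path: tuple[str, ...]
    kind: str = "complete"


@dataclass(frozen=True)
class CascadeLevel:
    """One level of competing junctions subdividing ``parent``'s mass."""

    parent: str
    branches: tuple[tuple[str, str], ...]  # (junction uid, child label)

    def branch_map(self) -> dict[str, str]:
        return dict(self.branches)


@dataclass(frozen=True)
class CascadeSpec:
    """Hierarchical competing-junction specification for one terminus."""

    terminus: str  # "N" | "C" | "E8variant"
    levels: tuple[CascadeLevel, ...]

    def parents(self) -> set[str]:
        return {lv.parent for lv in self.levels}

    def leaf_labels(self) -> tuple[str, ...]:
        """Child labels never subdivided by a later level, in order."""
        parents = self.parents()
        leaves = []
        for lv in self.levels:
            for _, child in lv.branches:
                if child not in parents:
                    leaves.append(child)
        return tuple(leaves)


@dataclass
class GeneModel:
    """Exon/junction/isoform architecture of one gene."""

    symbol: str
    strand: str
    chromosome: str
    exons: list[ExonDef]
    junctions: list[JunctionKey]
    isoforms: list[IsoformDef]
    cascades: list[CascadeSpec]
    five_prime_junctions: list[str]  # junction uids (ratio numerator)
    body_junctions: list[str]  # junction uids (ratio denominator)
    shared_body_exons: list[str] = field(default_factory=list)

    # -- lookups ---------------------------------------------------------

    def exon(self, label: str) -> ExonDef:
        for e in self.exons:
            if e.label == label:
                return e
        raise KeyError(f"{self.symbol}: unknown exon {label!r}")

    def junction(self, uid: str) -> JunctionKey:
        for j in self.junctions:
            if j.uid == uid:
                return j
        raise KeyError(f"{self.symbol}: unknown junction {uid!r}")

    def junction_for(
        self, donor: str, acceptor: str, variant: Optional[str] = None
    ) -> JunctionKey:
        for j in self.junctions:
            if (j.donor_exon, j.acceptor_exon, j.variant) == (donor, acceptor, variant):
                return j
        tag = f"{donor}-{acceptor}" + (f":{variant}" if variant else "")
        raise KeyError(f"{self.symbol}: no junction {tag}")

    def junction_by_coords(self) -> dict[tuple[str, int, int], JunctionKey]:
        return {
            (self.chromosome, j.intron_start, j.intron_end): j for j in self.junctions
        }

    def cascade(self, terminus: str) -> CascadeSpec:
        for c in self.cascades:
            if c.terminus == terminus:
                return c
        raise KeyError(f"{self.symbol}: no {terminus!r} cascade")

    def has_cascade(self, terminus: str) -> bool:
        return any(c.terminus == terminus for c in self.cascades)

    def isoform(self, name: str) -> IsoformDef:
        for iso in self.isoforms:
            if iso.name == name:
                return iso
        raise KeyError(f"{self.symbol}: unknown isoform {name!r}")

    # -- transcript composition ------------------------------------------

    def transcript_path(self, name: str) -> tuple[str, ...]:
        """Resolve a full-transcript name to its ordered exon labels.

        ``name`` is either a complete isoform (``"I3a"``, ``"E4p73"``) or a
        hyphenated N/C combination such as ``"dN-alpha"``.
        """
        by_name = {iso.name: iso for iso in self.isoforms}
        if name in by_name and by_name[name].kind == "complete":
            return by_name[name].exon_path
        if "-" not in name:
            raise KeyError(f"{self.symbol}: cannot resolve isoform name {name!r}")
        n_name, c_name = name.split("-", 1)
        try:
            prefix = by_name[n_name]
            suffix = by_name[c_name]
        except KeyError as exc:
            raise KeyError(f"{self.symbol}: cannot resolve isoform name {name!r}") from exc
        if prefix.kind != "n_prefix" or suffix.kind != "c_suffix":
            raise KeyError(f"{self.symbol}: {name!r} is not an N-C combination")
        return prefix.exon_path + tuple(self.shared_body_exons) + suffix.exon_path

    def transcript_junctions(self, name: str, e8s: bool = False) -> tuple[JunctionKey, ...]:
        """Junction path implied by a transcript name.

        With ``e8s=True`` the shortened-donor E8s variant is used where the
        model defines one for the E8->E9 step.
        """
        path = self.transcript_path(name)
        out = []
        for donor, acceptor in zip(path, path[1:]):
            key = None
            if e8s:
                try:
                    key = self.junction_for(donor, acceptor, "E8s")
                except KeyError:
                    key = None
            if key is None:
                key = self.junction_for(donor, acceptor, None)
            out.append(key)
        return tuple(out)

    def e8s_trim_bp(self) -> int:
        """Bases removed from the donor exon by the E8s shortened donor (0 if absent)."""
        for j in self.junctions:
            if j.variant == "E8s":
                full = self.junction_for(j.donor_exon, j.acceptor_exon, None)
                return full.intron_start - j.intron_start
        return 0

    def effective_exon_length(self, label: str, e8s: bool = False) -> int:
        length = self.exon(label).length_bp
        if e8s:
            for j in self.junctions:
                if j.variant == "E8s" and j.donor_exon == label:
                    length -= self.e8s_trim_bp()
        return length

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "symbol": self.symbol,
            "strand": self.strand,
            "chromosome": self.chromosome,
            "exons": [
                {"label": e.label, "start": e.start, "end": e.end} for e in self.exons
            ],
            "junctions": [
                {
                    "donor_exon": j.donor_exon,
                    "acceptor_exon": j.acceptor_exon,
                    "intron_start": j.intron_start,
                    "intron_end": j.intron_end,
                    "variant": j.variant,
                }
                for j in self.junctions
            ],
            "isoforms": [
                {"name": i.name, "exon_path": list(i.exon_path), "kind": i.kind}
                for i in self.isoforms
            ],
            "cascades": [
                {
                    "terminus": c.terminus,
                    "levels": [
                        {"parent": lv.parent, "branches": [list(b) for b in lv.branches]}
                        for lv in c.levels
                    ],
                }
                for c in self.cascades
            ],
            "five_prime_junctions": list(self.five_prime_junctions),
            "body_junctions": list(self.body_junctions),
            "shared_body_exons": list(self.shared_body_exons),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneModel":
        return cls(
            symbol=d["symbol"],
            strand=d["strand"],
            chromosome=d["chromosome"],
            exons=[ExonDef(**e) for e in d["exons"]],
            junctions=[JunctionKey(**j) for j in d["junctions"]],
            isoforms=[
                IsoformDef(i["name"], tuple(i["exon_path"]), i.get("kind", "complete"))
                for i in d["isoforms"]
            ],
            cascades=[
                CascadeSpec(
                    c["terminus"],
                    tuple(
                        CascadeLevel(
                            lv["parent"], tuple(tuple(b) for b in lv["branches"])
                        )
                        for lv in c["levels"]
                    ),
                )
                for c in d["cascades"]
            ],
            five_prime_junctions=list(d["five_prime_junctions"]),
            body_junctions=list(d["body_junctions"]),
            shared_body_exons=list(d.get("shared_body_exons", [])),
        )

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "GeneModel":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# model construction helpers


def _layout_exons(
    labels_lengths: Sequence[tuple[str, int]], first_start: int, intron_gap: int = 2000
) -> list[ExonDef]:
    """Lay exons along the chromosome in order with fixed intron gaps."""
    exons = []
    pos = first_start
    for label, length in labels_lengths:
        exons.append(ExonDef(label, pos, pos + length - 1))
        pos += length + intron_gap
    return exons


def _junction(exmap: Mapping[str, ExonDef], donor: str, acceptor: str,
              variant: Optional[str] = None, donor_trim: int = 0) -> JunctionKey:
    d, a = exmap[donor], exmap[acceptor]
    return JunctionKey(
        donor_exon=donor,
        acceptor_exon=acceptor,
        intron_start=d.end + 1 - donor_trim,
        intron_end=a.start - 1,
        variant=variant,
    )


def build_tp73_model() -> GeneModel:
    """TP73 (chromosome 1, plus strand).

    N-terminal choices: TA (P1 promoter, E3-E4 junction), dN (P2 promoter,
    E3'-E4), and the testis-specific I3a product (E3a-E4; an mRNA of only
    E3a and E4, lacking the shared body exons E5-E10).  C-terminal
    splicing from E10: alpha+beta (E10-E11, split at E12 into alpha
    E12-E13 vs beta E12-E14), gamma+epsilon quantified in tandem
    (E10-E12; their exon structures are not distinguishable from junction
    data alone), zeta (E10-E13), delta (E10-E14).  The putative
    E4-initiated transcript E4p73 (exons 4-14, alpha-spliced) is included
    for simulation: it carries every shared body junction but none of the
    E3/E3'/E3a junctions the N-terminal cascade reads.
    """
    lengths = [
        ("E1", 139), ("E2", 139), ("E3", 89), ("E3p", 247), ("E3a", 160),
        ("E4", 276), ("E5", 110), ("E6", 112), ("E7", 137), ("E8", 141),
        ("E9", 87), ("E10", 179), ("E11", 85), ("E12", 126), ("E13", 105),
        ("E14", 1822),
    ]
    exons = _layout_exons(lengths, first_start=3_569_000)
    ex = {e.label: e for e in exons}
    pairs = [
        ("E1", "E2"), ("E2", "E3"), ("E3", "E4"), ("E3p", "E4"), ("E3a", "E4"),
        ("E4", "E5"), ("E5", "E6"), ("E6", "E7"), ("E7", "E8"), ("E8", "E9"),
        ("E9", "E10"), ("E10", "E11"), ("E10", "E12"), ("E10", "E13"),
        ("E10", "E14"), ("E11", "E12"), ("E12", "E13"), ("E12", "E14"),
        ("E13", "E14"),
    ]
    junctions = [_junction(ex, d, a) for d, a in pairs]
    isoforms = [
        IsoformDef("TA", ("E1", "E2", "E3", "E4"), "n_prefix"),
        IsoformDef("dN", ("E3p", "E4"), "n_prefix"),
        IsoformDef("I3a", ("E3a", "E4"), "complete"),
        IsoformDef(
            "E4p73",
            ("E4", "E5", "E6", "E7", "E8", "E9", "E10", "E11", "E12", "E13", "E14"),
            "complete",
        ),
        IsoformDef("alpha", ("E11", "E12", "E13", "E14"), "c_suffix"),
        IsoformDef("beta", ("E11", "E12", "E14"), "c_suffix"),
        # gamma and epsilon are quantified in tandem from the single
        # E10-E12 junction; their downstream structure (which re-uses the
        # alpha/beta-discriminating E12-E13 / E12-E14 junctions) is
        # deliberately not attributed to the tandem transcript, so the
        # simulated tandem segment ends at E12.
        IsoformDef("gamma+epsilon", ("E12",), "c_suffix"),
        IsoformDef("zeta", ("E13", "E14"), "c_suffix"),
        IsoformDef("delta", ("E14",), "c_suffix"),
    ]
    cascades = [
        CascadeSpec(
            "N",
            (
                CascadeLevel(
                    ROOT,
                    (("E3-E4", "TA"), ("E3p-E4", "dN"), ("E3a-E4", "I3a")),
                ),
            ),
        ),
        CascadeSpec(
            "C",
            (
                CascadeLevel(
                    ROOT,
                    (
                        ("E10-E11", "alpha+beta"),
                        ("E10-E12", "gamma+epsilon"),
                        ("E10-E13", "zeta"),
                        ("E10-E14", "delta"),
                    ),
                ),
                CascadeLevel(
                    "alpha+beta",
                    (("E12-E13", "alpha"), ("E12-E14", "beta")),
                ),
            ),
        ),
    ]
    return GeneModel(
        symbol="TP73",
        strand="+",
        chromosome="chr1",
        exons=exons,
        junctions=junctions,
        isoforms=isoforms,
        cascades=cascades,
        five_prime_junctions=["E3-E4", "E3p-E4"],
        body_junctions=["E5-E6", "E6-E7", "E7-E8", "E8-E9", "E9-E10"],
        shared_body_exons=["E5", "E6", "E7", "E8", "E9", "E10"],
    )


def build_tp63_model() -> GeneModel:
    """TP63 (chromosome 3, plus strand).

    N-terminal choices: TA (E3-E4) and dN (E3'-E4).  C-terminal cascade
    from E10: gamma terminates in its own exon E11a (E10-E11a) versus
    non-gamma (E10-E11); non-gamma splits into delta (E11-E14) versus
    non-delta (E11-E12); non-delta splits into beta (E12-E14) versus
    alpha (E12-E13), each level multiplying by its parent's percentage so
    the four leaves sum to 100.  Exon 8 has two donor forms, full-length
    E8 and a 60-bp-shortened E8s, producing two distinguishable E8->E9
    junctions quantified as a separate two-leaf split.  Junctions for
    exon-4 skipping (E3/E3' to E5) and for the 216-bp cryptic exon in
    intron 4/5 are deliberately absent from the model: they lack
    tissue-specific signal and are excluded from quantification.
    """
    lengths = [
        ("E1", 240), ("E2", 130), ("E3", 96), ("E3p", 253),
        ("E4", 279), ("E5", 112), ("E6", 122), ("E7", 135), ("E8", 165),
        ("E9", 90), ("E10", 150), ("E11a", 1312), ("E11", 80), ("E12", 120),
        ("E13", 100), ("E14", 1406),
    ]
    exons = _layout_exons(lengths, first_start=189_349_000)
    ex = {e.label: e for e in exons}
    pairs = [
        ("E1", "E2"), ("E2", "E3"), ("E3", "E4"), ("E3p", "E4"),
        ("E4", "E5"), ("E5", "E6"), ("E6", "E7"), ("E7", "E8"), ("E8", "E9"),
        ("E9", "E10"), ("E10", "E11a"), ("E10", "E11"), ("E11", "E12"),
        ("E11", "E14"), ("E12", "E13"), ("E12", "E14"), ("E13", "E14"),
    ]
    junctions = [_junction(ex, d, a) for d, a in pairs]
    junctions.append(_junction(ex, "E8", "E9", variant="E8s", donor_trim=60))
    isoforms = [
        IsoformDef("TA", ("E1", "E2", "E3", "E4"), "n_prefix"),
        IsoformDef("dN", ("E3p", "E4"), "n_prefix"),
        IsoformDef("alpha", ("E11", "E12", "E13", "E14"), "c_suffix"),
        IsoformDef("beta", ("E11", "E12", "E14"), "c_suffix"),
        IsoformDef("gamma", ("E11a",), "c_suffix"),
        IsoformDef("delta", ("E11", "E14"), "c_suffix"),
    ]
    cascades = [
        CascadeSpec(
            "N",
            (CascadeLevel(ROOT, (("E3-E4", "TA"), ("E3p-E4", "dN"))),),
        ),
        CascadeSpec(
            "C",
            (
                CascadeLevel(
                    ROOT, (("E10-E11a", "gamma"), ("E10-E11", "non-gamma"))
                ),
                CascadeLevel(
                    "non-gamma", (("E11-E14", "delta"), ("E11-E12", "non-delta"))
                ),
                CascadeLevel(
                    "non-delta", (("E12-E14", "beta"), ("E12-E13", "alpha"))
                ),
            ),
        ),
        CascadeSpec(
            "E8variant",
            (CascadeLevel(ROOT, (("E8-E9", "E8"), ("E8-E9:E8s", "E8s"))),),
        ),
    ]
    return GeneModel(
        symbol="TP63",
        strand="+",
        chromosome="chr3",
        exons=exons,
        junctions=junctions,
        isoforms=isoforms,
        cascades=cascades,
        five_prime_junctions=["E3-E4", "E3p-E4"],
        body_junctions=["E5-E6", "E6-E7", "E7-E8", "E8-E9", "E8-E9:E8s", "E9-E10"],
        shared_body_exons=["E5", "E6", "E7", "E8", "E9", "E10"],
    )


# ---------------------------------------------------------------------------
# validation


def validate_model(model: GeneModel) -> list[str]:
    """Check all structural invariants; return human-readable violations.

    An empty list means the model is internally consistent: exon labels
    unique and well-formed, junction keys unique with intron_start <
    intron_end, cascade levels correctly chained with each leaf label
    appearing exactly once, ratio junction sets disjoint, and every
    referenced junction / isoform path resolvable.
    """
    problems: list[str] = []

    labels = [e.label for e in model.exons]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        problems.append(f"duplicate exon labels: {dupes}")
    for e in model.exons:
        if e.start > e.end:
            problems.append(f"exon {e.label}: start > end")

    keys = [(j.donor_exon, j.acceptor_exon, j.variant) for j in model.junctions]
    if len(keys) != len(set(keys)):
        problems.append("duplicate junction (donor, acceptor, variant) keys")
    known_uids = {j.uid for j in model.junctions}
    exon_set = set(labels)
    for j in model.junctions:
        if j.intron_start >= j.intron_end:
            problems.append(f"junction {j.uid}: intron_start >= intron_end")
        for lab in (j.donor_exon, j.acceptor_exon):
            if lab not in exon_set:
                problems.append(f"junction {j.uid}: unknown exon {lab}")

    for cascade in model.cascades:
        seen_children: list[str] = []
        defined = {ROOT}
        for lv in cascade.levels:
            if lv.parent not in defined:
                problems.append(
                    f"{cascade.terminus} cascade: level parent {lv.parent!r} "
                    "is not a child of a previous level"
                )
            for uid, child in lv.branches:
                if uid not in known_uids:
                    problems.append(
                        f"{cascade.terminus} cascade: unknown junction {uid!r}"
                    )
                seen_children.append(child)
                defined.add(child)
        leaves = cascade.leaf_labels()
        for leaf in leaves:
            if seen_children.count(leaf) > 1:
                problems.append(
                    f"{cascade.terminus} cascade: leaf {leaf!r} appears in "
                    "more than one branch"
                )

    if set(model.five_prime_junctions) & set(model.body_junctions):
        problems.append("ratio sets not disjoint")
    for uid in list(model.five_prime_junctions) + list(model.body_junctions):
        if uid not in known_uids:
            problems.append(f"ratio junction {uid!r} not in model junctions")

    for iso in model.isoforms:
        if iso.kind == "complete":
            path = iso.exon_path
            for d, a in zip(path, path[1:]):
                try:
                    model.junction_for(d, a, None)
                except KeyError:
                    problems.append(f"isoform {iso.name}: missing junction {d}-{a}")

    return problems


def resolve_model(model: Union[GeneModel, str, Path]) -> GeneModel:
    """Accept a GeneModel, a gene symbol ("TP73"/"TP63"), or a config path."""
    if isinstance(model, GeneModel):
        return model
    name = str(model)
    if name.upper() == "TP73":
        return build_tp73_model()
    if name.upper() == "TP63":
        return build_tp63_model()
    path = Path(name)
    if path.exists():
        return GeneModel.load(path)
    raise ValueError(
        f"cannot resolve gene model {model!r}: expected a GeneModel, "
        '"TP73", "TP63", or a path to a YAML model config'
    )
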