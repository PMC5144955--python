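"""Domain model for gene-order genomes and chromosome rearrangements.

A :class:`Genome` is a set of chromosome arms, each an ordered list of
oriented genes read in the centromere->telomere direction (index 0 is
centromere-proximal).  Rearrangement events -- reciprocal translocations,
inversions, transpositions, deletions, duplications and TE insertions --
are applied with :func:`apply_event`, which returns a new genome and never
mutates its input.

Coordinates are 0-based ordinals.  Cuts are "after index i": a breakpoint
ordinal of ``i`` severs the arm between genes ``i`` and ``i + 1``, and
``i = -1`` cuts before the first (most proximal) gene.
"""

from __future__ import annotations

import copy
import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence


class EventType(str, enum.Enum):
    RECIPROCAL_TRANSLOCATION = "reciprocal_translocation"
    INVERSION = "inversion"
    TRANSPOSITION = "transposition"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    TE_INSERTION = "te_insertion"
    # Produced only by the event classifier when evidence is inconclusive;
    # apply_event refuses it.
    UNCLASSIFIED = "unclassified"


#: Allowed gene orientations.  "?" marks an experimentally undetermined
#: orientation and is intended for curated fixtures, not simulation output.
ORIENTATIONS = ("+", "-", "?")


@dataclass(frozen=True)
class OrientedGene:
    """A gene (or gene-like element) with an orientation on its arm.

    ``family_id`` groups paralogs: members of a duplicated family share a
    family while keeping distinct ``gene_id`` values.
    """

    gene_id: str
    family_id: str
    orientation: str = "+"

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not self.family_id:
            raise ValueError("family_id must be non-empty")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}, got {self.orientation!r}")

    def flipped(self) -> "OrientedGene":
        """Return the gene with its orientation reversed ('?' stays '?')."""
        flip = {"+": "-", "-": "+", "?": "?"}
        return replace(self, orientation=flip[self.orientation])


@dataclass
class ChromosomeArm:
    """An ordered list of oriented genes; index 0 is centromere-proximal."""

    arm_id: str
    genes: list[OrientedGene] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate gene_id within arm {self.arm_id}")

    def __len__(self) -> int:
        return len(self.genes)

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def index_of(self, gene_id: str) -> int:
        for i, g in enumerate(self.genes):
            if g.gene_id == gene_id:
                return i
        raise KeyError(gene_id)


@dataclass
class Genome:
    """A taxon-labelled collection of chromosome arms.

    Gene ids are unique genome-wide; the same id appearing in two genomes
    denotes orthologs (markers are genes, one marker per gene).
    """

    taxon: str
    arms: dict[str, ChromosomeArm] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.arms, (list, tuple)):
            self.arms = {a.arm_id: a for a in self.arms}
        seen: set[str] = set()
        for arm in self.arms.values():
            for g in arm.genes:
                if g.gene_id in seen:
                    raise ValueError(f"gene_id {g.gene_id!r} duplicated across arms of {self.taxon}")
                seen.add(g.gene_id)

    def arm(self, arm_id: str) -> ChromosomeArm:
        try:
            return self.arms[arm_id]
        except KeyError:
            raise KeyError(f"unknown arm {arm_id!r} in genome {self.taxon!r}") from None

    def arm_ids(self) -> list[str]:
        return list(self.arms)

    def gene_ids(self) -> list[str]:
        return [g.gene_id for arm in self.arms.values() for g in arm.genes]

    def copy(self) -> "Genome":
        return copy.deepcopy(self)


@dataclass(frozen=True)
class RearrangementEvent:
    """A typed rearrangement with arm(s), cut ordinal(s) and optional payload.

    * reciprocal_translocation: 2 arms, 2 cuts; the distal segments beyond
      the cuts are exchanged.
    * inversion: 1 arm, 2 cuts ``(b1, b2)`` with ``b1 < b2``; the genes in
      ``(b1, b2]`` are reversed and their orientations flipped.
    * transposition: payload gene is excised and reinserted after the cut on
      the (last) named arm.
    * deletion: payload gene removed.  duplication: payload gene copied and
      the copy (suffix ``_dup<n>``, same family) inserted just distal to it.
    * te_insertion: a new element (family "TE") inserted after the cut.
    """

    etype: EventType
    arms: tuple[str, ...]
    breakpoints: tuple[int, ...] = ()
    payload: Optional[str] = None

    def __post_init__(self) -> None:
        et = EventType(self.etype)
        object.__setattr__(self, "etype", et)
        object.__setattr__(self, "arms", tuple(self.arms))
        object.__setattr__(self, "breakpoints", tuple(int(b) for b in self.breakpoints))
        if et is EventType.RECIPROCAL_TRANSLOCATION:
            if len(self.arms) != 2 or len(self.breakpoints) != 2:
                raise ValueError("reciprocal_translocation needs exactly 2 arms and 2 breakpoints")
            if self.arms[0] == self.arms[1]:
                raise ValueError("reciprocal_translocation arms must differ")
        elif et is EventType.INVERSION:
            if len(self.arms) != 1 or len(self.breakpoints) != 2:
                raise ValueError("inversion needs exactly 1 arm and 2 breakpoints")
            if not self.breakpoints[0] < self.breakpoints[1]:
                raise ValueError("inversion breakpoints must satisfy first < second")


@dataclass
class BreakpointInterval:
    """A marker-delimited interval where a query genome's arm assignment flips.

    ``ordinal_span`` is the (proximal, distal) pair of flanking-marker
    ordinals on the reference arm; the inferred cut lies strictly between
    them.  The ``*_query_arms`` sets are the full hit sets of the flanking
    markers; ``*_consensus_arm`` is the single candidate arm of the run the
    flank belongs to.
    """

    reference_arm: str
    query_taxon: str
    proximal_flank: str
    distal_flank: str
    ordinal_span: tuple[int, int]
    proximal_query_arms: frozenset[str]
    distal_query_arms: frozenset[str]
    proximal_consensus_arm: Optional[str] = None
    distal_consensus_arm: Optional[str] = None
    size_kb: Optional[float] = None

    def __post_init__(self) -> None:
        self.proximal_query_arms = frozenset(self.proximal_query_arms)
        self.distal_query_arms = frozenset(self.distal_query_arms)
        p, d = self.ordinal_span
        if not p < d:
            raise ValueError("proximal ordinal must be < distal ordinal")
        if self.proximal_query_arms == self.distal_query_arms:
            raise ValueError("flanking arm sets must differ across a breakpoint")

    @property
    def midpoint(self) -> float:
        p, d = self.ordinal_span
        return (p + d) / 2.0

    def flank_pair(self) -> tuple[str, str]:
        return (self.proximal_flank, self.distal_flank)


# ---------------------------------------------------------------------------
# event algebra


def _check_cut(arm: ChromosomeArm, cut: int) -> None:
    if not -1 <= cut <= len(arm) - 1:
        raise ValueError(
            f"cut ordinal {cut} out of range for arm {arm.arm_id} of length {len(arm)}"
        )


def _check_insert(arm: ChromosomeArm, cut: int) -> None:
    # insertion "after index i" may also target the very end (i = len-1)
    if not -1 <= cut <= len(arm) - 1 and not (len(arm) == 0 and cut == -1):
        raise ValueError(
            f"insertion ordinal {cut} out of range for arm {arm.arm_id} of length {len(arm)}"
        )


def apply_event(genome: Genome, event: RearrangementEvent) -> Genome:
    """Apply one rearrangement and return the resulting genome (input untouched).

    Gene content is conserved for translocation, inversion and
    transposition; deletion removes the payload gene, duplication and TE
    insertion add one gene.
    """
    g = genome.copy()
    et = event.etype
    if et is EventType.RECIPROCAL_TRANSLOCATION:
        a1, a2 = (g.arm(a) for a in event.arms)
        c1, c2 = event.breakpoints
        _check_cut(a1, c1)
        _check_cut(a2, c2)
        a1_new = a1.genes[: c1 + 1] + a2.genes[c2 + 1 :]
        a2_new = a2.genes[: c2 + 1] + a1.genes[c1 + 1 :]
        a1.genes, a2.genes = a1_new, a2_new
    elif et is EventType.INVERSION:
        arm = g.arm(event.arms[0])
        b1, b2 = event.breakpoints
        _check_cut(arm, b1)
        _check_cut(arm, b2)
        span = arm.genes[b1 + 1 : b2 + 1]
        arm.genes[b1 + 1 : b2 + 1] = [x.flipped() for x in reversed(span)]
    elif et is EventType.TRANSPOSITION:
        if event.payload is None:
            raise ValueError("transposition requires a payload gene id")
        src_arm_id = arm_location_of(g, event.payload)
        if src_arm_id is None:
            raise KeyError(f"payload gene {event.payload!r} not in genome")
        src = g.arm(src_arm_id)
        idx = src.index_of(event.payload)
        gene = src.genes.pop(idx)
        dst = g.arm(event.arms[-1])
        cut = event.breakpoints[-1]
        _check_insert(dst, cut)
        dst.genes.insert(cut + 1, gene)
    elif et is EventType.DELETION:
        if event.payload is None:
            raise ValueError("deletion requires a payload gene id")
        arm_id = arm_location_of(g, event.payload)
        if arm_id is None:
            raise KeyError(f"payload gene {event.payload!r} not in genome")
        arm = g.arm(arm_id)
        arm.genes.pop(arm.index_of(event.payload))
    elif et is EventType.DUPLICATION:
        if event.payload is None:
            raise ValueError("duplication requires a payload gene id")
        arm_id = arm_location_of(g, event.payload)
        if arm_id is None:
            raise KeyError(f"payload gene {event.payload!r} not in genome")
        arm = g.arm(arm_id)
        idx = arm.index_of(event.payload)
        src_gene = arm.genes[idx]
        existing = set(g.gene_ids())
        n = 1
        while f"{src_gene.gene_id}_dup{n}" in existing:
            n += 1
        arm.genes.insert(idx + 1, replace(src_gene, gene_id=f"{src_gene.gene_id}_dup{n}"))
    elif et is EventType.TE_INSERTION:
        arm = g.arm(event.arms[0])
        cut = event.breakpoints[0]
        _check_insert(arm, cut)
        te_id = event.payload or f"TE_{arm.arm_id}_{cut + 1}"
        if te_id in set(g.gene_ids()):
            raise ValueError(f"TE id {te_id!r} already present")
        arm.genes.insert(cut + 1, OrientedGene(te_id, "TE", "+"))
    else:
        raise ValueError(f"cannot apply event of type {et}")
    # rebuild validation (duplicate ids across arms etc.)
    return Genome(g.taxon, g.arms)


def apply_events(genome: Genome, events: Iterable[RearrangementEvent]) -> Genome:
    """Apply events in order; convenience for replaying logged histories."""
    g = genome
    for ev in events:
        g = apply_event(g, ev)
    return g


def arm_location_of(genome: Genome, gene_id: str) -> Optional[str]:
    """Return the arm carrying ``gene_id``, or ``None`` if the gene is absent.

    Absence is a first-class answer: it models gene loss (e.g. a family
    member deleted in one lineage) rather than an error.
    """
    for arm in genome.arms.values():
        for g in arm.genes:
            if g.gene_id == gene_id:
                return arm.arm_id
    return None


def arms_with_family(genome: Genome, family_id: str) -> set[str]:
    """All arms of ``genome`` carrying at least one gene of ``family_id``."""
    return {
        arm.arm_id
        for arm in genome.arms.values()
        if any(g.family_id == family_id for g in arm.genes)
    }
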