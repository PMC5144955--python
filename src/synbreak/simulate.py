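"""Ground-truthed synthetic inputs: genomes evolved on a tree, noisy marker
location-profile tables, and junction sequences with controlled
poly(dA:dT) homopolymer content.

Every generator is deterministic in the :class:`SimulationConfig` seed, and
the emitted :class:`TruthSet` carries the full per-branch event log so that
downstream inferences can be scored against the exact simulated history
(replaying the log from the ancestor reproduces each tip genome).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import dendropy
import numpy as np

from .core import (
    ChromosomeArm,
    EventType,
    Genome,
    OrientedGene,
    RearrangementEvent,
    apply_event,
    apply_events,
    arms_with_family,
)
from .collinearity import LocationProfileTable, MarkerRecord

#: Relative propensities of event types along a branch.  Inversions are the
#: commonest plant rearrangement class; exchanges between non-homologous
#: arms are rarer.
DEFAULT_EVENT_WEIGHTS: dict[EventType, float] = {
    EventType.RECIPROCAL_TRANSLOCATION: 0.20,
    EventType.INVERSION: 0.30,
    EventType.TRANSPOSITION: 0.15,
    EventType.DELETION: 0.15,
    EventType.DUPLICATION: 0.10,
    EventType.TE_INSERTION: 0.10,
}

#: Explicit schedule type: branch label -> events applied on that branch.
Schedule = Mapping[str, Sequence[RearrangementEvent]]


@dataclass
class SimulationConfig:
    """Study conditions for one simulation run.

    ``events_per_branch`` is either a Poisson mean per unit branch length
    (branch length as exposure; unit length assumed where the tree has
    none) or an explicit per-branch schedule.  ``tract_enrichment`` is the
    target poly(dA:dT) tract frequency per kb for synthesized junction
    sequences; the 18.4/kb default matches the density reported for a real
    translocation junction and serves as a realistic setting.
    """

    seed: int = 0
    n_arms: int = 2
    genes_per_arm: int = 20
    tree: str = "((A:1.0,B:1.0):1.0,C:2.0);"
    events_per_branch: Union[float, Schedule] = 0.5
    event_type_weights: Mapping[EventType, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_WEIGHTS)
    )
    detection_miss_rate: float = 0.0
    paralog_hit_rate: float = 0.0
    tract_enrichment: float = 18.4
    gc_content: float = 0.44

    def __post_init__(self) -> None:
        for name in ("detection_miss_rate", "paralog_hit_rate", "gc_content"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.tract_enrichment < 0:
            raise ValueError("tract_enrichment must be non-negative")
        w = dict(self.event_type_weights)
        total = sum(w.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"event type weights must sum to 1, got {total}")
        self.event_type_weights = {EventType(k): v for k, v in w.items()}

    def rng(self, stream: int = 0) -> np.random.Generator:
        """A named random stream derived from the run seed."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class TruthSet:
    """Simulated history: ancestor, tree, per-branch event logs and tips.

    ``event_log`` maps a node label (tip taxon or internal ``n<k>``) to the
    events applied on the branch leading to that node.
    """

    ancestor: Genome
    tree: dendropy.Tree
    tip_genomes: dict[str, Genome]
    event_log: dict[str, list[RearrangementEvent]]

    def events_to_tip(self, taxon: str) -> list[RearrangementEvent]:
        """All events on the root-to-tip path, in application order."""
        node = next(
            (lf for lf in self.tree.leaf_node_iter() if lf.taxon.label == taxon), None
        )
        if node is None:
            raise KeyError(f"tip {taxon!r} not in tree")
        labels = []
        while node.parent_node is not None:
            labels.append(_node_label(node))
            node = node.parent_node
        events: list[RearrangementEvent] = []
        for lab in reversed(labels):
            events.extend(self.event_log.get(lab, []))
        return events

    def replay_tip(self, taxon: str) -> Genome:
        """Re-derive a tip genome from the ancestor and the event log."""
        g = apply_events(self.ancestor, self.events_to_tip(taxon))
        g.taxon = taxon
        return g


def _node_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return node.label


def simulate_ancestral_genome(config: SimulationConfig) -> Genome:
    """Build the rearrangement-free ancestor: ``n_arms`` arms named by the
    homoeologous-group convention ("1L", "2L", ...), each with
    ``genes_per_arm`` forward-oriented genes ``g<arm>_<ordinal>``."""
    if config.n_arms < 1:
        raise ValueError("n_arms must be >= 1")
    if config.genes_per_arm < 2:
        raise ValueError("genes_per_arm must be >= 2")
    arms = []
    for k in range(1, config.n_arms + 1):
        arm_id = f"{k}L"
        genes = [
            OrientedGene(f"g{k}L_{i:03d}", f"fam{k}L_{i:03d}", "+")
            for i in range(config.genes_per_arm)
        ]
        arms.append(ChromosomeArm(arm_id, genes))
    return Genome("ancestor", {a.arm_id: a for a in arms})


# ---------------------------------------------------------------------------
# event sampling


def _feasible(etype: EventType, genome: Genome) -> bool:
    lens = [len(a) for a in genome.arms.values()]
    if etype is EventType.RECIPROCAL_TRANSLOCATION:
        return sum(1 for n in lens if n >= 2) >= 2
    if etype in (EventType.INVERSION, EventType.TRANSPOSITION, EventType.DELETION):
        return any(n >= 2 for n in lens)
    return len(lens) >= 1  # duplication / te_insertion


def sample_event(
    genome: Genome,
    rng: np.random.Generator,
    weights: Optional[Mapping[EventType, float]] = None,
) -> RearrangementEvent:
    """Draw one random valid event for the current genome state.

    Cut positions are uniform over positions that leave non-empty retained
    and exchanged/affected segments.  Infeasible types (e.g. a translocation
    in a one-arm genome) are excluded and the weights renormalized.
    """
    w = dict(weights or DEFAULT_EVENT_WEIGHTS)
    types = [t for t in w if w[t] > 0 and _feasible(t, genome)]
    if not types:
        raise ValueError("no feasible event type for this genome")
    probs = np.array([w[t] for t in types], dtype=float)
    probs /= probs.sum()
    etype = types[rng.choice(len(types), p=probs)]
    arms = sorted(genome.arms)
    if etype is EventType.RECIPROCAL_TRANSLOCATION:
        big = [a for a in arms if len(genome.arms[a]) >= 2]
        i, j = rng.choice(len(big), size=2, replace=False)
        a1, a2 = big[i], big[j]
        c1 = int(rng.integers(0, len(genome.arms[a1]) - 1))
        c2 = int(rng.integers(0, len(genome.arms[a2]) - 1))
        return RearrangementEvent(etype, (a1, a2), (c1, c2))
    if etype is EventType.INVERSION:
        big = [a for a in arms if len(genome.arms[a]) >= 2]
        a = big[rng.integers(0, len(big))]
        n = len(genome.arms[a])
        b1 = int(rng.integers(-1, n - 1))
        b2 = int(rng.integers(b1 + 1, n))
        return RearrangementEvent(etype, (a,), (b1, b2))
    if etype is EventType.TRANSPOSITION:
        big = [a for a in arms if len(genome.arms[a]) >= 2]
        src = big[rng.integers(0, len(big))]
        gene = genome.arms[src].genes[rng.integers(0, len(genome.arms[src]))].gene_id
        dst = arms[rng.integers(0, len(arms))]
        n_dst = len(genome.arms[dst]) - (1 if dst == src else 0)
        cut = int(rng.integers(-1, n_dst))
        return RearrangementEvent(etype, (dst,), (cut,), payload=gene)
    if etype is EventType.DELETION:
        big = [a for a in arms if len(genome.arms[a]) >= 2]
        a = big[rng.integers(0, len(big))]
        gene = genome.arms[a].genes[rng.integers(0, len(genome.arms[a]))].gene_id
        return RearrangementEvent(etype, (a,), (), payload=gene)
    if etype is EventType.DUPLICATION:
        a = arms[rng.integers(0, len(arms))]
        if len(genome.arms[a]) == 0:
            a = max(arms, key=lambda x: len(genome.arms[x]))
        gene = genome.arms[a].genes[rng.integers(0, len(genome.arms[a]))].gene_id
        return RearrangementEvent(etype, (a,), (), payload=gene)
    # TE insertion
    a = arms[rng.integers(0, len(arms))]
    cut = int(rng.integers(-1, len(genome.arms[a])))
    return RearrangementEvent(etype, (a,), (cut,))


def evolve_on_tree(ancestor: Genome, config: SimulationConfig) -> TruthSet:
    """Evolve the ancestor along the configured tree.

    Branches are visited in preorder; event counts per branch are Poisson
    with mean ``rate * branch_length`` (or taken verbatim from an explicit
    schedule keyed by node label), and each event is applied to the genome
    state inherited at the top of the branch.
    """
    try:
        tree = dendropy.Tree.get(data=config.tree, schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick tree: {exc}") from exc
    # stable labels for internal nodes
    k = 0
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and not node.label:
            node.label = f"n{k}"
            k += 1
    rng = config.rng(stream=1)
    schedule = (
        config.events_per_branch
        if isinstance(config.events_per_branch, Mapping)
        else None
    )
    rate = None if schedule is not None else float(config.events_per_branch)
    genomes: dict[int, Genome] = {}
    event_log: dict[str, list[RearrangementEvent]] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            genomes[id(node)] = ancestor
            continue
        parent = genomes[id(node.parent_node)]
        label = _node_label(node)
        if schedule is not None:
            events = list(schedule.get(label, []))
        else:
            exposure = node.edge.length if node.edge.length is not None else 1.0
            n_events = int(rng.poisson(rate * exposure))
            events = []
            g = parent
            for _ in range(n_events):
                ev = sample_event(g, rng, config.event_type_weights)
                g = apply_event(g, ev)
                events.append(ev)
        genomes[id(node)] = apply_events(parent, events)
        event_log[label] = events
    tips: dict[str, Genome] = {}
    for leaf in tree.leaf_node_iter():
        g = genomes[id(leaf)].copy()
        g.taxon = leaf.taxon.label
        tips[leaf.taxon.label] = g
    return TruthSet(ancestor=ancestor, tree=tree, tip_genomes=tips, event_log=event_log)


# ---------------------------------------------------------------------------
# marker location profiles


def emit_location_profiles(
    truth: TruthSet,
    reference_taxon: str,
    reference_arm: str,
    config: SimulationConfig,
    query_taxa: Optional[Sequence[str]] = None,
) -> LocationProfileTable:
    """Emit the ordered marker table of one reference arm.

    One marker per reference gene, in reference order; each query column
    holds the set of arms carrying a member of the marker's gene family
    (family-level hits model paralog cross-detection).  Noise per config:
    with ``detection_miss_rate`` a marker's hit set is emptied, and with
    ``paralog_hit_rate`` one uniformly chosen extra arm is added.
    """
    if reference_taxon not in truth.tip_genomes:
        raise KeyError(f"reference taxon {reference_taxon!r} not among tips")
    ref = truth.tip_genomes[reference_taxon]
    markers = ref.arm(reference_arm).genes
    taxa = list(query_taxa) if query_taxa is not None else [
        t for t in truth.tip_genomes if t != reference_taxon
    ]
    # noise stream keyed by the arm so different arms get independent noise
    rng = np.random.default_rng([config.seed, 2, *reference_arm.encode()])
    rows = []
    for i, gene in enumerate(markers):
        hits: dict[str, frozenset[str]] = {}
        for taxon in taxa:
            qg = truth.tip_genomes[taxon]
            found = arms_with_family(qg, gene.family_id)
            if rng.random() < config.detection_miss_rate:
                found = set()
            elif found and rng.random() < config.paralog_hit_rate:
                extra = [a for a in sorted(qg.arms) if a not in found]
                if extra:
                    found = found | {extra[rng.integers(0, len(extra))]}
            hits[taxon] = frozenset(found)
        band = int(rng.poisson(9)) + 1
        rows.append(MarkerRecord(gene.gene_id, i, hits, band_count=band))
    return LocationProfileTable(reference_arm, rows, reference_taxon=reference_taxon)


def location_profiles_from_genomes(
    reference: Genome, queries: Mapping[str, Genome]
) -> dict[str, LocationProfileTable]:
    """Noise-free location-profile tables for every reference arm.

    Hits are family-level (a marker detects all arms carrying a member of
    its gene family), the behaviour of a homology search against paralogs.
    """
    tables = {}
    for arm_id in reference.arm_ids():
        rows = []
        for i, gene in enumerate(reference.arms[arm_id].genes):
            hits = {
                taxon: frozenset(arms_with_family(qg, gene.family_id))
                for taxon, qg in queries.items()
            }
            rows.append(MarkerRecord(gene.gene_id, i, hits))
        tables[arm_id] = LocationProfileTable(arm_id, rows, reference_taxon=reference.taxon)
    return tables


# ---------------------------------------------------------------------------
# junction sequence synthesis


def _background(length: int, gc: float, rng: np.random.Generator, min_len: int) -> list[str]:
    """Random sequence at the given GC with no A or T homopolymer reaching
    ``min_len`` (so all tracts are the explicitly placed ones)."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    bases = "ACGT"
    seq: list[str] = []
    run_base, run_len = "", 0
    for _ in range(length):
        b = bases[rng.choice(4, p=p)]
        if b in "AT" and b == run_base and run_len == min_len - 1:
            others = [x for x in bases if x != b]
            b = others[rng.integers(0, 3)]
        if b == run_base:
            run_len += 1
        else:
            run_base, run_len = b, 1
        seq.append(b)
    return seq


def synthesize_junction_sequence(
    model: "JunctionModel",
    config: SimulationConfig,
    min_len: int = 6,
) -> str:
    """Synthesize a junction sequence matching a segment model's total length
    with poly(dA:dT) tracts placed at the configured per-kb frequency.

    Tract count is ``round(tract_enrichment * length / 1000)``; tract
    lengths are ``min_len`` plus a geometric excess, placed at uniform
    non-overlapping positions with non-A/T guard bases at both ends so each
    placed tract is maximal and the realized tract count is exact (hence
    the realized per-kb frequency is within rounding of the target, well
    inside +/-20% for sequences >= 2 kb).
    """
    from .junctions import JunctionModel  # local import to avoid cycle

    if not isinstance(model, JunctionModel):
        raise TypeError("model must be a JunctionModel")
    length = model.total_length
    rng = config.rng(stream=3)
    seq = _background(length, config.gc_content, rng, min_len)
    n_tracts = int(round(config.tract_enrichment * length / 1000.0))
    occupied = np.zeros(length, dtype=bool)
    placed = 0
    attempts = 0
    while placed < n_tracts:
        attempts += 1
        if attempts > 200 * max(n_tracts, 1):
            raise RuntimeError(
                f"could not place {n_tracts} tracts of >= {min_len} bp in {length} bp"
            )
        tract_len = min_len + int(rng.geometric(0.5)) - 1
        start = int(rng.integers(0, max(length - tract_len, 0) + 1))
        lo, hi = max(start - 1, 0), min(start + tract_len + 1, length)
        if occupied[lo:hi].any():
            continue
        base = "A" if rng.random() < 0.5 else "T"
        for i in range(start, start + tract_len):
            seq[i] = base
        # guard bases keep the tract maximal at exactly tract_len
        for i in (start - 1, start + tract_len):
            if 0 <= i < length and seq[i] == base:
                seq[i] = "C" if rng.random() < 0.5 else "G"
        occupied[lo:hi] = True
        placed += 1
    return "".join(seq)
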