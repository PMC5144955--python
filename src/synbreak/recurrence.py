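"""Rearrangement recurrence on a phylogeny and breakpoint-reuse calling.

A rearrangement carrier state is a binary character on the tips of a rooted
tree (1 = carrier, 0 = non-carrier, {0,1} = polymorphic/ambiguous, for
species in which the rearrangement is not fixed).  Two statistics quantify
recurrence:

* :func:`min_changes_fitch` -- Fitch small-parsimony minimum number of state
  changes of either direction;
* :func:`min_origins` -- minimum number of independent 0->1 gains over all
  ancestral labelings with the root constrained to non-carrier (losses are
  allowed and not counted).  Two or more origins on a tree whose carriers
  could also be explained by one gain plus losses is the parsimony signature
  of a recurrent rearrangement.

Breakpoint *reuse* across lineages is called by comparing two breakpoint
intervals projected onto a common reference gene order: identical flank
ortholog pairs mean the same breakpoint was used; distinct but nearby
intervals mark a fragile region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import dendropy

from .core import BreakpointInterval, EventType, RearrangementEvent
from .collinearity import CollinearBlock

#: Tip state spellings accepted in sidecar tables.
_STATE_ALIASES: dict[str, frozenset[int]] = {
    "0": frozenset({0}),
    "1": frozenset({1}),
    "ambiguous": frozenset({0, 1}),
    "0/1": frozenset({0, 1}),
    "polymorphic": frozenset({0, 1}),
}

StateLike = Union[int, str, frozenset, set]


def _as_state(value: StateLike) -> frozenset[int]:
    if isinstance(value, (set, frozenset)):
        s = frozenset(int(v) for v in value)
    elif isinstance(value, int):
        s = frozenset({value})
    else:
        s = _STATE_ALIASES.get(str(value).strip().lower())
        if s is None:
            raise ValueError(f"unrecognized tip state {value!r}")
    if not s or not s <= {0, 1}:
        raise ValueError(f"tip state must be a non-empty subset of {{0,1}}, got {value!r}")
    return s


@dataclass
class CharacterStateTree:
    """A rooted tree plus carrier states for every tip.

    ``tip_states`` maps tip label -> state; values may be 0/1 integers,
    strings ("0", "1", "ambiguous") or explicit sets.
    """

    tree: dendropy.Tree
    tip_states: dict[str, frozenset[int]]

    def __post_init__(self) -> None:
        self.tip_states = {k: _as_state(v) for k, v in self.tip_states.items()}
        leaves = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(leaves) < 2:
            raise ValueError("tree must have at least 2 tips")
        missing = [l for l in leaves if l not in self.tip_states]
        if missing:
            raise ValueError(f"unlabeled tips: {missing}")

    @classmethod
    def from_newick(
        cls, newick: str, tip_states: Mapping[str, StateLike]
    ) -> "CharacterStateTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        except Exception as exc:
            raise ValueError(f"malformed Newick tree: {exc}") from exc
        return cls(tree, dict(tip_states))


def min_changes_fitch(cst: CharacterStateTree) -> int:
    """Fitch minimum number of state changes for the binary carrier character.

    Ambiguous tips contribute their full state set and never force a change
    on their own.
    """
    changes = 0
    sets: dict[int, frozenset[int]] = {}
    for node in cst.tree.postorder_node_iter():
        if node.is_leaf():
            sets[id(node)] = cst.tip_states[node.taxon.label]
            continue
        children = [sets[id(c)] for c in node.child_nodes()]
        acc = children[0]
        for s in children[1:]:
            inter = acc & s
            if inter:
                acc = inter
            else:
                acc = acc | s
                changes += 1
        sets[id(node)] = acc
    return changes


def min_origins(
    cst: CharacterStateTree, root_state: int = 0, allow_losses: bool = False
) -> int:
    """Minimum number of independent 0->1 gains with the root state fixed.

    Dynamic program over the rooted tree: ``cost(v, s)`` is the minimum
    number of gain edges in the subtree of ``v`` given that ``v`` has state
    ``s``.  By default the character is irreversible (a fixed reciprocal
    translocation does not revert), so 1->0 edges are forbidden and the
    count is the Dollo-style number of independent origins; with
    ``allow_losses=True`` losses are permitted and simply not counted.  The
    root defaults to non-carrier, the outgroup condition under which
    independent origins are counted.
    """
    INF = math.inf
    cost: dict[int, dict[int, float]] = {}
    for node in cst.tree.postorder_node_iter():
        if node.is_leaf():
            allowed = cst.tip_states[node.taxon.label]
            cost[id(node)] = {s: (0 if s in allowed else INF) for s in (0, 1)}
            continue
        c: dict[int, float] = {}
        for s in (0, 1):
            total = 0.0
            for child in node.child_nodes():
                cc = cost[id(child)]
                terms = []
                for t in (0, 1):
                    if s == 1 and t == 0 and not allow_losses:
                        continue
                    terms.append(cc[t] + (1 if (s == 0 and t == 1) else 0))
                total += min(terms)
            c[s] = total
        cost[id(node)] = c
    root_cost = cost[id(cst.tree.seed_node)][root_state]
    if root_cost is math.inf:
        raise ValueError(f"root state {root_state} incompatible with tip states")
    return int(root_cost)


# ---------------------------------------------------------------------------
# event classification from breakpoint calls + collinear blocks


def _walk_from_blocks(blocks: Sequence[CollinearBlock]) -> list[tuple[int, str, int]]:
    """Reconstruct the (ref index, gene, out index) walk behind a chaining."""
    walk: list[tuple[int, str, int]] = []
    for blk in blocks:
        if blk.ref_indices is not None and blk.out_indices is not None:
            walk.extend(zip(blk.ref_indices, blk.genes, blk.out_indices))
        else:  # arithmetic fallback for hand-built blocks
            step = -1 if blk.strand == "reversed" else 1
            refs = range(blk.ref_range[0], blk.ref_range[1] + 1)
            outs = range(blk.out_range[0], blk.out_range[1] + step, step)
            walk.extend(zip(refs, blk.genes, outs))
    walk.sort()
    return walk


def _displacement_candidates(blocks: Sequence[CollinearBlock]) -> list[tuple[float, int]]:
    """(magnitude, block index) for singleton blocks that are out of place.

    Both arms are read in the same centromere->telomere frame, so the
    collinear spine runs forward and local inversions are reversed blocks
    *within* it.  A singleton is in place when its outgroup position lies
    strictly between the envelopes of the non-singleton blocks preceding
    and following it in reference order; otherwise it is a relocation
    candidate, weighted by its distance from those envelopes.
    """
    out: list[tuple[float, int]] = []
    for k, blk in enumerate(blocks):
        if not blk.possible_transposition:
            continue
        o = blk.out_range[0]
        prevs = [b for b in blocks[:k] if not b.possible_transposition]
        nexts = [b for b in blocks[k + 1 :] if not b.possible_transposition]
        lo = max(max(b.out_indices) for b in prevs) if prevs else None
        hi = min(min(b.out_indices) for b in nexts) if nexts else None
        fits = (lo is None or o > lo) and (hi is None or o < hi)
        if not fits:
            dists = [abs(o - x) for x in (lo, hi) if x is not None]
            out.append((min(dists) if dists else math.inf, k))
    return out


def _split_transpositions(
    blocks: Sequence[CollinearBlock],
) -> tuple[list[tuple[str, int]], list[CollinearBlock]]:
    """Separate relocated single genes from the collinear spine.

    Iteratively removes the most-displaced singleton and re-chains the
    remaining walk with rank-compressed outgroup positions, so that runs
    split only by a moved gene fuse back together; terminates when no
    displaced singleton remains.  Returns (gene id, reference index) pairs
    for the transposed genes and the final spine blocks (original reference
    coordinates).
    """
    from .collinearity import _chain_walk

    walk = _walk_from_blocks(blocks)
    removed: list[tuple[str, int]] = []
    gone: set[str] = set()
    while True:
        remaining = [w for w in walk if w[1] not in gone]
        ranks = {o: r for r, o in enumerate(sorted(o for _, _, o in remaining))}
        compressed = [(r, g, ranks[o]) for r, g, o in remaining]
        chained = _chain_walk(compressed)
        candidates = _displacement_candidates(chained)
        if not candidates:
            return removed, chained
        _, k = max(candidates, key=lambda mk: (mk[0], -mk[1]))
        removed.append((chained[k].genes[0], chained[k].ref_range[0]))
        gone.add(chained[k].genes[0])


def classify_event(
    calls: Mapping[str, Sequence[BreakpointInterval]],
    blocks: Mapping[str, Sequence[CollinearBlock]],
) -> list[RearrangementEvent]:
    """Classify rearrangements for one query taxon from reference-anchored
    evidence.

    ``calls`` maps reference arm -> breakpoint intervals from
    :func:`~synbreak.collinearity.profile_transition_scan`; ``blocks`` maps
    reference arm -> collinear blocks of the query's corresponding arm
    against the reference order.

    Rules, in order:

    * two reference arms each carrying one call, with each arm's distal
      consensus arm equal to the other's proximal consensus arm (the two
      distal segments swapped carriers) -> one reciprocal translocation;
    * a reversed-strand block of >= 2 genes -> an inversion on that arm;
    * a length-1 block displaced from the arithmetic walk of its neighbors
      -> a transposition of that gene;
    * any remaining call -> an ``unclassified`` event carrying the evidence.
    """
    events: list[RearrangementEvent] = []
    used: set[str] = set()
    ref_arms = sorted(calls)
    for i, x in enumerate(ref_arms):
        for y in ref_arms[i + 1 :]:
            if x in used or y in used:
                continue
            cx, cy = calls[x], calls[y]
            if len(cx) != 1 or len(cy) != 1:
                continue
            a, b = cx[0], cy[0]
            if (
                a.distal_consensus_arm == b.proximal_consensus_arm
                and b.distal_consensus_arm == a.proximal_consensus_arm
                and a.proximal_consensus_arm != b.proximal_consensus_arm
            ):
                events.append(
                    RearrangementEvent(
                        EventType.RECIPROCAL_TRANSLOCATION,
                        (a.proximal_consensus_arm, b.proximal_consensus_arm),
                        (a.ordinal_span[0], b.ordinal_span[0]),
                    )
                )
                used.update((x, y))
    for ref_arm in sorted(blocks):
        transposed, spine = _split_transpositions(list(blocks[ref_arm]))
        for blk in spine:
            if blk.strand == "reversed" and len(blk) >= 2:
                events.append(
                    RearrangementEvent(
                        EventType.INVERSION,
                        (ref_arm,),
                        (blk.ref_range[0] - 1, blk.ref_range[1]),
                    )
                )
        for gene, ref_idx in transposed:
            events.append(
                RearrangementEvent(
                    EventType.TRANSPOSITION, (ref_arm,), (ref_idx,), payload=gene
                )
            )
    for ref_arm in ref_arms:
        if ref_arm in used:
            continue
        for iv in calls[ref_arm]:
            events.append(
                RearrangementEvent(
                    EventType.UNCLASSIFIED,
                    (ref_arm,),
                    (iv.ordinal_span[0],),
                    payload=f"{iv.proximal_flank}|{iv.distal_flank}",
                )
            )
    return events


# ---------------------------------------------------------------------------
# breakpoint reuse


@dataclass(frozen=True)
class ReuseVerdict:
    """Outcome of comparing two breakpoint intervals on a common reference
    order: ``shared`` (both flank ortholog pairs identical),
    ``distinct_nearby`` (midpoints within the gene threshold) or
    ``distinct_far``."""

    category: str
    gene_distance: int
    shared_proximal_flank: bool
    shared_distal_flank: bool


def breakpoint_reuse_test(
    interval_a: BreakpointInterval,
    interval_b: BreakpointInterval,
    reference_order: Sequence[str],
    nearby_threshold: int = 5,
) -> ReuseVerdict:
    """Call breakpoint reuse between two lineages.

    Both intervals' flank ids must map (as orthologs) into
    ``reference_order``; the gene distance is the separation of the two
    interval midpoints on that order, rounded half-up to whole genes.
    """
    index = {g: i for i, g in enumerate(reference_order)}
    mids = []
    for iv in (interval_a, interval_b):
        try:
            p, d = index[iv.proximal_flank], index[iv.distal_flank]
        except KeyError as exc:
            raise KeyError(
                f"flank {exc.args[0]!r} of interval on {iv.reference_arm} has no "
                "ortholog in the common reference order"
            ) from None
        mids.append((p + d) / 2.0)
    shared_p = interval_a.proximal_flank == interval_b.proximal_flank
    shared_d = interval_a.distal_flank == interval_b.distal_flank
    distance = int(math.floor(abs(mids[0] - mids[1]) + 0.5))
    if shared_p and shared_d:
        category = "shared"
    elif distance <= nearby_threshold:
        category = "distinct_nearby"
    else:
        category = "distinct_far"
    return ReuseVerdict(category, distance, shared_p, shared_d)
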