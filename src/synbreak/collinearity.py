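"""Breakpoint delimitation from ordered marker profiles and collinear-block chaining.

The inference input is a :class:`LocationProfileTable`: markers of a
reference chromosome arm in physical order, each with the set of arms its
homolog hits in one or more query genomes.  A rearrangement shows up as a
*transition* in a query's arm-assignment column; the two markers flanking
the transition delimit the breakpoint.

Cross-genome gene-order comparison is done by greedy chaining of shared
genes into collinear blocks (same or reversed strand); a breakpoint that
contains a boundary between two ancestral blocks coincides with an ancient
rearrangement junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .core import BreakpointInterval

#: kb of physical distance per consensus BAC-fingerprint band.
KB_PER_BAND = 1.5


@dataclass
class MarkerRecord:
    """One ordered marker: its reference ordinal, optional fingerprint band
    count, and per-query-taxon arm hit sets (empty set = homolog not detected)."""

    marker_id: str
    ordinal: int
    hits: dict[str, frozenset[str]] = field(default_factory=dict)
    band_count: Optional[int] = None

    def __post_init__(self) -> None:
        self.hits = {t: frozenset(a) for t, a in self.hits.items()}


@dataclass
class LocationProfileTable:
    """Ordered markers of one reference arm with query-genome arm hits."""

    reference_arm: str
    rows: list[MarkerRecord]
    reference_taxon: Optional[str] = None

    def __post_init__(self) -> None:
        ords = [r.ordinal for r in self.rows]
        if any(b <= a for a, b in zip(ords, ords[1:])):
            raise ValueError("marker ordinals must be strictly increasing")

    def query_taxa(self) -> list[str]:
        taxa: list[str] = []
        for r in self.rows:
            for t in r.hits:
                if t not in taxa:
                    taxa.append(t)
        return taxa

    def column(self, query_taxon: str) -> list[frozenset[str]]:
        if query_taxon not in self.query_taxa():
            raise KeyError(f"query taxon {query_taxon!r} absent from table")
        return [r.hits.get(query_taxon, frozenset()) for r in self.rows]


def infer_candidate_arms(table: LocationProfileTable, query_taxon: str) -> frozenset[str]:
    """Arms whose presence varies along the query column.

    Homoeologous background arms (hit by essentially every marker, like the
    5BL/5DL copies behind a 5AL/4AL transition) carry no positional signal;
    the informative candidates are the arms present in some but not all
    non-empty hit sets.
    """
    col = [h for h in table.column(query_taxon) if h]
    if not col:
        return frozenset()
    everywhere = frozenset.intersection(*col)
    anywhere = frozenset.union(*col)
    return anywhere - everywhere


def _consensus(hits: frozenset[str], candidates: frozenset[str]) -> Optional[str]:
    """Single candidate arm hit by the marker, else None (missing/ambiguous).

    Multi-candidate hits are true ambiguity and are skipped like missing
    data; a tie can never elect an arm.
    """
    c = hits & candidates
    if len(c) == 1:
        return next(iter(c))
    return None


def profile_transition_scan(
    table: LocationProfileTable,
    query_taxon: str,
    min_run: int = 2,
    candidate_arms: Optional[Iterable[str]] = None,
) -> list[BreakpointInterval]:
    """Delimit breakpoints from arm-assignment transitions in a query column.

    Markers with empty (or non-candidate, or ambiguous) hit sets are skipped
    and do not interrupt runs.  A breakpoint is reported between two maximal
    runs of distinct consensus arms only when both runs contain at least
    ``min_run`` markers, so a single discordant marker never calls a
    breakpoint at the default ``min_run=2``.

    Parameters
    ----------
    candidate_arms:
        The query arms of the homoeologous groups under test (e.g.
        ``{"4AL", "5AL"}`` when scanning a 5DL reference against the wheat A
        genome).  When omitted, the variable arms of the column are used
        (constant cross-group background hits are uninformative).
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    col = table.column(query_taxon)
    if candidate_arms is None:
        candidates = infer_candidate_arms(table, query_taxon)
    else:
        candidates = frozenset(candidate_arms)
    # (row index, consensus arm) for informative markers only
    assigned = []
    for i, hits in enumerate(col):
        arm = _consensus(hits, candidates) if hits else None
        if arm is not None:
            assigned.append((i, arm))
    # maximal runs of identical consensus arm
    runs: list[tuple[str, list[int]]] = []
    for i, arm in assigned:
        if runs and runs[-1][0] == arm:
            runs[-1][1].append(i)
        else:
            runs.append((arm, [i]))
    intervals: list[BreakpointInterval] = []
    for (arm_a, idx_a), (arm_b, idx_b) in zip(runs, runs[1:]):
        if len(idx_a) < min_run or len(idx_b) < min_run:
            continue
        prox = table.rows[idx_a[-1]]
        dist = table.rows[idx_b[0]]
        size_kb = _gap_size_kb(table, idx_a[-1], idx_b[0])
        intervals.append(
            BreakpointInterval(
                reference_arm=table.reference_arm,
                query_taxon=query_taxon,
                proximal_flank=prox.marker_id,
                distal_flank=dist.marker_id,
                ordinal_span=(prox.ordinal, dist.ordinal),
                proximal_query_arms=prox.hits.get(query_taxon, frozenset()),
                distal_query_arms=dist.hits.get(query_taxon, frozenset()),
                proximal_consensus_arm=arm_a,
                distal_consensus_arm=arm_b,
                size_kb=size_kb,
            )
        )
    intervals.sort(key=lambda iv: iv.ordinal_span)
    return intervals


def _gap_size_kb(table: LocationProfileTable, i_prox: int, i_dist: int) -> Optional[float]:
    """Physical size of the flank-to-flank gap, if every marker in it has a
    band count; otherwise None."""
    span = table.rows[i_prox : i_dist + 1]
    if any(r.band_count is None for r in span):
        return None
    return physical_size(sum(r.band_count for r in span))


def physical_size(band_count_sum: int, kb_per_band: float = KB_PER_BAND) -> float:
    """Convert a consensus-fingerprint band count to kilobases (1.5 kb/band)."""
    if band_count_sum < 0:
        raise ValueError("band count must be non-negative")
    return band_count_sum * kb_per_band


@dataclass(frozen=True)
class GeneAnnotation:
    """An annotated gene inside a breakpoint interval: id, reference ordinal
    (fractional ordinals allowed for genes between markers) and its query
    arm hit set."""

    gene_id: str
    ordinal: float
    arms: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "arms", frozenset(self.arms))


def delimit_by_gene_pair(
    interval: BreakpointInterval, annotations: Sequence[GeneAnnotation]
) -> BreakpointInterval:
    """Refine a marker-delimited interval to its innermost discordant gene pair.

    Each annotated gene is assigned to the proximal or distal side by the
    side-specific arms of the interval's flanks (arms unique to one side);
    the interval is narrowed to the last proximal-side gene before the first
    distal-side gene.  If all annotations are concordant the interval is
    returned unchanged.
    """
    if any(b.ordinal <= a.ordinal for a, b in zip(annotations, annotations[1:])):
        raise ValueError("annotations must be ordered by ordinal")
    prox_specific = interval.proximal_query_arms - interval.distal_query_arms
    dist_specific = interval.distal_query_arms - interval.proximal_query_arms
    sides: list[Optional[str]] = []
    for ann in annotations:
        p, d = bool(ann.arms & prox_specific), bool(ann.arms & dist_specific)
        sides.append("P" if p and not d else "D" if d and not p else None)
    informative = [(ann, s) for ann, s in zip(annotations, sides) if s is not None]
    first_d = next((k for k, (_, s) in enumerate(informative) if s == "D"), None)
    if first_d is None or first_d == 0:
        return interval  # no transition within the annotation set
    if any(s == "P" for _, s in informative[first_d:]):
        return interval  # assignments are not a clean P->D transition
    prox_gene = informative[first_d - 1][0]
    dist_gene = informative[first_d][0]
    return BreakpointInterval(
        reference_arm=interval.reference_arm,
        query_taxon=interval.query_taxon,
        proximal_flank=prox_gene.gene_id,
        distal_flank=dist_gene.gene_id,
        ordinal_span=(prox_gene.ordinal, dist_gene.ordinal),
        proximal_query_arms=prox_gene.arms,
        distal_query_arms=dist_gene.arms,
        proximal_consensus_arm=interval.proximal_consensus_arm,
        distal_consensus_arm=interval.distal_consensus_arm,
        size_kb=interval.size_kb,
    )


# ---------------------------------------------------------------------------
# collinear block chaining


@dataclass
class CollinearBlock:
    """A maximal run of shared genes whose outgroup positions step by +1
    (``same``) or -1 (``reversed``).  Single-gene blocks are flagged as
    possible transpositions.  ``ref_indices``/``out_indices`` record the
    per-gene positions behind ``ref_range``/``out_range`` (reference
    indices of block members need not be contiguous when intervening genes
    are absent from the outgroup)."""

    genes: list[str]
    ref_range: tuple[int, int]  # first/last index in the reference order
    out_range: tuple[int, int]  # first/last index in the outgroup order
    strand: str  # "same" | "reversed"
    possible_transposition: bool = False
    ref_indices: Optional[list[int]] = None
    out_indices: Optional[list[int]] = None

    def __len__(self) -> int:
        return len(self.genes)


#: One shared gene in the chaining walk: (reference index, gene id, outgroup index).
WalkItem = tuple[int, str, int]


def _chain_walk(walk: Sequence[WalkItem]) -> list[CollinearBlock]:
    """Greedy left-to-right chaining of a shared-gene walk (reference order)."""
    blocks: list[CollinearBlock] = []
    cur: list[WalkItem] = []
    cur_dir: Optional[int] = None

    def close() -> None:
        nonlocal cur, cur_dir
        if not cur:
            return
        strand = "reversed" if cur_dir == -1 else "same"
        blocks.append(
            CollinearBlock(
                genes=[g for _, g, _ in cur],
                ref_range=(cur[0][0], cur[-1][0]),
                out_range=(cur[0][2], cur[-1][2]),
                strand=strand,
                possible_transposition=len(cur) == 1,
                ref_indices=[r for r, _, _ in cur],
                out_indices=[o for _, _, o in cur],
            )
        )
        cur, cur_dir = [], None

    for item in walk:
        if not cur:
            cur.append(item)
            continue
        step = item[2] - cur[-1][2]
        if step in (1, -1) and cur_dir in (None, step):
            cur.append(item)
            cur_dir = step
        else:
            close()
            cur.append(item)
    close()
    return blocks


def _order_ids(order: Sequence) -> list[str]:
    """Accept plain gene ids or (gene_id, orientation) pairs."""
    out = []
    for x in order:
        out.append(x[0] if isinstance(x, (tuple, list)) else str(x))
    return out


def chain_collinear_blocks(
    reference_order: Sequence, outgroup_order: Sequence
) -> list[CollinearBlock]:
    """Greedy left-to-right chaining of shared genes into collinear blocks.

    Genes absent from either order are ignored.  Walking the shared genes in
    reference order, a block extends while the outgroup index steps by +1
    (same strand) or -1 (reversed); any other step closes the block.  The
    blocks partition the shared-gene set.
    """
    ref_ids = _order_ids(reference_order)
    out_ids = _order_ids(outgroup_order)
    out_index = {g: i for i, g in enumerate(out_ids)}
    walk = [(i, g, out_index[g]) for i, g in enumerate(ref_ids) if g in out_index]
    return _chain_walk(walk)


def ancient_junction_overlap(
    breakpoint: BreakpointInterval, blocks: Sequence[CollinearBlock]
) -> str:
    """Test whether a breakpoint coincides with an ancestral block junction.

    An ordinal gap ``(p, d)`` admits the cut sites ``{p, ..., d-1}`` (cut
    after index ``i``).  The breakpoint is ``"coincident"`` iff its cut-site
    set intersects that of the gap between two adjacent collinear blocks,
    i.e. no marker separates the breakpoint from the ancestral junction.
    Block coordinates and marker ordinals must be on the same reference
    scale.
    """
    p, d = breakpoint.ordinal_span
    for a, b in zip(blocks, blocks[1:]):
        left, right = a.ref_range[1], b.ref_range[0]
        if p < right and left < d:
            return "coincident"
    return "not_coincident"
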