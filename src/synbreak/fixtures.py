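"""Curated mini-region fixture for the Triticeae 4L/5L translocation.

The fixture encodes the published gene panels of the 4L and 5L breakpoint
regions as ordered gene arrangements for five diploid genomes (wheat A,
*T. monococcum* A\\ :sup:`m`, *A. tauschii* D, rye R, barley H), the
Triticeae phylogeny with carrier states for the translocation, and the
segment anatomy of the sequenced 4AL translocation junctions.

The D genome is the collinear, non-carrier reference: its 4DL and 5DL
orders stand in for the incipient (pre-translocation) 4L and 5L arms.  The
rye 5RL/7RS and barley 4HL/5HL orders are *tentative*, deduced in the
source study from survey sequence and wheat-rye collinearity; the
``TENTATIVE_ARMS`` set records which.  Segment positions *inside* the 4AL
junction core (MITE and tandem-duplication placement) are schematic: only
the component lengths were published.
"""

from __future__ import annotations

from typing import Optional

from .core import ChromosomeArm, Genome, OrientedGene
from .collinearity import (
    GeneAnnotation,
    LocationProfileTable,
    MarkerRecord,
    ancient_junction_overlap,
    chain_collinear_blocks,
    profile_transition_scan,
)
from .junctions import JunctionModel, JunctionSegment, core_junction_length
from .recurrence import (
    CharacterStateTree,
    breakpoint_reuse_test,
    classify_event,
    min_changes_fitch,
    min_origins,
)


def _arm(arm_id: str, genes: list[tuple[str, str, str]]) -> ChromosomeArm:
    return ChromosomeArm(arm_id, [OrientedGene(g, f, o) for g, f, o in genes])


#: Family assignments; the PMEI-like genes are a single paralog family
#: derived from direct gene duplication.
_FAM = {
    "KDM": "KDM",
    "WD3L": "WD3L",
    "HLH": "HLH",
    "PINX1": "PINX1",
    "FBA1": "FBA1",
    "DAGK": "DAGK",
    "STK": "STK",
    "CCCH": "CCCH",
    "ASA1": "ASA1",
    "PMEI": "PMEI",
    "PMEIL1": "PMEI",
    "PMEIL2": "PMEI",
    "PLC3": "PLC3",
    "GAD1": "GAD1",
    "NC332": "NC332",
}


def _genes(spec: list[tuple[str, str]]) -> list[tuple[str, str, str]]:
    return [(g, _FAM[g], o) for g, o in spec]


def paper_genomes() -> dict[str, Genome]:
    """The five fixture genomes, restricted to the breakpoint-region panels.

    Gene ids are shared across genomes (orthologs); orientation on 5DL
    follows the published centromere-bound transcription of the
    ASA1/PMEI-family cluster; the wheat 5AL copy of HLH has orientation
    '?' (restructured; its fragment orientations were left undetermined).
    """
    d = Genome(
        "tauschii_D",
        {
            "4DL": _arm("4DL", _genes([
                ("KDM", "+"), ("WD3L", "+"), ("HLH", "+"), ("PINX1", "+"),
                ("FBA1", "+"), ("DAGK", "+"), ("STK", "+"),
            ])),
            "5DL": _arm("5DL", _genes([
                ("CCCH", "-"), ("ASA1", "-"), ("PMEIL2", "-"), ("PMEIL1", "-"),
                ("PMEI", "-"), ("PLC3", "+"), ("GAD1", "+"),
            ])),
        },
    )
    wheat = Genome(
        "wheat_A",
        {
            # incipient 4L proximal + translocated 5L distal segment
            "4AL": _arm("4AL", _genes([
                ("KDM", "+"), ("WD3L", "+"), ("PMEIL1", "-"), ("PMEI", "-"),
                ("PLC3", "+"), ("GAD1", "+"),
            ])),
            # incipient 5L proximal + translocated 4L distal segment
            "5AL": _arm("5AL", _genes([
                ("CCCH", "-"), ("ASA1", "-"), ("HLH", "?"), ("PINX1", "+"),
                ("DAGK", "+"), ("STK", "+"), ("FBA1", "+"),
            ])),
        },
    )
    mono = Genome(
        "monococcum_Am",
        {
            "4AmL": _arm("4AmL", _genes([
                ("KDM", "+"), ("WD3L", "+"), ("PMEIL1", "-"), ("PMEI", "-"),
                ("PLC3", "+"), ("GAD1", "+"),
            ])),
            "5AmL": _arm("5AmL", _genes([
                ("CCCH", "-"), ("ASA1", "-"), ("HLH", "+"), ("PINX1", "+"),
                ("DAGK", "+"), ("STK", "+"), ("FBA1", "+"),
            ])),
        },
    )
    rye = Genome(
        "rye_R",
        {
            # the rearranged 4RL (with the translocated 5L distal piece,
            # which in rye begins at GAD1) moved on to 7RS
            "7RS": _arm("7RS", _genes([("KDM", "+"), ("WD3L", "+"), ("GAD1", "+")])),
            "5RL": _arm("5RL", _genes([
                ("CCCH", "-"), ("ASA1", "-"), ("PMEI", "-"), ("PLC3", "+"),
                ("HLH", "+"), ("PINX1", "+"), ("FBA1", "+"), ("DAGK", "+"),
                ("STK", "+"),
            ])),
            # best rye hit of PMEIL1 is a chromosome-3 homolog
            "3RS": _arm("3RS", _genes([("PMEIL1", "-")])),
        },
    )
    barley = Genome(
        "barley_H",
        {
            # non-carrier, but with a tentative internal inversion
            # (HLH orientation inverted relative to the D genome)
            "4HL": _arm("4HL", _genes([
                ("KDM", "+"), ("WD3L", "+"), ("FBA1", "-"), ("PINX1", "-"),
                ("HLH", "-"), ("DAGK", "+"), ("STK", "+"),
            ])),
            # PLC3 relocated proximal to CCCH; PMEI lost; PMEIL distal
            "5HL": _arm("5HL", _genes([
                ("PLC3", "+"), ("CCCH", "-"), ("ASA1", "-"), ("PMEIL1", "-"),
                ("GAD1", "+"),
            ])),
        },
    )
    return {g.taxon: g for g in (d, wheat, mono, rye, barley)}


#: Arms whose gene order is tentative (survey-sequence or collinearity-deduced).
TENTATIVE_ARMS = frozenset({"5RL", "7RS", "3RS", "4HL", "5HL"})

#: Rooted Triticeae phylogeny (branch lengths ~ MY): barley diverged 11 MYA,
#: rye 7 MYA, Triticum/Aegilops 1.4 MYA.
PAPER_TREE = (
    "((((wheat_A:0.8,monococcum_Am:0.8):0.6,"
    "(tauschii_D:1.0,speltoides_S:1.0):0.4):5.6,rye_R:7.0):4.0,barley_H:11.0);"
)

#: 4L/5L translocation carrier states; A. speltoides has no fixture genome
#: but enters the character matrix as a non-carrier.
PAPER_TIP_STATES: dict[str, str] = {
    "wheat_A": "1",
    "monococcum_Am": "1",
    "tauschii_D": "0",
    "speltoides_S": "0",
    "rye_R": "1",
    "barley_H": "0",
}

#: Query arms of the two homoeologous groups under test, per query genome
#: (rye's 4L-derived material resides on 7RS).
CANDIDATE_ARMS: dict[str, frozenset[str]] = {
    "wheat_A": frozenset({"4AL", "5AL"}),
    "monococcum_Am": frozenset({"4AmL", "5AmL"}),
    "rye_R": frozenset({"7RS", "5RL"}),
    "barley_H": frozenset({"4HL", "5HL"}),
}


def urartu_4al_junction() -> JunctionModel:
    """Segment anatomy of the sequenced *T. urartu* 4AL translocation junction.

    The stop-to-stop interval is 2559 bp: the flanking 3' UTRs (706 bp of
    the 4L-side WD40-like gene, 235 bp of the 5L-side PMEI-like gene), a
    265-bp Stowaway MITE inserted after the *T. urartu*/*T. monococcum*
    split (lineage-specific), and the core junction sequence.  The split of
    the 1353-bp core around the MITE is schematic.
    """
    return JunctionModel(
        "Tu_4AL_junction",
        [
            JunctionSegment("WD3L_3UTR", "utr3", 706),
            JunctionSegment("core_proximal", "core", 900),
            JunctionSegment("Stowaway_MITE", "te_insertion", 265, lineage_specific=True),
            JunctionSegment("core_distal", "core", 453),
            JunctionSegment("PMEIL_3UTR", "utr3", 235),
        ],
    )


def monococcum_4al_junction() -> JunctionModel:
    """The *T. monococcum* 4AL junction (2506 bp): no MITE, but an 83-bp
    lineage-specific tandem duplication.  UTR lengths were published only
    for *T. urartu* and are reused here; the core split is schematic."""
    return JunctionModel(
        "Tm_4AL_junction",
        [
            JunctionSegment("WD3L_3UTR", "utr3", 706),
            JunctionSegment("core_proximal", "core", 700),
            JunctionSegment("tandem_dup_83", "tandem_duplication", 83, lineage_specific=True),
            JunctionSegment("core_distal", "core", 782),
            JunctionSegment("PMEIL_3UTR", "utr3", 235),
        ],
    )


#: Model-grass (outgroup) gene orders of the two breakpoint regions.  The 4L
#: region is two ancestrally-swapped blocks (HLH and FBA1 are
#: Triticeae-specific transpositions, absent here); the 5L region differs
#: from Triticeae by one inversion spanning the PMEI family and PLC3.
GRASS_4L_ORDER = ["PINX1", "DAGK", "STK", "KDM", "WD3L"]
GRASS_5L_ORDER = ["CCCH", "ASA1", "PLC3", "PMEI", "PMEIL1", "PMEIL2", "GAD1"]


def paper_profiles(
    genomes: Optional[dict[str, Genome]] = None,
) -> dict[str, LocationProfileTable]:
    """Location-profile tables for the 4DL and 5DL reference arms.

    Hits are exact-ortholog arm locations in each query genome (empty set
    where the gene was not detected, e.g. PMEIL2 in the A genomes or PMEI
    in barley)."""
    from .core import arm_location_of

    genomes = genomes or paper_genomes()
    ref = genomes["tauschii_D"]
    queries = ["wheat_A", "monococcum_Am", "rye_R", "barley_H"]
    tables = {}
    for ref_arm in ("4DL", "5DL"):
        rows = []
        for i, gene in enumerate(ref.arms[ref_arm].genes):
            hits = {}
            for q in queries:
                arm = arm_location_of(genomes[q], gene.gene_id)
                hits[q] = frozenset() if arm is None else frozenset({arm})
            rows.append(MarkerRecord(gene.gene_id, i, hits))
        tables[ref_arm] = LocationProfileTable(ref_arm, rows, reference_taxon="tauschii_D")
    return tables


def run_paper_demo(min_run: int = 1, nearby_threshold: int = 5) -> dict:
    """Run the whole inference pipeline on the curated fixture.

    ``min_run`` defaults to 1 here (unlike the genome-wide default of 2)
    because the panels are curated and noise-free and the rye 5L distal run
    is a single gene at the panel edge.  Returns a JSON-serializable,
    deterministic summary.
    """
    genomes = paper_genomes()
    tables = paper_profiles(genomes)
    ref = genomes["tauschii_D"]
    ref_orders = {a: ref.arms[a].gene_ids() for a in ("4DL", "5DL")}

    breakpoints: dict[str, dict[str, dict]] = {}
    calls_by_taxon: dict[str, dict[str, list]] = {}
    for taxon in ("wheat_A", "rye_R", "barley_H"):
        calls_by_taxon[taxon] = {}
        breakpoints[taxon] = {}
        for ref_arm, table in tables.items():
            ivs = profile_transition_scan(
                table, taxon, min_run=min_run, candidate_arms=CANDIDATE_ARMS[taxon]
            )
            calls_by_taxon[taxon][ref_arm] = ivs
            breakpoints[taxon][ref_arm] = [
                {
                    "proximal_flank": iv.proximal_flank,
                    "distal_flank": iv.distal_flank,
                    "ordinal_span": list(iv.ordinal_span),
                }
                for iv in ivs
            ]

    # collinear blocks of each query arm against its reference order
    corresponding = {
        "wheat_A": {"4DL": "4AL", "5DL": "5AL"},
        "rye_R": {"4DL": "7RS", "5DL": "5RL"},
        "barley_H": {"4DL": "4HL", "5DL": "5HL"},
    }
    events = {}
    for taxon, arm_map in corresponding.items():
        blocks = {
            ref_arm: chain_collinear_blocks(
                ref_orders[ref_arm], genomes[taxon].arms[q_arm].gene_ids()
            )
            for ref_arm, q_arm in arm_map.items()
        }
        evs = classify_event(calls_by_taxon[taxon], blocks)
        events[taxon] = [
            {
                "etype": ev.etype.value,
                "arms": list(ev.arms),
                "breakpoints": list(ev.breakpoints),
                "payload": ev.payload,
            }
            for ev in evs
        ]

    # breakpoint reuse between the wheat and rye lineages
    reuse = {}
    for label, ref_arm in (("4L", "4DL"), ("5L", "5DL")):
        (wa,) = calls_by_taxon["wheat_A"][ref_arm]
        (ry,) = calls_by_taxon["rye_R"][ref_arm]
        v = breakpoint_reuse_test(wa, ry, ref_orders[ref_arm], nearby_threshold)
        reuse[label] = {
            "category": v.category,
            "gene_distance": v.gene_distance,
            "shared_proximal_flank": v.shared_proximal_flank,
            "shared_distal_flank": v.shared_distal_flank,
        }

    cst = CharacterStateTree.from_newick(PAPER_TREE, PAPER_TIP_STATES)
    parsimony = {
        "fitch_changes": min_changes_fitch(cst),
        "min_origins": min_origins(cst, root_state=0),
    }

    # coincidence of the translocation breakpoints with ancient inversion
    # junctions seen against the model-grass orders
    grass_blocks = {
        "4DL": chain_collinear_blocks(ref_orders["4DL"], GRASS_4L_ORDER),
        "5DL": chain_collinear_blocks(ref_orders["5DL"], GRASS_5L_ORDER),
    }
    ancient = {}
    for taxon in ("wheat_A", "rye_R"):
        for label, ref_arm in (("4L", "4DL"), ("5L", "5DL")):
            (iv,) = calls_by_taxon[taxon][ref_arm]
            ancient[f"{taxon}_{label}"] = ancient_junction_overlap(
                iv, grass_blocks[ref_arm]
            )

    ju = urartu_4al_junction()
    junction_lengths = {
        "urartu_4AL_total_bp": ju.total_length,
        "urartu_4AL_junction_bp": core_junction_length(ju, exclude_classes={"utr3"}),
        "initial_4AL_junction_bp": core_junction_length(
            ju, exclude_classes={"utr3"}, exclude_lineage_specific=True
        ),
    }

    return {
        "breakpoints": breakpoints,
        "events": events,
        "reuse": reuse,
        "parsimony": parsimony,
        "ancient_junction": ancient,
        "junction_lengths": junction_lengths,
        "thresholds": {"min_run": min_run, "nearby_threshold": nearby_threshold},
    }
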