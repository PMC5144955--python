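"""Simulation-based validation experiments and brute-force oracles.

These functions quantify how reliably the inference recovers simulated
ground truth: breakpoint bracketing under clean and noisy marker detection,
event-classifier accuracy per rearrangement type, and agreement of the
parsimony routines with exhaustive-labeling enumeration.  The oracles here
are deliberately naive, independent re-computations (exhaustive enumeration,
regular expressions) used to cross-check the efficient implementations.
"""

from __future__ import annotations

import itertools
import re
from typing import Optional

import numpy as np

from .core import EventType, Genome, RearrangementEvent
from .collinearity import chain_collinear_blocks, profile_transition_scan
from .junctions import scan_tracts
from .recurrence import CharacterStateTree, classify_event, min_changes_fitch, min_origins
from .simulate import (
    SimulationConfig,
    emit_location_profiles,
    evolve_on_tree,
    simulate_ancestral_genome,
    synthesize_junction_sequence,
)

_TWO_TIP_TREE = "(carrier:1.0,sister:1.0);"


def _trial_seed(master: np.random.Generator) -> int:
    return int(master.integers(2**31))


def _single_event_truth(
    event: RearrangementEvent, seed: int, genes_per_arm: int, miss_rate: float = 0.0
):
    config = SimulationConfig(
        seed=seed,
        n_arms=2,
        genes_per_arm=genes_per_arm,
        tree=_TWO_TIP_TREE,
        events_per_branch={"carrier": [event]},
        detection_miss_rate=miss_rate,
    )
    ancestor = simulate_ancestral_genome(config)
    return evolve_on_tree(ancestor, config), config


def translocation_recovery(
    n_trials: int = 200,
    seed: int = 0,
    detection_miss_rate: float = 0.0,
    min_run: int = 2,
    genes_per_arm: int = 20,
) -> dict:
    """Fraction of simulated reciprocal translocations whose true cuts are
    bracketed by the scanned breakpoint intervals on both arms.

    Cuts are drawn uniformly among positions leaving at least ``min_run``
    markers on each flank of each arm (a cut whose flanking run does not
    exist is undetectable by construction, not by failure of the scan).
    Under zero noise, success additionally requires the flanks to be exactly
    adjacent to the true cut.
    """
    master = np.random.default_rng([seed, 10])
    lo, hi = min_run - 1, genes_per_arm - 1 - min_run
    recovered = 0
    for _ in range(n_trials):
        c1 = int(master.integers(lo, hi + 1))
        c2 = int(master.integers(lo, hi + 1))
        event = RearrangementEvent(
            EventType.RECIPROCAL_TRANSLOCATION, ("1L", "2L"), (c1, c2)
        )
        truth, config = _single_event_truth(
            event, _trial_seed(master), genes_per_arm, detection_miss_rate
        )
        ok = True
        for arm, cut in (("1L", c1), ("2L", c2)):
            table = emit_location_profiles(truth, "sister", arm, config)
            calls = profile_transition_scan(table, "carrier", min_run=min_run)
            if len(calls) != 1:
                ok = False
                break
            p, d = calls[0].ordinal_span
            if detection_miss_rate == 0.0:
                ok = (p, d) == (cut, cut + 1)
            else:
                ok = p <= cut < d
            if not ok:
                break
        recovered += ok
    return {"n": n_trials, "recovered": recovered, "rate_pct": 100.0 * recovered / n_trials}


def _sample_single_event(
    etype: EventType, master: np.random.Generator, n: int, min_run: int
) -> RearrangementEvent:
    if etype is EventType.RECIPROCAL_TRANSLOCATION:
        lo, hi = min_run - 1, n - 1 - min_run
        return RearrangementEvent(
            etype,
            ("1L", "2L"),
            (int(master.integers(lo, hi + 1)), int(master.integers(lo, hi + 1))),
        )
    if etype is EventType.INVERSION:
        b1 = int(master.integers(-1, n - 2))
        b2 = int(master.integers(b1 + 2, n))
        return RearrangementEvent(etype, ("1L",), (b1, b2))
    if etype is EventType.TRANSPOSITION:
        while True:
            i = int(master.integers(0, n))
            t = int(master.integers(-1, n - 1))  # cut in the arm after excision
            if abs((t + 1) - i) >= 2:
                return RearrangementEvent(
                    etype, ("1L",), (t,), payload=f"g1L_{i:03d}"
                )
    raise ValueError(f"unsupported event type {etype}")


def classifier_accuracy(
    etype: EventType,
    n_trials: int = 200,
    seed: int = 0,
    genes_per_arm: int = 20,
    min_run: int = 2,
) -> dict:
    """Fraction of noise-free single-event simulations for which the event
    classifier returns exactly one event of the true type (with the correct
    payload gene for transpositions).

    Simulated inversions span at least two genes; transpositions move a
    single gene at least two positions within its arm (shorter moves are
    not distinguishable from local inversions in gene-order data).
    """
    etype = EventType(etype)
    master = np.random.default_rng([seed, 20])
    correct = 0
    for _ in range(n_trials):
        event = _sample_single_event(etype, master, genes_per_arm, min_run)
        truth, config = _single_event_truth(event, _trial_seed(master), genes_per_arm)
        sister = truth.tip_genomes["sister"]
        carrier = truth.tip_genomes["carrier"]
        calls, blocks = {}, {}
        for arm in ("1L", "2L"):
            table = emit_location_profiles(truth, "sister", arm, config)
            calls[arm] = profile_transition_scan(table, "carrier", min_run=min_run)
            blocks[arm] = chain_collinear_blocks(
                sister.arms[arm].gene_ids(), carrier.arms[arm].gene_ids()
            )
        events = classify_event(calls, blocks)
        ok = len(events) == 1 and events[0].etype is etype
        if ok and etype is EventType.TRANSPOSITION:
            ok = events[0].payload == event.payload
        correct += ok
    return {"n": n_trials, "correct": correct, "rate_pct": 100.0 * correct / n_trials}


# ---------------------------------------------------------------------------
# exhaustive-labeling parsimony oracles


def _random_topology(labels: list[str], rng: np.random.Generator) -> str:
    if len(labels) == 1:
        return labels[0]
    k = int(rng.integers(1, len(labels)))
    return f"({_random_topology(labels[:k], rng)},{_random_topology(labels[k:], rng)})"


def exhaustive_parsimony(
    cst: CharacterStateTree, root_state: Optional[int] = None, allow_losses: bool = True
) -> int:
    """Brute-force minimum over all node labelings (internal nodes and
    resolutions of ambiguous tips) of the number of counted changes.

    With ``root_state=None`` and ``allow_losses=True`` every change counts
    (the Fitch length); with a fixed root state only 0->1 edges count, and
    ``allow_losses=False`` rejects labelings containing any 1->0 edge (the
    independent-origins count).
    """
    nodes = list(cst.tree.preorder_node_iter())
    free = []
    fixed: dict[int, int] = {}
    for node in nodes:
        if node.is_leaf():
            states = cst.tip_states[node.taxon.label]
            if len(states) == 1:
                fixed[id(node)] = next(iter(states))
            else:
                free.append(node)
        else:
            free.append(node)
    best = None
    for combo in itertools.product((0, 1), repeat=len(free)):
        labels = dict(fixed)
        labels.update({id(n): s for n, s in zip(free, combo)})
        if root_state is not None and labels[id(cst.tree.seed_node)] != root_state:
            continue
        cost = 0
        valid = True
        for node in nodes:
            if node.parent_node is None:
                continue
            s_parent, s_child = labels[id(node.parent_node)], labels[id(node)]
            if s_parent == 1 and s_child == 0 and not allow_losses:
                valid = False
                break
            if root_state is None:
                cost += s_parent != s_child
            else:
                cost += s_parent == 0 and s_child == 1
        if valid and (best is None or cost < best):
            best = cost
    if best is None:
        raise ValueError("no labeling satisfies the constraints")
    return best


def parsimony_oracle_agreement(n_trials: int = 500, seed: int = 0, max_tips: int = 8) -> dict:
    """Agreement of the Fitch and min-origins routines with the exhaustive
    oracle on random topologies with random (possibly ambiguous) tip states."""
    rng = np.random.default_rng([seed, 30])
    agree = 0
    for _ in range(n_trials):
        n_tips = int(rng.integers(2, max_tips + 1))
        labels = [f"t{i}" for i in range(n_tips)]
        newick = _random_topology(labels, rng) + ";"
        states = {
            lab: ("0", "1", "ambiguous")[rng.choice(3, p=[0.4, 0.4, 0.2])]
            for lab in labels
        }
        cst = CharacterStateTree.from_newick(newick, states)
        ok = min_changes_fitch(cst) == exhaustive_parsimony(cst)
        ok = ok and min_origins(cst, 0) == exhaustive_parsimony(
            cst, root_state=0, allow_losses=False
        )
        ok = ok and min_origins(cst, 0, allow_losses=True) == exhaustive_parsimony(
            cst, root_state=0, allow_losses=True
        )
        agree += ok
    return {"n": n_trials, "agree": agree, "rate_pct": 100.0 * agree / n_trials}


# ---------------------------------------------------------------------------
# tract scanner oracle + generator/scanner round trip


def regex_tract_oracle(sequence: str, min_len: int = 6) -> list[tuple[int, int, str]]:
    """(start, length, base) of maximal A/T runs >= min_len, by regex."""
    pat = re.compile(rf"A{{{min_len},}}|T{{{min_len},}}")
    return [(m.start(), m.end() - m.start(), m.group()[0]) for m in pat.finditer(sequence.upper())]


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def tract_scanner_agreement(n_trials: int = 1000, seed: int = 0, min_len: int = 6) -> dict:
    """Scanner vs regex oracle on random sequences (50-5000 bp, GC 0.2-0.8)."""
    rng = np.random.default_rng([seed, 40])
    agree = 0
    for _ in range(n_trials):
        length = int(rng.integers(50, 5001))
        gc = float(rng.uniform(0.2, 0.8))
        seq = random_sequence(rng, length, gc)
        found = [(t.start, t.length, t.base) for t in scan_tracts(seq, min_len).tracts]
        agree += found == regex_tract_oracle(seq, min_len)
    return {"n": n_trials, "agree": agree, "rate_pct": 100.0 * agree / n_trials}


def tract_roundtrip(
    seed: int = 0, length: int = 2500, enrichment: float = 18.4
) -> dict:
    """Synthesize a junction at a target poly(dA:dT) frequency and re-measure
    it with the scanner."""
    from .junctions import JunctionModel, JunctionSegment, frequency_per_kb

    model = JunctionModel(
        "synthetic_junction", [JunctionSegment("whole", "core", length)]
    )
    config = SimulationConfig(seed=seed, tract_enrichment=enrichment)
    seq = synthesize_junction_sequence(model, config)
    measured = frequency_per_kb(scan_tracts(seq))
    return {
        "target_per_kb": enrichment,
        "measured_per_kb": measured,
        "length_bp": length,
    }
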