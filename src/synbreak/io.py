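"""Readers and writers for the package's on-disk formats.

Internally everything is 0-based; BED output is 0-based half-open and GFF3
output is 1-based inclusive, converted only at this boundary.  Every writer
here has a matching reader that recovers the fields losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    BreakpointInterval,
    ChromosomeArm,
    Genome,
    OrientedGene,
    RearrangementEvent,
)
from .collinearity import LocationProfileTable, MarkerRecord
from .junctions import JunctionModel, JunctionSegment, Tract, TractProfile

PathLike = Union[str, Path]

GENOME_COLUMNS = ["taxon", "arm_id", "ordinal", "gene_id", "family_id", "orientation"]


# ---------------------------------------------------------------------------
# genomes as TSV


def write_genomes_tsv(genomes: Iterable[Genome], path: PathLike) -> None:
    rows = []
    for g in genomes:
        for arm_id in g.arm_ids():
            for i, gene in enumerate(g.arms[arm_id].genes):
                rows.append((g.taxon, arm_id, i, gene.gene_id, gene.family_id, gene.orientation))
    df = pd.DataFrame(rows, columns=GENOME_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_genomes_tsv(path: PathLike) -> dict[str, Genome]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(GENOME_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"genome table {path} lacks columns {sorted(missing)}")
    df["ordinal"] = df["ordinal"].astype(int)
    genomes: dict[str, Genome] = {}
    for taxon, tdf in df.groupby("taxon", sort=False):
        arms = {}
        for arm_id, adf in tdf.groupby("arm_id", sort=False):
            adf = adf.sort_values("ordinal")
            genes = [
                OrientedGene(r.gene_id, r.family_id, r.orientation)
                for r in adf.itertuples()
            ]
            arms[arm_id] = ChromosomeArm(arm_id, genes)
        genomes[taxon] = Genome(taxon, arms)
    return genomes


# ---------------------------------------------------------------------------
# event logs as JSON


def write_event_log(
    event_log: Mapping[str, Sequence[RearrangementEvent]], path: PathLike
) -> None:
    payload = {
        branch: [
            {
                "etype": ev.etype.value,
                "arms": list(ev.arms),
                "breakpoints": list(ev.breakpoints),
                "payload": ev.payload,
            }
            for ev in events
        ]
        for branch, events in event_log.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_event_log(path: PathLike) -> dict[str, list[RearrangementEvent]]:
    payload = json.loads(Path(path).read_text())
    return {
        branch: [
            RearrangementEvent(
                ev["etype"], tuple(ev["arms"]), tuple(ev["breakpoints"]), ev.get("payload")
            )
            for ev in events
        ]
        for branch, events in payload.items()
    }


# ---------------------------------------------------------------------------
# location profile tables as TSV

_FIXED_PROFILE_COLS = ["marker_id", "ref_arm", "ordinal", "band_count"]


def write_profile_tsv(table: LocationProfileTable, path: PathLike) -> None:
    taxa = table.query_taxa()
    rows = []
    for r in table.rows:
        row = {
            "marker_id": r.marker_id,
            "ref_arm": table.reference_arm,
            "ordinal": r.ordinal,
            "band_count": "" if r.band_count is None else r.band_count,
        }
        for t in taxa:
            row[t] = ",".join(sorted(r.hits.get(t, frozenset())))
        rows.append(row)
    pd.DataFrame(rows, columns=_FIXED_PROFILE_COLS + taxa).to_csv(
        path, sep="\t", index=False
    )


def read_profile_tsv(path: PathLike) -> LocationProfileTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_FIXED_PROFILE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"profile table {path} lacks columns {sorted(missing)}")
    taxa = [c for c in df.columns if c not in _FIXED_PROFILE_COLS]
    ref_arms = df["ref_arm"].unique()
    if len(ref_arms) != 1:
        raise ValueError(f"profile table {path} must describe one reference arm")
    rows = []
    for r in df.itertuples():
        hits = {}
        for t in taxa:
            raw = getattr(r, t)
            hits[t] = frozenset(raw.split(",")) if raw else frozenset()
        band = None if r.band_count == "" else int(r.band_count)
        rows.append(MarkerRecord(r.marker_id, int(r.ordinal), hits, band_count=band))
    return LocationProfileTable(ref_arms[0], rows)


# ---------------------------------------------------------------------------
# breakpoint calls as BED + JSON sidecar


def write_breakpoints(
    intervals: Sequence[BreakpointInterval], bed_path: PathLike, json_path: PathLike
) -> None:
    """BED: reference arm as sequence name, the flank-to-flank ordinal gap as
    a 0-based half-open interval.  The JSON sidecar carries the full call."""
    with open(bed_path, "w") as fh:
        for iv in intervals:
            p, d = iv.ordinal_span
            name = f"{iv.query_taxon}:{iv.proximal_flank}|{iv.distal_flank}"
            fh.write(f"{iv.reference_arm}\t{int(p)}\t{int(d)}\t{name}\n")
    payload = [
        {
            "reference_arm": iv.reference_arm,
            "query_taxon": iv.query_taxon,
            "proximal_flank": iv.proximal_flank,
            "distal_flank": iv.distal_flank,
            "ordinal_span": list(iv.ordinal_span),
            "proximal_query_arms": sorted(iv.proximal_query_arms),
            "distal_query_arms": sorted(iv.distal_query_arms),
            "proximal_consensus_arm": iv.proximal_consensus_arm,
            "distal_consensus_arm": iv.distal_consensus_arm,
            "size_kb": iv.size_kb,
        }
        for iv in intervals
    ]
    Path(json_path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_breakpoints(json_path: PathLike) -> list[BreakpointInterval]:
    payload = json.loads(Path(json_path).read_text())
    return [
        BreakpointInterval(
            reference_arm=d["reference_arm"],
            query_taxon=d["query_taxon"],
            proximal_flank=d["proximal_flank"],
            distal_flank=d["distal_flank"],
            ordinal_span=tuple(d["ordinal_span"]),
            proximal_query_arms=frozenset(d["proximal_query_arms"]),
            distal_query_arms=frozenset(d["distal_query_arms"]),
            proximal_consensus_arm=d.get("proximal_consensus_arm"),
            distal_consensus_arm=d.get("distal_consensus_arm"),
            size_kb=d.get("size_kb"),
        )
        for d in payload
    ]


# ---------------------------------------------------------------------------
# tract profiles as BED6 + density TSV


def write_tracts_bed(profile: TractProfile, seq_id: str, path: PathLike) -> None:
    with open(path, "w") as fh:
        for t in profile.tracts:
            name = "polyA" if t.base == "A" else "polyT"
            fh.write(f"{seq_id}\t{t.start}\t{t.end}\t{name}\t{t.length}\t+\n")


def read_tracts_bed(path: PathLike, sequence_length: int, min_len: int = 6) -> TractProfile:
    tracts = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        _, start, end, name, _, _ = line.split("\t")
        base = "A" if name == "polyA" else "T"
        tracts.append(Tract(int(start), int(end) - int(start), base))
    return TractProfile(sequence_length, tracts, min_len=min_len)


def write_density_tsv(density, bin_size: int, path: PathLike) -> None:
    df = pd.DataFrame(
        {"bin_start": [i * bin_size for i in range(len(density))], "density": list(density)}
    )
    df.to_csv(path, sep="\t", index=False)


def read_density_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# junction models as JSON; junction annotation as GFF3


def write_junction_model(model: JunctionModel, path: PathLike) -> None:
    payload = {
        "junction_id": model.junction_id,
        "segments": [
            {
                "label": s.label,
                "seg_class": s.seg_class,
                "length": s.length,
                "lineage_specific": s.lineage_specific,
            }
            for s in model.segments
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_junction_model(path: PathLike) -> JunctionModel:
    d = json.loads(Path(path).read_text())
    return JunctionModel(
        d["junction_id"],
        [
            JunctionSegment(
                s["label"], s["seg_class"], s["length"], s.get("lineage_specific", False)
            )
            for s in d["segments"]
        ],
    )


def write_junction_gff3(model: JunctionModel, path: PathLike) -> None:
    """Junction segments as GFF3 features (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    pos = 0  # 0-based running offset
    for i, s in enumerate(model.segments):
        start1, end1 = pos + 1, pos + s.length
        attrs = (
            f"ID=seg{i};Name={s.label};seg_class={s.seg_class};"
            f"lineage_specific={str(s.lineage_specific).lower()}"
        )
        lines.append(
            "\t".join(
                [
                    model.junction_id,
                    "synbreak",
                    "region",
                    str(start1),
                    str(end1),
                    ".",
                    ".",
                    ".",
                    attrs,
                ]
            )
        )
        pos += s.length
    Path(path).write_text("\n".join(lines) + "\n")


def read_junction_gff3(path: PathLike) -> JunctionModel:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, from_string=False
    )
    segments = []
    junction_id = None
    feats = sorted(db.all_features(), key=lambda f: f.start)
    for f in feats:
        junction_id = f.seqid
        segments.append(
            JunctionSegment(
                f.attributes["Name"][0],
                f.attributes["seg_class"][0],
                f.end - f.start + 1,
                f.attributes["lineage_specific"][0] == "true",
            )
        )
    if junction_id is None:
        raise ValueError(f"no features in {path}")
    return JunctionModel(junction_id, segments)


# ---------------------------------------------------------------------------
# FASTA / Newick / tip states


def write_fasta(records: Mapping[str, str], path: PathLike) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_newick(tree, path: PathLike) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def read_newick(path: PathLike):
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)


def write_tip_states(states: Mapping[str, object], path: PathLike) -> None:
    """Sidecar TSV: taxon, state in {0, 1, ambiguous}."""
    rows = []
    for taxon, st in states.items():
        if isinstance(st, (set, frozenset)):
            st = "ambiguous" if len(st) > 1 else str(next(iter(st)))
        rows.append((taxon, str(st)))
    pd.DataFrame(rows, columns=["taxon", "state"]).to_csv(path, sep="\t", index=False)


def read_tip_states(path: PathLike) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["taxon", "state"]:
        raise ValueError(f"tip-state table {path} must have columns taxon, state")
    return dict(zip(df["taxon"], df["state"]))
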