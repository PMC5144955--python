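"""Junction architecture accounting and poly(dA:dT) tract profiling.

A translocation *junction* is the fusion interval between the two genes
whose stop codons flank it.  Its printed anatomy is modelled as an ordered
list of labelled segments (3' UTRs, core junction sequence, TE insertions,
tandem duplications); subtracting segment classes recovers the derived
core-junction lengths (e.g. trimming the two 3' UTRs off a 2559-bp
stop-to-stop interval leaves the 1618-bp junction proper, and removing a
lineage-specific MITE dates the 1353-bp initial junction).

Poly(dA:dT) tracts -- homopolymeric runs of A, or of T, on the forward
strand -- are scanned as maximal runs of length >= 6 bp by default, and
their per-100-bp density profile and per-kb frequency summarize the
AT-tract landscape of a junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

SEGMENT_CLASSES = ("utr3", "core", "te_insertion", "tandem_duplication", "intergenic")


@dataclass(frozen=True)
class JunctionSegment:
    label: str
    seg_class: str
    length: int
    lineage_specific: bool = False

    def __post_init__(self) -> None:
        if self.seg_class not in SEGMENT_CLASSES:
            raise ValueError(f"unknown segment class {self.seg_class!r}")
        if self.length <= 0:
            raise ValueError("segment length must be positive")


@dataclass
class JunctionModel:
    """Ordered labelled segments of one junction interval."""

    junction_id: str
    segments: list[JunctionSegment]

    def __post_init__(self) -> None:
        self.segments = [
            s if isinstance(s, JunctionSegment) else JunctionSegment(*s)
            for s in self.segments
        ]

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)


def core_junction_length(
    model: JunctionModel,
    exclude_classes: Iterable[str] = (),
    exclude_lineage_specific: bool = False,
) -> int:
    """Total model length minus excluded segment classes (and, optionally,
    lineage-specific segments).  With nothing excluded this is the identity."""
    excl = set(exclude_classes)
    unknown = excl - set(SEGMENT_CLASSES)
    if unknown:
        raise ValueError(f"unknown segment classes {sorted(unknown)}")
    total = 0
    for seg in model.segments:
        if seg.seg_class in excl:
            continue
        if exclude_lineage_specific and seg.lineage_specific:
            continue
        total += seg.length
    return total


# ---------------------------------------------------------------------------
# tract scanning


@dataclass(frozen=True)
class Tract:
    """A maximal homopolymer run: 0-based start, length, and base (A or T)."""

    start: int
    length: int
    base: str

    @property
    def end(self) -> int:  # exclusive
        return self.start + self.length


@dataclass
class TractProfile:
    """Maximal poly(dA:dT) tracts of one sequence plus binning parameters."""

    sequence_length: int
    tracts: list[Tract]
    min_len: int = 6
    bin_size: int = 100

    def frequency_per_kb(self) -> float:
        return frequency_per_kb(self)

    def density(self) -> np.ndarray:
        return density_profile(self, self.bin_size)


_VALID = set("ACGTN")


def scan_tracts(sequence: str, min_len: int = 6) -> TractProfile:
    """Find maximal runs of A and maximal runs of T of length >= ``min_len``.

    The two base types are scanned separately on the forward strand (an
    A-run on one strand is a T-run on the other, so forward-only A and T
    runs capture both orientations of homopolymeric dA:dT); mixed A/T runs
    do not count.  N breaks runs.  Case-insensitive; characters outside
    {A,C,G,T,N} are an error.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seq = sequence.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    tracts: list[Tract] = []
    i, n = 0, len(seq)
    while i < n:
        b = seq[i]
        if b in "AT":
            j = i
            while j < n and seq[j] == b:
                j += 1
            if j - i >= min_len:
                tracts.append(Tract(i, j - i, b))
            i = j
        else:
            i += 1
    return TractProfile(sequence_length=n, tracts=tracts, min_len=min_len)


def density_profile(profile: TractProfile, bin_size: int = 100) -> np.ndarray:
    """Per-bin cumulative tract base count over tumbling windows.

    Bins tile ``[0, sequence_length)``; the last bin may be short.  A tract
    spanning a bin boundary contributes its per-base overlap to each bin,
    so the profile sums exactly to the total tract length.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n = profile.sequence_length
    n_bins = max((n + bin_size - 1) // bin_size, 0)
    dens = np.zeros(n_bins, dtype=int)
    for t in profile.tracts:
        first = t.start // bin_size
        last = (t.end - 1) // bin_size if t.length else first
        for b in range(first, last + 1):
            lo = max(t.start, b * bin_size)
            hi = min(t.end, (b + 1) * bin_size)
            dens[b] += hi - lo
    return dens


def frequency_per_kb(profile: TractProfile) -> float:
    """Number of tracts per kb of sequence."""
    if profile.sequence_length <= 0:
        raise ValueError("sequence length must be positive")
    return len(profile.tracts) * 1000.0 / profile.sequence_length
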