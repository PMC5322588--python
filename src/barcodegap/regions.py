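"""Split a complete ITS sequence into ITS1, 5.8S and ITS2.

The fungal ITS region is ITS1 + conserved 5.8S + ITS2.  Dedicated extractors
locate the 5.8S with profile models; this module uses a deliberately simpler,
exactly testable contract: the 5.8S is located by two short anchor motifs
(its first and last bases) matched by sliding-window Hamming distance with a
mismatch budget.  ITS1 is everything before the start anchor, 5.8S runs from
the start of the start anchor through the end of the end anchor, ITS2 is
everything after.

Failure to split (anchor absent, ambiguous, or an empty part) is a *value*
(``None``), not an exception: in the curation cascade an unsplittable record
is simply removed, mirroring how incomplete-ITS sequences drop out of a
barcode dataset.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError
from .records import RegionSet

#: Synthetic 158-bp stand-in for the conserved fungal 5.8S core, packaged as
#: a constant so that simulated sequences and the default anchor motifs agree
#: exactly.  It is a fixed arbitrary sequence, not any organism's 5.8S.
S58_CORE = (
    "GCGTTAGAGTTACCCATGTTGGGCTTGCTCGGGTGTACGAAGCACGTATACTTACCAATC"
    "TCTATCTCATGTAGGAGCTGGATGTCCTGCTTGGGTAGTACTTTATTAGAGTTGCATTCT"
    "AATAAGTTGATCTTAATTCTATGCCCCTGCCGGCTATC"
)

ANCHOR_LEN = 20


@dataclass(frozen=True)
class AnchorConfig:
    """Anchor motifs delimiting the 5.8S, plus a Hamming mismatch budget."""

    s58_start_motif: str = S58_CORE[:ANCHOR_LEN]
    s58_end_motif: str = S58_CORE[-ANCHOR_LEN:]
    max_mismatches: int = 2

    def __post_init__(self) -> None:
        if not self.s58_start_motif or not self.s58_end_motif:
            raise ConfigurationError("anchor motifs must be non-empty")
        if self.max_mismatches < 0:
            raise ConfigurationError("max_mismatches must be >= 0")


DEFAULT_ANCHORS = AnchorConfig()


def _best_hits(sequence: str, motif: str, max_mismatches: int) -> tuple[list[int], int]:
    """All offsets achieving the minimum Hamming distance <= budget.

    Returns (offsets, best_distance); offsets is empty when no window fits
    the budget.  Vectorized sliding-window scan over byte arrays.
    """
    m = len(motif)
    if m > len(sequence):
        return [], max_mismatches + 1
    seq_arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    motif_arr = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(seq_arr, m)
    dists = (windows != motif_arr).sum(axis=1)
    best = int(dists.min())
    if best > max_mismatches:
        return [], best
    return [int(i) for i in np.flatnonzero(dists == best)], best


def _unambiguous_best(sequence: str, motif: str, max_mismatches: int) -> int | None:
    """Leftmost best hit, or None if absent or ambiguous.

    Ambiguous means two equally good *non-overlapping* hits (offsets apart by
    at least the motif length); overlapping equal hits collapse to the
    leftmost.
    """
    hits, _best = _best_hits(sequence, motif, max_mismatches)
    if not hits:
        return None
    if any(b - a >= len(motif) for a, b in zip(hits, hits[1:])) or (
        len(hits) > 1 and hits[-1] - hits[0] >= len(motif)
    ):
        return None
    return hits[0]


def split_its(sequence: str, anchors: AnchorConfig = DEFAULT_ANCHORS) -> RegionSet | None:
    """Partition a complete ITS sequence into (ITS1, 5.8S, ITS2).

    Returns ``None`` (failure, not an error) when either anchor motif is
    absent within the mismatch budget, ambiguous, out of order, or when any
    of the three parts would be empty.
    """
    if not sequence:
        raise InputError("cannot split an empty sequence")
    seq = sequence.upper()
    start = _unambiguous_best(seq, anchors.s58_start_motif, anchors.max_mismatches)
    if start is None:
        return None
    end = _unambiguous_best(seq, anchors.s58_end_motif, anchors.max_mismatches)
    if end is None:
        return None
    s58_lo = start
    s58_hi = end + len(anchors.s58_end_motif)
    if end < start + len(anchors.s58_start_motif):
        return None  # end anchor not after start anchor
    if s58_lo == 0 or s58_hi >= len(seq):
        return None  # ITS1 or ITS2 would be empty
    return RegionSet(
        its1=seq[:s58_lo],
        s58=seq[s58_lo:s58_hi],
        its2=seq[s58_hi:],
        coords=((0, s58_lo), (s58_lo, s58_hi), (s58_hi, len(seq))),
    )
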