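"""Pairwise global alignment and uncorrected p-distance matrices.

The evaluation statistic of this package (PCI, barcode-gap class) is built
on *uncorrected p-distances*: the proportion of differing sites between two
aligned sequences, with no substitution-model correction.  Per genus and per
marker we produce a symmetric matrix of such distances.

Alignment: a plain Needleman–Wunsch global aligner with linear gap cost
(match +1, mismatch -1, gap -2) and deterministic tie-breaking (prefer
diagonal, then up).  Pairwise alignment of each pair independently is the
default; a ``prealigned`` mode ingests an externally computed multiple
alignment (FASTA with gaps) and only applies the p-distance column rules,
for users who prefer a dedicated MSA tool.

Gap columns are excluded pair-by-pair (pairwise deletion) by default; a
complete-deletion switch is available on the matrix builder.

The inner DP loop is JIT-compiled with numba when available and falls back
to pure Python otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, UndefinedDistanceError
from .records import SpecimenRecord, UNAMBIGUOUS

GAP = ord("-")


@dataclass(frozen=True)
class AlignParams:
    match: int = 1
    mismatch: int = -1
    gap: int = -2


DEFAULT_PARAMS = AlignParams()


def _nw_fill(a: np.ndarray, b: np.ndarray, match: int, mismatch: int, gap: int):
    """DP fill returning the traceback pointer matrix and final score.

    Pointers: 0 = diagonal, 1 = up (gap in b), 2 = left (gap in a); ties
    resolved in that priority order.
    """
    n, m = a.size, b.size
    score = np.empty((n + 1, m + 1), dtype=np.int64)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    for j in range(m + 1):
        score[0, j] = gap * j
        ptr[0, j] = 2
    for i in range(1, n + 1):
        score[i, 0] = gap * i
        ptr[i, 0] = 1
        ai = a[i - 1]
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + (match if ai == b[j - 1] else mismatch)
            up = score[i - 1, j] + gap
            left = score[i, j - 1] + gap
            best, p = diag, 0
            if up > best:
                best, p = up, 1
            if left > best:
                best, p = left, 2
            score[i, j] = best
            ptr[i, j] = p
    return ptr, score[n, m]


try:  # optional JIT; identical semantics either way
    from numba import njit

    _nw_fill = njit(cache=False)(_nw_fill)
except ImportError:  # pragma: no cover
    pass


def align_pair(
    a: str, b: str, params: AlignParams = DEFAULT_PARAMS
) -> tuple[str, str]:
    """Global (end-to-end) alignment of two unambiguous DNA sequences.

    Returns equal-length gapped strings.  Deterministic: on score ties the
    traceback prefers diagonal, then up.
    """
    if not a or not b:
        raise InputError("cannot align an empty sequence")
    for name, s in (("a", a), ("b", b)):
        if not set(s) <= UNAMBIGUOUS:
            raise InputError(f"sequence {name} contains non-ACGT characters")
    arr_a = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    ptr, _ = _nw_fill(
        arr_a, arr_b, np.int64(params.match), np.int64(params.mismatch), np.int64(params.gap)
    )
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = len(a), len(b)
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0 and i > 0 and j > 0:
            i -= 1
            j -= 1
            out_a.append(a[i])
            out_b.append(b[j])
        elif p == 1 and i > 0:
            i -= 1
            out_a.append(a[i])
            out_b.append("-")
        else:
            j -= 1
            out_a.append("-")
            out_b.append(b[j])
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def alignment_score(aligned_a: str, aligned_b: str, params: AlignParams = DEFAULT_PARAMS) -> int:
    """Score of an existing alignment under the linear gap model."""
    if len(aligned_a) != len(aligned_b):
        raise InputError("aligned sequences must have equal length")
    total = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            total += params.gap
        elif x == y:
            total += params.match
        else:
            total += params.mismatch
    return total


def p_distance(aligned_a: str, aligned_b: str) -> float:
    """Uncorrected p-distance under pairwise deletion of gap columns.

    mismatches / columns-where-both-have-a-base; raises
    :class:`UndefinedDistanceError` when no column is comparable.
    """
    if len(aligned_a) != len(aligned_b):
        raise InputError("aligned sequences must have equal length")
    comparable = 0
    mismatches = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            continue
        comparable += 1
        if x != y:
            mismatches += 1
    if comparable == 0:
        raise UndefinedDistanceError("no comparable (gap-free) columns")
    return mismatches / comparable


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric per-genus matrix of p-distances with (accession, species) labels."""

    labels: tuple[tuple[str, str], ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        v = self.values
        if v.shape != (n, n):
            raise InputError("matrix shape does not match labels")
        accessions = [a for a, _ in self.labels]
        if len(set(accessions)) != n:
            raise InputError("duplicate accessions in matrix labels")
        if len({s for _, s in self.labels}) < 2:
            raise InputError("matrix must cover >= 2 distinct species")
        if not np.allclose(v, v.T):
            raise InputError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise InputError("matrix diagonal must be zero")
        if v.min() < 0.0 or v.max() > 1.0:
            raise InputError("p-distances must lie in [0, 1]")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(s for _, s in self.labels)

    def __len__(self) -> int:
        return len(self.labels)


def genus_distance_matrix(
    records: list[SpecimenRecord],
    marker: str = "ITS",
    mode: str = "pairwise",
    params: AlignParams = DEFAULT_PARAMS,
    gap_columns: str = "pairwise",
) -> DistanceMatrix:
    """p-distance matrix over all records of one genus for one marker.

    ``mode='pairwise'`` aligns each pair independently with
    :func:`align_pair`; ``mode='prealigned'`` treats the record sequences as
    rows of an existing multiple alignment (equal lengths, '-' gaps allowed)
    and applies only the p-distance column rules.  ``gap_columns`` selects
    pairwise deletion (default) or ``'complete'`` deletion, which drops every
    column containing a gap in *any* sequence before all comparisons
    (prealigned mode only).
    """
    if len({r.genus for r in records}) != 1:
        raise InputError("records must all belong to one genus")
    if len({r.species_epithet for r in records}) < 2:
        raise InputError("need >= 2 distinct species to build a genus matrix")
    if mode not in ("pairwise", "prealigned"):
        raise InputError(f"unknown mode {mode!r}")
    if gap_columns not in ("pairwise", "complete"):
        raise InputError(f"unknown gap_columns policy {gap_columns!r}")

    if mode == "pairwise":
        seqs = [r.marker_sequence(marker) for r in records]
    else:
        seqs = [r.sequence for r in records]
        if len({len(s) for s in seqs}) != 1:
            raise InputError("prealigned mode requires equal-length rows")
        if gap_columns == "complete":
            cols = np.array([[c != "-" for c in s] for s in seqs]).all(axis=0)
            seqs = ["".join(np.array(list(s))[cols]) for s in seqs]

    n = len(records)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            if mode == "pairwise":
                ai, aj = align_pair(seqs[i], seqs[j], params)
            else:
                ai, aj = seqs[i], seqs[j]
            values[i, j] = values[j, i] = p_distance(ai, aj)
    labels = tuple((r.accession, r.species_epithet) for r in records)
    return DistanceMatrix(labels=labels, values=values)


def write_matrix_tsv(matrix: DistanceMatrix, path) -> None:
    """TSV with accession labels in the first row and column."""
    accs = [a for a, _ in matrix.labels]
    species = [s for _, s in matrix.labels]
    with open(path, "w") as fh:
        fh.write("accession\tspecies\t" + "\t".join(accs) + "\n")
        for acc, sp, row in zip(accs, species, matrix.values):
            fh.write(acc + "\t" + sp + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
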