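"""Read assignment to paralog references and abundance ratios.

Relative transcript abundance of two silk-gene paralogs is estimated by
assigning each RNA-seq read to its best-matching reference and taking
the ratio of read counts — over the whole gene, and restricted to the
3'-most window of coding sequence.  The windowed ratio is robust to
unequal gene lengths under heavy 3' bias of the sequencing libraries.

Assignment is an exhaustive ungapped scan: the placement with the
fewest mismatches over all references and offsets wins, with ties
broken by reference input order and then by leftmost offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .seqio import SequenceRecord

__all__ = ["ReadAssignment", "CountTable", "assign_reads", "count_reads", "abundance_ratio"]

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    reference_id: str  # or UNASSIGNED
    start: int  # offset on the reference; -1 when unassigned
    mismatches: int  # -1 when unassigned


@dataclass(frozen=True)
class CountTable:
    whole: dict[str, int]
    window: dict[str, int]
    total_reads: int
    window_size: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def assign_reads(
    reads: Sequence[SequenceRecord],
    references: Sequence[SequenceRecord],
    max_mismatch: int = 3,
    search_reverse: bool = False,
) -> list[ReadAssignment]:
    """Best ungapped placement of each read over all references.

    Forward orientation only by default; ``search_reverse`` also scans
    the reverse complement (mismatch ties prefer the forward hit).
    Reads with no placement within ``max_mismatch`` anywhere are
    returned as unassigned, as are reads longer than every reference.
    """
    ref_arrays = []
    for ref in references:
        fwd = _encode(ref.residues)
        ref_arrays.append((ref.id, fwd))
        if search_reverse:
            comp = ref.residues.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            ref_arrays.append((ref.id, _encode(comp)))

    out: list[ReadAssignment] = []
    for read in reads:
        q = _encode(read.residues)
        best: tuple[int, int, int] | None = None  # (mismatches, ref order, offset)
        for order, (_rid, arr) in enumerate(ref_arrays):
            if len(q) > len(arr):
                continue
            windows = sliding_window_view(arr, len(q))
            mm = np.count_nonzero(windows != q, axis=1)
            off = int(np.argmin(mm))
            m = int(mm[off])
            if m <= max_mismatch and (best is None or m < best[0]):
                best = (m, order, off)
        if best is None:
            out.append(ReadAssignment(read.id, UNASSIGNED, -1, -1))
        else:
            m, order, off = best
            out.append(ReadAssignment(read.id, ref_arrays[order][0], off, m))
    return out


def count_reads(
    assignments: Sequence[ReadAssignment],
    references: Sequence[SequenceRecord],
    read_length: int,
    window: int = 500,
) -> CountTable:
    """Whole-gene and 3'-window counts per reference.

    A read belongs to the 3' window when its placement overlaps the
    3'-most ``window`` coding bases by at least half the read length.
    """
    ref_len = {r.id: len(r.residues) for r in references}
    whole = {r.id: 0 for r in references}
    win = {r.id: 0 for r in references}
    for a in assignments:
        if a.reference_id == UNASSIGNED:
            continue
        whole[a.reference_id] += 1
        win_start = max(ref_len[a.reference_id] - window, 0)
        overlap = min(a.start + read_length, ref_len[a.reference_id]) - max(a.start, win_start)
        if overlap >= read_length / 2:
            win[a.reference_id] += 1
    return CountTable(whole=whole, window=win, total_reads=len(assignments), window_size=window)


def abundance_ratio(
    table: CountTable,
    numerator_ref: str,
    denominator_ref: str,
    mode: str = "whole",
) -> float | None:
    """Count ratio numerator/denominator; ``None`` when the denominator
    count is zero (undefined ratio, not an error)."""
    if mode not in ("whole", "window"):
        raise ValueError("mode must be 'whole' or 'window'")
    counts = table.whole if mode == "whole" else table.window
    num, den = counts[numerator_ref], counts[denominator_ref]
    if den == 0:
        return None
    return num / den
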