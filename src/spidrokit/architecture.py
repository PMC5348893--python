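"""Spacer detection, tandem-repeat detection, and repeat modularity.

Spidroin repetitive regions are interrupted by "spacers": Ser/Thr/Val-rich,
Gly/Ala-poor segments that are nearly identical in copy sequence within a
protein.  The repetitive region itself is organised into tandem (often
higher-order "ensemble") repeats whose period, copy number, and copy
identity vary widely among loci and species (periods from a handful of
residues to several hundred, 2 to tens of copies, copy identity roughly
0.8-0.97).  This module recovers both feature types from a bare protein
sequence.

The tandem-repeat detector is a seed-and-extend consensus method:
candidate periods are voted by recurring 4-mer spacings, each candidate is
extended copy-by-copy against a running consensus, and overlapping blocks
are resolved by score (copies x period x identity).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

from .seqio import Interval, SequenceRecord

__all__ = [
    "SpacerRegion",
    "RepeatBlock",
    "detect_spacers",
    "spacer_homogeneity",
    "find_tandem_repeats",
    "classify_modularity",
]


@dataclass(frozen=True)
class SpacerRegion:
    interval: Interval
    sequence: str
    gly_ala_fraction: float
    stv_fraction: float


@dataclass(frozen=True)
class RepeatBlock:
    interval: Interval
    period: int
    copies: float
    consensus: str
    mean_identity: float

    def score(self) -> float:
        return self.copies * self.period * self.mean_identity


def _ga_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("A")) / len(seq)


def detect_spacers(
    protein: SequenceRecord,
    n_margin: int = 150,
    c_margin: int = 100,
    window: int = 25,
    ga_ceiling: float = 0.25,
    min_len: int = 15,
    merge_gap: int = 5,
) -> list[SpacerRegion]:
    """Find Gly/Ala-poor spacer regions outside the terminal margins.

    A sliding window of length ``window`` moves over the non-terminal
    span; window start positions whose Gly+Ala fraction is <= ``ga_ceiling``
    are flagged, flagged windows are merged across gaps <= ``merge_gap``,
    each merged region is trimmed to the maximal sub-interval on which
    every covering window satisfies the ceiling, and regions shorter than
    ``min_len`` are dropped.
    """
    seq = protein.residues
    lo, hi = n_margin, len(seq) - c_margin
    if hi - lo < window:
        raise ValueError(
            f"protein length {len(seq)} too short for margins {n_margin}+{c_margin}"
        )
    flagged: list[int] = [
        s for s in range(lo, hi - window + 1)
        if _ga_fraction(seq[s : s + window]) <= ga_ceiling
    ]
    if not flagged:
        return []
    # merge flagged window starts whose gap exceeds merge_gap
    groups: list[list[int]] = [[flagged[0]]]
    for s in flagged[1:]:
        if s - groups[-1][-1] <= window + merge_gap:
            groups[-1].append(s)
        else:
            groups.append([s])
    out: list[SpacerRegion] = []
    for grp in groups:
        start, end = grp[0], grp[-1] + window
        start, end = max(start, lo), min(end, hi)
        if end - start < min_len:
            continue
        sub = seq[start:end]
        out.append(
            SpacerRegion(
                interval=Interval(start, end),
                sequence=sub,
                gly_ala_fraction=_ga_fraction(sub),
                stv_fraction=sum(sub.count(c) for c in "STV") / len(sub),
            )
        )
    return out


def spacer_homogeneity(spacers: list[SpacerRegion]) -> float | None:
    """Mean pairwise global-alignment identity; ``None`` when < 2 spacers."""
    from .phylo import global_align, alignment_identity

    if len(spacers) < 2:
        return None
    idents = []
    for i in range(len(spacers)):
        for j in range(i + 1, len(spacers)):
            aln = global_align(spacers[i].sequence, spacers[j].sequence)
            idents.append(alignment_identity(aln))
    return sum(idents) / len(idents)


def _candidate_periods(seq: str, min_period: int, max_period: int, k: int = 4) -> list[int]:
    """Periods voted by spacings between recurrences of the same k-mer."""
    positions: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        positions[seq[i : i + k]].append(i)
    votes: Counter[int] = Counter()
    for pos in positions.values():
        for a, b in zip(pos, pos[1:]):
            d = b - a
            if min_period <= d <= max_period:
                votes[d] += 1
    return [p for p, _ in votes.most_common(40)]


def _window_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(x == y for x, y in zip(a[:n], b[:n])) / n


def _consensus(copies: list[str], period: int) -> str:
    cols = []
    for i in range(period):
        col = Counter(c[i] for c in copies if i < len(c))
        cols.append(col.most_common(1)[0][0] if col else "X")
    return "".join(cols)


def _extend_block(
    seq: str, start: int, period: int, min_identity: float
) -> tuple[int, list[str]] | None:
    """Grow full period-length copies rightward from ``start`` against a
    running consensus; returns (end of full copies, copy list)."""
    first = seq[start : start + period]
    if len(first) < period:
        return None
    copies = [first]
    end = start + period
    while end + period <= len(seq):
        nxt = seq[end : end + period]
        cons = _consensus(copies, period)
        if _window_identity(nxt, cons) < min_identity:
            break
        copies.append(nxt)
        end += period
    if len(copies) < 2:
        return None
    return end, copies


def _canonical_period(cons: str, period: int, min_period: int, min_identity: float) -> int:
    """Smallest divisor of ``period`` at which the consensus repeats
    itself (lag self-identity >= min_identity); guards against locking
    onto a harmonic of the true repeat unit."""
    for q in range(min_period, period):
        if period % q:
            continue
        if _window_identity(cons[: period - q], cons[q:]) >= min_identity:
            return q
    return period


def _best_phase_block(
    seq: str, pos: int, period: int, min_identity: float
) -> tuple[int, int, list[str]] | None:
    """Extend from every start phase in [pos, pos + period) and keep the
    longest block; anchors may sit a few residues before the true array,
    so the phase with the cleanest copies wins."""
    best = None
    for delta in range(period):
        s = pos + delta
        if _window_identity(seq[s : s + period], seq[s + period : s + 2 * period]) < min_identity:
            continue
        grown = _extend_block(seq, s, period, min_identity)
        if grown is None:
            continue
        end, copies = grown
        if best is None or end - (pos + delta) > best[1] - best[0]:
            best = (pos + delta, end, copies)
    return best


def find_tandem_repeats(
    protein: SequenceRecord,
    min_period: int = 5,
    max_period: int = 600,
    min_copies: float = 2,
    min_identity: float = 0.70,
) -> list[RepeatBlock]:
    """Detect tandem-repeat blocks by seeded consensus extension.

    The final partial copy is counted fractionally and appended when it
    matches the consensus prefix at ``min_identity``.  Overlapping blocks
    are resolved greedily, keeping the higher copies x period x identity
    score.
    """
    seq = protein.residues
    raw: list[RepeatBlock] = []
    for period in _candidate_periods(seq, min_period, min(max_period, len(seq) // 2)):
        pos = 0
        while pos + 2 * period <= len(seq):
            # cheap anchor test before consensus extension
            if _window_identity(seq[pos : pos + period], seq[pos + period : pos + 2 * period]) < min_identity:
                pos += 1
                continue
            found = _best_phase_block(seq, pos, period, min_identity)
            if found is None:
                pos += 1
                continue
            start, end, copies = found
            cons = _consensus(copies, period)
            period_eff = period
            # collapse harmonics: re-extend at the fundamental period
            q = _canonical_period(cons, period, min_period, min_identity)
            if q != period:
                regrown = _best_phase_block(seq, start, q, min_identity)
                if regrown is not None and regrown[1] >= end - period:
                    period_eff = q
                    start, end, copies = regrown
                    cons = _consensus(copies, q)
            # fractional trailing copy
            tail = seq[end : end + period_eff]
            frac_len = 0
            if tail and _window_identity(tail, cons[: len(tail)]) >= min_identity:
                frac_len = len(tail)
            n_copies = len(copies) + frac_len / period_eff
            idents = [_window_identity(c, cons) for c in copies]
            if frac_len:
                idents.append(_window_identity(tail, cons[:frac_len]))
            mean_id = sum(idents) / len(idents)
            if n_copies >= min_copies and mean_id >= min_identity:
                raw.append(
                    RepeatBlock(
                        interval=Interval(start, end + frac_len),
                        period=period_eff,
                        copies=n_copies,
                        consensus=cons,
                        mean_identity=mean_id,
                    )
                )
            pos = max(end, pos + 1)
    # greedy overlap resolution by score
    raw.sort(key=lambda b: b.score(), reverse=True)
    kept: list[RepeatBlock] = []
    for blk in raw:
        if not any(blk.interval.overlaps(k.interval) for k in kept):
            kept.append(blk)
    kept.sort(key=lambda b: b.interval.start)
    return kept


def classify_modularity(blocks: list[RepeatBlock]) -> str:
    """Classify ensemble-repeat modularity of one protein.

    ``higher_order``: some block with period > 160 aa repeated at least
    once (>= 2 copies).  ``short_unit``: no such block, but some block of
    period <= 30 aa with > 10 copies.  Otherwise ``none``.
    """
    if any(b.period > 160 and b.copies >= 2 for b in blocks):
        return "higher_order"
    if any(b.period <= 30 and b.copies > 10 for b in blocks):
        return "short_unit"
    return "none"
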