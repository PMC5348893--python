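"""Motif-grammar annotation, composition, codon usage, and hydropathy.

Spidroin repetitive regions are dominated by a small vocabulary of amino
acid words: GGX (3₁-helix), poly-alanine runs A_n with n >= 4 and
alternating (GA)_n with n >= 2 (both beta-sheet forming), and GPG
(beta-spiral, associated with fiber extensibility).  This module finds
those words and quantifies them: the fraction of a protein covered by
GPG is the sequence-side variable of the structure-property regression.

Scanning semantics: within one motif class matches are greedy,
left-to-right, non-overlapping, and maximally extended (``AAAAA`` is one
run of 5, not two of 4).  Different classes are scanned independently
and may overlap each other.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import Interval, SequenceRecord

__all__ = [
    "MotifAnnotation",
    "CompositionProfile",
    "CodonUsageProfile",
    "MOTIF_CLASSES",
    "scan_motifs",
    "motif_coverage",
    "species_motif_average",
    "composition",
    "codon_usage",
    "hydropathy_profile",
    "format_percent",
]

MOTIF_CLASSES = ("GGX", "POLY_A", "GA_RUN", "GPG")


@dataclass(frozen=True)
class MotifAnnotation:
    motif_class: str
    interval: Interval
    matched: str

    def __post_init__(self) -> None:
        if self.motif_class not in MOTIF_CLASSES:
            raise ValueError(f"unknown motif class {self.motif_class!r}")
        if len(self.matched) != len(self.interval):
            raise ValueError("matched string length differs from interval length")


@dataclass(frozen=True)
class CompositionProfile:
    aa_fraction: dict[str, float]
    length: int


@dataclass(frozen=True)
class CodonUsageProfile:
    codon_count: dict[str, int]
    third_position_AT: dict[str, float]


def _scan_fixed_word(seq: str, length: int, predicate) -> list[Interval]:
    """Greedy left-to-right non-overlapping scan for fixed-length words."""
    out: list[Interval] = []
    i = 0
    n = len(seq)
    while i + length <= n:
        if predicate(seq[i : i + length]):
            out.append(Interval(i, i + length))
            i += length
        else:
            i += 1
    return out


def _scan_poly_a(seq: str, min_len: int = 4) -> list[Interval]:
    out: list[Interval] = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "A":
            j = i
            while j < n and seq[j] == "A":
                j += 1
            if j - i >= min_len:
                out.append(Interval(i, j))
            i = j
        else:
            i += 1
    return out


def _scan_ga_run(seq: str, min_units: int = 2) -> list[Interval]:
    """Maximal (GA)_n runs, n >= min_units; starts on G, whole units only."""
    out: list[Interval] = []
    i = 0
    n = len(seq)
    while i + 1 < n:
        if seq[i] == "G" and seq[i + 1] == "A":
            j = i
            while j + 1 < n and seq[j] == "G" and seq[j + 1] == "A":
                j += 2
            if (j - i) // 2 >= min_units:
                out.append(Interval(i, j))
            i = j
        else:
            i += 1
    return out


def scan_motifs(
    protein: SequenceRecord, classes: Iterable[str] = MOTIF_CLASSES
) -> list[MotifAnnotation]:
    """Annotate motif words on a protein; classes scanned independently.

    X in GGX is any amino acid, so GGG qualifies.  Results are sorted by
    (start, class).
    """
    if protein.alphabet != "protein":
        raise ValueError("scan_motifs requires a protein record")
    seq = protein.residues
    annotations: list[MotifAnnotation] = []
    for cls in classes:
        if cls == "GGX":
            ivs = _scan_fixed_word(seq, 3, lambda w: w[0] == "G" and w[1] == "G")
        elif cls == "GPG":
            ivs = _scan_fixed_word(seq, 3, lambda w: w == "GPG")
        elif cls == "POLY_A":
            ivs = _scan_poly_a(seq)
        elif cls == "GA_RUN":
            ivs = _scan_ga_run(seq)
        else:
            raise ValueError(f"unknown motif class {cls!r}")
        annotations.extend(
            MotifAnnotation(cls, iv, seq[iv.start : iv.end]) for iv in ivs
        )
    annotations.sort(key=lambda a: (a.interval.start, a.motif_class))
    return annotations


def motif_coverage(
    protein: SequenceRecord,
    motif_class: str,
    region: Interval | None = None,
) -> float:
    """Fraction of ``region`` (whole sequence if omitted) covered by a class."""
    if region is None:
        region = Interval(0, len(protein.residues))
    if len(region) == 0 or region.end > len(protein.residues):
        raise ValueError("empty or out-of-range region")
    covered = 0
    for ann in scan_motifs(protein, [motif_class]):
        lo = max(ann.interval.start, region.start)
        hi = min(ann.interval.end, region.end)
        if hi > lo:
            covered += hi - lo
    return covered / len(region)


def species_motif_average(
    proteins: Sequence[SequenceRecord], motif_class: str
) -> float:
    """Unweighted mean of per-sequence motif coverage across one species."""
    if not proteins:
        raise ValueError("no sequences supplied")
    return sum(motif_coverage(p, motif_class) for p in proteins) / len(proteins)


def format_percent(fraction: float) -> str:
    """Percent, rounded half away from zero to 2 decimals (e.g. 0.1279 -> '12.79')."""
    scaled = fraction * 10000.0
    rounded = math.floor(scaled + 0.5) if scaled >= 0 else math.ceil(scaled - 0.5)
    return f"{rounded / 100.0:.2f}"


def composition(protein: SequenceRecord) -> CompositionProfile:
    if protein.alphabet != "protein":
        raise ValueError("composition requires a protein record")
    counts = Counter(protein.residues)
    n = len(protein.residues)
    return CompositionProfile(
        aa_fraction={aa: c / n for aa, c in sorted(counts.items())}, length=n
    )


_CODON_TO_AA = {}
_BASES = "TCAG"
_AA_TABLE = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _CODON_TO_AA[_b1 + _b2 + _b3] = _AA_TABLE[16 * _i + 4 * _j + _k]


def codon_usage(cds: SequenceRecord) -> CodonUsageProfile:
    """Codon counts and per-amino-acid third-position A/T fraction.

    Codons containing ambiguity codes are skipped; the trailing partial
    codon is dropped.
    """
    if cds.alphabet != "nucleotide":
        raise ValueError("codon_usage requires a nucleotide record")
    seq = cds.residues.replace("U", "T")
    counts: Counter[str] = Counter()
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        if all(b in "ACGT" for b in codon):
            counts[codon] += 1
    by_aa: dict[str, list[int]] = {}
    for codon, c in counts.items():
        aa = _CODON_TO_AA[codon]
        at, total = by_aa.setdefault(aa, [0, 0])
        if codon[2] in "AT":
            by_aa[aa][0] = at + c
        by_aa[aa][1] = total + c
    third = {aa: at / total for aa, (at, total) in sorted(by_aa.items()) if total}
    return CodonUsageProfile(codon_count=dict(sorted(counts.items())), third_position_AT=third)


# Kyte & Doolittle residue hydropathy values.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def hydropathy_profile(
    protein: SequenceRecord, window: int = 7
) -> list[tuple[int, float]]:
    """Centered moving-average Kyte-Doolittle profile.

    Returns (position, score) for every position with a complete window;
    flanking positions with incomplete windows are omitted.
    """
    if protein.alphabet != "protein":
        raise ValueError("hydropathy requires a protein record")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    seq = protein.residues
    try:
        values = [KYTE_DOOLITTLE[c] for c in seq]
    except KeyError as exc:
        raise ValueError(f"no hydropathy value for residue {exc}") from exc
    half = window // 2
    out = []
    for center in range(half, len(seq) - half):
        score = sum(values[center - half : center + half + 1]) / window
        out.append((center, score))
    return out


def annotations_to_bed(
    protein: SequenceRecord, annotations: Iterable[MotifAnnotation]
) -> list[tuple[str, Interval, str]]:
    return [(protein.id, a.interval, a.motif_class) for a in annotations]


def profile_to_json(profile: CompositionProfile | CodonUsageProfile, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        json.dump(profile.__dict__, fh, indent=2, sort_keys=True)
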