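"""Sequence records, intervals, FASTA I/O, translation, and ORF finding.

All coordinates in this package are 0-based, half-open ``[start, end)``.
Spidroin coding sequences are deposited in coding orientation, so ORF
scanning is forward-strand by default; reverse-complement scanning is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SequenceRecord",
    "Interval",
    "read_fasta",
    "write_fasta",
    "translate",
    "find_longest_orf",
    "write_bed",
]

# IUPAC alphabets (uppercase).  Gap characters are rejected: records hold
# ungapped residues; alignments carry their own gapped strings.
NUCLEOTIDE_CHARS = set("ACGTURYSWKMBDHVN")
PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*")

Alphabet = Literal["nucleotide", "protein"]


@dataclass(frozen=True)
class Interval:
    """Half-open interval on a sequence: ``0 <= start < end``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass(frozen=True)
class SequenceRecord:
    """A named, ungapped nucleotide or protein sequence."""

    id: str
    alphabet: Alphabet
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        allowed = NUCLEOTIDE_CHARS if self.alphabet == "nucleotide" else PROTEIN_CHARS
        for pos, ch in enumerate(self.residues):
            if ch not in allowed:
                raise ValueError(
                    f"record {self.id!r}: non-IUPAC {self.alphabet} character "
                    f"{ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def subsequence(self, interval: Interval, id_suffix: str = "") -> "SequenceRecord":
        if interval.end > len(self.residues):
            raise ValueError("interval extends past end of sequence")
        return SequenceRecord(
            id=self.id + id_suffix,
            alphabet=self.alphabet,
            residues=self.residues[interval.start : interval.end],
        )


def _guess_alphabet(residues: str) -> Alphabet:
    # DNA-only character sets are a subset of the protein alphabet, so a
    # sequence is called nucleotide when >= 90% of residues are ACGTUN.
    core = sum(residues.count(c) for c in "ACGTUN")
    return "nucleotide" if core >= 0.9 * len(residues) else "protein"


def read_fasta(path: str | Path, alphabet: Alphabet | None = None) -> list[SequenceRecord]:
    """Read a multi-record FASTA file.

    Residues are uppercased and whitespace-stripped; record order is
    preserved.  ``alphabet`` may be forced; otherwise it is guessed per
    record from character content.

    Raises ``ValueError`` on an empty file, duplicate ids, or non-IUPAC
    characters.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper().replace(" ", "")
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        ab = alphabet if alphabet is not None else _guess_alphabet(residues)
        records.append(SequenceRecord(id=rec.id, alphabet=ab, residues=residues))
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA, wrapped at ``width`` columns."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def translate(cds: SequenceRecord, frame: int = 0) -> SequenceRecord:
    """Translate a nucleotide record with the standard genetic code.

    The trailing partial codon is dropped; stop codons render as ``*``;
    codons containing ambiguity render as ``X``.
    """
    if cds.alphabet != "nucleotide":
        raise ValueError(f"record {cds.id!r}: translation requires a nucleotide record")
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1, or 2")
    nt = cds.residues[frame:]
    nt = nt[: len(nt) - len(nt) % 3]
    if not nt:
        raise ValueError(f"record {cds.id!r}: no complete codon in frame {frame}")
    aa = str(Seq(nt).translate(table=1))
    # Biopython renders fully ambiguous codons as X already; normalise any
    # residual ambiguity codes to X for a clean protein alphabet.
    aa = "".join(c if c in "ACDEFGHIKLMNPQRSTVWY*" else "X" for c in aa)
    return SequenceRecord(id=cds.id, alphabet="protein", residues=aa)


_STOPS = {"TAA", "TAG", "TGA"}


def _orfs_forward(seq: str, min_len: int) -> list[Interval]:
    """All maximal ATG..stop intervals (stop included) in frames 0-2."""
    found: list[Interval] = []
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start is None and codon == "ATG":
                start = i
            elif start is not None and codon in _STOPS:
                if i + 3 - start >= min_len:
                    found.append(Interval(start, i + 3))
                start = None
    return found


def find_longest_orf(
    nt: SequenceRecord, min_len: int = 300, both_strands: bool = False
) -> Interval:
    """Locate the longest open reading frame (ATG to stop, stop included).

    Scans reading frames 0-2 of the forward strand; set ``both_strands``
    to also scan the reverse complement (interval reported in forward
    coordinates).  Raises ``ValueError`` if no ORF reaches ``min_len``.
    """
    if nt.alphabet != "nucleotide":
        raise ValueError("ORF search requires a nucleotide record")
    candidates = _orfs_forward(nt.residues, min_len)
    if both_strands:
        rc = str(Seq(nt.residues).reverse_complement())
        n = len(rc)
        for iv in _orfs_forward(rc, min_len):
            candidates.append(Interval(n - iv.end, n - iv.start))
    if not candidates:
        raise ValueError(f"record {nt.id!r}: no ORF of length >= {min_len} nt")
    return max(candidates, key=lambda iv: (len(iv), -iv.start))


def write_bed(
    annotations: Iterable[tuple[str, Interval, str]], path: str | Path
) -> None:
    """Export (seq id, interval, label) triples as BED-like TSV."""
    with open(Path(path), "w") as fh:
        for seq_id, iv, label in annotations:
            fh.write(f"{seq_id}\t{iv.start}\t{iv.end}\t{label}\n")
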