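"""Synthetic data generators with ground-truth logs.

Every input the pipeline consumes can be simulated here with the
statistical structure the analysis assumes: spidroin-like proteins
(conserved termini, a motif-grammar repeat array with near-identical
planted spacers), paralog families shaped by duplication, intergenic
gene conversion and slipped-strand expansion/contraction, 3'-biased
read sets at a known paralog abundance ratio, Brownian-motion trait
evolution on a tree, and noisy stiff-then-yielding tensile traces.

All generators draw from a single ``numpy.random.Generator`` seeded per
call and are bit-reproducible given (spec, seed).  Each generator ships
a truth record so that recovery tests compare pipeline output against
construction, never against other pipeline output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .seqio import Interval, SequenceRecord
from .tensile import TensileTrace

__all__ = [
    "SpidroinSpec",
    "EventLog",
    "generate_spidroin",
    "evolve_family",
    "generate_reads",
    "simulate_tensile",
    "analytic_tensile_properties",
    "simulate_bm_traits",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# codons per amino acid (standard code), split by third-base A/T vs G/C
_SYN = {
    "A": ["GCA", "GCT", "GCC", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGA", "GGT", "GGC", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATA", "ATT", "ATC"], "K": ["AAA", "AAG"],
    "L": ["TTA", "CTA", "CTT", "TTG", "CTC", "CTG"],
    "M": ["ATG"], "N": ["AAT", "AAC"], "P": ["CCA", "CCT", "CCC", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["AGA", "CGA", "CGT", "AGG", "CGC", "CGG"],
    "S": ["TCA", "TCT", "AGT", "TCC", "AGC", "TCG"],
    "T": ["ACA", "ACT", "ACC", "ACG"], "V": ["GTA", "GTT", "GTC", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}


@dataclass(frozen=True)
class SpidroinSpec:
    """Construction recipe for one synthetic spidroin.

    ``motif_mix`` gives target residue fractions of the repeat unit per
    motif class (GGX, POLY_A, GA_RUN, GPG); the remainder of each unit
    is serine linker.  Rates are per-site substitution probabilities
    applied per repeat copy / spacer copy / terminus.
    """

    n_term_len: int = 150
    c_term_len: int = 100
    motif_mix: Mapping[str, float] = field(
        default_factory=lambda: {"GGX": 0.30, "GA_RUN": 0.30, "POLY_A": 0.20, "GPG": 0.0}
    )
    repeat_period: int = 28
    repeat_copies: int = 12
    spacer_len: int = 30
    spacer_positions: tuple[int, ...] = ()  # insert a spacer after these copy indices
    repeat_rate: float = 0.0
    spacer_rate: float = 0.0
    terminal_rate: float = 0.0
    third_position_at_bias: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.motif_mix.values())
        if total > 1.0 + 1e-9 or any(w < 0 for w in self.motif_mix.values()):
            raise ValueError("motif weights must be >= 0 and sum to <= 1")
        for r in (self.repeat_rate, self.spacer_rate, self.terminal_rate):
            if not 0 <= r <= 0.5:
                raise ValueError("mutation rates must lie in [0, 0.5]")


@dataclass
class EventLog:
    """Ordered ground-truth record of simulated family events."""

    events: list[dict] = field(default_factory=list)

    def add(self, type: str, **kw) -> None:
        self.events.append({"type": type, **kw})

    def of_type(self, type: str) -> list[dict]:
        return [e for e in self.events if e["type"] == type]

    def to_jsonl(self, path: str | Path) -> None:
        with open(Path(path), "w") as fh:
            for ev in self.events:
                fh.write(json.dumps(ev) + "\n")


def _mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        choices = AA20.replace(chars[i], "")
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def _build_unit(spec: SpidroinSpec, rng: np.random.Generator) -> tuple[str, list[tuple[str, int, int]]]:
    """One clean repeat unit honouring the motif residue budget.

    Returns (unit string, list of (class, start, end) truth intervals
    local to the unit)."""
    period = spec.repeat_period
    words: list[tuple[str, str]] = []  # (class, word)
    for cls, weight in spec.motif_mix.items():
        budget = round(weight * period)
        while budget >= 3:
            if cls == "GGX":
                w = "GG" + "ASQY"[rng.integers(4)]
            elif cls == "GPG":
                w = "GPG"
            elif cls == "POLY_A":
                w = "A" * int(min(budget, rng.integers(4, 7)))
                if len(w) < 4:
                    break
            elif cls == "GA_RUN":
                w = "GA" * int(min(budget // 2, rng.integers(2, 5)))
                if len(w) < 4:
                    break
            else:
                raise ValueError(f"unknown motif class {cls!r}")
            words.append((cls, w))
            budget -= len(w)
    order = rng.permutation(len(words))
    unit = ""
    truth: list[tuple[str, int, int]] = []
    for idx in order:
        cls, w = words[idx]
        # separate consecutive run-type words with a serine so planted
        # instances stay maximal (A4 + A4 must not fuse into A8)
        if unit and truth and truth[-1][0] == cls and cls in ("POLY_A", "GA_RUN"):
            unit += "S"
        truth.append((cls, len(unit), len(unit) + len(w)))
        unit += w
    while len(unit) < period:
        unit += "S"
    return unit[:period], [t for t in truth if t[2] <= period]


def _spacer_sequence(length: int, rng: np.random.Generator) -> str:
    # Ser/Thr/Val-rich, Gly/Ala-free: the spacer compositional signature
    alphabet = "STV" * 3 + "QNED"
    return "".join(alphabet[rng.integers(len(alphabet))] for _ in range(length))


def _terminal_sequence(length: int, rng: np.random.Generator) -> str:
    # terminal domains are non-repetitive and not Gly/Ala-dominated
    alphabet = "LQERSKNADTIVFG"
    return "".join(alphabet[rng.integers(len(alphabet))] for _ in range(length))


def _back_translate(
    protein: str, at_bias: float, rng: np.random.Generator
) -> tuple[str, dict[str, int]]:
    codons: list[str] = []
    counts: dict[str, int] = {}
    for aa in protein:
        options = _SYN[aa]
        at = [c for c in options if c[2] in "AT"]
        gc = [c for c in options if c[2] in "GC"]
        if at and (not gc or rng.random() < at_bias):
            codon = at[rng.integers(len(at))]
        else:
            codon = gc[rng.integers(len(gc))]
        codons.append(codon)
        counts[codon] = counts.get(codon, 0) + 1
    return "".join(codons), counts


def generate_spidroin(
    spec: SpidroinSpec, seq_id: str = "synthetic_spidroin"
) -> tuple[SequenceRecord, SequenceRecord, dict]:
    """Build one spidroin protein + CDS with full truth annotations.

    Layout: N-terminus | (repeat copies with spacers planted after the
    copy indices in ``spacer_positions``) | C-terminus.  Truth holds the
    terminal/repeat/spacer intervals, the per-block repeat geometry, the
    planted motif intervals (positions as constructed, before mutation),
    and the codon counts of the back-translation.
    """
    rng = np.random.default_rng(spec.seed)
    unit, unit_truth = _build_unit(spec, rng)
    spacer = _spacer_sequence(spec.spacer_len, rng)
    n_term = _mutate_protein(_terminal_sequence(spec.n_term_len, rng), spec.terminal_rate, rng)
    c_term = _mutate_protein(_terminal_sequence(spec.c_term_len, rng), spec.terminal_rate, rng)

    parts: list[str] = [n_term]
    pos = len(n_term)
    motif_truth: list[tuple[str, int, int]] = []
    spacer_truth: list[Interval] = []
    blocks: list[dict] = []
    block_start, block_copies = pos, 0
    for copy_idx in range(spec.repeat_copies):
        copy = _mutate_protein(unit, spec.repeat_rate, rng)
        for cls, s, e in unit_truth:
            motif_truth.append((cls, pos + s, pos + e))
        parts.append(copy)
        pos += len(copy)
        block_copies += 1
        if copy_idx in spec.spacer_positions and copy_idx != spec.repeat_copies - 1:
            blocks.append(
                {"interval": Interval(block_start, pos), "period": spec.repeat_period,
                 "copies": block_copies}
            )
            sp = _mutate_protein(spacer, spec.spacer_rate, rng)
            spacer_truth.append(Interval(pos, pos + len(sp)))
            parts.append(sp)
            pos += len(sp)
            block_start, block_copies = pos, 0
    if block_copies:
        blocks.append(
            {"interval": Interval(block_start, pos), "period": spec.repeat_period,
             "copies": block_copies}
        )
    repeat_region = Interval(len(n_term), pos)
    parts.append(c_term)
    protein_seq = "".join(parts)

    cds_seq, codon_counts = _back_translate(protein_seq, spec.third_position_at_bias, rng)
    protein = SequenceRecord(id=seq_id, alphabet="protein", residues=protein_seq)
    cds = SequenceRecord(id=seq_id + "_cds", alphabet="nucleotide", residues=cds_seq)
    truth = {
        "n_term": Interval(0, len(n_term)),
        "c_term": Interval(pos, pos + len(c_term)),
        "repeat_region": repeat_region,
        "repeat_unit": unit,
        "repeat_blocks": blocks,
        "spacers": spacer_truth,
        "spacer_seq": spacer,
        "motifs": motif_truth,
        "codon_counts": codon_counts,
    }
    return protein, cds, truth


# ---------------------------------------------------------------------------
# gene-family simulation


def _substitute_nt(seq: list[str], n_events: int, rng: np.random.Generator) -> None:
    for _ in range(n_events):
        i = int(rng.integers(len(seq)))
        seq[i] = "ACGT".replace(seq[i], "")[rng.integers(3)]


def evolve_family(
    root_spec: SpidroinSpec,
    species_tree: dendropy.Tree,
    n_loci: int = 2,
    subst_rate: float = 1.0,
    root_divergence: float = 0.05,
    conversion_rate: float = 0.0,
    conversion_tract_len: int = 300,
    terminal_only: bool = True,
    slippage_rate: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, SequenceRecord], EventLog]:
    """Evolve a paralog family down a species tree at the CDS level.

    ``n_loci`` paralogs arise by duplication at the root; each is first
    diverged by ``root_divergence`` substitutions/site so paralogs are
    older than any speciation.  Along every branch, each locus receives
    Binomial(L, subst_rate x branch length) substitutions, then
    Poisson-distributed slippage events (duplicate or delete one repeat
    unit of coding sequence within the repeat region), then
    Poisson(conversion_rate x branch length) intergenic gene-conversion
    events copying a ``conversion_tract_len`` tract from one locus onto
    its paralog — restricted to the terminal-encoding regions when
    ``terminal_only`` (the concerted-evolution regime the terminal
    domains of real spidroin paralogs show).

    Returns sequences keyed ``"<species>|L<i>"`` and the event log.
    """
    rng = np.random.default_rng(seed)
    _, root_cds, _ = generate_spidroin(root_spec, "root")
    n_term_nt = 3 * root_spec.n_term_len
    c_term_nt = 3 * root_spec.c_term_len
    unit_nt = 3 * root_spec.repeat_period
    log = EventLog()

    loci: list[list[str]] = []
    for i in range(n_loci):
        seq = list(root_cds.residues)
        if i > 0:
            log.add("duplication", node="root", locus=i)
        n_mut = rng.binomial(len(seq), root_divergence)
        _substitute_nt(seq, int(n_mut), rng)
        loci.append(seq)

    _node_index = {nd: i for i, nd in enumerate(species_tree.preorder_node_iter())}

    def branch_label(node) -> str:
        return node.taxon.label if node.is_leaf() else f"node{_node_index[node]}"

    out: dict[str, SequenceRecord] = {}

    def descend(node, state: list[list[str]]) -> None:
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            child_state = [list(s) for s in state]
            for li, seq in enumerate(child_state):
                n_mut = rng.binomial(len(seq), min(subst_rate * bl, 0.75))
                _substitute_nt(seq, int(n_mut), rng)
                for _ in range(rng.poisson(slippage_rate * bl)):
                    lo, hi = n_term_nt, len(seq) - c_term_nt - unit_nt
                    if hi <= lo:
                        continue
                    start = int(rng.integers(lo, hi))
                    start -= (start - n_term_nt) % 3
                    tract = seq[start : start + unit_nt]
                    if rng.random() < 0.5:
                        seq[start:start] = tract
                        delta = unit_nt
                    else:
                        del seq[start : start + unit_nt]
                        delta = -unit_nt
                    log.add("slippage", node=branch_label(child), locus=li,
                            tract=[start, start + unit_nt], units=delta // unit_nt)
            n_conv = rng.poisson(conversion_rate * bl) if len(child_state) > 1 else 0
            for _ in range(n_conv):
                src, dst = rng.choice(len(child_state), size=2, replace=False)
                s_seq, d_seq = child_state[src], child_state[dst]
                if terminal_only:
                    # pick one terminal region; tract clipped to it
                    if rng.random() < 0.5:
                        lo, hi = 0, min(n_term_nt, len(s_seq), len(d_seq))
                    else:
                        span = min(c_term_nt, len(s_seq), len(d_seq))
                        tract = s_seq[len(s_seq) - span :]
                        d_seq[len(d_seq) - span :] = tract
                        log.add("conversion", node=branch_label(child),
                                source=int(src), target=int(dst),
                                tract=["3prime", span])
                        continue
                else:
                    lo, hi = 0, min(len(s_seq), len(d_seq))
                if hi - lo <= 0:
                    continue
                tl = min(conversion_tract_len, hi - lo)
                start = int(rng.integers(lo, hi - tl + 1))
                d_seq[start : start + tl] = s_seq[start : start + tl]
                log.add("conversion", node=branch_label(child), source=int(src),
                        target=int(dst), tract=[start, start + tl])
            if child.is_leaf():
                sp = child.taxon.label
                for li, seq in enumerate(child_state):
                    sid = f"{sp}|L{li}"
                    out[sid] = SequenceRecord(id=sid, alphabet="nucleotide",
                                              residues="".join(seq))
            else:
                descend(child, child_state)

    descend(species_tree.seed_node, loci)
    return out, log


def terminal_regions(
    record: SequenceRecord, n_term_nt: int, c_term_nt: int
) -> tuple[SequenceRecord, SequenceRecord, SequenceRecord]:
    """Split a family CDS into (N-terminal, repeat, C-terminal) records."""
    seq = record.residues
    return (
        record.subsequence(Interval(0, n_term_nt), "_N"),
        record.subsequence(Interval(n_term_nt, len(seq) - c_term_nt), "_R"),
        record.subsequence(Interval(len(seq) - c_term_nt, len(seq)), "_C"),
    )


# ---------------------------------------------------------------------------
# reads


def generate_reads(
    references: Sequence[SequenceRecord],
    depth: int,
    true_ratio: Mapping[str, float],
    read_len: int = 50,
    three_prime_decay: float = 0.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Draw ``depth`` reads from weighted references with 3' start bias.

    The locus of origin is drawn with probability proportional to
    ``true_ratio``; the start position s on a reference of usable span
    S = L - read_len has weight exp(-decay * (S - s) / S), i.e. uniform
    at decay 0 and concentrated at the 3' end for large decay.  Per-base
    substitution errors are i.i.d. at ``error_rate``.

    Returns (reads, truth counts per reference id); each read id ends
    with ``|<origin>`` so per-read truth is recoverable.
    """
    rng = np.random.default_rng(seed)
    ids = [r.id for r in references]
    weights = np.array([true_ratio[i] for i in ids], dtype=float)
    weights /= weights.sum()
    start_dists = []
    for ref in references:
        span = len(ref.residues) - read_len
        if span < 0:
            raise ValueError(f"reference {ref.id!r} shorter than read length")
        s = np.arange(span + 1)
        w = np.exp(-three_prime_decay * (span - s) / max(span, 1))
        start_dists.append(w / w.sum())
    reads: list[SequenceRecord] = []
    truth = {i: 0 for i in ids}
    origins = rng.choice(len(ids), size=depth, p=weights)
    for n, oi in enumerate(origins):
        ref = references[oi]
        start = int(rng.choice(len(start_dists[oi]), p=start_dists[oi]))
        seq = list(ref.residues[start : start + read_len])
        if error_rate > 0:
            for i in np.nonzero(rng.random(read_len) < error_rate)[0]:
                seq[i] = "ACGT".replace(seq[i], "")[rng.integers(3)]
        truth[ref.id] += 1
        reads.append(
            SequenceRecord(id=f"read{n}|{ref.id}", alphabet="nucleotide",
                           residues="".join(seq))
        )
    return reads, truth


# ---------------------------------------------------------------------------
# tensile traces


def analytic_tensile_properties(
    modulus_gpa: float, strength_mpa: float, extensibility: float,
    yield_strain: float = 0.02,
) -> dict[str, float]:
    """Closed-form properties of the bilinear true-stress/true-strain
    template used by ``simulate_tensile``."""
    e_mpa = modulus_gpa * 1000.0
    sigma_y = e_mpa * yield_strain
    toughness = 0.5 * sigma_y * yield_strain + (extensibility - yield_strain) * (
        sigma_y + strength_mpa
    ) / 2.0
    return {
        "modulus": modulus_gpa,
        "strength": strength_mpa,
        "extensibility": extensibility,
        "toughness": toughness,
    }


def simulate_tensile(
    modulus_gpa: float,
    strength_mpa: float,
    extensibility: float,
    noise_sd: float = 0.0,
    n_samples: int = 400,
    seed: int = 0,
    gage_length_mm: float = 10.0,
    diameter_um: float = 1.1,
    yield_strain: float = 0.02,
) -> TensileTrace:
    """Force-extension trace whose true-curve transform is a bilinear
    stiff-then-yielding curve ending at (extensibility, strength).

    The strain grid contains the yield point and the break point exactly,
    so the trapezoidal toughness of the noise-free trace equals the
    closed form.  Gaussian force noise (uN) is added per sample and a
    short post-break force collapse is appended.
    """
    if not 0 < yield_strain < extensibility:
        raise ValueError("need 0 < yield_strain < extensibility")
    e_mpa = modulus_gpa * 1000.0
    sigma_y = e_mpa * yield_strain
    if sigma_y > strength_mpa:
        raise ValueError("yield stress exceeds strength; lower modulus or yield strain")
    rng = np.random.default_rng(seed)
    n1 = max(2, int(n_samples * yield_strain / extensibility))
    n2 = max(2, n_samples - n1)
    strains = np.concatenate([
        np.linspace(0.0, yield_strain, n1, endpoint=False),
        np.linspace(yield_strain, extensibility, n2),
    ])
    stresses = np.where(
        strains <= yield_strain,
        e_mpa * strains,
        sigma_y + (strength_mpa - sigma_y) * (strains - yield_strain) / (extensibility - yield_strain),
    )
    a0 = math.pi * (diameter_um / 2.0) ** 2
    samples: list[tuple[float, float]] = []
    for eps, sigma in zip(strains, stresses):
        ext = gage_length_mm * (math.exp(eps) - 1.0)
        force = sigma * a0 * math.exp(-eps)
        if noise_sd > 0:
            force += rng.normal(0.0, noise_sd)
        samples.append((ext, max(force, 0.0)))
    # post-break collapse: force drops far below the running maximum
    last_ext = samples[-1][0]
    collapse = 0.05 * samples[-1][1]
    for j in range(1, 4):
        samples.append((last_ext * (1 + 0.002 * j), collapse))
    return TensileTrace(gage_length=gage_length_mm, diameter=diameter_um, samples=samples)


# ---------------------------------------------------------------------------
# Brownian traits


def simulate_bm_traits(
    tree: dendropy.Tree,
    sigma2: float,
    root_value: float = 0.0,
    seed: int = 0,
) -> dict[str, float]:
    """Brownian motion along branches: each child value is the parent
    value plus Normal(0, sigma2 x branch length).  Returns tip values."""
    rng = np.random.default_rng(seed)
    value = {tree.seed_node: float(root_value)}
    tips: dict[str, float] = {}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            pass
        else:
            bl = nd.edge.length or 0.0
            value[nd] = value[nd.parent_node] + rng.normal(0.0, math.sqrt(sigma2 * bl))
        if nd.is_leaf():
            tips[nd.taxon.label] = value[nd]
    return tips
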