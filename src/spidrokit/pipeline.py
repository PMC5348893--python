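"""End-to-end orchestration: validated run configs, per-stage report
builders, and provenance records.

Reports are plain dicts (JSON twin) with TSV export helpers so that a
run with the same config and seed is byte-identical apart from
timestamps, which appear only in logs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import dendropy
import pandas as pd
import yaml

from . import __version__
from .architecture import classify_modularity, detect_spacers, find_tandem_repeats, spacer_homogeneity
from .expression import abundance_ratio, assign_reads, count_reads
from .motifs import MOTIF_CLASSES, composition, format_percent, motif_coverage, scan_motifs
from .phylo import RegressionResult, pic, regress
from .seqio import SequenceRecord

__all__ = [
    "RunConfig",
    "ValidationError",
    "profile_report",
    "correlate",
    "expression_report",
    "provenance_record",
    "write_report",
]

EXIT_OK, EXIT_VALIDATION, EXIT_DATA = 0, 2, 3

_KNOWN_KEYS = {
    "seed", "out_dir", "inputs", "motif_classes", "spacer", "repeats",
    "alignment", "expression", "regression", "tensile",
}


class ValidationError(ValueError):
    """Config or input validation failure (CLI exit code 2)."""


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: Path = Path("spidrokit_out")
    inputs: dict[str, str] = field(default_factory=dict)
    params: dict[str, dict] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            out_dir=Path(raw.get("out_dir", "spidrokit_out")),
            inputs={k: str(v) for k, v in (raw.get("inputs") or {}).items()},
            params={k: v for k, v in raw.items() if k not in ("seed", "out_dir", "inputs")},
        )
        for name, p in cfg.inputs.items():
            if not Path(p).exists():
                raise ValidationError(f"input {name!r}: path {p} does not exist")
        return cfg

    def digest(self) -> str:
        blob = json.dumps(
            {"seed": self.seed, "inputs": self.inputs, "params": self.params},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def profile_report(
    records: Sequence[SequenceRecord],
    spacer_params: Mapping[str, Any] | None = None,
    repeat_params: Mapping[str, Any] | None = None,
) -> dict:
    """Architecture report per protein: motif annotations and coverage,
    composition, spacers with homogeneity, tandem repeats, modularity."""
    out: dict[str, Any] = {"sequences": {}}
    for rec in records:
        motifs = scan_motifs(rec)
        coverage = {cls: motif_coverage(rec, cls) for cls in MOTIF_CLASSES}
        comp = composition(rec)
        top3 = sorted(comp.aa_fraction, key=comp.aa_fraction.get, reverse=True)[:3]
        try:
            spacers = detect_spacers(rec, **(spacer_params or {}))
        except ValueError:
            spacers = []
        blocks = find_tandem_repeats(rec, **(repeat_params or {}))
        homog = spacer_homogeneity(spacers)
        out["sequences"][rec.id] = {
            "length": len(rec.residues),
            "top3_residues": top3,
            "coverage_percent": {c: format_percent(v) for c, v in coverage.items()},
            "motifs": [
                {"class": m.motif_class, "start": m.interval.start, "end": m.interval.end}
                for m in motifs
            ],
            "spacers": [
                {"start": s.interval.start, "end": s.interval.end,
                 "stv_fraction": round(s.stv_fraction, 4)}
                for s in spacers
            ],
            "spacer_homogeneity": None if homog is None else round(homog, 4),
            "repeats": [
                {"start": b.interval.start, "end": b.interval.end, "period": b.period,
                 "copies": round(b.copies, 2), "identity": round(b.mean_identity, 4)}
                for b in blocks
            ],
            "modularity": classify_modularity(blocks),
        }
    return out


def correlate(
    traits: pd.DataFrame,
    tree: dendropy.Tree | None,
    x_col: str = "gpg_percent",
    y_col: str = "extensibility",
    species_col: str = "species",
) -> dict[str, RegressionResult]:
    """Raw OLS of y on x across species, plus the contrasts regression
    (through the origin) when a tree is supplied."""
    x = traits[x_col].astype(float).to_numpy()
    y = traits[y_col].astype(float).to_numpy()
    out = {"raw": regress(x, y)}
    if tree is not None:
        xt = dict(zip(traits[species_col], x))
        yt = dict(zip(traits[species_col], y))
        cx = pic(tree, xt)
        cy = pic(tree, yt)
        sx, sy = cx.standardized, cy.standardized
        out["contrasts"] = regress(sx, sy, through_origin=True)
    return out


def expression_report(
    reads: Sequence[SequenceRecord],
    references: Sequence[SequenceRecord],
    numerator: str,
    denominator: str,
    max_mismatch: int = 3,
    window: int = 500,
) -> dict:
    """Paralog abundance table: whole-gene and 3'-window counts and ratios."""
    read_len = len(reads[0].residues) if reads else 0
    assignments = assign_reads(reads, references, max_mismatch=max_mismatch)
    table = count_reads(assignments, references, read_length=read_len, window=window)
    ratio = abundance_ratio(table, numerator, denominator, "whole")
    ratio3 = abundance_ratio(table, numerator, denominator, "window")
    return {
        "total_reads": table.total_reads,
        "assigned": sum(table.whole.values()),
        "whole_counts": table.whole,
        "window_counts": table.window,
        "ratio": None if ratio is None else round(ratio, 1),
        "ratio_3prime": None if ratio3 is None else round(ratio3, 1),
    }


def provenance_record(config: RunConfig, command: str) -> dict:
    return {
        "tool": "spidrokit",
        "version": __version__,
        "command": command,
        "seed": config.seed,
        "config_sha256_16": config.digest(),
    }


def write_report(report: dict, out_dir: str | Path, name: str) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{name}.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
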