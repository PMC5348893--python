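"""Fiber tensile mechanics: true stress/strain curves, derived
properties, and group comparisons.

A single silk fiber of gage length L0 (mm) and diameter d (um) is
extended to failure while force F (uN) is recorded.  True strain is
ln(L/L0) with L = L0 + extension; true stress is F·L/(A0·L0) with
A0 = pi(d/2)^2, which is F divided by the instantaneous cross-section
under the constant-volume assumption.  Derived properties: strength =
true stress at breakage (MPa), extensibility = true strain at breakage
(dimensionless ln mm/mm), Young's modulus = initial slope of the true
curve (GPa), toughness = area under the true curve to breakage (MJ/m^3,
numerically equal to J/cm^3).

Breakage is the last sample before force drops by more than half from
its running maximum (or the final sample when no such drop exists).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TensileTrace",
    "TensileProperties",
    "true_curve",
    "tensile_properties",
    "anova_oneway",
    "tukey_hsd",
    "read_trace",
    "write_trace",
]


@dataclass(frozen=True)
class TensileTrace:
    gage_length: float  # mm
    diameter: float  # um
    samples: list[tuple[float, float]]  # (extension mm, force uN), extension non-decreasing

    def __post_init__(self) -> None:
        if self.gage_length <= 0 or self.diameter <= 0:
            raise ValueError("gage length and diameter must be positive")
        ext = [e for e, _ in self.samples]
        if not ext or ext[0] < 0 or any(b < a for a, b in zip(ext, ext[1:])):
            raise ValueError("extensions must be non-decreasing from 0")
        if not all(math.isfinite(f) for _, f in self.samples):
            raise ValueError("forces must be finite")


@dataclass(frozen=True)
class TensileProperties:
    strength: float  # MPa
    extensibility: float  # ln(mm/mm)
    modulus: float  # GPa
    toughness: float  # MJ/m^3 == J/cm^3


def true_curve(trace: TensileTrace) -> list[tuple[float, float]]:
    """(true strain, true stress MPa) per sample.

    uN / um^2 = MPa, so stress in MPa is F_uN * (L/L0) / A0_um2.
    """
    l0 = trace.gage_length
    a0 = math.pi * (trace.diameter / 2.0) ** 2  # um^2
    out = []
    for ext_mm, force_un in trace.samples:
        length = l0 + ext_mm
        strain = math.log(length / l0)
        stress = force_un * (length / l0) / a0
        out.append((strain, stress))
    return out


def _break_index(stresses: Sequence[float], drop_fraction: float = 0.5) -> int:
    running_max = -math.inf
    for i, s in enumerate(stresses):
        if s < (1.0 - drop_fraction) * running_max:
            return i - 1
        running_max = max(running_max, s)
    return len(stresses) - 1


def tensile_properties(
    curve: Sequence[tuple[float, float]],
    modulus_strain_max: float = 0.02,
    drop_fraction: float = 0.5,
) -> TensileProperties:
    """Derive the four properties from a (strain, stress) curve.

    Modulus is the least-squares slope of stress on strain over
    strain <= ``modulus_strain_max`` (through the origin-free fit);
    toughness is the trapezoidal integral of stress over strain up to
    breakage.
    """
    strains = np.array([s for s, _ in curve])
    stresses = np.array([t for _, t in curve])
    bi = _break_index(stresses, drop_fraction)
    if bi < 1:
        raise ValueError("curve breaks before any extension")
    strength = float(stresses[bi])
    extensibility = float(strains[bi])
    mask = strains[: bi + 1] <= modulus_strain_max
    if mask.sum() < 2:
        mask = np.zeros(bi + 1, dtype=bool)
        mask[:2] = True  # fall back to the first two samples
    slope = float(np.polyfit(strains[: bi + 1][mask], stresses[: bi + 1][mask], 1)[0])
    toughness = float(np.trapezoid(stresses[: bi + 1], strains[: bi + 1]))
    return TensileProperties(
        strength=strength,
        extensibility=extensibility,
        modulus=slope / 1000.0,  # MPa -> GPa
        toughness=toughness,
    )


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> tuple[float, int, int, float]:
    """One-way ANOVA from explicit sums of squares.

    Returns (F, df_between, df_within, p).
    """
    labels = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in labels]
    k = len(data)
    if k < 2 or any(len(d) < 2 for d in data):
        raise ValueError("need >= 2 groups with >= 2 values each")
    n_total = sum(len(d) for d in data)
    grand = sum(d.sum() for d in data) / n_total
    ss_between = sum(len(d) * (d.mean() - grand) ** 2 for d in data)
    ss_within = sum(((d - d.mean()) ** 2).sum() for d in data)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0:
        f = 0.0 if ss_between == 0 else math.inf
    else:
        f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2)) if math.isfinite(f) else 0.0
    return float(f), df1, df2, p


def _letters_from_nonsig(labels: Sequence[str], nonsig: set[frozenset]) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not
    significantly different (insert-and-absorb algorithm)."""
    letters: list[set[str]] = [set(labels)]
    for a, b in combinations(labels, 2):
        if frozenset((a, b)) in nonsig:
            continue
        new_letters: list[set[str]] = []
        for grp in letters:
            if a in grp and b in grp:
                new_letters.append(grp - {a})
                new_letters.append(grp - {b})
            else:
                new_letters.append(grp)
        # absorb subsets
        letters = []
        for grp in new_letters:
            if not any(grp < other for other in new_letters if grp is not other):
                if grp not in letters:
                    letters.append(grp)
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    assignment: dict[str, str] = {lab: "" for lab in labels}
    for idx, grp in enumerate(letters):
        for lab in sorted(grp):
            assignment[lab] += alphabet[idx]
    return assignment


def tukey_hsd(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    n_mode: str = "harmonic_mean",
) -> dict[str, str]:
    """Tukey's HSD with a common sample size (harmonic mean of group
    sizes by default), returning a compact letter display."""
    labels = list(groups)
    data = {g: np.asarray(groups[g], dtype=float) for g in labels}
    k = len(labels)
    n_total = sum(len(d) for d in data.values())
    df_err = n_total - k
    mse = sum(((d - d.mean()) ** 2).sum() for d in data.values()) / df_err
    if n_mode == "harmonic_mean":
        n_eff = k / sum(1.0 / len(d) for d in data.values())
    elif n_mode == "min":
        n_eff = min(len(d) for d in data.values())
    else:
        raise ValueError("n_mode must be 'harmonic_mean' or 'min'")
    q_crit = stats.studentized_range.ppf(1 - alpha, k, df_err)
    hsd = q_crit * math.sqrt(mse / n_eff)
    nonsig = {
        frozenset((a, b))
        for a, b in combinations(labels, 2)
        if abs(data[a].mean() - data[b].mean()) <= hsd
    }
    return _letters_from_nonsig(labels, nonsig)


def write_trace(trace: TensileTrace, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write(f"# gage_length_mm\t{trace.gage_length}\n")
        fh.write(f"# diameter_um\t{trace.diameter}\n")
        fh.write("extension_mm\tforce_uN\n")
        for ext, force in trace.samples:
            fh.write(f"{ext:.9g}\t{force:.9g}\n")


def read_trace(path: str | Path) -> TensileTrace:
    gage = diameter = None
    samples: list[tuple[float, float]] = []
    with open(Path(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("\t")
                if key == "gage_length_mm":
                    gage = float(val)
                elif key == "diameter_um":
                    diameter = float(val)
            elif line[0].isdigit() or line[0] in "-.":
                ext, force = line.split("\t")
                samples.append((float(ext), float(force)))
    if gage is None or diameter is None:
        raise ValueError(f"{path}: missing gage_length_mm / diameter_um metadata")
    return TensileTrace(gage_length=gage, diameter=diameter, samples=samples)
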