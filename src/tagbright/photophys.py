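"""Beer-Lambert arithmetic for dye-conjugate photophysics.

Absorbance readings (A = epsilon * c * l) connect stock concentrations,
extinction coefficients of free dyes and of dye-protein conjugates, and
brightness comparisons between conjugates.  Brightness is epsilon * Phi
(extinction coefficient times fluorescence quantum yield); quantum yields
are external inputs — this module never assumes one.

Typical workflow: determine stock concentrations from the absorbance of the
dye in 0.1% SDS (where the reference epsilon of 100,000 M^-1 cm^-1
applies), then measure the conjugate absorbance at known concentration to
obtain the conjugate epsilon, verify label saturation by comparing 3 and 6
molar-equivalent readings, and finally form Halo:SNAP fold ratios.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

__all__ = [
    "AbsorbanceReading",
    "ConjugateRecord",
    "concentration_from_absorbance",
    "extinction_coefficient",
    "saturation_check",
    "brightness_fold",
    "read_absorbance_csv",
]

Context = Literal["sds", "buffer_free_dye", "conjugate_3eq", "conjugate_6eq"]


@dataclass(frozen=True)
class AbsorbanceReading:
    """One cuvette reading: absorbance, optional concentration, path length.

    ``path_cm`` defaults to the standard 1-cm cuvette.  ``concentration_M``
    is ``None`` when unknown (that is what the reading is for).
    """

    absorbance: float
    concentration_M: float | None = None
    path_cm: float = 1.0
    context: Context = "buffer_free_dye"
    dye: str = ""
    tag: str = "free"

    def __post_init__(self) -> None:
        if self.absorbance < 0:
            raise ValueError("absorbance must be >= 0")
        if self.path_cm <= 0:
            raise ValueError("path_cm must be positive")
        if self.concentration_M is not None and self.concentration_M <= 0:
            raise ValueError("concentration_M must be positive when given")


@dataclass(frozen=True)
class ConjugateRecord:
    """A dye-tag pair with its extinction coefficient and optional quantum yield."""

    dye: str
    tag: Literal["halo", "snap", "free"]
    epsilon: float  # M^-1 cm^-1
    quantum_yield: float | None = None

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.quantum_yield is not None and not 0 < self.quantum_yield <= 1:
            raise ValueError("quantum_yield must lie in (0, 1]")

    @property
    def brightness(self) -> float | None:
        """epsilon * Phi, or None when the quantum yield is not supplied."""
        if self.quantum_yield is None:
            return None
        return self.epsilon * self.quantum_yield


def concentration_from_absorbance(r: AbsorbanceReading, epsilon: float) -> float:
    """c = A / (epsilon * l) in mol/L."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    return r.absorbance / (epsilon * r.path_cm)


def extinction_coefficient(r: AbsorbanceReading) -> float:
    """epsilon = A / (c * l) in M^-1 cm^-1; requires a known concentration."""
    if r.concentration_M is None:
        raise ValueError("reading has no concentration; cannot derive epsilon")
    return r.absorbance / (r.concentration_M * r.path_cm)


def saturation_check(
    a3: AbsorbanceReading, a6: AbsorbanceReading, rel_tol: float = 0.05
) -> bool:
    """Did doubling the enzyme equivalents leave the absorbance unchanged?

    True iff ``|A6 - A3| / A3 <= rel_tol``: all free dye was consumed at 3
    equivalents already, so the conjugate epsilon is trustworthy.
    """
    if a3.dye != a6.dye or a3.path_cm != a6.path_cm:
        raise ValueError("saturation check requires readings of the same dye and path")
    if a3.absorbance == 0:
        raise ValueError("3-equivalent absorbance is zero; cannot form a ratio")
    return abs(a6.absorbance - a3.absorbance) / a3.absorbance <= rel_tol


def brightness_fold(
    a: ConjugateRecord, b: ConjugateRecord
) -> tuple[float, float | None]:
    """(epsilon fold, brightness fold) of conjugate a over conjugate b.

    The brightness fold (epsilon_a*Phi_a) / (epsilon_b*Phi_b) is ``None``
    unless both quantum yields are supplied.
    """
    epsilon_fold = a.epsilon / b.epsilon
    if a.brightness is None or b.brightness is None:
        return epsilon_fold, None
    return epsilon_fold, a.brightness / b.brightness


def read_absorbance_csv(path: str | Path) -> list[AbsorbanceReading]:
    """Read readings from a CSV with columns dye,tag,context,A,c_M,path_cm."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            c = row.get("c_M", "")
            out.append(
                AbsorbanceReading(
                    absorbance=float(row["A"]),
                    concentration_M=float(c) if c not in ("", "NA", None) else None,
                    path_cm=float(row.get("path_cm") or 1.0),
                    context=row.get("context", "buffer_free_dye"),  # type: ignore[arg-type]
                    dye=row.get("dye", ""),
                    tag=row.get("tag", "free"),
                )
            )
    return out
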