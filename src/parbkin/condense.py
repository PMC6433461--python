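"""DNA condensation classification and binding-competition slope analysis.

At permissive forces (≲1 pN) the protein compacts the tethered DNA; each
molecule's outcome is summarised by the fraction of its initial extension
lost.  Molecules losing more than 90% of their extension are *condensed*,
those losing less than 10% are *not condensed*, everything in between
(boundaries included) is *partially condensed*.

Binding competition is quantified from paired per-cycle integrated
intensities of the same molecules under two alternating conditions A and B
(e.g. labelled protein alone versus labelled protein plus a competitor):
the through-origin least-squares slope of A on B is 1 when the competitor
leaves labelled occupancy unchanged and rises above 1 in proportion to the
displaced fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .trace import IntensityTrace
from .kinetics import PhaseWindow

__all__ = [
    "CONDENSED",
    "PARTIAL",
    "NOT_CONDENSED",
    "MoleculeRecord",
    "CondensationSummary",
    "SlopeResult",
    "classify_molecule",
    "condensation_fractions",
    "competition_slope",
    "cycle_intensity",
    "records_to_frame",
]

CONDENSED = "condensed"
PARTIAL = "partial"
NOT_CONDENSED = "not_condensed"


@dataclass
class MoleculeRecord:
    """Per-molecule condensation outcome and paired condition intensities."""

    molecule_id: str
    extension_reduction: float
    condition: str = ""
    intensities_a: np.ndarray = field(default_factory=lambda: np.array([]))
    intensities_b: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if not 0 <= self.extension_reduction <= 1:
            raise ValueError("extension_reduction must be in [0, 1]")
        self.intensities_a = np.asarray(self.intensities_a, dtype=float)
        self.intensities_b = np.asarray(self.intensities_b, dtype=float)
        if self.intensities_a.size != self.intensities_b.size:
            raise ValueError("paired intensities must have equal length")


@dataclass
class CondensationSummary:
    """Class fractions over a set of molecules (fractions sum to 1)."""

    n_total: int
    fraction_condensed: float
    fraction_partial: float
    fraction_not_condensed: float

    def percentages(self) -> dict[str, int]:
        """Integer percentages for reporting."""
        return {
            CONDENSED: round(100 * self.fraction_condensed),
            PARTIAL: round(100 * self.fraction_partial),
            NOT_CONDENSED: round(100 * self.fraction_not_condensed),
        }


@dataclass
class SlopeResult:
    """Through-origin regression slope of paired intensities."""

    slope: float
    stderr: float
    n_pairs: int

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if self.stderr < 0:
            raise ValueError("stderr must be non-negative")


def classify_molecule(extension_reduction: float) -> str:
    """Classify one molecule by its fractional extension reduction.

    Strictly more than 0.9 is condensed, strictly less than 0.1 is not
    condensed; the boundaries and everything between are partial.
    """
    if not 0 <= extension_reduction <= 1:
        raise ValueError("extension_reduction must be in [0, 1]")
    if extension_reduction > 0.9:
        return CONDENSED
    if extension_reduction < 0.1:
        return NOT_CONDENSED
    return PARTIAL


def condensation_fractions(records: list[MoleculeRecord] | list[float]) -> CondensationSummary:
    """Fractions of condensed / partial / not-condensed molecules."""
    if len(records) == 0:
        raise ValueError("no molecules to summarise")
    reductions = [r.extension_reduction if isinstance(r, MoleculeRecord) else float(r)
                  for r in records]
    classes = [classify_molecule(x) for x in reductions]
    n = len(classes)
    return CondensationSummary(
        n_total=n,
        fraction_condensed=classes.count(CONDENSED) / n,
        fraction_partial=classes.count(PARTIAL) / n,
        fraction_not_condensed=classes.count(NOT_CONDENSED) / n,
    )


def competition_slope(pairs: np.ndarray | list[tuple[float, float]]) -> SlopeResult:
    """Zero-intercept least-squares slope of intensity A on intensity B.

    Pairs are pooled over molecules and cycles.  The slope is
    ``sum(A*B) / sum(B^2)``; its standard error comes from the
    through-origin regression residuals.  Identical conditions give a
    slope of 1; a competitor that scales labelled occupancy by a factor f
    gives a slope of 1/f.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (A, B) intensities")
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    if np.any(arr <= 0):
        raise ValueError("intensities must be positive")
    a, b = arr[:, 0], arr[:, 1]
    ssb = float(b @ b)
    if ssb == 0:
        raise ValueError("degenerate pairs: all B intensities are zero")
    slope = float(a @ b) / ssb
    resid = a - slope * b
    n = arr.shape[0]
    stderr = math.sqrt(float(resid @ resid) / (n - 1) / ssb)
    return SlopeResult(slope=slope, stderr=stderr, n_pairs=n)


def cycle_intensity(trace: IntensityTrace, window: PhaseWindow,
                    tail_s: float = 10.0) -> float:
    """Mean intensity over the final ``tail_s`` seconds of a phase window.

    This is the per-cycle intensity used for competition pairing: the tail
    average sits on the phase plateau, away from the exchange transient.
    """
    start = max(window.start, window.end - tail_s)
    sub = trace.crop(start, window.end)
    if len(sub) == 0:
        raise ValueError("tail window contains no samples")
    return float(sub.values.mean())


def records_to_frame(records: list[MoleculeRecord]) -> pd.DataFrame:
    """Per-molecule table: id, extension reduction, class, condition."""
    return pd.DataFrame({
        "molecule_id": [r.molecule_id for r in records],
        "extension_reduction": [r.extension_reduction for r in records],
        "class": [classify_molecule(r.extension_reduction) for r in records],
        "condition": [r.condition for r in records],
    })
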