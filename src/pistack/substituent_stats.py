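"""Substituent-effect relative energies and correlation/additivity statistics.

Substituent effects on stacking are quantified as interaction energies
relative to the unsubstituted benzene dimer evaluated under the same
potential and geometry convention:

    dE(X)    = E(C6H5X...C6H6)    - E(C6H6...C6H6)
    dE(X, Y) = E(C6H5X...C6H5Y)   - E(C6H6...C6H6)

Two statistics summarize agreement between a model and reference energies:
the squared Pearson correlation r^2 of the two dE lists and the RMSE of
their differences (no recentering).  The additivity analysis compares mixed
double-substituent effects dE(X, Y) against the sum dE(X) + dE(Y) of the two
single-substituent effects from the same model — near-perfect additivity is
the signature of substituent effects being local, direct interactions rather
than ring-mediated ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MissingBaselineError, PiStackError, UndefinedCorrelationError

__all__ = [
    "RelativeEnergyTable",
    "relative_energies",
    "correlate",
    "additivity",
    "AdditivityResult",
]

BASELINE = "H"


@dataclass
class RelativeEnergyTable:
    """Model (and optionally reference) energies relative to X = H."""

    frame: pd.DataFrame  # columns: system, x, z, E_model, dE_model[, E_reference, dE_reference]

    @property
    def dE_model(self) -> pd.Series:
        return self.frame.set_index("system")["dE_model"]

    @property
    def dE_reference(self) -> pd.Series:
        if "dE_reference" not in self.frame.columns:
            raise PiStackError("table has no reference energies")
        return self.frame.set_index("system")["dE_reference"]

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def relative_energies(
    systems: Mapping[str, tuple],
    evaluate: Callable[[object], float],
    baseline: str = BASELINE,
    reference: Mapping[str, float] | None = None,
) -> RelativeEnergyTable:
    """Build a relative-energy table.

    Parameters
    ----------
    systems : mapping
        ``label -> (spec, x, z)`` where ``spec`` is whatever the ``evaluate``
        callable consumes (typically a placed-dimer constructor input).  The
        label ``baseline`` (default ``"H"``) must be present: its energy
        anchors all dE values.
    evaluate : callable
        ``spec -> E`` total interaction energy in kcal/mol.
    reference : mapping, optional
        ``label -> reference total energy`` (e.g. from an external
        high-level method); relative reference energies are added when given.
    """
    if baseline not in systems:
        raise MissingBaselineError(
            f"baseline system {baseline!r} missing from the system list"
        )
    rows = []
    energies = {label: float(evaluate(spec[0])) for label, spec in systems.items()}
    e0 = energies[baseline]
    for label, (spec, x, z) in systems.items():
        row = {
            "system": label,
            "x": x,
            "z": z,
            "E_model": energies[label],
            "dE_model": energies[label] - e0,
        }
        rows.append(row)
    frame = pd.DataFrame(rows)
    if reference is not None:
        if baseline not in reference:
            raise MissingBaselineError(
                f"baseline system {baseline!r} missing from the reference energies"
            )
        r0 = reference[baseline]
        frame["E_reference"] = frame["system"].map(reference)
        frame["dE_reference"] = frame["E_reference"] - r0
    return RelativeEnergyTable(frame=frame)


def correlate(predicted: Sequence[float], reference: Sequence[float]) -> tuple[float, float]:
    """(r^2, RMSE) between two equal-length energy lists.

    r^2 is the squared Pearson correlation coefficient; RMSE is the root
    mean squared difference with no recentering, so a constant offset leaves
    r^2 = 1 but shows up fully in the RMSE.
    """
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise PiStackError("predicted and reference must be equal-length 1-D lists")
    if p.size < 3:
        raise PiStackError("need at least 3 points to correlate")
    if np.std(p) == 0 or np.std(r) == 0:
        raise UndefinedCorrelationError("zero variance in one of the lists")
    r2 = float(np.corrcoef(p, r)[0, 1] ** 2)
    rmse = float(np.sqrt(np.mean((p - r) ** 2)))
    return r2, rmse


@dataclass
class AdditivityResult:
    r2: float
    rmse: float
    residuals: pd.DataFrame  # columns: X, Y, dE_pair, dE_sum, residual


def _pair_labels(label: str) -> tuple[str, str]:
    if "·" in label:
        a, b = label.split("·", 1)
    elif ":" in label:
        a, b = label.split(":", 1)
    else:
        raise PiStackError(f"cannot split pair label {label!r}; use 'X·Y' or 'X:Y'")
    return a.strip(), b.strip()


def additivity(
    mixed: Mapping[str, float],
    single: Mapping[str, float],
) -> AdditivityResult:
    """Compare mixed-dimer effects against summed single-substituent effects.

    ``mixed`` maps pair labels ("X·Y" or "X:Y") to dE(X, Y); ``single`` maps
    substituent names to dE(X).  Every pair must resolve to two single
    entries.  Returns the r^2/RMSE of dE(X, Y) vs dE(X) + dE(Y) plus
    per-pair residuals dE(X, Y) - dE(X) - dE(Y).
    """
    rows = []
    for label, de_pair in mixed.items():
        x, y = _pair_labels(label)
        for s in (x, y):
            if s not in single:
                raise PiStackError(f"pair {label!r}: no single-substituent entry for {s!r}")
        de_sum = single[x] + single[y]
        rows.append({"X": x, "Y": y, "dE_pair": float(de_pair),
                     "dE_sum": float(de_sum), "residual": float(de_pair - de_sum)})
    res = pd.DataFrame(rows)
    r2, rmse = correlate(res["dE_pair"].to_numpy(), res["dE_sum"].to_numpy())
    return AdditivityResult(r2=r2, rmse=rmse, residuals=res)
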