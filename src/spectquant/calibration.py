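"""Scanner-calibration accuracy checks for quantitative SPECT/CT.

Quantification is only meaningful on a calibrated camera.  Two checks are
implemented: the per-sphere hot-insert accuracy equation

    accuracy(%) = (1 - |A_true - a_measured| / A_true) * 100

evaluated on reconstructed phantom spheres, and the relative deviation
between the planar- and SPECT-derived sensitivity conversion factors,
required to fall in the 0-5% band.  A scanner qualifies for quantification
when every sphere exceeds the vendor accuracy threshold (90% by default)
and the sensitivity deviation is within band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import pandas as pd


class CalibrationError(ValueError):
    """Raised for invalid calibration inputs."""


def accuracy(true_conc: float, measured_conc: float) -> float:
    """Per-sphere recovery accuracy in percent.

    May be negative when the absolute error exceeds the true concentration;
    reported as-is.
    """
    if true_conc <= 0:
        raise CalibrationError("true concentration must be positive")
    if measured_conc < 0:
        raise CalibrationError("measured concentration must be non-negative")
    return (1.0 - abs(true_conc - measured_conc) / true_conc) * 100.0


def sensitivity_deviation_pct(sensitivity_planar: float,
                              sensitivity_spect: float) -> float:
    """Relative deviation (%) between the two sensitivity conversion factors.

    The SPECT factor is the reference denominator since quantification runs
    on the SPECT reconstruction.
    """
    if sensitivity_spect <= 0 or sensitivity_planar <= 0:
        raise CalibrationError("sensitivities must be positive")
    return abs(sensitivity_planar - sensitivity_spect) / sensitivity_spect * 100.0


@dataclass(frozen=True)
class SphereAccuracy:
    sphere_id: str
    true_concentration: float
    measured_concentration: float
    accuracy_pct: float

    @classmethod
    def from_concentrations(cls, sphere_id: str, true_conc: float,
                            measured_conc: float) -> "SphereAccuracy":
        return cls(sphere_id, true_conc, measured_conc,
                   accuracy(true_conc, measured_conc))


def sphere_accuracies_from_table(table: pd.DataFrame) -> List[SphereAccuracy]:
    """Build per-sphere accuracies from a table with columns
    sphere_id, true_concentration, measured_concentration."""
    return [
        SphereAccuracy.from_concentrations(
            str(row["sphere_id"]),
            float(row["true_concentration"]),
            float(row["measured_concentration"]),
        )
        for _, row in table.iterrows()
    ]


def qualify_scanner(sphere_accuracies: Sequence[SphereAccuracy],
                    sensitivity_planar: float,
                    sensitivity_spect: float,
                    threshold_pct: float = 90.0,
                    max_deviation_pct: float = 5.0) -> dict:
    """Qualification report for quantitative use.

    Passes iff every sphere accuracy exceeds ``threshold_pct`` and the
    planar/SPECT sensitivity deviation lies within [0, max_deviation_pct].
    """
    if len(sphere_accuracies) == 0:
        raise CalibrationError("at least one sphere accuracy is required")
    failing = [s.sphere_id for s in sphere_accuracies
               if not s.accuracy_pct > threshold_pct]
    deviation = sensitivity_deviation_pct(sensitivity_planar, sensitivity_spect)
    deviation_ok = deviation <= max_deviation_pct
    return {
        "passed": not failing and deviation_ok,
        "threshold_pct": threshold_pct,
        "min_accuracy_pct": min(s.accuracy_pct for s in sphere_accuracies),
        "failing_spheres": failing,
        "sensitivity_deviation_pct": deviation,
        "deviation_ok": deviation_ok,
        "max_deviation_pct": max_deviation_pct,
        "n_spheres": len(sphere_accuracies),
    }
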