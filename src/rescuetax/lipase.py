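"""Relative lipase activity and the discrete IC50 rule.

Dose-response inhibition assays report a fluorescence slope (product
formation rate) per inhibitor concentration plus an uninhibited control.
Relative activity is residual/control x 100; the IC50 is defined discretely
as the lowest tested concentration at which activity falls to 50% or below —
no sigmoid fitting is involved, so the result is always one of the tested
concentrations (or none).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["relative_activity", "ic50", "dose_response"]


def relative_activity(residual_rate: float, control_rate: float) -> float:
    """Percent lipase activity: residual / negative-control x 100."""
    if control_rate <= 0:
        raise ValueError("negative-control rate must be positive")
    if residual_rate < 0:
        raise ValueError("residual rate must be nonnegative")
    return 100.0 * residual_rate / control_rate


def ic50(concentrations, activities) -> float | None:
    """Lowest tested concentration with activity <= 50%; None if never reached.

    ``concentrations`` must be strictly ascending; ``activities`` are percent
    activities aligned with them.
    """
    conc = np.asarray(concentrations, dtype=float)
    act = np.asarray(activities, dtype=float)
    if conc.shape != act.shape:
        raise ValueError("concentrations and activities must have equal length")
    if len(conc) == 0:
        raise ValueError("empty dose series")
    if (np.diff(conc) <= 0).any():
        raise ValueError("concentrations must be strictly ascending")
    hit = act <= 50.0
    if not hit.any():
        return None
    return float(conc[np.argmax(hit)])


def dose_response(measurements: pd.DataFrame) -> pd.DataFrame:
    """Relative activity per row of a (concentration, residual_rate, control_rate) table."""
    required = {"concentration", "residual_rate", "control_rate"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = measurements.sort_values("concentration").reset_index(drop=True)
    out["activity_pct"] = [
        relative_activity(r, c)
        for r, c in zip(out["residual_rate"], out["control_rate"])
    ]
    return out
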