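"""Residual diagnostics: calibration error versus distance to the heat source.

Thermometry error is not expected to be homogeneous in space — the steepest
temperature gradients, the metal artifact and the gas formation all sit next
to the probe, so residual variance should shrink with distance from the
emitting point. That hypothesis is tested with a Breusch-Pagan auxiliary
regression of squared residuals on distance: the LM flavour (n * R^2 against
chi^2_1) and the F flavour (the auxiliary regression's F statistic against
F(1, n-2)) are both reported; F is the headline output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan

from .core import ProbeGeometry


@dataclass
class HeteroscedasticityResult:
    lm: float
    lm_p_value: float
    f: float
    f_p_value: float
    n: int
    aux_slope: float  # sign tells whether variance grows or shrinks with x


def probe_distances(tip_positions: dict, probe: ProbeGeometry) -> pd.DataFrame:
    """Per-sensor distances (mm) to the shaft line, emitting point and tip.

    ``tip_positions`` maps sensor id -> world point (mm). Shaft distance is
    the perpendicular point-to-line distance through the probe tip along its
    direction; the emitting point sits ``emitting_offset_mm`` proximal to
    the tip.
    """
    u = probe.direction
    emit = probe.emitting_point_mm
    rows = []
    for sid, pos in tip_positions.items():
        p = np.asarray(pos, dtype=float).reshape(3)
        v = p - probe.tip_mm
        axial = float(v @ u)
        d_shaft = float(np.sqrt(max(float(v @ v) - axial**2, 0.0)))
        rows.append({
            "sensor_id": sid,
            "d_shaft_mm": d_shaft,
            "d_emit_mm": float(np.linalg.norm(p - emit)),
            "d_tip_mm": float(np.linalg.norm(v)),
        })
    return pd.DataFrame(rows).set_index("sensor_id")


def raw_errors(fit, samples: pd.DataFrame,
               heating_window_s: tuple[float, float] | None = (0.0, 300.0),
               scan_times_s: dict | None = None) -> pd.DataFrame:
    """Raw calibration error (measured - estimated temperature) per sample.

    When a heating window is given, samples are restricted to scans whose
    nominal time falls inside it (the active-heating phase); scan times are
    looked up from ``scan_times_s`` (scan_idx -> seconds) or assumed to be
    60 s per scan index when omitted.
    """
    df = samples.copy()
    if heating_window_s is not None:
        if scan_times_s is not None:
            times = df["scan_idx"].map(scan_times_s)
        else:
            times = df["scan_idx"] * 60.0
        lo, hi = heating_window_s
        df = df[(times >= lo) & (times <= hi)].copy()
    df["raw_error_c"] = df["temp_c"] - fit.predict(df["edw_mean"].to_numpy())
    return df


def breusch_pagan(residuals, x) -> HeteroscedasticityResult:
    """Breusch-Pagan test of residual variance against a single covariate."""
    e = np.asarray(residuals, dtype=float)
    x = np.asarray(x, dtype=float)
    if e.shape != x.shape or e.ndim != 1:
        raise ValueError("residuals and x must be 1D and of equal length")
    if e.size < 4:
        raise ValueError("Breusch-Pagan needs n >= 4")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant: auxiliary regression undefined")
    exog = sm.add_constant(x)
    lm, lm_p, f, f_p = het_breuschpagan(e, exog)
    slope = float(np.polyfit(x, e**2, 1)[0])
    return HeteroscedasticityResult(
        lm=float(lm), lm_p_value=float(lm_p), f=float(f), f_p_value=float(f_p),
        n=int(e.size), aux_slope=slope,
    )
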