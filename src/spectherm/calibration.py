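"""Temperature calibration from spectral CT electron density.

Two calibration families are implemented:

* **Polynomial** (orders 1-4): least-squares fit of temperature on powers of
  EDW. Fitting is performed on a centred/scaled EDW basis (powers of raw EDW
  around 100 are catastrophically ill-conditioned at order 3-4) and the
  coefficients are back-transformed to the raw basis for reporting.

* **Thermal expansion model**: the physical relation between electron density
  and temperature through the volumetric thermal-expansion coefficient
  ``alpha(T) = b*T**2 + c*T + d`` (degC^-1),

      EDW(T) = EDW(T0) / (1 + int_T0^T alpha(T') dT')
             = EDW(T0) / (1 + b/3*(T^3-T0^3) + c/2*(T^2-T0^2) + d*(T-T0)),

  fitted by nonlinear least squares. Warming tissue expands, electron density
  falls, so EDW decreases monotonically in T wherever alpha > 0.

Temperatures are degC throughout; alpha coefficients carry units degC^-3,
degC^-2, degC^-1 for b, c, d respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial
from scipy import optimize, stats
from sklearn.model_selection import KFold


@dataclass
class CorrelationResult:
    """Spearman rank correlation with a Fisher-z confidence interval."""

    rho: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class ExpansionParams:
    """Parameters of the thermal-expansion EDW(T) model.

    ``edw_t0`` is the electron density (% of water) at the reference
    temperature ``t0`` (degC); ``b, c, d`` are the quadratic alpha(T)
    coefficients. Soft tissue at body temperature sits near edw_t0 ~ 104.
    """

    edw_t0: float
    t0: float
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0

    def __post_init__(self):
        if self.edw_t0 <= 0:
            raise ValueError("EDW(T0) must be positive")


@dataclass
class CalibrationFit:
    """A fitted temperature-prediction model.

    ``kind`` is ``"poly"`` or ``"expansion"``. For polynomial fits,
    ``coefficients`` are raw-EDW-basis coefficients in ascending order
    (length order+1) and prediction uses the internally stored scaled basis
    for numerical stability. ``edw_range`` records the span of the training
    EDW values so thermometry maps can refuse to extrapolate.
    """

    kind: str
    order: int | None
    coefficients: np.ndarray
    rmse_c: float
    n: int
    edw_range: tuple[float, float]
    expansion: ExpansionParams | None = None
    _scaled: Polynomial | None = field(default=None, repr=False)

    def predict(self, edw) -> np.ndarray:
        """Predicted temperature (degC) at the given EDW values."""
        edw = np.asarray(edw, dtype=float)
        if self.kind != "poly":
            raise ValueError(
                "expansion-model fits predict EDW from temperature; invert with "
                "spectherm.mapping.invert_edw (bisection) to map EDW -> temperature"
            )
        return self._scaled(edw)

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "order": self.order,
            "coefficients": [float(c) for c in np.atleast_1d(self.coefficients)],
            "rmse_c": float(self.rmse_c),
            "n": int(self.n),
            "edw_range": [float(self.edw_range[0]), float(self.edw_range[1])],
        }
        if self.expansion is not None:
            e = self.expansion
            d["expansion"] = {
                "edw_t0": float(e.edw_t0), "t0": float(e.t0),
                "b": float(e.b), "c": float(e.c), "d": float(e.d),
            }
        return d


def rmse(measured, estimated) -> float:
    """Root mean squared error sqrt(sum((x_i - xhat_i)^2) / N)."""
    measured = np.asarray(measured, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if measured.shape != estimated.shape:
        raise ValueError("measured and estimated must have equal length")
    if measured.size == 0:
        raise ValueError("RMSE of empty input is undefined")
    return float(np.sqrt(np.mean((measured - estimated) ** 2)))


def spearman(x, y, ci_level: float = 0.95) -> CorrelationResult:
    """Spearman rank correlation with two-sided p and Fisher-z CI.

    rho uses average ranks for ties and the p-value the t-approximation
    (scipy's default). The confidence interval applies the Fisher z
    transform with the Bonett-Wright rank-based standard error
    sqrt((1 + rho^2/2) / (n - 3)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input vector")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    p = float(res.pvalue)
    if n > 3 and abs(rho) < 1.0:
        z = np.arctanh(rho)
        se = np.sqrt((1.0 + rho**2 / 2.0) / (n - 3))
        zcrit = stats.norm.ppf(0.5 + ci_level / 2.0)
        lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    elif abs(rho) >= 1.0:  # Fisher z diverges at |rho| = 1
        lo, hi = (-1.0, rho) if rho < 0 else (rho, 1.0)
    else:  # n == 3: too few points for a z interval
        lo, hi = -1.0, 1.0
    return CorrelationResult(rho=rho, p_value=p, ci_low=float(lo), ci_high=float(hi), n=n)


def fit_polynomial(edw, temp, order: int) -> CalibrationFit:
    """Least-squares polynomial calibration T = p(EDW), order 1-4."""
    edw = np.asarray(edw, dtype=float)
    temp = np.asarray(temp, dtype=float)
    if edw.shape != temp.shape or edw.ndim != 1:
        raise ValueError("edw and temp must be 1D and of equal length")
    if order < 1 or order > 4:
        raise ValueError(f"polynomial order must be in 1..4, got {order}")
    n = edw.size
    if n <= order + 1:
        raise ValueError(f"need more than order+1={order + 1} points, got {n}")
    if np.ptp(edw) == 0:
        raise ValueError("constant EDW: design matrix is rank-deficient")
    # fit in a centred/scaled basis; convert() maps back to raw EDW powers
    scaled = Polynomial.fit(edw, temp, deg=order)
    raw = scaled.convert()
    pred = scaled(edw)
    return CalibrationFit(
        kind="poly",
        order=order,
        coefficients=np.asarray(raw.coef, dtype=float),
        rmse_c=rmse(temp, pred),
        n=n,
        edw_range=(float(edw.min()), float(edw.max())),
        _scaled=scaled,
    )


def kfold_rmse(edw, temp, order: int, k: int = 5, seed: int = 0) -> float:
    """Pooled held-out RMSE of a polynomial calibration under k-fold CV.

    Folds come from a seeded shuffle into k near-equal parts; for each fold
    the model is fitted on the remainder and evaluated on the fold, and the
    squared errors are pooled over all held-out predictions.
    """
    edw = np.asarray(edw, dtype=float)
    temp = np.asarray(temp, dtype=float)
    if k < 2:
        raise ValueError("k-fold CV needs k >= 2")
    if edw.size < k:
        raise ValueError(f"need at least k={k} samples, got {edw.size}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    sq = np.empty_like(temp)
    for train, test in kf.split(edw):
        fit = fit_polynomial(edw[train], temp[train], order)
        sq[test] = (temp[test] - fit.predict(edw[test])) ** 2
    return float(np.sqrt(sq.mean()))


def alpha_at(params: ExpansionParams, temp) -> np.ndarray | float:
    """Volumetric thermal-expansion coefficient alpha(T) = b*T^2 + c*T + d."""
    t = np.asarray(temp, dtype=float)
    out = params.b * t**2 + params.c * t + params.d
    return float(out) if np.isscalar(temp) else out


def _alpha_integral(params: ExpansionParams, t: np.ndarray, as_printed: bool) -> np.ndarray:
    t0 = params.t0
    if as_printed:
        # audit mode: reproduces the published formula verbatim, where the c
        # term also carries (T^3 - T0^3) — dimensionally a typo, kept for
        # comparison against the printed equation only
        return (
            params.b / 3.0 * (t**3 - t0**3)
            + params.c / 2.0 * (t**3 - t0**3)
            + params.d * (t - t0)
        )
    return (
        params.b / 3.0 * (t**3 - t0**3)
        + params.c / 2.0 * (t**2 - t0**2)
        + params.d * (t - t0)
    )


def edw_forward(params: ExpansionParams, temp, as_printed: bool = False):
    """EDW predicted at temperature(s) by the thermal-expansion model.

    Raises in the unphysical regime where the expansion denominator
    ``1 + int alpha`` is not positive.
    """
    t = np.asarray(temp, dtype=float)
    den = 1.0 + _alpha_integral(params, t, as_printed)
    if np.any(den <= 0):
        raise ValueError("1 + integral(alpha) <= 0: unphysical expansion regime")
    out = params.edw_t0 / den
    return float(out) if np.isscalar(temp) else out


def fit_expansion(temp, edw, t0: float = 37.0, fix_b: bool = True,
                  max_nfev: int = 2000) -> ExpansionParams:
    """Fit the thermal-expansion model to measured (T, EDW) pairs.

    Nonlinear least squares over (EDW(T0), b, c, d), minimising squared EDW
    error; ``fix_b=True`` pins b = 0 so alpha(T) is linear in T. Starting
    values: EDW(T0) from the mean EDW of the coolest temperature decile, d
    from the slope of a linear EDW-vs-T fit divided by -EDW(T0) (the
    near-linear small-expansion regime), b = c = 0.
    """
    temp = np.asarray(temp, dtype=float)
    edw = np.asarray(edw, dtype=float)
    if temp.shape != edw.shape or temp.ndim != 1:
        raise ValueError("temp and edw must be 1D and of equal length")
    n_free = 3 if fix_b else 4
    if temp.size < n_free + 1:
        raise ValueError(f"need at least {n_free + 1} samples, got {temp.size}")
    if np.ptp(temp) < 10.0:
        raise ValueError("temperature span must be >= 10 degC to constrain alpha(T)")

    cool = temp <= np.quantile(temp, 0.1)
    edw0_init = float(edw[cool].mean())
    slope = float(np.polyfit(temp, edw, 1)[0])
    d_init = max(slope / -edw0_init, 1e-8)

    if fix_b:
        x0 = np.array([edw0_init, 0.0, d_init])
        scale = np.array([100.0, 1e-5, 1e-4])
        unpack = lambda th: ExpansionParams(edw_t0=th[0], t0=t0, b=0.0, c=th[1], d=th[2])
    else:
        x0 = np.array([edw0_init, 0.0, 0.0, d_init])
        scale = np.array([100.0, 1e-7, 1e-5, 1e-4])
        unpack = lambda th: ExpansionParams(edw_t0=th[0], t0=t0, b=th[1], c=th[2], d=th[3])

    def residual(th):
        p = unpack(th)
        den = 1.0 + _alpha_integral(p, temp, as_printed=False)
        # keep the optimiser out of the unphysical region with a smooth penalty
        bad = den <= 1e-6
        den = np.where(bad, 1e-6, den)
        return p.edw_t0 / den - edw

    res = optimize.least_squares(
        residual, x0, x_scale=scale, max_nfev=max_nfev,
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    if not res.success:
        raise RuntimeError(
            f"expansion fit did not converge ({res.message}); last iterate {res.x}"
        )
    return unpack(res.x)


def expansion_fit_summary(params: ExpansionParams, temp, edw) -> CalibrationFit:
    """Package a fitted expansion model with its in-sample EDW->T diagnostics."""
    temp = np.asarray(temp, dtype=float)
    edw = np.asarray(edw, dtype=float)
    pred_edw = edw_forward(params, temp)
    coeffs = np.array([params.b, params.c, params.d])
    return CalibrationFit(
        kind="expansion",
        order=None,
        coefficients=coeffs,
        rmse_c=rmse(edw, pred_edw),  # expansion model is fit in EDW units
        n=temp.size,
        edw_range=(float(edw.min()), float(edw.max())),
        expansion=params,
    )
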