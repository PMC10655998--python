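"""Plate immunoassay quantification: 4PL calibration, back-interpolation,
and detection/quantification limits.

The standard curve is the four-parameter logistic

    y = d + (a - d) / (1 + (x / c)^b)

with lower asymptote ``a`` (signal at zero analyte), upper asymptote ``d``,
inflection concentration ``c`` and slope ``b``; an optional asymmetry
exponent ``g`` extends it to 5PL. Samples are read off the fitted curve by
the closed-form inverse; signals outside the asymptote range are censored,
never extrapolated.

Limits follow blank statistics: the limit of detection (LOD) is the
concentration at the blank mean plus 2.5 blank SDs of signal, and the lower
limit of reliable quantification (LLOQ) is the lowest standard whose back
interpolation is within 100 +/- 20 %, whose duplicate CV is at most 20 %
and whose mean signal clears the blank mean by 9 blank SDs. The module is
platform-agnostic: electrochemiluminescence, time-resolved fluorescence and
multiplex plates all reduce to the same signal-versus-concentration table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .config import AssayQCParams
from .errors import FitError, PlateError

__all__ = [
    "Well",
    "CurveFit",
    "AssayLimits",
    "BackInterpResult",
    "wells_from_frame",
    "fit_curve",
    "back_interpolate",
    "compute_lod",
    "compute_lloq",
    "quantify_samples",
]


@dataclass(frozen=True)
class Well:
    """One well of a plate table."""

    row: str
    col: int
    role: str  # standard | blank | sample
    analyte: str
    signal: float
    nominal_conc: float | None = None
    replicate_group: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("standard", "blank", "sample"):
            raise PlateError(f"unknown well role {self.role!r}")
        if self.role == "standard" and (self.nominal_conc is None or not self.nominal_conc > 0):
            raise PlateError("standards must carry a positive nominal_conc")
        if not self.replicate_group:
            raise PlateError("replicate_group must be non-empty")
        if not np.isfinite(self.signal) or self.signal < 0:
            raise PlateError(f"signal must be finite and >= 0, got {self.signal}")


def wells_from_frame(df: pd.DataFrame) -> list[Well]:
    """Convert a validated plate DataFrame (see :func:`amyquant.io.read_plate`)
    into :class:`Well` objects."""
    wells = []
    for rec in df.to_dict("records"):
        conc = rec.get("nominal_conc")
        if conc is not None and (isinstance(conc, float) and math.isnan(conc)):
            conc = None
        wells.append(Well(
            row=str(rec["row"]), col=int(rec["col"]), role=str(rec["role"]),
            analyte=str(rec["analyte"]), signal=float(rec["signal"]),
            nominal_conc=conc, replicate_group=str(rec["replicate_group"]),
        ))
    return wells


@dataclass
class CurveFit:
    """Fitted standard-curve parameters."""

    model: str
    a: float
    d: float
    c: float
    b: float
    g: float | None = None
    weighting: str = "none"
    rss: float = math.nan
    converged: bool = False

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        base = 1.0 + np.power(np.where(x > 0, x, 0.0) / self.c, self.b)
        if self.model == "5PL":
            base = np.power(base, self.g)
        y = self.d + (self.a - self.d) / base
        return float(y) if y.ndim == 0 else y


class BackInterpResult(NamedTuple):
    """Concentration read off the curve, or a censoring status.

    ``conc`` is NaN whenever ``status`` is not ``"ok"``; status is one of
    ``ok``, ``below_range``, ``above_range``.
    """

    conc: float
    status: str


def _group_standards(standards: Sequence[Well]) -> pd.DataFrame:
    rows = [(w.nominal_conc, w.signal) for w in standards if w.role == "standard"]
    if not rows:
        raise FitError("no standard wells supplied")
    df = pd.DataFrame(rows, columns=["conc", "signal"])
    g = df.groupby("conc", sort=True)["signal"]
    out = pd.DataFrame({
        "nominal_conc": g.mean().index.to_numpy(dtype=float),
        "mean_signal": g.mean().to_numpy(),
        "sd_signal": g.std(ddof=1).fillna(0.0).to_numpy(),
        "n": g.size().to_numpy(),
    })
    return out


def fit_curve(standards: Sequence[Well], params: AssayQCParams | None = None) -> CurveFit:
    """Least-squares logistic fit to the standard duplicates.

    Initialisation is deterministic from the data: ``a`` at the lowest mean
    signal, ``d`` at the highest, ``c`` at the geometric mid-concentration
    and ``b`` at 1. At least five distinct standard concentrations are
    required; mean signals that decrease along the dilution series by more
    than 5 % of the overall signal range are treated as an ill-posed curve
    and rejected rather than silently fitted.
    """
    params = params or AssayQCParams()
    tab = _group_standards(standards)
    if len(tab) < 5:
        raise FitError(f"need >= 5 distinct standard concentrations, got {len(tab)}")
    conc = tab["nominal_conc"].to_numpy()
    means = tab["mean_signal"].to_numpy()
    rng_sig = means.max() - means.min()
    if rng_sig <= 0:
        raise FitError("standard signals are constant")
    dips = np.diff(means)
    if np.any(dips < -0.05 * rng_sig):
        raise FitError("standard mean signals are non-monotone beyond tolerance; "
                       "refusing to fit a logistic curve")

    x_all = np.array([w.nominal_conc for w in standards if w.role == "standard"], dtype=float)
    y_all = np.array([w.signal for w in standards if w.role == "standard"], dtype=float)
    if params.weighting == "1/y":
        w_all = np.sqrt(np.maximum(y_all, 1e-12))
    elif params.weighting == "1/y2":
        w_all = np.maximum(y_all, 1e-12)
    else:
        w_all = np.ones_like(y_all)

    a0 = float(means.min())
    d0 = float(means.max())
    c0 = float(np.exp(np.mean(np.log(conc))))
    five = params.curve_model == "5PL"

    def model(p: np.ndarray, x: np.ndarray) -> np.ndarray:
        a, d, c, b = p[:4]
        base = 1.0 + np.power(x / c, b)
        if five:
            base = np.power(base, p[4])
        return d + (a - d) / base

    def resid(p: np.ndarray) -> np.ndarray:
        return (model(p, x_all) - y_all) / w_all

    p0 = [a0, d0, c0, 1.0] + ([1.0] if five else [])
    lo = [-np.inf, -np.inf, conc.min() / 1e3, 1e-6] + ([1e-3] if five else [])
    hi = [np.inf, np.inf, conc.max() * 1e3, 50.0] + ([1e3] if five else [])
    sol = least_squares(resid, p0, bounds=(lo, hi), max_nfev=20000)
    p = sol.x
    fit = CurveFit(
        model=params.curve_model,
        a=float(p[0]), d=float(p[1]), c=float(p[2]), b=float(p[3]),
        g=float(p[4]) if five else None,
        weighting=params.weighting,
        rss=float(np.sum(sol.fun ** 2)),
        converged=bool(sol.success),
    )
    return fit


def back_interpolate(fit: CurveFit, signal: float) -> BackInterpResult:
    """Closed-form inverse of the fitted curve.

    ``x = c * ((a - d) / (y - d) - 1)^(1/b)`` for the 4PL (the 5PL inverse
    adds the asymmetry root). Signals at or beyond the asymptotes are
    censored as below/above range; no number is extrapolated.
    """
    if not fit.converged:
        raise FitError("cannot back-interpolate from a non-converged fit")
    y = float(signal)
    lo, hi = min(fit.a, fit.d), max(fit.a, fit.d)
    below_is_a = fit.a <= fit.d  # signal increases with concentration
    if y <= lo:
        return BackInterpResult(math.nan, "below_range" if below_is_a else "above_range")
    if y >= hi:
        return BackInterpResult(math.nan, "above_range" if below_is_a else "below_range")
    ratio = (fit.a - fit.d) / (y - fit.d)
    if fit.model == "5PL":
        ratio = ratio ** (1.0 / fit.g)
    x = fit.c * (ratio - 1.0) ** (1.0 / fit.b)
    return BackInterpResult(float(x), "ok")


class LODResult(NamedTuple):
    threshold_signal: float
    lod_conc: float
    status: str  # ok | censored_zero | above_range


def compute_lod(
    blanks: Sequence[Well],
    fit: CurveFit,
    params: AssayQCParams | None = None,
) -> LODResult:
    """Detection limit from blank statistics.

    The signal threshold is ``mean(blanks) + 2.5 * SD(blanks)`` (sample SD;
    set ``lod_add_blank_mean=False`` for the bare ``2.5 * SD`` form) and the
    LOD concentration is its back-interpolation. A threshold at or below
    the curve's lower asymptote censors the LOD at zero concentration.
    """
    params = params or AssayQCParams()
    sig = np.array([w.signal for w in blanks if w.role == "blank"], dtype=float)
    if len(sig) < 2:
        raise PlateError("need >= 2 blank wells for an SD-based limit")
    sd = float(sig.std(ddof=1))
    threshold = params.lod_sd_multiplier * sd
    if params.lod_add_blank_mean:
        threshold += float(sig.mean())
    bi = back_interpolate(fit, threshold)
    if bi.status == "below_range":
        return LODResult(threshold, 0.0, "censored_zero")
    if bi.status == "above_range":
        return LODResult(threshold, math.nan, "above_range")
    return LODResult(threshold, bi.conc, "ok")


@dataclass
class AssayLimits:
    """LOD/LLOQ and the per-standard qualification table.

    ``lloq_conc`` is NaN when no standard passes all three rules.
    ``per_standard`` has one row per nominal concentration with the mean
    signal, CV %, back interpolation % and the pass flag.
    """

    lod_conc: float
    lloq_conc: float
    lod_threshold_signal: float
    per_standard: pd.DataFrame = field(repr=False, default=None)


def compute_lloq(
    standards: Sequence[Well],
    blanks: Sequence[Well],
    fit: CurveFit,
    params: AssayQCParams | None = None,
) -> AssayLimits:
    """Qualify each standard and take the lowest passing one as the LLOQ.

    A standard passes iff its back interpolation lies within the configured
    band (default 80-120 %), its replicate CV is at most 20 % and its mean
    signal exceeds the blank mean by 9 blank SDs. Duplicates are grouped by
    nominal concentration.
    """
    params = params or AssayQCParams()
    tab = _group_standards(standards)
    blank_sig = np.array([w.signal for w in blanks if w.role == "blank"], dtype=float)
    if len(blank_sig) < 2:
        raise PlateError("need >= 2 blank wells")
    blank_gate = float(blank_sig.mean()) + params.blank_sd_multiplier * float(blank_sig.std(ddof=1))

    cv = 100.0 * tab["sd_signal"] / tab["mean_signal"].replace(0.0, np.nan)
    cv = cv.fillna(np.inf).to_numpy()
    backinterp = np.full(len(tab), np.nan)
    for i, (conc_i, mean_i) in enumerate(zip(tab["nominal_conc"], tab["mean_signal"])):
        bi = back_interpolate(fit, mean_i)
        if bi.status == "ok":
            backinterp[i] = 100.0 * bi.conc / conc_i
    passes = (
        (backinterp >= params.lloq_backinterp_low_pct)
        & (backinterp <= params.lloq_backinterp_high_pct)
        & (cv <= params.lloq_cv_max_pct)
        & (tab["mean_signal"].to_numpy() > blank_gate)
    )
    per_standard = pd.DataFrame({
        "nominal_conc": tab["nominal_conc"],
        "mean_signal": tab["mean_signal"],
        "cv_pct": cv,
        "backinterp_pct": backinterp,
        "passes": passes,
    })
    lloq = float(per_standard.loc[passes, "nominal_conc"].min()) if passes.any() else math.nan
    lod = compute_lod(blanks, fit, params)
    return AssayLimits(
        lod_conc=lod.lod_conc,
        lloq_conc=lloq,
        lod_threshold_signal=lod.threshold_signal,
        per_standard=per_standard,
    )


def quantify_samples(
    samples: Sequence[Well],
    fit: CurveFit,
    limits: AssayLimits,
    dilution: float = 1.0,
    tissue_norm: float | None = None,
) -> pd.DataFrame:
    """Back-interpolate sample duplicates against the fitted curve.

    Duplicates (grouped by ``replicate_group``) are averaged in signal
    space, read off the curve, multiplied by the dilution factor and
    optionally divided by a tissue mass for per-mass reporting. Censoring
    is one-way: wells whose mean signal sits below the LOD threshold, or
    outside the curve range, report NaN with a status flag; wells between
    LOD and LLOQ keep their estimate but are flagged ``<LLOQ``.
    """
    groups: dict[str, list[Well]] = {}
    for w in samples:
        if w.role == "sample":
            groups.setdefault(w.replicate_group, []).append(w)
    rows = []
    for name in sorted(groups):
        mean_sig = float(np.mean([w.signal for w in groups[name]]))
        if mean_sig < limits.lod_threshold_signal:
            rows.append((name, mean_sig, math.nan, "<LOD"))
            continue
        bi = back_interpolate(fit, mean_sig)
        if bi.status != "ok":
            rows.append((name, mean_sig, math.nan, bi.status))
            continue
        conc = bi.conc * dilution
        if tissue_norm is not None:
            conc /= tissue_norm
        status = "ok"
        if not math.isnan(limits.lloq_conc) and bi.conc < limits.lloq_conc:
            status = "<LLOQ"
        rows.append((name, mean_sig, conc, status))
    return pd.DataFrame(rows, columns=["sample", "mean_signal", "conc", "censor_status"])
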