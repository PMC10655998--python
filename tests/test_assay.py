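import math

import numpy as np
import pytest

from amyquant.assay import (
    Well,
    back_interpolate,
    compute_lloq,
    compute_lod,
    fit_curve,
    quantify_samples,
)
from amyquant.config import AssayQCParams
from amyquant.errors import FitError, PlateError
from amyquant.simulate import SyntheticPlateSpec, render_plate


def _std(conc, signal, group=None):
    return Well(row="A", col=1, role="standard", analyte="x", signal=signal,
                nominal_conc=conc, replicate_group=group or f"STD{conc}")


def _blank(signal):
    return Well(row="A", col=13, role="blank", analyte="x", signal=signal,
                replicate_group="BLANK")


def _noiseless_standards(spec=None):
    spec = spec or SyntheticPlateSpec(noise_cv_pct=0.0)
    wells, _ = render_plate(spec)
    return [w for w in wells if w.role == "standard"]


def test_noiseless_twelve_point_curve_recovers_parameters_exactly():
    fit = fit_curve(_noiseless_standards())
    assert fit.converged
    assert fit.a == pytest.approx(100.0, rel=1e-3)
    assert fit.d == pytest.approx(10000.0, rel=1e-3)
    assert fit.c == pytest.approx(50.0, rel=1e-3)
    assert fit.b == pytest.approx(1.2, rel=1e-3)


def test_midpoint_signal_back_interpolates_to_inflection():
    fit = fit_curve(_noiseless_standards())
    mid = (fit.a + fit.d) / 2
    assert back_interpolate(fit, mid).conc == pytest.approx(fit.c, rel=1e-9)


def test_forward_then_inverse_identity(rng):
    fit = fit_curve(_noiseless_standards())
    xs = np.exp(rng.uniform(np.log(0.5), np.log(400), size=200))
    for x in xs:
        bi = back_interpolate(fit, fit.predict(x))
        assert bi.status == "ok"
        assert bi.conc == pytest.approx(x, rel=1e-8)


def test_out_of_range_signals_are_censored_not_extrapolated():
    fit = fit_curve(_noiseless_standards())
    assert back_interpolate(fit, fit.d * 1.01).status == "above_range"
    assert back_interpolate(fit, fit.a * 0.5).status == "below_range"
    assert math.isnan(back_interpolate(fit, fit.d * 1.01).conc)


def test_too_few_concentrations_rejected():
    wells = [_std(c, 100 * c) for c in (1, 2, 4, 8)]
    with pytest.raises(FitError):
        fit_curve(wells)


def test_non_monotone_standards_rejected():
    concs = SyntheticPlateSpec().standard_concs
    spec = SyntheticPlateSpec(noise_cv_pct=0.0)
    wells = [_std(c, float(spec.curve(c))) for c in concs]
    # corrupt one mid-curve mean far beyond tolerance
    wells[4] = _std(wells[4].nominal_conc, wells[4].signal * 0.3)
    with pytest.raises(FitError):
        fit_curve(wells)


def test_parameter_recovery_under_multiplicative_noise():
    """At 1 % CV multiplicative noise with variance-matched weighting, the
    asymptotes and inflection recover within 5 % (slope within 10 %) on
    every one of 100 simulated plates."""
    params = AssayQCParams(weighting="1/y2")
    errs = []
    for seed in range(100):
        wells, _ = render_plate(SyntheticPlateSpec(noise_cv_pct=1.0, seed=seed))
        fit = fit_curve([w for w in wells if w.role == "standard"], params)
        errs.append([
            abs(fit.a - 100.0) / 100.0,
            abs(fit.d - 10000.0) / 10000.0,
            abs(fit.c - 50.0) / 50.0,
            abs(fit.b - 1.2) / 1.2,
        ])
    errs = np.asarray(errs)
    assert errs[:, :3].max() < 0.05
    assert errs[:, 3].max() < 0.10


def test_lod_arithmetic_on_known_blanks():
    fit = fit_curve(_noiseless_standards())
    lod = compute_lod([_blank(10), _blank(12), _blank(14)], fit)
    assert lod.threshold_signal == pytest.approx(17.0)  # 12 + 2.5 * 2


def test_lod_with_degenerate_blanks():
    fit = fit_curve(_noiseless_standards())
    lod = compute_lod([_blank(105), _blank(105)], fit)
    assert lod.threshold_signal == pytest.approx(105.0)
    # blanks at or below the asymptote censor the LOD at zero
    lod0 = compute_lod([_blank(99.0), _blank(99.0)], fit)
    assert lod0.status == "censored_zero" and lod0.lod_conc == 0.0


def test_literal_lod_formula_available():
    fit = fit_curve(_noiseless_standards())
    params = AssayQCParams(lod_add_blank_mean=False)
    lod = compute_lod([_blank(10), _blank(12), _blank(14)], fit, params)
    assert lod.threshold_signal == pytest.approx(5.0)  # 2.5 * SD only


def _constructed_lloq_plate():
    """Noiseless plate where exactly the top 8 standards pass: the lowest 4
    get inflated duplicate spread (CV > 20 %)."""
    spec = SyntheticPlateSpec(noise_cv_pct=0.0)
    concs = spec.standard_concs
    wells = []
    for i, c in enumerate(concs):
        y = float(spec.curve(c))
        if i >= 8:  # four lowest concentrations: duplicates 60 % apart
            wells += [_std(c, y * 0.7, f"STD{i}"), _std(c, y * 1.3, f"STD{i}")]
        else:
            wells += [_std(c, y, f"STD{i}"), _std(c, y, f"STD{i}")]
    blanks = [_blank(100.5), _blank(101.0)]
    return wells, blanks, concs


def test_lloq_is_lowest_passing_standard():
    wells, blanks, concs = _constructed_lloq_plate()
    fit = fit_curve(_noiseless_standards())  # clean fit; QC runs on the distorted plate
    limits = compute_lloq(wells, blanks, fit)
    expected = float(np.sort(concs)[::-1][7])  # 8th from the top
    assert limits.lloq_conc == pytest.approx(expected)
    table = limits.per_standard
    assert table["passes"].sum() == 8
    assert limits.lod_conc <= limits.lloq_conc
    # independent rule-by-rule check of every row
    blank_gate = 100.75 + 9 * np.std([100.5, 101.0], ddof=1)
    for row in table.itertuples():
        bi = back_interpolate(fit, row.mean_signal)
        backpct = 100 * bi.conc / row.nominal_conc if bi.status == "ok" else np.nan
        should = (not np.isnan(backpct) and 80 <= backpct <= 120
                  and row.cv_pct <= 20 and row.mean_signal > blank_gate)
        assert bool(row.passes) == should


def test_lloq_undefined_when_all_cv_fail():
    spec = SyntheticPlateSpec(noise_cv_pct=0.0)
    wells = []
    for i, c in enumerate(spec.standard_concs):
        y = float(spec.curve(c))
        wells += [_std(c, y * 0.7, f"S{i}"), _std(c, y * 1.3, f"S{i}")]
    fit = fit_curve(_noiseless_standards())
    limits = compute_lloq(wells, [_blank(100.5), _blank(101.0)], fit)
    assert math.isnan(limits.lloq_conc)


def test_samples_quantified_against_ground_truth():
    """Simulated samples at 2 % noise come back with small relative error,
    and censoring is one-way (no numeric value for censored wells)."""
    spec = SyntheticPlateSpec(noise_cv_pct=2.0, sample_concs=(5, 20, 80, 200), seed=3)
    wells, truth = render_plate(spec)
    std = [w for w in wells if w.role == "standard"]
    blanks = [w for w in wells if w.role == "blank"]
    samples = [w for w in wells if w.role == "sample"]
    fit = fit_curve(std, AssayQCParams(weighting="1/y2"))
    limits = compute_lloq(std, blanks, fit)
    out = quantify_samples(samples, fit, limits)
    rel = []
    for row in out.itertuples():
        true = truth["sample_concs"][row.sample]
        if row.censor_status in ("ok", "<LLOQ"):
            rel.append(abs(row.conc - true) / true)
        else:
            assert math.isnan(row.conc)
    assert np.median(rel) < 0.05


def test_sample_below_lod_censored():
    fit = fit_curve(_noiseless_standards())
    limits = compute_lloq(_noiseless_standards(), [_blank(102), _blank(108)], fit)
    low = Well(row="A", col=20, role="sample", analyte="x", signal=101.0,
               replicate_group="S1")
    out = quantify_samples([low], fit, limits)
    assert out.loc[0, "censor_status"] == "<LOD"
    assert math.isnan(out.loc[0, "conc"])


def test_dilution_and_mass_normalisation():
    fit = fit_curve(_noiseless_standards())
    limits = compute_lloq(_noiseless_standards(), [_blank(100.2), _blank(100.4)], fit)
    s = Well(row="A", col=20, role="sample", analyte="x",
             signal=float(fit.predict(50.0)), replicate_group="S1")
    out = quantify_samples([s], fit, limits, dilution=10.0, tissue_norm=2.0)
    assert out.loc[0, "conc"] == pytest.approx(50.0 * 10.0 / 2.0, rel=1e-6)


def test_blank_preconditions():
    fit = fit_curve(_noiseless_standards())
    with pytest.raises(PlateError):
        compute_lod([_blank(10)], fit)
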