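"""Viability arithmetic, 4PL fitting, ANOVA/Dunnett, combination grids."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pepscreen import dose_response as dr
from pepscreen import synthetic as syn


# ---------------------------------------------------------------------------
# percent viability

def test_viability_identity_and_zero():
    assert dr.percent_viability(0.9, 0.9, 0.05) == pytest.approx(100.0)
    assert dr.percent_viability(0.05, 0.9, 0.05) == pytest.approx(0.0)


def test_viability_hand_arithmetic():
    assert dr.percent_viability(0.45, 0.90, 0.05) == pytest.approx(100 * 0.40 / 0.85)


def test_viability_bad_control():
    with pytest.raises(dr.PlateError):
        dr.percent_viability(0.5, 0.05, 0.05)


def test_viability_affine_invariance(rng):
    for _ in range(50):
        blank = rng.uniform(0.01, 0.2)
        control = blank + rng.uniform(0.3, 1.0)
        treated = blank + rng.uniform(0.0, 1.0)
        c = rng.uniform(0.1, 10)
        assert dr.percent_viability(c * treated, c * control, c * blank) == pytest.approx(
            dr.percent_viability(treated, control, blank)
        )


# ---------------------------------------------------------------------------
# 4PL fitting

def _noiseless_dataset(top, bottom, ic50, hill, doses=(0, 12.5, 25, 50, 100, 200, 400), n_rep=3):
    doses = np.asarray(doses, dtype=float)
    v = dr.four_pl(doses, top, bottom, ic50, hill)
    return dr.DoseResponseDataset("test", doses, np.tile(v[:, None], (1, n_rep)), 72.0)


def test_4pl_model_top_at_zero_dose():
    assert dr.four_pl(0.0, 95.0, 5.0, 50.0, 2.0) == pytest.approx(95.0)


def test_4pl_noiseless_recovery():
    ds = _noiseless_dataset(100, 0, 50, 1.5)
    fit = dr.fit_4pl(ds, bootstrap=0)
    assert fit.converged
    for got, truth in [(fit.top, 100), (fit.bottom, 0), (fit.ic50, 50), (fit.hill, 1.5)]:
        assert abs(got - truth) <= 1e-6 * max(1.0, abs(truth))


@pytest.mark.parametrize("hill", [0.5, 1.0, 2.0, 4.0])
@pytest.mark.parametrize("ic50", [20.0, 80.0, 300.0])
def test_4pl_noiseless_grid(hill, ic50):
    ds = _noiseless_dataset(100, 0, ic50, hill)
    fit = dr.fit_4pl(ds, bootstrap=0)
    assert fit.converged
    assert abs(fit.ic50 - ic50) / ic50 < 1e-6
    assert abs(fit.hill - hill) / hill < 1e-6


def test_4pl_flat_data_no_inhibition_flag():
    ds = _noiseless_dataset(100, 100, 50, 1.5)
    fit = dr.fit_4pl(ds, bootstrap=0)
    assert fit.no_inhibition and not fit.converged
    assert np.isnan(fit.ic50)


def test_4pl_requires_four_doses():
    ds = dr.DoseResponseDataset("t", [0, 10, 100], np.full((3, 2), 50.0), 72.0)
    with pytest.raises(ValueError):
        dr.fit_4pl(ds)


def test_4pl_ic50_outside_range_flag():
    # true IC50 sits above the top tested dose, but inhibition is visible
    ds = _noiseless_dataset(100, 0, 40, 1.5, doses=(0, 1, 2, 4, 8, 16))
    fit = dr.fit_4pl(ds, bootstrap=0)
    assert fit.converged and fit.ic50_outside_range


def test_plate_roundtrip_recovers_truth_without_noise():
    scenario = dataclasses.replace(syn.C_ORI, noise_sd=0.0)
    plate = syn.gen_mtt(scenario, seed=7)
    ds = dr.viability_from_plate(plate, scenario.name, 72.0)
    fit = dr.fit_4pl(ds, bootstrap=0)
    assert abs(fit.ic50 - scenario.ic50_uM) / scenario.ic50_uM < 1e-6
    assert abs(fit.hill - scenario.hill) / scenario.hill < 1e-6


def test_plate_requires_blank_and_control():
    plate = syn.gen_mtt(syn.C_ORI, seed=1)
    no_blank = plate[plate["role"] != "blank"]
    with pytest.raises(dr.PlateError):
        dr.viability_from_plate(no_blank, "C-ori", 72.0)


def test_ic50_estimator_calibration():
    """Over 100 synthetic plates at the active-peptide scenario the median
    fitted IC50 (complete-inhibition convention) is within 2% of truth and
    its spread stays within 3x the nominal noise scale."""
    truth = syn.C_ORI.ic50_uM
    fits = []
    for seed in range(100, 200):
        plate = syn.gen_mtt(syn.C_ORI, seed=seed)
        ds = dr.viability_from_plate(plate, syn.C_ORI.name, 72.0)
        fit = dr.fit_4pl(ds, bootstrap=0, fix_bottom=0.0)
        assert fit.converged
        fits.append(fit.ic50)
    fits = np.array(fits)
    assert abs(np.median(fits) - truth) / truth < 0.02
    assert fits.std(ddof=1) < 3 * syn.C_ORI.noise_sd


def test_fix_bottom_noiseless_recovery():
    ds = _noiseless_dataset(100, 0, 75, 2.0)
    fit = dr.fit_4pl(ds, bootstrap=0, fix_bottom=0.0)
    assert fit.converged and fit.bottom == 0.0
    assert abs(fit.ic50 - 75) / 75 < 1e-6
    assert fit.se["bottom"] == 0.0


def test_bootstrap_sd_reported():
    plate = syn.gen_mtt(syn.C_ORI, seed=3)
    ds = dr.viability_from_plate(plate, "C-ori", 72.0)
    fit = dr.fit_4pl(ds, bootstrap=50)
    assert fit.converged and np.isfinite(fit.ic50_bootstrap_sd)
    assert 0 < fit.ic50_bootstrap_sd < 50


# ---------------------------------------------------------------------------
# ANOVA + Dunnett

def _long(groups: dict) -> pd.DataFrame:
    rows = [
        {"condition": name, "viability": v} for name, vals in groups.items() for v in vals
    ]
    return pd.DataFrame(rows)


def test_identical_conditions_not_significant(rng):
    vals = rng.normal(100, 1, 8)
    df = _long({"control": vals, "treated": vals + rng.normal(0, 1e-6, 8)})
    res = dr.compare_conditions(df, control="control")
    assert res.anova_p > 0.5
    assert (res.summary.loc[res.summary.condition == "treated", "p_adj"] > 0.5).all()
    assert (res.summary.loc[res.summary.condition == "treated", "flag"] == "").all()


def test_large_separation_highly_significant(rng):
    df = _long({"control": rng.normal(100, 1, 4), "treated": rng.normal(50, 1, 4)})
    res = dr.compare_conditions(df, control="control")
    p = float(res.summary.loc[res.summary.condition == "treated", "p_adj"].iloc[0])
    assert p < 0.01
    assert res.summary.loc[res.summary.condition == "treated", "flag"].iloc[0] == "**"


def test_single_replicate_rejected():
    df = _long({"control": [100, 101], "treated": [50]})
    with pytest.raises(ValueError, match="single replicate"):
        dr.compare_conditions(df, control="control")


def test_missing_control_rejected():
    df = _long({"a": [1, 2], "b": [3, 4]})
    with pytest.raises(ValueError):
        dr.compare_conditions(df, control="control")


def test_dunnett_adjusted_p_at_least_marginal_p(rng):
    """The many-to-one adjusted p can never undercut the single-comparison
    p computed from the same pooled-variance t statistic."""
    for trial in range(20):
        groups = {f"g{j}": rng.normal(100, 5, 4) for j in range(3)}
        control = rng.normal(100, 5, 4)
        dres = stats.dunnett(*groups.values(), control=control, rng=trial)
        n_total = 16
        df_resid = n_total - 4
        raw = 2 * stats.t.sf(np.abs(dres.statistic), df_resid)
        assert np.all(dres.pvalue >= raw - 1e-10)


# ---------------------------------------------------------------------------
# combination grids

def _combo_grid(rng, combo_shift=0.0, sd=2.0, n=4, center=False):
    rows = []
    for p in (0, 100):
        for d in (0, 0.1):
            mean = 100.0 - (20.0 if p else 0.0) - (30.0 if d else 0.0)
            if p and d:
                mean -= combo_shift
            noise = rng.normal(0, sd, n)
            if center:  # exact group means, scatter only within groups
                noise -= noise.mean()
            for r in range(n):
                rows.append(
                    {
                        "peptide_dose_uM": p,
                        "dox_dose_uM": d,
                        "replicate": r,
                        "viability": mean + noise[r],
                    }
                )
    return pd.DataFrame(rows)


def test_combo_equal_to_margins_not_significant(rng):
    # combo sits exactly at the peptide-margin level
    grid = _combo_grid(rng, combo_shift=-30.0, center=True)
    res = dr.combination_analysis(grid)
    cell = res[(res.peptide_dose_uM > 0) & (res.dox_dose_uM > 0)].iloc[0]
    assert cell["p_vs_pep_margin"] > 0.05


def test_combo_lower_than_margins_detected(rng):
    grid = _combo_grid(rng, combo_shift=10.0)  # 10 points below additive margins
    res = dr.combination_analysis(grid)
    cell = res[(res.peptide_dose_uM > 0) & (res.dox_dose_uM > 0)].iloc[0]
    assert cell["p_vs_pep_margin"] < 0.05
    assert cell["dir_vs_pep_margin"] == "lower"
    assert cell["dir_vs_control"] == "lower"


def test_combo_missing_margins_rejected(rng):
    grid = _combo_grid(rng)
    no_margin = grid[~((grid.peptide_dose_uM == 0) & (grid.dox_dose_uM > 0))]
    with pytest.raises(ValueError):
        dr.combination_analysis(no_margin)


def test_synthetic_combo_grid_analysis_runs(rng):
    grid = syn.gen_combo_mtt(seed=11)
    res = dr.combination_analysis(grid)
    cells = res[(res.peptide_dose_uM > 0) & (res.dox_dose_uM > 0)]
    assert not cells.empty
    assert {"p_vs_control", "p_vs_pep_margin", "p_vs_dox_margin"} <= set(cells.columns)
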