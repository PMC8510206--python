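"""MTT dose–response analysis: viability, 4PL IC50 fits, comparisons.

Cell viability is computed from 570-nm absorbances as

    % viability = 100 · (A_treated − A_blank) / (A_control − A_blank)

replicate-wise against the per-timepoint mean blank and mean corrected
control.  Dose–response curves are fitted with the four-parameter logistic

    V(d) = bottom + (top − bottom) / (1 + (d / IC50)^hill)

so that V(0) = top analytically (dose 0 is fitted, not dropped).  Group
comparisons use one-way ANOVA followed by Dunnett's many-to-one test
against the control, with the conventional significance flags
(* p < 0.05, ** p < 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import optimize, stats

PLATE_COLUMNS = ["condition", "compound", "dose_uM", "timepoint_h", "replicate", "absorbance", "role"]

DUNNETT_METHOD = "scipy.stats.dunnett (many-to-one multivariate t)"


class PlateError(ValueError):
    """Bad plate data (e.g. non-positive corrected control)."""


def percent_viability(treated_abs: float, control_abs: float, blank_abs: float) -> float:
    """Blank-corrected viability percentage for one well."""
    denom = control_abs - blank_abs
    if denom <= 0:
        raise PlateError(
            f"corrected control absorbance must be positive, got {denom:.4g}"
        )
    return 100.0 * (treated_abs - blank_abs) / denom


@dataclass
class DoseResponseDataset:
    """Viability matrix for one compound at one timepoint."""

    compound: str
    doses: np.ndarray            # µM, strictly increasing, includes 0
    viability: np.ndarray        # shape (n_doses, n_replicates), percent
    timepoint_h: float

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if np.any(self.doses < 0) or np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be non-negative and strictly increasing")
        if not np.all(np.isfinite(self.viability)):
            raise ValueError("viability contains non-finite values")

    def mean_sd(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose_uM": self.doses,
                "mean_viability": self.viability.mean(axis=1),
                "sd_viability": self.viability.std(axis=1, ddof=1),
            }
        )


def viability_from_plate(
    plate: pd.DataFrame, compound: str, timepoint_h: float
) -> DoseResponseDataset:
    """Apply the viability formula to a long-format plate table.

    Blank correction uses the per-timepoint mean blank; the control level
    is the mean corrected absorbance of the control wells.  Each treated
    well yields one replicate viability.
    """
    sub = plate[plate["timepoint_h"] == timepoint_h]
    blanks = sub.loc[sub["role"] == "blank", "absorbance"]
    controls = sub.loc[sub["role"] == "control", "absorbance"]
    if blanks.empty or controls.empty:
        raise PlateError(
            f"timepoint {timepoint_h} h needs >= 1 blank and >= 1 control well"
        )
    blank = float(blanks.mean())
    control = float(controls.mean())
    if control - blank <= 0:
        raise PlateError("corrected control absorbance is non-positive (bad plate)")
    treated = sub[(sub["role"] == "treated") & (sub["compound"] == compound)]
    piv = treated.pivot_table(
        index="dose_uM", columns="replicate", values="absorbance"
    ).sort_index()
    viability = 100.0 * (piv.to_numpy() - blank) / (control - blank)
    doses = piv.index.to_numpy(dtype=float)
    if doses[0] != 0.0:
        # dose 0 wells are the controls themselves
        n_rep = viability.shape[1]
        ctrl_v = 100.0 * (controls.to_numpy()[:n_rep] - blank) / (control - blank)
        doses = np.concatenate([[0.0], doses])
        viability = np.vstack([ctrl_v, viability])
    return DoseResponseDataset(compound, doses, viability, timepoint_h)


# ---------------------------------------------------------------------------
# 4PL fitting

def four_pl(d, top, bottom, ic50, hill):
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(d > 0, (d / ic50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


@dataclass
class FourPLFit:
    compound: str
    top: float
    bottom: float
    ic50: float
    hill: float
    se: dict = field(default_factory=dict)      # parameter standard errors
    converged: bool = True
    no_inhibition: bool = False
    ic50_outside_range: bool = False
    residual_sd: float = float("nan")
    ic50_bootstrap_sd: float = float("nan")
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "compound": self.compound,
            "top": self.top,
            "bottom": self.bottom,
            "ic50_uM": self.ic50,
            "hill": self.hill,
            "se": self.se,
            "converged": self.converged,
            "no_inhibition": self.no_inhibition,
            "ic50_outside_range": self.ic50_outside_range,
            "residual_sd": self.residual_sd,
            "ic50_bootstrap_sd": self.ic50_bootstrap_sd,
            "message": self.message,
        }


#: mean-viability dynamic range (percentage points) below which a curve is
#: reported as showing no inhibition rather than fitted for an IC50
NO_INHIBITION_RANGE = 20.0

_BOUNDS_LO = (0.0, 0.0, None, 0.1)   # top, bottom, ic50 (set per-data), hill
_BOUNDS_HI = (120.0, 120.0, None, 10.0)


def fit_4pl(
    dataset: DoseResponseDataset,
    bootstrap: int = 199,
    bootstrap_seed: int = 1234,
    fix_bottom: float | None = None,
) -> FourPLFit:
    """Bounded deterministic least-squares 4PL fit.

    Initializer: top = max mean viability, bottom = min mean viability,
    IC50 = dose nearest the half-way response, hill = 1; no random
    restarts.  Parameter standard errors come from the curvature
    (Jacobian) at the optimum; the IC50 additionally gets a replicate-level
    bootstrap SD (fixed seed, ``bootstrap`` resamples).

    ``fix_bottom`` pins the lower plateau (e.g. at 0 for a cytotoxicity
    assay whose response floor is known).  Estimating a plateau that truly
    sits on the 0% boundary truncates its sampling noise and drags the
    fitted IC50 downward by a few percent, so for complete-inhibition
    compounds ``fix_bottom=0.0`` is the calibrated convention.

    Flat curves (mean-viability range below ``NO_INHIBITION_RANGE``
    points) are flagged ``no_inhibition`` and not assigned an IC50.
    """
    doses = dataset.doses
    if len(doses) < 4:
        raise ValueError("need >= 4 distinct doses for a 4PL fit")
    means = dataset.viability.mean(axis=1)
    if means.max() - means.min() < NO_INHIBITION_RANGE:
        return FourPLFit(
            dataset.compound,
            top=float(means.mean()), bottom=float(means.mean()),
            ic50=float("nan"), hill=float("nan"),
            converged=False, no_inhibition=True,
            message="viability flat across doses; no IC50 estimated",
        )

    d_flat = np.repeat(doses, dataset.viability.shape[1])
    v_flat = dataset.viability.ravel()
    popt, pcov, ok, msg = _fit_once(doses, means, d_flat, v_flat, fix_bottom)
    if not ok:
        return FourPLFit(
            dataset.compound, *popt, converged=False, message=msg
        )
    top, bottom, ic50, hill = popt
    resid = v_flat - four_pl(d_flat, *popt)
    dof = max(len(v_flat) - 4, 1)
    residual_sd = float(np.sqrt(resid @ resid / dof))
    se = {}
    if pcov is not None and np.all(np.isfinite(pcov)):
        err = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        se = dict(zip(("top", "bottom", "ic50", "hill"), map(float, err)))

    boot_sd = float("nan")
    if bootstrap > 0:
        rng = np.random.default_rng(bootstrap_seed)
        n_rep = dataset.viability.shape[1]
        est = []
        for _ in range(bootstrap):
            idx = rng.integers(0, n_rep, size=n_rep)
            vb = dataset.viability[:, idx]
            mb = vb.mean(axis=1)
            pb, _, okb, _ = _fit_once(doses, mb, np.repeat(doses, n_rep), vb.ravel(), fix_bottom)
            if okb:
                est.append(pb[2])
        if len(est) >= 2:
            boot_sd = float(np.std(est, ddof=1))

    max_dose = doses.max()
    min_pos = doses[doses > 0].min()
    return FourPLFit(
        dataset.compound,
        top=float(top), bottom=float(bottom), ic50=float(ic50), hill=float(hill),
        se=se, converged=True,
        ic50_outside_range=not (min_pos <= ic50 <= max_dose),
        residual_sd=residual_sd,
        ic50_bootstrap_sd=boot_sd,
    )


def _fit_once(doses, means, d_flat, v_flat, fix_bottom=None):
    top0 = float(means.max())
    bottom0 = float(means.min()) if fix_bottom is None else float(fix_bottom)
    half = (top0 + bottom0) / 2.0
    pos = doses > 0
    ic50_0 = float(doses[pos][np.argmin(np.abs(means[pos] - half))])
    min_pos = doses[pos].min()
    ic50_lo, ic50_hi = min_pos / 1e3, doses.max() * 1e3
    try:
        if fix_bottom is None:
            p0 = (min(top0, 120.0), max(bottom0, 0.0), ic50_0, 1.0)
            lo = (_BOUNDS_LO[0], _BOUNDS_LO[1], ic50_lo, _BOUNDS_LO[3])
            hi = (_BOUNDS_HI[0], _BOUNDS_HI[1], ic50_hi, _BOUNDS_HI[3])
            popt, pcov = optimize.curve_fit(
                four_pl, d_flat, v_flat, p0=p0, bounds=(lo, hi),
                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000,
            )
            return popt, pcov, True, ""
        model = lambda d, top, ic50, hill: four_pl(d, top, fix_bottom, ic50, hill)
        p0 = (min(top0, 120.0), ic50_0, 1.0)
        lo = (_BOUNDS_LO[0], ic50_lo, _BOUNDS_LO[3])
        hi = (_BOUNDS_HI[0], ic50_hi, _BOUNDS_HI[3])
        p3, pcov3 = optimize.curve_fit(
            model, d_flat, v_flat, p0=p0, bounds=(lo, hi),
            method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000,
        )
        popt = np.array([p3[0], fix_bottom, p3[1], p3[2]])
        # expand covariance with a zero row/column for the fixed plateau
        pcov = np.zeros((4, 4))
        idx = [0, 2, 3]
        for a, ia in enumerate(idx):
            for b, ib in enumerate(idx):
                pcov[ia, ib] = pcov3[a, b]
        return popt, pcov, True, ""
    except (RuntimeError, ValueError) as exc:
        return (np.nan, np.nan, np.nan, np.nan), None, False, str(exc)


# ---------------------------------------------------------------------------
# ANOVA + Dunnett comparisons

@dataclass
class ComparisonResult:
    summary: pd.DataFrame        # condition, n, mean, sd, p_adj, flag
    anova_f: float
    anova_p: float
    control: str
    method: str = DUNNETT_METHOD


def _flag(p: float) -> str:
    return "**" if p < 0.01 else ("*" if p < 0.05 else "")


def compare_conditions(
    viability: pd.DataFrame,
    control: str,
    value_col: str = "viability",
    group_col: str = "condition",
    rng: int = 0,
) -> ComparisonResult:
    """One-way ANOVA over all conditions plus Dunnett's test of every
    non-control condition against the control.

    ``viability`` is long-format with one row per replicate.  Requires at
    least two replicates per condition.
    """
    groups = {k: g[value_col].to_numpy(dtype=float) for k, g in viability.groupby(group_col)}
    if control not in groups:
        raise ValueError(f"control condition {control!r} absent from table")
    if len(groups) < 2:
        raise ValueError("need >= 2 conditions including the control")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"condition {name!r} has a single replicate")
    treated_names = [k for k in groups if k != control]
    anova_f, anova_p = stats.f_oneway(*groups.values())
    dres = stats.dunnett(
        *[groups[k] for k in treated_names], control=groups[control], rng=rng
    )
    p_adj = dict(zip(treated_names, map(float, np.atleast_1d(dres.pvalue))))
    rows = []
    for name in [control] + treated_names:
        vals = groups[name]
        p = p_adj.get(name, float("nan"))
        rows.append(
            {
                "condition": name,
                "n": len(vals),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)),
                "p_adj": p,
                "flag": _flag(p) if name != control else "",
            }
        )
    return ComparisonResult(pd.DataFrame(rows), float(anova_f), float(anova_p), control)


# ---------------------------------------------------------------------------
# combination grids

def combination_analysis(
    grid: pd.DataFrame,
    peptide_col: str = "peptide_dose_uM",
    dox_col: str = "dox_dose_uM",
    value_col: str = "viability",
    rng: int = 0,
) -> pd.DataFrame:
    """Analyse a peptide × doxorubicin factorial viability grid.

    Requires monotherapy margins (rows with one of the two doses at 0) and
    the shared control (0, 0).  For every combination cell the cell is
    compared against its two monotherapy margins and the control with a
    Dunnett many-to-one adjustment (the three reference groups vs the
    cell), and the direction of the difference is reported.
    """
    def cell(p, d):
        vals = grid[(grid[peptide_col] == p) & (grid[dox_col] == d)][value_col]
        return vals.to_numpy(dtype=float)

    pep_doses = sorted(grid[peptide_col].unique())
    dox_doses = sorted(grid[dox_col].unique())
    if 0 not in pep_doses or 0 not in dox_doses:
        raise ValueError("combination grid must include monotherapy margins (dose 0)")
    control = cell(0, 0)
    if control.size == 0:
        raise ValueError("missing shared control cell (0, 0)")
    rows = []
    for p in pep_doses:
        for d in dox_doses:
            vals = cell(p, d)
            if vals.size == 0:
                continue
            row = {
                peptide_col: p,
                dox_col: d,
                "n": vals.size,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
            }
            if p > 0 and d > 0:
                pep_margin = cell(p, 0)
                dox_margin = cell(0, d)
                if pep_margin.size == 0 or dox_margin.size == 0:
                    raise ValueError(
                        f"cell ({p}, {d}) lacks a monotherapy margin"
                    )
                refs = [control, pep_margin, dox_margin]
                dres = stats.dunnett(*refs, control=vals, rng=rng)
                pvals = np.atleast_1d(dres.pvalue)
                for name, ref, pv in zip(
                    ("control", "pep_margin", "dox_margin"), refs, pvals
                ):
                    row[f"p_vs_{name}"] = float(pv)
                    row[f"dir_vs_{name}"] = (
                        "lower" if vals.mean() < ref.mean() else "higher"
                    )
                    row[f"flag_vs_{name}"] = _flag(float(pv))
            rows.append(row)
    return pd.DataFrame(rows)


def read_plate_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing plate column(s) {sorted(missing)}")
    return df
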