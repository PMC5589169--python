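"""Descriptive and comparative cohort statistics.

Covers the group-level comparisons reported alongside the classifier:
normalization of per-patient quantities to the control-group mean,
coefficients of variation, pairwise Welch t-tests between groups, ordinary
least-squares trends of normalized GP / HbA1c against disease duration and
of GP against blood lipids, and the insulin-therapy separation summary in
the (insulin dose, GP) plane.

These are reporting statistics: regressions are summarized by slope sign and
R² without any causal claim, and the therapy separating line is a reporting
device, not a fitted classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ParameterError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    n: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n": self.n,
        }


@dataclass(frozen=True)
class GroupComparison:
    means: dict[str, float]
    sds: dict[str, float]
    ns: dict[str, int]
    p_values: dict[tuple[str, str], float]

    def significant(self, alpha: float = 0.05) -> dict[tuple[str, str], bool]:
        return {pair: p < alpha for pair, p in self.p_values.items()}

    def to_dict(self) -> dict:
        return {
            "means": dict(self.means),
            "sds": dict(self.sds),
            "ns": dict(self.ns),
            "p_values": {f"{a}_vs_{b}": p for (a, b), p in self.p_values.items()},
            "p_lt_0.05": {
                f"{a}_vs_{b}": s for (a, b), s in self.significant(0.05).items()
            },
            "p_lt_0.001": {
                f"{a}_vs_{b}": s for (a, b), s in self.significant(0.001).items()
            },
        }


def normalize_to_control(values, control_mean: float) -> np.ndarray:
    """Divide each patient value by the control-group (G0) mean."""
    if control_mean == 0:
        raise ParameterError("control mean must be non-zero")
    return np.asarray(values, dtype=np.float64) / control_mean


def coefficient_of_variation(values) -> float:
    """Sample SD divided by the absolute mean."""
    values = np.asarray(values, dtype=np.float64)
    mean = values.mean()
    if mean == 0:
        raise ParameterError("coefficient of variation undefined for zero mean")
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    return float(sd / abs(mean))


def fit_linear_regression(x, y) -> RegressionFit:
    """Ordinary least squares of y on x; R² = 1 − SS_res/SS_tot."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 2:
        raise DegenerateInputError("regression needs >= 2 matched points")
    if np.ptp(x) == 0:
        raise DegenerateInputError("regression predictor is constant")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(x.size),
    )


def group_comparison(values, groups) -> GroupComparison:
    """Per-group mean/SD/n plus pairwise two-sided Welch t-tests.

    No multiplicity correction is applied (each pair is reported at face
    value); groups with fewer than 2 members are excluded and logged.
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    kept: dict[str, np.ndarray] = {}
    for g in sorted(set(groups.tolist())):
        v = values[groups == g]
        if v.size < 2:
            log.warning("group %s has < 2 members; excluded from comparison", g)
            continue
        kept[g] = v
    if len(kept) < 2:
        raise DegenerateInputError("need >= 2 groups with >= 2 members")
    names = list(kept)
    p_values = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            p = stats.ttest_ind(kept[a], kept[b], equal_var=False).pvalue
            p_values[(a, b)] = float(p)
    return GroupComparison(
        means={g: float(v.mean()) for g, v in kept.items()},
        sds={g: float(v.std(ddof=1)) for g, v in kept.items()},
        ns={g: int(v.size) for g, v in kept.items()},
        p_values=p_values,
    )


@dataclass(frozen=True)
class TherapySeparation:
    """Fractions of MDI / CSII patients on their expected side of a line in
    the (insulin dose, GP) plane.  CSII (pump) patients are expected below
    the line (more fluid membrane, lower GP), MDI above."""

    line_slope: float
    line_intercept: float
    frac_mdi_above: float
    frac_csii_below: float
    n_mdi: int
    n_csii: int

    @property
    def separation_fraction(self) -> float:
        return 0.5 * (self.frac_mdi_above + self.frac_csii_below)

    def to_dict(self) -> dict:
        return {
            "line_slope": self.line_slope,
            "line_intercept": self.line_intercept,
            "frac_mdi_above": self.frac_mdi_above,
            "frac_csii_below": self.frac_csii_below,
            "n_mdi": self.n_mdi,
            "n_csii": self.n_csii,
            "separation_fraction": self.separation_fraction,
        }


def therapy_separation_report(
    gp_mean, insulin_u_per_kg, therapy, line: tuple[float, float] | None = None
) -> TherapySeparation:
    """Assess how well a line separates the two insulin-therapy modes.

    ``line`` is (slope, intercept) of GP = slope·dose + intercept.  When
    omitted, a horizontal line at the midpoint of the two therapy groups'
    mean GP is used — a display convention, not a fit.
    """
    gp = np.asarray(gp_mean, dtype=np.float64)
    dose = np.asarray(insulin_u_per_kg, dtype=np.float64)
    ther = np.asarray(therapy)
    diabetic = (ther == "MDI") | (ther == "CSII")
    if not diabetic.any():
        raise DegenerateInputError("no diabetic (MDI/CSII) patients to assess")
    gp, dose, ther = gp[diabetic], dose[diabetic], ther[diabetic]
    mdi, csii = ther == "MDI", ther == "CSII"
    if line is None:
        if not (mdi.any() and csii.any()):
            raise DegenerateInputError(
                "default midpoint line needs both therapies present"
            )
        slope = 0.0
        intercept = 0.5 * (gp[mdi].mean() + gp[csii].mean())
    else:
        slope, intercept = float(line[0]), float(line[1])
    line_at = slope * dose + intercept
    frac_mdi = float(np.mean(gp[mdi] >= line_at[mdi])) if mdi.any() else 0.0
    frac_csii = float(np.mean(gp[csii] < line_at[csii])) if csii.any() else 0.0
    return TherapySeparation(
        line_slope=slope,
        line_intercept=intercept,
        frac_mdi_above=frac_mdi,
        frac_csii_below=frac_csii,
        n_mdi=int(mdi.sum()),
        n_csii=int(csii.sum()),
    )


def cohort_report(
    patient_frame, line: tuple[float, float] | None = None
) -> dict:
    """Full descriptive report for a per-patient table.

    ``patient_frame`` must carry columns ``group``, ``hba1c_pct``,
    ``cholesterol_mg_dl``, ``ldl_mg_dl``, ``insulin_u_per_kg``, ``therapy``,
    ``duration_years`` and ``mean_gp``.  Returns a JSON-serializable dict
    with group comparisons, coefficients of variation, control-normalized
    duration trends, per-group lipid regressions and the therapy separation
    summary.
    """
    df = patient_frame
    groups = df["group"].to_numpy()
    gp = df["mean_gp"].to_numpy(dtype=np.float64)
    hba1c = df["hba1c_pct"].to_numpy(dtype=np.float64)

    g0 = groups == "G0"
    if not g0.any():
        raise DegenerateInputError("cohort has no control (G0) patients")
    gp_norm = normalize_to_control(gp, float(gp[g0].mean()))
    hba1c_norm = normalize_to_control(hba1c, float(hba1c[g0].mean()))

    report: dict = {
        "gp_groups": group_comparison(gp, groups).to_dict(),
        "hba1c_groups": group_comparison(hba1c, groups).to_dict(),
        "cv": {
            "gp_g0": coefficient_of_variation(gp[g0]),
            "hba1c_g0": coefficient_of_variation(hba1c[g0]),
        },
    }

    duration = df["duration_years"].to_numpy(dtype=np.float64)
    if np.ptp(duration) > 0:
        report["duration_trend"] = {
            "gp_norm": fit_linear_regression(duration, gp_norm).to_dict(),
            "hba1c_norm": fit_linear_regression(duration, hba1c_norm).to_dict(),
        }

    lipids: dict = {}
    for lipid in ("cholesterol_mg_dl", "ldl_mg_dl"):
        per_group = {}
        for g in sorted(set(groups.tolist())):
            sel = groups == g
            x = df.loc[sel, lipid].to_numpy(dtype=np.float64)
            if sel.sum() >= 3 and np.ptp(x) > 0:
                per_group[g] = fit_linear_regression(x, gp[sel]).to_dict()
        lipids[lipid] = per_group
    report["gp_vs_lipids"] = lipids

    try:
        report["therapy_separation"] = therapy_separation_report(
            gp,
            df["insulin_u_per_kg"].to_numpy(dtype=np.float64),
            df["therapy"].to_numpy(),
            line=line,
        ).to_dict()
    except DegenerateInputError as exc:
        report["therapy_separation"] = {"skipped": str(exc)}
    return report
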