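"""Descriptive cohort statistics and figures.

Group comparisons of GP and HbA1c (Welch t-tests), coefficients of
variation, control-normalized trends against disease duration, per-group
GP-vs-lipid regressions, and the insulin-therapy separation in the
(insulin dose, GP) plane.  Writes results/stats_report.json and the scatter
figures under results/figures/.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from rbcfluidity import cohort_statistics as cs

GROUP_COLORS = {"G0": "tab:green", "G1": "tab:orange", "G2": "tab:red"}


def main() -> None:
    results = ROOT / "results"
    figures = results / "figures"
    figures.mkdir(parents=True, exist_ok=True)
    patients = pd.read_csv(results / "patients_gp.csv")

    report = cs.cohort_report(patients)
    (results / "stats_report.json").write_text(json.dumps(report, indent=2))

    gp_groups = report["gp_groups"]
    print("mean GP by group:", {g: round(m, 3) for g, m in gp_groups["means"].items()})
    print("GP pairwise p-values:",
          {k: f"{v:.2e}" for k, v in gp_groups["p_values"].items()})
    print("HbA1c pairwise p-values:",
          {k: f"{v:.2e}" for k, v in report["hba1c_groups"]["p_values"].items()})
    print("CV: GP(G0) = {:.3f}, HbA1c(G0) = {:.3f}".format(
        report["cv"]["gp_g0"], report["cv"]["hba1c_g0"]))
    trend = report["duration_trend"]
    print("normalized-GP vs duration: slope {:+.4f}/y, R^2 {:.3f}".format(
        trend["gp_norm"]["slope"], trend["gp_norm"]["r_squared"]))
    print("normalized-HbA1c vs duration: slope {:+.4f}/y, R^2 {:.3f}".format(
        trend["hba1c_norm"]["slope"], trend["hba1c_norm"]["r_squared"]))
    sep = report["therapy_separation"]
    print("therapy separation fraction:", round(sep["separation_fraction"], 3))

    # duration trend figure
    fig, ax = plt.subplots(figsize=(5, 4))
    g0_gp = patients.loc[patients.group == "G0", "mean_gp"].mean()
    for g, sub in patients.groupby("group"):
        ax.scatter(sub["duration_years"], sub["mean_gp"] / g0_gp,
                   c=GROUP_COLORS[g], label=g, s=25)
    fit = trend["gp_norm"]
    xs = patients["duration_years"].sort_values()
    ax.plot(xs, fit["intercept"] + fit["slope"] * xs, "k-", lw=1)
    ax.set_xlabel("years since diagnosis")
    ax.set_ylabel("GP / GP$_0$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(figures / "gp_vs_duration.png", dpi=150)

    # lipids figure
    fig, ax = plt.subplots(figsize=(5, 4))
    for g, sub in patients.groupby("group"):
        ax.scatter(sub["cholesterol_mg_dl"], sub["mean_gp"],
                   c=GROUP_COLORS[g], label=g, s=25)
    ax.set_xlabel("total cholesterol (mg/dl)")
    ax.set_ylabel("mean GP")
    ax.legend()
    fig.tight_layout()
    fig.savefig(figures / "gp_vs_cholesterol.png", dpi=150)

    # therapy plane figure
    diab = patients[patients.therapy != "none"]
    fig, ax = plt.subplots(figsize=(5, 4))
    for therapy, marker in (("MDI", "o"), ("CSII", "s")):
        sub = diab[diab.therapy == therapy]
        ax.scatter(sub["insulin_u_per_kg"], sub["mean_gp"], marker=marker,
                   label=therapy, s=30)
    xs = diab["insulin_u_per_kg"].sort_values()
    ax.plot(xs, sep["line_intercept"] + sep["line_slope"] * xs, "k--", lw=1)
    ax.set_xlabel("insulin dose (U/kg)")
    ax.set_ylabel("mean GP")
    ax.legend()
    fig.tight_layout()
    fig.savefig(figures / "gp_vs_insulin.png", dpi=150)

    print(f"figures written to {figures}")


if __name__ == "__main__":
    sys.exit(main())
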