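"""Evaluate the decision-support system and the scalar baselines.

Leave-one-person-out over the feature table: per channel standardize ->
PCA(99% variance) -> SVM per image, majority over the stack, weighted-voting
fusion of the two channels.  Compared against Gaussian Bayesian classifiers
on a single scalar per patient (HbA1c, and the stack-mean GP).  Prints the
three-way accuracy comparison and writes metrics.json / predictions.csv.
"""

import json
import sys
import time
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

import pandas as pd

from rbcfluidity import dss_classifier as dss


def main() -> None:
    results = ROOT / "results"
    features = pd.read_csv(results / "features.csv")
    patients = pd.read_csv(results / "patients_gp.csv")

    t0 = time.time()
    dss_result = dss.lopo_evaluate(features)
    print(f"DSS LOPO ({len(dss_result.folds)} folds) in {time.time() - t0:.1f}s")

    groups = patients["group"].to_numpy()
    gp_base = dss.lopo_bayes_scalar(patients["mean_gp"].to_numpy(), groups)
    hb_base = dss.lopo_bayes_scalar(patients["hba1c_pct"].to_numpy(), groups)

    payload = {
        "dss": dss_result.report.to_dict(),
        "gp_baseline": gp_base.report.to_dict(),
        "hba1c_baseline": hb_base.report.to_dict(),
    }
    (results / "metrics.json").write_text(json.dumps(payload, indent=2))
    dss_result.predictions_frame().to_csv(results / "predictions.csv", index=False)

    print(f"{'method':<16}{'accuracy':>9}")
    for name, report in (
        ("HbA1c (Bayes)", hb_base.report),
        ("mean GP (Bayes)", gp_base.report),
        ("DSS", dss_result.report),
    ):
        print(f"{name:<16}{report.accuracy:>9.2f}")
    print("\nDSS confusion matrix (rows = predicted, cols = true):")
    print(dss_result.report.confusion)


if __name__ == "__main__":
    sys.exit(main())
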