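"""Cohort statistics: refraction grouping, correlations, group tables, splines.

Loads the simulated cohort from step 01 (or regenerates it), applies the
exclusion rules (scan quality, cycloplegia at pupil < 6.0 mm), derives
spherical equivalent and refraction groups from the emulated refraction, and
produces the report tables:

* results/report_descriptives.csv       — cohort mean (SD) by sex
* results/report_correlations.csv       — biometry x MRI Pearson matrix
* results/report_group_means.csv        — group means (SD), ANOVA/chi-square p
* results/report_group_differences.csv  — myopia-emmetropia/-hyperopia deltas
* results/rcs_se_vs_shape.csv           — spline fit of SE on sphericity

Prints the headline numbers: group deltas and the SE correlations.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from oculomri import biostats as bs  # noqa: E402
from oculomri.config import CohortConfig  # noqa: E402
from oculomri.geometry import classify_shape  # noqa: E402
from oculomri.phantom import sample_cohort_records  # noqa: E402
from oculomri.pipeline import derive_refraction_columns  # noqa: E402

SEED = 1
N = 2963


def main() -> None:
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    cohort_csv = ROOT / "scratch" / "cohort_true_biometry.csv"
    if cohort_csv.exists():
        df = pd.read_csv(cohort_csv)
    else:
        df = sample_cohort_records(CohortConfig(), N,
                                   np.random.default_rng(SEED))

    mri, se_cohort, log = bs.apply_exclusions(df)
    print("exclusions:", log)

    se_cohort = derive_refraction_columns(se_cohort)
    # analysis columns: true geometry stands in for the measured biometry
    # at cohort scale (the measurement audit is step 03)
    se_cohort = se_cohort.rename(
        columns={
            "ps_length_true": "ps_length", "height_true": "height",
            "width_true": "width", "hs_true": "hs", "vs_true": "vs",
            "al_true": "al_mri",
        }
    )
    se_cohort["shape_h"] = [classify_shape(h) for h in se_cohort["hs"]]
    se_cohort["shape_v"] = [classify_shape(v) for v in se_cohort["vs"]]

    tables = bs.build_report(
        se_cohort,
        mri_vars=["height", "width", "ps_length", "hs", "vs", "al_mri"],
        biometry_vars=["se", "al_cr_ratio", "al_biometry", "cr",
                       "acd_biometry", "al_growth", "body_height",
                       "birth_weight", "gestational_age"],
    )
    for name, table in tables.items():
        table.to_csv(results / f"report_{name}.csv",
                     index=name == "correlations")

    fit = bs.rcs_regression(se_cohort["hs"].to_numpy(),
                            se_cohort["se"].to_numpy())
    grid = np.linspace(se_cohort["hs"].quantile(0.02),
                       se_cohort["hs"].quantile(0.98), 60)
    fit.predict(grid).to_csv(results / "rcs_se_vs_shape.csv", index=False)

    d = tables["group_differences"].set_index("variable")
    print(f"n analysed (SE cohort): {len(se_cohort)}")
    print("myopia - emmetropia PS length: "
          f"{d.loc['ps_length', 'myopia_minus_emmetropia']:+.2f} mm")
    print("myopia - hyperopia  PS length: "
          f"{d.loc['ps_length', 'myopia_minus_hyperopia']:+.2f} mm")
    for var in ("ps_length", "height", "width", "hs"):
        r, p = bs.pearson(se_cohort["se"].to_numpy(),
                          se_cohort[var].to_numpy())
        print(f"corr(SE, {var:9s}) r = {r:+.3f}  (p = {p:.2g})")
    frac_obl = (se_cohort["shape_h"] == "oblate").mean()
    myo = se_cohort[se_cohort["group"] == "myopia"]
    frac_pro_my = (myo["shape_h"] == "prolate").mean()
    print(f"oblate overall: {100 * frac_obl:.1f} %; "
          f"prolate among myopes: {100 * frac_pro_my:.1f} %")


if __name__ == "__main__":
    main()
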