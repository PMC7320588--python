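"""LOOCV model selection for lesion volume and brain-volume outcomes.

Block 1 predicts the total white-matter-lesion volume fraction from
{cardiovascular, cognitive, age, gender}; block 2 predicts the WM,
cortical GM and hippocampal volume fractions from {V_i, age, gender,
combined risk}.  Every nonempty predictor subset is scored by its
bias-corrected LOOCV RMSE; the winner is refit on the full sample.

Writes results/model_comparisons.csv and results/coefficients.csv.
"""

from pathlib import Path

import pandas as pd

from neurocohort import pipeline as pipe

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    data = {
        name: pd.read_csv(ROOT / "data" / f"{name}.csv")
        for name in ("clinical", "battery", "volumes", "lesions", "pet")
    }
    bundle = pipe.run_baseline(
        data["clinical"], data["battery"], data["volumes"], data["lesions"], data["pet"]
    )
    bundle["model_comparisons"].to_csv(ROOT / "model_comparisons.csv", index=False)
    bundle["coefficients"].to_csv(ROOT / "coefficients.csv", index=False)

    comp = bundle["model_comparisons"]
    print("selected models (bias-corrected LOOCV RMSE):")
    for _, r in comp[comp["selected"]].iterrows():
        print(f"  {r['outcome']:28s} ~ {r['predictors']:40s} RMSE = {r['loocv_rmse_bc']:.6g}")
    coef = bundle["coefficients"]
    wml = coef[(coef["outcome"] == "total_lesion_volume_frac") & (coef["term"] != "intercept")]
    print("\nlesion-volume model coefficients:")
    for _, r in wml.iterrows():
        print(f"  {r['term']:16s} t = {r['t']:6.2f}  p = {r['p']:.4g}")


if __name__ == "__main__":
    main()
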