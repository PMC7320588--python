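"""Median-split risk-group comparisons and association analyses.

Splits the cohort at the median of the combined risk score, regresses age
out of V_i and the six temporal thickness measures, Holm-corrects the
seven comparisons as one family, compares amyloid load (GCI) between the
groups on the PET subset, and computes the Spearman / partial-correlation
block (risk vs lesion classes, V_i vs GCI, GCI vs age, risk vs V_i given
age and gender).

Writes results/group_comparisons.csv and results/correlations.csv.
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
    bundle["group_comparisons"].to_csv(ROOT / "group_comparisons.csv", index=False)
    bundle["correlations"].to_csv(ROOT / "correlations.csv", index=False)

    gc = bundle["group_comparisons"]
    fam = gc[gc["family"] == "temporal_vi"]
    cut = fam["median_cut"].iloc[0]
    print(
        f"median split of combined risk at {cut:g}: "
        f"{fam['n_low'].iloc[0]} low vs {fam['n_high'].iloc[0]} high"
    )
    print("high-vs-low comparisons after age residualization (Holm family):")
    for _, r in fam.iterrows():
        mark = "*" if r["reject"] else " "
        print(f" {mark} {r['measure']:30s} t = {r['t']:6.2f}  p = {r['p_raw']:.4g}  holm = {r['p_holm']:.4g}")
    pet = gc[gc["family"] == "pet"]
    if len(pet):
        r = pet.iloc[0]
        print(f"amyloid GCI, high vs low risk: t({int(r['df'])}) = {r['t']:.2f}, p = {r['p_raw']:.2g}")
    print("\ncorrelations:")
    for _, r in bundle["correlations"].iterrows():
        cov = f" | {r['covariates']}" if r["covariates"] else ""
        print(f"  {r['x']} ~ {r['y']}{cov}: {r['method']} r = {r['estimate']:.3f}, p = {r['p_raw']:.4g}")


if __name__ == "__main__":
    main()
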