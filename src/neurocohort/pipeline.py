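"""End-to-end baseline analysis: scoring -> V_i -> volumetrics -> inference.

``run_baseline`` executes, in order: risk scoring, across-test variability,
derived volumetrics, a merge on ``subject_id``, and then the analysis plan:

1. model selection for total white-matter-lesion volume fraction over
   {cardiovascular, cognitive, age, gender};
2. model selection for WM / cortical GM / left / right hippocampal volume
   fractions over {v_i, age, gender, combined};
3. a median split of the combined risk score (low: <= median, high: >
   median), age regressed out, with pooled t-tests on V_i and the six
   temporal thickness measures corrected as one Holm family, plus the
   amyloid GCI comparison on the PET subset;
4. Spearman / partial correlations between risk scores, lesion classes,
   V_i, the GCI and age.

Every emitted p-value carries its Holm-adjusted partner and family label.
The pipeline is a pure function of its inputs: reruns are byte-identical.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import risk as risk_mod
from . import stats as st
from . import variability as var_mod
from . import volumetrics as vol_mod
from .errors import SchemaError

__all__ = [
    "THICKNESS_MEASURES",
    "default_plan",
    "merge_tables",
    "run_baseline",
    "descriptives",
    "write_report",
]

THICKNESS_MEASURES = (
    "medial_temporal_thickness_l",
    "medial_temporal_thickness_r",
    "parahippocampal_thickness_l",
    "parahippocampal_thickness_r",
    "entorhinal_thickness_l",
    "entorhinal_thickness_r",
)

VOLUME_OUTCOMES = ("wm_frac", "gm_frac", "hippocampus_left_frac", "hippocampus_right_frac")


def default_plan(alpha: float = 0.05) -> list:
    """The built-in analysis plan mirroring the baseline analyses."""
    return [
        {
            "name": "wml_model",
            "type": "model_selection",
            "outcomes": ["total_lesion_volume_frac"],
            "candidates": ["cardiovascular", "cognitive", "age", "gender"],
        },
        {
            "name": "volume_models",
            "type": "model_selection",
            "outcomes": list(VOLUME_OUTCOMES),
            "candidates": ["v_i", "age", "gender", "combined"],
        },
        {
            "name": "risk_group_comparison",
            "type": "group_comparison",
            "split_on": "combined",
            "measures": ["v_i", *THICKNESS_MEASURES],
            "residualize": ["age"],
            "family": "temporal_vi",
            "alpha": alpha,
        },
        {
            "name": "pet_group_comparison",
            "type": "group_comparison",
            "split_on": "combined",
            "measures": ["gci"],
            "residualize": ["age"],
            "family": "pet",
            "alpha": alpha,
        },
        {
            "name": "associations",
            "type": "correlation",
            "alpha": alpha,
            "family": "lesion_associations",
            "pairs": [
                ["cardiovascular", "juxtacortical_frac", "spearman"],
                ["cardiovascular", "periventricular_frac", "spearman"],
                ["cardiovascular", "deep_white_frac", "spearman"],
                ["cardiovascular", "fazekas", "spearman"],
                ["cardiovascular", "total_lesion_count", "spearman"],
            ],
        },
        {
            "name": "pet_associations",
            "type": "correlation",
            "alpha": alpha,
            "family": "pet",
            "pairs": [
                ["v_i", "gci", "spearman"],
                ["age", "gci", "spearman"],
            ],
        },
        {
            "name": "risk_variability",
            "type": "correlation",
            "alpha": alpha,
            "family": "risk_vi",
            "pairs": [["combined", "v_i", "partial", ["age", "gender"]]],
        },
    ]


def merge_tables(
    clinical: pd.DataFrame,
    battery: pd.DataFrame,
    volumes: pd.DataFrame,
    lesions: pd.DataFrame,
    pet: Optional[pd.DataFrame] = None,
    battery_specs: Sequence = var_mod.DEFAULT_BATTERY,
    **risk_kwargs,
) -> pd.DataFrame:
    """Score, derive and join all tables into one analysis frame.

    ``gender`` is recoded to a 0/1 female indicator for modeling; the PET
    table may cover only a subset (its ``gci`` is NaN elsewhere).
    """
    scores = risk_mod.score_cohort(clinical, **risk_kwargs)
    vi = var_mod.cohort_variability(battery, battery_specs)
    derived = vol_mod.derive_measures(volumes, lesions)
    merged = (
        clinical[["subject_id", "age", "gender"]]
        .merge(scores, on="subject_id", validate="1:1")
        .merge(vi, on="subject_id", validate="1:1")
        .merge(derived, on="subject_id", validate="1:1")
    )
    merged["gender"] = (merged["gender"] == "female").astype(float)
    if pet is not None and len(pet):
        merged = merged.merge(pet[["subject_id", "gci"]], on="subject_id", how="left")
    else:
        merged["gci"] = np.nan
    return merged


def _check_columns(merged: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in merged.columns]
    if missing:
        raise SchemaError(f"analysis table lacks columns {missing}")


def _run_model_selection(merged, block):
    comp_rows, coef_rows = [], []
    _check_columns(merged, block["outcomes"] + block["candidates"])
    for outcome in block["outcomes"]:
        sub = merged.dropna(subset=[outcome] + block["candidates"])
        comp = st.select_model(sub[outcome].to_numpy(), sub[block["candidates"]])
        for _, r in comp.table.iterrows():
            comp_rows.append(
                {
                    "block": block["name"],
                    "outcome": outcome,
                    "predictors": "+".join(r["predictors"]),
                    "k": r["k"],
                    "loocv_rmse_bc": r["loocv_rmse_bc"],
                    "loocv_rmse": r["loocv_rmse"],
                    "selected": tuple(r["predictors"]) == comp.selected,
                }
            )
        fit = comp.fit
        for name, b, se, t, p in zip(
            ("intercept",) + fit.predictors, fit.params, fit.bse, fit.tvalues, fit.pvalues
        ):
            coef_rows.append(
                {
                    "block": block["name"],
                    "outcome": outcome,
                    "term": name,
                    "coef": b,
                    "se": se,
                    "t": t,
                    "p": p,
                    "n": fit.n,
                    "df": fit.df_resid,
                }
            )
    return comp_rows, coef_rows


def _run_group_comparison(merged, block):
    measures = block["measures"]
    _check_columns(merged, [block["split_on"]] + measures + block.get("residualize", []))
    rows = []
    for m in measures:
        sub = merged.dropna(subset=[m, block["split_on"]] + block.get("residualize", []))
        if not len(sub):
            continue
        split = st.median_split(sub[block["split_on"]].to_numpy())
        y = sub[m].to_numpy(dtype=float)
        if block.get("residualize"):
            y = st.residualize(y, sub[block["residualize"]].to_numpy(dtype=float))
        low = y[(split["group"] == "low").to_numpy()]
        high = y[(split["group"] == "high").to_numpy()]
        t, df, p = st.two_sample_t(high, low)
        rows.append(
            {
                "block": block["name"],
                "family": block["family"],
                "measure": m,
                "median_cut": split.attrs["median"],
                "n_low": split.attrs["n_low"],
                "n_high": split.attrs["n_high"],
                "t": t,
                "df": df,
                "p_raw": p,
            }
        )
    return rows


def _run_correlations(merged, block):
    rows = []
    for pair in block["pairs"]:
        x, y, method = pair[0], pair[1], pair[2]
        covs = list(pair[3]) if len(pair) > 3 else []
        _check_columns(merged, [x, y] + covs)
        sub = merged.dropna(subset=[x, y] + covs)
        if len(sub) < max(3, len(covs) + 3):
            continue  # e.g. the PET subset is empty; the caller logs the block size
        if method == "spearman":
            res = st.spearman(sub[x].to_numpy(), sub[y].to_numpy())
        elif method == "partial":
            res = st.partial_correlation(
                sub[x].to_numpy(), sub[y].to_numpy(), sub[covs]
            )
        else:
            raise SchemaError(f"unknown correlation method {method!r}")
        rows.append(
            {
                "block": block["name"],
                "family": block["family"],
                "x": x,
                "y": y,
                "method": res.method,
                "covariates": "+".join(covs),
                "estimate": res.estimate,
                "n": res.n,
                "p_raw": res.pvalue,
            }
        )
    return rows


def _holm_by_family(df: pd.DataFrame, alpha: float) -> pd.DataFrame:
    if not len(df):
        df["p_holm"] = []
        df["reject"] = []
        return df
    out = []
    for fam, g in df.groupby("family", sort=False):
        adj = st.holm_bonferroni(g["p_raw"].to_numpy(), alpha=alpha, family=str(fam))
        g = g.copy()
        g["p_holm"] = adj.pvalues_adjusted
        g["reject"] = adj.reject
        out.append(g)
    return pd.concat(out).sort_index()


def run_baseline(
    clinical: pd.DataFrame,
    battery: pd.DataFrame,
    volumes: pd.DataFrame,
    lesions: pd.DataFrame,
    pet: Optional[pd.DataFrame] = None,
    plan: Optional[list] = None,
    alpha: float = 0.05,
    battery_specs: Sequence = var_mod.DEFAULT_BATTERY,
    **risk_kwargs,
) -> dict:
    """Run the whole baseline analysis; returns a bundle of result frames.

    Keys: ``merged``, ``model_comparisons``, ``coefficients``,
    ``group_comparisons``, ``correlations``, ``descriptives``, ``log``.
    """
    plan = default_plan(alpha) if plan is None else plan
    merged = merge_tables(
        clinical, battery, volumes, lesions, pet, battery_specs=battery_specs, **risk_kwargs
    )
    comp_rows, coef_rows, group_rows, corr_rows, log = [], [], [], [], []
    for block in plan:
        kind = block["type"]
        if kind == "model_selection":
            c, k = _run_model_selection(merged, block)
            comp_rows += c
            coef_rows += k
            sel = [r for r in c if r["selected"]]
            for r in sel:
                log.append(
                    f"[{block['name']}] {r['outcome']} ~ {r['predictors']} "
                    f"(bias-corrected LOOCV RMSE = {r['loocv_rmse_bc']:.6g})"
                )
        elif kind == "group_comparison":
            rows = _run_group_comparison(merged, block)
            if not rows:
                log.append(f"[{block['name']}] skipped: no subjects with required measures")
                continue
            group_rows += rows
            log.append(f"[{block['name']}] {len(rows)} comparisons, family {block['family']!r}")
        elif kind == "correlation":
            corr_rows += _run_correlations(merged, block)
            log.append(f"[{block['name']}] correlations computed")
        else:
            raise SchemaError(f"unknown block type {kind!r}")
    group = _holm_by_family(pd.DataFrame(group_rows), alpha)
    corrs = _holm_by_family(pd.DataFrame(corr_rows), alpha)
    return {
        "merged": merged,
        "model_comparisons": pd.DataFrame(comp_rows),
        "coefficients": pd.DataFrame(coef_rows),
        "group_comparisons": group,
        "correlations": corrs,
        "descriptives": descriptives(merged),
        "log": log,
    }


def _mean_sd(x) -> tuple:
    x = pd.Series(x).dropna()
    if not len(x):
        return (np.nan, np.nan)
    return (float(x.mean()), float(x.std(ddof=1)) if len(x) > 1 else np.nan)


def descriptives(merged: pd.DataFrame) -> pd.DataFrame:
    """Cohort-characteristics summary (volume fractions reported in percent)."""
    if not len(merged):
        raise SchemaError("descriptives needs a nonempty table")
    rows = [("n_subjects", float(len(merged)), np.nan)]

    def add(label, series, percent=False):
        m, s = _mean_sd(series)
        if percent:
            m, s = 100 * m, 100 * s
        rows.append((label, m, s))

    add("female_pct", merged["gender"], percent=True)
    add("age_years", merged["age"])
    for flag in risk_mod.CARDIOVASCULAR_FLAGS + risk_mod.COGNITIVE_FLAGS:
        if flag in merged.columns:
            add(f"{flag}_pct", merged[flag].astype(float), percent=True)
    for score in ("cardiovascular", "cognitive", "combined"):
        add(f"{score}_risk", merged[score])
    add("across_test_variability", merged["v_i"])
    for col, label in (
        ("gm_frac", "gray_matter_pct_tiv"),
        ("wm_frac", "white_matter_pct_tiv"),
        ("csf_frac", "csf_pct_tiv"),
        ("parenchymal_frac", "parenchymal_fraction_pct_tiv"),
    ):
        if col in merged.columns:
            add(label, merged[col], percent=True)
    if {"hippocampus_left_frac", "hippocampus_right_frac"} <= set(merged.columns):
        add(
            "hippocampal_pct_tiv",
            merged["hippocampus_left_frac"] + merged["hippocampus_right_frac"],
            percent=True,
        )
    if "total_lesion_count" in merged.columns:
        add("total_lesion_count", merged["total_lesion_count"])
        for col in (
            "total_lesion_volume_frac",
            "periventricular_frac",
            "juxtacortical_frac",
            "deep_white_frac",
        ):
            add(col, merged[col])
    if "gci" in merged.columns and merged["gci"].notna().any():
        gci = merged["gci"].dropna()
        rows.append(("pet_n", float(len(gci)), np.nan))
        add("gci", gci)
        pos = gci.apply(risk_mod.classify_amyloid)
        add("amyloid_positive_pct", pos.astype(float), percent=True)
    return pd.DataFrame(rows, columns=["measure", "value", "sd"])


def write_report(bundle: dict, outdir) -> None:
    """Write the result bundle as CSV tables plus a markdown summary."""
    import os

    os.makedirs(outdir, exist_ok=True)
    for key in (
        "model_comparisons",
        "coefficients",
        "group_comparisons",
        "correlations",
        "descriptives",
    ):
        bundle[key].to_csv(os.path.join(outdir, f"{key}.csv"), index=False)
    lines = ["# Baseline analysis report", ""]
    lines += [f"- {entry}" for entry in bundle["log"]]
    lines.append("")
    sel = bundle["model_comparisons"]
    if len(sel):
        lines.append("## Selected models")
        for _, r in sel[sel["selected"]].iterrows():
            lines.append(
                f"- {r['outcome']}: {r['predictors']} "
                f"(bias-corrected LOOCV RMSE {r['loocv_rmse_bc']:.6g})"
            )
        lines.append("")
    gc = bundle["group_comparisons"]
    if len(gc):
        lines.append("## Group comparisons (high vs low risk, age regressed out)")
        for _, r in gc.iterrows():
            lines.append(
                f"- {r['measure']}: t({int(r['df'])}) = {r['t']:.3f}, "
                f"p = {r['p_raw']:.4g} (Holm {r['p_holm']:.4g}, family {r['family']})"
            )
        lines.append("")
    with open(os.path.join(outdir, "summary.md"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
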