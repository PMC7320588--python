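"""Intra-subject across-test variability of a neuropsychological battery.

The battery's raw subtest scores are first reduced to K = 14 oriented
subtest columns (timed scores negated so that larger always means better,
paired subtests averaged on the z scale, TMT expressed as the B - A time
difference), then z-transformed column-wise on the whole sample:

    Z_ik = (x_ik - mean_k) / sd_k        (sample SD, n - 1)

For subject i the profile mean and the across-test variability are

    A_i = (1/K) sum_k Z_ik
    V_i = sqrt( sum_k (Z_ik - A_i)^2 / (K - 1) )

i.e. V_i is the sample standard deviation of the subject's own z-scores:
large V_i means inconsistent performance across cognitive domains, a
candidate early marker of decline that side-steps ceiling effects in
healthy cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DegenerateColumnError,
    MissingDataError,
    SchemaError,
    ValidationError,
)

__all__ = [
    "SubtestSpec",
    "ZMatrix",
    "DEFAULT_BATTERY",
    "load_battery",
    "save_battery",
    "reduce_battery",
    "zscore_cohort",
    "subject_mean",
    "across_test_variability",
    "cohort_variability",
]

HIGHER = "higher_is_better"
LOWER = "lower_is_better"


@dataclass(frozen=True)
class SubtestSpec:
    """How one oriented subtest column is built from raw battery fields.

    reduction:
        ``single``     — the column is one raw field;
        ``mean_of_z``  — z-score each component on the cohort, then average;
        ``difference`` — component1 - component2 (exactly two components).
    orientation:
        ``lower_is_better`` columns are negated before standardization.
    """

    name: str
    components: tuple
    orientation: str = HIGHER
    reduction: str = "single"

    def __post_init__(self):
        if self.orientation not in (HIGHER, LOWER):
            raise ValidationError(f"unknown orientation {self.orientation!r} for {self.name}")
        if self.reduction not in ("single", "mean_of_z", "difference"):
            raise ValidationError(f"unknown reduction {self.reduction!r} for {self.name}")
        if self.reduction == "difference" and len(self.components) != 2:
            raise ValidationError(f"difference reduction needs exactly 2 components ({self.name})")
        if self.reduction == "single" and len(self.components) != 1:
            raise ValidationError(f"single reduction needs exactly 1 component ({self.name})")


#: Default K = 14 battery: paired span tasks are averaged, timed executive
#: scores are lower-is-better, TMT enters as the B - A difference.
DEFAULT_BATTERY: tuple = (
    SubtestSpec("mmse", ("mmse",)),
    SubtestSpec("mattis", ("mattis",)),
    SubtestSpec("corsi", ("corsi_direct", "corsi_inverse"), reduction="mean_of_z"),
    SubtestSpec("digit_span", ("digit_direct", "digit_inverse"), reduction="mean_of_z"),
    SubtestSpec("grober_buschke", ("grober_buschke_total_recall",)),
    SubtestSpec("dms_immediate", ("dms_immediate",)),
    SubtestSpec("rey_immediate", ("rey_immediate",)),
    SubtestSpec("rey_3min", ("rey_3min",)),
    SubtestSpec("stroop_interference", ("stroop_interference_time",), orientation=LOWER),
    SubtestSpec("tmt_b_minus_a", ("tmt_b_time", "tmt_a_time"), orientation=LOWER, reduction="difference"),
    SubtestSpec("bref", ("bref",)),
    SubtestSpec("phonematic_fluency", ("phonematic_fluency",)),
    SubtestSpec("semantic_fluency", ("semantic_fluency",)),
    SubtestSpec("do80", ("do80",)),
)


@dataclass
class ZMatrix:
    """Cohort z-score matrix (subjects x K) with subtest names."""

    values: np.ndarray
    subtests: tuple
    subject_ids: tuple

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


def load_battery(path) -> tuple:
    """Read a battery definition from a YAML list of subtest mappings."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return tuple(
        SubtestSpec(
            name=d["name"],
            components=tuple(d["components"]),
            orientation=d.get("orientation", HIGHER),
            reduction=d.get("reduction", "single"),
        )
        for d in raw
    )


def save_battery(specs: Iterable[SubtestSpec], path) -> None:
    data = [
        {
            "name": s.name,
            "components": list(s.components),
            "orientation": s.orientation,
            "reduction": s.reduction,
        }
        for s in specs
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _zscore_column(col: np.ndarray, name: str) -> np.ndarray:
    # nan-aware so the missing='available' policy can defer completeness checks
    sd = np.nanstd(col, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateColumnError(f"subtest {name!r} has zero variance across the cohort")
    return (col - np.nanmean(col)) / sd


def reduce_battery(battery: pd.DataFrame, specs: Sequence[SubtestSpec] = DEFAULT_BATTERY) -> pd.DataFrame:
    """Build the subjects x K oriented subtest matrix from raw scores.

    Orientation is applied here, before any standardization; ``mean_of_z``
    components are z-scored on the cohort individually and then averaged.
    """
    if len(battery) < 2:
        raise ValidationError("battery reduction needs at least 2 subjects")
    cols = {}
    for spec in specs:
        for c in spec.components:
            if c not in battery.columns:
                raise SchemaError(f"battery table lacks column {c!r} (subtest {spec.name!r})")
        if spec.reduction == "single":
            col = battery[spec.components[0]].to_numpy(dtype=float)
        elif spec.reduction == "difference":
            a, b = (battery[c].to_numpy(dtype=float) for c in spec.components)
            col = a - b
        else:  # mean_of_z
            zs = [
                _zscore_column(battery[c].to_numpy(dtype=float), c) for c in spec.components
            ]
            col = np.mean(zs, axis=0)
        if spec.orientation == LOWER:
            col = -col
        cols[spec.name] = col
    return pd.DataFrame(cols, index=battery.index)


def zscore_cohort(scores: pd.DataFrame) -> ZMatrix:
    """Standardize every subtest column on the whole sample (sample SD)."""
    if len(scores) < 2:
        raise ValidationError("z-scoring needs at least 2 subjects")
    x = scores.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        bad = scores.columns[~np.isfinite(x).all(axis=0)].tolist()
        raise MissingDataError(f"non-finite values in subtest columns {bad}")
    z = np.column_stack(
        [_zscore_column(x[:, j], scores.columns[j]) for j in range(x.shape[1])]
    )
    ids = tuple(scores.index.astype(str)) if scores.index.name else tuple(map(str, scores.index))
    return ZMatrix(values=z, subtests=tuple(scores.columns), subject_ids=ids)


def subject_mean(z_row: np.ndarray) -> float:
    """A_i: mean of one subject's z-scores across the K subtests."""
    z_row = np.asarray(z_row, dtype=float)
    if z_row.size == 0:
        raise ValidationError("subject_mean needs at least one z-score")
    return float(z_row.mean())


def across_test_variability(z_row: np.ndarray) -> float:
    """V_i: sample SD (K - 1 denominator) of one subject's z-scores."""
    z_row = np.asarray(z_row, dtype=float)
    if z_row.size < 2:
        raise ValidationError("across_test_variability needs K >= 2 z-scores")
    a = z_row.mean()
    return float(np.sqrt(((z_row - a) ** 2).sum() / (z_row.size - 1)))


def cohort_variability(
    battery: pd.DataFrame,
    specs: Sequence[SubtestSpec] = DEFAULT_BATTERY,
    missing: str = "error",
    min_k: int = 8,
) -> pd.DataFrame:
    """Per-subject A_i and V_i for a whole battery table.

    ``battery`` must carry a ``subject_id`` column plus the raw score
    columns referenced by ``specs``.  Missing-data policy:

    * ``"error"`` (default): any subject with a missing raw score aborts
      the computation, listing the affected subjects;
    * ``"available"``: V_i is computed over the subject's available
      subtests with the denominator K replaced by ``k_used``; subjects
      with fewer than ``min_k`` subtests raise.

    Returns a frame with ``subject_id``, ``a_i``, ``v_i``, ``k_used``.
    """
    if missing not in ("error", "available"):
        raise ValidationError(f"unknown missing policy {missing!r}")
    if "subject_id" not in battery.columns:
        raise SchemaError("battery table lacks column 'subject_id'")
    raw = battery.set_index("subject_id")
    needed = sorted({c for s in specs for c in s.components})
    for c in needed:
        if c not in raw.columns:
            raise SchemaError(f"battery table lacks column {c!r}")
    incomplete = raw.index[raw[needed].isna().any(axis=1)].tolist()
    if incomplete and missing == "error":
        raise MissingDataError(
            f"missing battery scores for subjects {incomplete}; "
            "set missing='available' to compute over available subtests"
        )
    reduced = reduce_battery(raw[needed], specs)
    zmat = zscore_cohort(reduced) if not incomplete else None
    rows = []
    if zmat is not None:
        for i, sid in enumerate(raw.index):
            row = zmat.values[i]
            rows.append(
                {
                    "subject_id": sid,
                    "a_i": subject_mean(row),
                    "v_i": across_test_variability(row),
                    "k_used": zmat.k,
                }
            )
    else:
        # column statistics from available data only, then per-subject k_used
        z = reduced.copy()
        for c in z.columns:
            col = z[c]
            sd = col.std(ddof=1, skipna=True)
            if not np.isfinite(sd) or sd == 0:
                raise DegenerateColumnError(f"subtest {c!r} has zero variance across the cohort")
            z[c] = (col - col.mean(skipna=True)) / sd
        for sid in raw.index:
            row = z.loc[sid].to_numpy(dtype=float)
            row = row[np.isfinite(row)]
            if row.size < min_k:
                raise MissingDataError(
                    f"subject {sid} has only {row.size} subtests (< min_k={min_k})"
                )
            rows.append(
                {
                    "subject_id": sid,
                    "a_i": subject_mean(row),
                    "v_i": across_test_variability(row),
                    "k_used": int(row.size),
                }
            )
    return pd.DataFrame(rows)
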