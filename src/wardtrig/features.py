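"""Descriptive window features, quality filtering, and room standardization.

Per survey × window length, five descriptive features (min, max, mean,
median, SD) are computed from each modality's smoothed window series.  Four
independent quality criteria decide whether a survey enters the analysis:

1. off-map fraction of the window strictly below 50%;
2. at least 50% of the expected number of data points present;
3. the majority room has an environmental sensor (in particular, it is not
   ``off_map``);
4. the survey falls inside the 08:00–20:00 protocol frame.

Features of surviving rows are z-scored within their majority room, so a
value of 1 reads as "1 SD above that room's typical level" — comparable
across rooms and wards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MODALITIES, StudyDataset
from .layout import WardLayout
from .windowing import WindowData, WindowSpec, extract_window

FEATURE_NAMES = ("min", "max", "mean", "median", "sd")

PAS_COLS = ("pas_motor", "pas_verbal", "pas_resist", "pas_aggr")

QUALITY_CRITERIA = (
    "off_map_ge_50pct",
    "lt_50pct_expected_points",
    "majority_room_sensorless",
    "outside_8_to_20",
)


def binarize_pas(scores) -> dict[str, int]:
    """Presence/absence flags from the four PAS subtype scores (0–4).

    ``motor``/``verbal`` flag their own subtype; ``agitation`` flags any of
    the four subtypes — so resistance-to-care or aggression alone still
    counts as an agitated survey even though those subtypes are not
    modelled on their own.
    """
    vals = [int(s) for s in scores]
    if len(vals) != 4 or any(not 0 <= s <= 4 for s in vals):
        raise ValueError(f"PAS scores must be four values in 0..4, got {scores}")
    motor, verbal, resist, aggr = vals
    return {
        "motor": int(motor >= 1),
        "verbal": int(verbal >= 1),
        "agitation": int(any(v >= 1 for v in vals)),
    }


def compute_features(values: np.ndarray) -> dict[str, float]:
    """min/max/mean/median/sample-SD (n−1 denominator) plus n_points.

    An empty series yields NaN features (undefined), which later fails the
    quality stage; a single point has an undefined SD.
    """
    v = np.asarray(values, dtype=np.float64)
    n = len(v)
    if n == 0:
        out = {f: np.nan for f in FEATURE_NAMES}
    else:
        out = {
            "min": float(v.min()),
            "max": float(v.max()),
            "mean": float(v.mean()),
            "median": float(np.median(v)),
            "sd": float(v.std(ddof=1)) if n >= 2 else np.nan,
        }
    out["n_points"] = n
    return out


def assign_time_group(t_s: float) -> int:
    """Time-of-day group of a ward-clock timestamp.

    Half-open hour bins: [8,12) → 1, [12,16) → 2, [16,20) → 3, the
    wrap-around night bin [20,8) → 4.
    """
    h = (float(t_s) % 86400.0) / 3600.0
    if 8.0 <= h < 12.0:
        return 1
    if 12.0 <= h < 16.0:
        return 2
    if 16.0 <= h < 20.0:
        return 3
    return 4


@dataclass
class QualityReport:
    survey_id: str
    length_min: float
    failed_criteria: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.failed_criteria


def apply_quality_filters(
    wd: WindowData, layout: WardLayout, expected_points: float,
) -> QualityReport:
    """Evaluate the four quality criteria, each independently.

    Inequalities are exactly as printed: an off-map fraction of exactly 0.5
    fails (must be *less than* 50%); exactly half the expected points passes
    (*at least* 50%); a survey at exactly 20:00 is outside the frame.
    The unknown-location share is measured as off-map time fraction of the
    window, robust to sampling gaps.
    """
    failed = []
    if not wd.off_map_fraction < 0.5:
        failed.append("off_map_ge_50pct")
    n_min = min(wd.n_points.values()) if wd.series else 0
    if not n_min >= 0.5 * expected_points:
        failed.append("lt_50pct_expected_points")
    if not layout.has_sensor(wd.majority_room):
        failed.append("majority_room_sensorless")
    if assign_time_group(wd.t_survey_s) == 4:
        failed.append("outside_8_to_20")
    return QualityReport(wd.survey_id, wd.spec.length_min, failed)


# ---------------------------------------------------------------------------
# standardization

def standardize_features(
    rows: pd.DataFrame, feature_cols: list[str],
    room_col: str = "majority_room", fit_mask: pd.Series | None = None,
) -> tuple[pd.DataFrame, dict, list[str]]:
    """Z-score features within the majority room.

    The standardizer (per-room mean and n−1 SD per feature) is fitted on
    ``fit_mask`` rows (default: quality-passing rows) and applied to all
    rows.  Strata with fewer than 2 usable rows or zero SD yield NaN z
    values; each such exclusion is logged.

    Returns (rows with added ``z_<feature>`` columns, standardizer mapping
    ``(room, feature) -> (mean, sd)``, log lines).
    """
    out = rows.copy()
    if fit_mask is None:
        fit_mask = rows["passed"] if "passed" in rows else pd.Series(
            True, index=rows.index)
    standardizer: dict[tuple[str, str], tuple[float, float]] = {}
    log: list[str] = []
    for col in feature_cols:
        z = np.full(len(rows), np.nan)
        for room, sub in rows[fit_mask].groupby(room_col, sort=True):
            x = sub[col].to_numpy(dtype=np.float64)
            x = x[np.isfinite(x)]
            if len(x) < 2:
                log.append(f"{col}@{room}: <2 rows, z undefined")
                continue
            mu, sd = float(x.mean()), float(x.std(ddof=1))
            if sd == 0.0:
                log.append(f"{col}@{room}: zero SD, z undefined")
                continue
            standardizer[(str(room), col)] = (mu, sd)
            sel = (rows[room_col] == room).to_numpy()
            z[sel] = (rows.loc[sel, col].to_numpy(dtype=np.float64) - mu) / sd
        out[f"z_{col}"] = z
    return out, standardizer, log


# ---------------------------------------------------------------------------
# full table

def build_feature_table(
    dataset: StudyDataset,
    lengths_min: list[float],
    buffer_min: float = 12.0,
    modalities: tuple[str, ...] = MODALITIES,
    standardize: bool = True,
) -> tuple[pd.DataFrame, list[str], dict]:
    """One row per survey × window length: outcomes, context, features, z.

    The standardizer is re-fitted per window length on that length's
    quality-passing rows.  Returns (table, log lines, standardizers) where
    ``standardizers[length]["room|feature"] = (mean, sd)``.
    """
    feature_cols = [f"{m}_{f}" for m in modalities for f in FEATURE_NAMES]
    log: list[str] = []
    frames = []
    standardizers: dict[float, dict[str, tuple[float, float]]] = {}
    sv = dataset.surveys
    outcome = [binarize_pas([r[c] for c in PAS_COLS])
               for r in sv[list(PAS_COLS)].to_dict("records")]
    for length in lengths_min:
        spec = WindowSpec(length_min=length, buffer_min=buffer_min)
        expected = length * 60.0 / dataset.sensors.period_s
        recs = []
        for i, row in enumerate(sv.itertuples(index=False)):
            wd = extract_window(dataset, row.survey_id, row.patient_id,
                                row.t_s, spec, modalities)
            rep = apply_quality_filters(wd, dataset.layout, expected)
            rec = {
                "survey_id": row.survey_id,
                "patient_id": row.patient_id,
                "length": length,
                "t_s": row.t_s,
                "time_group": assign_time_group(row.t_s),
                "majority_room": wd.majority_room,
                "maj_room_group": dataset.layout.group_of(wd.majority_room)
                or "off_map",
                "off_map_fraction": wd.off_map_fraction,
                "passed": rep.passed,
                "failed_criteria": ";".join(rep.failed_criteria),
                **outcome[i],
            }
            for m in modalities:
                rec[f"n_points_{m}"] = wd.n_points[m]
                feats = compute_features(wd.series[m][1])
                for f in FEATURE_NAMES:
                    rec[f"{m}_{f}"] = feats[f]
            recs.append(rec)
        tab = pd.DataFrame(recs)
        n_pass = int(tab["passed"].sum())
        log.append(f"length {length:g}: {len(tab)} surveys, {n_pass} pass quality")
        if standardize:
            tab, std, slog = standardize_features(tab, feature_cols)
            standardizers[length] = {f"{room}|{col}": ms
                                     for (room, col), ms in std.items()}
            log.extend(f"length {length:g}: {s}" for s in slog)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True), log, standardizers
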