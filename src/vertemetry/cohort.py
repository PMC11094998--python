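"""Cohort classification, per-level/regional aggregation and findings.

Patients are classified by scoliosis severity from the largest Cobb angle
(mild < 20°, strong > 40°, medium for all in between — the boundary values
20° and 40° fall in the medium class) and by curve region from the apex of
the main curve: thoracic for apexes T2–T11, thoraco-lumbar for T12/L1,
lumbar for L2–L5, and combined when both a thoracic-range and a
lumbar-range apex are present.

Aggregation produces per-vertebral-level and regional arithmetic mean and
sample SD (n−1) of the spinous-tip distance L12 and the skin distance L13,
with missing L12 values excluded from mean and count.  Regional rows pool
all (patient, level) values in the region, not per-level means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometry import VERTEBRAL_LEVELS, VertebraMeasurement

__all__ = [
    "PatientRecord",
    "CohortTable",
    "classify_severity",
    "classify_region",
    "main_curve",
    "aggregate_levels",
    "regional_means",
    "findings_report",
    "SEVERITY_ORDER",
    "REGION_ORDER",
    "REGIONS",
]

SEVERITY_ORDER = ("mild", "medium", "strong")
REGION_ORDER = ("thoracic", "thoraco-lumbar", "lumbar", "combined")

_LEVEL_INDEX = {lv: i for i, lv in enumerate(VERTEBRAL_LEVELS)}
THORACIC_RANGE = frozenset(VERTEBRAL_LEVELS[_LEVEL_INDEX["T2"]:_LEVEL_INDEX["T11"] + 1])
THORACOLUMBAR_RANGE = frozenset(("T12", "L1"))
LUMBAR_RANGE = frozenset(VERTEBRAL_LEVELS[_LEVEL_INDEX["L2"]:_LEVEL_INDEX["L5"] + 1])

# regional rows of the summary tables: label -> member levels
REGIONS = {
    "T2...T11": tuple(sorted(THORACIC_RANGE, key=_LEVEL_INDEX.get)),
    "T12/L1": ("T12", "L1"),
    "L2...L5": tuple(sorted(LUMBAR_RANGE, key=_LEVEL_INDEX.get)),
}
_REGION_ROW_TO_REGION = {"T2...T11": "thoracic", "T12/L1": "thoraco-lumbar", "L2...L5": "lumbar"}


@dataclass(frozen=True)
class PatientRecord:
    """One patient: id, gender, Cobb curves (angle°, apex level), measurements."""

    patient_id: str
    gender: str  # female / male / unknown
    curves: tuple  # ((angle_deg, apex_level), ...)
    measurements: tuple  # (VertebraMeasurement, ...)

    def __post_init__(self):
        if not self.curves:
            raise ValueError("at least one curve entry is required for classification")
        for angle, apex in self.curves:
            if angle < 0:
                raise ValueError("Cobb angles must be >= 0")
            if apex not in _LEVEL_INDEX:
                raise ValueError(f"unknown apex level {apex!r}")


@dataclass
class CohortTable:
    """Per-level (and optionally regional) mean/SD table plus the raw values.

    ``table`` columns: group, level, L12_mean, L12_sd, L12_n, L13_mean,
    L13_sd, L13_n.  SD is NaN when n < 2.  ``values`` is the long-format
    per-(patient, level) data the table was aggregated from, retained so
    regional rows can pool raw values.
    """

    grouping: str
    table: pd.DataFrame
    values: pd.DataFrame = field(repr=False)


def classify_severity(max_cobb_deg: float) -> str:
    """Severity class from the largest Cobb angle."""
    if max_cobb_deg < 0:
        raise ValueError("Cobb angle must be >= 0")
    if max_cobb_deg < 20.0:
        return "mild"
    if max_cobb_deg > 40.0:
        return "strong"
    return "medium"


def main_curve(curves) -> tuple[float, str]:
    """The main curve: largest Cobb angle, ties broken toward the more
    cranial apex."""
    return max(curves, key=lambda c: (c[0], -_LEVEL_INDEX[c[1]]))


def classify_region(curves) -> str:
    """Curve-region class from the recorded apex levels.

    Combined requires at least one thoracic-range (T2–T11) and one
    lumbar-range (L2–L5) apex; otherwise the main curve's apex decides.
    """
    if not curves:
        raise ValueError("no curves recorded")
    apexes = {apex for _, apex in curves}
    if apexes & THORACIC_RANGE and apexes & LUMBAR_RANGE:
        return "combined"
    _, apex = main_curve(curves)
    if apex in THORACIC_RANGE:
        return "thoracic"
    if apex in THORACOLUMBAR_RANGE:
        return "thoraco-lumbar"
    if apex in LUMBAR_RANGE:
        return "lumbar"
    raise ValueError(f"unclassifiable region: main-curve apex {apex!r}")


def _group_of(record: PatientRecord, grouping: str) -> str:
    if grouping == "severity":
        return classify_severity(main_curve(record.curves)[0])
    if grouping == "region":
        return classify_region(record.curves)
    if grouping == "gender":
        return record.gender
    if grouping == "none":
        return "all"
    raise ValueError(f"unknown grouping {grouping!r}")


def _long_values(records, grouping: str) -> pd.DataFrame:
    rows = []
    for rec in records:
        group = _group_of(rec, grouping)
        for m in rec.measurements:
            rows.append({
                "patient_id": rec.patient_id,
                "group": group,
                "level": m.level,
                "L12": np.nan if m.L12_mm is None else float(m.L12_mm),
                "L13": np.nan if m.L13_mm is None else float(m.L13_mm),
            })
    return pd.DataFrame(rows, columns=["patient_id", "group", "level", "L12", "L13"])


def _summarize(df: pd.DataFrame, label_col_values) -> pd.DataFrame:
    rows = []
    for (group, label), sub in df.groupby(["group", "_label"], sort=False):
        row = {"group": group, "level": label}
        for q in ("L12", "L13"):
            vals = sub[q].dropna().to_numpy()
            n = len(vals)
            row[f"{q}_mean"] = float(np.mean(vals)) if n else np.nan
            row[f"{q}_sd"] = float(np.std(vals, ddof=1)) if n >= 2 else np.nan
            row[f"{q}_n"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def _group_sort_key(grouping: str):
    order = {"severity": SEVERITY_ORDER, "region": REGION_ORDER,
             "gender": ("female", "male", "unknown")}.get(grouping)
    if order is None:
        return lambda g: (0, g)
    rank = {g: i for i, g in enumerate(order)}
    return lambda g: (rank.get(g, len(rank)), g)


def aggregate_levels(records, grouping: str = "none") -> CohortTable:
    """Per-group, per-level mean and sample SD of L12 and L13.

    Missing L12 values (no identifiable spinous tip) are excluded from both
    the mean and the count; empty (group, level) cells are omitted.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one patient record")
    values = _long_values(records, grouping)
    df = values.copy()
    df["_label"] = df["level"]
    table = _summarize(df, None)
    gkey = _group_sort_key(grouping)
    table = table.sort_values(
        by=["group", "level"],
        key=lambda col: (col.map(lambda g: gkey(g)) if col.name == "group"
                         else col.map(_LEVEL_INDEX.get)),
        kind="stable",
    ).reset_index(drop=True)
    return CohortTable(grouping=grouping, table=table, values=values)


def regional_means(cohort_table: CohortTable) -> CohortTable:
    """Append pooled regional rows ("T2...T11", "T12/L1", "L2...L5", "all").

    Pooling is over all (patient, level) values in the region — not over
    per-level means — so regional SDs reflect between-patient and
    between-level spread together.  "all" pools every measured level,
    including C7/T1 when present.
    """
    values = cohort_table.values
    frames = [cohort_table.table]
    for label, levels in list(REGIONS.items()) + [("all", VERTEBRAL_LEVELS)]:
        sub = values[values["level"].isin(levels)].copy()
        if sub.empty:
            continue
        sub["_label"] = label
        frames.append(_summarize(sub, None))
    table = pd.concat(frames, ignore_index=True)
    return CohortTable(grouping=cohort_table.grouping, table=table, values=values)


def _cell(table: pd.DataFrame, group: str, label: str, col: str):
    sel = table[(table["group"] == group) & (table["level"] == label)]
    if sel.empty:
        return None
    val = sel.iloc[0][col]
    return None if pd.isna(val) else float(val)


def _pooled_mean(values: pd.DataFrame, group: str, levels, col: str):
    sub = values[(values["group"] == group) & (values["level"].isin(levels))][col].dropna()
    return float(sub.mean()) if len(sub) else None


def findings_report(tables: dict[str, CohortTable]) -> dict:
    """Descriptive findings across groups (a diagnostics report, not a test).

    Evaluates, per group: (i) SD(L13) > SD(L12) over all levels;
    (ii) the mild < medium < strong ordering of SD(L13); (iii) the
    upper-thoracic ratio mean(T1–T4)/mean(T5–T9) for L12 vs L13; and
    (iv) for region-grouped tables, whether the regional row with maximal
    SD(L13) corresponds to the group's own curve region.  Entries that
    cannot be computed are reported as None.
    """
    report: dict = {}

    def with_regions(ct: CohortTable) -> CohortTable:
        if not set(ct.table["level"]) & set(REGIONS) and "all" not in set(ct.table["level"]):
            return regional_means(ct)
        return ct

    for grouping, ct in tables.items():
        ct = with_regions(ct)
        groups = list(dict.fromkeys(ct.table["group"]))
        entry: dict = {"sd_L13_gt_sd_L12": {}, "upper_thoracic_ratio": {}}
        for g in groups:
            sd12 = _cell(ct.table, g, "all", "L12_sd")
            sd13 = _cell(ct.table, g, "all", "L13_sd")
            entry["sd_L13_gt_sd_L12"][g] = {
                "sd_L12": sd12, "sd_L13": sd13,
                "holds": None if sd12 is None or sd13 is None else bool(sd13 > sd12),
            }
            ratios = {}
            for q in ("L12", "L13"):
                hi = _pooled_mean(ct.values, g, ("T1", "T2", "T3", "T4"), q)
                mid = _pooled_mean(ct.values, g, ("T5", "T6", "T7", "T8", "T9"), q)
                ratios[q] = None if hi is None or mid is None or mid == 0 else hi / mid
            ratios["L12_ratio_gt_L13_ratio"] = (
                None if ratios["L12"] is None or ratios["L13"] is None
                else bool(ratios["L12"] > ratios["L13"])
            )
            entry["upper_thoracic_ratio"][g] = ratios

        if grouping == "severity":
            sds = {g: _cell(ct.table, g, "all", "L13_sd") for g in SEVERITY_ORDER}
            entry["severity_sd_ordering_L13"] = {
                "sd": sds,
                "holds": (None if any(v is None for v in sds.values())
                          else bool(sds["mild"] < sds["medium"] < sds["strong"])),
            }
        if grouping == "region":
            per_group = {}
            for g in groups:
                sds = {label: _cell(ct.table, g, label, "L13_sd") for label in REGIONS}
                known = {k: v for k, v in sds.items() if v is not None}
                if not known:
                    per_group[g] = {"sd": sds, "max_sd_region": None, "holds": None}
                    continue
                max_label = max(known, key=known.get)
                max_region = _REGION_ROW_TO_REGION[max_label]
                per_group[g] = {
                    "sd": sds,
                    "max_sd_region": max_region,
                    "holds": None if g == "combined" else bool(max_region == g),
                }
            entry["max_sd_region_matches_curve_region"] = per_group
        report[grouping] = entry
    return report
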