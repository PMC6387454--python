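"""ROI aggregation, blood-normalised uptake metrics and cohort statistics.

The analysis chain: ROI medians of the parameter maps → per-subject changes
relative to baseline → blood-normalised changes

    Δr1_norm  = Δr1  / Δr1_blood,
    Δr2*_norm = Δr2* / Δr1_blood,

both normalised by the same subject's blood Δr1 at the same timepoint.
Immediately post-infusion, while the agent is confined to the blood pool,
Δr1_norm approximates the cerebral blood volume fraction and Δr2*_norm is
proportional to it.  Blood Δr2* is never used for normalisation.

:func:`cohort_stats` reproduces the inference chain on an uptake table:
paired t-tests against baseline and between timepoints, linear regression of
Δr2* on Δr1 with Pearson correlation, coefficients of variation of the
normalised changes, and between-tissue paired comparisons.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NormalizedChange",
    "roi_median",
    "uptake_table_from_maps",
    "normalized_change",
    "normalized_change_table",
    "paired_ttest",
    "coefficient_of_variation",
    "cohort_stats",
    "format_stats_report",
]

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ("subject", "region", "timepoint", "r1_median", "r2star_median")


@dataclass
class NormalizedChange:
    """Per-subject relaxation-rate changes for one region and timepoint."""

    delta_r1: float
    delta_r2star: float
    delta_r1_norm: float
    delta_r2star_norm: float


# ---------------------------------------------------------------------------
# ROI aggregation
# ---------------------------------------------------------------------------

def roi_median(map_: np.ndarray, mask: np.ndarray) -> float:
    """Median of in-mask, non-sentinel (non-NaN) voxels of a parameter map.

    Returns NaN when the mask is empty or all in-mask voxels are sentinels;
    the number of excluded voxels is logged.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != np.shape(map_):
        raise ValueError("mask and map shapes differ")
    if not mask.any():
        logger.warning("roi_median: empty mask")
        return float("nan")
    vals = np.asarray(map_, dtype=float)[mask]
    n_excluded = int(np.isnan(vals).sum())
    if n_excluded:
        logger.info("roi_median: excluded %d sentinel voxels of %d", n_excluded, vals.size)
    if n_excluded == vals.size:
        return float("nan")
    return float(np.nanmedian(vals))


def uptake_table_from_maps(
    maps_by_timepoint: dict[str, dict[str, np.ndarray]],
    masks_by_region: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Build a single-subject uptake table from parameter maps and ROI masks.

    ``maps_by_timepoint[tp]`` holds ``'r1'`` and/or ``'r2star'`` maps; blood
    regions get NaN r2star (unusable for normalisation).
    """
    rows = []
    for tp, maps in maps_by_timepoint.items():
        for region, mask in masks_by_region.items():
            r1 = roi_median(maps["r1"], mask) if "r1" in maps else float("nan")
            if region == "blood" or "r2star" not in maps:
                r2s = float("nan")
            else:
                r2s = roi_median(maps["r2star"], mask)
            rows.append(
                dict(subject="sub01", region=region, timepoint=tp,
                     r1_median=r1, r2star_median=r2s)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Normalised changes
# ---------------------------------------------------------------------------

def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"uptake table lacks columns {sorted(missing)}")
    dup = table.duplicated(subset=["subject", "region", "timepoint"])
    if dup.any():
        raise ValueError("uptake table has duplicate subject×region×timepoint rows")
    return table


def normalized_change_table(
    table: pd.DataFrame, baseline: str = "pre"
) -> pd.DataFrame:
    """Per-subject normalised changes for every region and post-baseline timepoint.

    Returns a tidy frame with columns ``subject``, ``region``, ``timepoint``,
    ``delta_r1``, ``delta_r2star``, ``delta_r1_norm``, ``delta_r2star_norm``.
    Rows are emitted only where the subject has both a baseline and a target
    measurement; a missing blood row for a subject/timepoint raises.
    """
    table = _validate_table(table)
    wide = table.set_index(["subject", "region", "timepoint"]).sort_index()
    out = []
    timepoints = [t for t in table["timepoint"].unique() if t != baseline]
    for (subject, region), grp in table.groupby(["subject", "region"], observed=True):
        if region == "blood":
            continue
        grp = grp.set_index("timepoint")
        if baseline not in grp.index:
            continue
        for tp in timepoints:
            if tp not in grp.index:
                continue
            try:
                blood_t = wide.loc[(subject, "blood", tp), "r1_median"]
                blood_0 = wide.loc[(subject, "blood", baseline), "r1_median"]
            except KeyError:
                raise KeyError(
                    f"missing blood r1 row for subject {subject!r} at "
                    f"timepoint {tp!r} or baseline {baseline!r}"
                ) from None
            d_blood = blood_t - blood_0
            d_r1 = grp.loc[tp, "r1_median"] - grp.loc[baseline, "r1_median"]
            d_r2s = grp.loc[tp, "r2star_median"] - grp.loc[baseline, "r2star_median"]
            norm = d_blood if d_blood != 0 else np.nan
            out.append(
                dict(
                    subject=subject,
                    region=region,
                    timepoint=tp,
                    delta_r1=d_r1,
                    delta_r2star=d_r2s,
                    delta_r1_blood=d_blood,
                    delta_r1_norm=d_r1 / norm,
                    delta_r2star_norm=d_r2s / norm,
                )
            )
    return pd.DataFrame(out)


def normalized_change(
    table: pd.DataFrame, region: str, timepoint: str, baseline: str = "pre"
) -> NormalizedChange:
    """Normalised change for one region/timepoint.

    For a single-subject table this is that subject's value; for a cohort it
    is computed from the group means of the medians (the per-subject values
    live in :func:`normalized_change_table`).
    """
    table = _validate_table(table)
    means = (
        table.groupby(["region", "timepoint"], observed=True)[
            ["r1_median", "r2star_median"]
        ].mean()
    )

    def get(reg, tp, col):
        try:
            return float(means.loc[(reg, tp), col])
        except KeyError:
            raise KeyError(f"no rows for region {reg!r} at timepoint {tp!r}") from None

    d_r1 = get(region, timepoint, "r1_median") - get(region, baseline, "r1_median")
    d_r2s = get(region, timepoint, "r2star_median") - get(
        region, baseline, "r2star_median"
    )
    d_blood = get("blood", timepoint, "r1_median") - get("blood", baseline, "r1_median")
    if d_blood == 0:
        if d_r1 == 0 and d_r2s == 0:
            return NormalizedChange(0.0, 0.0, 0.0, 0.0)
        raise ZeroDivisionError(
            f"blood delta r1 is zero at timepoint {timepoint!r}; "
            "normalised change undefined"
        )
    return NormalizedChange(d_r1, d_r2s, d_r1 / d_blood, d_r2s / d_blood)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def paired_ttest(a, b) -> tuple[float, float, int]:
    """Two-sided paired t-test with NaN pairs dropped.

    Degenerate zero-variance differences are resolved analytically: all-equal
    pairs give (t=0, p=1); a constant nonzero shift gives (t=±inf, p=0).
    Returns (t, p, n_pairs).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("paired_ttest: dropped %d incomplete pairs", n_dropped)
    a, b = a[keep], b[keep]
    n = len(a)
    if n < 2:
        logger.warning("paired_ttest: <2 complete pairs, test skipped")
        return float("nan"), float("nan"), n
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0:
            return 0.0, 1.0, n
        return math.copysign(float("inf"), d[0]), 0.0, n
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), n


def coefficient_of_variation(values) -> float:
    """CoV in percent: population standard deviation over mean × 100."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        return float("nan")
    m = v.mean()
    if m == 0:
        return float("nan")
    return float(np.std(v, ddof=0) / m * 100.0)


def _regression(x, y) -> dict:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3 or np.ptp(x) == 0:
        return dict(n=int(len(x)), slope=np.nan, intercept=np.nan,
                    r_squared=np.nan, pearson_r=np.nan, p_value=np.nan)
    res = stats.linregress(x, y)
    return dict(
        n=int(len(x)),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
    )


def cohort_stats(table: pd.DataFrame, baseline: str = "pre") -> dict:
    """Cohort-level statistics on an uptake table.

    Returns a nested dict with, per region and post-baseline timepoint:
    group means/SDs of the medians, paired t-tests of each rate against
    baseline and between consecutive post-infusion timepoints, linear
    regression of Δr2* on Δr1 (intercept, slope, R², Pearson r), normalised
    changes with coefficients of variation, and paired between-tissue
    comparisons of the normalised changes.  Raw p-values, no multiplicity
    correction.
    """
    table = _validate_table(table)
    if table["subject"].nunique() < 3:
        raise ValueError("cohort statistics require >=3 subjects")
    changes = normalized_change_table(table, baseline=baseline)
    wide = table.pivot_table(
        index=["subject", "region"], columns="timepoint",
        values=["r1_median", "r2star_median"], aggfunc="first", observed=True,
    )
    regions = [r for r in table["region"].unique() if r != "blood"]
    timepoints = [t for t in changes["timepoint"].unique()]

    report: dict = {"regions": {}, "between_tissue": {}, "n_subjects": int(table["subject"].nunique())}
    for region in table["region"].unique():
        sub = wide.loc[(slice(None), region), :]
        entry: dict = {"timepoints": {}}
        for tp in timepoints:
            tp_entry: dict = {}
            for rate in ("r1_median", "r2star_median"):
                if (rate, tp) not in sub.columns or (rate, baseline) not in sub.columns:
                    continue
                vals_t = sub[(rate, tp)].to_numpy()
                vals_0 = sub[(rate, baseline)].to_numpy()
                if np.all(np.isnan(vals_t)):
                    continue
                t, p, n = paired_ttest(vals_t, vals_0)
                tp_entry[rate.replace("_median", "")] = dict(
                    mean=float(np.nanmean(vals_t)),
                    sd=float(np.nanstd(vals_t, ddof=1)) if n > 1 else np.nan,
                    delta_mean=float(np.nanmean(vals_t - vals_0)),
                    t_vs_baseline=t, p_vs_baseline=p, n=n,
                )
            ch = changes[(changes["region"] == region) & (changes["timepoint"] == tp)]
            if len(ch):
                for metric in ("delta_r1_norm", "delta_r2star_norm"):
                    vals = ch[metric].to_numpy()
                    if np.all(np.isnan(vals)):
                        continue  # e.g. r1 not acquired at this timepoint
                    tp_entry[metric] = dict(
                        mean=float(np.nanmean(vals)),
                        cov_pct=coefficient_of_variation(vals),
                    )
                if not (ch["delta_r1"].isna().all() or ch["delta_r2star"].isna().all()):
                    tp_entry["regression_dr2star_on_dr1"] = _regression(
                        ch["delta_r1"], ch["delta_r2star"]
                    )
            entry["timepoints"][str(tp)] = tp_entry
        # between consecutive post-baseline timepoints
        entry["between_timepoints"] = {}
        for tp_a, tp_b in itertools.combinations(timepoints, 2):
            for rate in ("r1_median", "r2star_median"):
                if (rate, tp_a) not in sub.columns or (rate, tp_b) not in sub.columns:
                    continue
                a = sub[(rate, tp_a)].to_numpy()
                b = sub[(rate, tp_b)].to_numpy()
                if np.all(np.isnan(a)) or np.all(np.isnan(b)):
                    continue
                t, p, n = paired_ttest(b, a)
                entry["between_timepoints"][f"{rate.replace('_median','')}:{tp_a}_vs_{tp_b}"] = dict(
                    t=t, p=p, n=n
                )
        report["regions"][region] = entry

    # between-tissue comparisons of normalised changes (all pairs)
    for tp in timepoints:
        for metric in ("delta_r1_norm", "delta_r2star_norm"):
            piv = changes[changes["timepoint"] == tp].pivot(
                index="subject", columns="region", values=metric
            )
            for ra, rb in itertools.combinations(regions, 2):
                if ra not in piv.columns or rb not in piv.columns:
                    continue
                complete = (piv[ra].notna() & piv[rb].notna()).sum()
                if complete < 2:
                    continue  # metric unavailable at this timepoint
                t, p, n = paired_ttest(piv[ra], piv[rb])
                report["between_tissue"][f"{metric}:{ra}_vs_{rb}:{tp}"] = dict(t=t, p=p, n=n)
    return report


def format_stats_report(report: dict) -> str:
    """Human-readable rendering of :func:`cohort_stats` output."""
    lines = [f"Cohort statistics (n = {report['n_subjects']} subjects)", ""]
    for region, entry in report["regions"].items():
        lines.append(f"[{region}]")
        for tp, tp_entry in entry["timepoints"].items():
            for rate in ("r1", "r2star"):
                if rate in tp_entry:
                    d = tp_entry[rate]
                    lines.append(
                        f"  {tp:>7s} {rate:7s} mean={d['mean']:.3f} "
                        f"Δ={d['delta_mean']:+.3f} t={d['t_vs_baseline']:.2f} "
                        f"p={d['p_vs_baseline']:.3g} (n={d['n']})"
                    )
            for metric in ("delta_r1_norm", "delta_r2star_norm"):
                if metric in tp_entry:
                    d = tp_entry[metric]
                    lines.append(
                        f"  {tp:>7s} {metric:17s} mean={d['mean']:.4f} "
                        f"CoV={d['cov_pct']:.0f}%"
                    )
        lines.append("")
    if report["between_tissue"]:
        lines.append("Between-tissue paired comparisons (normalised changes):")
        for key, d in report["between_tissue"].items():
            lines.append(f"  {key:40s} t={d['t']:.2f} p={d['p']:.3g} (n={d['n']})")
    return "\n".join(lines)
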