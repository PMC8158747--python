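"""Volume- and region-stratified detection metrics and the study's statistics.

Per stratum: sensitivity TP/(TP+FN), false positives per case, and
F1 = 2·TP / (2·TP + FP + FN). TP/FN are stratified by the ground-truth
instance (its volume group or pancreas region); FP by the predicted
instance. Cumulative curves report sensitivity and FP rate for lesions of
equal or larger volume at each threshold. Statistical comparisons: Pearson
chi-square on regional detection rates, paired t-test on per-case counts,
and McNemar's test (continuity-corrected chi-square, exact binomial for
small discordant counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .instances import LesionInstance, MatchResult
from .regions import REGION_NAMES, RegionMap, assign_lesion_region

GROUP_LABELS = ("10-50", ">50-200", ">200-600", ">600")


@dataclass(frozen=True)
class VolumeGroups:
    """Volume strata in mm³: [b0, b1], (b1, b2], (b2, b3], (b3, ∞)."""

    boundaries: tuple[float, float, float, float] = (10.0, 50.0, 200.0, 600.0)
    labels: tuple[str, ...] = GROUP_LABELS

    def __post_init__(self):
        b = self.boundaries
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValidationError("volume-group boundaries must be strictly increasing")

    @property
    def floor(self) -> float:
        return self.boundaries[0]

    def group_of(self, volume_mm3: float) -> int:
        """0-based group index; raises for volumes below the exclusion floor."""
        b = self.boundaries
        if volume_mm3 < b[0]:
            raise ValidationError(f"volume {volume_mm3} mm³ is below the exclusion floor {b[0]}")
        for g in range(len(b) - 1):
            if volume_mm3 <= b[g + 1]:
                return g
        return len(b) - 1


def _metrics_row(stratum, tp: int, fp: int, fn: int, n_cases: int) -> dict:
    denom = tp + fn
    f1_denom = 2 * tp + fp + fn
    return {
        "stratum": stratum,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "n_cases": n_cases,
        "sensitivity": tp / denom if denom else np.nan,
        "fp_per_case": fp / n_cases,
        "f1": 2 * tp / f1_denom if f1_denom else np.nan,
    }


def _as_lists(match, gt, pred):
    if isinstance(match, MatchResult):
        return [match], [gt], [pred]
    return list(match), list(gt), list(pred)


def _status_iter(matches, gts, preds):
    """Yield (case_index, status, instance) with status in {tp, fn, fp}."""
    for c, (m, gt, pred) in enumerate(zip(matches, gts, preds)):
        gt_by_id = {g.id: g for g in gt}
        pred_by_id = {p.id: p for p in pred}
        for gid, pid, _ in m.pairs:
            yield c, "tp", gt_by_id[gid]
        for gid in m.fn_gt_ids:
            yield c, "fn", gt_by_id[gid]
        for pid in m.fp_pred_ids:
            yield c, "fp", pred_by_id[pid]


def overall_metrics(match, gt, pred, n_cases: int) -> dict:
    """Unstratified TP/FP/FN with sensitivity, FPs/case and F1."""
    matches, gts, preds = _as_lists(match, gt, pred)
    tp = sum(m.n_tp for m in matches)
    fp = sum(m.n_fp for m in matches)
    fn = sum(m.n_fn for m in matches)
    return _metrics_row("all", tp, fp, fn, n_cases)


def stratified_metrics(
    match,
    gt,
    pred,
    strata: VolumeGroups | RegionMap | Sequence[RegionMap],
    n_cases: int,
) -> pd.DataFrame:
    """Per-stratum TP/FP/FN, sensitivity, FPs/case and F1.

    ``strata`` is either :class:`VolumeGroups` (stratify by instance volume)
    or one :class:`RegionMap` per case (stratify by pancreas region). TP/FN
    use the ground-truth instance's stratum; FP the predicted instance's.
    """
    matches, gts, preds = _as_lists(match, gt, pred)
    if n_cases < 1:
        raise ValidationError("n_cases must be >= 1")

    if isinstance(strata, VolumeGroups):
        labels = list(strata.labels)

        def stratum_of(case_idx, inst):
            return strata.group_of(inst.volume_mm3)

    else:
        region_maps = [strata] * len(matches) if isinstance(strata, RegionMap) else list(strata)
        if len(region_maps) != len(matches):
            raise ValidationError("need one RegionMap per case")
        labels = [REGION_NAMES[k] for k in (1, 2, 3)]

        def stratum_of(case_idx, inst):
            return assign_lesion_region(inst, region_maps[case_idx]) - 1

    counts = {lab: {"tp": 0, "fp": 0, "fn": 0} for lab in labels}
    for c, status, inst in _status_iter(matches, gts, preds):
        counts[labels[stratum_of(c, inst)]][status] += 1
    return pd.DataFrame(
        [_metrics_row(lab, d["tp"], d["fp"], d["fn"], n_cases) for lab, d in counts.items()]
    )


def cumulative_curves(match, gt, pred, thresholds: Sequence[float], n_cases: int) -> pd.DataFrame:
    """Sensitivity and FP rate for lesions of equal or larger volume.

    At each threshold v: sensitivity over GT instances with volume >= v,
    FPs/case over predicted FP instances with volume >= v. Sensitivity is
    NaN-flagged when no GT instance reaches the threshold.
    """
    matches, gts, preds = _as_lists(match, gt, pred)
    records = list(_status_iter(matches, gts, preds))
    rows = []
    for v in thresholds:
        tp = sum(1 for _, s, i in records if s == "tp" and i.volume_mm3 >= v)
        fn = sum(1 for _, s, i in records if s == "fn" and i.volume_mm3 >= v)
        fp = sum(1 for _, s, i in records if s == "fp" and i.volume_mm3 >= v)
        rows.append(
            {
                "threshold_mm3": v,
                "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                "fp_per_case": fp / n_cases,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PairedCountComparison:
    mean_gt: float
    mean_pred: float
    mean_difference: float
    t_statistic: float | None
    p_value: float | None
    degenerate: bool


def compare_counts(gt_per_case: Sequence[float], pred_per_case: Sequence[float]) -> PairedCountComparison:
    """Paired t-test on per-case lesion counts (two-sided).

    Zero variance of the paired differences is flagged degenerate rather
    than producing an infinite statistic.
    """
    a = np.asarray(gt_per_case, dtype=float)
    b = np.asarray(pred_per_case, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValidationError("need equal-length paired lists with at least 2 cases")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return PairedCountComparison(
            float(a.mean()), float(b.mean()), float(diff.mean()), None, None, True
        )
    t, p = stats.ttest_rel(a, b)
    return PairedCountComparison(float(a.mean()), float(b.mean()), float(diff.mean()), float(t), float(p), False)


@dataclass
class RateTestResult:
    chi2: float
    df: int
    p_value: float
    small_sample_warning: bool


def regional_rate_test(detected_by_region: Sequence[int], total_by_region: Sequence[int]) -> RateTestResult:
    """Pearson chi-square on the 3×2 detected/missed table across regions."""
    det = np.asarray(detected_by_region, dtype=float)
    tot = np.asarray(total_by_region, dtype=float)
    if det.shape != (3,) or tot.shape != (3,):
        raise ValidationError("expected 3 detected and 3 total counts")
    if np.any(tot <= 0):
        raise ValidationError("every region must contain at least one lesion")
    if np.any(det > tot):
        raise ValidationError("detected counts cannot exceed totals")
    table = np.stack([det, tot - det])  # 2 x 3 detected/missed
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    return RateTestResult(float(chi2), int(df), float(p), bool((expected < 1).any()))


@dataclass
class McNemarResult:
    statistic: float | None
    p_value: float | None
    exact: bool
    degenerate: bool


def mcnemar_test(b: int, c: int) -> McNemarResult:
    """McNemar's test on discordant-pair counts.

    The statistic is the continuity-corrected chi-square form
    (|b−c|−1)²/(b+c), df 1. The p-value comes from that chi-square when
    b+c >= 25 and from the exact two-sided binomial otherwise.
    b = c = 0 is degenerate.
    """
    if b < 0 or c < 0:
        raise ValidationError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return McNemarResult(None, None, False, True)
    stat = (abs(b - c) - 1.0) ** 2 / n
    if n < 25:
        p = min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5))
        return McNemarResult(float(stat), float(p), True, False)
    return McNemarResult(float(stat), float(stats.chi2.sf(stat, df=1)), False, False)


@dataclass
class GTSummary:
    n_cysts: int
    n_cases: int
    mean_per_case: float
    sd_per_case: float
    volume_min: float
    volume_max: float
    volume_mean: float

    def report(self) -> dict:
        """Summary with the per-case mean rounded to one decimal."""
        return {
            "n_cysts": self.n_cysts,
            "n_cases": self.n_cases,
            "mean_per_case": round(self.mean_per_case, 1),
            "sd_per_case": round(self.sd_per_case, 1),
            "volume_min_mm3": round(self.volume_min, 1),
            "volume_max_mm3": round(self.volume_max, 1),
            "volume_mean_mm3": round(self.volume_mean, 1),
        }


def summarize_gt(gt_per_case: dict) -> GTSummary:
    """Descriptive statistics over ground-truth lesions per case.

    ``gt_per_case`` maps case id to a list of lesion volumes (mm³) or of
    :class:`LesionInstance`.
    """
    if not gt_per_case:
        raise ValidationError("need at least one case")
    volumes = []
    counts = []
    for case, items in gt_per_case.items():
        vols = [i.volume_mm3 if isinstance(i, LesionInstance) else float(i) for i in items]
        volumes.extend(vols)
        counts.append(len(vols))
    counts = np.asarray(counts, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    return GTSummary(
        n_cysts=int(counts.sum()),
        n_cases=len(counts),
        mean_per_case=float(counts.mean()),
        sd_per_case=float(counts.std(ddof=1)) if len(counts) > 1 else 0.0,
        volume_min=float(volumes.min()) if volumes.size else np.nan,
        volume_max=float(volumes.max()) if volumes.size else np.nan,
        volume_mean=float(volumes.mean()) if volumes.size else np.nan,
    )
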