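"""Sensitivity assessment of genotyping assays from allele-mixture series.

Before an allele-discrimination assay is trusted to quantify an allelic
ratio, it is run on gDNA mixtures of the two homozygotes at known ratios.
Under exponential amplification the per-well signal difference

    dCt(r) = ct_fam - ct_vic = -log2(r) / log2(1 + E) + delta

is linear in log2 of the mixture ratio ``r``, with slope -1 at perfect
efficiency (E = 1) and intercept equal to the assay's dye bias ``delta``.
An assay passes when its fitted response is close to that line and a
heterozygous control sample sits where a 1:1 mixture should; an assay whose
response is flat or scrambled cannot resolve allelic ratios and fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from aseqpcr.simulate import parse_ratio_sample_id

HET_CONTROL_ID = "het_control"

REASON_SLOPE = "SLOPE_OUT_OF_RANGE"
REASON_FIT = "POOR_FIT"
REASON_NON_MONOTONE = "NON_MONOTONE"
REASON_HET_CONTROL = "HET_CONTROL_INCONSISTENT"


@dataclass
class CalibrationSeries:
    """Per-ratio replicate dCt values for one assay, plus the 1:1 control."""

    assay_id: str
    points: list[tuple[float, list[float]]]
    het_control: list[float] = field(default_factory=list)
    n_dropped_wells: int = 0

    def ratios(self) -> np.ndarray:
        return np.array([r for r, _ in self.points])

    def means(self) -> np.ndarray:
        return np.array([float(np.mean(d)) for _, d in self.points])

    def sems(self) -> np.ndarray:
        return np.array(
            [stats.sem(d) if len(d) > 1 else 0.0 for _, d in self.points]
        )


@dataclass
class CalibrationResult:
    """Fitted mixture-response line and the assay's QC verdict."""

    assay_id: str
    slope: float
    intercept: float
    r_squared: float
    monotone: bool
    het_consistent: bool
    verdict: str
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.verdict == "PASS"

    def to_dict(self) -> dict:
        return {
            "assay_id": self.assay_id,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "monotone": self.monotone,
            "het_consistent": self.het_consistent,
            "verdict": self.verdict,
            "reasons": list(self.reasons),
        }


def summarize_series(wells: pd.DataFrame, assay_id: str | None = None) -> CalibrationSeries:
    """Collect per-ratio replicate dCt values from a mixture-series plate.

    The mixture ratio is parsed from the sample name (``mix_4_1`` style);
    the ``het_control`` sample is kept separate as the 1:1 control.  Wells
    with a censored channel are dropped; a ratio whose replicates are all
    censored is an error.
    """
    if assay_id is None:
        ids = wells["assay_id"].unique()
        if len(ids) != 1:
            raise ValueError(f"plate holds {len(ids)} assays; pass assay_id explicitly")
        assay_id = str(ids[0])
    sub = wells[wells["assay_id"] == assay_id]

    by_ratio: dict[float, list[float]] = {}
    het: list[float] = []
    n_dropped = 0
    for row in sub.itertuples():
        if math.isnan(row.ct_fam) or math.isnan(row.ct_vic):
            n_dropped += 1
            continue
        dct = row.ct_fam - row.ct_vic
        if row.sample_id == HET_CONTROL_ID:
            het.append(dct)
            continue
        ratio = parse_ratio_sample_id(row.sample_id)
        if ratio is None:
            raise ValueError(
                f"cannot parse mixture ratio from sample_id {row.sample_id!r}"
            )
        by_ratio.setdefault(ratio, []).append(dct)

    empty = {
        parse_ratio_sample_id(s)
        for s in sub["sample_id"].unique()
        if s != HET_CONTROL_ID and parse_ratio_sample_id(s) is not None
    } - set(by_ratio)
    if empty:
        raise ValueError(
            f"assay {assay_id}: no surviving replicates at ratios {sorted(empty)}"
        )

    points = sorted(by_ratio.items())
    return CalibrationSeries(assay_id, [(r, d) for r, d in points], het, n_dropped)


def _strictly_monotone(values: np.ndarray) -> bool:
    diffs = np.diff(values)
    return bool(np.all(diffs < 0) or np.all(diffs > 0))


def _monotone_within_noise(
    series: CalibrationSeries,
    means: np.ndarray,
    slope: float,
    pooled_sd: float,
    z: float = 2.5,
) -> bool:
    """Monotone mixture response, tolerating inversions explainable by noise.

    Strictly monotone means always qualify.  Otherwise the response still
    counts as monotone when the fitted slope is non-zero and every adjacent
    inversion against the slope's direction is smaller than ``z`` standard
    errors of that gap -- so a flat response (no direction) or a scrambled
    one (large inversions) fails, while triplicate noise on a genuinely
    ordered series does not.
    """
    if _strictly_monotone(means):
        return True
    if abs(slope) < 1e-12:
        return False
    direction = 1.0 if slope > 0 else -1.0
    sizes = [len(d) for _, d in series.points]
    for i, gap in enumerate(np.diff(means)):
        se_gap = pooled_sd * math.sqrt(1.0 / sizes[i] + 1.0 / sizes[i + 1])
        if gap * direction <= -z * se_gap:
            return False
    return True


def fit_calibration(
    series: CalibrationSeries,
    slope_tol: float = 0.3,
    r2_min: float = 0.9,
    het_tol_se: float = 2.0,
) -> CalibrationResult:
    """Fit mean dCt against log2(mixture ratio) and apply the QC criteria.

    PASS requires |slope| within ``slope_tol`` of 1, R^2 >= ``r2_min``,
    strictly monotone per-ratio means, and (when a het control is present)
    its mean within ``het_tol_se`` standard errors of the fitted dCt at
    ratio 1 -- i.e. of the intercept, the dye-bias estimate.  The standard
    error combines the het-control mean's error (from the pooled
    within-group replicate SD, which is stable at triplicate depth) with
    the intercept's regression error.
    """
    ratios = series.ratios()
    if len(ratios) < 2:
        raise ValueError(
            f"assay {series.assay_id}: need >= 2 distinct ratios, got {len(ratios)}"
        )
    x = np.log2(ratios)
    y = series.means()

    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    # within-group replicate scatter, pooled over all ratio groups and the
    # het control; stable even at triplicate depth
    groups = [d for _, d in series.points] + \
        ([series.het_control] if series.het_control else [])
    ss_within = sum(float(np.sum((np.asarray(g) - np.mean(g)) ** 2)) for g in groups)
    dof_within = sum(len(g) - 1 for g in groups)
    pooled_sd = math.sqrt(ss_within / dof_within) if dof_within > 0 else 0.0

    reasons = []
    if not (1.0 - slope_tol) <= abs(slope) <= (1.0 + slope_tol):
        reasons.append(REASON_SLOPE)
    if r_squared < r2_min:
        reasons.append(REASON_FIT)
    monotone = _monotone_within_noise(series, y, slope, pooled_sd)
    if not monotone:
        reasons.append(REASON_NON_MONOTONE)

    het_consistent = True
    if series.het_control:
        het_mean = float(np.mean(series.het_control))
        se_het = pooled_sd / math.sqrt(len(series.het_control))
        # regression SE of the intercept (x = log2 ratio, k mean points whose
        # sampling variance comes from the pooled replicate SD)
        k = len(x)
        sxx = float(np.sum((x - x.mean()) ** 2))
        n_bar = float(np.mean([len(d) for _, d in series.points]))
        var_mean = pooled_sd**2 / n_bar
        se_b0 = math.sqrt(var_mean * (1.0 / k + x.mean() ** 2 / sxx)) if sxx > 0 else 0.0
        tol = max(het_tol_se * math.hypot(se_het, se_b0), 1e-6)
        het_consistent = bool(abs(het_mean - intercept) <= tol)
        if not het_consistent:
            reasons.append(REASON_HET_CONTROL)

    verdict = "PASS" if not reasons else "FAIL"
    return CalibrationResult(
        assay_id=series.assay_id,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r_squared),
        monotone=monotone,
        het_consistent=het_consistent,
        verdict=verdict,
        reasons=reasons,
    )


def calibrate_plate(
    wells: pd.DataFrame, slope_tol: float = 0.3, r2_min: float = 0.9
) -> list[CalibrationResult]:
    """Summarize and fit every assay on a mixture-series plate."""
    return [
        fit_calibration(summarize_series(wells, assay), slope_tol, r2_min)
        for assay in sorted(wells["assay_id"].unique())
    ]
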