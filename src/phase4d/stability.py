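"""Feature-stability classification across respiratory phases via ICC(A,1).

A feature is treated as a quantity measured repeatedly on each patient by the
phases acting as "raters".  The two-way mixed-effects intraclass correlation
for absolute agreement of single measurements, ICC(A,1) (McGraw & Wong), is

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

with subjects-by-raters ANOVA mean squares (rows MS_R, columns MS_C, error
MS_E), n subjects and k raters.  A feature is classed stable when the lower
bound of the F-based 95% confidence interval is at least 0.85
(good-to-excellent agreement).

Two phase subsets are supported: all phases ("stability (10)") and, for
single-phase feature sets, each patient's selected phase with its two cyclic
neighbours ("stability (3)", raters identified by relative position -1/0/+1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .core_data import FeatureMatrix, PhaseFeatureTable
from .feature_sets import neighbour_average
from .phase_selection import StablePhaseResult

logger = logging.getLogger("phase4d")

STABILITY_THRESHOLD = 0.85

#: The valid (set method, assessment) combinations: neighbour-phase
#: assessments only apply to single-phase feature sets.
VALID_COMBINATIONS: tuple[tuple[str, str], ...] = tuple(
    (m, a) for m in ("personalised", "phase50")
    for a in ("none", "stability10", "stability3", "averaging3")
) + tuple(
    (m, a) for m in ("mean", "median") for a in ("none", "stability10")
)


@dataclass
class StabilityRecord:
    feature: str
    roi: str
    icc: float
    ci_low: float
    ci_high: float
    phase_subset: str
    stable: bool


def icc_a1(data: np.ndarray, alpha: float = 0.05) -> tuple[float, float, float]:
    """ICC(A,1) point estimate and F-based 95% CI for a subjects x raters matrix.

    Returns ``(nan, nan, nan)`` when the total variance is zero (agreement is
    undefined); callers class such features unstable.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 5 or x.shape[1] < 2:
        raise ValueError("need a subjects x raters matrix with >=5 subjects, >=2 raters")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in ICC input")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        return (np.nan, np.nan, np.nan)
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssb = k * ((row_means - grand) ** 2).sum()
    ssj = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssb - ssj
    msb = ssb / (n - 1)
    msj = ssj / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msb + (k - 1) * mse + k * (msj - mse) / n
    if denom == 0:
        return (np.nan, np.nan, np.nan)
    icc = (msb - mse) / denom
    # McGraw-Wong F-based interval (Satterthwaite df for the denominator)
    if mse == 0:
        return (icc, icc, icc)
    fj = msj / mse
    vn = (n - 1) * (k - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * k ** 2 * icc ** 2 * fj ** 2 \
        + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f_u = f_dist.ppf(1 - alpha / 2, n - 1, v)
    f_l = f_dist.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msb - f_u * mse) / (
        f_u * (k * msj + (k * n - k - n) * mse) + n * msb)
    hi = n * (f_l * msb - mse) / (
        k * msj + (k * n - k - n) * mse + n * f_l * msb)
    return (float(icc), float(lo), float(hi))


def classify_stability(table: PhaseFeatureTable, subset: str = "all_phases",
                       stable_phases: StablePhaseResult | None = None,
                       centre: str | None = None,
                       threshold: float = STABILITY_THRESHOLD) -> list[StabilityRecord]:
    """Classify every feature (per ROI) as stable or unstable.

    ``subset`` is ``"all_phases"`` or ``"neighbours"``; for the latter either a
    fixed ``centre`` phase label (e.g. "50%") or a per-patient
    ``stable_phases`` result supplies each patient's rater triple.
    """
    phases = list(table.phases)
    P = len(phases)
    records: list[StabilityRecord] = []
    for roi in table.rois:
        if not (table.data["roi"] == roi).any():
            continue
        wide = table.wide(roi)
        features = wide.index.get_level_values("feature").unique()
        for feat in features:
            block = wide.xs(feat, level="feature")
            if subset == "all_phases":
                mat = block.to_numpy(dtype=float)
                desc = "all_phases"
            elif subset == "neighbours":
                rows = []
                for patient in block.index:
                    label = centre if centre is not None else \
                        stable_phases.selected[patient]
                    i = phases.index(label)
                    cols = [phases[(i - 1) % P], phases[i], phases[(i + 1) % P]]
                    rows.append(block.loc[patient, cols].to_numpy(dtype=float))
                mat = np.asarray(rows)
                desc = f"neighbours_of({centre or 'personalised'})"
            else:
                raise ValueError(f"unknown subset {subset!r}")
            ok = np.isfinite(mat).all(axis=1)
            mat = mat[ok]
            if mat.shape[0] < 5:
                icc, lo, hi = np.nan, np.nan, np.nan
            else:
                icc, lo, hi = icc_a1(mat)
            if np.isnan(icc):
                logger.info("feature %s (%s): ICC undefined, classed unstable",
                            feat, roi)
                stable = False
            else:
                stable = lo >= threshold
            records.append(StabilityRecord(feature=feat, roi=roi, icc=icc,
                                           ci_low=lo, ci_high=hi,
                                           phase_subset=desc, stable=stable))
    return records


def records_to_frame(records: list[StabilityRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def apply_assessment(matrix: FeatureMatrix, table: PhaseFeatureTable,
                     method: str,
                     stable_phases: StablePhaseResult | None = None,
                     threshold: float = STABILITY_THRESHOLD) -> FeatureMatrix:
    """Apply one of the four stability-assessment regimes to a feature set.

    ``none`` is the identity; ``stability10``/``stability3`` drop unstable
    features; ``averaging3`` replaces values with the neighbour-phase mean.
    Combinations outside the 12 valid ones raise a configuration error.
    """
    combo = (matrix.set_method, method)
    if combo not in VALID_COMBINATIONS:
        raise ValueError(
            f"invalid combination {combo}: neighbour-phase assessment applies "
            "only to single-phase feature sets (phase50, personalised)")
    if method == "none":
        return FeatureMatrix(values=matrix.values.copy(),
                            set_method=matrix.set_method, assessment="none",
                            roi_of=matrix.roi_of)
    if method == "averaging3":
        centre = "50%" if matrix.set_method == "phase50" else stable_phases.selected
        return neighbour_average(table, centre)
    if method == "stability10":
        records = classify_stability(table, "all_phases", threshold=threshold)
    else:  # stability3
        if matrix.set_method == "phase50":
            records = classify_stability(table, "neighbours", centre="50%",
                                         threshold=threshold)
        else:
            records = classify_stability(table, "neighbours",
                                         stable_phases=stable_phases,
                                         threshold=threshold)
    stable_feats = {r.feature for r in records if r.stable}
    keep = [c for c in matrix.values.columns if c in stable_feats]
    dropped = matrix.values.shape[1] - len(keep)
    logger.info("%s: dropped %d unstable features, %d remain",
                method, dropped, len(keep))
    return FeatureMatrix(values=matrix.values[keep].copy(),
                        set_method=matrix.set_method, assessment=method,
                        roi_of=matrix.roi_of)
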