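"""Outcome-independent feature filtering: volume decorrelation, redundancy,
standardisation.

ROI volume is a major radiomics confounder, so features whose Spearman rank
correlation with tumour volume exceeds 0.5 in magnitude are removed first.
Remaining features are then pruned for mutual redundancy per ROI scope:
whenever a pair correlates above 0.5 (|Pearson|), the member with the largest
mean absolute correlation to all other remaining features is removed, greedily
re-evaluating after each removal.  Finally features are z-scored (mean 0,
unit sample SD) once, before any cross-validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .core_data import FeatureMatrix

logger = logging.getLogger("phase4d")

RHO_MAX = 0.5
R_MAX = 0.5


@dataclass
class RemovalAudit:
    """Per-stage removal log supporting percentage-remaining reporting."""

    rows: list[tuple[str, str, float]] = field(default_factory=list)

    def add(self, feature: str, stage: str, statistic: float) -> None:
        self.rows.append((feature, stage, statistic))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["feature", "stage", "statistic"])


def volume_filter(matrix: FeatureMatrix, volume: pd.Series,
                  rho_max: float = RHO_MAX,
                  audit: RemovalAudit | None = None) -> FeatureMatrix:
    """Drop features with |Spearman rho| to tumour volume above ``rho_max``.

    Constant features (undefined rho) are retained with a warning.
    """
    vol = volume.loc[matrix.values.index].to_numpy(dtype=float)
    keep = []
    for feat in matrix.values.columns:
        x = matrix.values[feat].to_numpy(dtype=float)
        if np.all(x == x[0]):
            warnings.warn(f"feature {feat!r} constant; volume rho undefined, retained",
                          stacklevel=2)
            keep.append(feat)
            continue
        rho = spearmanr(x, vol).statistic
        if abs(rho) > rho_max:
            if audit is not None:
                audit.add(feat, "volume", float(rho))
        else:
            keep.append(feat)
    logger.info("volume filter: %d -> %d features",
                matrix.values.shape[1], len(keep))
    return FeatureMatrix(values=matrix.values[keep].copy(),
                        set_method=matrix.set_method,
                        assessment=matrix.assessment, roi_of=matrix.roi_of)


def redundancy_filter(matrix: FeatureMatrix, r_max: float = R_MAX,
                      audit: RemovalAudit | None = None) -> FeatureMatrix:
    """Iteratively remove mutually correlated features, per ROI scope.

    Tumour and peritumour features are pruned independently.  At each step the
    feature (among members of any |r| > ``r_max`` pair) with the largest mean
    |r| to all other remaining features in scope is removed; ties go to the
    lexicographically later name.
    """
    kept_all = []
    scopes: dict[str, list[str]] = {}
    for feat in matrix.values.columns:
        scopes.setdefault(matrix.roi_of.get(feat, "all"), []).append(feat)
    for roi, feats in scopes.items():
        remaining = list(feats)
        while len(remaining) >= 2:
            sub = matrix.values[remaining]
            corr = sub.corr(method="pearson").abs().to_numpy()
            np.fill_diagonal(corr, 0.0)
            corr = np.nan_to_num(corr)
            pair_mask = corr > r_max
            if not pair_mask.any():
                break
            in_pair = pair_mask.any(axis=0)
            mean_corr = corr.sum(axis=1) / (len(remaining) - 1)
            candidates = [(mean_corr[i], remaining[i], i)
                          for i in np.nonzero(in_pair)[0]]
            # largest mean correlation; ties -> lexicographically later name
            score, name, idx = max(candidates, key=lambda t: (t[0], t[1]))
            if audit is not None:
                audit.add(name, "redundancy", float(score))
            remaining.pop(idx)
        kept_all.extend(remaining)
    kept = [c for c in matrix.values.columns if c in set(kept_all)]
    logger.info("redundancy filter: %d -> %d features",
                matrix.values.shape[1], len(kept))
    return FeatureMatrix(values=matrix.values[kept].copy(),
                        set_method=matrix.set_method,
                        assessment=matrix.assessment, roi_of=matrix.roi_of)


def standardise(matrix: FeatureMatrix) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Z-score each feature (sample SD); returns the matrix and the
    (mean, sd) parameters so the transform can be inverted.

    Constant features are dropped with a warning.
    """
    if matrix.values.shape[0] < 2:
        raise ValueError("need at least 2 patients to standardise")
    means = matrix.values.mean()
    sds = matrix.values.std(ddof=1)
    constant = sds == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant features dropped",
                      stacklevel=2)
    keep = sds.index[~constant]
    z = (matrix.values[keep] - means[keep]) / sds[keep]
    params = pd.DataFrame({"mean": means[keep], "sd": sds[keep]})
    out = FeatureMatrix(values=z, set_method=matrix.set_method,
                       assessment=matrix.assessment, roi_of=matrix.roi_of)
    return out, params
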