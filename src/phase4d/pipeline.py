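"""End-to-end assembly: the 12 feature set x assessment combinations.

The fixed filtering order for every combination is stability assessment,
volume decorrelation, redundancy elimination, then standardisation, producing
nested subsets ready for the supervised selectors and the model harness.
"""

from __future__ import annotations

import logging

import pandas as pd

from .core_data import FeatureMatrix, PhaseFeatureTable
from .feature_sets import build_feature_set
from .phase_selection import StablePhaseResult, select_stable_phases
from .stability import VALID_COMBINATIONS, apply_assessment
from .unsupervised_selection import (RemovalAudit, redundancy_filter,
                                     standardise, volume_filter)

logger = logging.getLogger("phase4d")


def prepare_feature_tables(table: PhaseFeatureTable, volume: pd.Series,
                           stable: StablePhaseResult | None = None,
                           threshold: float = 0.85,
                           combos=VALID_COMBINATIONS
                           ) -> dict[tuple[str, str], FeatureMatrix]:
    """Build every valid (set method, assessment) feature matrix, filtered
    and standardised.  Returns a dict keyed by the combination."""
    if stable is None and any(m == "personalised" for m, _ in combos):
        stable = select_stable_phases(table)
    base_sets: dict[str, FeatureMatrix] = {}
    out: dict[tuple[str, str], FeatureMatrix] = {}
    for method, assessment in combos:
        if method not in base_sets:
            base_sets[method] = build_feature_set(
                table, method, stable if method == "personalised" else None)
        fm = apply_assessment(base_sets[method], table, assessment,
                              stable_phases=stable, threshold=threshold)
        audit = RemovalAudit()
        fm = volume_filter(fm, volume, audit=audit)
        fm = redundancy_filter(fm, audit=audit)
        fm, _ = standardise(fm)
        logger.info("%s+%s: %d features after filtering",
                    method, assessment, fm.values.shape[1])
        out[(method, assessment)] = fm
    return out
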