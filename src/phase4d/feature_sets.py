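"""Construction of the four candidate single feature sets.

Each method collapses the phase axis of a phase-feature table to one value per
patient-feature:

* ``mean`` — mean across all phases,
* ``median`` — median across all phases (midpoint of order statistics for an
  even phase count),
* ``phase50`` — the value at the 50% (end-exhale by convention) phase,
* ``personalised`` — the value at each patient's most stable phase.

``neighbour_average`` additionally averages the selected phase with its two
cyclic neighbours (e.g. centre 70% averages 60%, 70% and 80%), the noise
reduction used by the "averaging (3)" assessment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_data import FeatureMatrix, PhaseFeatureTable
from .phase_selection import StablePhaseResult, _roi_map

SET_METHODS = ("mean", "median", "phase50", "personalised")


def _collapse(table: PhaseFeatureTable, fn) -> pd.DataFrame:
    frames = []
    for roi in table.rois:
        if not (table.data["roi"] == roi).any():
            continue
        wide = table.wide(roi)
        series = fn(wide)
        frames.append(series.unstack(level="feature"))
    return pd.concat(frames, axis=1).sort_index()


def build_feature_set(table: PhaseFeatureTable, method: str,
                      stable: StablePhaseResult | None = None) -> FeatureMatrix:
    """Collapse the phase axis with one of the four set-construction methods."""
    if method not in SET_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {SET_METHODS}")
    if method == "personalised":
        if stable is None:
            raise ValueError("personalised method requires a StablePhaseResult")
        from .phase_selection import personalised_values
        return personalised_values(table, stable)
    if method == "phase50":
        if "50%" not in table.phases:
            raise ValueError("no phase labelled 50% in table")
        values = _collapse(table, lambda w: w["50%"])
    elif method == "mean":
        values = _collapse(table, lambda w: w.mean(axis=1))
    else:  # median: midpoint of middle order statistics for even counts
        values = _collapse(table, lambda w: w.median(axis=1))
    return FeatureMatrix(values=values, set_method=method, roi_of=_roi_map(table))


def neighbour_average(table: PhaseFeatureTable,
                      centre: pd.Series | str) -> FeatureMatrix:
    """Mean of the three cyclic phases centred on each patient's phase.

    ``centre`` is either a per-patient Series of phase labels (personalised)
    or a single label applied to all patients (e.g. ``"50%"``).
    """
    phases = list(table.phases)
    P = len(phases)
    if P < 3:
        raise ValueError("need at least 3 phases")

    def triple(label: str) -> list[str]:
        i = phases.index(label)
        return [phases[(i - 1) % P], phases[i], phases[(i + 1) % P]]

    frames = []
    for roi in table.rois:
        if not (table.data["roi"] == roi).any():
            continue
        wide = table.wide(roi)
        rows = {}
        for patient, block in wide.groupby(level="patient"):
            label = centre if isinstance(centre, str) else centre[patient]
            cols = block[triple(label)]
            if cols.isna().any().any():
                raise ValueError(
                    f"missing neighbour-phase cell for patient {patient!r}")
            s = cols.mean(axis=1)
            s.index = s.index.get_level_values("feature")
            rows[patient] = s
        frames.append(pd.DataFrame(rows).T)
    values = pd.concat(frames, axis=1).sort_index()
    values.index.name = "patient"
    method = "phase50" if isinstance(centre, str) else "personalised"
    return FeatureMatrix(values=values, set_method=method,
                        assessment="averaging3", roi_of=_roi_map(table))
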