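"""Personalised most-stable-phase selection.

For each patient and feature, the cyclic neighbour difference

    dX[p] = |x[p] - x[p-1]| + |x[p] - x[p+1]|      (indices mod P)

measures how much the feature changes between phase ``p`` and its two
respiratory neighbours (phase 0% neighbours 90% and 10%).  The phase with
minimum dX is the most stable phase for that patient-feature pair; the modal
winner across all features (both ROIs, both image types by default) is the
patient's personalised phase.  Ties — in the per-feature argmin and the
per-patient mode — are broken toward the phase cyclically closest to the 50%
(exhale) label, then toward the lower phase index, reflecting the prior that
stable phases cluster near exhale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import FeatureMatrix, PhaseFeatureTable

logger = logging.getLogger("phase4d")


@dataclass
class StablePhaseResult:
    """Per-patient selected phase with per-phase vote tallies."""

    selected: pd.Series            # patient -> phase label
    votes: pd.DataFrame            # patient x phase vote counts
    per_feature: pd.DataFrame      # patient x feature winning phase label

    @property
    def patients(self) -> list:
        return list(self.selected.index)


def neighbour_difference(x: np.ndarray) -> np.ndarray:
    """Summed absolute difference of each phase to its two cyclic neighbours.

    Accepts a 1-D series (length P >= 3) or a 2-D array with phases on the
    last axis; returns an array of the same shape.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError("need at least 3 phases")
    if not np.all(np.isfinite(x)):
        bad = np.argwhere(~np.isfinite(x))
        raise ValueError(f"non-finite value at phase index {bad[0][-1]}")
    prev = np.roll(x, 1, axis=-1)
    nxt = np.roll(x, -1, axis=-1)
    return np.abs(x - prev) + np.abs(x - nxt)


def _tiebreak_order(P: int, centre: int) -> np.ndarray:
    """Phase indices ranked by (cyclic distance to centre, index)."""
    idx = np.arange(P)
    dist = np.minimum(np.abs(idx - centre), P - np.abs(idx - centre))
    return idx[np.lexsort((idx, dist))]


def stable_phase_per_feature(dx: np.ndarray, centre: int | None = None) -> int:
    """Argmin of the neighbour difference with a deterministic tie-break.

    Ties go to the phase with smallest cyclic distance to ``centre`` (the 50%
    label by default, i.e. index P//2), then to the lower index.
    """
    dx = np.asarray(dx, dtype=float)
    P = dx.shape[-1]
    centre = P // 2 if centre is None else centre
    order = _tiebreak_order(P, centre)
    best = dx.min()
    for i in order:
        if dx[i] == best:
            return int(i)
    raise AssertionError("unreachable")


def stable_phase_per_patient(winners: np.ndarray, P: int,
                             centre: int | None = None) -> tuple[int, np.ndarray]:
    """Modal winning phase across features, with vote tally.

    Returns ``(phase index, votes)`` where ``votes[p]`` counts features whose
    most stable phase is ``p``.  Ties broken as in
    :func:`stable_phase_per_feature`.
    """
    winners = np.asarray(winners, dtype=int)
    if winners.size == 0:
        raise ValueError("no voting features")
    votes = np.bincount(winners, minlength=P)
    centre = P // 2 if centre is None else centre
    order = _tiebreak_order(P, centre)
    best = votes.max()
    for i in order:
        if votes[i] == best:
            return int(i), votes
    raise AssertionError("unreachable")


def _phase_centre(table: PhaseFeatureTable) -> int:
    phases = list(table.phases)
    return phases.index("50%") if "50%" in phases else len(phases) // 2


def select_stable_phases(table: PhaseFeatureTable,
                         features: list[str] | None = None,
                         include_constant: bool = True) -> StablePhaseResult:
    """Run the per-feature vote and per-patient majority selection.

    ``features`` restricts the voting set (default: all features from both
    ROIs).  Constant features vote via the tie-break phase unless
    ``include_constant`` is False.  Patients with a missing cell in any phase
    of a feature have that feature excluded from their vote, with a logged
    count.
    """
    P = table.n_phases
    centre = _phase_centre(table)
    wide = pd.concat([table.wide(r) for r in table.rois
                      if (table.data["roi"] == r).any()])
    if features is not None:
        wide = wide[wide.index.get_level_values("feature").isin(features)]
    selected, vote_rows, feat_rows = {}, {}, {}
    n_dropped = 0
    for patient, block in wide.groupby(level="patient"):
        vals = block.to_numpy(dtype=float)
        feats = block.index.get_level_values("feature")
        ok = np.isfinite(vals).all(axis=1)
        n_dropped += int((~ok).sum())
        vals, feats = vals[ok], feats[ok]
        if vals.shape[0] == 0:
            raise ValueError(f"patient {patient!r} has no complete features")
        dx = neighbour_difference(vals)
        if not include_constant:
            keep = ~(dx == 0).all(axis=1)
            dx, feats = dx[keep], feats[keep]
            if dx.shape[0] == 0:
                raise ValueError(f"patient {patient!r}: all features constant")
        winners = np.array([stable_phase_per_feature(row, centre) for row in dx])
        sel, votes = stable_phase_per_patient(winners, P, centre)
        selected[patient] = table.phases[sel]
        vote_rows[patient] = votes
        feat_rows[patient] = pd.Series(
            [table.phases[w] for w in winners], index=feats)
    if n_dropped:
        logger.warning("%d patient-features dropped from vote (missing cells)",
                       n_dropped)
    votes_df = pd.DataFrame(vote_rows, index=list(table.phases)).T
    per_feature = pd.DataFrame(feat_rows).T
    return StablePhaseResult(selected=pd.Series(selected).sort_index(),
                             votes=votes_df.sort_index(),
                             per_feature=per_feature.sort_index())


def personalised_values(table: PhaseFeatureTable,
                        result: StablePhaseResult) -> FeatureMatrix:
    """Gather every feature at each patient's single selected phase."""
    missing = set(table.patients) - set(result.patients)
    if missing:
        raise ValueError(f"no selected phase for patients {sorted(missing)}")
    frames = []
    for roi in table.rois:
        if not (table.data["roi"] == roi).any():
            continue
        wide = table.wide(roi)
        rows = {}
        for patient, block in wide.groupby(level="patient"):
            phase = result.selected[patient]
            col = block[phase]
            if col.isna().any():
                bad = col.index.get_level_values("feature")[col.isna()][0]
                raise ValueError(
                    f"missing cell at selected phase {phase} for patient "
                    f"{patient!r}, feature {bad!r}")
            col.index = col.index.get_level_values("feature")
            rows[patient] = col
        frames.append(pd.DataFrame(rows).T)
    values = pd.concat(frames, axis=1).sort_index()
    values.index.name = "patient"
    roi_of = _roi_map(table)
    return FeatureMatrix(values=values, set_method="personalised",
                        roi_of=roi_of)


def _roi_map(table: PhaseFeatureTable) -> dict[str, str]:
    return dict(table.data[["feature", "roi"]]
                .drop_duplicates().itertuples(index=False, name=None))
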