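"""Data model and I/O for phase-feature tables, clinical covariates and outcomes.

The central container is :class:`PhaseFeatureTable`, a long-format table with
one value per (patient, phase, roi, feature) cell.  Respiratory phases form a
cyclic, ordered axis (default ``0%`` ... ``90%`` in steps of 10); feature-set
construction and phase-selection operations index phases cyclically.

Clinical and survival records are plain pandas DataFrames validated by the
functions below.  Missing feature cells are kept missing (never imputed):
operations that need a phase exclude patients missing it and log the count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("phase4d")

SCHEMA_VERSION = "1"

#: Default cyclic phase labels: ten respiratory bins from peak inhale (0%).
DEFAULT_PHASES: tuple[str, ...] = tuple(f"{10 * i}%" for i in range(10))

#: Region-of-interest labels: tumour features (TFs) and peritumoural features (PFs).
ROIS: tuple[str, ...] = ("tumour", "peritumour")

CLINICAL_FIELDS = ("patient", "sex", "age", "t_stage", "ecog", "lobe",
                   "tumour_volume", "motion_amplitude")


class SchemaError(ValueError):
    """A required column is missing or unmappable."""


class IntegrityError(ValueError):
    """Duplicate or inconsistent cells in an input table."""


@dataclass
class PhaseFeatureTable:
    """Long-format feature table X[feature, patient, phase, roi].

    Parameters
    ----------
    data:
        DataFrame with columns ``patient, phase, roi, feature, value``.
    phases:
        Ordered cyclic phase labels.  Index ``i`` has cyclic neighbours
        ``(i - 1) % P`` and ``(i + 1) % P``.
    """

    data: pd.DataFrame
    phases: tuple[str, ...] = DEFAULT_PHASES
    rois: tuple[str, ...] = ROIS
    missing: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"patient", "phase", "roi", "feature", "value"}
        missing_cols = required - set(self.data.columns)
        if missing_cols:
            raise SchemaError(f"missing columns: {sorted(missing_cols)}")
        dup = self.data.duplicated(subset=["patient", "phase", "roi", "feature"])
        if dup.any():
            raise IntegrityError(
                f"{int(dup.sum())} duplicate (patient, phase, roi, feature) rows")
        unknown = set(self.data["phase"]) - set(self.phases)
        if unknown:
            raise SchemaError(f"unknown phase labels: {sorted(unknown)}")
        self.data = self.data.copy()
        self.data["phase"] = pd.Categorical(
            self.data["phase"], categories=list(self.phases), ordered=True)
        self.data.sort_values(["patient", "roi", "feature", "phase"],
                              inplace=True, kind="mergesort")
        self.data.reset_index(drop=True, inplace=True)
        self.missing = self._find_missing()

    @property
    def patients(self) -> list:
        return sorted(self.data["patient"].unique())

    @property
    def features(self) -> list[str]:
        return sorted(self.data["feature"].unique())

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    def _find_missing(self) -> pd.DataFrame:
        """Cells absent from the full patient x phase x roi x feature grid."""
        pats = self.data["patient"].unique()
        feats_per_roi = {r: g["feature"].unique()
                         for r, g in self.data.groupby("roi", observed=True)}
        rows = []
        for roi, feats in feats_per_roi.items():
            sub = self.data[self.data["roi"] == roi]
            pivot = sub.pivot_table(index=["patient", "feature"], columns="phase",
                                    values="value", aggfunc="first", observed=False,
                                    dropna=False)
            full = pd.MultiIndex.from_product([pats, feats],
                                              names=["patient", "feature"])
            pivot = pivot.reindex(full)
            isna = pivot.isna()
            if isna.values.any():
                pidx, ph = np.nonzero(isna.values)
                for i, j in zip(pidx, ph):
                    pat, feat = pivot.index[i]
                    rows.append((pat, pivot.columns[j], roi, feat))
        if rows:
            logger.warning("%d missing feature cells flagged", len(rows))
        return pd.DataFrame(rows, columns=["patient", "phase", "roi", "feature"])

    def wide(self, roi: str) -> pd.DataFrame:
        """(patient, feature) x phase matrix for one ROI; NaN where missing."""
        sub = self.data[self.data["roi"] == roi]
        out = sub.pivot_table(index=["patient", "feature"], columns="phase",
                              values="value", aggfunc="first", observed=False,
                              dropna=False)
        return out[list(self.phases)]

    def to_csv(self, path) -> None:
        df = self.data.copy()
        df["schema_version"] = SCHEMA_VERSION
        df.to_csv(path, index=False)


def load_phase_features(path, schema: dict[str, str] | None = None,
                        phases: tuple[str, ...] = DEFAULT_PHASES) -> PhaseFeatureTable:
    """Load a long-format feature CSV.

    ``schema`` maps canonical column names (patient, phase, roi, feature,
    value) to the file's column names, for files using different headers.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    df = df[[c for c in df.columns if c != "schema_version"]]
    return PhaseFeatureTable(df, phases=phases)


@dataclass
class FeatureMatrix:
    """One value per patient-feature after feature-set construction.

    ``provenance`` records the (set method, assessment method) pair, which must
    be one of the 12 valid combinations when assessment has been applied.
    """

    values: pd.DataFrame                 # index: patient, columns: feature
    set_method: str                      # mean | median | phase50 | personalised
    assessment: str = "none"             # none | stability10 | stability3 | averaging3
    roi_of: dict[str, str] = field(default_factory=dict)

    @property
    def patients(self) -> list:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    @property
    def provenance(self) -> tuple[str, str]:
        return (self.set_method, self.assessment)


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(CLINICAL_FIELDS) - set(df.columns)
    if missing:
        raise SchemaError(f"clinical table missing columns: {sorted(missing)}")
    bad_vol = df["tumour_volume"].notna() & (df["tumour_volume"] <= 0)
    if bad_vol.any():
        raise IntegrityError("tumour_volume must be positive")
    return df


def validate_survival(df: pd.DataFrame) -> pd.DataFrame:
    missing = {"patient", "time", "event"} - set(df.columns)
    if missing:
        raise SchemaError(f"survival table missing columns: {sorted(missing)}")
    if (df["time"] <= 0).any():
        raise IntegrityError("survival time must be positive")
    if not df["event"].isin([0, 1]).all():
        raise IntegrityError("event indicator must be 0/1")
    return df


def complete_case_filter(clinical: pd.DataFrame,
                         required: list[str]) -> pd.DataFrame:
    """Keep only records with no missing value in ``required`` columns.

    Order is preserved.  An empty result raises a warning, not an error.
    """
    if not required:
        return clinical.copy()
    unknown = set(required) - set(clinical.columns)
    if unknown:
        raise SchemaError(f"unknown required variables: {sorted(unknown)}")
    keep = clinical[required].notna().all(axis=1)
    out = clinical[keep].copy()
    if out.empty:
        warnings.warn("complete-case filter removed every record", stacklevel=2)
    logger.info("complete-case filter: %d -> %d records", len(clinical), len(out))
    return out


_LOBE_MERGE = {"lower": "lower", "middle": "upper+middle", "upper": "upper+middle",
               "upper+middle": "upper+middle"}
_ECOG_MERGE = {0: "0+1", 1: "0+1", 2: "2", 3: "3",
               "0": "0+1", "1": "0+1", "2": "2", "3": "3", "0+1": "0+1"}
_TSTAGE_MERGE = {"T1": "T1", "T2": "T2+T3", "T3": "T2+T3", "T2+T3": "T2+T3"}


def merge_categories(clinical: pd.DataFrame) -> pd.DataFrame:
    """Apply the sparse-category merges: middle lobe into upper, ECOG 0 into
    1, and T3 (rare in an early-stage SABR cohort) into T2.

    Near-empty categories make the Cox design quasi-separated, so they are
    folded into their nearest neighbour before dummy coding.  Idempotent;
    unknown categories raise.
    """
    out = clinical.copy()

    def _map(series, mapping, name):
        def one(v):
            if pd.isna(v):
                return v
            if v not in mapping:
                raise ValueError(f"unknown {name} category: {v!r}")
            return mapping[v]
        return series.map(one)

    out["lobe"] = _map(out["lobe"], _LOBE_MERGE, "lobe")
    out["ecog"] = _map(out["ecog"], _ECOG_MERGE, "ecog")
    out["t_stage"] = _map(out["t_stage"], _TSTAGE_MERGE, "t_stage")
    return out
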