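"""Final Cox models, bootstrap validation, and fraction of new information.

The baseline clinical model regresses distant-failure hazard on tumour
volume, lobe location (middle merged into upper), sex, age, T stage and ECOG
performance status (0 merged into 1).  Each clinical-radiomics (CR) model adds
one radiomic signature.  Added value is quantified by the adequacy index
LR_C / LR_CR — the ratio of likelihood-ratio chi-square statistics of the
nested models against the null — and its complement, the fraction of new
information 1 - LR_C/LR_CR: the proportion of explainable outcome variation
contributed by the radiomic signature.  For comparability with the wider
radiomics literature, the concordance index is summarised as the median and
percentile 95% CI over bootstrap resamples, each refit on the resample and
scored on the original data unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.utils import concordance_index as _lifelines_cindex

logger = logging.getLogger("phase4d")

CLINICAL_COVARIATES = ("tumour_volume", "lobe", "sex", "age", "t_stage", "ecog")


@dataclass
class FittedCox:
    model: CoxPHFitter
    covariates: list[str]
    loglik: float
    lr_chi2: float

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.model.params_)

    @property
    def p_values(self) -> pd.Series:
        return self.model.summary["p"]


@dataclass
class ModelComparison:
    label: str
    lr_clinical: float
    lr_cr: float
    adequacy: float
    fraction_new: float
    cindex_median: float = float("nan")
    cindex_ci: tuple[float, float] = (float("nan"), float("nan"))
    hazard_ratios: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    p_values: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    signature: list[str] = field(default_factory=list)


def clinical_design(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix for the clinical base model.

    Categorical covariates (sex, t_stage, ecog, lobe) are dummy-coded with the
    first category as reference; volume and age enter linearly.
    """
    df = clinical.set_index("patient") if "patient" in clinical.columns \
        else clinical
    parts = [df[["tumour_volume", "age"]].astype(float)]
    for col in ("sex", "t_stage", "ecog", "lobe"):
        dummies = pd.get_dummies(df[col].astype(str), prefix=col,
                                 drop_first=True, dtype=float)
        parts.append(dummies)
    return pd.concat(parts, axis=1)


def fit_cox(design: pd.DataFrame, time, event) -> FittedCox:
    """Maximum partial-likelihood Cox fit with LR chi-square against the null."""
    df = design.copy()
    df["__time"] = np.asarray(time, dtype=float)
    df["__event"] = np.asarray(event, dtype=float)
    if df.isna().any().any():
        raise ValueError("missing covariate values")
    if len(df) <= design.shape[1]:
        raise ValueError("more covariates than patients")
    cph = CoxPHFitter(penalizer=0.0)
    cph.fit(df, duration_col="__time", event_col="__event")
    lr = cph.log_likelihood_ratio_test()
    return FittedCox(model=cph, covariates=list(design.columns),
                     loglik=float(cph.log_likelihood_),
                     lr_chi2=float(lr.test_statistic))


def concordance_index(time, event, risk) -> float:
    """Harrell's C for risk scores (higher risk, earlier event)."""
    risk = np.asarray(risk, dtype=float)
    if not np.all(np.isfinite(risk)):
        raise ValueError("non-finite risk scores")
    return float(_lifelines_cindex(np.asarray(time, float), -risk,
                                   np.asarray(event, int)))


def bootstrap_cindex(design: pd.DataFrame, time, event, B: int = 500,
                     seed: int = 0) -> tuple[float, float, float]:
    """Median and percentile 95% CI of the c-index over bootstrap refits.

    Each resample (with replacement, size n) refits the model, which then
    scores the *original* data unchanged.  Resamples with zero events are
    redrawn with a logged count.
    """
    if B < 2:
        raise ValueError("need B >= 2 bootstrap resamples")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    n = len(design)
    rng = np.random.default_rng(seed)
    X = design.to_numpy(dtype=float)
    cs, redraws = [], 0
    while len(cs) < B:
        idx = rng.integers(0, n, size=n)
        if event[idx].sum() == 0:
            redraws += 1
            continue
        sub = pd.DataFrame(X[idx], columns=design.columns)
        try:
            fit = fit_cox(sub, time[idx], event[idx])
        except Exception:
            redraws += 1
            continue
        risk = X @ fit.model.params_.to_numpy()
        cs.append(concordance_index(time, event, risk))
    if redraws:
        logger.info("%d bootstrap resamples redrawn", redraws)
    cs = np.asarray(cs)
    lo, hi = np.percentile(cs, [2.5, 97.5])
    return float(np.median(cs)), float(lo), float(hi)


def fraction_new_information(clinical_fit: FittedCox,
                             cr_fit: FittedCox, label: str = "") -> ModelComparison:
    """Adequacy index LR_C/LR_CR and fraction of new information 1 - adequacy.

    The models must be nested (CR covariates contain the clinical ones) and
    fit on the same patients.
    """
    if not set(clinical_fit.covariates) <= set(cr_fit.covariates):
        raise ValueError("models are not nested")
    if cr_fit.lr_chi2 == 0:
        raise ValueError("LR chi-square of the full model is zero; "
                         "fraction of new information undefined")
    adequacy = clinical_fit.lr_chi2 / cr_fit.lr_chi2
    return ModelComparison(
        label=label, lr_clinical=clinical_fit.lr_chi2, lr_cr=cr_fit.lr_chi2,
        adequacy=adequacy, fraction_new=1.0 - adequacy,
        hazard_ratios=cr_fit.hazard_ratios, p_values=cr_fit.p_values)


# ------------------------------------------------------------------- harness

def run_model_harness(feature_tables: dict, clinical: pd.DataFrame,
                      time, event, selector: str = "mrmr",
                      repeats: int = 40, folds: int = 5, B: int = 500,
                      seed: int = 0) -> list[ModelComparison]:
    """Fit the clinical baseline plus one CR model per valid combination.

    ``feature_tables`` maps (set_method, assessment) labels to standardised
    :class:`~phase4d.core_data.FeatureMatrix` objects (already filtered).
    Returns a 13-row comparison (12 CR models + clinical baseline) when all 12
    combinations are supplied.
    """
    from .stability import VALID_COMBINATIONS
    from .supervised_selection import build_signature, run_cv

    invalid = set(feature_tables) - set(VALID_COMBINATIONS)
    if invalid:
        raise ValueError(f"invalid feature set/assessment combinations: {sorted(invalid)}")
    cdesign = clinical_design(clinical)
    cfit = fit_cox(cdesign, time, event)
    med, lo, hi = bootstrap_cindex(cdesign, time, event, B=B, seed=seed)
    out = [ModelComparison(label="clinical", lr_clinical=cfit.lr_chi2,
                           lr_cr=cfit.lr_chi2, adequacy=1.0, fraction_new=0.0,
                           cindex_median=med, cindex_ci=(lo, hi),
                           hazard_ratios=cfit.hazard_ratios,
                           p_values=cfit.p_values)]
    for combo, fm in feature_tables.items():
        label = f"{combo[0]}+{combo[1]}"
        X = fm.values.loc[cdesign.index]
        runs = run_cv(X, cdesign, time, event, selector,
                      repeats=repeats, folds=folds, seed=seed)
        sig = build_signature(runs)
        if not sig.features:
            logger.warning("%s: empty signature; CR model equals clinical", label)
            design = cdesign
        else:
            design = pd.concat([cdesign, X[sig.features]], axis=1)
        crfit = fit_cox(design, time, event)
        comp = fraction_new_information(cfit, crfit, label=label)
        comp.signature = sig.features
        comp.cindex_median, *ci = bootstrap_cindex(design, time, event,
                                                   B=B, seed=seed)
        comp.cindex_ci = tuple(ci)
        out.append(comp)
    return out


def comparison_frame(comparisons: list[ModelComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append({"model": c.label, "lr_clinical": c.lr_clinical,
                     "lr_cr": c.lr_cr, "adequacy": c.adequacy,
                     "fraction_new": c.fraction_new,
                     "cindex_median": c.cindex_median,
                     "cindex_lo": c.cindex_ci[0], "cindex_hi": c.cindex_ci[1],
                     "signature": ";".join(c.signature)})
    return pd.DataFrame(rows)
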