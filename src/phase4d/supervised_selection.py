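"""Supervised feature selection inside repeated event-matched stratified CV.

Three selectors are compared, each run independently over 200 train/test
samples from 40 repeats of five-fold stratified cross-validation whose folds
preserve the event/censor proportion ("event-matching"):

1. univariable — features with Wald p < 0.05 in a univariable Cox regression;
2. multivariable — features that significantly improve the clinical Cox model
   in a likelihood-ratio test (p < 0.05), tested one at a time;
3. MRMR — greedy minimum-redundancy maximum-relevance ranking, where relevance
   is the sign-aligned concordance of the feature rescaled to [0, 1]
   (2*(c - 0.5)) and redundancy the mean |Pearson r| to already-selected
   features; features are added while relevance - redundancy > 0.

Per run, the selected features plus clinical covariates form a Cox model
scored by concordance on train and test; selectors are ranked by
``C_test - |C_test - C_train|`` from median concordances.  The signature is
the occurrence-ranked feature list truncated to the rounded median per-run
selected-set size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from ._coxutils import fit_cox_fast, harrell_cindex

logger = logging.getLogger("phase4d")

ALPHA = 0.05
SELECTORS = ("univariable", "multivariable", "mrmr")


@dataclass
class CVRun:
    repeat: int
    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    selected: list[str] = field(default_factory=list)
    c_train: float = float("nan")
    c_test: float = float("nan")


@dataclass
class Signature:
    features: list[str]
    occurrence: pd.Series
    length: int


def scv_partition(event: np.ndarray, repeats: int = 40, folds: int = 5,
                  seed: int = 0) -> list[CVRun]:
    """Event-matched stratified K-fold partitions, ``repeats`` times.

    Events and non-events are shuffled separately and dealt round-robin, so
    every fold's event count differs from the ideal proportion by at most one
    patient.  Reproducible under ``seed``.
    """
    event = np.asarray(event).astype(bool)
    n = event.size
    if event.sum() < folds or (~event).sum() < folds:
        raise ValueError(f"need at least {folds} events and {folds} non-events")
    rng = np.random.default_rng(seed)
    ev_idx = np.flatnonzero(event)
    ce_idx = np.flatnonzero(~event)
    runs = []
    for rep in range(repeats):
        fold_of = np.empty(n, dtype=int)
        for pool in (ev_idx, ce_idx):
            perm = rng.permutation(pool)
            fold_of[perm] = np.arange(perm.size) % folds
        for k in range(folds):
            test = np.flatnonzero(fold_of == k)
            train = np.flatnonzero(fold_of != k)
            runs.append(CVRun(repeat=rep, fold=k, train_idx=train, test_idx=test))
    return runs


# ------------------------------------------------------------------ selectors

def select_univariable(X: pd.DataFrame, time, event,
                       alpha: float = ALPHA) -> list[str]:
    """Features significant in a univariable Cox regression (Wald p < alpha)."""
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    out = []
    for feat in X.columns:
        x = X[feat].to_numpy(dtype=float)[:, None]
        fit = fit_cox_fast(time, event, x)
        if not fit.converged or not np.isfinite(fit.se[0]) or fit.se[0] == 0:
            logger.debug("univariable fit failed for %s, skipped", feat)
            continue
        p = 2 * norm.sf(abs(fit.beta[0] / fit.se[0]))
        if p < alpha:
            out.append(feat)
    return out


def select_multivariable(X: pd.DataFrame, clinical: pd.DataFrame, time, event,
                         alpha: float = ALPHA) -> list[str]:
    """Features that improve the clinical Cox model in an LR test (p < alpha).

    Each feature is added one at a time to the fixed clinical base model.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    C = clinical.to_numpy(dtype=float)
    base = fit_cox_fast(time, event, C)
    out = []
    for feat in X.columns:
        design = np.column_stack([C, X[feat].to_numpy(dtype=float)])
        fit = fit_cox_fast(time, event, design)
        if not fit.converged:
            logger.debug("multivariable fit failed for %s, skipped", feat)
            continue
        lr = 2.0 * (fit.loglik - base.loglik)
        if lr < 0:
            continue
        if chi2.sf(lr, 1) < alpha:
            out.append(feat)
    return out


def _aligned_relevance(x, time, event) -> float:
    """2*(c - 0.5) with the concordance sign-aligned so relevance >= 0."""
    c = harrell_cindex(time, event, x)
    c = max(c, 1.0 - c)
    return 2.0 * (c - 0.5)


def select_mrmr(X: pd.DataFrame, time, event) -> list[str]:
    """Greedy MRMR for survival: add argmax(relevance - redundancy) while > 0."""
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    feats = list(X.columns)
    if not feats:
        return []
    rel = {f: _aligned_relevance(X[f].to_numpy(float), time, event)
           for f in feats}
    arr = X.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.abs(np.corrcoef(arr, rowvar=False))
    corr = np.atleast_2d(np.nan_to_num(corr))
    col = {f: i for i, f in enumerate(feats)}
    selected: list[str] = []
    remaining = set(feats)
    while remaining:
        best_f, best_score = None, -np.inf
        for f in sorted(remaining):
            red = (np.mean([corr[col[f], col[s]] for s in selected])
                   if selected else 0.0)
            score = rel[f] - red
            if score > best_score:
                best_f, best_score = f, score
        if best_score <= 0:
            break
        selected.append(best_f)
        remaining.discard(best_f)
    return selected


_SELECT_FN = {"univariable": lambda X, C, t, d: select_univariable(X, t, d),
              "multivariable": select_multivariable,
              "mrmr": lambda X, C, t, d: select_mrmr(X, t, d)}


# ------------------------------------------------------------------- CV loop

def performance_ranking(c_test: float, c_train: float) -> float:
    """Test concordance penalised by the train/test gap:
    ``C_test - |C_test - C_train|``."""
    return c_test - abs(c_test - c_train)


def run_cv(X: pd.DataFrame, clinical: pd.DataFrame, time, event,
           selector: str, repeats: int = 40, folds: int = 5,
           seed: int = 0) -> list[CVRun]:
    """Execute the selector inside every CV run and score train/test models."""
    if selector not in SELECTORS:
        raise ValueError(f"unknown selector {selector!r}")
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    runs = scv_partition(event, repeats=repeats, folds=folds, seed=seed)
    sel_fn = _SELECT_FN[selector]
    C = clinical.to_numpy(dtype=float)
    for run in runs:
        tr, te = run.train_idx, run.test_idx
        Xtr = X.iloc[tr]
        run.selected = sel_fn(Xtr, clinical.iloc[tr], time[tr], event[tr])
        full = np.column_stack([C, X.to_numpy(dtype=float)[:, [
            X.columns.get_loc(f) for f in run.selected]]]) \
            if run.selected else C
        fit = fit_cox_fast(time[tr], event[tr], full[tr])
        risk = full @ fit.beta
        try:
            run.c_train = harrell_cindex(time[tr], event[tr], risk[tr])
            run.c_test = harrell_cindex(time[te], event[te], risk[te])
        except ValueError:
            logger.debug("no comparable pairs in run %d/%d", run.repeat, run.fold)
    return runs


def rank_selectors(results: dict[str, list[CVRun]]) -> tuple[str, pd.DataFrame]:
    """Per-selector performance ranking from median train/test concordances.

    Returns the argmax selector and the comparison table.
    """
    rows = []
    for name, runs in results.items():
        c_tr = float(np.nanmedian([r.c_train for r in runs]))
        c_te = float(np.nanmedian([r.c_test for r in runs]))
        rows.append({"selector": name, "c_train": c_tr, "c_test": c_te,
                     "ranking": performance_ranking(c_te, c_tr)})
    table = pd.DataFrame(rows).set_index("selector")
    return table["ranking"].idxmax(), table


def build_signature(runs: list[CVRun]) -> Signature:
    """Occurrence-ranked feature list truncated to the median per-run size.

    A fractional median size rounds half up.  Ties at the cut are broken by
    lower mean per-run selection position, then by name.
    """
    counts: dict[str, int] = {}
    positions: dict[str, list[int]] = {}
    sizes = []
    for run in runs:
        sizes.append(len(run.selected))
        for pos, f in enumerate(run.selected):
            counts[f] = counts.get(f, 0) + 1
            positions.setdefault(f, []).append(pos)
    if not counts:
        logger.warning("no features selected in any run; empty signature")
        return Signature(features=[], occurrence=pd.Series(dtype=int), length=0)
    length = int(math.floor(np.median(sizes) + 0.5))
    ranked = sorted(counts,
                    key=lambda f: (-counts[f], np.mean(positions[f]), f))
    occ = pd.Series({f: counts[f] for f in ranked})
    return Signature(features=ranked[:length], occurrence=occ, length=length)
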