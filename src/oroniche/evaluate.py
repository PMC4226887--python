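"""Model evaluation, selection, and variable importance.

Implements the evaluator suite used to pick among candidate maxent
models — test AUC (accuracy), sample-size-corrected AIC (complexity,
computed from raw probabilities at the presences) and minimal predicted
area (prediction parsimony) — plus the PCA-based choice of the replicate
most representative of its 50-replicate cloud, rank-sum candidate
ranking, the max-SSS binarisation threshold, three variable-importance
metrics (percent contribution, permutation importance, jackknife gains),
response curves and suitability–elevation profiling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grid import ConfigurationError, Grid
from .maxent import (
    FeatureSet,
    MaxentModel,
    ReplicateRun,
    build_features,
    fit_maxent,
    regularized_gain,
)
from .overlap import RangeMask
from .terrain import PredictorStack

__all__ = [
    "auc",
    "aicc_closed_form",
    "aicc",
    "threshold_max_sss",
    "mpa",
    "select_representative_replicate",
    "CandidateResult",
    "rank_candidates",
    "percent_contribution",
    "permutation_importance",
    "jackknife_gains",
    "response_curve",
    "apply_threshold",
    "suitability_elevation_profile",
]


def auc(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """ROC AUC in its rank-statistic form: the probability that a random
    presence outscores a random background point, ties counting half.

    Computed from average ranks, which equals the exhaustive
    (wins + 0.5·ties) / (n_presence·n_background) count.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ConfigurationError("auc requires non-empty score sets")
    ranks = stats.rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2
    return float(u / (p.size * b.size))


def aicc_closed_form(lnl: float, k: int, n: int) -> float:
    """AICc = −2 lnL + 2k + 2k(k+1)/(n−k−1)."""
    return -2.0 * lnl + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def aicc(raw_at_presences: np.ndarray, k: int) -> tuple[float, str | None]:
    """AICc of a maxent model from its raw probabilities at the presences.

    ``k`` is the number of nonzero coefficients; n is the presence count.
    Returns (value, None), or (nan, reason) when undefined — presence
    count too small (n ≤ k+1) or a presence with zero raw probability.
    """
    raw = np.asarray(raw_at_presences, dtype=float)
    n = raw.size
    if np.any(raw <= 0):
        return float("nan"), "zero raw probability at a presence"
    if n <= k + 1:
        return float("nan"), f"too few presences (n={n}) for k={k} parameters"
    lnl = float(np.log(raw).sum())
    return aicc_closed_form(lnl, k, n), None


def threshold_max_sss(
    presence_scores: np.ndarray, background_scores: np.ndarray
) -> float:
    """Threshold maximising sensitivity + specificity.

    Candidates are the distinct observed scores; sensitivity counts
    presences at or above the threshold, specificity counts background
    strictly below it.  Ties go to the lowest qualifying threshold.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ConfigurationError("threshold selection requires non-empty score sets")
    candidates = np.unique(np.concatenate([p, b]))
    sens = (p[None, :] >= candidates[:, None]).mean(axis=1)
    spec = (b[None, :] < candidates[:, None]).mean(axis=1)
    total = sens + spec
    return float(candidates[int(np.argmax(total))])  # argmax → first (lowest) tie


def mpa(
    calibration_scores: np.ndarray,
    presence_scores: np.ndarray,
    inclusion: float = 1.0,
) -> float:
    """Minimal predicted area: fraction of calibration cells predicted at
    or above the threshold that keeps ``inclusion`` of the presences
    inside (inclusion = 1.0 ⇒ the minimum presence prediction).

    Lower is better; invariant under any strictly increasing transform
    of the scores.
    """
    if not 0 < inclusion <= 1:
        raise ConfigurationError("inclusion must be in (0, 1]")
    cal = np.asarray(calibration_scores, dtype=float)
    p = np.asarray(presence_scores, dtype=float)
    thr = float(np.quantile(p, 1.0 - inclusion))
    return float(np.mean(cal >= thr))


def select_representative_replicate(
    metrics: np.ndarray, variance_cutoff: float = 0.95
) -> int:
    """Index of the replicate closest to the centre of the replicate cloud.

    The metric matrix (replicates × metrics) is standardised, projected
    by PCA, and the replicate minimising Euclidean distance to the cloud
    centroid in the component space covering at least
    ``variance_cutoff`` of the variance is returned.  Ties break to the
    lowest replicate index; with fewer than two replicates the only one
    is returned.
    """
    M = np.atleast_2d(np.asarray(metrics, dtype=float))
    r = M.shape[0]
    if r < 2:
        return 0
    mean = M.mean(axis=0)
    sd = M.std(axis=0)
    Xs = np.where(sd > 0, (M - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    if not np.any(Xs != 0):
        return 0
    # PCA by SVD of the (already centred per column) standardized matrix
    Xc = Xs - Xs.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    var = S ** 2
    total = var.sum()
    if total <= 0:
        return 0
    cum = np.cumsum(var) / total
    q = int(np.searchsorted(cum, variance_cutoff - 1e-12) + 1)
    q = min(q, len(S))
    proj = (U * S)[:, :q]
    d = np.linalg.norm(proj - proj.mean(axis=0), axis=1)
    return int(np.argmin(d))


@dataclass
class CandidateResult:
    """One variable-set × β candidate with its selection metrics."""

    variables: list[str]
    beta: float
    auc_test: float
    aicc: float
    mpa: float
    representative_id: int
    aicc_reason: str | None = None
    group: str = ""
    model: MaxentModel | None = None
    replicates: list[ReplicateRun] | None = None
    contribution: dict[str, float] = field(default_factory=dict)
    rank_sum: float = float("nan")

    @property
    def label(self) -> str:
        return ", ".join(self.variables)


def rank_candidates(candidates: list[CandidateResult]) -> list[CandidateResult]:
    """Rank candidates by the sum of their ranks on test AUC (higher
    better), AICc (lower better) and MPA (lower better).

    Candidates with missing AICc take the worst AICc rank; rank-sum ties
    break to the lower AICc.
    """
    if not candidates:
        return []
    aucs = np.array([c.auc_test for c in candidates])
    aiccs = np.array([c.aicc for c in candidates])
    mpas = np.array([c.mpa for c in candidates])
    aicc_filled = np.where(np.isnan(aiccs), np.inf, aiccs)
    r_auc = stats.rankdata(-aucs)
    r_aicc = stats.rankdata(aicc_filled)
    r_mpa = stats.rankdata(mpas)
    rank_sum = r_auc + r_aicc + r_mpa
    for c, rs in zip(candidates, rank_sum):
        c.rank_sum = float(rs)
    order = sorted(
        range(len(candidates)),
        key=lambda i: (rank_sum[i], aicc_filled[i], candidates[i].label),
    )
    return [candidates[i] for i in order]


def percent_contribution(contribution: dict[str, float]) -> dict[str, float]:
    """Normalise per-variable training-gain credits to percentages.

    Credits are the objective improvements accumulated per source
    variable during coordinate-descent training; negatives (which cannot
    arise from monotone updates, but are clipped defensively) count as 0.
    A model with zero total gain gets a uniform attribution and a
    warning.
    """
    vals = {v: max(0.0, float(c)) for v, c in contribution.items()}
    total = sum(vals.values())
    if total <= 0:
        warnings.warn("zero total training gain; uniform contribution attribution",
                      stacklevel=2)
        n = len(vals)
        return {v: 100.0 / n for v in vals}
    return {v: 100.0 * c / total for v, c in vals.items()}


def permutation_importance(
    model: MaxentModel,
    point_values: np.ndarray,
    presence_rows: np.ndarray,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation importance per variable, as percentages.

    For each variable, its values are randomly permuted across the
    training points (presences + background together), the linear
    predictor is recomputed, and the drop in training AUC is recorded;
    drops are normalised to sum 100.
    """
    fs = model.feature_set
    rng = np.random.default_rng(seed)
    V = np.asarray(point_values, dtype=float)
    is_pres = np.zeros(V.shape[0], dtype=bool)
    is_pres[np.asarray(presence_rows, dtype=int)] = True
    scores = fs.transform(V) @ model.coefs
    base = auc(scores[is_pres], scores[~is_pres])
    drops: dict[str, float] = {}
    for i, name in enumerate(fs.variables):
        Vp = V.copy()
        Vp[:, i] = rng.permutation(Vp[:, i])
        s = fs.transform(Vp) @ model.coefs
        drops[name] = max(0.0, base - auc(s[is_pres], s[~is_pres]))
    total = sum(drops.values())
    if total <= 0:
        return {v: 0.0 for v in drops}
    return {v: 100.0 * d / total for v, d in drops.items()}


def jackknife_gains(
    stack: PredictorStack,
    presences: tuple[np.ndarray, np.ndarray],
    background: tuple[np.ndarray, np.ndarray],
    beta: float = 1.0,
    classes: set[str] | None = None,
    hinge_knots: int = 20,
    max_iter: int = 5000,
    tol: float = 1e-7,
) -> pd.DataFrame:
    """Jackknife variable importance: regularised training gain of models
    refit with only each variable and with all variables except it."""
    names = stack.names
    if len(names) < 2:
        raise ConfigurationError("jackknife requires at least 2 variables")

    def _gain(subset: list[str]) -> float:
        try:
            fs = build_features(stack.subset(subset), background, presences,
                                classes=classes, hinge_knots=hinge_knots)
            F_bg = fs.at_cells(*background)
            F_p = fs.at_cells(*presences)
            X = np.vstack([F_bg, F_p])
            pidx = np.arange(len(F_bg), len(X))
            model = fit_maxent(fs, X, pidx, beta=beta, max_iter=max_iter, tol=tol)
            return regularized_gain(model)
        except Exception as exc:  # refit failure → missing entry
            warnings.warn(f"jackknife refit failed for {subset}: {exc}", stacklevel=2)
            return float("nan")

    rows = []
    for name in names:
        rows.append(
            {
                "variable": name,
                "gain_only": _gain([name]),
                "gain_without": _gain([n for n in names if n != name]),
            }
        )
    return pd.DataFrame(rows)


def response_curve(
    model: MaxentModel, variable: str, n_points: int = 100
) -> pd.DataFrame:
    """Suitability response to one variable, others held at background
    means (continuous) or modal categories (categorical).

    Continuous variables sweep their background range; categorical ones
    return one row per category.
    """
    fs = model.feature_set
    if variable not in fs.variables:
        raise ConfigurationError(f"variable {variable!r} not in the model")
    col = fs.variables.index(variable)
    baseline = np.array(
        [
            fs.background_mode.get(n, 0) if n in fs.stack.categorical
            else fs.background_mean.get(n, 0.0)
            for n in fs.variables
        ],
        dtype=float,
    )
    if variable in fs.stack.categorical:
        cats = sorted(
            d.category for d in fs.descriptors
            if d.variable == variable and d.kind == "category"
        )
        V = np.tile(baseline, (len(cats), 1))
        V[:, col] = cats
        return pd.DataFrame({"value": cats,
                             "suitability": model.logistic_from_features(fs.transform(V))})
    bounds = [(d.lo, d.hi) for d in fs.descriptors
              if d.variable == variable and d.kind == "linear"]
    if bounds:
        lo, hi = bounds[0]
    else:
        lo = min((d.lo for d in fs.descriptors if d.variable == variable), default=0.0)
        hi = max((d.hi for d in fs.descriptors if d.variable == variable), default=1.0)
    values = np.linspace(lo, hi, n_points)
    V = np.tile(baseline, (n_points, 1))
    V[:, col] = values
    return pd.DataFrame({"value": values,
                         "suitability": model.logistic_from_features(fs.transform(V))})


def apply_threshold(
    prediction: Grid,
    threshold: float,
    validation_records: pd.DataFrame | None = None,
) -> tuple[RangeMask, float, float]:
    """Binarise a suitability surface at ``threshold``.

    Returns the suitable-area mask, the suitable fraction of valid
    cells, and the percentage of validation records falling in suitable
    cells (nan when no validation set is given).
    """
    vals = np.asarray(prediction.values, dtype=float)
    valid = prediction.mask
    suitable = valid & (vals >= threshold)
    fraction = float(suitable.sum() / valid.sum()) if valid.any() else float("nan")
    coverage = float("nan")
    if validation_records is not None and len(validation_records):
        rows, cols = prediction.cell_of(
            validation_records["lon"].to_numpy(), validation_records["lat"].to_numpy()
        )
        coverage = 100.0 * float(np.mean(suitable[rows, cols]))
    return RangeMask(grid=prediction.like(suitable), species_id="suitable"), fraction, coverage


def suitability_elevation_profile(
    prediction: Grid,
    elev: Grid,
    threshold: float,
    region_mask: np.ndarray | None = None,
    bin_width: float = 100.0,
) -> tuple[pd.DataFrame, float]:
    """Mean suitability per elevation bin, and the lower suitable-elevation
    boundary — the lowest bin whose mean suitability reaches the
    threshold (nan if none does).

    Empty bins are skipped; an empty region yields an empty profile.
    """
    prediction.require_aligned(elev, "prediction and elevation grids")
    valid = prediction.mask & elev.mask
    if region_mask is not None:
        valid = valid & region_mask
    if not valid.any():
        return pd.DataFrame(columns=["bin_low", "bin_high", "n_cells",
                                     "mean_suitability"]), float("nan")
    z = np.asarray(elev.values, dtype=float)[valid]
    s = np.asarray(prediction.values, dtype=float)[valid]
    lo = np.floor(z.min() / bin_width) * bin_width
    edges = np.arange(lo, z.max() + bin_width, bin_width)
    idx = np.clip(np.digitize(z, edges) - 1, 0, len(edges) - 1)
    rows = []
    boundary = float("nan")
    for b in range(len(edges)):
        sel = idx == b
        if not sel.any():
            continue
        mean_s = float(s[sel].mean())
        rows.append({"bin_low": edges[b], "bin_high": edges[b] + bin_width,
                     "n_cells": int(sel.sum()), "mean_suitability": mean_s})
        if np.isnan(boundary) and mean_s >= threshold:
            boundary = float(edges[b])
    return pd.DataFrame(rows), boundary
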