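"""Presence-background maximum-entropy modelling.

Fits the Gibbs distribution ``raw(x) = exp(Σ_j w_j f_j(x)) / Z`` over the
calibration cells (background sample plus training presences) that
minimises the L1-regularised objective

    L(w) = ln Z(w) − (1/m) Σ_presences η(x_i) + Σ_j λ_j |w_j|,

the negative mean log raw probability at the presences plus a per-feature
penalty λ_j = β·s_j/√m, where s_j is the feature's sample standard
deviation over the presences (floored at a small constant), m the
presence count and β the global regularization multiplier.  This is the
convex dual of maximum-entropy density estimation subject to relaxed
feature-expectation constraints: at the optimum every feature satisfies
|E_raw[f_j] − presence mean of f_j| ≤ λ_j.

The optimizer is cyclic coordinate descent with a per-coordinate Newton
step and soft-thresholding, safeguarded by backtracking on the true
objective, so the objective decreases monotonically.  Per-update
objective improvements are credited to the updated feature's source
variable, which is what the percent-contribution importance metric
consumes.

Features are built from the predictor stack: continuous variables are
rescaled to [0, 1] using background min/max and expand to linear,
quadratic and hinge features (hinge knots at background quantiles);
categorical variables expand to one indicator per category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .grid import ConfigurationError, Grid, PipelineError
from .terrain import PredictorStack

__all__ = [
    "FeatureDescriptor",
    "FeatureSet",
    "MaxentModel",
    "ReplicateMetrics",
    "ReplicateRun",
    "build_features",
    "default_feature_classes",
    "fit_maxent",
    "train_replicates",
    "regularized_gain",
    "predict_raw",
    "predict_logistic",
    "LAMBDA_STD_FLOOR",
]

#: Floor on the presence standard deviation entering the per-feature
#: penalty, so near-constant features still receive a nonzero penalty.
LAMBDA_STD_FLOOR = 1e-3


@dataclass
class FeatureDescriptor:
    variable: str
    kind: str  # linear | quadratic | hinge | product | category
    lo: float = 0.0
    hi: float = 1.0
    knot: float | None = None
    category: int | None = None
    partner: str | None = None  # second variable of a product feature
    constant: bool = False

    def label(self) -> str:
        if self.kind == "hinge":
            return f"hinge({self.variable}@{self.knot:g})"
        if self.kind == "category":
            return f"{self.variable}=={self.category}"
        if self.kind == "product":
            return f"{self.variable}*{self.partner}"
        return f"{self.kind}({self.variable})"


@dataclass
class FeatureSet:
    """Deterministic feature expansion over a predictor stack.

    Stores the descriptors plus the background statistics needed to
    evaluate features at arbitrary points (prediction, permutation
    importance, response curves).
    """

    stack: PredictorStack
    descriptors: list[FeatureDescriptor]
    background_mean: dict[str, float]
    background_mode: dict[str, int]

    @property
    def variables(self) -> list[str]:
        return self.stack.names

    @property
    def n_features(self) -> int:
        return len(self.descriptors)

    @property
    def feature_variables(self) -> list[str]:
        return [d.variable for d in self.descriptors]

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Feature matrix for a (n_points, n_variables) value matrix in
        ``self.variables`` order.  Continuous features are clamped to the
        background [0, 1] training range."""
        values = np.asarray(values, dtype=float)
        col = {name: i for i, name in enumerate(self.variables)}
        out = np.empty((values.shape[0], self.n_features))
        for j, d in enumerate(self.descriptors):
            v = values[:, col[d.variable]]
            if d.kind == "linear":
                f = (v - d.lo) / (d.hi - d.lo) if d.hi > d.lo else np.zeros_like(v)
            elif d.kind == "quadratic":
                f = (v * v - d.lo) / (d.hi - d.lo) if d.hi > d.lo else np.zeros_like(v)
            elif d.kind == "hinge":
                f = (v - d.knot) / (d.hi - d.knot)
                f = np.maximum(f, 0.0)
            elif d.kind == "category":
                f = (v == d.category).astype(float)
            elif d.kind == "product":
                v2 = values[:, col[d.partner]]
                a = (v - d.lo) / (d.hi - d.lo) if d.hi > d.lo else np.zeros_like(v)
                lo2, hi2 = d.knot, d.category  # reuse slots for partner bounds
                b = (v2 - lo2) / (hi2 - lo2) if hi2 > lo2 else np.zeros_like(v2)
                f = np.clip(a, 0, 1) * np.clip(b, 0, 1)
            else:  # pragma: no cover
                raise ConfigurationError(f"unknown feature kind {d.kind!r}")
            if d.kind in {"linear", "quadratic", "hinge"}:
                f = np.clip(f, 0.0, 1.0)
            out[:, j] = f
        return out

    def at_cells(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return self.transform(self.stack.sample(rows, cols))


def default_feature_classes(n_presences: int) -> set[str]:
    """Feature classes enabled by presence sample size: linear + quadratic
    always, hinge added from 15 presences up."""
    if n_presences >= 15:
        return {"linear", "quadratic", "hinge"}
    return {"linear", "quadratic"}


def build_features(
    stack: PredictorStack,
    background: tuple[np.ndarray, np.ndarray],
    presences: tuple[np.ndarray, np.ndarray] | None = None,
    classes: set[str] | None = None,
    hinge_knots: int = 20,
) -> FeatureSet:
    """Expand the stack's variables into model features.

    Scaling bounds and hinge knots come from the background sample;
    categorical category lists come from background plus presences.  A
    categorical variable with a single observed category is dropped with
    a warning.
    """
    classes = classes or {"linear", "quadratic", "hinge"}
    bg_vals = stack.sample(*background)
    pres_vals = stack.sample(*presences) if presences is not None else None
    descriptors: list[FeatureDescriptor] = []
    bg_mean: dict[str, float] = {}
    bg_mode: dict[str, int] = {}
    lin_bounds: dict[str, tuple[float, float]] = {}
    for i, name in enumerate(stack.names):
        v = bg_vals[:, i]
        ok = np.isfinite(v)
        if name in stack.categorical:
            cats = set(np.unique(v[ok]).astype(int).tolist())
            if pres_vals is not None:
                pv = pres_vals[:, i]
                cats |= set(np.unique(pv[np.isfinite(pv)]).astype(int).tolist())
            cats = sorted(cats)
            vals, counts = np.unique(v[ok].astype(int), return_counts=True)
            bg_mode[name] = int(vals[np.argmax(counts)]) if len(vals) else 0
            if len(cats) < 2:
                warnings.warn(f"categorical {name!r} has a single category; dropped",
                              stacklevel=2)
                continue
            for c in cats:
                descriptors.append(FeatureDescriptor(variable=name, kind="category",
                                                     category=int(c)))
            continue
        lo, hi = float(np.min(v[ok])), float(np.max(v[ok]))
        bg_mean[name] = float(np.mean(v[ok]))
        lin_bounds[name] = (lo, hi)
        constant = not hi > lo
        if "linear" in classes:
            descriptors.append(
                FeatureDescriptor(variable=name, kind="linear", lo=lo, hi=hi,
                                  constant=constant)
            )
        if "quadratic" in classes:
            sq = v[ok] ** 2
            lo2, hi2 = float(sq.min()), float(sq.max())
            descriptors.append(
                FeatureDescriptor(variable=name, kind="quadratic", lo=lo2, hi=hi2,
                                  constant=not hi2 > lo2)
            )
        if "hinge" in classes and not constant:
            qs = np.quantile(v[ok], np.arange(1, hinge_knots + 1) / (hinge_knots + 1))
            for knot in sorted(set(float(q) for q in qs)):
                if hi > knot:
                    descriptors.append(
                        FeatureDescriptor(variable=name, kind="hinge", lo=lo, hi=hi,
                                          knot=knot)
                    )
    if "product" in classes:
        cont = [n for n in stack.names if n in lin_bounds]
        for i, a in enumerate(cont):
            for b in cont[i + 1:]:
                (lo_a, hi_a), (lo_b, hi_b) = lin_bounds[a], lin_bounds[b]
                if hi_a > lo_a and hi_b > lo_b:
                    descriptors.append(
                        FeatureDescriptor(variable=a, kind="product", lo=lo_a, hi=hi_a,
                                          knot=lo_b, category=hi_b, partner=b)
                    )
    return FeatureSet(stack=stack, descriptors=descriptors,
                      background_mean=bg_mean, background_mode=bg_mode)


@dataclass
class MaxentModel:
    """A fitted maximum-entropy model.

    ``log_z`` normalises over the calibration support used at fit time,
    so ``raw`` values are probabilities on that support (they sum to 1
    there); ``entropy`` is the Shannon entropy of the fitted raw
    distribution, which parameterises the logistic transform.
    """

    feature_set: FeatureSet | None
    coefs: np.ndarray
    lambdas: np.ndarray
    beta: float
    log_z: float
    entropy: float
    objective: float
    n_support: int
    converged: bool
    n_iter: int
    contribution: dict[str, float] = field(default_factory=dict)
    presence_mean: np.ndarray | None = None
    warning: str | None = None

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefs))

    # -- prediction -------------------------------------------------------
    def raw_from_features(self, F: np.ndarray) -> np.ndarray:
        return np.exp(F @ self.coefs - self.log_z)

    def logistic_from_features(self, F: np.ndarray) -> np.ndarray:
        r = self.raw_from_features(F) * np.exp(self.entropy)
        return r / (1.0 + r)

    def predict_cells(self, rows: np.ndarray, cols: np.ndarray,
                      output: str = "raw") -> np.ndarray:
        F = self.feature_set.at_cells(rows, cols)
        if output == "raw":
            return self.raw_from_features(F)
        if output == "logistic":
            return self.logistic_from_features(F)
        raise ConfigurationError("output must be 'raw' or 'logistic'")

    def predict_grid(self, output: str = "raw",
                     within: np.ndarray | None = None) -> Grid:
        """Suitability surface over the stack's valid cells (optionally
        restricted to a boolean ``within`` mask); other cells are nodata."""
        stack = self.feature_set.stack
        valid = stack.mask
        if within is not None:
            valid = valid & within
        rows, cols = np.nonzero(valid)
        out = np.full(stack.reference.shape, np.nan)
        if len(rows):
            out[rows, cols] = self.predict_cells(rows, cols, output=output)
        return stack.reference.like(out)

    # -- serialization ----------------------------------------------------
    def to_text(self, path: str | Path) -> None:
        lines = [
            f"# oroniche maxent model",
            f"beta\t{float(self.beta)!r}",
            f"log_z\t{float(self.log_z)!r}",
            f"entropy\t{float(self.entropy)!r}",
            f"objective\t{float(self.objective)!r}",
            f"n_support\t{self.n_support}",
            f"converged\t{int(self.converged)}",
            "# variable\tkind\tlo\thi\tknot\tcategory\tpartner\tcoef\tlambda",
        ]
        for d, w, lam in zip(self.feature_set.descriptors, self.coefs, self.lambdas):
            lines.append(
                "\t".join(
                    [d.variable, d.kind, repr(d.lo), repr(d.hi),
                     repr(d.knot), repr(d.category), str(d.partner), repr(float(w)),
                     repr(float(lam))]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n")


def load_model(path: str | Path, stack: PredictorStack) -> MaxentModel:
    """Load a coefficient file saved by :meth:`MaxentModel.to_text`,
    re-attaching it to a predictor stack for prediction.

    Background means/modes are not stored in the file, so response
    curves are unavailable on a loaded model; prediction is exact.
    """
    lines = [ln for ln in Path(path).read_text().splitlines()
             if ln and not ln.startswith("#")]
    header: dict[str, str] = {}
    rows: list[list[str]] = []
    for ln in lines:
        parts = ln.split("\t")
        if len(parts) == 2:
            header[parts[0]] = parts[1]
        else:
            rows.append(parts)
    descriptors, coefs, lams = [], [], []

    def _opt(tok: str):
        return None if tok == "None" else float(tok)

    for parts in rows:
        var, kind, lo, hi, knot, cat, partner, coef, lam = parts
        c = _opt(cat)
        descriptors.append(FeatureDescriptor(
            variable=var, kind=kind, lo=float(lo), hi=float(hi),
            knot=_opt(knot), category=c if kind == "product" or c is None else int(c),
            partner=None if partner == "None" else partner,
        ))
        coefs.append(float(coef))
        lams.append(float(lam))
    fs = FeatureSet(stack=stack, descriptors=descriptors,
                    background_mean={}, background_mode={})
    return MaxentModel(
        feature_set=fs, coefs=np.array(coefs), lambdas=np.array(lams),
        beta=float(header["beta"]), log_z=float(header["log_z"]),
        entropy=float(header["entropy"]), objective=float(header["objective"]),
        n_support=int(header["n_support"]), converged=bool(int(header["converged"])),
        n_iter=0,
    )


def _soft(z: float, lam: float) -> float:
    if z > lam:
        return z - lam
    if z < -lam:
        return z + lam
    return 0.0


def fit_maxent(
    features: FeatureSet | None,
    X: np.ndarray,
    presence_idx: np.ndarray,
    beta: float = 1.0,
    max_iter: int = 5000,
    tol: float = 1e-7,
    lambda_floor: float = LAMBDA_STD_FLOOR,
) -> MaxentModel:
    """Fit the regularised maxent objective on an explicit support.

    Parameters
    ----------
    features
        The FeatureSet that produced ``X`` (may be None for bare-matrix
        fits, e.g. oracle comparisons).
    X
        (n_support, n_features) feature matrix over the calibration
        support — background cells plus training presence cells.
    presence_idx
        Row indices of the presences within ``X``.
    beta
        Global regularization multiplier scaling every per-feature
        penalty.
    max_iter
        Maximum number of full coordinate cycles.
    tol
        Convergence: stop when a full cycle improves the objective by
        less than this.
    """
    X = np.asarray(X, dtype=float)
    presence_idx = np.asarray(presence_idx, dtype=int)
    N, J = X.shape
    m = len(presence_idx)
    if m < 2:
        raise PipelineError("maxent fit requires at least 2 presences")
    if N == 0 or N == m:
        raise PipelineError("maxent fit requires a non-empty background")
    if beta < 0:
        raise ConfigurationError("beta must be >= 0")
    Xp = X[presence_idx]
    pbar = Xp.mean(axis=0)
    s = Xp.std(axis=0, ddof=0)
    lam = beta * np.maximum(s, lambda_floor) / np.sqrt(m)
    constant = np.ptp(X, axis=0) == 0

    feature_vars = (features.feature_variables if features is not None
                    else [f"f{j}" for j in range(J)])
    w = np.zeros(J)
    eta = np.zeros(N)
    pw = 0.0  # pbar @ w
    pen = 0.0  # lam @ |w|
    obj = float(np.log(N))  # logsumexp(0) = ln N
    contribution: dict[str, float] = {v: 0.0 for v in feature_vars}
    converged = False
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        obj_start = obj
        for j in range(J):
            if constant[j]:
                continue
            xj = X[:, j]
            mx = eta.max()
            e = np.exp(eta - mx)
            Z = e.sum()
            raw = e / Z
            Ej = float(raw @ xj)
            g = Ej - pbar[j]
            H = float(raw @ (xj * xj)) - Ej * Ej
            H = max(H, 1e-12)
            z = H * w[j] - g
            w_new = _soft(z, lam[j]) / H
            d = w_new - w[j]
            if d == 0.0:
                continue
            # backtracking line search on the true objective
            accepted = False
            step = 1.0
            for _ in range(40):
                wj_trial = w[j] + step * d
                eta_trial = eta + (wj_trial - w[j]) * xj
                f_trial = (
                    float(logsumexp(eta_trial))
                    - (pw + pbar[j] * (wj_trial - w[j]))
                    + (pen - lam[j] * abs(w[j]) + lam[j] * abs(wj_trial))
                )
                if f_trial <= obj - 1e-15:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                continue
            contribution[feature_vars[j]] += obj - f_trial
            pw += pbar[j] * (wj_trial - w[j])
            pen += lam[j] * (abs(wj_trial) - abs(w[j]))
            eta = eta_trial
            w[j] = wj_trial
            obj = f_trial
        if obj_start - obj < tol:
            converged = True
            break
    warning = None if converged else "maxent fit did not converge within max_iter"
    if warning:
        warnings.warn(warning, stacklevel=2)
    log_z = float(logsumexp(eta))
    raw = np.exp(eta - log_z)
    nz = raw > 0
    entropy = float(-(raw[nz] * np.log(raw[nz])).sum())
    return MaxentModel(
        feature_set=features,
        coefs=w,
        lambdas=lam,
        beta=beta,
        log_z=log_z,
        entropy=entropy,
        objective=obj,
        n_support=N,
        converged=converged,
        n_iter=n_iter,
        contribution=contribution,
        presence_mean=pbar,
        warning=warning,
    )


def regularized_gain(model: MaxentModel) -> float:
    """Regularised training gain: ln(n_support) − objective.

    Equals the mean log raw probability at the presences relative to the
    uniform distribution, minus the regularization penalty; the uniform
    (all-zero coefficient) model has gain exactly 0.
    """
    return float(np.log(model.n_support) - model.objective)


def predict_raw(model: MaxentModel, within: np.ndarray | None = None) -> Grid:
    """Raw suitability surface (normalised over the calibration support)."""
    return model.predict_grid(output="raw", within=within)


def predict_logistic(model: MaxentModel, within: np.ndarray | None = None) -> Grid:
    """Logistic suitability: raw·e^H / (1 + raw·e^H) ∈ (0, 1)."""
    return model.predict_grid(output="logistic", within=within)


# -- replicated training --------------------------------------------------

@dataclass
class ReplicateMetrics:
    """The five per-replicate evaluation metrics used for representative-
    replicate selection."""

    reg_training_gain: float
    test_gain: float
    test_auc: float
    ten_pct_threshold: float
    ten_pct_area: float

    def as_array(self) -> np.ndarray:
        return np.array([self.reg_training_gain, self.test_gain, self.test_auc,
                         self.ten_pct_threshold, self.ten_pct_area])

    NAMES = ("reg_training_gain", "test_gain", "test_auc",
             "ten_pct_threshold", "ten_pct_area")


@dataclass
class ReplicateRun:
    replicate_id: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    model: MaxentModel
    metrics: ReplicateMetrics


def train_replicates(
    features: FeatureSet,
    presences: tuple[np.ndarray, np.ndarray],
    background: tuple[np.ndarray, np.ndarray],
    beta: float = 1.0,
    n_replicates: int = 50,
    test_fraction: float = 0.25,
    seed: int = 0,
    max_iter: int = 5000,
    tol: float = 1e-7,
) -> list[ReplicateRun]:
    """Train ``n_replicates`` models on independent seeded train/test
    splits of the presences (default 25% held out per replicate).

    Each replicate's support is the background cells plus its training
    presences; metrics are computed against the shared background draw.
    """
    from .evaluate import auc  # local import: evaluate has no maxent dependency

    p_rows, p_cols = presences
    m = len(p_rows)
    n_test = int(round(test_fraction * m))
    n_train = m - n_test
    if n_test < 1 or n_train < 2:
        raise PipelineError(
            f"too few presences ({m}) for a {test_fraction:.0%} test split; "
            f"need at least {int(np.ceil(1 / test_fraction)) + 2}"
        )
    F_pres = features.at_cells(p_rows, p_cols)
    F_bg = features.at_cells(*background)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_replicates)
    runs: list[ReplicateRun] = []
    for rep in range(n_replicates):
        rng = np.random.default_rng(children[rep])
        test_idx = np.sort(rng.choice(m, size=n_test, replace=False))
        train_idx = np.setdiff1d(np.arange(m), test_idx)
        X = np.vstack([F_bg, F_pres[train_idx]])
        pidx = np.arange(len(F_bg), len(F_bg) + len(train_idx))
        model = fit_maxent(features, X, pidx, beta=beta, max_iter=max_iter, tol=tol)
        raw_bg = model.raw_from_features(F_bg)
        raw_test = model.raw_from_features(F_pres[test_idx])
        logistic_train = model.logistic_from_features(F_pres[train_idx])
        logistic_support = model.logistic_from_features(X)
        thr10 = float(np.percentile(logistic_train, 10))
        area10 = float(np.mean(logistic_support >= thr10))
        with np.errstate(divide="ignore"):
            test_gain = float(np.mean(np.log(raw_test)) + np.log(model.n_support))
        metrics = ReplicateMetrics(
            reg_training_gain=regularized_gain(model),
            test_gain=test_gain,
            test_auc=auc(raw_test, raw_bg),
            ten_pct_threshold=thr10,
            ten_pct_area=area10,
        )
        runs.append(ReplicateRun(rep, train_idx, test_idx, model, metrics))
    return runs
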