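"""End-to-end broad-scale and fine-scale modelling pipelines.

A run chains: record filtering → homogenisation → spatial thinning →
bias grid → calibration area → background sampling → correlation screen
→ candidate-model grid (variable sets × regularization multipliers) →
replicated maxent fits → evaluator suite → rank-sum selection →
binarisation threshold → importance tables → suitability–elevation
profile, producing a :class:`RunReport` whose tables serialise to CSV.

Every source of randomness derives from one master seed through a fixed
stage-key scheme, so a full run is a pure function of (inputs, config,
master seed) and report tables are byte-identical across reruns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate, maxent, prep
from .grid import ConfigurationError, Grid, PipelineError
from .terrain import PredictorStack, variable_group

__all__ = ["RunConfig", "RunReport", "run_broad_scale", "run_fine_scale",
           "stage_seed", "BROAD_MENU", "FINE_MENU"]

BROAD_MENU = ["ABR", "ELEV", "B4", "B8", "B10", "B12", "B15", "B17", "LAND"]
FINE_MENU = ["ELEV", "SLO", "ORI", "DIS-ROCK", "DIS-FOREST", "DIS-URBAN"]

# A-priori ecological priority for the correlation screen: when two
# predictors exceed the cutoff, the one earlier in this list survives.
# Local relief and summer temperature outrank the variables that merely
# track the elevation gradient (elevation itself, wettest-quarter
# temperature, the precipitation surfaces).
DEFAULT_PRIORITY = {
    "broad": ["ABR", "B10", "B4", "B12", "B15", "B17", "ELEV", "B8", "LAND"],
    "fine": ["DIS-ROCK", "SLO", "ELEV", "ORI", "DIS-FOREST", "DIS-URBAN"],
}

# Fixed stage keys: stage_seed(master, stage[, index]) feeds a
# SeedSequence with (master, key[, index]), so adding stages never
# perturbs existing ones.
_STAGE_KEYS = {
    "homogenize_source": 1,
    "homogenize_region": 2,
    "thin": 3,
    "background": 4,
    "replicates": 5,
    "permutation": 6,
}


def stage_seed(master: int, stage: str, index: int = 0) -> int:
    key = _STAGE_KEYS[stage]
    ss = np.random.SeedSequence((int(master), key, int(index)))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Configuration of a full modelling run.

    The scale profile fixes the defaults of its stage chain (broad:
    1 km-analogue cells, 10 km thinning, 500 km calibration buffer, bias
    grid; fine: 100 m cells, one-record-per-cell thinning, no climate
    variables); every default is overridable.
    """

    scale: str = "broad"
    variables: list[str] | None = None  # None → scale menu ∩ stack
    candidate_sets: list[list[str]] | None = None  # None → group unions
    beta_grid: tuple[float, ...] = (0.5, 1.0, 2.0)
    n_replicates: int = 50
    test_fraction: float = 0.25
    n_background: int = 10_000
    require_verified: bool = True
    max_uncertainty: float = 1000.0
    homogenize: bool = True
    homogenize_ratio: float = 1.5
    thin_distance: float = 10_000.0
    buffer_radius: float | None = 500_000.0  # None → whole valid grid
    bias_weights: dict[int, float] | None = None
    correlation_cutoff: float = 0.65
    priority: list[str] | None = None
    feature_classes: set[str] | None = None  # None → by presence count
    hinge_knots: int = 20
    max_iter: int = 5000
    tol: float = 1e-7
    mpa_inclusion: float = 1.0
    pca_variance_cutoff: float = 0.95
    profile_bin_width: float = 100.0
    seed: int = 0

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        data = tomllib.loads(Path(path).read_text())
        kwargs = {}
        for f in cls.__dataclass_fields__:
            if f in data:
                kwargs[f] = data[f]
        if "beta_grid" in kwargs:
            kwargs["beta_grid"] = tuple(kwargs["beta_grid"])
        if "feature_classes" in kwargs and kwargs["feature_classes"] is not None:
            kwargs["feature_classes"] = set(kwargs["feature_classes"])
        if "bias_weights" in kwargs and kwargs["bias_weights"] is not None:
            kwargs["bias_weights"] = {int(k): float(v)
                                      for k, v in kwargs["bias_weights"].items()}
        return cls(**kwargs)


@dataclass
class RunReport:
    """All numbers a run produces, each traceable to a logged stage."""

    scale: str
    seed: int
    counts: dict[str, int]
    screen_log: pd.DataFrame
    candidate_table: pd.DataFrame
    best: evaluate.CandidateResult
    threshold: float
    suitable_fraction: float
    validation_coverage_pct: float
    importance: pd.DataFrame
    profile: pd.DataFrame
    lower_boundary: float
    prediction: Grid
    suitable_mask: Grid
    stages: list[str] = field(default_factory=list)

    def best_summary(self) -> dict:
        return {
            "variables": list(self.best.variables),
            "beta": self.best.beta,
            "auc_test": self.best.auc_test,
            "aicc": self.best.aicc,
            "mpa": self.best.mpa,
            "threshold_max_sss": self.threshold,
            "suitable_fraction": self.suitable_fraction,
            "validation_coverage_pct": self.validation_coverage_pct,
            "lower_suitable_elevation": self.lower_boundary,
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.10g"
        self.candidate_table.to_csv(out / "candidates.csv", index=False,
                                    float_format=fmt)
        self.importance.to_csv(out / "importance.csv", index=False, float_format=fmt)
        self.profile.to_csv(out / "profile.csv", index=False, float_format=fmt)
        self.screen_log.to_csv(out / "screen_log.csv", index=False, float_format=fmt)
        summary = {"scale": self.scale, "seed": self.seed, "counts": self.counts,
                   "best": self.best_summary()}
        (out / "report.json").write_text(json.dumps(summary, indent=2,
                                                    default=_json_default))
        self.prediction.write_ascii(out / "prediction.asc")
        self.suitable_mask.write_ascii(out / "suitable_mask.asc")
        if self.best.model is not None:
            self.best.model.to_text(out / "best_model.txt")
        (out / "run_log.txt").write_text("\n".join(self.stages) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return None if np.isnan(o) else float(o)
    if isinstance(o, float) and np.isnan(o):
        return None
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _enumerate_candidate_sets(variables: list[str]) -> list[list[str]]:
    """Default candidate grid: every non-empty union of the variable-type
    groups (climatic / topographic / habitat) present in the menu."""
    from itertools import combinations

    groups: dict[str, list[str]] = {}
    for v in variables:
        groups.setdefault(variable_group(v), []).append(v)
    names = sorted(groups)
    sets = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            sets.append([v for v in variables if variable_group(v) in combo])
    return sets


def _stage(stages: list[str], name: str, fn, *args, **kwargs):
    try:
        result = fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    stages.append(name)
    return result


def _run(
    stack: PredictorStack,
    records: pd.DataFrame,
    cfg: RunConfig,
    elev: Grid | None,
    regions: Grid | None,
    validation_records: pd.DataFrame | None,
) -> RunReport:
    stages: list[str] = []
    counts: dict[str, int] = {"input_records": len(records)}
    menu = cfg.variables or [v for v in (BROAD_MENU if cfg.scale == "broad" else FINE_MENU)
                             if v in stack.names]
    if cfg.scale == "fine":
        climatic = [v for v in menu if variable_group(v) == "climatic"]
        if climatic:
            raise ConfigurationError(
                f"climatic variables {climatic} are not allowed at the fine scale: "
                "they are collinear with elevation at 100 m resolution"
            )
    missing = [v for v in menu if v not in stack.names]
    if missing:
        raise ConfigurationError(f"variables missing from the stack: {missing}")
    stack = stack.subset(menu)
    reference = stack.reference
    if elev is None and "ELEV" in stack.names:
        elev = stack.grids["ELEV"]

    # -- occurrence preparation ------------------------------------------
    filtered, filter_report = _stage(
        stages, "filter", prep.filter_records, records,
        require_verified=cfg.require_verified, max_uncertainty=cfg.max_uncertainty,
    )
    counts.update({f"filter_{k}": v for k, v in filter_report.items()})
    if cfg.homogenize:
        filtered = _stage(stages, "homogenize_source", prep.homogenize_strata,
                          filtered, "source_type", cfg.homogenize_ratio,
                          stage_seed(cfg.seed, "homogenize_source"))
        if filtered["region"].astype(str).nunique() > 1:
            filtered = _stage(stages, "homogenize_region", prep.homogenize_strata,
                              filtered, "region", cfg.homogenize_ratio,
                              stage_seed(cfg.seed, "homogenize_region"))
        counts["after_homogenize"] = len(filtered)
    if cfg.scale == "broad":
        thinned = _stage(stages, "thin_spatial", prep.thin_spatial, filtered,
                         cfg.thin_distance, stage_seed(cfg.seed, "thin"),
                         reference.geographic)
    else:
        thinned = _stage(stages, "thin_one_per_cell", prep.thin_one_per_cell,
                         filtered, reference, stage_seed(cfg.seed, "thin"))
    counts["after_thinning"] = len(thinned)

    # -- calibration area, bias, background ------------------------------
    if cfg.buffer_radius is not None:
        calibration = _stage(stages, "calibration_area", prep.calibration_area,
                             thinned, reference, cfg.buffer_radius)
    else:
        calibration = reference.like(np.ones(reference.shape, dtype=bool))
        stages.append("calibration_area(full-extent)")
    bias = None
    if cfg.bias_weights is not None:
        if regions is None:
            raise ConfigurationError("bias_weights given but no regions grid")
        bias = _stage(stages, "bias_grid", prep.build_bias_grid, regions,
                      cfg.bias_weights)
    bg_rows, bg_cols = _stage(
        stages, "background", prep.sample_background, cfg.n_background,
        calibration, bias, stack.mask, stage_seed(cfg.seed, "background"),
    )
    counts["background_points"] = len(bg_rows)

    # -- correlation screen ----------------------------------------------
    default_priority = [v for v in DEFAULT_PRIORITY[cfg.scale] if v in menu]
    default_priority += [v for v in menu if v not in default_priority]
    stack, screen_log = _stage(stages, "correlation_screen", prep.correlation_screen,
                               stack, (bg_rows, bg_cols), cfg.correlation_cutoff,
                               cfg.priority or default_priority)
    screen_df = pd.DataFrame(screen_log, columns=["dropped", "kept", "rho", "reason"])
    counts["surviving_variables"] = len(stack.names)

    # -- candidate grid ---------------------------------------------------
    p_rows, p_cols = reference.cell_of(thinned["lon"].to_numpy(),
                                       thinned["lat"].to_numpy())
    on_valid = stack.mask[p_rows, p_cols]
    p_rows, p_cols = p_rows[on_valid], p_cols[on_valid]
    counts["presences_on_valid_cells"] = len(p_rows)
    if len(p_rows) < 4:
        raise PipelineError("stage 'presences' failed: too few presences on valid cells")
    candidate_sets = cfg.candidate_sets or _enumerate_candidate_sets(stack.names)
    candidate_sets = [[v for v in s if v in stack.names] for s in candidate_sets]
    candidate_sets = [s for s in candidate_sets if s]
    counts["candidate_models"] = len(candidate_sets) * len(cfg.beta_grid)
    m = len(p_rows)
    classes = cfg.feature_classes or maxent.default_feature_classes(m)
    cal_valid = np.asarray(calibration.values, dtype=bool) & stack.mask
    cal_rows, cal_cols = np.nonzero(cal_valid)

    candidates: list[evaluate.CandidateResult] = []
    cand_index = 0
    for var_set in candidate_sets:
        sub = stack.subset(var_set)
        fs = maxent.build_features(sub, (bg_rows, bg_cols), (p_rows, p_cols),
                                   classes=classes, hinge_knots=cfg.hinge_knots)
        for beta in cfg.beta_grid:
            runs = maxent.train_replicates(
                fs, (p_rows, p_cols), (bg_rows, bg_cols), beta=beta,
                n_replicates=cfg.n_replicates, test_fraction=cfg.test_fraction,
                seed=stage_seed(cfg.seed, "replicates", cand_index),
                max_iter=cfg.max_iter, tol=cfg.tol,
            )
            metric_matrix = np.array([r.metrics.as_array() for r in runs])
            rep_id = evaluate.select_representative_replicate(
                metric_matrix, cfg.pca_variance_cutoff)
            # refit on all presences for AICc / MPA / maps
            F_bg = fs.at_cells(bg_rows, bg_cols)
            F_p = fs.at_cells(p_rows, p_cols)
            X = np.vstack([F_bg, F_p])
            pidx = np.arange(len(F_bg), len(X))
            model = maxent.fit_maxent(fs, X, pidx, beta=beta,
                                      max_iter=cfg.max_iter, tol=cfg.tol)
            raw_pres = model.raw_from_features(F_p)
            aicc_val, aicc_reason = evaluate.aicc(raw_pres, model.n_nonzero)
            raw_cal = model.predict_cells(cal_rows, cal_cols, output="raw")
            mpa_val = evaluate.mpa(raw_cal, raw_pres, inclusion=cfg.mpa_inclusion)
            contribs = [evaluate.percent_contribution(r.model.contribution)
                        for r in runs]
            mean_contrib = {v: float(np.mean([c[v] for c in contribs]))
                            for v in fs.variables}
            candidates.append(evaluate.CandidateResult(
                variables=list(var_set), beta=beta,
                auc_test=float(np.mean([r.metrics.test_auc for r in runs])),
                aicc=aicc_val, mpa=mpa_val, representative_id=rep_id,
                aicc_reason=aicc_reason,
                group="+".join(sorted({variable_group(v) for v in var_set})),
                model=model, replicates=runs, contribution=mean_contrib,
            ))
            cand_index += 1
    stages.append("candidates")
    ranked = evaluate.rank_candidates(candidates)
    best = ranked[0]
    stages.append("selection")
    candidate_table = pd.DataFrame([
        {
            "model": c.label, "group": c.group, "beta": c.beta,
            "auc_test": c.auc_test, "aicc": c.aicc, "mpa": c.mpa,
            "rank_sum": c.rank_sum, "representative_replicate": c.representative_id,
            "aicc_missing_reason": c.aicc_reason or "",
            "contribution_rank": " > ".join(sorted(
                c.contribution, key=lambda v: -c.contribution[v])),
        }
        for c in ranked
    ])

    # -- best-model outputs ----------------------------------------------
    best_fs = best.model.feature_set
    F_p_best = best_fs.at_cells(p_rows, p_cols)
    F_bg_best = best_fs.at_cells(bg_rows, bg_cols)
    logistic_pres = best.model.logistic_from_features(F_p_best)
    logistic_bg = best.model.logistic_from_features(F_bg_best)
    threshold = evaluate.threshold_max_sss(logistic_pres, logistic_bg)
    prediction = best.model.predict_grid(output="logistic", within=cal_valid)
    val = validation_records if validation_records is not None else thinned
    suitable_mask, suitable_fraction, coverage = evaluate.apply_threshold(
        prediction, threshold, val)
    stages.append("threshold")

    # importance: averaged contribution + permutation + jackknife
    all_rows = np.concatenate([p_rows, bg_rows])
    all_cols = np.concatenate([p_cols, bg_cols])
    V = best_fs.stack.sample(all_rows, all_cols)
    perm = evaluate.permutation_importance(
        best.model, V, np.arange(len(p_rows)),
        seed=stage_seed(cfg.seed, "permutation"))
    if len(best.variables) >= 2:
        jack = evaluate.jackknife_gains(
            best_fs.stack, (p_rows, p_cols), (bg_rows, bg_cols), beta=best.beta,
            classes=classes, hinge_knots=cfg.hinge_knots,
            max_iter=cfg.max_iter, tol=cfg.tol)
    else:
        jack = pd.DataFrame({"variable": best.variables,
                             "gain_only": [np.nan], "gain_without": [np.nan]})
    importance = pd.DataFrame({
        "variable": list(best.contribution),
        "percent_contribution": [best.contribution[v] for v in best.contribution],
        "permutation_importance": [perm.get(v, 0.0) for v in best.contribution],
    }).merge(jack, on="variable", how="left")
    importance = importance.sort_values(
        "percent_contribution", ascending=False).reset_index(drop=True)
    stages.append("importance")

    if elev is not None:
        profile, boundary = evaluate.suitability_elevation_profile(
            prediction, elev, threshold, bin_width=cfg.profile_bin_width)
    else:
        profile, boundary = pd.DataFrame(), float("nan")
    stages.append("profile")

    return RunReport(
        scale=cfg.scale, seed=cfg.seed, counts=counts, screen_log=screen_df,
        candidate_table=candidate_table, best=best, threshold=float(threshold),
        suitable_fraction=float(suitable_fraction),
        validation_coverage_pct=float(coverage), importance=importance,
        profile=profile, lower_boundary=boundary, prediction=prediction,
        suitable_mask=suitable_mask.grid, stages=stages,
    )


def run_broad_scale(
    stack: PredictorStack,
    records: pd.DataFrame,
    cfg: RunConfig | None = None,
    elev: Grid | None = None,
    regions: Grid | None = None,
    validation_records: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> RunReport:
    """Run the broad-scale chain (filter → thin 10 km → bias → 500 km
    calibration buffer → screen → candidates → selection → maps)."""
    cfg = cfg or RunConfig(scale="broad")
    if cfg.scale != "broad":
        raise ConfigurationError("run_broad_scale requires cfg.scale == 'broad'")
    report = _run(stack, records, cfg, elev, regions, validation_records)
    if out_dir is not None:
        report.write(out_dir)
    return report


def run_fine_scale(
    stack: PredictorStack,
    records: pd.DataFrame,
    cfg: RunConfig | None = None,
    elev: Grid | None = None,
    validation_records: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> RunReport:
    """Run the fine-scale chain (one-record-per-cell thinning, topographic
    and distance-to-habitat predictors only)."""
    cfg = cfg or RunConfig(scale="fine", buffer_radius=None)
    if cfg.scale != "fine":
        raise ConfigurationError("run_fine_scale requires cfg.scale == 'fine'")
    report = _run(stack, records, cfg, elev, None, validation_records)
    if out_dir is not None:
        report.write(out_dir)
    return report
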