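"""Model evaluation statistics and stepwise selection.

Covers the evaluation side of presence-background modeling: rank-based AUC,
the 10% training-omission rule, leave-one-out (jackknife) cross-validation,
sample-size-corrected AIC over the standardized raw distribution, the
feature-class x regularization-multiplier candidate grid, and a three-step
stepwise selection (omission rate, then AUC difference, then AICc).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import maxent
from .maxent import FeatureExpansion, MaxentModel, ModelConfig

log = logging.getLogger(__name__)

__all__ = [
    "EvalSummary",
    "GridResult",
    "auc",
    "omission_threshold_10p",
    "omission_rate_10p",
    "jackknife_cv",
    "aicc",
    "aicc_for_model",
    "run_grid",
    "stepwise_select",
    "DEFAULT_FEATURE_CLASSES",
    "DEFAULT_MULTIPLIERS",
]

DEFAULT_FEATURE_CLASSES = ("L", "H", "LQ", "LQH")
DEFAULT_MULTIPLIERS = (0.5, 1.0, 2.0, 5.0)


def auc(presence_scores, background_scores) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted one half.

    The probability that a random presence outscores a random background
    point.  All-identical scores give 0.5 by the tie rule.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score sets must be nonempty")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2
    return float(u / (p.size * b.size))


def omission_threshold_10p(train_scores) -> float:
    """Smallest training score with at least 90% of training scores >= it.

    Drops the lowest floor(0.1 n) training scores; the next score up is the
    threshold.  With fewer than 10 training scores the minimum is used (and
    a warning logged) since no score can be dropped.
    """
    s = np.sort(np.asarray(train_scores, dtype=float))
    n = s.size
    if n == 0:
        raise ValueError("empty training scores")
    if n < 10:
        log.warning("omission threshold: fewer than 10 training scores, using the minimum")
        return float(s[0])
    return float(s[math.floor(0.1 * n)])


def omission_rate_10p(train_scores, test_scores) -> float:
    """Fraction of test scores strictly below the 10% training threshold."""
    t = omission_threshold_10p(train_scores)
    test = np.asarray(test_scores, dtype=float)
    if test.size == 0:
        raise ValueError("empty test scores")
    return float((test < t).mean())


def aicc(presence_probs, k: int) -> float:
    """AICc from standardized presence probabilities and parameter count.

    ``presence_probs`` are the model's raw scores at presences, standardized
    to sum to one over the prediction domain; ``k`` is the count of nonzero
    feature weights.  Undefined (NaN) when n - k - 1 <= 0.
    """
    p = np.asarray(presence_probs, dtype=float)
    n = p.size
    if n - k - 1 <= 0:
        return float("nan")
    ll = float(np.log(p).sum())
    return 2 * k - 2 * ll + 2 * k * (k + 1) / (n - k - 1)


def aicc_for_model(model: MaxentModel, x_presence: np.ndarray) -> float:
    """AICc of a fitted model (domain = its training background sample)."""
    probs = maxent.predict_raw(model, x_presence)
    return aicc(probs, model.n_params)


@dataclass
class EvalSummary:
    """Per-configuration evaluation statistics (one candidate-grid row)."""

    config: ModelConfig
    train_auc: float
    auc_diff_avg: float
    or10_avg: float
    or10_sd: float
    aicc: float  # NaN when undefined
    n_params: int
    delta_aicc: float = float("nan")
    n_failed_folds: int = 0

    def as_row(self) -> dict:
        return {
            "Feature class": self.config.feature_class,
            "Regularization multiplier": self.config.regularization_multiplier,
            "Train AUC": self.train_auc,
            "AUC mean difference": self.auc_diff_avg,
            "Mean OR 10%": self.or10_avg,
            "SD OR 10%": self.or10_sd,
            "AICc": self.aicc,
            "ΔAICc": self.delta_aicc,
            "Number of parameters": self.n_params,
        }


@dataclass
class GridResult:
    """Ordered evaluation summaries, one per grid configuration."""

    summaries: list[EvalSummary] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.summaries)

    def __iter__(self):
        return iter(self.summaries)

    def finalize_delta_aicc(self) -> None:
        defined = [s.aicc for s in self.summaries if math.isfinite(s.aicc)]
        if not defined:
            return
        best = min(defined)
        for s in self.summaries:
            s.delta_aicc = s.aicc - best if math.isfinite(s.aicc) else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.as_row() for s in self.summaries])


def jackknife_cv(
    expansion: FeatureExpansion,
    config: ModelConfig,
    betas: np.ndarray | None = None,
    max_folds: int | None = None,
    seed: int | None = None,
    warm_start: np.ndarray | None = None,
    **fit_kwargs,
) -> dict:
    """Leave-one-presence-out cross-validation on a shared background.

    Each fold drops one presence, refits, and records the fold's training
    AUC, the validation AUC of the held-out presence against the background,
    and a 0/1 omission by the 10% training-threshold rule.  ``max_folds``
    caps how many presences serve as hold-outs (a seeded uniform subset);
    the default evaluates every presence.  Non-convergent folds are excluded
    from the averages with a count.
    """
    n = len(expansion.x_presence)
    if n < 3:
        raise ValueError("jackknife needs at least 3 presences")
    rng = np.random.default_rng(seed)
    fold_ids = np.arange(n)
    if max_folds is not None and max_folds < n:
        fold_ids = np.sort(rng.choice(n, size=max_folds, replace=False))

    train_aucs, val_aucs, omissions = [], [], []
    n_failed = 0
    for i in fold_ids:
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        fold_exp = FeatureExpansion(
            features=expansion.features,
            norm_min=expansion.norm_min,
            norm_max=expansion.norm_max,
            x_presence=expansion.x_presence[keep],
            x_background=expansion.x_background,
            hinge_scale=expansion.hinge_scale,
        )
        fold_betas = betas if betas is not None else maxent.default_betas(fold_exp)
        model = maxent.fit(
            fold_exp, config, betas=fold_betas, warm_start=warm_start, **fit_kwargs
        )
        if not model.converged:
            n_failed += 1
            continue
        s_train = fold_exp.x_presence @ model.weights
        s_bg = fold_exp.x_background @ model.weights
        s_test = float(expansion.x_presence[i] @ model.weights)
        train_aucs.append(auc(s_train, s_bg))
        val_aucs.append(auc([s_test], s_bg))
        omissions.append(float(s_test < omission_threshold_10p(s_train)))
    if n_failed:
        log.warning("jackknife_cv: %d of %d folds did not converge", n_failed, len(fold_ids))
    if not train_aucs:
        raise RuntimeError("jackknife_cv: no fold converged")
    om = np.asarray(omissions)
    return {
        "train_auc_folds": train_aucs,
        "val_auc_folds": val_aucs,
        "omission_folds": omissions,
        "auc_diff_avg": float(np.mean(np.asarray(train_aucs) - np.asarray(val_aucs))),
        "or10_avg": float(om.mean()),
        "or10_sd": float(om.std(ddof=1)) if om.size > 1 else 0.0,  # sample SD
        "n_failed_folds": n_failed,
    }


def run_grid(
    table: pd.DataFrame,
    kinds: dict[str, str],
    feature_classes=DEFAULT_FEATURE_CLASSES,
    multipliers=DEFAULT_MULTIPLIERS,
    seed: int | None = None,
    max_folds: int | None = None,
    n_hinge_knots: int = 50,
    **fit_kwargs,
) -> tuple[GridResult, dict[str, MaxentModel]]:
    """Evaluate every feature-class x multiplier configuration.

    For each configuration: fit on all presences (train AUC, AICc, parameter
    count), then jackknife cross-validate (omission and AUC-difference
    statistics).  ΔAICc is computed against the grid-wide minimum, including
    configurations later filtered out by selection.  Per-configuration
    failures are recorded and the grid continues.  Returns the grid plus the
    full-data fitted models keyed by configuration label.
    """
    result = GridResult()
    models: dict[str, MaxentModel] = {}
    for fc in feature_classes:
        expansion = maxent.build_features(
            table, ModelConfig(feature_class=fc), kinds, n_hinge_knots=n_hinge_knots
        )
        for rm in multipliers:
            config = ModelConfig(feature_class=fc, regularization_multiplier=rm)
            try:
                full = maxent.fit(expansion, config, **fit_kwargs)
                s_pres = expansion.x_presence @ full.weights
                s_bg = expansion.x_background @ full.weights
                cv = jackknife_cv(
                    expansion,
                    config,
                    max_folds=max_folds,
                    seed=seed,
                    warm_start=full.weights,
                    **fit_kwargs,
                )
                summary = EvalSummary(
                    config=config,
                    train_auc=auc(s_pres, s_bg),
                    auc_diff_avg=cv["auc_diff_avg"],
                    or10_avg=cv["or10_avg"],
                    or10_sd=cv["or10_sd"],
                    aicc=aicc_for_model(full, expansion.x_presence),
                    n_params=full.n_params,
                    n_failed_folds=cv["n_failed_folds"],
                )
                models[config.label] = full
                result.summaries.append(summary)
            except Exception:  # noqa: BLE001 - grid continues past failures
                log.exception("run_grid: configuration %s failed", config.label)
    result.finalize_delta_aicc()
    return result, models


def _sort_key(s: EvalSummary):
    a = s.aicc if math.isfinite(s.aicc) else float("inf")
    return (s.or10_avg, s.auc_diff_avg, a)


def stepwise_select(grid: GridResult) -> tuple[EvalSummary, dict]:
    """Three-step stepwise selection over a candidate grid.

    1. Keep the ceil(m/2) summaries with the lowest mean 10% omission rate
       (ties at the cut broken by lower AUC difference, then lower AICc).
    2. Among survivors, keep those with AUC difference strictly below the
       survivors' median; if none fall strictly below, keep all.
    3. Return the survivor with the minimum defined AICc.

    Summaries with non-finite omission or AUC-difference statistics are
    excluded before step 1.  Returns the chosen summary and an audit trail.
    """
    usable = [
        s
        for s in grid.summaries
        if math.isfinite(s.or10_avg) and math.isfinite(s.auc_diff_avg)
    ]
    if not usable:
        raise ValueError("no usable summaries in the grid")
    m = len(usable)
    ordered = sorted(usable, key=_sort_key)
    step1 = ordered[: math.ceil(m / 2)]

    med = float(np.median([s.auc_diff_avg for s in step1]))
    step2 = [s for s in step1 if s.auc_diff_avg < med]
    if not step2:
        step2 = list(step1)

    defined = [s for s in step2 if math.isfinite(s.aicc)]
    if not defined:
        raise ValueError(
            "all AICc undefined among survivors: "
            + ", ".join(s.config.label for s in step2)
        )
    chosen = min(defined, key=lambda s: s.aicc)
    audit = {
        "n_input": len(grid.summaries),
        "n_usable": m,
        "step1_kept": [s.config.label for s in step1],
        "auc_diff_median": med,
        "step2_kept": [s.config.label for s in step2],
        "chosen": chosen.config.label,
        "chosen_aicc": chosen.aicc,
        "chosen_n_params": chosen.n_params,
    }
    return chosen, audit
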