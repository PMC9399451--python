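"""L1-regularized maximum-entropy presence-background model.

The model estimates a probability distribution over background cells that is
as close to uniform as possible (maximum entropy) while matching feature
expectations at presence locations, softened by an L1 penalty.  Writing
``f(x)`` for the feature vector of a cell and ``λ`` for the weights, the fit
maximizes the penalized log-likelihood

    J(λ) = (1/n) Σ_presence λ·f(x_i)  −  ln Z(λ)  −  Σ_j rm·β_j·|λ_j|,

with ``Z(λ) = Σ_background exp(λ·f(x))``.  This is a regularized Gibbs /
log-linear density; the stationarity conditions are the classic maxent
constraints softened by the penalty: active features match their presence
mean to within ``rm·β_j``.

Features are built from covariates per the configured feature class —
linear (L), quadratic (Q), hinge (H: piecewise-linear ramps at background
quantiles) — with categorical covariates always expanded into per-class
indicators.  Optimization is cyclic coordinate ascent with exact
one-dimensional line search (bracketed root of the orthant-wise derivative)
and an active-set sweep driven by KKT violations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

log = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "FeatureExpansion",
    "MaxentModel",
    "build_features",
    "default_betas",
    "fit",
    "predict_raw",
    "predict_cloglog",
    "percent_contribution",
]

FEATURE_CLASSES = ("L", "H", "LQ", "LQH")

# weights larger than this are clamped (only reachable under separation
# with a vanishing penalty; tail hinge features can legitimately need
# weights of a few tens, so the cap sits well above them)
LAMBDA_MAX = 200.0


@dataclass(frozen=True)
class ModelConfig:
    """Feature class and regularization multiplier of one candidate model."""

    feature_class: str = "LQ"
    regularization_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(
                f"feature_class must be one of {FEATURE_CLASSES}, got {self.feature_class!r}"
            )
        if not self.regularization_multiplier > 0:
            raise ValueError("regularization_multiplier must be positive")

    @property
    def label(self) -> str:
        return f"{self.feature_class}_rm{self.regularization_multiplier:g}"


@dataclass(frozen=True)
class Feature:
    """One model feature: a transformation of a single source variable."""

    variable: str
    kind: str  # linear | quadratic | hinge | category
    param: float | None = None  # hinge knot (raw units) or class code


@dataclass
class FeatureExpansion:
    """Feature definitions plus normalized design matrices.

    Raw feature values are min-max normalized on the background sample and
    clamped to [0, 1] (presence rows outside the background range are
    clamped rather than extrapolated).
    """

    features: list[Feature]
    norm_min: np.ndarray  # per-feature minimum used for scaling
    norm_max: np.ndarray
    x_presence: np.ndarray  # (n_presence, F), values in [0, 1]
    x_background: np.ndarray  # (n_background, F)
    hinge_scale: dict[str, tuple[float, float]] = field(default_factory=dict)  # var -> (bg min, bg max)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def variables(self) -> list[str]:
        seen: list[str] = []
        for f in self.features:
            if f.variable not in seen:
                seen.append(f.variable)
        return seen


def _raw_feature_columns(
    df: pd.DataFrame,
    config: ModelConfig,
    kinds: dict[str, str],
    background: pd.DataFrame,
    n_hinge_knots: int,
    classes_by_var: dict[str, list[int]],
) -> list[tuple[Feature, np.ndarray]]:
    """Raw (un-normalized) feature columns for the rows of ``df``."""
    fc = config.feature_class
    cols: list[tuple[Feature, np.ndarray]] = []
    for var in [c for c in df.columns if c in kinds]:
        x = df[var].to_numpy(dtype=float)
        if kinds[var] == "categorical":
            # indicators for every class observed anywhere in training
            for code in classes_by_var[var]:
                cols.append((Feature(var, "category", float(code)), (x == code).astype(float)))
            continue
        bg = background[var].to_numpy(dtype=float)
        bg_min, bg_max = float(np.min(bg)), float(np.max(bg))
        if bg_max == bg_min:
            log.warning("build_features: %s is constant on background; features dropped", var)
            continue
        if "L" in fc:
            cols.append((Feature(var, "linear"), x))
        if "Q" in fc:
            # squares are centered on the background mean: the spanned
            # function space {1, x, x^2} is identical, but the quadratic
            # feature decorrelates from the linear one, which keeps peaked
            # responses representable with moderate weights (raw squares of
            # a variable with small coefficient of variation are nearly
            # collinear with the variable itself)
            mu = float(np.mean(bg))
            cols.append((Feature(var, "quadratic", mu), (x - mu) ** 2))
        if "H" in fc:
            qs = np.arange(n_hinge_knots) / n_hinge_knots
            knots = np.unique(np.quantile(bg, qs))
            for k in knots:
                if k >= bg_max:
                    continue
                cols.append(
                    (Feature(var, "hinge", float(k)), np.maximum(0.0, (x - k) / (bg_max - k)))
                )
    return cols


def build_features(
    table: pd.DataFrame,
    config: ModelConfig,
    kinds: dict[str, str],
    n_hinge_knots: int = 50,
) -> FeatureExpansion:
    """Expand a covariate table into the configured feature set.

    ``table`` must contain a ``role`` column tagging rows ``presence`` or
    ``background`` plus one column per covariate named in ``kinds``.
    Continuous variables expand per the feature class (L: identity; Q: adds
    squares; H: adds hinges ``max(0, (x-k)/(max-k))`` at ``n_hinge_knots``
    uniform background quantiles, forward hinges only); categorical
    variables always expand to one indicator per observed class.  All
    features are min-max normalized on the background sample; a feature with
    no background spread (e.g. a class seen only at presences) falls back to
    the combined presence+background range.
    """
    pres = table[table["role"] == "presence"]
    bg = table[table["role"] == "background"]
    if len(pres) < 1 or len(bg) < 2:
        raise ValueError("need at least 1 presence and 2 background rows")

    classes_by_var = {
        var: sorted(set(table[var].dropna().astype(int)))
        for var, kind in kinds.items()
        if kind == "categorical" and var in table.columns
    }
    pres_cols = _raw_feature_columns(pres, config, kinds, bg, n_hinge_knots, classes_by_var)
    bg_cols = _raw_feature_columns(bg, config, kinds, bg, n_hinge_knots, classes_by_var)
    features = [f for f, _ in pres_cols]
    assert features == [f for f, _ in bg_cols]
    hinge_scale = {
        var: (float(bg[var].min()), float(bg[var].max()))
        for var in kinds
        if kinds[var] != "categorical" and var in bg.columns
    }

    xp = np.column_stack([c for _, c in pres_cols]) if features else np.empty((len(pres), 0))
    xb = np.column_stack([c for _, c in bg_cols]) if features else np.empty((len(bg), 0))

    lo = xb.min(axis=0)
    hi = xb.max(axis=0)
    flat = hi == lo
    if flat.any():
        # no background spread: normalize on the combined range instead
        both = np.vstack([xp, xb])
        lo = np.where(flat, both.min(axis=0), lo)
        hi = np.where(flat, both.max(axis=0), hi)
    keep = hi > lo
    if not keep.all():
        dropped = [features[i].variable for i in np.flatnonzero(~keep)]
        log.warning("build_features: dropped constant features from %s", sorted(set(dropped)))
    features = [f for f, k in zip(features, keep) if k]
    xp, xb, lo, hi = xp[:, keep], xb[:, keep], lo[keep], hi[keep]

    span = hi - lo
    xp = np.clip((xp - lo) / span, 0.0, 1.0)
    xb = np.clip((xb - lo) / span, 0.0, 1.0)
    return FeatureExpansion(
        features=features,
        norm_min=lo,
        norm_max=hi,
        x_presence=xp,
        x_background=xb,
        hinge_scale=hinge_scale,
    )


# ---------------------------------------------------------------------------
# default L1 penalty schedule
# ---------------------------------------------------------------------------

# published reference-implementation interpolation tables: per feature kind,
# (presence sample sizes, beta values); interpolated in n and clamped at the
# table ends
_BETA_TABLES = {
    "linear": ([10, 30, 100], [1.0, 0.2, 0.05]),
    "quadratic": ([0, 10, 17], [1.3, 0.8, 0.5]),
    "hinge": ([0, 1], [0.5, 0.5]),
    "category": ([0, 10, 17], [0.65, 0.5, 0.25]),
}
_BETA_FLOOR = 1e-4


def default_betas(expansion: FeatureExpansion) -> np.ndarray:
    """Per-feature default penalties: table value x presence SD / sqrt(n).

    Follows the published defaults: a feature-kind constant interpolated in
    presence sample size, scaled by the feature's presence-sample standard
    deviation over sqrt(n), floored to keep every penalty positive.
    """
    n = len(expansion.x_presence)
    sd = expansion.x_presence.std(axis=0)
    betas = np.empty(expansion.n_features)
    for j, f in enumerate(expansion.features):
        xs, ys = _BETA_TABLES[f.kind]
        base = float(np.interp(n, xs, ys))
        betas[j] = max(base * sd[j] / np.sqrt(n), _BETA_FLOOR)
    return betas


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class MaxentModel:
    """Fitted maxent model: weights, penalties, normalizers, entropy."""

    expansion: FeatureExpansion
    config: ModelConfig
    weights: np.ndarray  # λ per feature
    betas: np.ndarray  # β_j per feature (before the rm multiplier)
    log_z: float  # ln Σ_background exp(λ·f)
    entropy: float  # H of the fitted raw distribution over background
    converged: bool
    n_iter: int
    contribution_credit: dict[str, float]  # per-variable objective-gain credit

    @property
    def n_params(self) -> int:
        return int(np.count_nonzero(self.weights))

    def to_json(self) -> str:
        payload = {
            "config": {
                "feature_class": self.config.feature_class,
                "regularization_multiplier": self.config.regularization_multiplier,
            },
            "features": [
                {"variable": f.variable, "kind": f.kind, "param": f.param}
                for f in self.expansion.features
            ],
            "norm_min": self.expansion.norm_min.tolist(),
            "norm_max": self.expansion.norm_max.tolist(),
            "weights": self.weights.tolist(),
            "betas": self.betas.tolist(),
            "log_z": self.log_z,
            "entropy": self.entropy,
            "converged": self.converged,
            "schema_version": 1,
        }
        return json.dumps(payload, indent=1)


def _objective(lam, m_pres, x_bg, penalty) -> tuple[float, float]:
    """Penalized objective and ln Z for weights ``lam``."""
    s = x_bg @ lam
    smax = s.max()
    log_z = smax + np.log(np.exp(s - smax).sum())
    return float(lam @ m_pres - log_z - penalty @ np.abs(lam)), float(log_z)


def fit(
    expansion: FeatureExpansion,
    config: ModelConfig,
    betas: np.ndarray | None = None,
    tol: float = 1e-5,
    kkt_tol: float = 1e-5,
    max_iter: int = 3000,
    seed: int | None = None,
    warm_start: np.ndarray | None = None,
) -> MaxentModel:
    """Fit by cyclic coordinate ascent with exact 1-D line search.

    Each sweep updates, in fixed feature order, every coordinate whose KKT
    stationarity condition is violated beyond ``kkt_tol``; each update solves
    its one-dimensional penalized subproblem exactly (soft-thresholded root
    of the derivative).  Stops when the penalized objective improves by less
    than ``tol`` over a sweep and no KKT violation remains, or at
    ``max_iter`` sweeps (model returned flagged non-converged).  ``betas``
    defaults to the published sample-size schedule; ``seed`` is accepted for
    interface symmetry (the optimizer is deterministic).
    """
    x_bg = expansion.x_background
    x_pres = expansion.x_presence
    n_bg, n_feat = x_bg.shape
    if betas is None:
        betas = default_betas(expansion)
    betas = np.asarray(betas, dtype=float)
    rm = config.regularization_multiplier
    penalty = rm * betas

    m_pres = x_pres.mean(axis=0)
    lam = np.zeros(n_feat) if warm_start is None else np.array(warm_start, dtype=float)
    scores = x_bg @ lam
    credit: dict[str, float] = {v: 0.0 for v in expansion.variables}

    def log_partition(s):
        smax = s.max()
        return smax + np.log(np.exp(s - smax).sum())

    obj = float(lam @ m_pres - log_partition(scores) - penalty @ np.abs(lam))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # refresh the linear predictor (incremental updates drift over
        # thousands of sweeps), then KKT-scan for coordinates worth updating
        scores = x_bg @ lam
        shift = scores.max()
        w = np.exp(scores - shift)
        q = w / w.sum()
        e_model = q @ x_bg
        gap = m_pres - e_model
        viol = np.where(
            lam != 0,
            np.abs(gap - penalty * np.sign(lam)),
            np.maximum(np.abs(gap) - penalty, 0.0),
        )
        active = np.flatnonzero(viol > kkt_tol)
        if active.size == 0:
            converged = True
            break

        for j in active:
            f_j = x_bg[:, j]
            # weights with feature j removed from the linear predictor
            s0 = scores - lam[j] * f_j
            shift = s0.max()
            w0 = np.exp(s0 - shift)

            def mean_at(t: float) -> float:
                e = w0 * np.exp(t * f_j)
                return float((e @ f_j) / e.sum())

            pj = penalty[j]
            e0 = mean_at(0.0)
            if m_pres[j] - e0 > pj:
                g = lambda t: m_pres[j] - mean_at(t) - pj
                hi_b = 1.0
                while g(hi_b) > 0 and hi_b < LAMBDA_MAX:
                    hi_b *= 2
                t_new = min(hi_b, LAMBDA_MAX) if g(min(hi_b, LAMBDA_MAX)) > 0 else brentq(
                    g, 0.0, hi_b, xtol=1e-12
                )
            elif m_pres[j] - e0 < -pj:
                g = lambda t: m_pres[j] - mean_at(t) + pj
                lo_b = -1.0
                while g(lo_b) < 0 and lo_b > -LAMBDA_MAX:
                    lo_b *= 2
                t_new = max(lo_b, -LAMBDA_MAX) if g(max(lo_b, -LAMBDA_MAX)) < 0 else brentq(
                    g, lo_b, 0.0, xtol=1e-12
                )
            else:
                t_new = 0.0

            if t_new != lam[j]:
                # objective delta along this coordinate (for contribution)
                def part(t):
                    e = w0 * np.exp(t * f_j)
                    return shift + np.log(e.sum())

                d_obj = (
                    (t_new - lam[j]) * m_pres[j]
                    - (part(t_new) - part(lam[j]))
                    - pj * (abs(t_new) - abs(lam[j]))
                )
                credit[expansion.features[j].variable] += abs(float(d_obj))
                scores = s0 + t_new * f_j
                lam[j] = t_new

        new_obj = float(lam @ m_pres - log_partition(scores) - penalty @ np.abs(lam))
        assert new_obj >= obj - 1e-9, "coordinate ascent decreased the objective"
        if new_obj - obj < tol:
            # objective has stalled; one more KKT scan decides convergence
            obj = new_obj
            shift = scores.max()
            w = np.exp(scores - shift)
            q = w / w.sum()
            gap = m_pres - q @ x_bg
            viol = np.where(
                lam != 0,
                np.abs(gap - penalty * np.sign(lam)),
                np.maximum(np.abs(gap) - penalty, 0.0),
            )
            if viol.max(initial=0.0) <= kkt_tol:
                converged = True
                break
        obj = new_obj

    log_z = log_partition(scores)
    p = np.exp(scores - log_z)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    entropy = float(-plogp.sum())
    if not converged:
        log.warning("fit: not converged after %d sweeps (config %s)", max_iter, config.label)
    return MaxentModel(
        expansion=expansion,
        config=config,
        weights=lam,
        betas=betas,
        log_z=float(log_z),
        entropy=entropy,
        converged=converged,
        n_iter=it,
        contribution_credit=credit,
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def design_matrix(model: MaxentModel, table: pd.DataFrame, kinds: dict[str, str]) -> np.ndarray:
    """Normalized design matrix for new rows, using training normalizers.

    Feature values are clamped to the training [0, 1] normalization range;
    unseen categorical classes produce all-zero indicators (logged).
    """
    exp = model.expansion
    n = len(table)
    x = np.empty((n, exp.n_features))
    seen_codes = {
        (f.variable, f.param) for f in exp.features if f.kind == "category"
    }
    for var in {f.variable for f in exp.features if f.kind == "category"}:
        codes = set(table[var].dropna().astype(int))
        unseen = {c for c in codes if (var, float(c)) not in seen_codes}
        if unseen:
            log.info("predict: %s has unseen classes %s (all indicators 0)", var, sorted(unseen))
    for j, f in enumerate(exp.features):
        v = table[f.variable].to_numpy(dtype=float)
        if f.kind == "linear":
            raw = v
        elif f.kind == "quadratic":
            raw = (v - f.param) ** 2  # param = background mean used in training
        elif f.kind == "hinge":
            # rebuild the training ramp max(0, (x-k)/(bg_max-k))
            bg_max = exp.hinge_scale[f.variable][1]
            raw = np.maximum(0.0, (v - f.param) / (bg_max - f.param))
        else:  # category
            raw = (v == f.param).astype(float)
        span = exp.norm_max[j] - exp.norm_min[j]
        x[:, j] = np.clip((raw - exp.norm_min[j]) / span, 0.0, 1.0)
    return x


def predict_raw(model: MaxentModel, x: np.ndarray) -> np.ndarray:
    """Raw output exp(λ·f)/Z on a normalized design matrix ``x``.

    Z is fixed from training, so the raw values over the training background
    sum to one.
    """
    return np.exp(x @ model.weights - model.log_z)


def predict_cloglog(model: MaxentModel, x: np.ndarray) -> np.ndarray:
    """Complementary log-log suitability: 1 - exp(-e^H · raw), in (0, 1)."""
    return 1.0 - np.exp(-np.exp(model.entropy) * predict_raw(model, x))


def percent_contribution(model: MaxentModel) -> dict[str, float]:
    """Percent contribution per source variable from the training path.

    Absolute objective-gain deltas accumulated during coordinate updates are
    summed per variable and normalized to 100.  If no credit was earned (an
    all-zero model) the raw zeros are returned un-normalized.
    """
    credit = model.contribution_credit
    total = sum(credit.values())
    if total == 0:
        log.warning("percent_contribution: all-zero model, contributions undefined")
        return {v: 0.0 for v in credit}
    return {v: 100.0 * c / total for v, c in credit.items()}
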