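"""Context-specific missing-data strategies.

Two strategies, matching the two data-collection contexts the analysis must
serve:

* **normal-range fill** — a missing physiologic variable is presumed to have
  been judged normal by the clinician and contributes 0 points to the acute
  physiology score.  The fill acts on *points*, never on raw values.
* **multiple imputation by predictive mean matching (PMM)** — missing values
  are presumed to reflect resource constraints, not normality; chained
  equations impute raw values from observed donors, the analysis is run on
  each completed copy, and per-imputation estimates are pooled with Rubin's
  rules.

The PMM imputer is deterministic given its seed, visits variables in the
configured order, draws regression coefficients from the standard
noninformative linear-model posterior (proper imputation), and only ever
donates observed values (the hot-deck property).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .apache2 import ScoringDefinition, score_components


class MissingnessError(Exception):
    pass


# ---------------------------------------------------------------------------
# normal-range fill
# ---------------------------------------------------------------------------


def normal_fill(
    wide: pd.DataFrame,
    definition: ScoringDefinition,
    acute_renal_failure=None,
) -> pd.DataFrame:
    """Score the wide table and resolve every absent component to 0 points.

    No raw values are invented: present extrema are scored normally, absent
    components get the normal-range weight of 0, so the fill can only leave
    the observed-components APS unchanged, never decrease it.
    """
    points = score_components(wide, definition, acute_renal_failure)
    return points.fillna(0.0)


# ---------------------------------------------------------------------------
# predictive mean matching
# ---------------------------------------------------------------------------


@dataclass
class MiConfig:
    """Multiple-imputation settings (defaults follow the analysis protocol:
    30 imputations of 100 chained-equation cycles, 5 PMM donors)."""

    m: int = 30
    iterations: int = 100
    donors_k: int = 5
    seed: int = 0
    predictors: list[str] = field(default_factory=list)  # extra complete columns

    def validate(self) -> None:
        if self.m < 1:
            raise MissingnessError("m must be >= 1")
        if self.iterations < 1:
            raise MissingnessError("iterations must be >= 1")
        if self.donors_k < 1:
            raise MissingnessError("donors_k must be >= 1")


@dataclass
class ImputationSet:
    """m completed copies of the wide table; observed cells are identical
    across copies, only originally-missing cells vary."""

    completed: list[pd.DataFrame]
    missing_mask: pd.DataFrame

    @property
    def m(self) -> int:
        return len(self.completed)


def _pmm_match(
    yhat_obs: np.ndarray,
    y_obs: np.ndarray,
    yhat_mis: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """For each missing case, donate the observed value of one of the k
    observed cases with nearest predictive mean (uniform donor draw)."""
    order = np.argsort(yhat_obs, kind="stable")
    sorted_hat = yhat_obs[order]
    sorted_y = y_obs[order]
    n_obs = len(sorted_hat)
    k = min(k, n_obs)
    pos = np.searchsorted(sorted_hat, yhat_mis)
    # candidate window: the k sorted neighbours on each side contain the k
    # nearest predictive means
    lo = np.clip(pos - k, 0, max(n_obs - 2 * k, 0))
    cand = lo[:, None] + np.arange(min(2 * k, n_obs))[None, :]
    dist = np.abs(sorted_hat[cand] - yhat_mis[:, None])
    if cand.shape[1] > k:
        nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
    else:
        nearest = np.argsort(dist, axis=1, kind="stable")
    choice = rng.integers(0, nearest.shape[1], size=len(yhat_mis))
    picked = np.take_along_axis(
        np.take_along_axis(cand, nearest, axis=1), choice[:, None], axis=1
    )[:, 0]
    return sorted_y[picked]


def _bayes_draw(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(beta_hat, beta_draw) under the noninformative linear-model posterior."""
    n, p = X.shape
    G = X.T @ X + 1e-8 * np.eye(p)
    L = np.linalg.cholesky(G)
    beta_hat = np.linalg.solve(G, X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    sigma2 = resid @ resid / rng.chisquare(dof)
    u = rng.standard_normal(p)
    beta_draw = beta_hat + np.sqrt(sigma2) * np.linalg.solve(L.T, u)
    return beta_hat, beta_draw


def mi_pmm(
    wide: pd.DataFrame,
    mi: MiConfig,
    variables: list[str] | None = None,
    predictors: pd.DataFrame | None = None,
) -> ImputationSet:
    """Chained-equation PMM imputation of the wide table's numeric columns.

    Parameters
    ----------
    wide:
        Table whose numeric columns in ``variables`` may contain NaN.
    mi:
        Imputation settings; ``mi.seed`` drives every random draw.
    variables:
        Columns eligible for imputation, visited in this (fixed) order each
        cycle; defaults to every numeric column containing a NaN.
    predictors:
        Extra always-complete predictor columns (e.g. registry indicators,
        ICU survival status, length of stay), aligned with ``wide``.
    """
    mi.validate()
    if variables is None:
        num = wide.select_dtypes(include=[np.number])
        variables = [c for c in num.columns if num[c].isna().any()]
    mask = wide[variables].isna() if variables else pd.DataFrame(index=wide.index)

    if predictors is not None:
        if len(predictors) != len(wide):
            raise MissingnessError("predictors not aligned with the wide table")
        P = predictors.to_numpy(dtype=float)
        if np.isnan(P).any():
            raise MissingnessError("predictor columns must be complete")
    else:
        P = np.empty((len(wide), 0))

    incomplete = [v for v in variables if mask[v].any()]
    for v in incomplete:
        n_obs = int((~mask[v]).sum())
        if n_obs < mi.donors_k:
            raise MissingnessError(
                f"variable {v!r}: only {n_obs} observed rows, "
                f"fewer than donors_k={mi.donors_k}"
            )

    all_model_cols = list(variables)
    completed: list[pd.DataFrame] = []
    root = np.random.SeedSequence(mi.seed)
    for chain_seq in root.spawn(mi.m):
        rng = np.random.default_rng(chain_seq)
        data = wide.copy()
        M = data[all_model_cols].to_numpy(dtype=float) if all_model_cols else np.empty((len(wide), 0))
        miss = mask.to_numpy() if len(all_model_cols) else np.empty((len(wide), 0), bool)
        # initialise missing cells with random observed draws
        for j, v in enumerate(all_model_cols):
            mj = miss[:, j]
            if mj.any():
                obs = M[~mj, j]
                M[mj, j] = rng.choice(obs, size=int(mj.sum()), replace=True)
        ones = np.ones((len(wide), 1))
        col_index = {v: j for j, v in enumerate(all_model_cols)}
        for _ in range(mi.iterations if incomplete else 0):
            for v in incomplete:
                j = col_index[v]
                mj = miss[:, j]
                X = np.hstack([ones, P, np.delete(M, j, axis=1)])
                y = M[:, j]
                beta_hat, beta_draw = _bayes_draw(X[~mj], y[~mj], rng)
                yhat_obs = X[~mj] @ beta_hat
                yhat_mis = X[mj] @ beta_draw
                M[mj, j] = _pmm_match(yhat_obs, y[~mj], yhat_mis, mi.donors_k, rng)
        for j, v in enumerate(all_model_cols):
            data[v] = M[:, j]
        completed.append(data)
    return ImputationSet(completed=completed, missing_mask=mask)


def score_imputations(
    imp: ImputationSet,
    definition: ScoringDefinition,
    acute_renal_failure=None,
) -> list[pd.DataFrame]:
    """Component points of every completed copy (all components resolved)."""
    out = []
    for data in imp.completed:
        pts = score_components(data, definition, acute_renal_failure)
        bad = pts.columns[pts.isna().any()].tolist()
        if bad:
            raise MissingnessError(
                f"components {bad} still unresolved after imputation "
                "(structurally absent inputs cannot be imputed)"
            )
        out.append(pts)
    return out


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------


@dataclass
class PooledEstimate:
    point: float
    within_var: float
    between_var: float
    total_var: float
    ci95: tuple[float, float]
    df: float
    m: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))


def rubin_pool(estimates, variances, alpha: float = 0.05) -> PooledEstimate:
    """Pool m per-imputation (estimate, variance) pairs with Rubin's rules.

    point = mean of estimates; W = mean of variances; B = sample variance of
    estimates; T = W + (1 + 1/m) B.  The 95% interval uses a t reference with
    Rubin's degrees of freedom nu = (m-1) (1 + W / ((1+1/m) B))^2; when B = 0
    (or m = 1) the total variance collapses to W and the reference is normal.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1 or len(q) < 1:
        raise MissingnessError("estimates and variances must be equal-length 1-d lists")
    m = len(q)
    point = float(q.mean())
    W = float(u.mean())
    B = float(q.var(ddof=1)) if m > 1 else 0.0
    T = W + (1.0 + 1.0 / m) * B
    if m > 1 and B > 0:
        with np.errstate(over="ignore"):
            df = float((m - 1) * (1.0 + np.float64(W) / ((1.0 + 1.0 / m) * B)) ** 2)
        crit = float(
            stats.t.ppf(1.0 - alpha / 2.0, df)
            if np.isfinite(df)
            else stats.norm.ppf(1.0 - alpha / 2.0)
        )
    else:
        df = float(np.inf)
        crit = float(stats.norm.ppf(1.0 - alpha / 2.0))
    half = crit * float(np.sqrt(T))
    return PooledEstimate(
        point=point,
        within_var=W,
        between_var=B,
        total_var=T,
        ci95=(point - half, point + half),
        df=df,
        m=m,
    )


def expected_deaths_variance(risks) -> float:
    """Within-imputation variance of expected deaths, Sum r (1 - r),
    treating the predicted risks as independent Bernoulli means."""
    r = np.asarray(risks, dtype=float)
    return float(np.sum(r * (1.0 - r)))
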