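"""Standardized mortality ratios, funnel-plot control limits and reports.

The SMR of a unit (an ICU or a whole quality registry) is its observed death
count at ICU discharge divided by its expected death count, the sum of the
admissions' predicted mortality risks (identically: mean risk x n).  Funnel
plots draw each unit's SMR against its expected deaths together with control
limits for the null hypothesis SMR = 1, computed from exact Poisson tail
quantiles with continuity interpolation so the stated coverage is ~ 1 - alpha
even at small expected counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .missingness import PooledEstimate, expected_deaths_variance, rubin_pool


class BenchmarkError(Exception):
    pass


def expected_deaths(risks) -> float:
    """Expected death count: the sum of predicted risks (= mean risk x n)."""
    r = np.asarray(risks, dtype=float)
    if r.size == 0:
        raise BenchmarkError("expected_deaths of an empty risk list")
    if np.isnan(r).any() or (r <= 0).any() or (r >= 1).any():
        raise BenchmarkError("risks must lie strictly inside (0, 1)")
    return float(r.sum())


def compute_smr(
    table: pd.DataFrame,
    unit_col: str = "registry",
    death_col: str = "icu_death",
    risk_col: str = "risk",
) -> pd.DataFrame:
    """Per-unit observed deaths, expected deaths and SMR.

    ``unit_col`` selects the aggregation level (e.g. ``"icu"`` or
    ``"registry"``); a registry's expected deaths equal the sum over its ICUs
    exactly, so the registry SMR is (sum O) / (sum E), not a mean of ICU SMRs.
    """
    g = table.groupby(unit_col, sort=True)
    out = pd.DataFrame(
        {
            "unit": g.size().index,
            "n_admissions": g.size().to_numpy(),
            "observed": g[death_col].sum().to_numpy().astype(int),
            "expected": g[risk_col].sum().to_numpy(),
        }
    )
    zero = out["expected"] <= 0
    if zero.any():
        import warnings

        warnings.warn(
            f"units with zero expected deaths reported without SMR: "
            f"{out['unit'][zero].tolist()}",
            stacklevel=2,
        )
    out["smr"] = np.where(zero, np.nan, out["observed"] / out["expected"])
    return out


# ---------------------------------------------------------------------------
# funnel limits
# ---------------------------------------------------------------------------


def _interp_poisson_quantile(p: float, mu: float) -> float:
    """Continuity-interpolated Poisson quantile.

    With F the Poisson(mu) CDF and k the smallest integer with F(k) >= p, the
    interpolated quantile is (k-1) + (p - F(k-1)) / (F(k) - F(k-1)), taking
    F(-1) = 0 — a piecewise-linear inverse CDF so the implied two-sided
    coverage is approximately the nominal level instead of conservative.
    """
    k = int(stats.poisson.ppf(p, mu))
    Fk = stats.poisson.cdf(k, mu)
    Fk1 = stats.poisson.cdf(k - 1, mu) if k > 0 else 0.0
    if Fk == Fk1:  # degenerate tail; fall back to the integer quantile
        return float(k)
    return (k - 1) + (p - Fk1) / (Fk - Fk1)


@dataclass
class FunnelLimits:
    alpha: float
    expected: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    centre: float = 1.0

    def contains(self, expected, smr) -> np.ndarray:
        """Whether (E, SMR) points fall inside the limits (limits inclusive)."""
        lo = np.interp(expected, self.expected, self.lower)
        hi = np.interp(expected, self.expected, self.upper)
        return (np.asarray(smr) >= lo) & (np.asarray(smr) <= hi)


def funnel_limits(expected_grid, alpha: float = 0.05) -> FunnelLimits:
    """SMR control limits under O ~ Poisson(E) at each expected count E.

    lower(E) = q(alpha/2)/E and upper(E) = q(1-alpha/2)/E with q the
    continuity-interpolated Poisson quantile; both curves bracket 1 and
    tighten toward 1 as E grows.
    """
    if not 0.0 < alpha < 1.0:
        raise BenchmarkError(f"alpha must be in (0, 1), got {alpha}")
    E = np.sort(np.asarray(expected_grid, dtype=float))
    if (E <= 0).any():
        raise BenchmarkError("expected values must be > 0")
    lower = np.array([_interp_poisson_quantile(alpha / 2.0, e) / e for e in E])
    upper = np.array([_interp_poisson_quantile(1.0 - alpha / 2.0, e) / e for e in E])
    return FunnelLimits(alpha=alpha, expected=E, lower=lower, upper=upper)


# ---------------------------------------------------------------------------
# pooled (multiply imputed) funnels
# ---------------------------------------------------------------------------


@dataclass
class PooledUnitStats:
    unit: str
    n_admissions: int
    observed: int
    expected_per_imputation: list[float]
    pooled: PooledEstimate
    smr_point: float
    smr_lo95: float
    smr_hi95: float


def pooled_smr(
    cohort: pd.DataFrame,
    risks_per_imputation: list[pd.Series],
    unit_col: str = "registry",
    death_col: str = "icu_death",
) -> list[PooledUnitStats]:
    """Registry-level SMRs under multiple imputation.

    Expected deaths are computed separately on each completed dataset and
    pooled with Rubin's rules; the SMR point estimate divides the observed
    deaths by the pooled expected count, and the interval endpoints are
    O/E_hi and O/E_lo (division by E reverses the interval order).
    """
    out: list[PooledUnitStats] = []
    units = sorted(cohort[unit_col].unique())
    for unit in units:
        rows = cohort[unit_col] == unit
        O = int(cohort.loc[rows, death_col].sum())
        n = int(rows.sum())
        Es, Vs = [], []
        for risks in risks_per_imputation:
            r = np.asarray(risks)[np.asarray(rows)]
            Es.append(expected_deaths(r))
            Vs.append(expected_deaths_variance(r))
        pooled = rubin_pool(Es, Vs)
        e_lo, e_hi = pooled.ci95
        out.append(
            PooledUnitStats(
                unit=str(unit),
                n_admissions=n,
                observed=O,
                expected_per_imputation=Es,
                pooled=pooled,
                smr_point=O / pooled.point,
                smr_lo95=O / e_hi if e_hi > 0 else np.nan,
                smr_hi95=O / e_lo if e_lo > 0 else np.inf,
            )
        )
    return out


def pooled_funnel(
    stats_list: list[PooledUnitStats], alpha: float = 0.05, n_grid: int = 100
) -> dict[str, FunnelLimits]:
    """Funnel limit overlays for the pooled point and both interval bounds."""
    points = np.array([s.pooled.point for s in stats_list])
    los = np.array([s.pooled.ci95[0] for s in stats_list])
    his = np.array([s.pooled.ci95[1] for s in stats_list])
    out = {}
    for name, E in (("point", points), ("lower95", los), ("upper95", his)):
        E = E[E > 0]
        if len(E) == 0:
            continue
        grid = np.linspace(max(E.min() * 0.5, 0.5), E.max() * 1.2, n_grid)
        out[name] = funnel_limits(grid, alpha)
    return out


# ---------------------------------------------------------------------------
# demographics report
# ---------------------------------------------------------------------------


def round_half_up(x: float, digits: int = 1) -> float:
    """Decimal half-up rounding (so 56.25 -> 56.3, not banker's 56.2)."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: int, total: int, digits: int = 1) -> float:
    """Percentage as reported in demographics tables: 100*count/total,
    half-up rounded to one decimal."""
    if total <= 0:
        raise BenchmarkError("percentage of a non-positive total")
    return round_half_up(100.0 * count / total, digits)


def _median_iqr(x: pd.Series, digits: int = 1) -> str:
    med = round_half_up(float(x.median()), digits)
    q1 = round_half_up(float(x.quantile(0.25)), digits)
    q3 = round_half_up(float(x.quantile(0.75)), digits)
    return f"{med} ({q1}-{q3})"


def demographics_table(scored: pd.DataFrame, source_col: str = "source") -> pd.DataFrame:
    """Per-source demographics and outcomes: N ICUs, N patients, age median
    (IQR), male N (%), APACHE II score median (IQR), ICU mortality N (%),
    ICU length of stay median (IQR)."""
    rows = {}
    for source, g in scored.groupby(source_col):
        n = len(g)
        male = int((g["sex"] == "M").sum())
        deaths = int(g["icu_death"].sum())
        rows[source] = {
            "Number of ICUs": g["icu"].nunique() if "icu" in g else np.nan,
            "Number of patients": n,
            "Age Median (IQR)": _median_iqr(g["age"], 0),
            "Male, N (%)": f"{male} ({pct(male, n)})",
            "APACHE II score, Median (IQR)": _median_iqr(g["total"], 1),
            "ICU mortality, N (%)": f"{deaths} ({pct(deaths, n)})",
            "ICU length of stay (Days), Median (IQR)": _median_iqr(
                g["icu_los_days"], 1
            ),
        }
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def outlier_table(stats_df: pd.DataFrame, limits: FunnelLimits) -> pd.DataFrame:
    """Units outside the control limits, with their side."""
    lo = np.interp(stats_df["expected"], limits.expected, limits.lower)
    hi = np.interp(stats_df["expected"], limits.expected, limits.upper)
    out = stats_df.copy()
    out["side"] = np.where(
        out["smr"] > hi, "above", np.where(out["smr"] < lo, "below", "inside")
    )
    return out[out["side"] != "inside"].reset_index(drop=True)


def plot_funnel(
    stats_df: pd.DataFrame,
    limits: FunnelLimits,
    path: str | Path,
    title: str = "SMR funnel plot",
) -> Path:
    """Render the funnel (dots = units, centre line at 1, limit curves).

    Output is deterministic: rendering the same inputs twice gives
    byte-identical SVG.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    with plt.rc_context({"svg.hashsalt": "icubench"}):
        fig, ax = plt.subplots(figsize=(7, 5))
        ax.plot(limits.expected, limits.lower, "k--", lw=1,
                label=f"{100 * (1 - limits.alpha):g}% control limits")
        ax.plot(limits.expected, limits.upper, "k--", lw=1)
        ax.axhline(limits.centre, color="grey", lw=1)
        ax.scatter(stats_df["expected"], stats_df["smr"], zorder=3, s=28)
        ax.set_xlabel("Expected number of deaths")
        ax.set_ylabel("SMR")
        ax.set_title(title)
        ax.legend(frameon=False)
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        try:
            fig.savefig(path, metadata={"Date": None} if path.suffix == ".svg" else None)
        except OSError as exc:
            plt.close(fig)
            raise BenchmarkError(f"cannot write funnel plot to {path}: {exc}") from exc
        plt.close(fig)
    return path
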