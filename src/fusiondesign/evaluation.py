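"""Performance metrics for the method-comparison simulations.

Metrics are evaluated at fixed parameter slices with exact binomial Monte
Carlo standard errors (``sqrt(r(1-r)/n)``) and Wilson 95% intervals,
rather than smoothing the power/FPR surface: the quantities of interest
are slice values (e.g. power at omega = gamma = 1 as a function of
lambda), where slicing is unbiased.

Definitions
-----------
false-positive rate
    fraction of null datasets (``lambda_true = 0``) with two-sided Wald
    ``p < alpha`` — sign-agnostic, since a false positive misleads in
    either direction.
power
    fraction of effect datasets with ``p < alpha`` *and* a sign-correct
    (positive) estimated reduction.
relative bias
    ``(mean estimated reduction / 100 - lambda) / lambda`` per condition.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "compute_fpr",
    "compute_power",
    "compute_relative_bias",
    "power_ratio",
    "performance_curve",
    "plot_performance",
]

_CONDITION_COLS = ("scenario", "omega", "gamma", "lambda_true")


def _wilson(successes: float, n: int, level: float = 0.95):
    from statsmodels.stats.proportion import proportion_confint

    return proportion_confint(successes, n, alpha=1 - level, method="wilson")


def _rate_summary(grouped, col_flag: str, metric: str) -> pd.DataFrame:
    rows = []
    for keys, g in grouped:
        keys = keys if isinstance(keys, tuple) else (keys,)
        n = len(g)
        hits = int(g[col_flag].sum())
        r = hits / n
        lo, hi = _wilson(hits, n)
        rows.append({**dict(zip(["method", *_CONDITION_COLS], keys)),
                     "metric": metric, "value": r,
                     "mc_se": np.sqrt(r * (1 - r) / n),
                     "ci_low": lo, "ci_high": hi, "n_sims": n,
                     "n_converged": int(g["converged"].sum())})
    return pd.DataFrame(rows)


def _prepare(results: pd.DataFrame) -> pd.DataFrame:
    out = results.copy()
    # a failed fit never counts as a detection
    out["p_value"] = out["p_value"].fillna(1.0)
    return out


def compute_fpr(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """False-positive rate per method x condition among null datasets."""
    res = _prepare(results)
    null = res[res["lambda_true"] == 0].copy()
    if null.empty:
        raise ValueError("no null datasets (lambda_true == 0) in the results")
    null["significant"] = null["p_value"] < alpha
    grouped = null.groupby(["method", *_CONDITION_COLS], sort=True)
    return _rate_summary(grouped, "significant", "fpr")


def compute_power(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Sign-correct power per method x condition among effect datasets."""
    res = _prepare(results)
    eff = res[res["lambda_true"] > 0].copy()
    if eff.empty:
        raise ValueError("no effect datasets (lambda_true > 0) in the results")
    eff["detected"] = (eff["p_value"] < alpha) & (eff["reduction_est_pct"] > 0)
    grouped = eff.groupby(["method", *_CONDITION_COLS], sort=True)
    return _rate_summary(grouped, "detected", "power")


def compute_relative_bias(results: pd.DataFrame) -> pd.DataFrame:
    """Relative bias of the estimated reduction per method x condition."""
    eff = results[results["lambda_true"] > 0]
    if eff.empty:
        raise ValueError("no effect datasets (lambda_true > 0) in the results")
    rows = []
    for keys, g in eff.groupby(["method", *_CONDITION_COLS], sort=True):
        lam = keys[-1]
        est = g["reduction_est_pct"].dropna()
        mean_red = est.mean() / 100.0
        bias = (mean_red - lam) / lam
        rows.append({**dict(zip(["method", *_CONDITION_COLS], keys)),
                     "metric": "relative_bias", "value": bias,
                     "mc_se": est.std(ddof=1) / 100.0 / lam / np.sqrt(len(est)),
                     "n_sims": len(g), "n_converged": int(g["converged"].sum())})
    return pd.DataFrame(rows)


def power_ratio(results: pd.DataFrame, numerator_method: str,
                denominator_method: str,
                lambda_grid: Sequence[float] | None = None,
                alpha: float = 0.05) -> float:
    """Ratio of grid-averaged powers of two methods over a lambda grid.

    The default grid is every ``lambda_true > 0`` value present. A zero
    denominator returns ``inf`` (the numerator method detects effects the
    denominator never does).
    """
    power = compute_power(results, alpha=alpha)
    if lambda_grid is not None:
        grid = np.asarray(sorted(lambda_grid), dtype=float)
        power = power[np.isclose(power["lambda_true"].to_numpy()[:, None],
                                 grid[None, :]).any(axis=1)]
    means = {}
    for method in (numerator_method, denominator_method):
        sub = power[power["method"] == method]
        if sub.empty or (lambda_grid is not None
                         and len(sub["lambda_true"].unique()) < len(set(lambda_grid))):
            raise ValueError(f"method {method!r} missing at one or more grid points")
        means[method] = sub.groupby("lambda_true")["value"].mean().mean()
    if means[denominator_method] == 0:
        import warnings

        warnings.warn(f"denominator method {denominator_method!r} has zero mean power",
                      stacklevel=2)
        return float("inf")
    return float(means[numerator_method] / means[denominator_method])


def performance_curve(results: pd.DataFrame, variable: str,
                      metric: str = "power", alpha: float = 0.05) -> pd.DataFrame:
    """Metric vs one structural variable at fixed values of the others.

    ``variable`` is one of ``omega``, ``gamma``, ``lambda_true``. The
    results table is expected to hold the other parameters at fixed slice
    values (the study defaults omega = gamma = 1, lambda = 0.5); every
    distinct value of ``variable`` becomes one point with a Wilson 95%
    interval.
    """
    if variable not in ("omega", "gamma", "lambda_true"):
        raise ValueError("variable must be omega, gamma or lambda_true")
    fn = {"power": compute_power, "fpr": compute_fpr,
          "relative_bias": lambda r: compute_relative_bias(r)}[metric]
    summary = fn(results, alpha=alpha) if metric != "relative_bias" else fn(results)
    keep = ["method", variable, "metric", "value", "mc_se", "n_sims"]
    if "ci_low" in summary.columns:
        keep += ["ci_low", "ci_high"]
    return (summary[keep]
            .sort_values(["method", variable])
            .reset_index(drop=True))


def plot_performance(curves: pd.DataFrame, variable: str, ax=None,
                     ylabel: str | None = None):
    """Plot one performance curve per method with Wilson error bands."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for method, g in curves.groupby("method"):
        g = g.sort_values(variable)
        ax.plot(g[variable], g["value"], marker="o", label=method)
        if "ci_low" in g.columns:
            ax.fill_between(g[variable], g["ci_low"], g["ci_high"], alpha=0.2)
    ax.set_xlabel(variable)
    ax.set_ylabel(ylabel or curves["metric"].iloc[0])
    ax.legend(fontsize=8)
    return ax
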