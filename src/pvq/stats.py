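"""Regression and group summaries over the clearance tables.

The central analysis is an ordinary-least-squares regression of tracer
influx on amyloid plaque burden, pooling every slice x region row of a
regional signal table — the construction behind the observation that
regions with more amyloid receive less CSF.  Group comparisons (genotype,
age, vessel type, CAA status, region) are prepared as tidy mean ± SEM
tables; the inferential ANOVA itself is delegated to standard statistical
software and is deliberately not reimplemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError


@dataclass
class RegressionResult:
    """Simple linear regression summary, y = intercept + slope * x."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    residual_sd: float
    slope_se: float
    x_name: str = "x"
    y_name: str = "y"
    fit_x: np.ndarray = field(default_factory=lambda: np.empty(0))
    fit_y: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n": self.n,
            "residual_sd": self.residual_sd,
            "slope_se": self.slope_se,
            "x": self.x_name,
            "y": self.y_name,
        }


def linear_regression(x: np.ndarray, y: np.ndarray,
                      x_name: str = "x", y_name: str = "y") -> RegressionResult:
    """OLS of y on x with the usual summary statistics."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError("regression needs at least 3 finite (x, y) pairs")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in the predictor")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    grid = np.linspace(x.min(), x.max(), 50)
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=int(x.size),
        residual_sd=float(np.sqrt(model.mse_resid)),
        slope_se=float(model.bse[1]),
        x_name=x_name,
        y_name=y_name,
        fit_x=grid,
        fit_y=float(model.params[0]) + float(model.params[1]) * grid,
    )


def burden_influx_regression(
    table: pd.DataFrame,
    tracer_role: str = "FITC3K",
    stratify_by_region: bool = False,
):
    """Regress influx signal on plaque burden over all slice x region rows.

    ``table`` is a regional signal table in long format (columns
    ``channel``, ``mean_signal``, ``plaque_burden_pct``).  All rows for the
    requested tracer are pooled — each slice x region pair is one point.
    With ``stratify_by_region`` a dict of per-region results is returned
    instead.
    """
    required = {"channel", "mean_signal", "plaque_burden_pct"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"regional table lacks columns {sorted(missing)}")
    sub = table[table["channel"] == tracer_role]
    if sub.empty:
        raise ValidationError(f"no rows for tracer {tracer_role!r}")
    if stratify_by_region:
        return {
            region: linear_regression(
                g["plaque_burden_pct"], g["mean_signal"],
                x_name="plaque_burden_pct", y_name=f"influx_{tracer_role}",
            )
            for region, g in sub.groupby("region")
        }
    return linear_regression(
        sub["plaque_burden_pct"], sub["mean_signal"],
        x_name="plaque_burden_pct", y_name=f"influx_{tracer_role}",
    )


def group_summary(
    table: pd.DataFrame,
    by: list[str] | str,
    value: str,
) -> pd.DataFrame:
    """Mean, SEM and n of ``value`` per group.

    Groups with no finite observations are omitted with a warning.  The
    long-format input itself is the export for external ANOVA software;
    this function only prepares the descriptive table (SEM = sd / sqrt(n),
    with the sample standard deviation).
    """
    import warnings

    if isinstance(by, str):
        by = [by]
    for col in by + [value]:
        if col not in table.columns:
            raise ValidationError(f"column {col!r} missing from the table")
    rows = []
    for keys, g in table.groupby(by, dropna=False, sort=True):
        vals = pd.to_numeric(g[value], errors="coerce").dropna()
        if vals.empty:
            warnings.warn(f"group {keys!r} has no observations; omitted", stacklevel=2)
            continue
        keys = keys if isinstance(keys, tuple) else (keys,)
        n = len(vals)
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        rows.append(
            dict(zip(by, keys))
            | {"mean": float(vals.mean()), "sem": sd / np.sqrt(n), "n": n}
        )
    return pd.DataFrame(rows, columns=by + ["mean", "sem", "n"])


def plot_regression(result: RegressionResult, x, y, path) -> None:
    """Scatter of the data with the fitted line, written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(x, y, s=14, alpha=0.7, edgecolor="none")
    ax.plot(result.fit_x, result.fit_y, color="crimson")
    ax.set_xlabel(result.x_name)
    ax.set_ylabel(result.y_name)
    ax.set_title(
        f"slope={result.slope:.3g}, $R^2$={result.r_squared:.3f}, p={result.p_value:.2g}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
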