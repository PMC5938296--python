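"""Potential dose reduction from fitted VGR coefficients.

Replacing the reference reconstruction with an algorithm whose latent quality
advantage is ``b`` while quality gains ``a`` per unit natural-log tube load
permits cutting the tube load by the fraction

    DR = 1 - exp(-b / a)

at equal perceived image quality.  DR is negative when the alternative is
worse (b < 0) and approaches 1 as b/a grows; it requires a > 0 (quality must
improve with dose).  Confidence intervals propagate the uncertainty of the
ratio r = b/a and map its interval through the monotone transform
1 - exp(-r): first-order delta method (default), Fieller's quadratic ratio
interval, or a seeded parametric bootstrap of (a, b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import ModelSpec, VGRFit, fit_fixed, fit_mixed, significance_stars


@dataclass
class DoseReductionEstimate:
    """DR point estimate with confidence interval.

    ``significant`` mirrors the reporting convention of suppressing the DR
    cell when the algorithm coefficient is not significant at 0.05; the
    numeric estimate stays available regardless.
    """

    dr: float
    ci_low: float
    ci_high: float
    level: float
    ci_method: str
    algorithm: str | None = None
    criterion: object = None
    significant: bool | None = None
    unbounded: bool = False

    def as_percent(self) -> tuple[float, float, float]:
        return 100.0 * self.dr, 100.0 * self.ci_low, 100.0 * self.ci_high

    def __str__(self) -> str:
        d, lo, hi = self.as_percent()
        s = f"{d:.0f}% ({lo:.0f}%; {hi:.0f}%)"
        if self.significant is False:
            s += "  [not significant]"
        return s


def dose_reduction(a: float, b: float) -> float:
    """Potential dose-reduction fraction ``1 - exp(-b/a)``.

    Parameters
    ----------
    a : float
        Coefficient for natural-log tube load; must be positive (image
        quality must increase with dose for the trade-off to exist).
    b : float
        Coefficient of the replacement algorithm relative to the reference.
    """
    if not a > 0:
        raise ValueError(
            "dose reduction undefined: the tube-load coefficient a must be "
            "positive (quality must increase with dose)"
        )
    return 1.0 - float(np.exp(-b / a))


def _ratio_moments(fit: VGRFit, algorithm: str) -> tuple[float, float, float, float, float]:
    if fit.a is None:
        raise ValueError("fit has no log-tube-load coefficient")
    if algorithm not in fit.b:
        raise ValueError(f"fit has no coefficient for algorithm {algorithm!r}")
    names = fit.fixed_names
    ia = names.index("log_tube_load")
    ib = names.index(f"algo:{algorithm}")
    a = fit.coef["log_tube_load"]
    b = fit.coef[f"algo:{algorithm}"]
    va = float(fit.cov_fixed[ia, ia])
    vb = float(fit.cov_fixed[ib, ib])
    cab = float(fit.cov_fixed[ia, ib])
    return a, b, va, vb, cab


def dose_reduction_ci(
    fit: VGRFit,
    algorithm: str,
    level: float = 0.95,
    ci_method: str = "delta",
    n_boot: int = 10_000,
    seed: int | None = None,
) -> DoseReductionEstimate:
    """Dose-reduction estimate with confidence interval from a fitted model.

    delta
        First-order variance of r = b/a from the (a, b) covariance; the
        symmetric interval on r maps through the monotone 1 - exp(-r).
    fieller
        Roots of the Fieller quadratic in r; when the denominator a is not
        significantly positive the interval is unbounded and reported as such
        (infinite endpoints), never silently truncated.
    bootstrap
        Parametric resampling of (a, b) from the fitted Gaussian, percentile
        interval on DR; requires ``seed`` for reproducibility.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    a, b, va, vb, cab = _ratio_moments(fit, algorithm)
    if ci_method in ("delta", "fieller") and not a > 0:
        raise ValueError("dose reduction undefined for a <= 0")
    dr = dose_reduction(a, b)
    z = norm.ppf(0.5 + level / 2.0)
    unbounded = False

    if ci_method == "delta":
        r = b / a
        var_r = vb / a**2 + (b**2 / a**4) * va - 2.0 * (b / a**3) * cab
        half = z * np.sqrt(max(var_r, 0.0))
        lo, hi = r - half, r + half
        ci = (1.0 - np.exp(-lo), 1.0 - np.exp(-hi))
    elif ci_method == "fieller":
        # (b - r a)^2 = z^2 (vb - 2 r cab + r^2 va)
        A = a**2 - z**2 * va
        B = -2.0 * (a * b - z**2 * cab)
        C = b**2 - z**2 * vb
        disc = B**2 - 4.0 * A * C
        if A <= 0 or disc < 0:
            unbounded = True
            ci = (-np.inf, np.inf)
        else:
            r1 = (-B - np.sqrt(disc)) / (2.0 * A)
            r2 = (-B + np.sqrt(disc)) / (2.0 * A)
            ci = (1.0 - np.exp(-r1), 1.0 - np.exp(-r2))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        cov = np.array([[va, cab], [cab, vb]])
        draws = rng.multivariate_normal([a, b], cov, size=n_boot)
        ok = draws[:, 0] > 0
        if not ok.any():
            raise ValueError("no bootstrap draws with a > 0")
        drs = 1.0 - np.exp(-draws[ok, 1] / draws[ok, 0])
        alpha = 1.0 - level
        ci = tuple(np.quantile(drs, [alpha / 2.0, 1.0 - alpha / 2.0]))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    p_b = fit.p_values.get(f"algo:{algorithm}", np.nan)
    return DoseReductionEstimate(
        dr=dr,
        ci_low=float(min(ci)),
        ci_high=float(max(ci)),
        level=level,
        ci_method=ci_method,
        algorithm=algorithm,
        criterion=fit.criterion,
        significant=bool(p_b < 0.05) if np.isfinite(p_b) else None,
        unbounded=unbounded,
    )


def dr_table(
    records: pd.DataFrame,
    criteria,
    spec: ModelSpec | None = None,
    mixed: bool = True,
    level: float = 0.95,
    ci_method: str = "delta",
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-criterion coefficients and dose-reduction estimates.

    Fits the VGR model per criterion (mixed by default) on the configured
    dose interval, then reports a, each algorithm coefficient with its
    significance stars, and the DR percentage with confidence limits.
    ``dr_percent`` cells for a non-significant b are suppressed in
    ``dr_display`` (rendered "-") but kept numerically.  Fit failures for one
    criterion are recorded in an ``error`` column without aborting the rest.
    """
    spec = spec or ModelSpec()
    rows = []
    for crit in criteria:
        try:
            fit = (fit_mixed if mixed else fit_fixed)(records, spec, criterion=crit)
        except Exception as exc:  # propagate per criterion, keep going
            rows.append({"criterion": crit, "error": str(exc)})
            continue
        row: dict = {
            "criterion": crit,
            "a": fit.a,
            "a_stars": fit.stars("log_tube_load"),
            "error": "",
        }
        for algo in sorted(fit.b):
            est = dose_reduction_ci(
                fit, algo, level=level, ci_method=ci_method, seed=seed
            )
            d, lo, hi = est.as_percent()
            row[f"b_{algo}"] = fit.b[algo]
            row[f"b_{algo}_stars"] = fit.stars(f"algo:{algo}")
            row[f"dr_{algo}_percent"] = d
            row[f"dr_{algo}_ci_low"] = lo
            row[f"dr_{algo}_ci_high"] = hi
            row[f"dr_{algo}_display"] = (
                f"{d:.0f}% ({lo:.0f}%; {hi:.0f}%)" if est.significant else "-"
            )
        rows.append(row)
    return pd.DataFrame(rows)


def dr_table_from_coefficients(
    coefficients: pd.DataFrame,
    a_col: str = "a",
    b_cols: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Dose-reduction percentages from given (a, b) coefficient columns.

    Bypasses fitting: useful for reproducing published coefficient tables or
    for what-if calculations.  Returns the input with one
    ``dr_<b column>_percent`` column per algorithm coefficient, rounded to
    the nearest integer per cent alongside the exact value.
    """
    out = coefficients.copy()
    if b_cols is None:
        b_cols = tuple(c for c in coefficients.columns
                       if c.startswith("b") and c != a_col)
    for bc in b_cols:
        exact = [
            100.0 * dose_reduction(float(r[a_col]), float(r[bc]))
            for _, r in coefficients.iterrows()
        ]
        out[f"dr_{bc}_percent"] = exact
        out[f"dr_{bc}_rounded"] = [int(np.rint(v)) for v in exact]
    return out


__all__ = [
    "DoseReductionEstimate",
    "dose_reduction",
    "dose_reduction_ci",
    "dr_table",
    "dr_table_from_coefficients",
    "significance_stars",
]
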