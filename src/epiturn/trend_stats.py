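"""Nested cubic-model comparison for proportion-vs-day curves.

H0 explains the proportion by a cubic in the day alone; H1 adds a
genotype main effect and its interactions with every day term:

    H0:  Y ~ X + X^2 + X^3
    H1:  Y ~ (X + X^2 + X^3) * G

Both are ordinary least squares with genotype coded 0/1; the comparison
is the standard extra-sum-of-squares F-test between nested linear models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CubicModelFit:
    """An OLS fit of one of the nested cubic models."""

    coefficients: dict[str, float]
    ssr: float                # residual sum of squares
    df_resid: int
    n: int
    design_columns: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.ssr < -1e-12:
            raise ValueError("SSR must be non-negative")
        self.ssr = max(self.ssr, 0.0)


_H0_COLS = ("Intercept", "X", "X2", "X3")
_H1_COLS = ("Intercept", "X", "X2", "X3", "G", "X:G", "X2:G", "X3:G")


def _design(x: np.ndarray, g: np.ndarray | None) -> np.ndarray:
    cols = [np.ones_like(x), x, x**2, x**3]
    if g is not None:
        cols += [g, x * g, x**2 * g, x**3 * g]
    return np.column_stack(cols)


def _ols(design: np.ndarray, y: np.ndarray, names: tuple[str, ...]) -> CubicModelFit:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ssr = float(resid @ resid)
    return CubicModelFit(
        coefficients=dict(zip(names, map(float, beta))),
        ssr=ssr,
        df_resid=len(y) - design.shape[1],
        n=len(y),
        design_columns=names,
    )


def fit_models(table: pd.DataFrame) -> tuple[CubicModelFit, CubicModelFit]:
    """Fit the nested cubic models to a (Y, X, G) table.

    Genotype is coded 0 for the lexicographically first level and 1 for
    the second; exactly two levels are required for H1.
    """
    required = {"Y", "X", "G"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns {sorted(missing)}")
    y = np.asarray(table["Y"], dtype=float)
    x = np.asarray(table["X"], dtype=float)
    levels = sorted(pd.unique(table["G"]))
    if len(levels) != 2:
        raise ValueError(f"H1 needs exactly two genotypes, got {levels}")
    if len(y) <= len(_H1_COLS):
        raise ValueError(f"need n > {len(_H1_COLS)} observations, got {len(y)}")
    g = (table["G"] == levels[1]).to_numpy(dtype=float)
    fit_h0 = _ols(_design(x, None), y, _H0_COLS)
    fit_h1 = _ols(_design(x, g), y, _H1_COLS)
    return fit_h0, fit_h1


def compare_anova(fit_h0: CubicModelFit, fit_h1: CubicModelFit) -> tuple[float, float]:
    """Extra-sum-of-squares F-test of H1 against H0.

    F = ((SSR0 - SSR1) / (df0 - df1)) / (SSR1 / df1), with the p-value
    from F(df0 - df1, df1).
    """
    if fit_h0.n != fit_h1.n:
        raise ValueError("fits are not on the same data (n differs)")
    if not set(fit_h0.design_columns) < set(fit_h1.design_columns):
        raise ValueError("fits are not nested")
    df_diff = fit_h0.df_resid - fit_h1.df_resid
    if df_diff <= 0 or fit_h1.df_resid <= 0:
        raise ValueError("invalid degrees of freedom for the comparison")
    num = max(fit_h0.ssr - fit_h1.ssr, 0.0) / df_diff
    den = fit_h1.ssr / fit_h1.df_resid
    if den == 0.0:
        return float("inf"), 0.0
    f = num / den
    p = float(stats.f.sf(f, df_diff, fit_h1.df_resid))
    return float(f), p
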