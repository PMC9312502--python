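"""Correlation suites linking indices to measured irrigation and fluxes.

Spearman/Pearson correlation matrices with two-sided p-values and
pairwise-complete missing-value handling, ordinary-least-squares R², a
univariate variance-explained reduction of distance-based redundancy
analysis (for a univariate response with Euclidean distance, dbRDA is OLS,
so the statistic is 100·R²), and per-analyte flux associations.

For small samples (n ≤ 9) the Spearman p-value is computed exactly by
enumerating all n! rank permutations; the usual t-approximation is reported
alongside.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EXACT_P_MAX_N = 9


def spearman_exact_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided permutation p for Spearman's ρ (n ≤ 9).

    Enumerates all n! permutations of the y midranks against the fixed x
    midranks; p is the fraction of permutations whose |ρ| is at least the
    observed |ρ| (ties in ρ counted as extreme).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have the same length")
    if n > EXACT_P_MAX_N:
        raise ValueError(f"exact enumeration limited to n <= {EXACT_P_MAX_N}")
    if n < 2:
        raise ValueError("need n >= 2")
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    sx = xr.std()
    sy = yr.std()
    if sx == 0 or sy == 0:
        raise ValueError("constant variable: Spearman undefined")

    def rho_of(yperm: np.ndarray) -> np.ndarray:
        # Pearson correlation of midranks, vectorised over permutations
        return ((yperm * xr).mean(axis=-1) - xr.mean() * yr.mean()) / (sx * sy)

    obs = float(rho_of(yr[None, :])[0])
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.int8)
    rhos = rho_of(yr[perms])
    return float(np.mean(np.abs(rhos) >= abs(obs) - 1e-12))


@dataclass
class CorrelationMatrix:
    """Symmetric correlation matrix with p-values and per-pair n."""

    variables: list[str]
    coefficients: pd.DataFrame
    pvalues: pd.DataFrame
    n: pd.DataFrame
    method: str
    exact_pvalues: pd.DataFrame | None = None

    def matrix_layout(self) -> pd.DataFrame:
        """Mixed table: coefficients above the diagonal, p-values below."""
        out = self.coefficients.copy()
        for i, a in enumerate(self.variables):
            for j, b in enumerate(self.variables):
                if i > j:
                    out.loc[a, b] = self.pvalues.loc[a, b]
                elif i == j:
                    out.loc[a, b] = np.nan
        return out


def corr_matrix(
    table: pd.DataFrame,
    method: str = "spearman",
    exact_small_n: bool = True,
) -> CorrelationMatrix:
    """Correlation matrix over the columns of ``table``.

    Missing values are handled pairwise-complete; each cell needs at least
    3 complete pairs.  A constant variable leaves its cells undefined (NaN),
    reported as missing rather than 0.  Spearman uses midranks for ties;
    with ``exact_small_n`` cells with n ≤ 9 additionally carry an exact
    permutation p-value.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    cols = list(table.columns)
    k = len(cols)
    coef = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pval = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    nmat = pd.DataFrame(np.zeros((k, k), dtype=int), index=cols, columns=cols)
    exact = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    has_exact = False
    np.fill_diagonal(pval.values, 0.0)
    for a, b in itertools.combinations(cols, 2):
        pair = table[[a, b]].dropna()
        n = len(pair)
        nmat.loc[a, b] = nmat.loc[b, a] = n
        if n < 3:
            coef.loc[a, b] = coef.loc[b, a] = np.nan
            continue
        x = pair[a].to_numpy(dtype=float)
        y = pair[b].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            coef.loc[a, b] = coef.loc[b, a] = np.nan
            continue
        if method == "spearman":
            r, p = stats.spearmanr(x, y)
            if exact_small_n and n <= EXACT_P_MAX_N:
                exact.loc[a, b] = exact.loc[b, a] = spearman_exact_p(x, y)
                has_exact = True
        else:
            r, p = stats.pearsonr(x, y)
        coef.loc[a, b] = coef.loc[b, a] = float(r)
        pval.loc[a, b] = pval.loc[b, a] = float(p)
    return CorrelationMatrix(
        variables=cols,
        coefficients=coef,
        pvalues=pval,
        n=nmat,
        method=method,
        exact_pvalues=exact if has_exact else None,
    )


@dataclass
class LinearFit:
    r2: float
    slope: float
    intercept: float
    pvalue: float
    n: int


def linear_r2(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary-least-squares fit of y on x; R² is the squared Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.all(x == x[0]):
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return LinearFit(
        r2=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        pvalue=float(res.pvalue),
        n=int(x.size),
    )


def variance_explained(predictor: Sequence[float], response: Sequence[float]) -> float:
    """% of response variance explained by one predictor (OLS).

    For a univariate response under Euclidean distance this coincides with
    the constrained fraction of a distance-based redundancy analysis.
    """
    return 100.0 * linear_r2(predictor, response).r2


def flux_association(
    index_by_station: Mapping[str, float],
    fluxes: pd.DataFrame,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Spearman association of an index with per-analyte solute effluxes.

    ``fluxes`` is long format with columns ``station, analyte, value``;
    repeated visits per station are aggregated by ``"mean"`` or ``"max"``
    (or kept as-is with ``None``, pairing each visit with its station's
    index).  Analytes with fewer than 3 matched stations are skipped with a
    warning row (rho and p NaN).
    """
    for col in ("station", "analyte", "value"):
        if col not in fluxes.columns:
            raise ValueError(f"flux table is missing column {col!r}")
    if aggregate is not None:
        if aggregate not in ("mean", "max"):
            raise ValueError("aggregate must be 'mean', 'max' or None")
        fluxes = (
            fluxes.groupby(["station", "analyte"], as_index=False)["value"]
            .agg(aggregate)
        )
    rows = []
    for analyte, grp in fluxes.groupby("analyte", sort=True):
        matched = grp[grp["station"].astype(str).isin(index_by_station)]
        n = len(matched)
        if n < 3:
            rows.append(
                {"analyte": analyte, "rho": np.nan, "p": np.nan, "n": n,
                 "significant": False,
                 "warning": "fewer than 3 matched stations; skipped"}
            )
            continue
        idx = [index_by_station[str(s)] for s in matched["station"]]
        rho, p = stats.spearmanr(idx, matched["value"].to_numpy(dtype=float))
        rows.append(
            {"analyte": analyte, "rho": float(rho), "p": float(p), "n": n,
             "significant": bool(p < 0.05), "warning": ""}
        )
    return pd.DataFrame(rows)
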