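"""Multiple imputation by chained equations and Rubin's-rules pooling.

Assuming data are missing at random, each variable with missing cells is
imputed from a conditional model given all other variables, cycling through
the variables (in ascending order of missingness) for a fixed number of
sweeps, independently for each of M chains.  Draws are "approximate proper":
the conditional model's coefficients are perturbed by a draw from their
estimated sampling covariance, and for continuous variables the residual
variance is drawn from its scaled inverse chi-square before adding residual
noise.  Declared conditional families:

* ``continuous`` — normal linear model (OLS), sigma^2 ~ RSS / chi2(n-p),
  beta* ~ N(beta_hat, sigma*^2 (X'X)^-1), y* = X beta* + N(0, sigma*);
* ``binary`` — logistic model, beta* ~ N(beta_hat, Cov_hat), Bernoulli draw;
* ``categorical`` — multinomial logit, analogous perturbed draw.

If a binary/multinomial conditional fit fails (e.g. perfect separation in a
sparse chain), that sweep falls back to an observed-margin draw for the
affected variable.

Pooling: for M completed-data estimates Q_m with variances U_m, Rubin's rules
give Qbar = mean(Q), Ubar = mean(U), B = var(Q) (sample variance),
T = Ubar + (1 + 1/M) B, with large-sample df (M-1)(1 + Ubar/((1+1/M)B))^2
(infinite when B = 0) and a t-based 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["ImputationSet", "PooledEstimate", "mice", "rubin_pool"]

_FAMILIES = ("continuous", "binary", "categorical")


@dataclass
class ImputationSet:
    """M completed copies of an analysis table plus provenance."""

    datasets: list[pd.DataFrame]
    types: dict[str, str]
    n_iter: int
    seed: int

    @property
    def m(self) -> int:
        return len(self.datasets)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        import json

        for i, df in enumerate(self.datasets):
            df.to_csv(outdir / f"imputed_{i:02d}.csv")
        (outdir / "manifest.json").write_text(
            json.dumps(
                {"m": self.m, "n_iter": self.n_iter, "seed": self.seed, "types": self.types},
                indent=2,
                sort_keys=True,
            )
        )


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of M completed-data estimates."""

    estimate: float  # Qbar
    within_var: float  # Ubar
    between_var: float  # B
    total_var: float  # T = Ubar + (1 + 1/M) B
    df: float
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        se = np.sqrt(self.total_var)
        tq = stats.norm.ppf(0.975) if np.isinf(self.df) else stats.t.ppf(0.975, self.df)
        self.ci_low = self.estimate - tq * se
        self.ci_high = self.estimate + tq * se


def rubin_pool(estimates: Sequence[float], variances: Sequence[float]) -> PooledEstimate:
    """Pool M point estimates and their (within-imputation) variances."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.ndim != 1 or q.shape != u.shape:
        raise ValueError("estimates and variances must be equal-length 1-d vectors")
    m = len(q)
    if m < 2:
        raise ValueError("Rubin pooling requires M >= 2 imputations")
    qbar = float(q.mean())
    ubar = float(u.mean())
    b = float(q.var(ddof=1))
    t = ubar + (1 + 1 / m) * b
    df = float("inf") if b == 0 else (m - 1) * (1 + ubar / ((1 + 1 / m) * b)) ** 2
    return PooledEstimate(qbar, ubar, b, t, df)


def _predictor_matrix(df: pd.DataFrame, exclude: str, types: Mapping[str, str]) -> np.ndarray:
    """Numeric predictor matrix (intercept + all other variables, categoricals one-hot)."""
    cols = [np.ones(len(df))]
    for name in df.columns:
        if name == exclude:
            continue
        if types.get(name) == "categorical":
            series = df[name]
            levels = sorted(series.dropna().unique())
            for lv in levels[1:]:
                cols.append((series == lv).to_numpy(dtype=float))
        else:
            cols.append(df[name].to_numpy(dtype=float))
    return np.column_stack(cols)


def _perturbed_params(params: np.ndarray, cov: np.ndarray, rng) -> np.ndarray:
    cov = np.atleast_2d(cov)
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(cov)))
    except np.linalg.LinAlgError:
        return params
    return params + chol @ rng.standard_normal(len(params))


def _draw_continuous(yobs, Xobs, Xmis, rng):
    n, p = Xobs.shape
    beta, *_ = np.linalg.lstsq(Xobs, yobs, rcond=None)
    resid = yobs - Xobs @ beta
    dof = max(n - p, 1)
    sigma2_star = float(resid @ resid) / stats.chi2.rvs(dof, random_state=rng)
    xtx_inv = np.linalg.pinv(Xobs.T @ Xobs)
    beta_star = _perturbed_params(beta, sigma2_star * xtx_inv, rng)
    return Xmis @ beta_star + np.sqrt(sigma2_star) * rng.standard_normal(len(Xmis))


def _draw_binary(yobs, Xobs, Xmis, rng):
    if len(np.unique(yobs)) < 2:
        p = float(np.mean(yobs))
        return (rng.random(len(Xmis)) < p).astype(float)
    try:
        res = sm.Logit(yobs, Xobs).fit(disp=0, maxiter=100)
        beta_star = _perturbed_params(np.asarray(res.params), np.asarray(res.cov_params()), rng)
        eta = np.clip(Xmis @ beta_star, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
    except Exception:  # separation / singular fit: observed-margin fallback
        p = float(np.mean(yobs))
    return (rng.random(len(Xmis)) < p).astype(float)


def _draw_categorical(yobs, Xobs, Xmis, rng):
    levels = np.array(sorted(np.unique(yobs)))
    if len(levels) < 2:
        return np.full(len(Xmis), levels[0], dtype=float)
    codes = np.searchsorted(levels, yobs)
    try:
        res = sm.MNLogit(codes, Xobs).fit(disp=0, maxiter=100, method="newton")
        params = np.asarray(res.params)  # p x (L-1)
        flat = _perturbed_params(params.ravel(order="F"), np.asarray(res.cov_params()), rng)
        params = flat.reshape(params.shape, order="F")
        eta = np.column_stack([np.zeros(len(Xmis)), Xmis @ params])
        eta = np.clip(eta - eta.max(axis=1, keepdims=True), -700, 0)
        probs = np.exp(eta)
        probs /= probs.sum(axis=1, keepdims=True)
    except Exception:
        freqs = np.bincount(codes, minlength=len(levels)) / len(codes)
        probs = np.tile(freqs, (len(Xmis), 1))
    u = rng.random(len(Xmis))
    drawn = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return levels[np.clip(drawn, 0, len(levels) - 1)].astype(float)


_DRAWERS = {"continuous": _draw_continuous, "binary": _draw_binary, "categorical": _draw_categorical}


def mice(
    table: pd.DataFrame,
    types: Mapping[str, str],
    m: int = 20,
    n_iter: int = 10,
    seed: int = 0,
) -> ImputationSet:
    """Chained-equations multiple imputation of ``table``.

    ``types`` declares the conditional family for every column with missing
    cells.  Requires at least one fully observed column.  Deterministic given
    (seed, m, n_iter); observed cells are never altered.
    """
    table = table.copy()
    miss_frac = table.isna().mean()
    with_missing = [c for c in table.columns if miss_frac[c] > 0]
    for col in with_missing:
        if miss_frac[col] >= 1.0:
            raise ValueError(f"variable {col!r} is 100% missing and cannot be imputed")
        if col not in types:
            raise ValueError(f"variable {col!r} has missing cells but no declared type")
        if types[col] not in _FAMILIES:
            raise ValueError(f"variable {col!r}: unknown type {types[col]!r} (use {_FAMILIES})")
    if not any(miss_frac[c] == 0 for c in table.columns):
        raise ValueError("chained equations need at least one fully observed variable")
    if not with_missing:
        return ImputationSet([table.copy() for _ in range(m)], dict(types), n_iter, seed)

    order = sorted(with_missing, key=lambda c: (miss_frac[c], c))  # ascending missingness
    masks = {c: table[c].isna().to_numpy() for c in with_missing}
    root = np.random.default_rng(seed)
    chain_seeds = root.integers(0, 2**31 - 1, size=m)
    datasets = []
    for chain in range(m):
        rng = np.random.default_rng(chain_seeds[chain])
        df = table.copy()
        # initial fill: random draws from each variable's observed values
        for col in order:
            obs = df[col].dropna().to_numpy()
            df.loc[masks[col], col] = rng.choice(obs, size=masks[col].sum(), replace=True)
        for _ in range(n_iter):
            for col in order:
                mask = masks[col]
                X = _predictor_matrix(df, exclude=col, types=types)
                yobs = df.loc[~mask, col].to_numpy(dtype=float)
                drawn = _DRAWERS[types[col]](yobs, X[~mask], X[mask], rng)
                df.loc[mask, col] = drawn
        datasets.append(df)
    return ImputationSet(datasets, dict(types), n_iter, seed)
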