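"""Longitudinal latent class analysis of a binary activity panel.

The model: person i belongs to one of K latent trajectory classes with prior
probabilities pi_k; given the class, the wave indicators y_it in {0, 1} are
independent Bernoulli with class- and wave-specific success probabilities
rho[k, t] (local independence).  Persons with missing waves contribute
likelihood factors only for the waves they were observed at (full-information
maximum likelihood under MAR):

    L_i = sum_k pi_k  prod_{t observed}  rho[k,t]^y_it (1 - rho[k,t])^(1-y_it)

Estimation is by EM with multiple seeded random restarts.  Internally the
panel is collapsed to its distinct response patterns (at most 3^T of them),
so a fit costs the same for n = 500 and n = 500,000.

Label switching is resolved by :func:`order_classes`: classes are sorted by
descending mean response probability across waves, so the most-active class
("always active") is always class 1 and can serve as a stable regression
baseline.

The public surface follows the statsmodels Model/Results convention::

    model = LatentClassModel(panel, k_classes=4)
    res = model.fit(seed=0)
    res.summary()
    post = res.predict_posterior()
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .simulate import PAPanel

__all__ = [
    "LatentClassModel",
    "LatentClassResults",
    "loglik",
    "em_fit",
    "posterior",
    "order_classes",
    "select_model",
]

RHO_FLOOR = 1e-6  # boundary clamp on response probabilities


def _collapse(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Collapse an n x T {0,1,nan} array to unique patterns with counts.

    Returns (Y, M, w, inverse): Y the pattern values with missing coded 0,
    M the observed-mask, w the pattern counts, inverse mapping rows->patterns.
    """
    if np.isnan(y).all(axis=1).any():
        raise ValueError("panel contains a person with all waves missing; exclude upstream")
    codes = np.where(np.isnan(y), 2, y).astype(np.int8)
    patterns, inverse, counts = np.unique(codes, axis=0, return_inverse=True, return_counts=True)
    M = (patterns != 2).astype(float)
    Y = np.where(patterns == 2, 0, patterns).astype(float)
    return Y, M, counts.astype(float), inverse


def _pattern_loglik(pi, rho, Y, M):
    """Per-pattern log of sum_k pi_k * prod_t(observed) Bernoulli terms; also per-class part."""
    lr, l1r = np.log(rho), np.log1p(-rho)
    per_class = (Y * M) @ lr.T + ((1 - Y) * M) @ l1r.T + np.log(pi)[None, :]
    return logsumexp(per_class, axis=1), per_class


def loglik(pi: np.ndarray, rho: np.ndarray, panel: PAPanel | np.ndarray) -> float:
    """FIML log-likelihood of (pi, rho) on a panel (missing waves skipped)."""
    y = panel.data.to_numpy(dtype=float) if isinstance(panel, PAPanel) else np.asarray(panel, float)
    pi = np.asarray(pi, dtype=float)
    rho = np.clip(np.atleast_2d(np.asarray(rho, dtype=float)), RHO_FLOOR, 1 - RHO_FLOOR)
    Y, M, w, _ = _collapse(y)
    lse, _ = _pattern_loglik(pi, rho, Y, M)
    return float(w @ lse)


@dataclass
class LatentClassResults:
    """Fitted latent class model: estimates, fit statistics, posteriors."""

    model: "LatentClassModel"
    k_classes: int
    class_probs: np.ndarray  # pi, shape (K,)
    response_probs: np.ndarray  # rho, shape (K, T)
    llf: float
    converged: bool
    n_iter: int
    n_starts: int
    loglik_path: np.ndarray = field(repr=False)  # per-iteration loglik of the winning start

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def df_model(self) -> int:
        """Free parameters: (K-1) mixing weights + K*T response probabilities."""
        return (self.k_classes - 1) + self.k_classes * self.response_probs.shape[1]

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.df_model

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.df_model * np.log(self.nobs)

    @property
    def relative_entropy(self) -> float:
        """1 - mean posterior entropy / ln K; 1 = perfectly crisp assignment."""
        if self.k_classes == 1:
            return 1.0
        post = self.predict_posterior().iloc[:, : self.k_classes].to_numpy()
        with np.errstate(invalid="ignore"):
            ent = -np.nansum(post * np.log(np.clip(post, 1e-300, None)))
        return 1.0 - ent / (self.nobs * np.log(self.k_classes))

    def predict_posterior(self) -> pd.DataFrame:
        """Per-person class posteriors, modal class (ties -> lower index) and max posterior."""
        Y, M, _, inverse = _collapse(self.model.endog)
        _, per_class = _pattern_loglik(self.class_probs, self.response_probs, Y, M)
        post = np.exp(per_class - logsumexp(per_class, axis=1, keepdims=True))[inverse]
        out = pd.DataFrame(
            post,
            index=self.model.person_ids,
            columns=[f"p_class{k + 1}" for k in range(self.k_classes)],
        )
        out["modal_class"] = post.argmax(axis=1) + 1  # argmax ties -> lowest index
        out["max_posterior"] = post.max(axis=1)
        return out

    def ordered(self) -> "LatentClassResults":
        """Canonical label order: classes sorted by descending mean rho (stable)."""
        key = -self.response_probs.mean(axis=1)
        perm = np.argsort(key, kind="stable")
        return LatentClassResults(
            model=self.model,
            k_classes=self.k_classes,
            class_probs=self.class_probs[perm].copy(),
            response_probs=self.response_probs[perm].copy(),
            llf=self.llf,
            converged=self.converged,
            n_iter=self.n_iter,
            n_starts=self.n_starts,
            loglik_path=self.loglik_path,
        )

    def summary(self) -> str:
        ages = self.model.wave_ages
        lines = [
            "Latent class model (binary indicators, local independence, FIML)",
            f"  n = {self.nobs}, waves = {ages}, K = {self.k_classes}",
            f"  log-likelihood = {self.llf:.4f}   AIC = {self.aic:.2f}   BIC = {self.bic:.2f}",
            f"  relative entropy = {self.relative_entropy:.4f}"
            f"   converged = {self.converged} (iter {self.n_iter}, {self.n_starts} starts)",
            "  class  pi      " + "  ".join(f"rho(age {a})" for a in ages),
        ]
        for k in range(self.k_classes):
            rho_str = "  ".join(f"{v:10.4f}" for v in self.response_probs[k])
            lines.append(f"  {k + 1:5d}  {self.class_probs[k]:.4f}  {rho_str}")
        return "\n".join(lines)


class LatentClassModel:
    """Latent class (binary mixture) model for a PA panel.

    Parameters
    ----------
    panel : PAPanel or array-like
        n x T matrix of 0/1/NaN indicators.  Persons with no observed wave
        are excluded with a warning (their count is recorded in
        ``n_excluded``).
    k_classes : int
        Number of latent classes, K >= 1.
    wave_ages : sequence of int, optional
        Labels for the waves (taken from the panel when given one).
    """

    def __init__(self, panel: PAPanel | np.ndarray, k_classes: int, wave_ages=None):
        if k_classes < 1:
            raise ValueError("k_classes must be >= 1")
        if isinstance(panel, PAPanel):
            panel, n_dropped = panel.drop_all_missing()
            y = panel.data.to_numpy(dtype=float)
            self.person_ids = panel.data.index
            self.wave_ages = panel.wave_ages
        else:
            y = np.asarray(panel, dtype=float)
            keep = ~np.isnan(y).all(axis=1)
            n_dropped = int((~keep).sum())
            y = y[keep]
            self.person_ids = pd.RangeIndex(len(y))
            self.wave_ages = list(wave_ages) if wave_ages is not None else list(range(y.shape[1]))
        if n_dropped:
            warnings.warn(f"excluded {n_dropped} person(s) with no observed wave", stacklevel=2)
        self.n_excluded = n_dropped
        if y.shape[0] == 0 or y.shape[1] == 0:
            raise ValueError("empty panel")
        self.endog = y
        self.k_classes = int(k_classes)
        self._Y, self._M, self._w, self._inverse = _collapse(y)
        if self.k_classes > len(self._w):
            warnings.warn(
                f"K={self.k_classes} exceeds the {len(self._w)} distinct observed response "
                "patterns; the model may not be identified",
                stacklevel=2,
            )

    @property
    def nobs(self) -> int:
        return self.endog.shape[0]

    @classmethod
    def from_long(cls, path, k_classes: int, ages=None) -> "LatentClassModel":
        """Build from a long-format CSV (person_id, age, active01; empty = missing)."""
        panel = PAPanel.from_long(path)
        if ages is not None:
            panel = panel.subset_ages(ages)
        return cls(panel, k_classes)

    # -- EM ----------------------------------------------------------------
    def _em_once(self, pi, rho, tol, max_iter):
        Y, M, w = self._Y, self._M, self._w
        n = w.sum()
        path = []
        prev = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            lse, per_class = _pattern_loglik(pi, rho, Y, M)
            ll = float(w @ lse)
            path.append(ll)
            # E-step
            R = np.exp(per_class - lse[:, None]) * w[:, None]  # pattern x K responsibilities
            # M-step
            pi = R.sum(axis=0) / n
            denom = R.T @ M
            num = R.T @ (Y * M)
            with np.errstate(invalid="ignore", divide="ignore"):
                rho = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.5)
            rho = np.clip(rho, RHO_FLOOR, 1 - RHO_FLOOR)
            pi = np.clip(pi, 1e-12, None)
            pi = pi / pi.sum()
            if ll - prev < tol * max(1.0, abs(ll)) and it > 1:
                converged = True
                break
            prev = ll
        ll_final = loglik_patterns = float(self._w @ _pattern_loglik(pi, rho, Y, M)[0])
        path.append(loglik_patterns)
        return pi, rho, ll_final, converged, it, np.asarray(path)

    def fit(
        self,
        n_starts: int = 20,
        tol: float = 1e-8,
        max_iter: int = 1000,
        seed: int | None = 0,
        sort_classes: bool = True,
    ) -> LatentClassResults:
        """EM from ``n_starts`` seeded random initializations; best fit returned.

        Initialization: pi from a flat Dirichlet draw, rho uniform in
        [0.2, 0.8].  Convergence when the relative log-likelihood change
        drops below ``tol``.  K = 1 is a closed form (observed per-wave
        proportions) and skips EM.
        """
        K, T = self.k_classes, self._Y.shape[1]
        if K == 1:
            denom = self._w @ self._M
            num = self._w @ (self._Y * self._M)
            rho = np.clip(num / denom, RHO_FLOOR, 1 - RHO_FLOOR)[None, :]
            pi = np.ones(1)
            ll = loglik(pi, rho, self.endog)
            return LatentClassResults(self, 1, pi, rho, ll, True, 0, 1, np.array([ll]))
        rng = np.random.default_rng(seed)
        best = None
        for _ in range(n_starts):
            pi0 = rng.dirichlet(np.ones(K))
            rho0 = rng.uniform(0.2, 0.8, size=(K, T))
            fitres = self._em_once(pi0, rho0, tol, max_iter)
            if best is None or fitres[2] > best[2]:
                best = fitres
        pi, rho, ll, converged, n_iter, path = best
        if not converged:
            warnings.warn("EM did not converge; best iterate returned", stacklevel=2)
        res = LatentClassResults(self, K, pi, rho, ll, converged, n_iter, n_starts, path)
        return res.ordered() if sort_classes else res


# -- thin functional wrappers (the operation-level API) ---------------------


def em_fit(
    panel: PAPanel | np.ndarray,
    k_classes: int,
    n_starts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int | None = 0,
    sort_classes: bool = True,
) -> LatentClassResults:
    return LatentClassModel(panel, k_classes).fit(
        n_starts=n_starts, tol=tol, max_iter=max_iter, seed=seed, sort_classes=sort_classes
    )


def posterior(results: LatentClassResults) -> pd.DataFrame:
    return results.predict_posterior()


def order_classes(results: LatentClassResults) -> LatentClassResults:
    return results.ordered()


def select_model(
    panel: PAPanel | np.ndarray,
    k_range=range(2, 7),
    n_starts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int | None = 0,
) -> tuple[pd.DataFrame, int, dict[int, LatentClassResults]]:
    """Fit a range of K and tabulate fit indices.

    Returns (fit table, K minimizing BIC, per-K results).  The BIC choice is
    a reported default, never silently applied downstream.
    """
    rows, fits = [], {}
    for K in k_range:
        res = LatentClassModel(panel, K).fit(n_starts=n_starts, tol=tol, max_iter=max_iter, seed=seed)
        fits[K] = res
        rows.append(
            {
                "K": K,
                "loglik": res.llf,
                "n_params": res.df_model,
                "AIC": res.aic,
                "BIC": res.bic,
                "relative_entropy": res.relative_entropy,
                "converged": res.converged,
            }
        )
    table = pd.DataFrame(rows).set_index("K")
    chosen = int(table["BIC"].idxmin())
    return table, chosen, fits
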