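"""Inferential stage: per-wave odds ratios, trajectory-class relative risk
ratios and descriptive statistics.

Two families of models mirror the study design:

* per-wave logistic regressions of the binary adult activity indicator on the
  two childhood PAI indicators plus childhood controls — reported as odds
  ratios (OR) with Wald 95% CIs;
* "two-step" multinomial logistic regression of the modal latent trajectory
  class (from :mod:`paitraj.lca`) on PAI plus controls, with the most-active
  class ("always active") as baseline — reported as relative risk ratios
  (RRR), i.e. exponentiated multinomial-logit coefficients.

Both are maximum-likelihood fits via statsmodels (Newton iterations); CIs are
Wald intervals, symmetric on the log scale.  Three model tags are produced:
``univariate`` (PAI only), ``fully_adjusted`` (all controls including
self-reported childhood activity) and ``excl_child_pa``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .lca import LatentClassModel, LatentClassResults
from .simulate import PAPanel

__all__ = [
    "RegressionResult",
    "SeparationError",
    "build_design",
    "fit_logistic",
    "fit_multinomial",
    "two_step",
    "descriptives",
    "proportion_ci",
    "two_proportion_chisq",
    "spearman",
    "CONTROL_COLUMNS",
]

Z975 = stats.norm.ppf(0.975)

#: childhood controls entering the adjusted models (categorical ones expanded)
CONTROL_COLUMNS = (
    "birthweight",
    "mother_smoked",
    "father_social_class",
    "childhood_bmi",
    "enuresis",
    "poor_coordination",
    "bsag_score",
    "rutter_score",
    "general_ability",
    "days_off_school",
    "hospital_admissions",
)
CATEGORICAL_CONTROLS = ("father_social_class",)


class SeparationError(RuntimeError):
    """Raised when a covariate perfectly separates the outcome."""


@dataclass
class RegressionResult:
    """A fitted (multinomial) logistic regression in tidy form.

    ``table`` has one row per (outcome class,) term: coefficient, SE,
    exponentiated effect (OR or RRR) and Wald 95% CI.
    """

    model_tag: str
    table: pd.DataFrame
    nobs: int
    converged: bool
    llf: float

    def effects(self, term: str) -> pd.DataFrame:
        return self.table[self.table["term"] == term]

    def summary(self) -> str:
        head = f"{self.model_tag}: n={self.nobs}, loglik={self.llf:.3f}, converged={self.converged}"
        return head + "\n" + self.table.to_string(index=False, float_format=lambda v: f"{v:.4f}")


def build_design(
    covariates: pd.DataFrame,
    terms: tuple[str, ...],
    add_intercept: bool = True,
) -> pd.DataFrame:
    """Design matrix from a covariate table.

    Categorical controls enter as indicator contrasts with the most frequent
    category as reference; everything else enters linearly.
    """
    cols: dict[str, np.ndarray] = {}
    if add_intercept:
        cols["intercept"] = np.ones(len(covariates))
    for name in terms:
        if name in CATEGORICAL_CONTROLS:
            series = covariates[name]
            ref = series.value_counts().idxmax()
            for level in sorted(series.unique()):
                if level == ref:
                    continue
                cols[f"{name}_{int(level)}"] = (series == level).to_numpy(dtype=float)
        else:
            cols[name] = covariates[name].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=covariates.index)


def _check_design(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("design matrix contains missing values; complete the data first")
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear or duplicated columns)")


def _find_separating_column(y: np.ndarray, X: pd.DataFrame) -> str | None:
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        if len(np.unique(x)) < 2:
            continue
        lo1, hi0 = x[y == 1].min(initial=np.inf), x[y == 0].max(initial=-np.inf)
        lo0, hi1 = x[y == 0].min(initial=np.inf), x[y == 1].max(initial=-np.inf)
        if lo1 > hi0 or lo0 > hi1:
            return col
    return None


def _wald_table(terms, coefs, ses, pvals, effect_name) -> pd.DataFrame:
    coefs, ses = np.asarray(coefs, float), np.asarray(ses, float)
    return pd.DataFrame(
        {
            "term": terms,
            "coef": coefs,
            "se": ses,
            effect_name: np.exp(coefs),
            "ci_low": np.exp(coefs - Z975 * ses),
            "ci_high": np.exp(coefs + Z975 * ses),
            "p": pvals,
        }
    )


def fit_logistic(y, X: pd.DataFrame, model_tag: str = "logistic") -> RegressionResult:
    """Binary logistic regression with Wald 95% CIs on the OR scale."""
    y = np.asarray(y, dtype=float)
    _check_design(X)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(method="newton", maxiter=200, tol=1e-12, disp=0)
        except Exception as exc:  # complete separation or numerical blow-up
            col = _find_separating_column(y.astype(int), X)
            hint = f" (column {col!r} separates the outcome)" if col else ""
            raise SeparationError(f"logistic fit failed{hint}: {exc}") from exc
    if np.abs(res.params).max() > 30:
        col = _find_separating_column(y.astype(int), X)
        raise SeparationError(
            f"apparent complete separation (column {col!r})" if col else "apparent complete separation"
        )
    table = _wald_table(list(X.columns), res.params, res.bse, np.asarray(res.pvalues), "or")
    return RegressionResult(model_tag, table, int(res.nobs), bool(res.mle_retvals["converged"]), float(res.llf))


def fit_multinomial(
    classes, X: pd.DataFrame, baseline=None, model_tag: str = "multinomial"
) -> RegressionResult:
    """Multinomial logistic regression; RRRs relative to ``baseline``.

    ``classes`` is a categorical vector; ``baseline`` defaults to its
    smallest value (class 1 = "always active" after canonical ordering).
    Baseline-class coefficients are fixed at 0 and not reported.
    """
    classes = pd.Series(np.asarray(classes), index=X.index)
    levels = sorted(classes.unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 outcome classes present")
    baseline = levels[0] if baseline is None else baseline
    if baseline not in levels:
        raise ValueError(f"baseline class {baseline!r} not present in the data")
    counts = classes.value_counts()
    if (counts == 0).any():
        raise ValueError("empty outcome class")
    nonbase = [lv for lv in levels if lv != baseline]
    codes = classes.map({baseline: 0, **{lv: j + 1 for j, lv in enumerate(nonbase)}}).to_numpy()
    _check_design(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.MNLogit(codes, X).fit(method="newton", maxiter=500, tol=1e-10, disp=0)
    if np.abs(np.asarray(res.params)).max() > 30:
        raise SeparationError("apparent separation in multinomial fit")
    params = np.asarray(res.params)  # k_vars x (K-1)
    bses = np.asarray(res.bse)
    pvals = np.asarray(res.pvalues)
    tables = []
    for j, lv in enumerate(nonbase):
        tab = _wald_table(list(X.columns), params[:, j], bses[:, j], pvals[:, j], "rrr")
        tab.insert(0, "outcome_class", lv)
        tables.append(tab)
    table = pd.concat(tables, ignore_index=True)
    return RegressionResult(model_tag, table, int(res.nobs), bool(res.mle_retvals["converged"]), float(res.llf))


def two_step(
    panel: PAPanel,
    pai: pd.DataFrame,
    controls: pd.DataFrame,
    k_classes: int = 4,
    trajectory_ages=(33, 42, 50, 55),
    by_sex: bool = True,
    n_starts: int = 20,
    seed: int = 0,
    class_labels: dict[int, str] | None = None,
) -> dict:
    """LCA then multinomial regression of modal class on PAI (+ controls).

    Step 1 fits the latent class model per sex on the trajectory waves,
    canonically ordered so class 1 is the most-active ("always active")
    baseline.  Step 2 treats the modal class as an observed outcome and fits
    the three tagged multinomial models.

    Returns ``{sex: {"lca": LatentClassResults, "modal": Series,
    "models": {tag: RegressionResult}}}``.
    """
    out: dict = {}
    groups = ("male", "female") if by_sex else ("all",)
    for sex in groups:
        sub = panel.subset_sex(sex) if by_sex else panel
        sub = sub.subset_ages(trajectory_ages)
        res: LatentClassResults = LatentClassModel(sub, k_classes).fit(n_starts=n_starts, seed=seed)
        post = res.predict_posterior()
        modal = post["modal_class"]
        ids = modal.index.intersection(pai.index).intersection(controls.index)
        modal = modal.loc[ids]
        pai_sub, ctrl_sub = pai.loc[ids], controls.loc[ids]
        designs = {
            "univariate": build_design(pai_sub.join(ctrl_sub), ("active01", "spectator01")),
            "fully_adjusted": build_design(
                pai_sub.join(ctrl_sub), ("active01", "spectator01", "child_pa") + CONTROL_COLUMNS
            ),
            "excl_child_pa": build_design(
                pai_sub.join(ctrl_sub), ("active01", "spectator01") + CONTROL_COLUMNS
            ),
        }
        models = {
            tag: fit_multinomial(modal, X, baseline=1, model_tag=f"{tag}[{sex}]")
            for tag, X in designs.items()
        }
        if class_labels:
            for m in models.values():
                m.table["outcome_class"] = m.table["outcome_class"].map(class_labels)
        out[sex] = {"lca": res, "modal": modal, "models": models}
    return out


# -- descriptive statistics -------------------------------------------------


def proportion_ci(x) -> tuple[float, float, float]:
    """Sample proportion with Wald 95% CI (clipped to [0, 1])."""
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) == 0:
        return float("nan"), float("nan"), float("nan")
    p = float(x.mean())
    half = Z975 * np.sqrt(p * (1 - p) / len(x))
    return p, max(0.0, p - half), min(1.0, p + half)


def two_proportion_chisq(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """1-df two-sample proportion chi-square (pooled variance, no continuity correction)."""
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    chi2 = (p1 - p2) ** 2 / (pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def spearman(a, b) -> float:
    """Spearman rank correlation (average ranks for ties); nan when degenerate."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    return float(stats.spearmanr(a, b).statistic)


def descriptives(
    panel: PAPanel, gold: pd.DataFrame, covariates: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Per-sex activity proportions, sex-difference tests, and PAI correlations."""
    rows = []
    for age in panel.wave_ages:
        by_sex = {}
        for sex in ("male", "female"):
            col = panel.subset_sex(sex).data[age]
            p, lo, hi = proportion_ci(col)
            by_sex[sex] = (col.notna().sum(), int(col.sum(skipna=True)), p, lo, hi)
        nm, xm, pm, lom, him = by_sex["male"]
        nf, xf, pf, lof, hif = by_sex["female"]
        chi2, pval = two_proportion_chisq(xm, nm, xf, nf)
        rows.append(
            {
                "age": age,
                "male_prop": pm,
                "male_ci_low": lom,
                "male_ci_high": him,
                "female_prop": pf,
                "female_ci_low": lof,
                "female_ci_high": hif,
                "chi2_1df": chi2,
                "p_value": pval,
            }
        )
    prop_table = pd.DataFrame(rows)

    ids = gold.index.intersection(covariates.index)
    child_pa = covariates.loc[ids, "child_pa"]
    corr_table = pd.DataFrame(
        {
            "spearman_rho_child_pa": [
                spearman(gold.loc[ids, "active01"], child_pa),
                spearman(gold.loc[ids, "spectator01"], child_pa),
            ]
        },
        index=["active01", "spectator01"],
    )
    mention_rows = []
    for sex in ("male", "female"):
        sids = covariates.index[covariates["sex"] == sex].intersection(gold.index)
        g = gold.loc[sids]
        any_pa = ((g["active01"] == 1) | (g["spectator01"] == 1)).mean()
        mention_rows.append(
            {
                "sex": sex,
                "pct_any_mention": 100 * float(any_pa),
                "pct_active_only": 100 * float(((g["active01"] == 1) & (g["spectator01"] == 0)).mean()),
                "pct_both": 100 * float(((g["active01"] == 1) & (g["spectator01"] == 1)).mean()),
                "pct_spectator_only": 100 * float(((g["active01"] == 0) & (g["spectator01"] == 1)).mean()),
            }
        )
    return {
        "proportions": prop_table,
        "pai_correlations": corr_table,
        "pai_prevalence": pd.DataFrame(mention_rows),
    }
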