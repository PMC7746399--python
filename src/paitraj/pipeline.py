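"""End-to-end orchestration: simulate -> agreement -> classify -> descriptives
-> latent trajectories -> imputation -> association, driven by one TOML
config, with every stage writing its artifact before the next starts.

Stage outputs are pure functions of (inputs, seeds): re-running a stage with
the same config reproduces its artifact byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    CONTROL_COLUMNS,
    SeparationError,
    build_design,
    descriptives,
    fit_logistic,
    two_step,
)
from .classifier import (
    DEFAULT_LAMBDA_GRID,
    build_vocabulary,
    compare_predictions,
    cross_validate,
    featurize_corpus,
    lexicon_baseline,
    predict_corpus,
    train,
)
from .corpus import rater_agreement, read_corpus, read_coding_table, tokenize
from .impute import mice, rubin_pool
from .lca import LatentClassModel, select_model
from .simulate import (
    ACTIVE_LEXICON,
    SPECTATOR_LEXICON,
    CohortConfig,
    PAPanel,
    generate_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunConfigError", "run_all"]


class RunConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration (one simulate-block XOR explicit inputs)."""

    simulate: dict | None = None
    inputs: dict | None = None
    classifier: dict = field(default_factory=dict)
    lca: dict = field(default_factory=dict)
    association: dict = field(default_factory=dict)
    mi: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise RunConfigError("config must contain exactly one of [simulate] and [inputs]")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {"simulate", "inputs", "classifier", "lca", "association", "mi", "seed"}
        unknown = set(raw) - known
        if unknown:
            raise RunConfigError(f"unknown config section(s): {sorted(unknown)}")
        return cls(
            simulate=raw.get("simulate"),
            inputs=raw.get("inputs"),
            classifier=dict(raw.get("classifier", {})),
            lca=dict(raw.get("lca", {})),
            association=dict(raw.get("association", {})),
            mi=dict(raw.get("mi", {})),
            seed=int(raw.get("seed", 0)),
        )

    def cohort_config(self) -> CohortConfig:
        assert self.simulate is not None
        kwargs = dict(self.simulate)
        kwargs.setdefault("seed", self.seed)
        if "missing_probs" in kwargs:  # shorthand: per-wave base probabilities
            from .simulate import MissingSpec

            probs = kwargs.pop("missing_probs")
            ages = kwargs.get("wave_ages", (23, 33, 42, 50, 55))
            kwargs["missing_spec"] = MissingSpec({int(a): float(p) for a, p in zip(ages, probs)})
        for key in ("wave_ages", "trajectory_ages"):
            if key in kwargs:
                kwargs[key] = tuple(int(a) for a in kwargs[key])
        try:
            return CohortConfig(**kwargs)
        except TypeError as exc:
            raise RunConfigError(f"invalid [simulate] key: {exc}") from exc

    def fingerprint(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _stage(name: str, quiet: bool):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            if not quiet:
                logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is not None:
                logger.error("stage %s: FAILED after %.1fs", name, dt)
            elif not quiet:
                logger.info("stage %s: done in %.1fs", name, dt)
            return False

    return _Timer()


def run_all(config: RunConfig, outdir: str | Path, quiet: bool = False) -> dict:
    """Execute the full analysis; returns the report dict (also written as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config": dataclasses.asdict(config),
            "config_hash": config.fingerprint(),
            "package_version": __version__,
        }
    }

    # -- stage 1: data -----------------------------------------------------
    with _stage("simulate/load", quiet):
        if config.simulate is not None:
            cohort = generate_cohort(config.cohort_config())
            cohort_dir = outdir / "cohort"
            cohort.save(cohort_dir)
            essays = cohort.essays
            coding = cohort.coding_table
            covariates = cohort.covariates
            panel = cohort.pa_panel
            active_lex = cohort.config.active_lexicon
        else:
            paths = config.inputs
            essays = read_corpus(paths["essays"])
            coding = read_coding_table(paths["coding_table"])
            covariates = pd.read_csv(paths["covariates"], index_col="person_id")
            sex = covariates["sex"]
            panel = PAPanel.from_long(paths["pa_panel"], sex=sex)
            active_lex = tuple(paths.get("active_lexicon", ACTIVE_LEXICON))
        report["corpus"] = {
            "n_essays": len(essays),
            "n_female": int(sum(r.sex == "female" for r in essays)),
        }

    # -- stage 2: inter-rater agreement ------------------------------------
    with _stage("agreement", quiet):
        kappas = rater_agreement(coding[["person_id", "rater_id", "active01", "spectator01"]])
        report["agreement"] = {
            "kappa_active": round(kappas["active01"], 10),
            "kappa_spectator": round(kappas["spectator01"], 10),
            "n_coded": int(coding["person_id"].nunique()),
        }
        _write_json(outdir / "agreement.json", report["agreement"])

    # -- stage 3: classifier -----------------------------------------------
    with _stage("classifier", quiet):
        cc = config.classifier
        nmax = int(cc.get("nmax", 3))
        min_doc_frac = float(cc.get("min_doc_frac", 0.02))
        k_folds = int(cc.get("k", 10))
        inner_k = int(cc.get("inner_k", 5))
        lam_grid = tuple(cc.get("lambda_grid", DEFAULT_LAMBDA_GRID))
        clf_seed = int(cc.get("seed", config.seed))

        token_docs = [tokenize(r.text) for r in essays]
        vocab = build_vocabulary(token_docs, nmax=nmax, min_doc_frac=min_doc_frac)
        id_to_row = {r.person_id: i for i, r in enumerate(essays)}

        # training set: consensus codes of the doubly-rated subset
        consensus = (
            coding.drop_duplicates("person_id")
            .set_index("person_id")[["consensus_active01", "consensus_spectator01"]]
            if "consensus_active01" in coding.columns
            else coding.groupby("person_id")[["active01", "spectator01"]].max().rename(
                columns={"active01": "consensus_active01", "spectator01": "consensus_spectator01"}
            )
        )
        train_rows = [id_to_row[pid] for pid in consensus.index]
        X_all = featurize_corpus(token_docs, vocab)
        X_train = X_all[train_rows]

        cv_reports, predictions = {}, {}
        for target, col in (("active", "consensus_active01"), ("spectator", "consensus_spectator01")):
            y = consensus[col].to_numpy(dtype=int)
            rep = cross_validate(
                X_train, y, k=k_folds, lam_grid=lam_grid, seed=clf_seed, target=target, inner_k=inner_k
            )
            cv_reports[target] = rep.to_dict()
            lam_final = max(rep.selected_lambdas)  # sparsest of the fold winners
            model = train(X_train, y, lam=lam_final, target=target, vocab=vocab)
            model.save(vocab, outdir / f"model_{target}.csv", outdir / f"model_{target}.json")
            predictions[target] = predict_corpus(model, essays, vocab)
        pred_df = pd.DataFrame(
            {"active01": predictions["active"], "spectator01": predictions["spectator"]}
        )
        pred_df.rename_axis("person_id").to_csv(outdir / "predictions.csv")
        _write_json(outdir / "cv_report.json", cv_reports)
        report["classifier"] = cv_reports

        lex_preds = lexicon_baseline(essays, active_lex)
        gold_train = consensus["consensus_active01"]
        comp = compare_predictions(
            predictions["active"].loc[consensus.index], lex_preds.loc[consensus.index], gold_train
        )
        comp.to_csv(outdir / "lexicon_comparison.csv")
        report["lexicon_comparison"] = {
            r: {c: round(float(v), 10) for c, v in row.items()} for r, row in comp.iterrows()
        }

    # -- stage 4: descriptives ---------------------------------------------
    with _stage("descriptives", quiet):
        desc = descriptives(panel, pred_df, covariates)
        for name, table in desc.items():
            table.to_csv(outdir / f"descriptives_{name}.csv", index=name != "proportions")
        prev = desc["pai_prevalence"].set_index("sex")
        report["pai_prevalence_pct"] = {
            sex: round(float(prev.loc[sex, "pct_any_mention"]), 10) for sex in prev.index
        }

    # -- stage 5: latent trajectory classes --------------------------------
    with _stage("lca", quiet):
        lc = config.lca
        traj_ages = tuple(int(a) for a in lc.get("trajectory_ages", (33, 42, 50, 55)))
        n_starts = int(lc.get("n_starts", 20))
        tol = float(lc.get("tol", 1e-8))
        lca_seed = int(lc.get("seed", config.seed))
        by_sex = bool(config.association.get("by_sex", True))
        k_fixed = lc.get("k")
        k_range = lc.get("k_range", [2, 6])

        lca_report = {}
        groups = ("male", "female") if by_sex else ("all",)
        for sex in groups:
            sub = panel.subset_sex(sex) if by_sex else panel
            sub = sub.subset_ages(traj_ages)
            table, bic_choice, fits = select_model(
                sub, range(int(k_range[0]), int(k_range[1]) + 1), n_starts=n_starts, tol=tol, seed=lca_seed
            )
            table.to_csv(outdir / f"lca_fit_table_{sex}.csv")
            chosen = int(k_fixed) if k_fixed is not None else bic_choice
            res = fits.get(chosen)
            if res is None:
                res = LatentClassModel(sub, chosen).fit(n_starts=n_starts, tol=tol, seed=lca_seed)
            post = res.predict_posterior()
            post.rename_axis("person_id").to_csv(outdir / f"lca_posteriors_{sex}.csv")
            _write_json(
                outdir / f"lca_model_{sex}.json",
                {
                    "K": res.k_classes,
                    "pi": [round(v, 10) for v in res.class_probs],
                    "rho": [[round(v, 10) for v in row] for row in res.response_probs],
                    "loglik": round(res.llf, 6),
                    "AIC": round(res.aic, 6),
                    "BIC": round(res.bic, 6),
                    "relative_entropy": round(res.relative_entropy, 10),
                    "bic_chosen_K": bic_choice,
                },
            )
            rho = res.response_probs
            lca_report[sex] = {
                "bic_chosen_K": bic_choice,
                "K_used": res.k_classes,
                "class_probs": [round(v, 6) for v in res.class_probs],
                # late-minus-early activity: positive = rising trajectory
                "rho_trend": [round(v, 6) for v in rho[:, -2:].sum(1) - rho[:, :2].sum(1)],
                "relative_entropy": round(res.relative_entropy, 6),
            }
        report["lca"] = lca_report

    # -- stage 6: multiple imputation --------------------------------------
    with _stage("impute", quiet):
        mi_cfg = config.mi
        m = int(mi_cfg.get("m", 20))
        n_iter = int(mi_cfg.get("n_iter", 10))
        mi_seed = int(mi_cfg.get("seed", config.seed))
        analysis = pred_df.join(covariates.drop(columns=["sex"])).join(
            panel.data.rename(columns=lambda a: f"pa_{a}")
        )
        types = {f"pa_{a}": "binary" for a in panel.wave_ages}
        types.update(
            {
                "birthweight": "continuous",
                "mother_smoked": "binary",
                "father_social_class": "categorical",
                "childhood_bmi": "continuous",
                "enuresis": "binary",
                "poor_coordination": "binary",
                "bsag_score": "continuous",
                "rutter_score": "continuous",
                "general_ability": "continuous",
                "days_off_school": "continuous",
                "hospital_admissions": "continuous",
                "child_pa": "categorical",
                "active01": "binary",
                "spectator01": "binary",
            }
        )
        imp = mice(analysis, types, m=m, n_iter=n_iter, seed=mi_seed)
        imp.save(outdir / "imputations")

    # -- stage 7: association ----------------------------------------------
    with _stage("associate", quiet):
        sexes = ("male", "female") if by_sex else ("all",)
        sex_series = panel.sex

        # 7a. per-wave logistic ORs pooled across imputations (fully adjusted)
        or_rows = []
        terms = ("active01", "spectator01", "child_pa") + CONTROL_COLUMNS
        for sex in sexes:
            ids = sex_series.index if sex == "all" else sex_series.index[sex_series == sex]
            for age in panel.wave_ages:
                per_term: dict[str, tuple[list, list]] = {}
                for df_imp in imp.datasets:
                    sub = df_imp.loc[df_imp.index.intersection(ids)]
                    X = build_design(sub, ("active01", "spectator01") + terms[2:])
                    try:
                        fit = fit_logistic(sub[f"pa_{age}"], X, model_tag=f"wave{age}")
                    except SeparationError as exc:
                        logger.warning("wave %s (%s): imputation skipped: %s", age, sex, exc)
                        continue
                    for _, row in fit.table.iterrows():
                        per_term.setdefault(row["term"], ([], []))
                        per_term[row["term"]][0].append(row["coef"])
                        per_term[row["term"]][1].append(row["se"] ** 2)
                if not per_term or len(per_term["active01"][0]) < 2:
                    logger.warning("wave %s (%s): fewer than 2 usable imputations; row omitted", age, sex)
                    continue
                for term in ("active01", "spectator01"):
                    pooled = rubin_pool(*per_term[term])
                    or_rows.append(
                        {
                            "model_tag": "fully_adjusted",
                            "sex": sex,
                            "age": age,
                            "term": term,
                            "or": np.exp(pooled.estimate),
                            "ci_low": np.exp(pooled.ci_low),
                            "ci_high": np.exp(pooled.ci_high),
                        }
                    )
        or_table = pd.DataFrame(or_rows)
        or_table.to_csv(outdir / "per_wave_ors.csv", index=False)

        # 7b. two-step trajectory RRRs (FIML panel, fully observed covariates)
        k_used = {s: report["lca"][s]["K_used"] for s in report["lca"]}
        ts = two_step(
            panel,
            pred_df,
            covariates,
            k_classes=max(k_used.values()),
            trajectory_ages=traj_ages,
            by_sex=by_sex,
            n_starts=n_starts,
            seed=lca_seed,
        )
        rrr_tables = []
        for sex, bundle in ts.items():
            for tag, fit in bundle["models"].items():
                tab = fit.table.copy()
                tab.insert(0, "sex", sex)
                tab.insert(0, "model_tag", tag.split("[")[0])
                rrr_tables.append(tab)
        rrr_table = pd.concat(rrr_tables, ignore_index=True)
        rrr_table.to_csv(outdir / "trajectory_rrr.csv", index=False)
        pai_rrr = rrr_table[
            (rrr_table["model_tag"] == "fully_adjusted")
            & rrr_table["term"].isin(["active01", "spectator01"])
        ]
        report["trajectory_rrr"] = [
            {
                "sex": r["sex"],
                "outcome_class": int(r["outcome_class"]),
                "term": r["term"],
                "rrr": round(float(r["rrr"]), 10),
                "ci_low": round(float(r["ci_low"]), 10),
                "ci_high": round(float(r["ci_high"]), 10),
            }
            for _, r in pai_rrr.iterrows()
        ]

    _write_json(outdir / "report.json", report)
    return report
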