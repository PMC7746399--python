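"""Synthetic cohort generator.

Emulates the design of a birth-cohort study in which 11-year-olds wrote short
essays about their imagined adult lives and later reported, at ages 23, 33,
42, 50 and 55, whether they exercised at least once a week.  Every quantity a
downstream stage estimates is known by construction:

* each child carries gold binary physical-activity-identity (PAI) labels —
  ``active01`` (mentions doing sport) and ``spectator01`` (mentions watching
  sport) — and the essay text contains a phrase from the corresponding
  lexicon if and only if the label is 1;
* a latent trajectory class (default four classes: always active,
  fluctuating/increasing, declining, always inactive) is drawn per person
  from a multinomial logit whose linear predictor is a per-sex baseline plus
  per-class log relative-risk effects of the two PAI indicators (baseline
  class: always active);
* the binary activity panel is drawn wave-by-wave as independent Bernoulli
  given class (local independence holds by construction);
* panel entries are then deleted missing-at-random, with per-wave
  probabilities that may depend on always-observed covariates.

Default parameter values follow the published cohort wherever the source
prints them (per-sex class proportions, per-sex PAI mention splits,
inter-rater agreement levels); the class-conditional response curves and the
missingness rates are not printed and are fixed here once at realistic,
well-separated values (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import EssayRecord, tokenize, write_corpus

__all__ = [
    "CohortConfigError",
    "MissingSpec",
    "CovariateSpec",
    "FillerModel",
    "CohortConfig",
    "PAPanel",
    "SyntheticCohort",
    "default_filler_model",
    "generate_essay",
    "generate_cohort",
    "apply_missingness",
    "simulate_coding",
    "ACTIVE_LEXICON",
    "SPECTATOR_LEXICON",
]


class CohortConfigError(ValueError):
    """Invalid cohort configuration; the message names the offending field."""


# Words reported as most predictive of an active mention in the fitted
# classifier; used as the default generator lexicon and as the manual-lexicon
# baseline.
ACTIVE_LEXICON: tuple[str, ...] = (
    "swimming",
    "football",
    "play",
    "horse",
    "team",
    "swim",
    "dance",
    "tennis",
    "riding",
    "footballer",
)

# Spectator vocabulary, chosen disjoint from the active lexicon so that the
# two gold labels stay separately identifiable from text.
SPECTATOR_LEXICON: tuple[str, ...] = (
    "watching",
    "stadium",
    "supporters",
    "spectator",
    "grandstand",
    "cheering",
)

_SEXES = ("male", "female")
_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class CovariateSpec:
    """One childhood control variable: name, distribution family, parameters.

    Supported families: ``normal(mean, sd)``, ``bernoulli(p)``,
    ``categorical(p1..pm)`` (values 1..m) and ``poisson(lam)``.
    """

    name: str
    dist: str
    params: tuple[float, ...]

    def validate(self) -> None:
        if self.dist not in ("normal", "bernoulli", "categorical", "poisson"):
            raise CohortConfigError(f"covariate_spec[{self.name}]: unknown distribution {self.dist!r}")
        if self.dist == "bernoulli" and not 0 <= self.params[0] <= 1:
            raise CohortConfigError(f"covariate_spec[{self.name}]: bernoulli p outside [0, 1]")
        if self.dist == "categorical":
            p = np.asarray(self.params, dtype=float)
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise CohortConfigError(f"covariate_spec[{self.name}]: categorical probs must be a simplex")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.dist == "normal":
            return rng.normal(self.params[0], self.params[1], size=n)
        if self.dist == "bernoulli":
            return rng.binomial(1, self.params[0], size=n).astype(float)
        if self.dist == "poisson":
            return rng.poisson(self.params[0], size=n).astype(float)
        return rng.choice(np.arange(1, len(self.params) + 1), size=n, p=self.params).astype(float)


@dataclass(frozen=True)
class MissingSpec:
    """MAR missingness model for the activity panel.

    Per wave, P(missing) = expit(logit(base_prob) + sum_j coef_j * x_j) with
    x_j drawn from the always-observed covariates (MAR by construction).
    ``covariate_coefs`` maps covariate name -> coefficient on the logit scale,
    shared across waves.
    """

    base_probs: Mapping[int, float]  # wave age -> baseline missingness probability
    covariate_coefs: Mapping[str, float] = field(default_factory=dict)

    def validate(self, wave_ages: Sequence[int], covariate_names: Sequence[str]) -> None:
        for age in wave_ages:
            if age not in self.base_probs:
                raise CohortConfigError(f"missing_spec: no base probability for wave age {age}")
            p = self.base_probs[age]
            if not 0 <= p <= 1:
                raise CohortConfigError(f"missing_spec: base probability for age {age} outside [0, 1]")
        for name in self.covariate_coefs:
            if name not in covariate_names:
                raise CohortConfigError(
                    f"missing_spec: covariate {name!r} is not an observed covariate (MAR violated)"
                )


@dataclass(frozen=True)
class FillerModel:
    """Template sentences used as neutral essay filler.

    Each template is a tuple of tokens; the token ``*`` is a slot filled with
    a random neutral noun.  Filler vocabulary must be disjoint from both
    lexica so that gold labels and lexicon presence coincide exactly.
    """

    templates: tuple[tuple[str, ...], ...]
    slot_words: tuple[str, ...]

    def vocabulary(self) -> set[str]:
        vocab = {t for tpl in self.templates for t in tpl if t != "*"}
        return vocab | set(self.slot_words)


def default_filler_model() -> FillerModel:
    templates = (
        ("when", "i", "am", "25", "i", "will", "live", "in", "a", "house", "with", "a", "*"),
        ("i", "will", "be", "married", "to", "<name>", "and", "we", "will", "have", "two", "children"),
        ("my", "work", "will", "be", "in", "a", "*", "and", "i", "will", "earn", "good", "money"),
        ("i", "live", "at", "<xxxx>", "near", "the", "*"),
        ("in", "the", "morning", "i", "will", "make", "breakfast", "for", "my", "family"),
        ("my", "house", "will", "have", "a", "big", "garden", "with", "a", "*"),
        ("i", "would", "like", "to", "drive", "a", "car", "to", "my", "work"),
        ("my", "mother", "and", "father", "will", "come", "to", "visit", "us", "on", "sundays"),
        ("i", "will", "have", "a", "dog", "called", "<name>"),
        ("at", "night", "i", "will", "read", "books", "about", "a", "*"),
        ("we", "will", "go", "on", "holiday", "to", "the", "seaside", "every", "summer"),
        ("i", "want", "to", "be", "a", "nurse", "when", "i", "grow", "up"),
        ("my", "home", "will", "be", "clean", "and", "tidy", "and", "warm"),
        ("i", "will", "cook", "dinner", "and", "my", "husband", "will", "wash", "up"),
        ("on", "my", "birthday", "we", "will", "have", "a", "cake", "and", "a", "party"),
        ("i", "shall", "work", "in", "an", "office", "in", "the", "town"),
        ("my", "children", "will", "go", "to", "the", "school", "near", "our", "house"),
        ("i", "will", "save", "my", "money", "in", "the", "bank", "for", "a", "rainy", "day"),
    )
    slot_words = ("kitchen", "factory", "shop", "farm", "river", "castle", "garage", "library")
    return FillerModel(templates=templates, slot_words=slot_words)


# Sentence frames that embed a lexicon phrase (slot ``%``).
_ACTIVE_FRAMES = (
    ("my", "biggest", "interest", "will", "still", "be", "%"),
    ("on", "saturdays", "i", "will", "do", "%", "with", "my", "friends"),
    ("i", "like", "%", "very", "much", "and", "i", "will", "keep", "it", "up"),
    ("after", "work", "i", "will", "go", "for", "%"),
)
_SPECTATOR_FRAMES = (
    ("on", "saturdays", "we", "go", "%", "with", "my", "father"),
    ("i", "will", "be", "in", "the", "%", "when", "the", "big", "game", "is", "on"),
    ("we", "will", "join", "the", "%", "at", "the", "ground"),
)


@dataclass(frozen=True)
class CohortConfig:
    """All true parameters of a synthetic cohort.

    Defaults encode the published study's conditions: per-sex trajectory-class
    proportions, per-sex PAI mention splits, Table-2-scale PAI effects on
    class membership, waves at ages 23/33/42/50/55 with trajectories fitted
    on 33-55 only.
    """

    n_persons: int = 2000
    female_frac: float = 0.495
    wave_ages: tuple[int, ...] = (23, 33, 42, 50, 55)
    trajectory_ages: tuple[int, ...] = (33, 42, 50, 55)
    class_names: tuple[str, ...] = (
        "always_active",
        "fluctuating_increasing",
        "declining",
        "always_inactive",
    )
    class_probs_by_sex: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "male": (0.60, 0.05, 0.19, 0.16),
            "female": (0.49, 0.26, 0.19, 0.06),
        }
    )
    # K x T, rows = classes, columns = wave_ages
    response_probs: tuple[tuple[float, ...], ...] = (
        (0.55, 0.94, 0.92, 0.94, 0.93),
        (0.25, 0.05, 0.12, 0.88, 0.96),
        (0.45, 0.95, 0.88, 0.12, 0.05),
        (0.15, 0.05, 0.04, 0.05, 0.03),
    )
    # per sex, per PAI indicator: log relative-risk-ratio per class
    # (baseline class = first = always active, coefficient fixed at 0)
    pai_class_effects: Mapping[str, Mapping[str, tuple[float, ...]]] = field(
        default_factory=lambda: {
            "male": {
                "active": (0.0, float(np.log(0.85)), float(np.log(0.803)), float(np.log(0.659))),
                "spectator": (0.0, float(np.log(0.889)), float(np.log(1.157)), float(np.log(0.794))),
            },
            "female": {
                "active": (0.0, float(np.log(0.774)), float(np.log(0.842)), float(np.log(1.036))),
                "spectator": (0.0, float(np.log(0.828)), float(np.log(0.873)), float(np.log(1.127))),
            },
        }
    )
    covariate_spec: tuple[CovariateSpec, ...] = (
        CovariateSpec("birthweight", "normal", (3.32, 0.53)),
        CovariateSpec("mother_smoked", "bernoulli", (0.41,)),
        CovariateSpec("father_social_class", "categorical", (0.06, 0.17, 0.50, 0.17, 0.10)),
        CovariateSpec("childhood_bmi", "normal", (17.5, 2.1)),
        CovariateSpec("enuresis", "bernoulli", (0.10,)),
        CovariateSpec("poor_coordination", "bernoulli", (0.06,)),
        CovariateSpec("bsag_score", "poisson", (8.0,)),
        CovariateSpec("rutter_score", "normal", (6.5, 3.0)),
        CovariateSpec("general_ability", "normal", (45.0, 15.0)),
        CovariateSpec("days_off_school", "poisson", (6.0,)),
        CovariateSpec("hospital_admissions", "poisson", (0.4,)),
    )
    active_lexicon: tuple[str, ...] = ACTIVE_LEXICON
    spectator_lexicon: tuple[str, ...] = SPECTATOR_LEXICON
    # per sex: (P(active only), P(active and spectator), P(spectator only))
    mention_probs: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "male": (0.206, 0.157, 0.059),
            "female": (0.281, 0.022, 0.032),
        }
    )
    corruption_rate: float = 0.01
    corrupt_lexicon_tokens: bool = False  # "hard mode": corruption may hit lexicon phrases too
    missing_spec: MissingSpec = field(
        default_factory=lambda: MissingSpec(
            base_probs={23: 0.05, 33: 0.08, 42: 0.12, 50: 0.15, 55: 0.18}
        )
    )
    # probability each synthetic rater flips a gold code (calibrated so the
    # expected kappas sit near the published 0.90 / 0.82)
    rater_flip_probs: tuple[float, float] = (0.023, 0.020)
    filler_model: FillerModel = field(default_factory=default_filler_model)
    seed: int = 0

    # -- derived sizes ----------------------------------------------------
    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def n_waves(self) -> int:
        return len(self.wave_ages)

    def validate(self) -> None:
        if self.n_persons <= 0:
            raise CohortConfigError("n_persons must be positive")
        if not 0 <= self.female_frac <= 1:
            raise CohortConfigError("female_frac outside [0, 1]")
        K, T = self.n_classes, self.n_waves
        if K < 2:
            raise CohortConfigError("class_names: need K >= 2 trajectory classes")
        if T < 2:
            raise CohortConfigError("wave_ages: need T >= 2 waves")
        if not set(self.trajectory_ages) <= set(self.wave_ages):
            raise CohortConfigError("trajectory_ages must be a subset of wave_ages")
        for sex in _SEXES:
            pi = np.asarray(self.class_probs_by_sex[sex], dtype=float)
            if pi.shape != (K,):
                raise CohortConfigError(f"class_probs_by_sex[{sex}]: expected length {K}")
            if (pi < 0).any() or abs(pi.sum() - 1.0) > 1e-12:
                raise CohortConfigError(f"class_probs_by_sex[{sex}]: must sum to 1 with entries >= 0")
            m = np.asarray(self.mention_probs[sex], dtype=float)
            if (m < 0).any() or m.sum() > 1 + 1e-12:
                raise CohortConfigError(f"mention_probs[{sex}]: probabilities outside [0, 1]")
            for which in ("active", "spectator"):
                eff = np.asarray(self.pai_class_effects[sex][which], dtype=float)
                if eff.shape != (K,):
                    raise CohortConfigError(f"pai_class_effects[{sex}][{which}]: expected length {K}")
                if eff[0] != 0.0:
                    raise CohortConfigError(
                        f"pai_class_effects[{sex}][{which}]: baseline-class coefficient must be 0"
                    )
        rho = np.asarray(self.response_probs, dtype=float)
        if rho.shape != (K, T):
            raise CohortConfigError(f"response_probs: expected shape {(K, T)}, got {rho.shape}")
        if (rho < 0).any() or (rho > 1).any():
            raise CohortConfigError("response_probs: entries outside [0, 1]")
        if not 0 <= self.corruption_rate <= 1:
            raise CohortConfigError("corruption_rate outside [0, 1]")
        if not self.active_lexicon or not self.spectator_lexicon:
            raise CohortConfigError("active_lexicon/spectator_lexicon must be non-empty")
        lex_tokens = {t for p in self.active_lexicon + self.spectator_lexicon for t in tokenize(p)}
        clash = self.filler_model.vocabulary() & lex_tokens
        if clash:
            raise CohortConfigError(f"filler_model: vocabulary overlaps lexica: {sorted(clash)}")
        for spec in self.covariate_spec:
            spec.validate()
        self.missing_spec.validate(self.wave_ages, [c.name for c in self.covariate_spec])

    def with_(self, **kwargs) -> "CohortConfig":
        """Return a copy with fields replaced (dataclasses.replace wrapper)."""
        return replace(self, **kwargs)


@dataclass
class PAPanel:
    """Binary activity panel: persons x wave ages, NaN marks a missing wave."""

    data: pd.DataFrame  # index person_id, integer columns = wave ages, float 0/1/NaN
    sex: pd.Series  # person_id -> 'male' | 'female'

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == 0) | (vals == 1)
        if not ok.all():
            raise ValueError("PA panel values must be 0, 1 or missing")

    @property
    def wave_ages(self) -> list[int]:
        return [int(c) for c in self.data.columns]

    def subset_ages(self, ages: Sequence[int]) -> "PAPanel":
        return PAPanel(self.data[list(ages)].copy(), self.sex.copy())

    def subset_sex(self, sex: str) -> "PAPanel":
        keep = self.sex[self.sex == sex].index
        return PAPanel(self.data.loc[keep].copy(), self.sex.loc[keep].copy())

    def drop_all_missing(self) -> tuple["PAPanel", int]:
        """Drop persons with no observed wave; return (panel, n_dropped)."""
        observed = self.data.notna().any(axis=1)
        n_dropped = int((~observed).sum())
        return PAPanel(self.data.loc[observed].copy(), self.sex.loc[observed].copy()), n_dropped

    def to_long(self, path: str | Path) -> None:
        long = (
            self.data.rename_axis("person_id")
            .reset_index()
            .melt(id_vars="person_id", var_name="age", value_name="active01")
            .sort_values(["person_id", "age"], kind="stable")
        )
        long["active01"] = long["active01"].map(lambda v: "" if pd.isna(v) else str(int(v)))
        long.to_csv(path, index=False)

    @classmethod
    def from_long(cls, path: str | Path, sex: pd.Series | None = None) -> "PAPanel":
        long = pd.read_csv(path, dtype={"person_id": str})
        wide = long.pivot(index="person_id", columns="age", values="active01").astype(float)
        wide.columns = [int(c) for c in wide.columns]
        if sex is None:
            sex = pd.Series("male", index=wide.index)
        return cls(wide, sex.loc[wide.index])


@dataclass
class SyntheticCohort:
    """A complete generated cohort, with ground truth attached."""

    config: CohortConfig
    essays: list[EssayRecord]
    gold_labels: pd.DataFrame  # person_id (index), active01, spectator01
    covariates: pd.DataFrame  # person_id (index), sex + childhood controls + child_pa
    true_class: pd.Series  # person_id -> class index in 1..K
    pa_panel: PAPanel  # post-missingness
    pa_panel_complete: PAPanel  # pre-missingness
    coding_table: pd.DataFrame  # simulated two-rater coding of a training subset

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_corpus(self.essays, outdir / "essays.jsonl")
        self.gold_labels.rename_axis("person_id").to_csv(outdir / "gold_labels.csv")
        self.covariates.rename_axis("person_id").to_csv(outdir / "covariates.csv")
        self.true_class.rename_axis("person_id").rename("true_class").to_csv(outdir / "true_class.csv")
        self.pa_panel.to_long(outdir / "pa_panel.csv")
        self.pa_panel_complete.to_long(outdir / "pa_panel_complete.csv")
        self.coding_table.to_csv(outdir / "coding_table.csv", index=False)


def _corrupt_token(token: str, rng: np.random.Generator) -> str:
    """Random single-character substitution (spelling-mistake emulation)."""
    if token.startswith("<") or len(token) == 0:
        return token
    i = int(rng.integers(len(token)))
    return token[:i] + _LETTERS[int(rng.integers(26))] + token[i + 1 :]


def generate_essay(
    active01: int,
    spectator01: int,
    active_lexicon: Sequence[str] = ACTIVE_LEXICON,
    spectator_lexicon: Sequence[str] = SPECTATOR_LEXICON,
    filler_model: FillerModel | None = None,
    rng: np.random.Generator | None = None,
    corruption_rate: float = 0.0,
    corrupt_lexicon_tokens: bool = False,
) -> str:
    """One synthetic future-oriented essay.

    Contains at least one active-lexicon phrase iff ``active01 == 1`` and at
    least one spectator-lexicon phrase iff ``spectator01 == 1``.  Spelling
    corruption (random single-character substitutions) is applied to filler
    tokens at ``corruption_rate``; lexicon tokens are corrupted only when
    ``corrupt_lexicon_tokens`` is set, so gold separability survives the
    default noise.
    """
    if not active_lexicon or not spectator_lexicon:
        raise ValueError("lexica must be non-empty")
    fm = filler_model if filler_model is not None else default_filler_model()
    rng = rng if rng is not None else np.random.default_rng()

    sentences: list[tuple[list[str], set[int]]] = []  # (tokens, protected positions)
    n_filler = int(rng.integers(3, 8))
    tpl_idx = rng.integers(len(fm.templates), size=n_filler)
    for j in tpl_idx:
        toks = [
            fm.slot_words[int(rng.integers(len(fm.slot_words)))] if t == "*" else t
            for t in fm.templates[int(j)]
        ]
        sentences.append((toks, set()))

    def add_phrase_sentences(lexicon: Sequence[str], frames) -> None:
        for _ in range(int(rng.integers(1, 3))):  # 1-2 mentions per positive label
            phrase = tokenize(lexicon[int(rng.integers(len(lexicon)))])
            frame = frames[int(rng.integers(len(frames)))]
            toks: list[str] = []
            protected: set[int] = set()
            for t in frame:
                if t == "%":
                    protected.update(range(len(toks), len(toks) + len(phrase)))
                    toks.extend(phrase)
                else:
                    toks.append(t)
            sentences.append((toks, protected))

    if active01:
        add_phrase_sentences(active_lexicon, _ACTIVE_FRAMES)
    if spectator01:
        add_phrase_sentences(spectator_lexicon, _SPECTATOR_FRAMES)

    order = rng.permutation(len(sentences))
    out_tokens: list[str] = []
    for j in order:
        toks, protected = sentences[int(j)]
        for pos, tok in enumerate(toks):
            if corruption_rate > 0 and rng.random() < corruption_rate:
                if corrupt_lexicon_tokens or pos not in protected:
                    tok = _corrupt_token(tok, rng)
            out_tokens.append(tok)
    return " ".join(out_tokens)


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _draw_child_pa(sex: np.ndarray, active: np.ndarray, spectator: np.ndarray, rng) -> np.ndarray:
    """Self-reported childhood sport (1=hardly ever, 2=sometimes, 3=most days).

    Base per-sex distributions put 54% of boys and 37% of girls at 'most
    days'; an active (and, weakly, a spectator) PAI shifts mass upward,
    inducing the small positive rank correlations seen in the source data.
    """
    base = {"male": np.array([0.16, 0.30, 0.54]), "female": np.array([0.26, 0.37, 0.37])}
    out = np.empty(len(sex), dtype=float)
    u = rng.random(len(sex))
    for s in _SEXES:
        for a in (0, 1):
            for sp in (0, 1):
                m = (sex == s) & (active == a) & (spectator == sp)
                if not m.any():
                    continue
                p = base[s].copy()
                shift = 0.12 * a + 0.08 * sp
                moved = np.minimum(p[:2], [shift / 2, shift / 2])
                p[:2] -= moved
                p[2] += moved.sum()
                cum = np.cumsum(p)
                out[m] = 1 + np.searchsorted(cum, u[m], side="right")
    return np.clip(out, 1, 3)


def apply_missingness(
    panel_complete: PAPanel,
    covariates: pd.DataFrame,
    missing_spec: MissingSpec,
    rng: np.random.Generator,
) -> PAPanel:
    """Delete panel entries missing-at-random per the spec'd logit model."""
    missing_spec.validate(panel_complete.wave_ages, list(covariates.columns))
    n = len(panel_complete.data)
    lin_cov = np.zeros(n)
    for name, coef in missing_spec.covariate_coefs.items():
        lin_cov += coef * covariates.loc[panel_complete.data.index, name].to_numpy(dtype=float)
    data = panel_complete.data.copy()
    for age in panel_complete.wave_ages:
        base = missing_spec.base_probs[age]
        if base <= 0:
            p = np.zeros(n)
        elif base >= 1:
            p = np.ones(n)
        else:
            p = 1.0 / (1.0 + np.exp(-(np.log(base / (1 - base)) + lin_cov)))
        mask = rng.random(n) < p
        col = data[age].to_numpy(dtype=float)
        col[mask] = np.nan
        data[age] = col
    return PAPanel(data, panel_complete.sex.copy())


def simulate_coding(
    gold_labels: pd.DataFrame,
    flip_probs: tuple[float, float],
    rng: np.random.Generator,
    n_essays: int = 500,
) -> pd.DataFrame:
    """Two synthetic raters coding a random training subset.

    Each rater independently reports the gold code flipped with a small
    probability (one rate per code), emulating near-but-not-perfect manual
    agreement.  Returns a long coding table plus a ``consensus`` column equal
    to the gold code (full agreement reached through discussion).
    """
    ids = gold_labels.index.to_numpy()
    take = min(n_essays, len(ids))
    chosen = rng.choice(ids, size=take, replace=False)
    sub = gold_labels.loc[chosen]
    rows = []
    for rater in ("r1", "r2"):
        a = sub["active01"].to_numpy() ^ (rng.random(take) < flip_probs[0]).astype(int)
        s = sub["spectator01"].to_numpy() ^ (rng.random(take) < flip_probs[1]).astype(int)
        rows.append(
            pd.DataFrame(
                {
                    "person_id": chosen,
                    "rater_id": rater,
                    "active01": a,
                    "spectator01": s,
                    "consensus_active01": sub["active01"].to_numpy(),
                    "consensus_spectator01": sub["spectator01"].to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a complete synthetic cohort; deterministic given config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, K = config.n_persons, config.n_classes
    person_id = np.array([f"p{i:06d}" for i in range(n)])

    sex = np.where(rng.random(n) < config.female_frac, "female", "male")

    # PAI gold labels from the per-sex mention splits
    active = np.zeros(n, dtype=int)
    spectator = np.zeros(n, dtype=int)
    u = rng.random(n)
    for s in _SEXES:
        p_ao, p_both, p_so = config.mention_probs[s]
        m = sex == s
        active[m & (u < p_ao + p_both)] = 1
        spectator[m & (u >= p_ao) & (u < p_ao + p_both + p_so)] = 1

    # childhood covariates
    cov = {"sex": sex}
    for spec in config.covariate_spec:
        cov[spec.name] = spec.draw(n, rng)
    cov["child_pa"] = _draw_child_pa(sex, active, spectator, rng)
    covariates = pd.DataFrame(cov, index=person_id)

    # latent class via multinomial logit
    logits = np.zeros((n, K))
    for s in _SEXES:
        m = sex == s
        base = np.log(np.asarray(config.class_probs_by_sex[s], dtype=float).clip(1e-300))
        eff_a = np.asarray(config.pai_class_effects[s]["active"], dtype=float)
        eff_s = np.asarray(config.pai_class_effects[s]["spectator"], dtype=float)
        logits[m] = base + np.outer(active[m], eff_a) + np.outer(spectator[m], eff_s)
    probs = _softmax_rows(logits)
    u = rng.random(n)
    true_class0 = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)

    # complete panel: independent Bernoulli given class
    rho = np.asarray(config.response_probs, dtype=float)
    y = (rng.random((n, config.n_waves)) < rho[true_class0]).astype(float)
    sex_series = pd.Series(sex, index=person_id, name="sex")
    panel_complete = PAPanel(
        pd.DataFrame(y, index=person_id, columns=list(config.wave_ages)), sex_series
    )
    panel = apply_missingness(panel_complete, covariates, config.missing_spec, rng)

    # essays with embedded lexicon phrases
    essays = [
        EssayRecord(
            person_id=pid,
            sex=sx,
            text=generate_essay(
                a,
                sp,
                config.active_lexicon,
                config.spectator_lexicon,
                config.filler_model,
                rng,
                corruption_rate=config.corruption_rate,
                corrupt_lexicon_tokens=config.corrupt_lexicon_tokens,
            ),
            active01=int(a),
            spectator01=int(sp),
        )
        for pid, sx, a, sp in zip(person_id, sex, active, spectator)
    ]

    gold = pd.DataFrame({"active01": active, "spectator01": spectator}, index=person_id)
    coding = simulate_coding(gold, config.rater_flip_probs, rng)
    return SyntheticCohort(
        config=config,
        essays=essays,
        gold_labels=gold,
        covariates=covariates,
        true_class=pd.Series(true_class0 + 1, index=person_id, name="true_class"),
        pa_panel=panel,
        pa_panel_complete=panel_complete,
        coding_table=coding,
    )
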