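"""Essay corpus I/O, tokenization and inter-rater agreement.

The corpus is a set of short free-text essays, one per child, in which
identifying details have been replaced by the placeholders ``<name>`` and
``<xxxx>``.  Essays are stored as JSONL (one object per line with keys
``person_id``, ``sex``, ``text``) or as CSV with the same columns.  Manual
codings of a training subset live in a separate coding table with one row per
(person, rater) pair and the two binary codes ``active01`` / ``spectator01``.

Tokenization is deliberately minimal: lower-casing plus splitting on anything
that is not a letter, digit or apostrophe, with the anonymization placeholders
preserved as single tokens.  Spelling is never corrected — the transcribed
essays contain genuine spelling mistakes and are used as-is.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EssayRecord",
    "CorpusError",
    "read_corpus",
    "write_corpus",
    "tokenize",
    "cohen_kappa",
    "read_coding_table",
    "write_coding_table",
    "rater_agreement",
]

#: placeholders survive tokenization as single tokens
_TOKEN_RE = re.compile(r"<name>|<xxxx>|[a-z0-9']+")

_SEXES = ("male", "female")


class CorpusError(ValueError):
    """Raised for malformed corpus or coding files."""


@dataclass(frozen=True)
class EssayRecord:
    """One child's essay with sex and optional gold PAI codes."""

    person_id: str
    sex: str
    text: str
    active01: int | None = None
    spectator01: int | None = None

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise CorpusError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if not self.text.strip():
            raise CorpusError(f"empty essay text for person {self.person_id!r}")


def tokenize(text: str) -> list[str]:
    """Lower-case and split *text* into tokens.

    Tokens are maximal runs of letters/digits/apostrophes; the anonymization
    placeholders ``<name>`` and ``<xxxx>`` are kept as single tokens.
    Idempotent on re-joined output.
    """
    return _TOKEN_RE.findall(text.lower())


def _records_from_rows(rows: Iterable[dict], source: str) -> list[EssayRecord]:
    records: list[EssayRecord] = []
    seen: set[str] = set()
    for lineno, row in enumerate(rows, start=1):
        missing = {"person_id", "sex", "text"} - set(row)
        if missing:
            raise CorpusError(f"{source}: missing required column(s) {sorted(missing)}")
        pid = str(row["person_id"])
        if pid in seen:
            raise CorpusError(f"{source}, record {lineno}: duplicate person_id {pid!r}")
        seen.add(pid)
        text = str(row["text"]) if row["text"] is not None else ""
        if not text.strip():
            raise CorpusError(f"{source}, record {lineno}: empty essay text")
        records.append(EssayRecord(person_id=pid, sex=str(row["sex"]), text=text))
    return records


def read_corpus(path: str | Path) -> list[EssayRecord]:
    """Read an essay corpus from a JSONL or CSV file (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".jsonl":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rows.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise CorpusError(f"{path}, line {lineno}: invalid JSON ({exc})") from exc
        records = _records_from_rows(rows, str(path))
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            records = _records_from_rows(reader, str(path))
    if not records:
        logger.warning("corpus file %s contains no records", path)
    return records


def write_corpus(records: Sequence[EssayRecord], path: str | Path) -> None:
    """Write a corpus as JSONL or CSV, chosen by file extension."""
    path = Path(path)
    if path.suffix.lower() == ".jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for r in records:
                fh.write(
                    json.dumps(
                        {"person_id": r.person_id, "sex": r.sex, "text": r.text},
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    else:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["person_id", "sex", "text"])
            for r in records:
                writer.writerow([r.person_id, r.sex, r.text])


def cohen_kappa(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Cohen's kappa for two binary ratings of the same items.

    kappa = (p_o - p_e) / (1 - p_e), where p_o is the observed agreement
    fraction and p_e the chance agreement implied by the two raters' marginal
    label frequencies.  Returns ``nan`` when p_e == 1 (both raters constant
    with the same value), where kappa is undefined.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("labels_a and labels_b must be equal-length non-empty 1-d vectors")
    for name, v in (("labels_a", a), ("labels_b", b)):
        if not np.isin(v, (0, 1)).all():
            raise ValueError(f"{name} must be binary (0/1)")
    p_o = float(np.mean(a == b))
    pa1, pb1 = float(a.mean()), float(b.mean())
    p_e = pa1 * pb1 + (1.0 - pa1) * (1.0 - pb1)
    if p_e >= 1.0 - 1e-15:
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def read_coding_table(path: str | Path) -> pd.DataFrame:
    """Read a rater-coding table (person_id, rater_id, active01, spectator01)."""
    df = pd.read_csv(path, dtype={"person_id": str, "rater_id": str})
    required = {"person_id", "rater_id", "active01", "spectator01"}
    missing = required - set(df.columns)
    if missing:
        raise CorpusError(f"{path}: missing required column(s) {sorted(missing)}")
    if df.duplicated(subset=["person_id", "rater_id"]).any():
        raise CorpusError(f"{path}: a rater coded the same essay more than once")
    for col in ("active01", "spectator01"):
        if not df[col].isin((0, 1)).all():
            raise CorpusError(f"{path}: column {col} must be binary (0/1)")
    return df


def write_coding_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def rater_agreement(table: pd.DataFrame) -> dict[str, float]:
    """Cohen's kappa for the 'active' and 'spectator' codes of two raters.

    The table must contain exactly two raters covering the same essays; the
    two codes are assessed separately, mirroring the two reported agreement
    statistics of the manual training-set coding.
    """
    raters = sorted(table["rater_id"].unique())
    if len(raters) != 2:
        raise CorpusError(f"expected exactly 2 raters, found {len(raters)}")
    wide = table.pivot(index="person_id", columns="rater_id", values=["active01", "spectator01"])
    if wide.isna().any().any():
        raise CorpusError("the two raters did not code the same set of essays")
    return {
        code: cohen_kappa(wide[(code, raters[0])].to_numpy(), wide[(code, raters[1])].to_numpy())
        for code in ("active01", "spectator01")
    }
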