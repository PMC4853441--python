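"""Behavioral scoring and demographic adjustment.

Semantic fluency is the number of correct, non-repeated animals named in a
2-minute trial; phonemic fluency is the sum of correct, non-repeated words
produced in two 1-minute letter trials (N and A).  Raw scores are converted
to z scores adjusted for age, sex and education by within-sample linear
regression, and dichotomized against normative 5th-percentile cutoffs
(performance strictly below the cutoff counts as impaired).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FluencyScores",
    "AdjustmentResult",
    "ImpairmentFlag",
    "NormTable",
    "score_fluency_trial",
    "combine_phonemic",
    "fluency_scores",
    "adjust_for_demographics",
    "dichotomize",
    "correlation_table",
    "SEMANTIC",
    "PHONEMIC",
    "TRIAL_ANIMALS",
    "TRIAL_LETTER_N",
    "TRIAL_LETTER_A",
]

# Canonical test/trial column names used throughout the package.
TRIAL_ANIMALS = "animals_2min"
TRIAL_LETTER_N = "letterN_1min"
TRIAL_LETTER_A = "letterA_1min"
SEMANTIC = "semantic_fluency"
PHONEMIC = "phonemic_fluency"


@dataclass(frozen=True)
class FluencyScores:
    """Raw per-trial counts and the two derived fluency scores."""

    subject_id: str
    animals: float
    letter_n: float
    letter_a: float

    @property
    def semantic_raw(self) -> float:
        return self.animals

    @property
    def phonemic_raw(self) -> float:
        """N + A; NaN when either trial is missing."""
        if not (np.isfinite(self.letter_n) and np.isfinite(self.letter_a)):
            return float("nan")
        return combine_phonemic(self.letter_n, self.letter_a)


@dataclass(frozen=True)
class ImpairmentFlag:
    subject_id: str
    test: str
    impaired: bool
    cutoff_used: float


class NormTable:
    """Normative 5th-percentile cutoffs per test.

    The published Dutch norms themselves are not redistributable, so cutoffs
    are supplied as configuration: a ``{test: cutoff}`` mapping, or a JSON /
    two-column CSV file.
    """

    def __init__(self, cutoffs: Mapping[str, float]):
        self._cutoffs = {str(k): float(v) for k, v in cutoffs.items()}
        for test, cut in self._cutoffs.items():
            if not np.isfinite(cut):
                raise ValueError(f"norm cutoff for {test!r} must be finite, got {cut}")

    @classmethod
    def from_file(cls, path: str | Path) -> "NormTable":
        path = Path(path)
        if path.suffix.lower() == ".json":
            return cls(json.loads(path.read_text()))
        frame = pd.read_csv(path)
        return cls({str(r.iloc[0]): float(r.iloc[1]) for _, r in frame.iterrows()})

    def cutoff(self, test: str) -> float:
        if test not in self._cutoffs:
            raise KeyError(f"no norm cutoff defined for test {test!r}")
        return self._cutoffs[test]

    def __contains__(self, test: str) -> bool:
        return test in self._cutoffs

    def as_dict(self) -> dict[str, float]:
        return dict(self._cutoffs)


def score_fluency_trial(
    words: Iterable[str],
    validity_rule: Callable[[str], bool] | None = None,
) -> int:
    """Count correct, non-repeated words in one fluency trial.

    Words are compared case-insensitively after whitespace trimming;
    repetitions count once.  ``validity_rule`` decides correctness per
    (normalized) word — language-specific judgments are injected by the
    caller, not hard-coded.
    """
    if validity_rule is None:
        validity_rule = lambda w: True  # noqa: E731
    seen: set[str] = set()
    count = 0
    for word in words:
        norm = word.strip().lower()
        if not norm or norm in seen:
            continue
        seen.add(norm)
        if validity_rule(norm):
            count += 1
    return count


def combine_phonemic(n_letter_n: float, n_letter_a: float) -> float:
    """Sum of the two letter-trial counts (phonemic fluency score)."""
    if n_letter_n < 0 or n_letter_a < 0:
        raise ValueError("trial counts must be non-negative")
    return float(n_letter_n) + float(n_letter_a)


def fluency_scores(frame: pd.DataFrame) -> pd.DataFrame:
    """Derive semantic and phonemic fluency columns from per-trial counts.

    Expects trial columns ``animals_2min``, ``letterN_1min``, ``letterA_1min``
    (missing allowed).  Phonemic fluency is NaN when either letter trial is
    missing.
    """
    out = frame.copy()
    out[SEMANTIC] = frame[TRIAL_ANIMALS]
    both = frame[TRIAL_LETTER_N].notna() & frame[TRIAL_LETTER_A].notna()
    phon = pd.Series(np.nan, index=frame.index, dtype=float)
    phon[both] = frame.loc[both, TRIAL_LETTER_N] + frame.loc[both, TRIAL_LETTER_A]
    out[PHONEMIC] = phon
    return out


@dataclass(frozen=True)
class AdjustmentResult:
    """Demographically adjusted z scores for one test.

    z is the least-squares residual of ``raw ~ 1 + age + sex + education``
    divided by the residual standard deviation (n - p denominator, p = 4
    regressors including the intercept).  Subjects with a missing raw score
    get a missing z.
    """

    test: str
    z: pd.Series
    coefficients: dict[str, float]
    residual_sd: float
    n_used: int
    ddof: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.z.index, "test": self.test, "z": self.z.values})


def adjust_for_demographics(
    raw: pd.Series,
    age: pd.Series,
    sex: pd.Series,
    education: pd.Series,
    test: str = "score",
    min_subjects: int = 5,
) -> AdjustmentResult:
    """Standardize a raw score after regressing out age, sex and education.

    The fit is sample-referenced: coefficients and the residual sd come from
    the cohort itself.  Education enters as a single linear ordinal covariate
    (Verhage 1-7); sex as its 0/1 code.

    Raises on fewer than ``min_subjects`` complete cases, a rank-deficient
    design, or zero residual variance.
    """
    data = pd.DataFrame({"raw": raw, "age": age, "sex": sex, "education": education})
    complete = data.dropna()
    n = len(complete)
    if n < min_subjects:
        raise ValueError(f"test {test!r}: only {n} complete cases, need >= {min_subjects}")
    X = np.column_stack(
        [
            np.ones(n),
            complete["age"].to_numpy(float),
            complete["sex"].to_numpy(float),
            complete["education"].to_numpy(float),
        ]
    )
    y = complete["raw"].to_numpy(float)
    rank = np.linalg.matrix_rank(X)
    # constant demographics collapse the fit to plain standardization
    keep = [0] + [j for j in range(1, 4) if np.ptp(X[:, j]) > 0]
    Xr = X[:, keep]
    if np.linalg.matrix_rank(Xr) < Xr.shape[1]:
        raise ValueError(
            f"test {test!r}: demographic design is rank deficient (rank {rank} of {X.shape[1]})"
        )
    beta, *_ = np.linalg.lstsq(Xr, y, rcond=None)
    resid = y - Xr @ beta
    p = Xr.shape[1]
    if n <= p:
        raise ValueError(f"test {test!r}: {n} cases cannot identify {p} coefficients")
    resid_var = float(resid @ resid) / (n - p)
    if resid_var <= 0 or not np.isfinite(resid_var) or np.isclose(resid_var, 0.0):
        raise ValueError(f"test {test!r}: zero residual variance, z scores undefined")
    resid_sd = float(np.sqrt(resid_var))
    z = pd.Series(np.nan, index=raw.index, dtype=float)
    z.loc[complete.index] = resid / resid_sd
    names = ["intercept", "age", "sex", "education"]
    coef = {names[j]: float(b) for j, b in zip(keep, beta)}
    return AdjustmentResult(
        test=test, z=z, coefficients=coef, residual_sd=resid_sd, n_used=n, ddof=p
    )


def dichotomize(score: float, norms: NormTable, test: str, subject_id: str = "") -> ImpairmentFlag:
    """Flag performance strictly below the normative cutoff as impaired.

    A score exactly at the cutoff is *not* impaired ("below the 5th
    percentile" reads as a strict inequality).  A missing score yields a
    flag with ``impaired=False`` and NaN propagated by the caller; here a
    NaN score raises to force explicit handling.
    """
    cutoff = norms.cutoff(test)
    if not np.isfinite(score):
        raise ValueError(f"cannot dichotomize missing score for {test!r}")
    return ImpairmentFlag(
        subject_id=subject_id, test=test, impaired=bool(score < cutoff), cutoff_used=cutoff
    )


def dichotomize_series(scores: pd.Series, norms: NormTable, test: str) -> pd.Series:
    """Vector version: boolean flags with NaN kept for missing scores."""
    cutoff = norms.cutoff(test)
    out = pd.Series(pd.NA, index=scores.index, dtype="boolean")
    finite = scores.notna()
    out[finite] = scores[finite] < cutoff
    return out


def correlation_table(measures: pd.DataFrame, tests: Sequence[str] | None = None) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations with two-tailed p values.

    Returns a tidy frame with columns ``test_a, test_b, r, p, n`` covering
    every unordered pair (both orders emitted so the table is symmetric; the
    diagonal carries r = 1).  Pairs with fewer than 3 jointly non-missing
    subjects, or a constant series, get NaN r with a ``reason``.
    """
    if tests is None:
        tests = list(measures.columns)
    rows = []
    for a in tests:
        for b in tests:
            xa, xb = measures[a], measures[b]
            joint = xa.notna() & xb.notna()
            n = int(joint.sum())
            r = p = float("nan")
            reason = ""
            if a == b:
                r, p = 1.0, 0.0
            elif n < 3:
                reason = f"only {n} jointly non-missing subjects"
            elif xa[joint].nunique() < 2 or xb[joint].nunique() < 2:
                reason = "constant series"
            else:
                res = stats.pearsonr(xa[joint], xb[joint])
                r, p = float(res.statistic), float(res.pvalue)
            rows.append({"test_a": a, "test_b": b, "r": r, "p": p, "n": n, "reason": reason})
    return pd.DataFrame(rows)
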