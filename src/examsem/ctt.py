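"""Classical-test-theory statistics for exam score data.

Classical test theory decomposes an observed exam score into a true score
plus independent measurement error, ``X = T + E``.  Two summary statistics
follow:

* **reliability** — the proportion of observed-score variance attributable
  to true scores, conventionally estimated from item-level data by
  Cronbach's coefficient alpha;
* **standard error of measurement (SEM)** — the standard deviation of the
  error component, ``SEM = SD · sqrt(1 − reliability)``, i.e. the spread of
  the scores a single candidate would obtain over repeated parallel
  administrations.

Reliability is a joint property of an assessment *and* of the ability
spread of the cohort sitting it; the SEM is (to a good approximation) a
property of the assessment alone.  This module provides both routes to the
SEM — via reliability and directly from item variances without ever forming
alpha — together with the Spearman-Brown prophecy for test lengthening and
the Ghiselli correction for restriction of range.

All variances and standard deviations use the sample (``n − 1``) convention
throughout; alpha is invariant to that choice, but the first-principles SEM
identity requires one consistent convention.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("examsem")

__all__ = [
    "CttError",
    "MissingDataError",
    "DegenerateCohortError",
    "ItemResponseMatrix",
    "ReliabilityReport",
    "ProphecyQuery",
    "RangeRestrictionQuery",
    "cronbach_alpha",
    "sem_from_reliability",
    "sem_first_principles",
    "reliability_report",
    "spearman_brown_prophecy",
    "items_needed_for_target",
    "restriction_of_range_correlation",
    "score_summary",
]


class CttError(ValueError):
    """Base class for classical-test-theory input errors."""


class MissingDataError(CttError):
    """A response matrix contains missing cells (never imputed)."""


class DegenerateCohortError(CttError):
    """All candidates obtained the same total score; alpha is undefined."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ItemResponseMatrix:
    """A candidate × item matrix of scored responses.

    ``responses[i, j]`` is candidate *i*'s mark on item *j* — binary 0/1 for
    best-of-five style items, or partial-credit marks.  Missing cells are a
    declared error: scoring an exam with absent responses is a policy
    decision that must be made upstream, not silently imputed here.
    """

    responses: np.ndarray
    candidate_ids: tuple[str, ...]
    item_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.responses, dtype=float)
        if arr.ndim != 2:
            raise CttError("responses must be a 2-D candidate × item matrix")
        n, k = arr.shape
        if n < 2 or k < 2:
            raise CttError(
                f"need at least 2 candidates and 2 items, got {n} × {k}"
            )
        if np.isnan(arr).any():
            raise MissingDataError("missing cell in item-response matrix")
        if not np.isfinite(arr).all():
            raise CttError("non-finite response value")
        if len(self.candidate_ids) != n or len(self.item_ids) != k:
            raise CttError("id labels do not match matrix dimensions")
        object.__setattr__(self, "responses", arr)

    @property
    def n_candidates(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.responses, (0.0, 1.0)).all())

    @property
    def total_scores(self) -> np.ndarray:
        return self.responses.sum(axis=1)

    @classmethod
    def from_array(cls, responses) -> "ItemResponseMatrix":
        """Wrap a bare array, generating ``c1.. / i1..`` labels."""
        arr = np.asarray(responses, dtype=float)
        if arr.ndim != 2:
            raise CttError("responses must be a 2-D candidate × item matrix")
        n, k = arr.shape
        return cls(
            responses=arr,
            candidate_ids=tuple(f"c{i + 1}" for i in range(n)),
            item_ids=tuple(f"i{j + 1}" for j in range(k)),
        )

    @classmethod
    def from_csv(cls, path) -> "ItemResponseMatrix":
        """Read the strict item-response CSV dialect.

        First column: candidate id; header row: item ids; every remaining
        cell numeric.  Any blank cell raises :class:`MissingDataError`.
        """
        df = pd.read_csv(path, index_col=0)
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise CttError(f"empty item-response file: {path}")
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise CttError(f"non-numeric cell in {path}: {exc}") from exc
        if np.isnan(values).any():
            raise MissingDataError(f"missing cell in {path}")
        return cls(
            responses=values,
            candidate_ids=tuple(str(c) for c in df.index),
            item_ids=tuple(str(c) for c in df.columns),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.responses,
            index=list(self.candidate_ids),
            columns=list(self.item_ids),
        ).to_csv(path, index_label="candidate")


@dataclass(frozen=True)
class ReliabilityReport:
    """The (n items, score SD, alpha, SEM) quartet for one assessment."""

    n_candidates: int
    n_items: int
    alpha: float
    score_sd: float
    sem: float
    warnings: tuple[str, ...] = field(default=())

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_candidates": self.n_candidates,
                "n_items": self.n_items,
                "alpha": round(self.alpha, 10),
                "score_sd": round(self.score_sd, 10),
                "sem": round(self.sem, 10),
                "warnings": list(self.warnings),
            }
        )


@dataclass(frozen=True)
class ProphecyQuery:
    """How many parallel items does a target reliability require?"""

    current_reliability: float
    current_n_items: int
    target_reliability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.current_reliability < 1.0:
            raise CttError("current_reliability must be in [0, 1)")
        if not 0.0 <= self.target_reliability < 1.0:
            raise CttError("target_reliability must be in [0, 1)")
        if self.current_n_items < 1:
            raise CttError("current_n_items must be >= 1")


@dataclass(frozen=True)
class RangeRestrictionQuery:
    """Inputs for the Ghiselli restriction-of-range correction."""

    unrestricted_r: float
    unrestricted_sd: float
    restricted_sd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.unrestricted_r <= 1.0:
            raise CttError("unrestricted_r must be in [0, 1]")
        if self.restricted_sd <= 0:
            raise CttError("restricted_sd must be positive")
        if self.restricted_sd > self.unrestricted_sd:
            raise CttError("not a restriction: restricted SD exceeds unrestricted SD")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _item_and_total_variance(matrix: ItemResponseMatrix) -> tuple[float, float]:
    sum_item_var = float(matrix.responses.var(axis=0, ddof=1).sum())
    total_var = float(matrix.total_scores.var(ddof=1))
    if total_var == 0.0:
        raise DegenerateCohortError("degenerate cohort: identical total scores")
    return sum_item_var, total_var


def cronbach_alpha(matrix: ItemResponseMatrix) -> float:
    """Cronbach's coefficient alpha, ``k/(k−1) · (1 − Σσ_i²/σ_X²)``.

    Item columns with zero variance (everyone right, or everyone wrong) are
    legal and simply contribute 0 to ``Σσ_i²``.  The result is ≤ 1 but may
    be negative for pathological data; it is returned unchanged (see
    :func:`reliability_report` for the warning flag).
    """
    sum_item_var, total_var = _item_and_total_variance(matrix)
    k = matrix.n_items
    return k / (k - 1) * (1.0 - sum_item_var / total_var)


def sem_from_reliability(score_sd: float, reliability: float) -> float:
    """SEM via the textbook formula ``SD · sqrt(1 − reliability)``."""
    if score_sd < 0:
        raise CttError("score_sd must be non-negative")
    if not 0.0 <= reliability <= 1.0:
        raise CttError(
            f"reliability {reliability!r} outside [0, 1]; SEM undefined "
            "(clamp or reject upstream)"
        )
    return score_sd * math.sqrt(1.0 - reliability)


def sem_first_principles(matrix: ItemResponseMatrix) -> float:
    """SEM directly from item variances, without ever forming alpha.

    Substituting alpha into ``SD · sqrt(1 − alpha)`` and simplifying gives

        SEM = sqrt( (k · Σσ_i² − σ_X²) / (k − 1) )

    which needs only the per-item variances and the total-score variance.
    Algebraically identical to the reliability route under one consistent
    variance convention; a floating-point-negative radicand is clamped to 0.
    """
    sum_item_var, total_var = _item_and_total_variance(matrix)
    k = matrix.n_items
    radicand = (k * sum_item_var - total_var) / (k - 1)
    if radicand < 0.0:
        logger.warning(
            "first-principles SEM radicand %.3e < 0 (floating point); clamped to 0",
            radicand,
        )
        radicand = 0.0
    return math.sqrt(radicand)


def reliability_report(matrix: ItemResponseMatrix) -> ReliabilityReport:
    """Full (n items, SD, alpha, SEM) quartet for one response matrix.

    The SEM is taken from the first-principles route, which stays defined
    even when alpha is negative; a negative alpha is returned as-is and
    flagged in ``warnings`` rather than clamped.
    """
    alpha = cronbach_alpha(matrix)
    sd = float(matrix.total_scores.std(ddof=1))
    sem = sem_first_principles(matrix)
    warnings: tuple[str, ...] = ()
    if alpha < 0.0:
        warnings = ("negative_alpha",)
    return ReliabilityReport(
        n_candidates=matrix.n_candidates,
        n_items=matrix.n_items,
        alpha=alpha,
        score_sd=sd,
        sem=sem,
        warnings=warnings,
    )


def spearman_brown_prophecy(reliability: float, length_factor: float) -> float:
    """Prophesied reliability of a test lengthened by ``length_factor``.

    ``r_new = n·r / (1 + (n − 1)·r)`` for parallel added items; ``n < 1``
    prophesies a shortened test.
    """
    if not 0.0 <= reliability < 1.0:
        raise CttError("reliability must be in [0, 1)")
    if length_factor <= 0:
        raise CttError("length_factor must be positive")
    n = length_factor
    return n * reliability / (1.0 + (n - 1.0) * reliability)


def items_needed_for_target(query: ProphecyQuery) -> int:
    """Smallest whole number of items reaching the target reliability.

    Inverts the Spearman-Brown formula for the length factor,
    ``n = target(1 − current) / (current(1 − target))``, scales the current
    item count and takes the ceiling, so prophecy at the returned count is
    guaranteed ≥ target while one item fewer falls short.
    """
    if query.current_reliability == 0.0:
        raise CttError("current reliability 0: no finite length reaches the target")
    factor = (
        query.target_reliability
        * (1.0 - query.current_reliability)
        / (query.current_reliability * (1.0 - query.target_reliability))
    )
    exact = query.current_n_items * factor
    # guard the ceiling against upward floating-point drift on exact answers
    nearest = round(exact)
    if abs(exact - nearest) < 1e-9 * max(1.0, abs(exact)):
        return int(nearest)
    return math.ceil(exact)


def restriction_of_range_correlation(query: RangeRestrictionQuery) -> float:
    """Ghiselli's correction: expected correlation under explicit selection.

    With ``u`` the ratio of restricted to unrestricted SD of the selection
    variable, a correlation ``r`` in the unrestricted population attenuates
    to ``r·u / sqrt(1 − r²(1 − u²))`` in the selected one.  Equal SDs leave
    the correlation unchanged.
    """
    r = query.unrestricted_r
    u = query.restricted_sd / query.unrestricted_sd
    return r * u / math.sqrt(1.0 - r * r * (1.0 - u * u))


def score_summary(scores) -> tuple[float, float]:
    """Sample mean and sample SD (``n − 1``) of a mark vector."""
    arr = np.asarray(scores, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise CttError("need at least 2 scores")
    return float(arr.mean()), float(arr.std(ddof=1))
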