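"""Validation harness: case filters, hit definitions, error tables.

The protocol mirrors how diagnostic decision-support panels are
validated against archival pathology data:

* cases are excluded when they carry fewer than three usable marker
  results, when every usable marker is tagged prognostic/therapeutic
  only (so the panel says nothing about tumour origin), when ground
  truth is required but missing, or when the case id duplicates an
  earlier one;
* a *strict hit* counts a case as correct when the originally reported
  diagnosis appears in the engine's top-k (default 10) differential;
* an *inclusive hit* additionally accepts a top-k entry that shares the
  truth's cell of origin and an identical graded profile on every
  marker graded for both, differing at most in anatomic site class
  (e.g. nodal vs extranodal marginal zone lymphoma);
* per-entity error counts and overall hit/error rates are aggregated
  into an :class:`EvaluationReport`, and accuracy across datasets is
  compared with a Pearson chi-square test on the 2 x g table of
  (accurate, error) counts.

Printed percentages are rounded half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .cases import CaseProfile
from .inference import RankedDifferential, posterior, top_k
from .knowledge import KnowledgeBase

__all__ = [
    "CaseFilterReport",
    "HitOutcome",
    "EvaluationReport",
    "filter_cases",
    "strict_hit",
    "inclusive_hit",
    "evaluate",
    "rate",
    "compare_datasets",
]

EXCLUSION_REASONS = ("too_few_markers", "prognostic_only", "no_diagnosis", "duplicate")


@dataclass(frozen=True)
class CaseFilterReport:
    included: tuple[CaseProfile, ...]
    excluded: tuple[tuple[CaseProfile, str], ...]

    @property
    def exclusion_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in EXCLUSION_REASONS}
        for _, reason in self.excluded:
            counts[reason] += 1
        return counts


@dataclass(frozen=True)
class HitOutcome:
    case_id: str
    strict: bool
    inclusive: bool
    rank_of_truth: int | None = None
    undeterminable: bool = False

    def __post_init__(self) -> None:
        if self.strict and not self.inclusive:
            raise ValueError("a strict hit is always an inclusive hit")


@dataclass(frozen=True)
class EvaluationReport:
    """Per-entity and overall hit/error tallies with printed rates."""

    per_entity: Mapping[str, tuple[int, int]]  # disease -> (errors, total)
    mode: str = "strict"
    k: int = 10
    outcomes: tuple[HitOutcome, ...] = field(default=(), compare=False)

    @property
    def total(self) -> int:
        return sum(n for _, n in self.per_entity.values())

    @property
    def errors(self) -> int:
        return sum(e for e, _ in self.per_entity.values())

    @property
    def accurate(self) -> int:
        return self.total - self.errors

    @property
    def hit_rate(self) -> float:
        return rate(self.accurate, self.total)

    @property
    def error_rate(self) -> float:
        return rate(self.errors, self.total)

    def entity_error_rate(self, disease: str) -> float:
        e, n = self.per_entity[disease]
        return rate(e, n)

    def per_entity_rows(self) -> list[dict]:
        """Rows for the per-entity error table (entity, errors, total, percent)."""
        return [
            {"entity": d, "errors": e, "total": n, "error_rate_pct": rate(e, n)}
            for d, (e, n) in self.per_entity.items()
        ]

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "k": self.k,
            "accurate": self.accurate,
            "errors": self.errors,
            "total": self.total,
            "hit_rate_pct": self.hit_rate,
            "error_rate_pct": self.error_rate,
        }


def rate(numerator: int, denominator: int) -> float:
    """Percentage ``numerator/denominator*100`` rounded half-up to one decimal.

    Exact decimal arithmetic, so printed ratios such as 570/602 -> 94.7
    reproduce to the digit.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError(f"numerator {numerator} outside [0, {denominator}]")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def filter_cases(
    cases: Sequence[CaseProfile],
    kb: KnowledgeBase,
    min_markers: int = 3,
    require_diagnosis: bool = True,
) -> CaseFilterReport:
    """Partition cases into included/excluded per the validation protocol.

    Exclusion reasons, checked in order (each excluded case carries the
    first that applies): ``duplicate`` case id, ``too_few_markers``
    (< ``min_markers`` usable results), ``prognostic_only`` (no usable
    diagnostic-role marker), ``no_diagnosis`` (missing ground truth when
    ``require_diagnosis``).  Never raises: this is a report.
    """
    included: list[CaseProfile] = []
    excluded: list[tuple[CaseProfile, str]] = []
    seen: set[str] = set()
    for case in cases:
        if case.case_id in seen:
            excluded.append((case, "duplicate"))
            continue
        seen.add(case.case_id)
        usable = case.observed
        if len(usable) < min_markers:
            excluded.append((case, "too_few_markers"))
            continue
        roles = [kb.marker_role(r.marker) for r in usable]
        if not any(role == "diagnostic" for role in roles):
            excluded.append((case, "prognostic_only"))
            continue
        if require_diagnosis and not case.original_diagnosis:
            excluded.append((case, "no_diagnosis"))
            continue
        included.append(case)
    return CaseFilterReport(tuple(included), tuple(excluded))


def strict_hit(
    case: CaseProfile, rd: RankedDifferential, kb: KnowledgeBase | None = None
) -> HitOutcome:
    """Does the alias-normalised original diagnosis appear in the top-k?

    When ``kb`` is given the truth is resolved through its alias table
    first, so "MALT lymphoma" matches a canonical "Extranodal marginal
    zone lymphoma of MALT" entry.
    """
    if not case.original_diagnosis:
        raise ValueError(f"case {case.case_id!r} has no original diagnosis")
    truth = case.original_diagnosis
    if kb is not None:
        truth = kb.resolve_disease(truth) or truth
    rank = rd.rank(truth)
    hit = rank is not None
    return HitOutcome(case.case_id, strict=hit, inclusive=hit, rank_of_truth=rank)


def _profiles_indistinguishable(kb: KnowledgeBase, a: str, b: str) -> bool:
    """Same lineage and identical grades on every marker graded for both."""
    pa, pb = kb.profile(a), kb.profile(b)
    if pa.lineage != pb.lineage:
        return False
    shared = set(pa.expression) & set(pb.expression)
    return all(pa.expression[m] == pb.expression[m] for m in shared)


def inclusive_hit(
    case: CaseProfile, rd: RankedDifferential, kb: KnowledgeBase
) -> HitOutcome:
    """Strict hit, or a top-k entry indistinguishable from the truth.

    An entry counts when it shares the truth's lineage and an identical
    KB expression profile over all markers graded for both entities,
    differing at most in site class.  If the truth is absent from the
    KB the outcome is flagged undeterminable (inclusive falls back to
    strict).
    """
    outcome = strict_hit(case, rd, kb)
    if outcome.strict:
        return outcome
    truth = kb.resolve_disease(case.original_diagnosis)
    if truth is None:
        return HitOutcome(case.case_id, strict=False, inclusive=False, undeterminable=True)
    near = any(_profiles_indistinguishable(kb, truth, name) for name in rd.names)
    return HitOutcome(case.case_id, strict=False, inclusive=near, rank_of_truth=None)


def evaluate(
    cases: Sequence[CaseProfile],
    kb: KnowledgeBase,
    k: int = 10,
    mode: str = "strict",
    prior: Mapping[str, float] | str = "uniform",
) -> EvaluationReport:
    """Run the engine on every case and aggregate hits by true entity.

    Cases are assumed pre-filtered (see :func:`filter_cases`).  The
    alias-normalised original diagnosis keys the per-entity table; a
    truth absent from the KB keeps its own spelling and, by definition,
    can never be a hit.
    """
    if mode not in ("strict", "inclusive"):
        raise ValueError(f"mode must be 'strict' or 'inclusive', got {mode!r}")
    if not cases:
        raise ValueError("no cases to evaluate")
    per_entity: dict[str, list[int]] = {}
    outcomes: list[HitOutcome] = []
    for case in cases:
        truth = case.original_diagnosis
        if not truth:
            raise ValueError(f"case {case.case_id!r} has no original diagnosis")
        truth = kb.resolve_disease(truth) or truth
        rd = top_k(posterior(case, kb, prior=prior), k)
        if mode == "strict":
            outcome = strict_hit(case, rd, kb)
            hit = outcome.strict
        else:
            outcome = inclusive_hit(case, rd, kb)
            hit = outcome.inclusive
        outcomes.append(outcome)
        tally = per_entity.setdefault(truth, [0, 0])
        tally[1] += 1
        if not hit:
            tally[0] += 1
    return EvaluationReport(
        per_entity={d: (e, n) for d, (e, n) in sorted(per_entity.items())},
        mode=mode,
        k=k,
        outcomes=tuple(outcomes),
    )


def compare_datasets(
    counts: Sequence[tuple[int, int]],
) -> tuple[float, int, float]:
    """Pearson chi-square on a 2 x g table of (accurate, error) counts.

    Returns ``(statistic, df, p_value)`` with ``df = g - 1``.  No
    continuity correction is applied (the comparison is across g >= 2
    dataset groups, not a 2x2-only design).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] != 2:
        raise ValueError("need a g x 2 table of (accurate, error) counts with g >= 2")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero row or column sum in contingency table")
    result = stats.chi2_contingency(table.T, correction=False)
    return float(result.statistic), int(result.dof), float(result.pvalue)
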