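"""Naive-Bayes posterior ranking over candidate diagnoses.

Given one case's observed marker results and a graded knowledge base,
the engine computes for every disease d

    P(d | panel)  proportional to  P(d) * prod_m P(result_m | d)

with per-marker likelihoods drawn from the knowledge-base grade of
(d, marker): the grade's representative frequency f when the marker is
observed positive, 1 - f when negative.  Markers the KB does not grade
for a disease are uninformative (likelihood 0.5); markers absent from
the KB registry altogether are skipped with a warning.  All likelihoods
are clamped to [0.01, 0.99] so a single atypical result cannot
annihilate the true diagnosis.  The product is accumulated in log space
and normalised over the full candidate set; the top-k view truncates
without renormalising, so displayed probabilities remain posteriors
over all candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np

from .cases import CaseProfile, MarkerResult, NOT_DONE, POSITIVE
from .knowledge import DiseaseProfile, KnowledgeBase

__all__ = [
    "LIKELIHOOD_CLAMP",
    "NEUTRAL_LIKELIHOOD",
    "RankedDifferential",
    "DifferentialTable",
    "marker_likelihood",
    "posterior",
    "top_k",
    "build_differential_table",
    "edit_table",
    "format_percentage",
]

logger = logging.getLogger(__name__)

#: Likelihoods are clamped to [eps, 1 - eps].
LIKELIHOOD_CLAMP = 0.01
#: Likelihood for a marker the KB does not grade for a disease.
NEUTRAL_LIKELIHOOD = 0.5


@dataclass(frozen=True)
class RankedDifferential:
    """Posterior probabilities over candidate diseases, sorted descending.

    Ties are broken by canonical name ascending, so output is fully
    deterministic.  ``k`` is the requested maximum length; before
    truncation the probabilities sum to 1 over the full candidate set.
    """

    entries: tuple[tuple[str, float], ...]
    k: int

    def probability(self, disease: str) -> float | None:
        for name, p in self.entries:
            if name == disease:
                return p
        return None

    def rank(self, disease: str) -> int | None:
        """1-based rank of ``disease`` among the entries, or None."""
        for i, (name, _) in enumerate(self.entries, start=1):
            if name == disease:
                return i
        return None

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.entries)


def marker_likelihood(d: DiseaseProfile, m: MarkerResult, kb: KnowledgeBase) -> float:
    """P(observed result of one marker | disease), clamped to [0.01, 0.99]."""
    if m.result == NOT_DONE:
        raise ValueError(f"marker {m.marker!r} was not done; filter before scoring")
    grade = d.grade(m.marker)
    if grade is None:
        return NEUTRAL_LIKELIHOOD
    f = kb.grade_table.frequency(grade)
    p = f if m.result == POSITIVE else 1.0 - f
    return min(max(p, LIKELIHOOD_CLAMP), 1.0 - LIKELIHOOD_CLAMP)


def posterior(
    case: CaseProfile,
    kb: KnowledgeBase,
    prior: Mapping[str, float] | str = "uniform",
) -> RankedDifferential:
    """Full posterior over all KB diseases for one case.

    ``prior`` is either ``"uniform"`` or a mapping of disease name to
    prior probability summing to 1 over the KB.  Observed markers not in
    the KB registry are skipped with a logged warning.  Raises if the
    case has no usable (performed, registry-known) results.
    """
    if len(kb) == 0:
        raise ValueError("empty knowledge base")
    names = list(kb.disease_names)

    if prior == "uniform":
        log_prior = np.full(len(names), -np.log(len(names)))
    else:
        weights = np.array([float(prior.get(n, 0.0)) for n in names])
        if not np.isclose(weights.sum(), 1.0, atol=1e-6) or (weights < 0).any():
            raise ValueError("prior must be non-negative and sum to 1 over KB diseases")
        with np.errstate(divide="ignore"):
            log_prior = np.log(weights)

    observed = case.observed
    usable: list[MarkerResult] = []
    for r in observed:
        canonical = kb.resolve_marker(r.marker)
        if canonical is None:
            logger.warning(
                "case %s: marker %r not in the knowledge base registry; skipped",
                case.case_id,
                r.marker,
            )
            continue
        usable.append(MarkerResult(canonical, r.result))
    if not usable:
        raise ValueError(f"case {case.case_id!r} has no usable marker results")
    # canonical accumulation order: makes the result bit-identical no matter
    # how the panel was presented, so tie-breaks are stable too
    usable.sort(key=lambda r: r.marker)

    log_scores = log_prior.copy()
    for i, name in enumerate(names):
        d = kb.profile(name)
        for r in usable:
            log_scores[i] += np.log(marker_likelihood(d, r, kb))

    log_scores -= log_scores.max()
    probs = np.exp(log_scores)
    probs /= probs.sum()

    order = sorted(range(len(names)), key=lambda i: (-probs[i], names[i]))
    entries = tuple((names[i], float(probs[i])) for i in order)
    return RankedDifferential(entries=entries, k=len(entries))


def top_k(rd: RankedDifferential, k: int = 10) -> RankedDifferential:
    """First ``k`` entries; probabilities are not renormalised."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return RankedDifferential(entries=rd.entries[:k], k=k)


def format_percentage(p: float) -> str:
    """Render a probability as a percentage, half-up to one decimal."""
    return str(Decimal(p * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# -- differential comparison table ---------------------------------------


@dataclass(frozen=True)
class DifferentialTable:
    """Diseases-as-rows x markers-as-columns grid of grade labels.

    Cells the KB does not grade read ``"unknown"``.  Mirrors the
    side-by-side profile-comparison view pathologists use to weigh a
    shortlist of entities against a candidate antibody panel.
    """

    row_diseases: tuple[str, ...]
    column_markers: tuple[str, ...]
    cells: tuple[tuple[str, ...], ...]

    def cell(self, disease: str, marker: str) -> str:
        i = self.row_diseases.index(disease)
        j = self.column_markers.index(marker)
        return self.cells[i][j]

    def render(self) -> str:
        """Plain-text rendering with aligned columns."""
        header = ["Disease", *self.column_markers]
        rows = [
            [d, *row] for d, row in zip(self.row_diseases, self.cells)
        ]
        widths = [max(len(str(r[j])) for r in [header, *rows]) for j in range(len(header))]
        lines = [
            "  ".join(str(v).ljust(w) for v, w in zip(r, widths)).rstrip()
            for r in [header, *rows]
        ]
        return "\n".join(lines)


def build_differential_table(
    kb: KnowledgeBase, diseases: Sequence[str], markers: Sequence[str]
) -> DifferentialTable:
    """Build the comparison grid for the requested diseases and markers.

    Names are alias-resolved; unresolvable ones are reported together in
    a single error.  Requested row/column order is preserved.
    """
    bad: list[str] = []
    rows: list[str] = []
    for name in diseases:
        canonical = kb.resolve_disease(name)
        if canonical is None:
            bad.append(f"disease {name!r}")
        else:
            rows.append(canonical)
    cols: list[str] = []
    for name in markers:
        canonical = kb.resolve_marker(name)
        if canonical is None:
            bad.append(f"marker {name!r}")
        else:
            cols.append(canonical)
    if bad:
        raise KeyError("unresolvable names: " + ", ".join(bad))
    cells = tuple(
        tuple(kb.profile(d).grade(m) or "unknown" for m in cols) for d in rows
    )
    return DifferentialTable(tuple(rows), tuple(cols), cells)


def edit_table(
    t: DifferentialTable,
    action: str,
    name: str,
    kb: KnowledgeBase,
) -> DifferentialTable:
    """Add or remove one row (disease) or column (marker); returns a new table."""
    if action in ("add_row", "remove_row"):
        canonical = kb.resolve_disease(name) if action == "add_row" else name
        rows = list(t.row_diseases)
        if action == "add_row":
            if canonical is None:
                raise KeyError(f"unresolvable disease {name!r}")
            if canonical in rows:
                raise ValueError(f"disease {canonical!r} already in table")
            rows.append(canonical)
        else:
            resolved = kb.resolve_disease(name) or name
            if resolved not in rows:
                raise KeyError(f"disease {name!r} not in table")
            rows.remove(resolved)
        return build_differential_table(kb, rows, t.column_markers)
    if action in ("add_column", "remove_column"):
        cols = list(t.column_markers)
        if action == "add_column":
            canonical = kb.resolve_marker(name)
            if canonical is None:
                raise KeyError(f"unresolvable marker {name!r}")
            if canonical in cols:
                raise ValueError(f"marker {canonical!r} already in table")
            cols.append(canonical)
        else:
            resolved = kb.resolve_marker(name) or name
            if resolved not in cols:
                raise KeyError(f"marker {name!r} not in table")
            cols.remove(resolved)
        return build_differential_table(kb, t.row_diseases, cols)
    raise ValueError(f"unknown action {action!r}")
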