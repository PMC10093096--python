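"""Synthetic knowledge bases and case cohorts for engine validation.

Because real graded-expression databases and hospital IHC archives are
proprietary, everything here is generated: a knowledge base whose
disease profiles share a controllable fraction of grades (``overlap``),
and cohorts of cases drawn from those profiles with Bernoulli sampling
at each grade's representative frequency, optionally corrupted by
random result flips (``atypical_rate``) that emulate the atypical
immunophenotypes responsible for real-world misses.

Construction of overlap: a single template profile of uniform-random
grades is drawn; each disease copies the template and resamples
``ceil((1 - overlap) * n_markers)`` randomly chosen positions with
fresh uniform grades.  ``overlap=1`` makes every profile identical,
``overlap=0`` makes them independent.  A configurable fraction of
markers may instead be designated *disease-specific*: graded ``++``
for exactly one disease and ``-`` everywhere else, recreating the
contrast between entities with near-pathognomonic markers (TdT, CD56,
EBER) and marker-poor ones.

All randomness flows from one integer seed, split into independent
per-stage streams (knowledge base, cohort, experiments) so partial
runs reproduce exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .cases import CaseProfile, MarkerResult, NEGATIVE, POSITIVE
from .evaluation import EvaluationReport, evaluate
from .grading import GRADE_LABELS
from .inference import posterior
from .knowledge import DiseaseProfile, KnowledgeBase

__all__ = [
    "SimulationConfig",
    "generate_kb",
    "simulate_cases",
    "recovery_experiment",
    "atypical_flip_experiment",
]

_LINEAGE_CYCLE = ("B-cell", "T/NK-cell", "B-cell", "T/NK-cell", "Hodgkin")

# Stage indices for seed-stream splitting.
_STAGE_KB = 0
_STAGE_CASES = 1
_STAGE_EXPERIMENT = 2


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    Defaults emulate the scale of a nationwide lymphoma validation
    cohort: ~150 candidate entities, panels of 8 markers per case
    (archival panels average ~8 stains), ~20 archived cases per entity,
    moderate profile overlap between entities and a small rate of
    atypical (flipped) results.
    """

    n_diseases: int = 150
    n_markers: int = 60
    overlap: float = 0.2
    panel_size: int = 8
    cases_per_disease: int = 20
    atypical_rate: float = 0.05
    specific_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_diseases, self.n_markers, self.panel_size, self.cases_per_disease) < 1:
            raise ValueError("all counts must be >= 1")
        for name in ("overlap", "atypical_rate", "specific_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.panel_size > self.n_markers:
            raise ValueError(
                f"panel_size {self.panel_size} exceeds n_markers {self.n_markers}"
            )

    def rng(self, stage: int) -> np.random.Generator:
        """Independent random stream for one pipeline stage."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stage]))


def _names(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def generate_kb(cfg: SimulationConfig) -> KnowledgeBase:
    """Draw a synthetic knowledge base under ``cfg`` (deterministic in seed)."""
    rng = cfg.rng(_STAGE_KB)
    markers = _names("M", cfg.n_markers)
    disease_names = _names("D", cfg.n_diseases)

    n_specific = int(math.floor(cfg.specific_fraction * cfg.n_markers))
    specific = markers[:n_specific]
    shared = markers[n_specific:]

    template = {m: GRADE_LABELS[rng.integers(len(GRADE_LABELS))] for m in shared}
    n_resample = math.ceil((1.0 - cfg.overlap) * len(shared))

    profiles = []
    for i, name in enumerate(disease_names):
        expression = dict(template)
        if n_resample and shared:
            chosen = rng.choice(len(shared), size=min(n_resample, len(shared)), replace=False)
            for j in chosen:
                expression[shared[j]] = GRADE_LABELS[rng.integers(len(GRADE_LABELS))]
        for j, m in enumerate(specific):
            # each specific marker is pathognomonic for one disease (round-robin)
            expression[m] = "++" if j % cfg.n_diseases == i else "-"
        profiles.append(
            DiseaseProfile(
                name=name,
                lineage=_LINEAGE_CYCLE[i % len(_LINEAGE_CYCLE)],
                expression=expression,
            )
        )
    return KnowledgeBase(
        diseases=tuple(profiles),
        markers={m: "diagnostic" for m in markers},
    )


def simulate_cases(kb: KnowledgeBase, cfg: SimulationConfig) -> list[CaseProfile]:
    """Sample a labelled cohort from ``kb``: ``cases_per_disease`` per entity.

    Each case observes ``panel_size`` markers drawn uniformly without
    replacement; each observed marker is positive with the probability
    of its grade and the result is flipped with ``atypical_rate``.
    """
    if len(kb) == 0:
        raise ValueError("empty knowledge base")
    all_markers = sorted(kb.markers)
    if cfg.panel_size > len(all_markers):
        raise ValueError(
            f"panel_size {cfg.panel_size} exceeds the {len(all_markers)} KB markers"
        )
    rng = cfg.rng(_STAGE_CASES)
    cases: list[CaseProfile] = []
    for d in kb.diseases:
        for c in range(cfg.cases_per_disease):
            idx = rng.choice(len(all_markers), size=cfg.panel_size, replace=False)
            results = []
            for j in sorted(idx):
                m = all_markers[j]
                grade = d.grade(m)
                p = kb.grade_table.frequency(grade) if grade is not None else 0.5
                pos = rng.random() < p
                if cfg.atypical_rate and rng.random() < cfg.atypical_rate:
                    pos = not pos
                results.append(MarkerResult(m, POSITIVE if pos else NEGATIVE))
            cases.append(
                CaseProfile(
                    case_id=f"{d.name}-c{c:04d}",
                    results=tuple(results),
                    original_diagnosis=d.name,
                )
            )
    return cases


def recovery_experiment(
    cfg: SimulationConfig, k: int = 10
) -> tuple[float, EvaluationReport]:
    """Generate a KB and cohort, evaluate, and return the strict hit rate.

    The stand-in for external validation: cases are scored against the
    very knowledge base that generated them, so the hit rate measures
    how well the ranking engine recovers the generating entity under
    the configured overlap, panel size and atypicality.
    """
    kb = generate_kb(cfg)
    cases = simulate_cases(kb, cfg)
    report = evaluate(cases, kb, k=k, mode="strict")
    return report.hit_rate, report


def atypical_flip_experiment(
    cfg: SimulationConfig, n_cases: int = 200
) -> float:
    """Fraction of cases whose true-diagnosis rank strictly worsens after
    one highly specific result is flipped.

    For each trial a disease with at least one ``++`` marker is drawn
    and its most disease-specific strong marker is chosen: the ``++``
    marker whose expected positivity across the *other* entities is
    lowest (the synthetic counterpart of a pathognomonic stain such as
    cyclin D1 in mantle cell lymphoma).  A panel containing that marker
    is sampled from the disease's own profile with the strong marker
    observed positive.  The marker is then flipped to negative — the
    analogue of an atypical antigen-negative tumour — and the true
    disease's rank in the full posterior is compared before and after.
    """
    kb = generate_kb(cfg)
    rng = cfg.rng(_STAGE_EXPERIMENT)
    all_markers = sorted(kb.markers)
    eligible = [
        d for d in kb.diseases if any(g == "++" for g in d.expression.values())
    ]
    if not eligible:
        raise ValueError("no disease has a '++' marker under this configuration")

    def specificity_target(d: DiseaseProfile) -> str:
        """The '++' marker least expressed by the other diseases."""
        strong = sorted(m for m, g in d.expression.items() if g == "++")
        others = [o for o in kb.diseases if o.name != d.name]

        def mean_freq(m: str) -> float:
            freqs = [
                kb.grade_table.frequency(o.grade(m))
                for o in others
                if o.grade(m) is not None
            ]
            return sum(freqs) / len(freqs) if freqs else 0.5

        return min(strong, key=lambda m: (mean_freq(m), m))

    demoted = 0
    for i in range(n_cases):
        d = eligible[rng.integers(len(eligible))]
        target = specificity_target(d)
        others = [m for m in all_markers if m != target]
        idx = rng.choice(len(others), size=cfg.panel_size - 1, replace=False)
        results = [MarkerResult(target, POSITIVE)]
        for j in sorted(idx):
            m = others[j]
            p = kb.grade_table.frequency(d.grade(m))
            results.append(MarkerResult(m, POSITIVE if rng.random() < p else NEGATIVE))
        case = CaseProfile(case_id=f"flip-{i:04d}", results=tuple(results),
                           original_diagnosis=d.name)
        rank_before = posterior(case, kb).rank(d.name)
        flipped = tuple(
            MarkerResult(r.marker, NEGATIVE) if r.marker == target else r
            for r in case.results
        )
        rank_after = posterior(replace(case, results=flipped), kb).rank(d.name)
        if rank_after > rank_before:
            demoted += 1
    return demoted / n_cases
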