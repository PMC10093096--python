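import random

import pytest

from ihcdx import DiseaseProfile, KnowledgeBase, demo_knowledge_base
from ihcdx.cases import CaseProfile, MarkerResult
from ihcdx.grading import GRADE_LABELS


@pytest.fixture(scope="session")
def demo_kb() -> KnowledgeBase:
    return demo_knowledge_base()


def make_random_kb(rng: random.Random, n_diseases: int, n_markers: int) -> KnowledgeBase:
    """Small random KB built with the stdlib RNG, independent of the
    package's own synthetic generator."""
    markers = [f"mk{i}" for i in range(n_markers)]
    diseases = []
    for i in range(n_diseases):
        expression = {
            m: rng.choice(GRADE_LABELS)
            for m in markers
            if rng.random() < 0.8  # leave some markers ungraded
        }
        diseases.append(
            DiseaseProfile(name=f"dz{i}", lineage="B-cell", expression=expression)
        )
    return KnowledgeBase(diseases=tuple(diseases), markers={m: "diagnostic" for m in markers})


def make_random_case(rng: random.Random, kb: KnowledgeBase, case_id: str = "c0") -> CaseProfile:
    markers = sorted(kb.markers)
    n = rng.randint(1, len(markers))
    chosen = rng.sample(markers, n)
    return CaseProfile(
        case_id=case_id,
        results=tuple(
            MarkerResult(m, rng.choice(["positive", "negative"])) for m in chosen
        ),
    )
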