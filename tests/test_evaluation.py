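"""Validation harness: filters, hit definitions, rates, chi-square."""

import random

import numpy as np
import pytest

from conftest import make_random_kb
from ihcdx import (
    DiseaseProfile,
    KnowledgeBase,
    compare_datasets,
    evaluate,
    filter_cases,
    inclusive_hit,
    posterior,
    rate,
    strict_hit,
    top_k,
)
from ihcdx.cases import CaseProfile, MarkerResult
from ihcdx.evaluation import HitOutcome
from ihcdx.inference import RankedDifferential

POS = "positive"
NEG = "negative"


def case_of(case_id="c", truth=None, **results):
    return CaseProfile(
        case_id,
        tuple(MarkerResult(m, r) for m, r in results.items()),
        original_diagnosis=truth,
    )


# -- rate -----------------------------------------------------------------


@pytest.mark.parametrize(
    "num, den, expected",
    [
        (570, 602, 94.7),
        (0, 42, 0.0),
        (2715, 2993, 90.7),
        (63, 436, 14.4),
        (1, 3, 33.3),
        (1, 8, 12.5),
    ],
)
def test_rate_half_up_one_decimal(num, den, expected):
    assert rate(num, den) == expected


def test_rate_rejects_bad_inputs():
    with pytest.raises(ValueError):
        rate(1, 0)
    with pytest.raises(ValueError):
        rate(5, 3)
    with pytest.raises(ValueError):
        rate(-1, 3)


# -- case filtering -------------------------------------------------------


@pytest.fixture
def filter_kb():
    return KnowledgeBase(
        diseases=(DiseaseProfile("dz", "B-cell", {"CD20": "++", "CD3": "-"}),),
        markers={
            "CD20": "diagnostic",
            "CD3": "diagnostic",
            "CD5": "diagnostic",
            "p53": "prognostic_only",
            "EGFR": "prognostic_only",
        },
    )


def test_filter_reasons(filter_kb):
    two_markers = case_of("few", truth="dz", CD20=POS, CD3=NEG)
    three_markers = case_of("ok", truth="dz", CD20=POS, CD3=NEG, CD5=NEG)
    prognostic = case_of("prog", truth="dz", p53=POS, EGFR=NEG, CD20="not_done")
    no_truth = case_of("anon", CD20=POS, CD3=NEG, CD5=NEG)
    dupe = case_of("ok", truth="dz", CD20=POS, CD3=NEG, CD5=NEG)

    report = filter_cases([two_markers, three_markers, prognostic, no_truth, dupe], filter_kb)
    assert [c.case_id for c in report.included] == ["ok"]
    reasons = {c.case_id: r for c, r in report.excluded}
    assert reasons == {
        "few": "too_few_markers",
        "prog": "too_few_markers",  # not_done CD20 leaves only 2 usable
        "anon": "no_diagnosis",
        "ok": "duplicate",
    }


def test_filter_prognostic_only_panel(filter_kb):
    # three usable results, none with a diagnostic role
    prognostic = CaseProfile(
        "prog",
        (
            MarkerResult("p53", POS),
            MarkerResult("EGFR", NEG),
            MarkerResult("unregistered", POS),
        ),
        original_diagnosis="dz",
    )
    report = filter_cases([prognostic], filter_kb)
    assert report.excluded[0][1] == "prognostic_only"


def test_filter_partition_is_exhaustive(filter_kb):
    cases = [case_of(f"c{i}", truth="dz", CD20=POS, CD3=NEG, CD5=POS) for i in range(5)]
    cases.append(case_of("short", truth="dz", CD20=POS))
    report = filter_cases(cases, filter_kb)
    assert len(report.included) + len(report.excluded) == len(cases)


# -- hit definitions ------------------------------------------------------


def rd_of(*names):
    n = len(names)
    return RankedDifferential(tuple((nm, 1 / n) for nm in names), k=n)


def test_strict_hit_rank_recorded():
    out = strict_hit(case_of(truth="b"), rd_of("a", "b", "c"))
    assert out.strict and out.inclusive and out.rank_of_truth == 2
    miss = strict_hit(case_of(truth="z"), rd_of("a", "b", "c"))
    assert not miss.strict and miss.rank_of_truth is None


def test_strict_hit_requires_truth():
    with pytest.raises(ValueError):
        strict_hit(case_of(), rd_of("a"))


def test_strict_implies_inclusive_enforced():
    with pytest.raises(ValueError):
        HitOutcome("c", strict=True, inclusive=False)


@pytest.fixture
def mzl_kb():
    """Nodal and extranodal marginal zone lymphoma: same lineage, same
    profile, different site; plus a distinct third entity."""
    shared = {"CD20": "++", "CD5": "-", "CD10": "-", "CD23": "-/+"}
    return KnowledgeBase(
        diseases=(
            DiseaseProfile("Extranodal marginal zone lymphoma of MALT", "B-cell", shared, "extranodal"),
            DiseaseProfile("Nodal marginal zone lymphoma", "B-cell", shared, "nodal"),
            DiseaseProfile("Mantle cell lymphoma", "B-cell",
                           {"CD20": "++", "CD5": "++", "CD10": "-", "CD23": "-"}, "nodal"),
        ),
        markers={m: "diagnostic" for m in ("CD20", "CD5", "CD10", "CD23")},
        aliases={"MALT lymphoma": "Extranodal marginal zone lymphoma of MALT"},
    )


def test_alias_spelling_counts_as_strict_hit(mzl_kb):
    rd = rd_of("Extranodal marginal zone lymphoma of MALT")
    out = strict_hit(case_of(truth="MALT lymphoma"), rd, mzl_kb)
    assert out.strict


def test_inclusive_hit_for_site_only_difference(mzl_kb):
    case = case_of(truth="Nodal marginal zone lymphoma")
    rd = rd_of("Extranodal marginal zone lymphoma of MALT")
    out = inclusive_hit(case, rd, mzl_kb)
    assert not out.strict and out.inclusive


def test_profile_difference_blocks_inclusive_hit(mzl_kb):
    case = case_of(truth="Mantle cell lymphoma")  # CD5/CD23 differ from MZL
    rd = rd_of("Nodal marginal zone lymphoma")
    out = inclusive_hit(case, rd, mzl_kb)
    assert not out.inclusive


def test_inclusive_undeterminable_for_unknown_truth(mzl_kb):
    out = inclusive_hit(case_of(truth="not in kb"), rd_of("Mantle cell lymphoma"), mzl_kb)
    assert out.undeterminable and not out.inclusive


def test_strict_implies_inclusive_property():
    rng = random.Random(77)
    kb = make_random_kb(rng, 6, 6)
    names = kb.disease_names
    for trial in range(200):
        markers = rng.sample(sorted(kb.markers), rng.randint(1, 6))
        case = CaseProfile(
            f"t{trial}",
            tuple(MarkerResult(m, rng.choice([POS, NEG])) for m in markers),
            original_diagnosis=rng.choice(names),
        )
        rd = top_k(posterior(case, kb), rng.choice([1, 3, 6]))
        out = inclusive_hit(case, rd, kb)
        if out.strict:
            assert out.inclusive


# -- evaluate -------------------------------------------------------------


@pytest.fixture
def toy_kb():
    return KnowledgeBase(
        diseases=tuple(
            DiseaseProfile(n, "B-cell", e)
            for n, e in {
                "A": {"CD20": "++", "CD3": "-"},
                "B": {"CD20": "-", "CD3": "++"},
                "C": {"CD20": "+", "CD3": "+"},
            }.items()
        ),
        markers={"CD20": "diagnostic", "CD3": "diagnostic"},
    )


def test_evaluate_hand_aggregation(toy_kb):
    """3 cases of A; the engine puts A in the top-1 for 2 of them."""
    cases = [
        case_of("a1", truth="A", CD20=POS, CD3=NEG),   # typical -> hit
        case_of("a2", truth="A", CD20=POS, CD3=NEG),   # typical -> hit
        case_of("a3", truth="A", CD20=NEG, CD3=POS),   # atypical -> B wins
    ]
    report = evaluate(cases, toy_kb, k=1, mode="strict")
    assert report.per_entity["A"] == (1, 3)
    assert report.entity_error_rate("A") == 33.3
    assert report.summary()["hit_rate_pct"] == 66.7


def test_evaluate_all_hits_zero_error(toy_kb):
    cases = [case_of(f"c{i}", truth="A", CD20=POS, CD3=NEG) for i in range(4)]
    report = evaluate(cases, toy_kb, k=3, mode="strict")
    assert report.error_rate == 0.0 and report.hit_rate == 100.0


def test_evaluate_conservation_on_random_cohort():
    rng = random.Random(5)
    kb = make_random_kb(rng, 5, 6)
    cases = []
    for i in range(60):
        markers = rng.sample(sorted(kb.markers), 3)
        cases.append(
            CaseProfile(
                f"c{i}",
                tuple(MarkerResult(m, rng.choice([POS, NEG])) for m in markers),
                original_diagnosis=rng.choice(kb.disease_names),
            )
        )
    report = evaluate(cases, kb, k=3, mode="strict")
    assert sum(n for _, n in report.per_entity.values()) == report.total == 60
    assert sum(e for e, _ in report.per_entity.values()) == report.errors
    assert report.accurate + report.errors == report.total


def test_hit_rate_nondecreasing_in_k(toy_kb):
    rng = random.Random(11)
    cases = []
    for i in range(30):
        cases.append(
            case_of(
                f"c{i}",
                truth=rng.choice(toy_kb.disease_names),
                CD20=rng.choice([POS, NEG]),
                CD3=rng.choice([POS, NEG]),
            )
        )
    rates = [evaluate(cases, toy_kb, k=k, mode="strict").hit_rate for k in (1, 2, 3)]
    assert rates == sorted(rates)


def test_evaluate_empty_rejected(toy_kb):
    with pytest.raises(ValueError):
        evaluate([], toy_kb)


def test_evaluate_inclusive_at_least_strict(mzl_kb):
    cases = [
        case_of("n1", truth="Nodal marginal zone lymphoma", CD20=POS, CD5=NEG, CD10=NEG),
        case_of("m1", truth="MALT lymphoma", CD20=POS, CD5=NEG, CD10=NEG),
        case_of("x1", truth="Mantle cell lymphoma", CD20=POS, CD5=POS, CD10=NEG),
    ]
    strict = evaluate(cases, mzl_kb, k=1, mode="strict")
    inclusive = evaluate(cases, mzl_kb, k=1, mode="inclusive")
    assert inclusive.hit_rate >= strict.hit_rate


# -- chi-square -----------------------------------------------------------


def test_chi_square_zero_for_identical_proportions():
    stat, df, p = compare_datasets([(100, 10), (200, 20)])
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert df == 1
    assert p == pytest.approx(1.0)


def test_chi_square_df_and_symmetry():
    counts = [(570, 32), (365, 17), (2715, 278)]
    stat, df, p = compare_datasets(counts)
    assert df == 2
    stat_swapped, df2, p2 = compare_datasets(list(reversed(counts)))
    assert stat_swapped == pytest.approx(stat)
    assert p2 == pytest.approx(p)


def test_chi_square_matches_textbook_formula():
    """Independent oracle: sum over cells of (O - E)^2 / E."""
    counts = [(570, 32), (365, 17), (2715, 278)]
    observed = np.array(counts, dtype=float)
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    expected = row @ col / observed.sum()
    oracle = ((observed - expected) ** 2 / expected).sum()
    stat, df, _ = compare_datasets(counts)
    assert stat == pytest.approx(oracle, abs=1e-9)


def test_chi_square_rejects_degenerate_tables():
    with pytest.raises(ValueError):
        compare_datasets([(5, 5)])  # single group
    with pytest.raises(ValueError):
        compare_datasets([(0, 0), (3, 4)])  # zero row sum
    with pytest.raises(ValueError):
        compare_datasets([(5, 0), (3, 0)])  # zero column sum
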