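"""A small curated lymphoma knowledge base for demos and tests.

Two dozen hematolymphoid entities with textbook-style graded
immunophenotypes (WHO-classification immunoarchitecture as summarised
in standard hematopathology references), over a registry of ~30
commonly stained markers.  Grades encode the typical fraction of cases
positive: ``++`` 75-100%, ``+`` 50-74%, ``+/-`` 30-49%, ``-/+``
10-29%, ``-`` 0-9%.  This is a demonstration profile set, not a
clinical database: grades are curated conventions at entity level and
carry no institutional calibration.

Includes the classic near-indistinguishable pair (nodal vs extranodal
marginal zone lymphoma: same lineage and profile, different site),
which exercises the inclusive-hit rule, and prognostic-only markers
(p53, EGFR) for the panel-exclusion filter.
"""

from __future__ import annotations

from .knowledge import DiseaseProfile, KnowledgeBase

__all__ = ["demo_knowledge_base"]

_MARKERS: dict[str, str] = {
    **{
        m: "diagnostic"
        for m in (
            "CD45", "CD20", "CD79a", "PAX5", "CD3", "CD2", "CD4", "CD5", "CD7",
            "CD8", "CD10", "CD15", "CD21", "CD23", "CD25", "CD30", "CD56",
            "CD138", "Bcl-2", "Bcl-6", "MUM1", "Cyclin D1", "SOX11", "TdT",
            "Ki-67", "EBER", "ALK", "EMA", "PD-1", "Granzyme B",
        )
    },
    "p53": "prognostic_only",
    "EGFR": "prognostic_only",
}

_MZL_PROFILE = {
    "CD20": "++", "CD79a": "++", "PAX5": "++", "CD3": "-", "CD5": "-/+",
    "CD10": "-", "CD23": "-/+", "Bcl-2": "+", "Bcl-6": "-", "MUM1": "-/+",
    "Cyclin D1": "-", "TdT": "-", "CD30": "-", "CD56": "-",
}

_CHL_PROFILE = {
    "CD30": "++", "CD15": "+", "PAX5": "+/-", "CD20": "-/+", "CD3": "-",
    "CD45": "-", "EBER": "+/-", "ALK": "-", "EMA": "-/+", "CD79a": "-/+",
    "MUM1": "++",
}

# (name, lineage, site_class, expression)
_DISEASES: list[tuple[str, str, str | None, dict[str, str]]] = [
    (
        "Diffuse large B-cell lymphoma, NOS", "B-cell", "nodal",
        {
            "CD45": "++", "CD20": "++", "CD79a": "++", "PAX5": "++", "CD3": "-",
            "CD5": "-/+", "CD10": "+/-", "CD23": "-", "Bcl-2": "+", "Bcl-6": "+",
            "MUM1": "+/-", "Cyclin D1": "-", "TdT": "-", "CD30": "-/+",
            "Ki-67": "++", "EBER": "-", "CD56": "-",
        },
    ),
    (
        "Follicular lymphoma", "B-cell", "nodal",
        {
            "CD45": "++", "CD20": "++", "CD79a": "++", "PAX5": "++", "CD10": "++",
            "Bcl-2": "++", "Bcl-6": "++", "CD3": "-", "CD5": "-", "CD23": "-/+",
            "Cyclin D1": "-", "MUM1": "-/+", "TdT": "-", "Ki-67": "+/-",
            "CD30": "-",
        },
    ),
    (
        "Mantle cell lymphoma", "B-cell", "nodal",
        {
            "CD45": "++", "CD20": "++", "CD79a": "++", "CD5": "++",
            "Cyclin D1": "++", "SOX11": "+", "CD10": "-", "CD23": "-",
            "Bcl-2": "++", "Bcl-6": "-", "CD3": "-", "MUM1": "-/+", "TdT": "-",
            "Ki-67": "+/-",
        },
    ),
    (
        "Chronic lymphocytic leukemia/small lymphocytic lymphoma", "B-cell", "nodal",
        {
            "CD45": "++", "CD20": "+", "CD79a": "++", "CD5": "++", "CD23": "++",
            "CD10": "-", "Cyclin D1": "-", "Bcl-2": "++", "Bcl-6": "-",
            "CD3": "-", "MUM1": "-/+", "TdT": "-", "Ki-67": "-/+",
        },
    ),
    (
        "Extranodal marginal zone lymphoma of MALT", "B-cell", "extranodal",
        _MZL_PROFILE,
    ),
    (
        "Nodal marginal zone lymphoma", "B-cell", "nodal",
        _MZL_PROFILE,
    ),
    (
        "Burkitt lymphoma", "B-cell", "extranodal",
        {
            "CD45": "++", "CD20": "++", "CD79a": "++", "CD10": "++", "Bcl-6": "++",
            "Bcl-2": "-", "Ki-67": "++", "CD3": "-", "CD5": "-", "TdT": "-",
            "Cyclin D1": "-", "MUM1": "-/+", "CD23": "-",
        },
    ),
    (
        "B lymphoblastic leukemia/lymphoma", "B-cell", "nodal",
        {
            "TdT": "++", "CD10": "++", "PAX5": "++", "CD79a": "+", "CD20": "-/+",
            "CD45": "+", "CD3": "-", "Ki-67": "++", "Bcl-2": "+/-", "CD5": "-",
        },
    ),
    (
        "T lymphoblastic leukemia/lymphoma", "T/NK-cell", "nodal",
        {
            "TdT": "++", "CD3": "+", "CD7": "++", "CD2": "+", "CD5": "+",
            "CD4": "+/-", "CD8": "+/-", "CD10": "+/-", "CD20": "-",
            "CD45": "+", "Ki-67": "++",
        },
    ),
    (
        "Plasma cell myeloma", "B-cell", "extranodal",
        {
            "CD138": "++", "MUM1": "++", "CD79a": "+/-", "CD20": "-/+",
            "CD56": "+", "CD45": "-/+", "CD3": "-", "Cyclin D1": "-/+",
            "PAX5": "-", "EBER": "-",
        },
    ),
    (
        "Plasmablastic lymphoma", "B-cell", "extranodal",
        {
            "CD138": "++", "MUM1": "++", "CD30": "+/-", "CD79a": "+/-",
            "CD20": "-/+", "EBER": "+", "Ki-67": "++", "ALK": "-", "CD45": "-/+",
            "CD3": "-", "PAX5": "-/+", "CD56": "-/+",
        },
    ),
    (
        "Primary mediastinal (thymic) large B-cell lymphoma", "B-cell", "nodal",
        {
            "CD45": "++", "CD20": "++", "CD79a": "++", "PAX5": "++", "CD30": "+/-",
            "CD23": "+", "CD15": "-", "CD10": "-/+", "Bcl-6": "+", "MUM1": "+",
            "CD3": "-", "EBER": "-",
        },
    ),
    (
        "Extranodal NK/T-cell lymphoma, nasal type", "T/NK-cell", "extranodal",
        {
            "CD56": "++", "EBER": "++", "CD3": "+", "CD2": "++",
            "Granzyme B": "++", "CD20": "-", "CD5": "-/+", "CD4": "-",
            "CD8": "-/+", "CD45": "+", "CD30": "-/+",
        },
    ),
    (
        "Peripheral T-cell lymphoma, NOS", "T/NK-cell", "nodal",
        {
            "CD45": "++", "CD3": "++", "CD4": "+", "CD2": "+", "CD5": "+",
            "CD7": "+/-", "CD8": "-/+", "CD20": "-", "CD30": "-/+", "CD56": "-/+",
            "EBER": "-/+", "TdT": "-",
        },
    ),
    (
        "Angioimmunoblastic T-cell lymphoma", "T/NK-cell", "nodal",
        {
            "CD45": "++", "CD3": "++", "CD4": "++", "PD-1": "++", "CD10": "+",
            "Bcl-6": "+", "CD21": "+", "CD20": "-", "CD8": "-/+", "CD2": "+",
            "CD5": "+", "EBER": "+/-",
        },
    ),
    (
        "ALCL, ALK-positive", "T/NK-cell", "nodal",
        {
            "CD30": "++", "ALK": "++", "EMA": "+", "CD3": "-/+", "CD4": "+",
            "CD2": "+", "CD20": "-", "CD15": "-", "Granzyme B": "+",
            "CD45": "+", "EBER": "-",
        },
    ),
    (
        "ALCL, ALK-negative", "T/NK-cell", "nodal",
        {
            "CD30": "++", "ALK": "-", "EMA": "+/-", "CD3": "-/+", "CD4": "+",
            "CD2": "+", "CD20": "-", "CD15": "-", "Granzyme B": "+",
            "CD45": "+", "EBER": "-",
        },
    ),
    (
        "Adult T-cell leukemia/lymphoma", "T/NK-cell", "nodal",
        {
            "CD45": "++", "CD3": "++", "CD4": "++", "CD25": "++", "CD7": "-",
            "CD8": "-", "CD20": "-", "CD30": "-/+", "CD2": "+", "CD5": "+",
        },
    ),
    (
        "Mycosis fungoides", "T/NK-cell", "cutaneous",
        {
            "CD45": "++", "CD3": "++", "CD4": "++", "CD8": "-/+", "CD7": "-/+",
            "CD2": "+", "CD5": "+", "CD20": "-", "CD30": "-/+", "CD25": "-/+",
        },
    ),
    (
        "Classical Hodgkin lymphoma, NOS", "Hodgkin", "nodal",
        _CHL_PROFILE,
    ),
    (
        "Nodular sclerosis classical Hodgkin lymphoma", "Hodgkin", "nodal",
        {**_CHL_PROFILE, "EBER": "-/+"},
    ),
    (
        "Nodular lymphocyte-predominant Hodgkin lymphoma", "Hodgkin", "nodal",
        {
            "CD20": "++", "CD45": "++", "PAX5": "++", "Bcl-6": "++", "EMA": "+",
            "CD30": "-", "CD15": "-", "CD3": "-", "EBER": "-", "CD79a": "+",
            "MUM1": "-/+",
        },
    ),
    (
        "Primary cutaneous follicle center lymphoma", "B-cell", "cutaneous",
        {
            "CD20": "++", "CD79a": "++", "PAX5": "++", "Bcl-6": "++",
            "CD10": "+/-", "Bcl-2": "-/+", "CD3": "-", "Cyclin D1": "-",
            "MUM1": "-", "CD45": "++",
        },
    ),
    (
        "Lymphoplasmacytic lymphoma", "B-cell", "nodal",
        {
            "CD45": "++", "CD20": "++", "CD79a": "++", "CD138": "+/-",
            "CD5": "-/+", "CD10": "-", "CD23": "-/+", "MUM1": "+/-",
            "Cyclin D1": "-", "CD3": "-", "Bcl-2": "+",
        },
    ),
]

_ALIASES = {
    "DLBCL": "Diffuse large B-cell lymphoma, NOS",
    "DLBCL, NOS": "Diffuse large B-cell lymphoma, NOS",
    "MALT lymphoma": "Extranodal marginal zone lymphoma of MALT",
    "Extranodal marginal zone lymphoma of MALT (lymphoma)": "Extranodal marginal zone lymphoma of MALT",
    "MCL": "Mantle cell lymphoma",
    "FL": "Follicular lymphoma",
    "CLL/SLL": "Chronic lymphocytic leukemia/small lymphocytic lymphoma",
    "ENKTL": "Extranodal NK/T-cell lymphoma, nasal type",
    "PTCL, NOS": "Peripheral T-cell lymphoma, NOS",
    "AITL": "Angioimmunoblastic T-cell lymphoma",
    "cHL": "Classical Hodgkin lymphoma, NOS",
    "NLPHL": "Nodular lymphocyte-predominant Hodgkin lymphoma",
    "cyclinD1": "Cyclin D1",
    "Ki67": "Ki-67",
    "Bcl2": "Bcl-2",
    "Bcl6": "Bcl-6",
}


def demo_knowledge_base() -> KnowledgeBase:
    """Build the curated demo knowledge base (24 lymphoma entities)."""
    return KnowledgeBase(
        diseases=tuple(
            DiseaseProfile(name=n, lineage=lin, site_class=site, expression=expr)
            for n, lin, site, expr in _DISEASES
        ),
        markers=dict(_MARKERS),
        aliases=dict(_ALIASES),
    )
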