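"""Disease x marker graded-expression knowledge base.

A :class:`KnowledgeBase` is the table from which diagnostic likelihoods
are drawn: for every disease entity it stores a mapping from marker name
to a five-level expression grade (see :mod:`ihcdx.grading`), together
with lineage (cell of origin) and an optional anatomic site class.  A
marker registry carries role tags so that panels containing only
prognostic/therapeutic markers (e.g. EGFR, p53) can be excluded from
evaluation, and an alias table maps alternative spellings of disease and
marker names onto canonical ones.

Serialisation is JSON (nested, the default) or CSV in long format
(``disease,lineage,site_class,marker,grade``) for hand authoring; a
save/load round trip is the identity.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .grading import DEFAULT_GRADE_TABLE, GradeBand, GradeTable

__all__ = [
    "canonical_key",
    "DiseaseProfile",
    "KnowledgeBase",
    "KnowledgeBaseError",
    "load_knowledge_base",
    "save_knowledge_base",
]

LINEAGES = ("B-cell", "T/NK-cell", "Hodgkin", "histiocytic", "other")
MARKER_ROLES = ("diagnostic", "prognostic_only")


class KnowledgeBaseError(ValueError):
    """Schema or consistency violation in a knowledge base."""


def canonical_key(name: str) -> str:
    """Normalisation key: case-insensitive, whitespace collapsed."""
    return re.sub(r"\s+", " ", name.strip()).casefold()


@dataclass(frozen=True)
class DiseaseProfile:
    """One disease entity and its graded marker-expression profile.

    Markers absent from ``expression`` are *unknown* for this disease
    (as opposed to negative); the inference engine treats them as
    uninformative.
    """

    name: str
    lineage: str
    expression: Mapping[str, str]
    site_class: str | None = None

    def __post_init__(self) -> None:
        if self.lineage not in LINEAGES:
            raise KnowledgeBaseError(
                f"disease {self.name!r}: lineage {self.lineage!r} not in {LINEAGES}"
            )
        object.__setattr__(self, "expression", dict(self.expression))

    def grade(self, marker: str) -> str | None:
        """Grade label for ``marker``, or None if unknown for this disease."""
        return self.expression.get(marker)


@dataclass(frozen=True)
class KnowledgeBase:
    """Collection of disease profiles plus marker registry and aliases.

    ``markers`` maps canonical marker name -> role (``diagnostic`` or
    ``prognostic_only``); ``aliases`` maps alternative spellings (of
    diseases or markers) to canonical names.  All resolution goes
    through :meth:`resolve_disease` / :meth:`resolve_marker`, which are
    idempotent: a canonical name resolves to itself.
    """

    diseases: tuple[DiseaseProfile, ...]
    markers: Mapping[str, str] = field(default_factory=dict)
    aliases: Mapping[str, str] = field(default_factory=dict)
    grade_table: GradeTable = field(default_factory=lambda: DEFAULT_GRADE_TABLE)

    def __post_init__(self) -> None:
        object.__setattr__(self, "diseases", tuple(self.diseases))
        object.__setattr__(self, "markers", dict(self.markers))
        object.__setattr__(self, "aliases", dict(self.aliases))
        self._validate()
        object.__setattr__(
            self, "_by_key", {canonical_key(d.name): d for d in self.diseases}
        )
        object.__setattr__(
            self, "_marker_by_key", {canonical_key(m): m for m in self.markers}
        )
        object.__setattr__(
            self,
            "_alias_by_key",
            {canonical_key(a): c for a, c in self.aliases.items()},
        )

    def _validate(self) -> None:
        keys = [canonical_key(d.name) for d in self.diseases]
        dupes = {k for k in keys if keys.count(k) > 1}
        if dupes:
            raise KnowledgeBaseError(f"duplicate disease names: {sorted(dupes)}")
        valid_labels = set(self.grade_table.labels)
        for d in self.diseases:
            for m, g in d.expression.items():
                if g not in valid_labels:
                    raise KnowledgeBaseError(
                        f"disease {d.name!r}, marker {m!r}: unknown grade label {g!r}"
                    )
                if m not in self.markers:
                    raise KnowledgeBaseError(
                        f"disease {d.name!r} references marker {m!r} absent from the registry"
                    )
        for m, role in self.markers.items():
            if role not in MARKER_ROLES:
                raise KnowledgeBaseError(f"marker {m!r}: role {role!r} not in {MARKER_ROLES}")

    # -- lookup -----------------------------------------------------------

    @property
    def disease_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.diseases)

    def resolve_disease(self, name: str) -> str | None:
        """Canonical disease name for ``name`` (alias-aware), or None."""
        key = canonical_key(name)
        key = canonical_key(self._alias_by_key.get(key, key))
        d = self._by_key.get(key)
        return d.name if d is not None else None

    def resolve_marker(self, name: str) -> str | None:
        """Canonical registry marker name for ``name``, or None."""
        key = canonical_key(name)
        key = canonical_key(self._alias_by_key.get(key, key))
        return self._marker_by_key.get(key)

    def profile(self, name: str) -> DiseaseProfile:
        canonical = self.resolve_disease(name)
        if canonical is None:
            raise KeyError(f"unknown disease {name!r}")
        return self._by_key[canonical_key(canonical)]

    def marker_role(self, marker: str) -> str | None:
        canonical = self.resolve_marker(marker)
        return self.markers.get(canonical) if canonical else None

    def __len__(self) -> int:
        return len(self.diseases)

    def with_diseases(self, diseases: Iterable[DiseaseProfile]) -> "KnowledgeBase":
        return replace(self, diseases=tuple(diseases))


# -- serialisation --------------------------------------------------------


def _kb_to_dict(kb: KnowledgeBase) -> dict:
    return {
        "grade_table": [
            {"label": b.label, "lo": b.lo, "hi": b.hi, "frequency": b.frequency}
            for b in kb.grade_table.bands
        ],
        "markers": [{"name": m, "role": r} for m, r in kb.markers.items()],
        "diseases": [
            {
                "name": d.name,
                "lineage": d.lineage,
                "site_class": d.site_class,
                "expression": dict(d.expression),
            }
            for d in kb.diseases
        ],
        "aliases": dict(kb.aliases),
    }


def _kb_from_dict(doc: dict) -> KnowledgeBase:
    try:
        if "grade_table" in doc:
            table = GradeTable(
                tuple(
                    GradeBand(b["label"], b["lo"], b["hi"], b["frequency"])
                    for b in doc["grade_table"]
                )
            )
        else:
            table = DEFAULT_GRADE_TABLE
        markers = {m["name"]: m.get("role", "diagnostic") for m in doc.get("markers", [])}
        diseases = tuple(
            DiseaseProfile(
                name=d["name"],
                lineage=d["lineage"],
                site_class=d.get("site_class"),
                expression=d.get("expression", {}),
            )
            for d in doc.get("diseases", [])
        )
    except (KeyError, TypeError) as exc:
        raise KnowledgeBaseError(f"malformed knowledge-base record: {exc}") from exc
    return KnowledgeBase(
        diseases=diseases,
        markers=markers,
        aliases=doc.get("aliases", {}),
        grade_table=table,
    )


def load_knowledge_base(source: str | Path) -> KnowledgeBase:
    """Read a knowledge base from JSON (nested) or CSV (long format).

    The format is picked by file extension.  CSV rows are
    ``disease,lineage,site_class,marker,grade``; markers default to role
    ``diagnostic`` (CSV carries no registry).  All invariants are
    checked; violations raise :class:`KnowledgeBaseError` naming the
    offending disease/marker.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        return _load_csv(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise KnowledgeBaseError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    return _kb_from_dict(doc)


def _load_csv(path: Path) -> KnowledgeBase:
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"disease", "lineage", "marker", "grade"}
    if not required.issubset(df.columns):
        raise KnowledgeBaseError(
            f"{path}: CSV must have columns {sorted(required)}; got {list(df.columns)}"
        )
    diseases: dict[str, dict] = {}
    markers: dict[str, str] = {}
    for idx, row in df.iterrows():
        name = row["disease"].strip()
        rec = diseases.setdefault(
            name,
            {
                "lineage": row["lineage"].strip(),
                "site_class": (row.get("site_class") or "").strip() or None,
                "expression": {},
            },
        )
        marker = row["marker"].strip()
        if marker:
            if marker in rec["expression"]:
                raise KnowledgeBaseError(f"{path}: row {idx + 2}: duplicate ({name}, {marker})")
            rec["expression"][marker] = row["grade"].strip()
            markers.setdefault(marker, "diagnostic")
    return KnowledgeBase(
        diseases=tuple(
            DiseaseProfile(name=n, lineage=r["lineage"], site_class=r["site_class"], expression=r["expression"])
            for n, r in diseases.items()
        ),
        markers=markers,
    )


def save_knowledge_base(kb: KnowledgeBase, dest: str | Path) -> Path:
    """Write ``kb`` to JSON or CSV by extension; returns the path written."""
    path = Path(dest)
    if path.suffix.lower() == ".csv":
        rows = [
            {
                "disease": d.name,
                "lineage": d.lineage,
                "site_class": d.site_class or "",
                "marker": m,
                "grade": g,
            }
            for d in kb.diseases
            for m, g in d.expression.items()
        ]
        pd.DataFrame(rows, columns=["disease", "lineage", "site_class", "marker", "grade"]).to_csv(
            path, index=False
        )
    else:
        path.write_text(json.dumps(_kb_to_dict(kb), indent=2) + "\n")
    return path
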