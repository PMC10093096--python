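"""Per-patient IHC panels: one case = a set of marker results.

Each marker in a case is read as ``positive``, ``negative`` or
``not_done``; ``not_done`` entries never influence the posterior.  Cases
optionally carry the original (ground-truth) diagnosis and an anatomic
site, which the validation harness needs.

Interchange formats:

* CSV, one row per (case, marker): header
  ``case_id,marker,result[,original_diagnosis,site]`` with result in
  ``{+, -, nd}``.
* JSON: a list of ``{case_id, site, original_diagnosis,
  results: {marker: "+"|"-"|"nd"}}`` objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "POSITIVE",
    "NEGATIVE",
    "NOT_DONE",
    "MarkerResult",
    "CaseProfile",
    "load_cases",
    "save_cases",
]

POSITIVE = "positive"
NEGATIVE = "negative"
NOT_DONE = "not_done"
_RESULTS = (POSITIVE, NEGATIVE, NOT_DONE)

_SHORT = {"+": POSITIVE, "-": NEGATIVE, "nd": NOT_DONE}
_TO_SHORT = {v: k for k, v in _SHORT.items()}


@dataclass(frozen=True)
class MarkerResult:
    marker: str
    result: str

    def __post_init__(self) -> None:
        if self.result not in _RESULTS:
            raise ValueError(
                f"marker {self.marker!r}: result {self.result!r} not in {_RESULTS}"
            )


@dataclass(frozen=True)
class CaseProfile:
    """One patient's observed IHC panel with optional ground truth."""

    case_id: str
    results: tuple[MarkerResult, ...]
    original_diagnosis: str | None = None
    site: str | None = None
    flags: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "results", tuple(self.results))
        markers = [r.marker for r in self.results]
        dupes = {m for m in markers if markers.count(m) > 1}
        if dupes:
            raise ValueError(f"case {self.case_id!r}: duplicate markers {sorted(dupes)}")

    @property
    def observed(self) -> tuple[MarkerResult, ...]:
        """Results actually performed (positive or negative)."""
        return tuple(r for r in self.results if r.result != NOT_DONE)


def _normalise_result(raw: str) -> str | None:
    """Map a raw result token to a canonical value, or None if inconclusive."""
    token = str(raw).strip().lower()
    if token in _SHORT:
        return _SHORT[token]
    if token in _RESULTS:
        return token
    if token in {"pos", "positive(+)", "1"}:
        return POSITIVE
    if token in {"neg", "negative(-)", "0"}:
        return NEGATIVE
    return None


def parse_results(raw: dict[str, str], case_id: str = "?") -> tuple[tuple[MarkerResult, ...], tuple[str, ...]]:
    """Convert marker -> raw-token mapping into results plus inconclusive flags.

    Tokens outside the recognised vocabulary are flagged (not silently
    dropped): the marker is kept as ``not_done`` and a flag
    ``inconclusive:<marker>=<token>`` recorded on the case.
    """
    results, flags = [], []
    for marker, raw_value in raw.items():
        value = _normalise_result(raw_value)
        if value is None:
            flags.append(f"inconclusive:{marker}={raw_value}")
            value = NOT_DONE
        results.append(MarkerResult(marker, value))
    return tuple(results), tuple(flags)


def load_cases(source: str | Path) -> list[CaseProfile]:
    """Read case profiles from CSV (one row per marker) or JSON."""
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, dtype=str)
        if not {"case_id", "marker", "result"}.issubset(df.columns):
            raise ValueError(f"{path}: case CSV needs columns case_id,marker,result")
        cases = []
        for cid, group in df.groupby("case_id", sort=False):
            raw = dict(zip(group["marker"], group["result"]))
            results, flags = parse_results(raw, cid)
            meta = group.iloc[0]
            cases.append(
                CaseProfile(
                    case_id=str(cid),
                    results=results,
                    original_diagnosis=_opt(meta.get("original_diagnosis")),
                    site=_opt(meta.get("site")),
                    flags=flags,
                )
            )
        return cases
    docs = json.loads(path.read_text())
    cases = []
    for doc in docs:
        results, flags = parse_results(doc.get("results", {}), doc.get("case_id", "?"))
        cases.append(
            CaseProfile(
                case_id=str(doc["case_id"]),
                results=results,
                original_diagnosis=doc.get("original_diagnosis"),
                site=doc.get("site"),
                flags=flags,
            )
        )
    return cases


def _opt(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    return text or None


def save_cases(cases: Sequence[CaseProfile], dest: str | Path) -> Path:
    """Write cases to CSV or JSON by extension."""
    path = Path(dest)
    if path.suffix.lower() == ".csv":
        rows = [
            {
                "case_id": c.case_id,
                "marker": r.marker,
                "result": _TO_SHORT[r.result],
                "original_diagnosis": c.original_diagnosis or "",
                "site": c.site or "",
            }
            for c in cases
            for r in c.results
        ]
        pd.DataFrame(
            rows, columns=["case_id", "marker", "result", "original_diagnosis", "site"]
        ).to_csv(path, index=False)
    else:
        docs = [
            {
                "case_id": c.case_id,
                "site": c.site,
                "original_diagnosis": c.original_diagnosis,
                "results": {r.marker: _TO_SHORT[r.result] for r in c.results},
            }
            for c in cases
        ]
        path.write_text(json.dumps(docs, indent=2) + "\n")
    return path
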