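"""Five-level graded expression scale for IHC marker positivity.

Pathology knowledge bases record, for each (disease, marker) pair, the
expected fraction of cases of that disease staining positive for the
marker, binned into five ordered categories:

    ``++``   75-100% of cases positive
    ``+``    50-74%
    ``+/-``  30-49%
    ``-/+``  10-29%
    ``-``    0-9%

The printed integer brackets are extended to the continuous scale as
half-open intervals [0, 10), [10, 30), [30, 50), [50, 75), [75, 100],
which agree with the integer endpoints everywhere.  Inference needs a
point probability per grade; the convention here is the midpoint of the
printed integer bracket, rescaled to [0, 1] (e.g. ``++`` -> 0.875).  The
whole mapping lives in a single editable :class:`GradeTable` so that an
alternative calibration is a one-object change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GRADE_LABELS",
    "GradeBand",
    "GradeTable",
    "DEFAULT_GRADE_TABLE",
    "grade_from_percentage",
    "grade_to_frequency",
]

#: Grade labels in increasing order of expression frequency.
GRADE_LABELS: tuple[str, ...] = ("-", "-/+", "+/-", "+", "++")


@dataclass(frozen=True)
class GradeBand:
    """One grade: its label, percentage interval and point frequency.

    Parameters
    ----------
    label
        One of ``GRADE_LABELS``.
    lo, hi
        Closed integer percentage bounds as printed (e.g. 75, 100 for
        ``++``).  On the continuous scale the band covers ``[lo, hi + 1)``
        except the top band, which is closed at 100.
    frequency
        Representative positivity probability in (0, 1) used by the
        inference engine; must lie strictly inside ``[lo, hi] / 100``.
    """

    label: str
    lo: float
    hi: float
    frequency: float

    def __post_init__(self) -> None:
        if not 0 <= self.lo <= self.hi <= 100:
            raise ValueError(f"invalid interval [{self.lo}, {self.hi}] for {self.label!r}")
        if not self.lo / 100 < self.frequency < self.hi / 100 or not 0 < self.frequency < 1:
            raise ValueError(
                f"frequency {self.frequency} for grade {self.label!r} must lie strictly "
                f"inside ({self.lo / 100}, {self.hi / 100})"
            )


@dataclass(frozen=True)
class GradeTable:
    """Ordered collection of :class:`GradeBand` tiling 0-100%."""

    bands: tuple[GradeBand, ...] = field(
        default_factory=lambda: (
            GradeBand("-", 0, 9, 0.045),
            GradeBand("-/+", 10, 29, 0.195),
            GradeBand("+/-", 30, 49, 0.395),
            GradeBand("+", 50, 74, 0.62),
            GradeBand("++", 75, 100, 0.875),
        )
    )

    def __post_init__(self) -> None:
        labels = tuple(b.label for b in self.bands)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate grade labels")
        # Bands must tile [0, 100] in increasing order with no gap.
        if self.bands[0].lo != 0 or self.bands[-1].hi != 100:
            raise ValueError("grade bands must span 0-100%")
        for a, b in zip(self.bands, self.bands[1:]):
            if b.lo != a.hi + 1:
                raise ValueError(f"gap or overlap between {a.label!r} and {b.label!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(b.label for b in self.bands)

    def band(self, label: str) -> GradeBand:
        for b in self.bands:
            if b.label == label:
                return b
        raise KeyError(f"unknown grade label {label!r}; expected one of {self.labels}")

    def grade_from_percentage(self, p: float) -> str:
        """Return the grade label whose band contains percentage ``p``.

        Bands are half-open on the continuous scale ([0,10), [10,30),
        [30,50), [50,75), [75,100]) so the map is total on [0, 100].
        """
        if not 0 <= p <= 100:
            raise ValueError(f"percentage {p!r} outside [0, 100]")
        for b in self.bands[:-1]:
            if p < b.hi + 1:
                return b.label
        return self.bands[-1].label

    def frequency(self, label: str) -> float:
        """Representative positivity probability for grade ``label``."""
        return self.band(label).frequency


#: Module-wide default; the midpoint convention described above.
DEFAULT_GRADE_TABLE = GradeTable()


def grade_from_percentage(p: float, table: GradeTable = DEFAULT_GRADE_TABLE) -> str:
    """Bin a positivity percentage into one of the five grade labels."""
    return table.grade_from_percentage(p)


def grade_to_frequency(g: str, table: GradeTable = DEFAULT_GRADE_TABLE) -> float:
    """Point positivity probability for a grade label (midpoint convention)."""
    return table.frequency(g)
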