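"""Case/non-case 2x2 contingency tables over a report store.

In the case/non-case design, cases are reports carrying the event of
interest and non-cases are all other reports in the database; exposure is
presence of the drug (or any member of a pooled class) on the report:

                event   no event
    exposed       a        b
    unexposed     c        d

The comparator is every other report in the deduplicated, windowed store,
not just antipsychotic reports.
"""

from __future__ import annotations

import csv
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

from .ingest import AdrReport


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 exposure-by-event cell counts.

    Cells are non-negative; they are integers for observed tables and may be
    half-integers after a Haldane–Anscombe continuity correction.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in table {self.cells()}")

    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def n_exposed(self) -> float:
        return self.a + self.b

    @property
    def n_events(self) -> float:
        return self.a + self.c

    def has_zero_cell(self) -> bool:
        return 0 in self.cells()


@dataclass(frozen=True)
class ExposureDef:
    """A named exposure: one compound, or a pooled class of compounds."""

    label: str
    member_compounds: frozenset[str]

    def __post_init__(self) -> None:
        # members must use the canonical (dictionary-produced) spelling
        if not self.member_compounds:
            raise ValueError(f"exposure {self.label!r} has no member compounds")

    @classmethod
    def single(cls, compound: str) -> "ExposureDef":
        return cls(label=compound, member_compounds=frozenset({compound}))


@dataclass(frozen=True)
class StoreSummary:
    """Store-level marginals: total reports N and total event cases E."""

    n: int
    e: int

    def __post_init__(self) -> None:
        if not 0 <= self.e <= self.n:
            raise ValueError(f"event count {self.e} outside [0, {self.n}]")


def summarize(store: Sequence[AdrReport] | Iterable[AdrReport]) -> StoreSummary:
    n = e = 0
    for r in store:
        n += 1
        e += r.event_flag
    return StoreSummary(n=n, e=e)


def build_table(
    store: Sequence[AdrReport] | Iterable[AdrReport], exposure: ExposureDef
) -> ContingencyTable:
    """Count the 2x2 cells for one exposure definition.

    A report is exposed iff its compound set intersects the exposure's
    members; the four cells partition the store exhaustively.
    """
    a = b = c = d = 0
    members = exposure.member_compounds
    for r in store:
        exposed = not members.isdisjoint(r.compounds)
        if exposed:
            if r.event_flag:
                a += 1
            else:
                b += 1
        elif r.event_flag:
            c += 1
        else:
            d += 1
    return ContingencyTable(a=a, b=b, c=c, d=d)


def build_all_tables(
    store: Sequence[AdrReport],
    exposures: Sequence[ExposureDef],
    min_cases: int = 1,
) -> tuple[list[tuple[ExposureDef, ContingencyTable]], list[ExposureDef]]:
    """Tables for every exposure, applying the minimum-case inclusion rule.

    Exposures with fewer than ``min_cases`` event cases (the a cell) are
    excluded and returned in the skipped list; input order is preserved.
    The study default ``min_cases=1`` requires at least one adverse-event
    case per drug.
    """
    if not exposures:
        raise ValueError("exposure list must be non-empty")
    if min_cases < 1:
        raise ValueError("min_cases must be >= 1")
    kept: list[tuple[ExposureDef, ContingencyTable]] = []
    skipped: list[ExposureDef] = []
    for exp in exposures:
        t = build_table(store, exp)
        if t.a < min_cases:
            skipped.append(exp)
        else:
            kept.append((exp, t))
    return kept, skipped


def pool_class_table(
    store: Sequence[AdrReport], class_members: Iterable[str], label: str = "class"
) -> ContingencyTable:
    """Union-exposure table for a pooled compound class.

    A report naming several class members counts once (report-level union),
    so pooled cells are not sums of per-drug cells when reports carry
    multiple class drugs.
    """
    members = frozenset(class_members)
    return build_table(store, ExposureDef(label=label, member_compounds=members))


def tables_to_csv(
    rows: Iterable[tuple[ExposureDef, ContingencyTable]], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "a", "b", "c", "d", "n"])
        for exp, t in rows:
            w.writerow([exp.label, t.a, t.b, t.c, t.d, t.n])
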