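"""Ingestion of FAERS-dialect quarterly tables into a deduplicated report store.

The FDA distributes FAERS quarterly extracts as dollar-sign-delimited ASCII
tables (DEMO, DRUG, REAC, INDI). This module parses that dialect, collapses
multiple versions of the same safety report to the latest one, normalizes
verbatim drug-name strings to canonical study compounds, restricts to a
receipt-date window, and flags reports that carry a target adverse-event
preferred term (the study default: MedDRA PTs "Sedation" / "Somnolence").
"""

from __future__ import annotations

import csv
import json
import logging
import re
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path

import pandas as pd

from .compounds import (
    DEFAULT_FORMULATION_RULES,
    OTHER,
    default_entries,
)

logger = logging.getLogger(__name__)

#: Default study window: receipt dates 2004-01-01 through 2020-09-30 inclusive.
DEFAULT_WINDOW_START = date(2004, 1, 1)
DEFAULT_WINDOW_END = date(2020, 9, 30)

#: Default target MedDRA preferred terms (matched case-insensitively).
DEFAULT_TARGET_TERMS = frozenset({"sedation", "somnolence"})

#: Suspect-drug role codes in the FAERS DRUG table.
SUSPECT_ROLES = frozenset({"PS", "SS"})

_REQUIRED_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": ("caseid", "caseversion", "fda_dt"),
    "drug": ("caseid", "caseversion", "drugname", "role_cod"),
    "reac": ("caseid", "caseversion", "pt"),
    "indi": ("caseid", "caseversion", "indi_pt"),
}


class FormatError(ValueError):
    """A source table violates the declared dialect (e.g. missing column)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DateWindow:
    """Inclusive receipt-date window for report inclusion."""

    start: date = DEFAULT_WINDOW_START
    end: date = DEFAULT_WINDOW_END

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"window start {self.start} is after end {self.end}")

    def contains(self, d: date) -> bool:
        return self.start <= d <= self.end


@dataclass(frozen=True)
class EventTermSet:
    """Target adverse-event preferred terms, compared case-insensitively."""

    preferred_terms: frozenset[str] = DEFAULT_TARGET_TERMS

    def __post_init__(self) -> None:
        if not self.preferred_terms:
            raise ValueError("event term set must be non-empty")
        object.__setattr__(
            self, "preferred_terms", frozenset(t.lower() for t in self.preferred_terms)
        )

    def matches(self, reactions: Iterable[str]) -> bool:
        return any(r.lower() in self.preferred_terms for r in reactions)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["term"])
            for t in sorted(self.preferred_terms):
                w.writerow([t])

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventTermSet":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        return cls(frozenset(r["term"] for r in rows))


def _word_pattern(pattern: str) -> re.Pattern[str]:
    # Word-boundary match so e.g. "promazine" does not hit inside
    # "chlorpromazine"; digits/letters on either side block the match.
    return re.compile(r"(?<![a-z0-9])" + re.escape(pattern.lower()) + r"(?![a-z0-9])")


@dataclass
class DrugDictionary:
    """Verbatim drug-string -> canonical compound map, formulation-aware.

    Entries are matched case-insensitively on word boundaries, longest pattern
    first. Formulation rules run before the parent compound is accepted: when
    the parent matched and the rule's token is present in the verbatim string,
    the distinct formulation compound (e.g. an LAI ester) is returned instead.
    Strings matching nothing map to ``"other"``.
    """

    entries: dict[str, str] = field(default_factory=default_entries)
    formulation_rules: tuple[tuple[str, str, str], ...] = DEFAULT_FORMULATION_RULES

    def __post_init__(self) -> None:
        self.entries = {k.lower(): v.lower() for k, v in self.entries.items()}
        self._compiled = [
            (_word_pattern(pat), canon)
            for pat, canon in sorted(
                self.entries.items(), key=lambda kv: (-len(kv[0]), kv[0])
            )
        ]
        self._rule_compiled = [
            (_word_pattern(token), parent.lower(), canon.lower())
            for token, parent, canon in self.formulation_rules
        ]

    def map(self, verbatim: str) -> str:
        """Resolve one verbatim drug-name string to a canonical compound."""
        if not verbatim or not verbatim.strip():
            raise ValueError("verbatim drug name must be non-empty")
        name = verbatim.lower()
        canonical = OTHER
        for rx, canon in self._compiled:
            if rx.search(name):
                canonical = canon
                break
        for token_rx, parent, formulation in self._rule_compiled:
            if canonical == parent and token_rx.search(name):
                return formulation
        return canonical

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["kind", "pattern", "parent", "canonical"])
            for pat, canon in sorted(self.entries.items()):
                w.writerow(["entry", pat, "", canon])
            for token, parent, canon in self.formulation_rules:
                w.writerow(["formulation", token, parent, canon])

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugDictionary":
        entries: dict[str, str] = {}
        rules: list[tuple[str, str, str]] = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                if row["kind"] == "entry":
                    entries[row["pattern"]] = row["canonical"]
                elif row["kind"] == "formulation":
                    rules.append((row["pattern"], row["parent"], row["canonical"]))
                else:
                    raise FormatError(f"unknown dictionary row kind {row['kind']!r}")
        return cls(entries=entries, formulation_rules=tuple(rules))


def map_drug_name(verbatim: str, dictionary: DrugDictionary) -> str:
    """Canonical compound for a verbatim string (total, deterministic)."""
    return dictionary.map(verbatim)


@dataclass(frozen=True)
class AdrReport:
    """One deduplicated safety report.

    ``compounds`` are canonical names (study compounds plus ``"other"``);
    ``event_flag`` is true iff the report's reactions intersect the target
    preferred terms under which the store was built.
    """

    case_id: str
    receipt_date: date
    compounds: frozenset[str]
    reactions: frozenset[str]
    indications: frozenset[str]
    event_flag: bool

    def to_json(self) -> str:
        return json.dumps(
            {
                "case_id": self.case_id,
                "receipt_date": self.receipt_date.isoformat(),
                "compounds": sorted(self.compounds),
                "reactions": sorted(self.reactions),
                "indications": sorted(self.indications),
                "event_flag": self.event_flag,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, line: str) -> "AdrReport":
        obj = json.loads(line)
        return cls(
            case_id=obj["case_id"],
            receipt_date=date.fromisoformat(obj["receipt_date"]),
            compounds=frozenset(obj["compounds"]),
            reactions=frozenset(obj["reactions"]),
            indications=frozenset(obj["indications"]),
            event_flag=obj["event_flag"],
        )


@dataclass
class RawRecordSet:
    """Parsed (not yet normalized) FAERS-dialect tables plus parse tallies."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    indi: pd.DataFrame
    malformed: Counter = field(default_factory=Counter)

    def counts(self) -> tuple[int, int, int, int]:
        return len(self.demo), len(self.drug), len(self.reac), len(self.indi)


@dataclass
class ReportStore:
    """Sequence of deduplicated, windowed, drug-normalized reports."""

    reports: list[AdrReport]
    tallies: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self):
        return iter(self.reports)

    def __getitem__(self, i):
        return self.reports[i]

    @property
    def n_events(self) -> int:
        return sum(r.event_flag for r in self.reports)


def write_store(reports: Iterable[AdrReport], path: str | Path) -> None:
    """Write reports to the JSON-lines interchange format (one per line)."""
    with open(path, "w") as fh:
        for r in reports:
            fh.write(r.to_json() + "\n")


def read_store(path: str | Path) -> ReportStore:
    with open(path) as fh:
        reports = [AdrReport.from_json(line) for line in fh if line.strip()]
    return ReportStore(reports=reports)


# ---------------------------------------------------------------------------
# Parsing / deduplication / store construction
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, table: str, delimiter: str) -> tuple[pd.DataFrame, int]:
    required = _REQUIRED_COLUMNS[table]
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, engine="python")
    except pd.errors.EmptyDataError:
        logger.warning("%s table %s is empty", table.upper(), path)
        return pd.DataFrame(columns=list(required)), 0
    df.columns = [c.strip().lower() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{table.upper()} table {path} lacks column {col!r}")
    df = df[list(required)]
    ok = df["caseid"].notna() & df["caseversion"].str.fullmatch(r"\d+", na=False)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s table %s: %d malformed rows dropped", table.upper(), path, n_bad)
    df = df[ok].reset_index(drop=True)
    df["caseversion"] = df["caseversion"].astype(int)
    return df, n_bad


def parse_tables(
    paths: Mapping[str, str | Path], delimiter: str = "$"
) -> RawRecordSet:
    """Parse FAERS-dialect tables into a :class:`RawRecordSet`.

    ``paths`` maps table names (``demo``, ``drug``, ``reac``, optionally
    ``indi``) to file locations. Malformed rows (missing case id, non-integer
    version) are tallied and logged, never silently dropped.
    """
    if "demo" not in paths or "drug" not in paths or "reac" not in paths:
        raise FormatError("paths must name at least the demo, drug and reac tables")
    malformed: Counter = Counter()
    frames: dict[str, pd.DataFrame] = {}
    for table in ("demo", "drug", "reac", "indi"):
        if table in paths:
            frames[table], n_bad = _read_table(paths[table], table, delimiter)
            malformed[table] = n_bad
        else:
            frames[table] = pd.DataFrame(columns=list(_REQUIRED_COLUMNS[table]))
    return RawRecordSet(
        demo=frames["demo"],
        drug=frames["drug"],
        reac=frames["reac"],
        indi=frames["indi"],
        malformed=malformed,
    )


def deduplicate(records: RawRecordSet) -> RawRecordSet:
    """Collapse each case to its latest version.

    Keeps, per case id, the DEMO row with the greatest (version, receipt date)
    pair — the FDA-recommended reading of versioned resubmissions — and drops
    DRUG/REAC/INDI rows belonging to discarded versions. Ties on both keys
    keep the last-parsed row (logged). Idempotent.
    """
    demo = records.demo.copy()
    demo["_order"] = range(len(demo))
    demo = demo.sort_values(
        ["caseid", "caseversion", "fda_dt", "_order"], kind="stable"
    )
    dup_mask = demo.duplicated(["caseid", "caseversion", "fda_dt"], keep=False)
    if dup_mask.any():
        tied = demo.loc[dup_mask, "caseid"].unique()
        logger.warning(
            "deduplicate: %d case(s) tied on (version, date); keeping last-parsed: %s",
            len(tied),
            ", ".join(map(str, tied[:10])),
        )
    kept = demo.groupby("caseid", sort=False).tail(1)
    kept = kept.sort_values("_order").drop(columns="_order").reset_index(drop=True)
    keys = set(zip(kept["caseid"], kept["caseversion"]))
    demo_ids = set(kept["caseid"])

    def _filter(df: pd.DataFrame) -> pd.DataFrame:
        # rows of discarded versions go; orphans (no DEMO row at all) stay,
        # to be tallied during store construction
        if df.empty:
            return df
        mask = [
            cid not in demo_ids or (cid, ver) in keys
            for cid, ver in zip(df["caseid"], df["caseversion"])
        ]
        return df[mask].reset_index(drop=True)

    return RawRecordSet(
        demo=kept,
        drug=_filter(records.drug),
        reac=_filter(records.reac),
        indi=_filter(records.indi),
        malformed=records.malformed.copy(),
    )


def _parse_fda_date(raw: str) -> date | None:
    try:
        return datetime.strptime(str(raw).strip(), "%Y%m%d").date()
    except (ValueError, TypeError):
        return None


def build_store(
    records: RawRecordSet,
    dictionary: DrugDictionary | None = None,
    terms: EventTermSet | None = None,
    window: DateWindow | None = None,
    suspect_only: bool = False,
) -> ReportStore:
    """Assemble :class:`AdrReport` objects from deduplicated records.

    Reports with receipt dates outside ``window`` are excluded; unparseable
    dates are rejected and tallied; verbatim drug names resolve through
    ``dictionary`` (unmatched -> ``"other"``, tallied); ``event_flag`` is set
    from ``terms``. With ``suspect_only`` the drug count is restricted to
    suspect role codes (PS/SS); by default any role counts.
    """
    dictionary = dictionary or DrugDictionary()
    terms = terms or EventTermSet()
    window = window or DateWindow()

    demo_ids = set(records.demo["caseid"])
    orphan_drug = int((~records.drug["caseid"].isin(demo_ids)).sum()) if len(records.drug) else 0
    orphan_reac = int((~records.reac["caseid"].isin(demo_ids)).sum()) if len(records.reac) else 0

    drug = records.drug
    if suspect_only and len(drug):
        drug = drug[drug["role_cod"].str.upper().isin(SUSPECT_ROLES)]

    name_cache: dict[str, str] = {}
    unmatched: Counter = Counter()

    def _resolve(verbatim: str) -> str:
        canon = name_cache.get(verbatim)
        if canon is None:
            canon = dictionary.map(verbatim)
            name_cache[verbatim] = canon
            if canon == OTHER:
                unmatched[verbatim] = 0
        if canon == OTHER:
            unmatched[verbatim] += 1
        return canon

    drugs_by_case: dict[str, set[str]] = {}
    if len(drug):
        for cid, name in zip(drug["caseid"], drug["drugname"]):
            if pd.isna(name) or not str(name).strip():
                continue
            drugs_by_case.setdefault(cid, set()).add(_resolve(str(name)))
    reac_by_case: dict[str, set[str]] = {}
    if len(records.reac):
        for cid, pt in zip(records.reac["caseid"], records.reac["pt"]):
            if pd.isna(pt):
                continue
            reac_by_case.setdefault(cid, set()).add(str(pt))
    indi_by_case: dict[str, set[str]] = {}
    if len(records.indi):
        for cid, term in zip(records.indi["caseid"], records.indi["indi_pt"]):
            if pd.isna(term):
                continue
            indi_by_case.setdefault(cid, set()).add(str(term))

    reports: list[AdrReport] = []
    n_rejected_date = 0
    n_excluded_window = 0
    for cid, raw_dt in zip(records.demo["caseid"], records.demo["fda_dt"]):
        d = _parse_fda_date(raw_dt)
        if d is None:
            n_rejected_date += 1
            continue
        if not window.contains(d):
            n_excluded_window += 1
            continue
        reactions = frozenset(reac_by_case.get(cid, set()))
        reports.append(
            AdrReport(
                case_id=str(cid),
                receipt_date=d,
                compounds=frozenset(drugs_by_case.get(cid, set())),
                reactions=reactions,
                indications=frozenset(indi_by_case.get(cid, set())),
                event_flag=terms.matches(reactions),
            )
        )
    reports.sort(key=lambda r: r.case_id)
    tallies = {
        "n_demo_rows": len(records.demo),
        "n_retained": len(reports),
        "n_excluded_window": n_excluded_window,
        "n_rejected_date": n_rejected_date,
        "orphan_drug_rows": orphan_drug,
        "orphan_reac_rows": orphan_reac,
        "unmatched_drug_names": dict(unmatched),
        "malformed_rows": dict(records.malformed),
    }
    return ReportStore(reports=reports, tallies=tallies)
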