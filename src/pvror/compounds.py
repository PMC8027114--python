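"""Study compound roster: 37 antipsychotics, class membership, name dictionary.

Long-acting injectable (LAI) ester formulations that are studied as their own
compounds (aripiprazole lauroxil, haloperidol decanoate, paliperidone
palmitate) are kept distinct from their parent molecules via formulation
rules; ester forms that are *not* separate study compounds (e.g. fluphenazine
decanoate) fall back to the parent.
"""

from __future__ import annotations

TYPICAL: tuple[str, ...] = (
    "chlorpromazine",
    "chlorprothixene",
    "cyamemazine",
    "droperidol",
    "fluphenazine",
    "haloperidol",
    "haloperidol decanoate",
    "loxapine",
    "periciazine",
    "perphenazine",
    "pimozide",
    "pipamperone",
    "prochlorperazine",
    "promazine",
    "thioridazine",
    "thiothixene",
    "trifluoperazine",
    "zuclopenthixol",
)

ATYPICAL: tuple[str, ...] = (
    "amisulpride",
    "aripiprazole",
    "aripiprazole lauroxil",
    "asenapine",
    "blonanserin",
    "brexpiprazole",
    "cariprazine",
    "clozapine",
    "iloperidone",
    "lurasidone",
    "melperone",
    "olanzapine",
    "paliperidone",
    "paliperidone palmitate",
    "pimavanserin",
    "quetiapine",
    "risperidone",
    "tiapride",
    "ziprasidone",
)

#: All 37 study compounds, alphabetical.
STUDY_COMPOUNDS: tuple[str, ...] = tuple(sorted(TYPICAL + ATYPICAL))

#: Canonical label for any drug string that is not a study compound.
OTHER = "other"

#: Pooled exposure classes (first- vs second-generation antipsychotics).
CLASSES: dict[str, tuple[str, ...]] = {
    "typical": TYPICAL,
    "atypical": ATYPICAL,
}

# Brand / trade names that reports commonly carry verbatim. Not exhaustive —
# a production dictionary would be far larger — but enough to exercise the
# brand-resolution path; anything unmatched maps to OTHER.
_BRANDS: dict[str, str] = {
    "abilify": "aripiprazole",
    "aristada": "aripiprazole lauroxil",
    "clozaril": "clozapine",
    "fanapt": "iloperidone",
    "geodon": "ziprasidone",
    "haldol": "haloperidol",
    "invega": "paliperidone",
    "latuda": "lurasidone",
    "loxitane": "loxapine",
    "nuplazid": "pimavanserin",
    "orap": "pimozide",
    "rexulti": "brexpiprazole",
    "risperdal": "risperidone",
    "saphris": "asenapine",
    "seroquel": "quetiapine",
    "stelazine": "trifluoperazine",
    "thorazine": "chlorpromazine",
    "vraylar": "cariprazine",
    "zyprexa": "olanzapine",
    "invega sustenna": "paliperidone palmitate",
    "invega trinza": "paliperidone palmitate",
    "risperdal consta": "risperidone",
    "haldol decanoate": "haloperidol decanoate",
}


def default_entries() -> dict[str, str]:
    """Verbatim-pattern -> canonical-compound entries (generics + brands)."""
    entries = {name: name for name in STUDY_COMPOUNDS}
    entries.update(_BRANDS)
    return entries


#: (formulation token, parent compound, formulation compound): when the parent
#: matches and the token appears in the verbatim string, the formulation wins.
DEFAULT_FORMULATION_RULES: tuple[tuple[str, str, str], ...] = (
    ("lauroxil", "aripiprazole", "aripiprazole lauroxil"),
    ("decanoate", "haloperidol", "haloperidol decanoate"),
    ("palmitate", "paliperidone", "paliperidone palmitate"),
)
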