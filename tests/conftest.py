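"""Shared fixtures: a hand-written dialect quarter and synthetic stores."""

from __future__ import annotations

from pathlib import Path

import pytest

from pvror import SyntheticConfig, sample_reports

# A small hand-enumerated quarter in the ingestion dialect:
# 12 DEMO rows over 10 case ids (C001 and C002 carry two versions each),
# 30 DRUG rows, 18 REAC rows, 3 INDI rows. C003 predates the study window,
# C007 postdates it, C004 carries an unparseable date.
DEMO_ROWS = """caseid$caseversion$fda_dt
C001$1$20100105
C001$2$20100110
C002$2$20120301
C002$1$20120201
C003$1$20031231
C004$1$BADDATE
C005$1$20040101
C006$1$20200930
C007$1$20201001
C008$1$20150615
C009$1$20150616
C010$1$20150617
"""

DRUG_ROWS = """caseid$caseversion$drugname$role_cod
C001$1$HALDOL$PS
C001$1$IBUPROFEN$C
C001$2$HALDOL DECANOATE 100$PS
C001$2$ASPIRIN$C
C001$2$RISPERIDONE$SS
C002$1$SEROQUEL$PS
C002$2$Quetiapine fumarate 50mg$PS
C002$2$OLANZAPINE$SS
C002$2$GABAPENTIN$C
C003$1$CLOZAPINE$PS
C003$1$IBUPROFEN$C
C004$1$RISPERDAL$PS
C005$1$ZUCLOPENTHIXOL$PS
C005$1$METFORMIN$C
C005$1$OMEPRAZOLE$C
C006$1$TIAPRIDE$PS
C006$1$CYAMEMAZINE$SS
C006$1$SERTRALINE$C
C007$1$PIMOZIDE$PS
C008$1$ARIPIPRAZOLE LAUROXIL$PS
C008$1$ABILIFY$C
C008$1$AMOXICILLIN$C
C009$1$PROMAZINE HCL$PS
C009$1$CHLORPROMAZINE$SS
C009$1$WARFARIN$C
C009$1$LEVOTHYROXINE$C
C010$1$ibuprofen$C
C010$1$LISINOPRIL$C
C010$1$QUETIAPINE$PS
C010$1$ATORVASTATIN$C
"""

REAC_ROWS = """caseid$caseversion$pt
C001$1$Nausea
C001$2$Somnolence
C001$2$Headache
C002$2$SEDATION
C002$2$Somnolence
C002$1$Dizziness
C003$1$Somnolence
C004$1$Sedation
C005$1$Somnolence
C005$1$Nausea
C006$1$Sedation
C006$1$Tremor
C007$1$Somnolence
C008$1$Rash
C008$1$Fatigue
C009$1$Somnolence
C010$1$Headache
C010$1$Insomnia
"""

INDI_ROWS = """caseid$caseversion$indi_pt
C001$2$Schizophrenia
C005$1$Bipolar disorder
C010$1$Insomnia
"""


@pytest.fixture()
def quarter_dir(tmp_path: Path) -> Path:
    d = tmp_path / "quarter"
    d.mkdir()
    (d / "demo.txt").write_text(DEMO_ROWS)
    (d / "drug.txt").write_text(DRUG_ROWS)
    (d / "reac.txt").write_text(REAC_ROWS)
    (d / "indi.txt").write_text(INDI_ROWS)
    return d


@pytest.fixture()
def quarter_paths(quarter_dir: Path) -> dict[str, Path]:
    return {name: quarter_dir / f"{name}.txt" for name in ("demo", "drug", "reac", "indi")}


def small_synthetic_config(
    n_reports: int = 1000, seed: int = 7, dup_rate: float = 0.0
) -> SyntheticConfig:
    """A dense little corpus (few compounds, common exposure) for table tests."""
    compounds = ["drugA", "drugB", "drugC", "drugD", "drugE"]
    thetas = [1.0, 2.0, 4.0, 8.0, 1.0]
    return SyntheticConfig(
        n_reports=n_reports,
        p0=0.10,
        exposure_probs={c: 0.08 for c in compounds},
        theta=dict(zip(compounds, thetas)),
        dup_rate=dup_rate,
        seed=seed,
    )


@pytest.fixture(scope="session")
def store_1k():
    reports, truth = sample_reports(small_synthetic_config())
    return reports, truth
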