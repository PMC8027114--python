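"""Synthetic spontaneous-report corpora with known ground truth.

The generator emulates the features of a FAERS quarterly extract that the
pipeline consumes: reports carrying one or more drugs and one or more
reaction preferred terms, versioned duplicate case submissions, receipt
dates for windowing, a background event rate, and per-drug planted
odds multipliers.

Generative model, per report i and compound d:

* exposure  X_id ~ Bernoulli(pi_d), independent across compounds;
* event     Y_i  ~ Bernoulli(p_i) with logit p_i = logit(p0) + sum_d X_id ln(theta_d).

The logistic (multiplicative-odds) form makes each planted theta_d the exact
conditional odds ratio of the event for exposure d, so in the rare-exposure,
rare-event regime the marginal reporting odds ratio targets theta_d and
parameter recovery is well defined. Event reports carry one target preferred
term ("Sedation" or "Somnolence", uniformly); every report carries 1-3 decoy
terms from a vocabulary of 60 and one decoy (non-study) drug, so term and
drug matching are exercised.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.special import expit, logit
from scipy.stats import spearmanr

from .compounds import STUDY_COMPOUNDS, OTHER
from .contingency import ContingencyTable
from .ingest import (
    DEFAULT_WINDOW_END,
    DEFAULT_WINDOW_START,
    AdrReport,
    DateWindow,
)
from .ror import AnalysisSettings, estimate_table

#: Decoy reaction vocabulary (>= 50 terms) to exercise preferred-term matching.
BACKGROUND_TERMS: tuple[str, ...] = (
    "Nausea", "Headache", "Dizziness", "Vomiting", "Fatigue", "Rash",
    "Pruritus", "Diarrhoea", "Constipation", "Dry mouth", "Insomnia",
    "Anxiety", "Tremor", "Weight increased", "Weight decreased", "Dyspnoea",
    "Chest pain", "Palpitations", "Hypertension", "Hypotension", "Syncope",
    "Fall", "Arthralgia", "Myalgia", "Back pain", "Abdominal pain",
    "Oedema peripheral", "Pyrexia", "Cough", "Pneumonia", "Urinary retention",
    "Blurred vision", "Tinnitus", "Vertigo", "Dysphagia", "Akathisia",
    "Dystonia", "Dyskinesia", "Parkinsonism", "Agitation", "Confusional state",
    "Hallucination", "Depression", "Suicidal ideation", "Mania",
    "Hyperglycaemia", "Hyperprolactinaemia", "Galactorrhoea", "Amenorrhoea",
    "Neutropenia", "Leukopenia", "Anaemia", "Hepatotoxicity",
    "Renal impairment", "QT prolonged", "Tachycardia", "Bradycardia",
    "Seizure", "Memory impairment", "Malaise",
)

#: Non-study drugs given to every report (all map to the "other" comparator).
DECOY_DRUGS: tuple[str, ...] = (
    "IBUPROFEN", "METFORMIN", "LISINOPRIL", "ATORVASTATIN", "OMEPRAZOLE",
    "AMOXICILLIN", "LEVOTHYROXINE", "SERTRALINE", "GABAPENTIN", "WARFARIN",
)

INDICATIONS: tuple[str, ...] = (
    "Schizophrenia", "Bipolar disorder", "Depression", "Anxiety", "Insomnia",
    "Agitation", "Delirium", "Autism spectrum disorder", "Dementia",
    "Off label use",
)

TARGET_TERMS: tuple[str, str] = ("Sedation", "Somnolence")

#: Planted odds-multiplier range mirroring the observed span of per-drug
#: reporting odds ratios across the 37 study compounds (1.4 to 13.3).
THETA_RANGE: tuple[float, float] = (1.4, 13.3)
DEFAULT_EXPOSURE_PROB = 1e-3
DEFAULT_BASELINE_RATE = 0.01


class SyntheticConfig(BaseModel):
    """Generative parameters for one synthetic corpus."""

    n_reports: int = Field(gt=0)
    p0: float = Field(default=DEFAULT_BASELINE_RATE, ge=0, lt=1)
    exposure_probs: dict[str, float]
    theta: dict[str, float]
    background_terms: tuple[str, ...] = BACKGROUND_TERMS
    dup_rate: float = Field(default=0.0, ge=0, lt=1)
    seed: int = 0
    window_start: date = DEFAULT_WINDOW_START
    window_end: date = DEFAULT_WINDOW_END

    @field_validator("exposure_probs")
    @classmethod
    def _probs_valid(cls, v: dict[str, float]) -> dict[str, float]:
        for name, p in v.items():
            if not 0 <= p < 1:
                raise ValueError(f"exposure probability for {name!r} outside [0, 1): {p}")
        return v

    @field_validator("theta")
    @classmethod
    def _theta_valid(cls, v: dict[str, float]) -> dict[str, float]:
        for name, t in v.items():
            if t <= 0:
                raise ValueError(f"odds multiplier for {name!r} must be positive: {t}")
        return v

    @model_validator(mode="after")
    def _keys_match(self) -> "SyntheticConfig":
        if set(self.exposure_probs) != set(self.theta):
            raise ValueError("exposure_probs and theta must cover the same compounds")
        if len(self.background_terms) < 50:
            raise ValueError("decoy vocabulary must have at least 50 terms")
        return self

    @property
    def compounds(self) -> list[str]:
        return sorted(self.theta)


def study_config(
    n_reports: int = 500_000,
    seed: int = 0,
    dup_rate: float = 0.0,
    compounds: tuple[str, ...] = STUDY_COMPOUNDS,
) -> SyntheticConfig:
    """The default study-condition corpus: 37 compounds with planted odds
    multipliers geometrically spaced over the observed ROR span 1.4-13.3,
    per-compound exposure probability 1e-3 and baseline event rate 0.01.
    """
    lo, hi = THETA_RANGE
    thetas = np.geomspace(lo, hi, num=len(compounds))
    return SyntheticConfig(
        n_reports=n_reports,
        p0=DEFAULT_BASELINE_RATE,
        exposure_probs={c: DEFAULT_EXPOSURE_PROB for c in compounds},
        theta={c: float(t) for c, t in zip(sorted(compounds), thetas)},
        dup_rate=dup_rate,
        seed=seed,
    )


@dataclass(frozen=True)
class GroundTruth:
    """Planted parameters plus closed-form expected 2x2 cells per compound."""

    theta: dict[str, float]
    expected_tables: dict[str, tuple[float, float, float, float]]
    expected_events: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "theta": self.theta,
                    "expected_tables": {k: list(v) for k, v in self.expected_tables.items()},
                    "expected_events": self.expected_events,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def _expected_event_prob(
    l0: float, pis: np.ndarray, logths: np.ndarray, condition_on: Optional[int] = None
) -> float:
    """E[P(event)] marginal over exposures, by subset enumeration.

    Exact (full enumeration) up to 15 compounds. For larger rosters the sum
    truncates at 3 simultaneous exposures (2 co-exposures when conditioning
    on one compound) and renormalizes; at the exposure probabilities such
    rosters use (~1e-3) the neglected mass is O(1e-7) relative, far below
    sampling resolution.
    """
    idx = [i for i in range(len(pis)) if i != condition_on]
    base = l0 if condition_on is None else l0 + logths[condition_on]
    if len(idx) <= 15:
        max_size = len(idx)
    else:
        max_size = 3 if condition_on is None else 2
    total_mass = 0.0
    total_p = 0.0
    log_q = float(np.sum(np.log1p(-pis[idx]))) if idx else 0.0
    for size in range(0, max_size + 1):
        for subset in itertools.combinations(idx, size):
            lp = log_q
            shift = 0.0
            for j in subset:
                lp += math.log(pis[j]) - math.log1p(-pis[j])
                shift += logths[j]
            mass = math.exp(lp)
            total_mass += mass
            total_p += mass * float(expit(base + shift))
    return total_p / total_mass


def ground_truth(cfg: SyntheticConfig) -> GroundTruth:
    """Closed-form expected tables under the generative model."""
    compounds = cfg.compounds
    pis = np.array([cfg.exposure_probs[c] for c in compounds])
    logths = np.log([cfg.theta[c] for c in compounds])
    n = cfg.n_reports
    if cfg.p0 == 0:
        tables = {c: (0.0, n * pis[i], 0.0, n * (1 - pis[i])) for i, c in enumerate(compounds)}
        return GroundTruth(theta=dict(cfg.theta), expected_tables=tables, expected_events=0.0)
    l0 = float(logit(cfg.p0))
    p_marginal = _expected_event_prob(l0, pis, logths)
    e_total = n * p_marginal
    tables: dict[str, tuple[float, float, float, float]] = {}
    for i, c in enumerate(compounds):
        if pis[i] == 0:
            a = b = 0.0
        else:
            p_exposed = _expected_event_prob(l0, pis, logths, condition_on=i)
            a = n * pis[i] * p_exposed
            b = n * pis[i] - a
        ccell = e_total - a
        dcell = n - a - b - ccell
        tables[c] = (a, b, ccell, dcell)
    return GroundTruth(theta=dict(cfg.theta), expected_tables=tables, expected_events=e_total)


def _sample_exposures(
    rng: np.random.Generator, n: int, pis: np.ndarray
) -> list[np.ndarray]:
    """Per-compound arrays of exposed report indices (iid Bernoulli law)."""
    out = []
    for p in pis:
        k = rng.binomial(n, p) if p > 0 else 0
        out.append(np.sort(rng.choice(n, size=k, replace=False)) if k else np.empty(0, dtype=int))
    return out


def sample_reports(cfg: SyntheticConfig) -> tuple[list[AdrReport], GroundTruth]:
    """Draw one synthetic corpus; deterministic given the config's seed."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reports
    compounds = cfg.compounds
    pis = np.array([cfg.exposure_probs[c] for c in compounds])
    logths = np.log([cfg.theta[c] for c in compounds])

    exposures = _sample_exposures(rng, n, pis)
    logits = np.full(n, logit(cfg.p0) if cfg.p0 > 0 else -np.inf)
    for idx, lt in zip(exposures, logths):
        logits[idx] += lt
    events = rng.random(n) < expit(logits) if cfg.p0 > 0 else np.zeros(n, bool)

    compounds_per_report: list[list[str]] = [[] for _ in range(n)]
    for name, idx in zip(compounds, exposures):
        for i in idx:
            compounds_per_report[i].append(name)

    target_pick = rng.integers(0, 2, size=n)
    n_decoy_terms = rng.integers(1, 4, size=n)
    decoy_terms = rng.integers(0, len(cfg.background_terms), size=int(n_decoy_terms.sum()))
    decoy_offsets = np.concatenate(([0], np.cumsum(n_decoy_terms)))
    decoy_drug = rng.integers(0, len(DECOY_DRUGS), size=n)
    has_indication = rng.random(n) < 0.5
    indication_pick = rng.integers(0, len(INDICATIONS), size=n)
    span_days = (cfg.window_end - cfg.window_start).days
    day_offsets = rng.integers(0, span_days + 1, size=n)

    width = max(8, len(str(n)))
    reports: list[AdrReport] = []
    for i in range(n):
        reactions = {
            cfg.background_terms[j]
            for j in decoy_terms[decoy_offsets[i] : decoy_offsets[i + 1]]
        }
        if events[i]:
            reactions.add(TARGET_TERMS[target_pick[i]])
        reports.append(
            AdrReport(
                case_id=f"SYN{i:0{width}d}",
                receipt_date=cfg.window_start + timedelta(days=int(day_offsets[i])),
                compounds=frozenset(compounds_per_report[i]) | {OTHER},
                reactions=frozenset(reactions),
                indications=(
                    frozenset({INDICATIONS[indication_pick[i]]}) if has_indication[i] else frozenset()
                ),
                event_flag=bool(events[i]),
            )
        )
    return reports, ground_truth(cfg)


def write_faers_dialect(
    reports: list[AdrReport],
    out_dir: str | Path,
    dup_rate: float = 0.0,
    seed: int = 0,
    delimiter: str = "$",
) -> dict[str, Path]:
    """Emit DEMO/DRUG/REAC/INDI tables in the ingestion dialect.

    A ``dup_rate`` fraction of cases (``round(dup_rate * n)``, chosen by the
    seeded RNG) is additionally emitted as an earlier version-1 submission
    with an earlier receipt date and a truncated reaction list, so that
    parse -> deduplicate -> build_store recovers exactly the input reports.
    """
    if not reports:
        raise ValueError("cannot write an empty report corpus")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_dup = int(round(dup_rate * len(reports)))
    dup_idx = set(rng.choice(len(reports), size=n_dup, replace=False)) if n_dup else set()

    paths = {name: out_dir / f"{name}.txt" for name in ("demo", "drug", "reac", "indi")}
    with open(paths["demo"], "w") as demo, open(paths["drug"], "w") as drug, open(
        paths["reac"], "w"
    ) as reac, open(paths["indi"], "w") as indi:
        demo.write(delimiter.join(["caseid", "caseversion", "fda_dt"]) + "\n")
        drug.write(delimiter.join(["caseid", "caseversion", "drugname", "role_cod"]) + "\n")
        reac.write(delimiter.join(["caseid", "caseversion", "pt"]) + "\n")
        indi.write(delimiter.join(["caseid", "caseversion", "indi_pt"]) + "\n")

        def emit(r: AdrReport, version: int, dt: date, drop_reaction: bool) -> None:
            demo.write(delimiter.join([r.case_id, str(version), dt.strftime("%Y%m%d")]) + "\n")
            for comp in sorted(r.compounds):
                verbatim = DECOY_DRUGS[0] if comp == OTHER else comp.upper()
                role = "C" if comp == OTHER else "PS"
                drug.write(delimiter.join([r.case_id, str(version), verbatim, role]) + "\n")
            terms = sorted(r.reactions)
            if drop_reaction and len(terms) > 1:
                terms = terms[:-1]
            for pt in terms:
                reac.write(delimiter.join([r.case_id, str(version), pt]) + "\n")
            for term in sorted(r.indications):
                indi.write(delimiter.join([r.case_id, str(version), term]) + "\n")

        for i, r in enumerate(reports):
            final_version = 2 if i in dup_idx else 1
            if i in dup_idx:
                emit(r, 1, r.receipt_date - timedelta(days=30), drop_reaction=True)
            emit(r, final_version, r.receipt_date, drop_reaction=False)
    return paths


# ---------------------------------------------------------------------------
# Parameter-recovery harness
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    """Per-compound recovery of planted odds multipliers across replicates."""

    compounds: list[str]
    theta: np.ndarray
    mean_ror: np.ndarray
    coverage: np.ndarray
    signal_rate: np.ndarray
    spearman: float
    replicates: int
    estimator: str

    @property
    def relative_error(self) -> np.ndarray:
        return np.abs(self.mean_ror - self.theta) / self.theta

    def to_dict(self) -> dict:
        return {
            "replicates": self.replicates,
            "estimator": self.estimator,
            "spearman": self.spearman,
            "compounds": {
                c: {
                    "theta": float(self.theta[i]),
                    "mean_ror": float(self.mean_ror[i]),
                    "relative_error": float(self.relative_error[i]),
                    "coverage": float(self.coverage[i]),
                    "signal_rate": float(self.signal_rate[i]),
                }
                for i, c in enumerate(self.compounds)
            },
        }


def _sample_tables(
    rng: np.random.Generator, cfg: SyntheticConfig
) -> list[ContingencyTable]:
    """One replicate of per-compound 2x2 tables under the generative law.

    Count-level sampler: identical in distribution to aggregating the tables
    of a full :func:`sample_reports` corpus (Bernoulli exposures, logistic
    event model) but without materializing report objects, so replicated
    recovery experiments stay cheap.
    """
    n = cfg.n_reports
    compounds = cfg.compounds
    pis = np.array([cfg.exposure_probs[c] for c in compounds])
    logths = np.log([cfg.theta[c] for c in compounds])
    exposures = _sample_exposures(rng, n, pis)
    sizes = np.array([len(e) for e in exposures])
    all_idx = np.concatenate(exposures) if sizes.sum() else np.empty(0, dtype=int)
    all_lt = np.repeat(logths, sizes)
    uniq, inv = np.unique(all_idx, return_inverse=True)
    logit_u = np.full(len(uniq), logit(cfg.p0) if cfg.p0 > 0 else -np.inf)
    np.add.at(logit_u, inv, all_lt)
    y_u = rng.random(len(uniq)) < expit(logit_u) if cfg.p0 > 0 else np.zeros(len(uniq), bool)
    e_unexposed = rng.binomial(n - len(uniq), cfg.p0)
    e_total = int(y_u.sum()) + int(e_unexposed)
    tables = []
    offset = 0
    for m in sizes:
        a = int(y_u[inv[offset : offset + m]].sum())
        offset += m
        c = e_total - a
        tables.append(ContingencyTable(a=a, b=int(m) - a, c=c, d=n - int(m) - c))
    return tables


def recovery_experiment(
    cfg: SyntheticConfig, replicates: int = 1, estimator: str = "woolf"
) -> RecoveryReport:
    """Estimate each compound's ROR over replicate corpora and summarize.

    Reports, per compound: the arithmetic mean ROR across replicates, the
    empirical coverage of the planted theta by the confidence interval, and
    the signal rate; plus the Spearman rank correlation between planted theta
    and mean ROR across compounds. In the rare-exposure regime the marginal
    ROR targets theta, so mean ROR near theta and high rank correlation
    demonstrate parameter and rank recovery.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    compounds = cfg.compounds
    theta = np.array([cfg.theta[c] for c in compounds])
    settings = AnalysisSettings(estimator=estimator, correct_zero_cells=True)
    rors = np.empty((replicates, len(compounds)))
    covered = np.zeros((replicates, len(compounds)), bool)
    signal = np.zeros((replicates, len(compounds)), bool)
    for r in range(replicates):
        for j, t in enumerate(_sample_tables(rng, cfg)):
            est = estimate_table(t, settings)
            rors[r, j] = est.ror
            covered[r, j] = est.ci_low <= theta[j] <= est.ci_high
            signal[r, j] = est.ci_low > 1
    mean_ror = rors.mean(axis=0)
    rho = float(spearmanr(theta, mean_ror).statistic) if len(compounds) > 1 else float("nan")
    return RecoveryReport(
        compounds=compounds,
        theta=theta,
        mean_ror=mean_ror,
        coverage=covered.mean(axis=0),
        signal_rate=signal.mean(axis=0),
        spearman=rho,
        replicates=replicates,
        estimator=estimator,
    )
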