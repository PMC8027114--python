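"""Reporting odds ratio inference and signal classification.

The reporting odds ratio (ROR) for a drug-event pair is (a/b)/(c/d) from the
case/non-case 2x2 table: the odds of the event among reports of the drug
versus the odds among all other reports. Two interval estimators are
provided, both first-class:

* ``woolf`` — the asymptotic log-odds-ratio interval,
  exp(ln ROR ± z * sqrt(1/a + 1/b + 1/c + 1/d)), optionally after a
  Haldane–Anscombe 0.5 continuity correction when a cell is zero;
* ``exact`` — the conditional maximum-likelihood odds ratio under Fisher's
  noncentral hypergeometric law (conditioning on both table margins), with
  the central exact interval obtained by inverting the one-sided conditional
  tail tests at (1 - level)/2 each.

A drug-event pair is a signal when the lower 95% confidence bound of its
ROR exceeds one (strictly) and the case count meets the inclusion minimum.
"""

from __future__ import annotations

import hashlib
import json
import math
from collections.abc import Sequence
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln
from scipy.stats import norm

from .contingency import ContingencyTable, ExposureDef, build_all_tables, summarize
from .ingest import AdrReport

#: Normal quantile for a two-sided 95% interval.
Z_95 = 1.959964


class UndefinedEstimateError(ValueError):
    """The estimate is undefined for this table (zero cell, no correction)."""


class DegenerateTableError(ValueError):
    """Both-margin conditioning leaves a single attainable table."""


@dataclass(frozen=True)
class RorEstimate:
    """Point estimate and confidence bounds for one 2x2 table."""

    ror: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    z: float = Z_95
    estimator: str = "woolf"
    corrected: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ValueError(f"confidence level {self.level} outside (0, 1)")
        if math.isfinite(self.ror) and math.isfinite(self.ci_low) and math.isfinite(self.ci_high):
            if not (0 <= self.ci_low <= self.ror + 1e-12 and self.ror <= self.ci_high * (1 + 1e-12)):
                raise ValueError(
                    f"inconsistent estimate: {self.ci_low} <= {self.ror} <= {self.ci_high} fails"
                )


@dataclass(frozen=True)
class SignalResult:
    """Classified drug-event association."""

    label: str
    case_count: float
    estimate: RorEstimate
    signal: bool


def compute_ror(t: ContingencyTable) -> float:
    """Point estimate (a*d)/(b*c); requires b > 0 and c > 0."""
    if t.b == 0:
        raise UndefinedEstimateError("ROR undefined: cell b (exposed, no event) is zero")
    if t.c == 0:
        raise UndefinedEstimateError("ROR undefined: cell c (unexposed, event) is zero")
    return (t.a * t.d) / (t.b * t.c)


def woolf_ci(t: ContingencyTable, level: float = 0.95) -> tuple[float, float]:
    """Asymptotic log-ROR interval; requires all four cells positive.

    Log-symmetric about the point estimate: ci_low * ci_high = ROR**2.
    """
    if t.has_zero_cell():
        raise UndefinedEstimateError(
            "Woolf interval undefined with a zero cell; apply continuity_correct first"
        )
    z = norm.ppf(0.5 + level / 2)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    log_ror = math.log(compute_ror(t))
    return math.exp(log_ror - z * se), math.exp(log_ror + z * se)


def continuity_correct(t: ContingencyTable) -> ContingencyTable:
    """Haldane–Anscombe correction: add 0.5 to every cell when any is zero.

    Identity on tables with no zero cell.
    """
    if not t.has_zero_cell():
        return t
    return ContingencyTable(a=t.a + 0.5, b=t.b + 0.5, c=t.c + 0.5, d=t.d + 0.5)


# ---------------------------------------------------------------------------
# Exact conditional inference (Fisher noncentral hypergeometric)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionalModel:
    """Noncentral hypergeometric law of the a cell given both table margins.

    With N reports, n1 = a+b exposed and m1 = a+c events, the a cell given
    both margins follows P(X=x) ∝ C(n1,x) C(N-n1, m1-x) psi^x over the
    attainable support; psi is the odds-ratio parameter.
    """

    n: int
    n_exposed: int
    n_events: int
    support: np.ndarray = field(repr=False, compare=False, default=None)
    _log_base: np.ndarray = field(repr=False, compare=False, default=None)

    @classmethod
    def from_table(cls, t: ContingencyTable) -> "ConditionalModel":
        cells = t.cells()
        if any(c != int(c) for c in cells):
            raise ValueError("exact conditional inference requires integer cell counts")
        n = int(t.n)
        n1 = int(t.n_exposed)
        m1 = int(t.n_events)
        lo = max(0, m1 + n1 - n)
        hi = min(m1, n1)
        if hi <= lo:
            raise DegenerateTableError(
                f"margins (exposed={n1}, events={m1}, N={n}) admit a single table"
            )
        support = np.arange(lo, hi + 1)
        log_base = (
            gammaln(n1 + 1)
            - gammaln(support + 1)
            - gammaln(n1 - support + 1)
            + gammaln(n - n1 + 1)
            - gammaln(m1 - support + 1)
            - gammaln(n - n1 - m1 + support + 1)
        )
        return cls(n=n, n_exposed=n1, n_events=m1, support=support, _log_base=log_base)

    def _pmf(self, log_psi: float) -> np.ndarray:
        logw = self._log_base + self.support * log_psi
        w = np.exp(logw - logw.max())
        return w / w.sum()

    def mean(self, log_psi: float) -> float:
        """E[X] under psi = exp(log_psi); strictly increasing in psi."""
        return float(self._pmf(log_psi) @ self.support)

    def sf(self, x: int, log_psi: float) -> float:
        """P(X >= x); increasing in psi."""
        return float(self._pmf(log_psi)[self.support >= x].sum())

    def cdf(self, x: int, log_psi: float) -> float:
        """P(X <= x); decreasing in psi."""
        return float(self._pmf(log_psi)[self.support <= x].sum())


def _solve(f, lo: float = -40.0, hi: float = 40.0) -> float:
    """Brent root of f over log-psi, expanding the bracket as needed."""
    flo, fhi = f(lo), f(hi)
    step = hi - lo
    while flo * fhi > 0 and step < 2800.0:
        lo, hi = lo - step, hi + step
        step = hi - lo
        flo, fhi = f(lo), f(hi)
    return brentq(f, lo, hi, xtol=1e-13, rtol=4 * np.finfo(float).eps)


def _log_crude_or(t: ContingencyTable) -> float:
    """Log continuity-corrected crude odds ratio; seeds solver brackets."""
    return math.log(((t.a + 0.5) * (t.d + 0.5)) / ((t.b + 0.5) * (t.c + 0.5)))


def conditional_mle_or(t: ContingencyTable) -> float:
    """Conditional MLE of the odds ratio (the estimate an exact 2x2 test reports).

    Maximizes the noncentral hypergeometric likelihood given both margins,
    equivalently solves E_psi[X] = a. Returns 0.0 / +inf when the a cell sits
    on the lower / upper boundary of the attainable support.
    """
    model = ConditionalModel.from_table(t)
    a = int(t.a)
    if a == model.support[0]:
        return 0.0
    if a == model.support[-1]:
        return math.inf
    center = _log_crude_or(t)
    return math.exp(_solve(lambda lp: model.mean(lp) - a, center - 2.0, center + 2.0))


def exact_ci(t: ContingencyTable, level: float = 0.95) -> tuple[float, float]:
    """Central exact conditional interval at the given level.

    Each bound inverts a one-sided conditional tail test at (1-level)/2:
    at ci_low the probability of observing >= a equals (1-level)/2; at
    ci_high the probability of observing <= a equals (1-level)/2. Boundary
    a cells yield a one-sided interval with a 0 or +inf endpoint.
    """
    if not 0 < level < 1:
        raise ValueError(f"confidence level {level} outside (0, 1)")
    model = ConditionalModel.from_table(t)
    a = int(t.a)
    alpha2 = (1 - level) / 2
    center = _log_crude_or(t)
    if a == model.support[0]:
        lo = 0.0
    else:
        lo = math.exp(_solve(lambda lp: model.sf(a, lp) - alpha2, center - 4.0, center + 1.0))
    if a == model.support[-1]:
        hi = math.inf
    else:
        hi = math.exp(_solve(lambda lp: model.cdf(a, lp) - alpha2, center - 1.0, center + 4.0))
    return lo, hi


def classify_signal(
    est: RorEstimate, case_count: float, min_cases: int = 1
) -> bool:
    """Signal rule: lower CI bound strictly above one, with enough cases."""
    return est.ci_low > 1 and case_count >= min_cases


# ---------------------------------------------------------------------------
# Whole-store analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalysisSettings:
    """Estimation settings shared across an analysis run."""

    estimator: str = "woolf"
    level: float = 0.95
    min_cases: int = 1
    correct_zero_cells: bool = False

    def __post_init__(self) -> None:
        if self.estimator not in ("woolf", "exact"):
            raise ValueError(f"unknown estimator {self.estimator!r}")

    def fingerprint(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def estimate_table(t: ContingencyTable, settings: AnalysisSettings) -> RorEstimate:
    """One RorEstimate from one table under the given settings.

    The continuity correction applies only on the Woolf path; exact
    conditional inference handles boundary tables natively via one-sided
    infinite bounds.
    """
    if settings.estimator == "exact":
        ror = conditional_mle_or(t)
        lo, hi = exact_ci(t, settings.level)
        return RorEstimate(
            ror=ror, ci_low=lo, ci_high=hi, level=settings.level,
            z=float("nan"), estimator="exact", corrected=False,
        )
    corrected = False
    tt = t
    if tt.has_zero_cell():
        if not settings.correct_zero_cells:
            raise UndefinedEstimateError(
                f"zero cell in table {t.cells()}; enable correct_zero_cells or use exact"
            )
        tt = continuity_correct(tt)
        corrected = True
    z = norm.ppf(0.5 + settings.level / 2)
    lo, hi = woolf_ci(tt, settings.level)
    return RorEstimate(
        ror=compute_ror(tt), ci_low=lo, ci_high=hi, level=settings.level,
        z=float(z), estimator="woolf", corrected=corrected,
    )


@dataclass
class AnalysisResult:
    """Signal results plus the store marginals and settings fingerprint."""

    results: list[SignalResult]
    skipped: list[str]
    n: int
    e: int
    settings: AnalysisSettings

    @property
    def fingerprint(self) -> str:
        return self.settings.fingerprint()


def analyze(
    store: Sequence[AdrReport],
    exposures: Sequence[ExposureDef],
    settings: AnalysisSettings | None = None,
) -> AnalysisResult:
    """Full case/non-case analysis: tables -> estimates -> signal calls."""
    settings = settings or AnalysisSettings()
    if not exposures:
        summary = summarize(store)
        return AnalysisResult([], [], summary.n, summary.e, settings)
    try:
        kept, skipped = build_all_tables(store, exposures, settings.min_cases)
    except ValueError as err:
        raise ValueError(f"table construction failed: {err}") from err
    summary = summarize(store)
    results: list[SignalResult] = []
    for exp, t in kept:
        try:
            est = estimate_table(t, settings)
        except (UndefinedEstimateError, DegenerateTableError) as err:
            raise type(err)(f"estimation failed for {exp.label!r}: {err}") from err
        results.append(
            SignalResult(
                label=exp.label,
                case_count=t.a,
                estimate=est,
                signal=classify_signal(est, t.a, settings.min_cases),
            )
        )
    return AnalysisResult(
        results=results,
        skipped=[e.label for e in skipped],
        n=summary.n,
        e=summary.e,
        settings=settings,
    )


def results_to_csv(result: AnalysisResult, path: str | Path) -> None:
    """CSV export: label, a, N, E, ror, ci_low, ci_high, estimator, signal."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "a", "n", "e", "ror", "ci_low", "ci_high", "estimator", "signal"])
        for r in result.results:
            w.writerow(
                [
                    r.label,
                    r.case_count,
                    result.n,
                    result.e,
                    repr(r.estimate.ror),
                    repr(r.estimate.ci_low),
                    repr(r.estimate.ci_high),
                    r.estimate.estimator,
                    r.signal,
                ]
            )


def results_from_json(path: str | Path) -> AnalysisResult:
    """Reload an AnalysisResult written by :func:`results_to_json`."""
    with open(path) as fh:
        payload = json.load(fh)
    settings = AnalysisSettings(**payload["settings"])
    results = [
        SignalResult(
            label=r["label"],
            case_count=r["a"],
            estimate=RorEstimate(
                ror=r["ror"], ci_low=r["ci_low"], ci_high=r["ci_high"],
                level=settings.level, z=float("nan"),
                estimator=r["estimator"], corrected=r["corrected"],
            ),
            signal=r["signal"],
        )
        for r in payload["results"]
    ]
    return AnalysisResult(
        results=results, skipped=payload["skipped"],
        n=payload["n"], e=payload["e"], settings=settings,
    )


def results_to_json(result: AnalysisResult, path: str | Path) -> None:
    payload = {
        "n": result.n,
        "e": result.e,
        "settings": asdict(result.settings),
        "fingerprint": result.fingerprint,
        "skipped": result.skipped,
        "results": [
            {
                "label": r.label,
                "a": r.case_count,
                "ror": r.estimate.ror,
                "ci_low": r.estimate.ci_low,
                "ci_high": r.estimate.ci_high,
                "estimator": r.estimate.estimator,
                "corrected": r.estimate.corrected,
                "signal": r.signal,
            }
            for r in result.results
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
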