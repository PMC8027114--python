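# pvror — reporting odds-ratio disproportionality analysis

`pvror` is a Python library for case/non-case disproportionality analysis
of spontaneous adverse-event report databases, in the style of
FAERS-based pharmacovigilance studies. It covers the full path from raw
quarterly report tables to a ranked signal table:

1. **Ingestion** — parse `$`-delimited DEMO/DRUG/REAC/INDI tables,
   deduplicate case versions, map verbatim drug names to canonical
   compounds (including long-acting injectable formulations), and flag
   reports naming a target adverse-event term.
2. **Contingency construction** — per-compound and pooled-class 2×2
   tables (cases vs non-cases × exposed vs not).
3. **Inference** — the reporting odds ratio (ROR) with either the Woolf
   asymptotic interval (optional Haldane–Anscombe zero-cell correction) or
   exact conditional inference under Fisher's noncentral hypergeometric
   law (conditional MLE + central exact interval).
4. **Signal classification and reporting** — a pair is a signal when the
   lower 95% bound exceeds 1; outputs are ranked tables and forest-plot
   exports, all byte-deterministic under a fixed seed.
5. **Synthetic generator** — a first-class spontaneous-report simulator
   with planted odds multipliers and closed-form expected tables, used to
   validate estimator behavior by parameter-recovery experiments.

The statistical model in brief: for a drug–event pair with table cells
$a$ (drug & event), $b$ (drug, no event), $c$ (other reports, event),
$d$ (other reports, no event),

$$\mathrm{ROR} = \frac{a\,d}{b\,c}, \qquad
\mathrm{CI}_{95} = \exp\!\Big(\ln\mathrm{ROR} \pm 1.96\,\sqrt{\tfrac1a+\tfrac1b+\tfrac1c+\tfrac1d}\Big),$$

with the exact-conditional alternative described in
[docs/methods.md](docs/methods.md).

## Worked example

```python
from pvror import AnalysisSettings, ContingencyTable, classify_signal, estimate_table

t = ContingencyTable(a=224, b=1366, c=99_027, d=9_272_619)
est = estimate_table(t, AnalysisSettings(estimator="woolf"))
print(est.ror, est.ci_low, est.ci_high)   # 15.355  13.330  17.687
print(classify_signal(est, case_count=t.a))  # True

est = estimate_table(t, AnalysisSettings(estimator="exact"))
print(est.ror, est.ci_low, est.ci_high)   # 15.355  13.270  17.700
```

Recovery of planted effects from a synthetic corpus
(`python examples/02_synthetic_recovery.py`):

```
recovery over 200 replicates (spearman theta vs mean ROR = 1.000):
  compound          theta  mean ROR  rel err  coverage  signal rate
  clozapine          5.00     5.020    0.39%    95.50%      100.00%
  haloperidol        2.00     1.980    0.99%    96.00%       57.50%
  quetiapine         1.00     1.030    2.97%    96.50%        3.50%
  zuclopenthixol    13.00    12.972    0.22%    97.00%      100.00%
```

The `examples/` directory has three short narrative scripts: estimators on
hand-built tables, synthetic parameter recovery, and the full pipeline
(corpus → dialect files → ingest → ranked table → forest export). A thin
CLI wraps the same pipeline:

```sh
pvror run --config run.yaml --seed 7
```

## Repository layout

- `src/pvror/` — library (`ingest`, `contingency`, `ror`, `simulate`,
  `report`, `pipeline`, `cli`)
- `tests/` — unit, property-based, and acceptance tests
- `examples/` — narrative scripts
- `docs/methods.md` — statistical methods, generator design and estimand
  discussion, numerical choices
- `scripts/acceptance.py` — standalone measurement of the package's
  headline quantities

## Reproduction

All results in this repository reproduce from a fresh checkout:

```sh
pip install --no-build-isolation -e . && pip install pytest hypothesis mpmath
pytest -q                                   # full suite, ~10 min on one CPU
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` derives every random draw from `--seed` and writes
a JSON report of computed quantities (oracle deviations, interval
coverage, null signal rate, study-scale recovery error, pipeline
round-trip checks). Examples run with `python examples/<name>.py`; each
fixes its own seed, and all pipeline artifacts are byte-deterministic
given a seed.
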