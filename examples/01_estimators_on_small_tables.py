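"""Estimate reporting odds ratios on a few hand-built 2x2 tables.

The case/non-case 2x2 table for a drug-event pair counts
a = drug & event, b = drug & no event, c = other reports & event,
d = other reports & no event. The ROR is (a*d)/(b*c); a pair is a signal
when the lower 95% bound exceeds 1.
"""

from pvror import (
    AnalysisSettings,
    ContingencyTable,
    RorEstimate,
    classify_signal,
    estimate_table,
)

tables = {
    "clear signal (a=224)": ContingencyTable(a=224, b=1366, c=99_027, d=9_272_619),
    "few cases, wide CI (a=6)": ContingencyTable(a=6, b=330, c=99_245, d=9_273_655),
    "zero cell (a=0)": ContingencyTable(a=0, b=120, c=99_251, d=9_273_865),
}

for name, t in tables.items():
    print(f"\n{name}: cells a,b,c,d = {t.cells()}")
    for settings in (
        AnalysisSettings(estimator="woolf", correct_zero_cells=True),
        AnalysisSettings(estimator="exact"),
    ):
        est: RorEstimate = estimate_table(t, settings)
        signal = classify_signal(est, case_count=t.a)
        print(
            f"  {settings.estimator:5s}: ROR {est.ror:8.3f} "
            f"[{est.ci_low:8.3f}, {est.ci_high:8.3f}]  signal={signal}"
        )
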