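# Methods

`pvror` implements case/non-case disproportionality analysis for
spontaneous-report pharmacovigilance data, together with a synthetic
spontaneous-report generator whose planted effect sizes make estimator
behavior checkable against a known ground truth.

## 1. Case/non-case design

Within a report store, a *case* is a report listing at least one target
adverse-event preferred term (default: "Sedation", "Somnolence",
case-insensitive); every other report is a non-case. For a drug exposure
$D$ (a single compound, or the union of a compound class) the 2×2 table is

|                | event (case) | no event |
|----------------|--------------|----------|
| exposed to $D$ | $a$          | $b$      |
| not exposed    | $c$          | $d$      |

Exposure is report-level: a report naming several members of a class counts
once (`pool_class_table` takes the union, so pooled cells are not sums of
per-drug cells).

## 2. Reporting odds ratio and intervals

The reporting odds ratio is $\mathrm{ROR} = \dfrac{a\,d}{b\,c}$.

**Woolf (asymptotic) interval.**
$\exp\!\big(\ln \mathrm{ROR} \pm z_{1-\alpha/2}\sqrt{1/a + 1/b + 1/c + 1/d}\big)$
with $z_{0.975} = 1.959964$. It requires all four cells positive; when a
cell is zero the opt-in Haldane–Anscombe correction adds 0.5 to every cell
(identity on tables without zeros, applied only on the Woolf path).

**Exact conditional inference.** Conditioning on both table margins, the
$a$ cell follows Fisher's noncentral hypergeometric law
$P_\psi(X = x) \propto \binom{n_1}{x}\binom{N - n_1}{m_1 - x}\,\psi^x$
over the attainable support, where $\psi$ is the odds-ratio parameter,
$n_1 = a+b$, $m_1 = a+c$, $N$ the table total. The conditional MLE solves
$E_\psi[X] = a$ (the mean is strictly increasing in $\psi$); when $a$ sits
on the support boundary the MLE is $0$ or $+\infty$. The central exact
interval inverts the one-sided conditional tail tests:
$P_{\psi_{\mathrm{lo}}}(X \ge a) = \alpha/2$ and
$P_{\psi_{\mathrm{hi}}}(X \le a) = \alpha/2$; boundary $a$ yields a
one-sided interval. This matches what an exact 2×2 test reports
(conditional MLE plus central interval).

**Signal rule.** A drug–event pair is a signal when the lower bound of the
95% interval strictly exceeds 1 and the case count $a$ meets the inclusion
minimum (default 1).

## 3. Ingestion

The parser reads `$`-delimited quarterly tables `DEMO` (`caseid`,
`caseversion`, `fda_dt`), `DRUG` (`drugname`, `role_cod`), `REAC` (`pt`),
`INDI` (`indi_pt`). Malformed rows are tallied, not fatal; a missing
required column raises a `FormatError` naming it. Deduplication keeps, per
`caseid`, the row with the largest (`caseversion`, `fda_dt`); ties are
logged. Receipt dates are parsed as `%Y%m%d` and filtered to the analysis
window (default 2004-01-01 through 2020-09-30). Optionally only suspect
drugs (`role_cod` PS/SS) count as exposure.

Verbatim drug names map to canonical compounds via a dictionary of
word-boundary regex patterns (longest pattern first; generic and brand
entries). Formulation rules run after the parent match so e.g.
"HALOPERIDOL DECANOATE" maps to the long-acting injectable compound
`haloperidol decanoate` rather than `haloperidol`. Unmatched names map to
`other` and are tallied.

## 4. Synthetic report generator

Per report $i$, exposures are independent Bernoulli draws,
$X_{id} \sim \mathrm{Bern}(\pi_d)$, and the event follows a logistic model

$$\operatorname{logit} p_i = \operatorname{logit} p_0 + \sum_d X_{id} \ln \theta_d .$$

The logistic form makes each planted $\theta_d$ the *exact conditional*
odds ratio of its exposure (holding the other exposures fixed), so
parameter recovery is a well-defined target. Event reports carry exactly
one target term; all reports carry 1–3 decoy background terms (from a
60-term list) and a decoy drug mapping to `other`. Receipt dates are
uniform in the window. The dialect writer emits the same four-table
format the parser reads, optionally with older case versions at rate
`dup_rate` to exercise deduplication, closing the loop
generator → files → parser → store.

**Ground truth.** Expected 2×2 cells have a closed form by enumerating
exposure subsets: exact (all subsets) for rosters of ≤ 15 compounds;
for larger rosters subsets are truncated at size 3 (size 2 when
conditioning), with neglected mass $O\big((D\pi)^4\big) \approx 10^{-7}$
at the study conditions, and renormalized.

**Count-level sampler.** Replicated recovery experiments draw the per-
compound tables directly at count level (identical in law to aggregating a
full corpus) so thousands of 500,000-report replicates stay cheap.

## 5. Study conditions (generator defaults)

`study_config()` fixes the evaluation regime:

| parameter | default | rationale |
|-----------|---------|-----------|
| compounds | 37 antipsychotics (18 typical, 19 atypical; LAIs distinct) | the head-to-head roster under study |
| $\theta_d$ | geometrically spaced over $[1.4, 13.3]$ across the sorted roster | spans the observed ROR range; geometric spacing is uniform on the log-odds scale on which the model is linear |
| $\pi_d$ | $10^{-3}$ | rare-exposure regime of a spontaneous-report database |
| $p_0$ | $0.01$ | target-event background reporting proportion ≈ 99,251 / 9,373,236 |
| $n$ | 500,000 | enough reports that every compound has $E[a] \ge 7$ |
| window | 2004-01-01 … 2020-09-30 | the ingestion default |

## 6. Estimand: marginal ROR versus planted conditional θ

The ROR computed from the marginal 2×2 table is *not* identical to the
conditional $\theta_d$: with 37 independent exposures a small fraction of
exposed reports are co-exposed to other compounds, and the odds
nonlinearity makes the mixed numerator odds less than proportionally
inflated (non-collapsibility of the odds ratio). From the closed-form
expected tables at the study conditions, the expected-cell odds ratio
deviates from $\theta$ monotonically: −0.4% at $\theta = 1.4$ down to
−5.0% at $\theta = 13.3$. With one compound only, the expected-cell OR
equals $\theta$ exactly, confirming the deviation is co-exposure mixing,
not an estimator defect. The arithmetic mean of the per-replicate ROR adds
a small positive finite-sample term (≈ +0.2%, from $E[1/b]$ curvature);
measured over 20,000 replicate corpora the worst per-compound deviation of
the mean ROR from $\theta$ is −4.8%, at the top of the planted range. Any
acceptance band of ±5% on $|\,\overline{\mathrm{ROR}} - \theta\,|/\theta$
therefore genuinely holds at these conditions, but with a thin margin
(~0.2%): recovery experiments must use enough replicates (Monte-Carlo SE
≈ 0.1% per compound at 20,000) to resolve the true mean against the band.

**Generator scope and limits.** Exposures are independent across compounds
(no co-prescription correlation); events are driven by a single latent
probability (no term-level confounding); duplication is version-based
only; reporting dates carry no trend. These are deliberate simplifications
that keep the ground truth closed-form.

## 7. Numerical choices

- Conditional pmf weights are computed as `gammaln` log-binomials plus
  $x \ln \psi$, normalized by max-subtraction; means and tails come from
  the normalized weights directly.
- Root-finding is Brent's method on $\ln \psi$ (`xtol = 1e-13`), with the
  bracket seeded around the continuity-corrected crude log-OR and expanded
  geometrically if it does not straddle the root.
- Exact-CI endpoints invert the tail equations to ≈ 1e-13 in $\ln\psi$;
  residual tail error at the returned bounds is ≤ 1e-8. Reference R
  `fisher.test` bounds agree to ~0.2% (its `uniroot` tolerance), while the
  tail probabilities evaluated at our bounds equal $\alpha/2$ to full
  precision.
- All CSV/JSON artifacts use `repr` float formatting, sorted keys and no
  timestamps; SVG export fixes the hash salt and drops the date, so a
  fixed seed reproduces every artifact byte-for-byte.
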