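# pvsignals

Pharmacovigilance signal detection on spontaneous-report data, built for
case/non-case analyses of a two-drug oncology regimen (an anti-VEGF antibody
plus an alkylating agent in glioblastoma, and any structurally similar
study): from raw FAERS-style / CVARD-style text extracts through cohort
construction to disproportionality screening, drug–drug interaction signal
analysis, time-to-onset description and IRAE reporting-odds regression — all
validated against a built-in synthetic spontaneous-reporting-system
generator with injectable ground truth.

Spontaneous reporting systems have no exposure denominators, so nothing here
estimates incidence or causal risk: every statistic quantifies *reporting*
disproportionality, and the outputs are signal-prioritisation tables.

## What it computes

For each exposure group (combination, each monotherapy) and each
preferred-term adverse event, a report-level 2×2 table (a, b, c, d) against
the rest of the analysis set feeds three statistics:

* **PRR** = (a/(a+b)) / (c/(c+d)), with Pearson χ² and a log-normal 95% CI
  — signal when PRR ≥ 2, χ² ≥ 4, n ≥ 3;
* **ROR** = ad/bc with 95% CI — signal when the CI lower bound > 1, n ≥ 3;
* **Ω** = log₂((a + 0.5)/(E + 0.5)) with E = (a+b)(a+c)/N, an
  observed-to-expected shrinkage statistic with exact gamma-posterior 95%
  credibility bounds — signal when the lower bound > 0, n ≥ 3.

Agreement across the three rules is graded Strong / Moderate / Weak and
combined with the PRR magnitude into High / Medium / Low priority. A
2×2×2 stratification (each drug × event) yields combination-vs-monotherapy
PRRs and the multiplicative-interaction contrast
OR(1,1)/(OR(1,0)·OR(0,1)). Onset timing is summarised per (group, term)
(median, IQR, min, max) with an exploratory Weibull fit whose shape β
classifies onset clustering (β > 1.2 late, 0.8–1.2 constant, < 0.8 early).
A multivariable logistic model estimates IRAE reporting odds by regimen,
adjusted for sex, age band, weight group and reporter type, with
deterministic separation handling and McFadden R² / AIC / BIC.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

```python
import pvsignals as pv

# one (group, term) contingency table: 7 of 713 combination reports carry
# the event, 55 of 10 340 comparator reports
t = pv.ContingencyTable(a=7, b=706, c=55, d=10285)
omega, lo, hi, e = pv.compute_omega(t)   # 0.737, (-0.523, 1.611), E = 4.00
prr, chi2, prr_ci, _ = pv.compute_prr(t) # 1.846, chi2 = 2.42
```

The Ω point estimate 0.737 says the event is reported about 2^0.737 ≈ 1.7×
more often than expected under independence, but the credibility interval
(−0.52, 1.61) spans zero — with n = 7 this is not a signal, and PRR < 2
agrees.

End to end on simulated data with injected signals:

```python
from pvsignals import run_pipeline
from pvsignals.config import PipelineConfig, demo_simulation_config

bundle = run_pipeline(PipelineConfig(simulate=demo_simulation_config(0), seed=0))
print(bundle.screen.publication_frame().head(8).to_string(index=False))
```

```
Group              Adverse event  N  Omega      95% CI PRR ROR Omega Sig Consistency Priority
COMBO           Thrombocytopenia 67  1.666 (1.30-1.99) Yes Yes       Yes      Strong   Medium
COMBO Lymphocyte count decreased 40  1.671 (1.19-2.08) Yes Yes       Yes      Strong   Medium
COMBO                Neutropenia 40  1.345 (0.86-1.76) Yes Yes       Yes      Strong   Medium
COMBO               Pancytopenia 23  1.068 (0.42-1.60) Yes Yes       Yes      Strong   Medium
COMBO                 Arthralgia 15  0.657 (-0.16-1.29) No  No        No        None     None
COMBO                  Diarrhoea 13 -0.222 (-1.11-0.46) No  No        No        None     None
COMBO  Pneumonia cytomegaloviral 13  2.375 (1.49-3.05) Yes Yes       Yes      Strong     High
COMBO              Enterocolitis  8  1.902 (0.73-2.73) Yes Yes       Yes      Strong     High
```

The demo configuration injects monotherapy haematological signals (which
propagate multiplicatively into the combination group — hence the Strong but
Medium-priority haematology rows) and combination-specific interaction
multipliers on opportunistic infections — which surface as the High-priority
rows, exactly the injected truth recorded in `bundle.truth`.

The same pipeline runs from the shell:

```bash
pvsignals demo-config --seed 0 > config.json
pvsignals run-all config.json -o out/
```

writing the baseline table, three per-group screen tables, two
per-comparator interaction tables, TTO summaries, Weibull fits, the
regression table and a run manifest. Reruns with the same configuration are
byte-identical.

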