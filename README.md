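# lhxpop

Survival, causes of death, and density-dependent predation pressure for
juvenile Steller sea lions (*Eumetopias jubatus*), estimated from
post-mortem satellite returns of abdominally implanted archival life-history
transmitters (LHX tags), and a conceptual age-structured framework for
asking whether predation alone can hold the population at its current ~20%
of peak abundance.

The package is aimed at quantitative wildlife ecologists working with
known-fate telemetry: it implements the full chain from raw tag-return
tallies to population-level inference, each stage usable on its own.

## The estimators

**Detection correction.** Dual-implanted animals report a death through
either of two independently failing transmitters. With `C_single` single
and `C_dual` dual returns,

```
P_fail  = C_single / (C_single + 2 C_dual)
P_detect = 1 - P_fail**2 = 1 / F
E_corr  = F * (detected events)
```

Confidence ranges for `P_fail` (and the implied integer range of `E_corr`)
come from inverting a Monte Carlo simulation of per-tag failures over a
grid of candidate probabilities. Homogeneity of detection across strata
(live vs carcass-test deployments, predation vs non-traumatic events) is
checked with odds ratios and two-tailed Fisher exact tests.

**Cause of death.** A tag released by dismemberment equilibrates to sea
temperature within minutes and transmits immediately; a tag in an intact
carcass cools by Newtonian (single-compartment) cooling with rate
`k = k_ref (m_ref / m)^(2/3)` and surfaces days later. Fitting `m` to a
gradual trace flags partial dismemberment when the fitted cooling mass is a
small fraction of the animal's expected mass. The predation proportion
`PP` gets a Monte Carlo lower confidence limit from the CDF of simulated
binomial predation counts.

**Survival (Mayfield).** Within an age class, `DMR = E_corr / d_exp`,
`DSR = 1 - DMR`, annual survival `DSR^365.25`, with Johnson's variance
`var(DSR) = e (d - e) / d^3` and a tag-failure-adjusted lower limit that
re-computes the Johnson bound at the upper confidence limit of `E_corr`.

**Demography.** Per-sex survivorship schedules over age-years 1–31 split
each year's mortality into predation and other causes
(`s_i + m_p,i + m_np,i = 1`). *Minimum natality* — the birth rate that
balances a schedule — is the pup seed over females aged 5–21. A
density-dependent framework holds per-capita non-predation mortality fixed
and sweeps absolute predator consumption between the contemporary (20%)
and pre-decline (100%) anchors under flat, linear and sigmoid (Type
III-like) numerical responses, reporting consumption, survival, female
recruitment, the juvenile fraction J/T and the pup difference (seed minus
births; positive means decline).

## Worked example

```
$ python examples/01_detection_correction.py
per-tag uplink failure  P_fail   = 0.1053  (95% ci 0.030-0.263)
event detection         P_detect = 0.9889
correction factor       F        = 1.0112
corrected event count   E_corr   = 12.13 -> integer 12 (95% ci 12-13)
```

From 4 single and 17 dual returns, roughly one tag in ten fails to uplink,
but with two tags per animal only ~1% of deaths go unreported: the 12
detected mortalities need no upward correction. The other examples walk
through classification (11 of 12 deaths carry a predation signature,
`PP >= 0.917`, lower CL 0.78), the survival table (annual survival 0.641
in year two; 0.49 cumulative over ages 13–60 months), minimum natality
(0.60 → 0.92 → 0.69 across schedule variants) and the abundance sweep
(only the sigmoid response yields a stable equilibrium at 20% of peak
abundance). The `lhx` command exposes the same stages from a shell
(`lhx report --out-dir report` runs everything).

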