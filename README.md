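# argus-cua

Cost-utility analysis of the **Argus II retinal prosthesis** versus usual
care in Retinitis Pigmentosa (RP), as a tested, config-driven
decision-modelling package: a four-state Markov cohort model with annual
cycles, discounted cost/QALY accumulation, deterministic and probabilistic
incremental cost-effectiveness ratios (ICERs), net monetary benefit and
cost-effectiveness acceptability curves, the full published scenario grid,
and a calibration module that resolves the structural choices the published
model description leaves open.

**Who it is for.** Health-economics researchers and HTA analysts who want a
reproducible, scriptable reimplementation of this evaluation — to audit it,
to adapt its inputs to another country or tariff year, or to use it as a
worked example of Markov cohort cost-utility modelling with Beta-PERT
probabilistic sensitivity analysis.

## The model in brief

States: minimal light perception (MLP, the RP baseline where the usual-care
cohort stays), light perception (VA+), counting fingers (VA++), reading
letters (VA+++), plus a bookkeeping state for explanted devices. The
implanted cohort is allocated across the improved states in the first
cycle, drifts upward at 10%/year afterwards, and faces an annual
explantation hazard. Per cycle t the model accrues occupancy-weighted costs
C_t and utilities U_t, discounted at r = 3.5%:

    PV = Σ_{t=0}^{H−1} X_t · (1+r)^−t          (first cycle undiscounted)

    ICER = ΔC / ΔQ ,   NMB(λ) = λ·ΔQ − ΔC ,   CEAC(λ) = P(NMB(λ) > 0)

where ΔC, ΔQ are discounted increments of the prosthesis arm over usual
care and λ is the willingness-to-pay per QALY. The probabilistic analysis
draws every uncertain parameter from a Beta-PERT distribution over its
published ±25% range (Beta(5,5) rescaled to [min, max]) and re-runs both
arms 1,000 times; the probabilistic ICER is the ratio of means.

All model inputs are embedded (the published parameter table: 10 costs, 5
probabilities, 6 utilities, 3.5% discount rates, cohort of 1,000 patients
aged 46, horizons 25/20/10 years); no external data are needed. YAML/JSON
config files can override any of them — see `docs/methods.md` for the full
model description, the calibration evidence, and known limitations.

## Worked example

```bash
argus-cua grid -n 1000 --seed 0 --outdir out/
```

prints, per scenario, the published table layout (euros rounded half-up,
QALYs to two decimals). For the 25-year base case:

```
== base25 ==
          Disc costs Disc QALYs Disc costs (PSA) Disc QALYs (PSA)
Argus II     243,526       7.32          243,849             7.32
CAU          201,091       4.44          200,763             4.42
Increment     42,435       2.89           43,086             2.90
ICERs         14,698                      14,871
```

Reading it: over 25 years a prosthesis patient accrues €243,526 in
discounted direct costs and 7.32 discounted QALYs versus €201,091 and 4.44
for usual care — the device costs €42,435 more and yields 2.89 extra QALYs,
i.e. €14,698 per QALY gained (published: €14,603; the probabilistic
column re-estimates it as €14,871 under parameter uncertainty, published
€14,482). CSV exports of every table, the per-draw cost-effectiveness
plane and the acceptability curve land in `out/`, together with a run
manifest recording seed, structure and overrides.

The same from Python:

```python
from argus_cua import default_table1, StructureConfig, run_scenario

res = run_scenario("base25", default_table1(), StructureConfig(), n=1000, seed=0)
print(res.icer)                 # 14697.96…
print(res.psa_summary["icer"])  # 14871.27…
```

Other verbs: `argus-cua run h10` (one scenario), `argus-cua psa`
(CE-plane/CEAC exports), `argus-cua calibrate` (score all 128 candidate
structures against the published tables and report the winner with its
deviation table).

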