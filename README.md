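# protdeg

Kinetics of targeted protein degradation in exponentially growing
*Escherichia coli*: an ODE model of synthesis–dilution–degradation, a
balanced-growth estimator for apparent degradation rates, and simulation
tools for designing inducible protein knockdowns.

## Who this is for

Synthetic biologists and metabolic engineers who use degron tags (e.g.
N-degron / N-end-rule tags degraded by the ClpAP protease) to deplete a
target protein, and who need to separate true proteolysis from dilution by
growth — the confound that dominates in fast-growing cultures.

## The model

Per-cell protein abundance P (proteins·cell⁻¹) obeys

    dP/dt = α − μ·P − Vmax·P/(Km + P)

with synthesis rate α (proteins·cell⁻¹·h⁻¹), specific growth rate μ (h⁻¹)
acting as dilution, and Michaelis–Menten proteolysis (Vmax, Km). When
P ≫ Km, degradation saturates and the balance becomes linear:

    dP/dt + μ·P = α − β,   β ≈ Vmax.

During balanced exponential growth P is stationary, so α − β can be read
from finite-difference slopes of activity/OD time courses. Measuring a
degradation-free control strain (e.g. ΔclpP) with the same construct gives
α alone, and subtraction yields the **apparent degradation rate**

    β = (net rate of control) − (net rate of test condition),

reported with propagated s.e.m. and a Welch test against the control.

## Worked example

Simulate a two-arm balanced-growth experiment (test strain with
Vmax = 15,000 proteins·cell⁻¹·h⁻¹ vs a degradation-free control, both at
α = 40,000, μ = 1 h⁻¹), then recover β from the simulated measurements:

```python
from protdeg import (Condition, DegradationModelParams, ExperimentDesign,
                     generate_balanced_growth, estimate_net_rate, estimate_beta)

wt    = Condition("WT",    DegradationModelParams(alpha=40000, mu=1.0, vmax=15000, km=600))
dclpp = Condition("dclpP", DegradationModelParams(alpha=40000, mu=1.0, vmax=0,     km=600),
                  is_control=True)
design = ExperimentDesign(conditions=(wt, dclpp), replicates=6, noise_cv=0.05, seed=1)

tcs  = generate_balanced_growth(design)
test = [estimate_net_rate(tc) for tc in tcs if tc.condition == "WT"]
ctrl = [estimate_net_rate(tc) for tc in tcs if tc.condition == "dclpP"]
res  = estimate_beta(test, ctrl, condition="WT", control="dclpP")
print(f"beta = {res.beta:.0f} +/- {res.sem:.0f} proteins/cell/h (n={res.n})")
```

```
beta = 15621 +/- 533 proteins/cell/h (n=6)
```

The estimate recovers the simulated truth (15,000) within one standard
error; dividing by the calibration slope (≈10 proteins·cell⁻¹ per
RFU·OD600⁻¹) expresses it as ≈1500 RFU·OD⁻¹·h⁻¹.

The same pipeline is scriptable from a shell:

```bash
protdeg simulate  --config config.yaml --out sim.csv
protdeg estimate  --data sim.csv --control dclpP --out betas.csv
protdeg knockdown --config config.yaml --out sweep.csv --plot knockdown.png
```

`knockdown` compares depleting a protein by synthesis repression alone
versus repression plus induced degradation: at μ = 1 h⁻¹ the half-time
drops from ln 2 ≈ 0.69 h to ≈0.46 h, and the benefit grows sharply as
growth slows (≈6× faster at μ = 0.1 h⁻¹).

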