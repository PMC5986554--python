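# amykin

Kinetic analysis of amyloid-β(1–42) aggregation for researchers studying how
membrane lipid composition modulates amyloid fibrillation. The package fits
Thioflavin T (ThT) fluorescence time courses to the autocatalytic
nucleation–elongation model, extracts nucleation and elongation rate
constants, compares them across conditions as fold changes, classifies AFM
particle measurements into protofibril/fibril species, and generates fully
seeded synthetic data for both modalities.

## The model

Aβ-42 fibrillation is treated as two reactions: slow nucleus formation
(rate constant *k*ₙ, s⁻¹) followed by fast aggregate-catalysed elongation
(rate constant *k*ₑ, L mol⁻¹ s⁻¹). With initial monomer concentration *a*
(mol/L), the fibrillar fraction *f* obeys

    df/dt = k (1 − f)(ρ + f),   f(0) = 0,

with *k* = *k*ₑ·*a* and ρ = *k*ₙ/*k*, which integrates in closed form to

    f(t) = ρ (exp[(1 + ρ)kt] − 1) / (1 + ρ exp[(1 + ρ)kt]).

ρ ≪ 1 gives the familiar sigmoid with a pronounced lag phase. A ThT trace is
modelled as F(t) = F₀ + ΔF·f(t); the fit estimates (ln *k*, ln ρ, F₀, ΔF) by
bounded least squares with multi-start restarts, then reports
*k*ₙ = ρ·*k* and *k*ₑ = *k*/*a*.

## Worked example

```python
import amykin

rates = amykin.KineticRates(kn=3.73e-6, ke=3.378, a=80e-6)  # peptide alone, 80 µM
p = amykin.reduce_rates(rates)
print(p.k, p.rho)                     # 0.00027024  0.013802545885139133
print(amykin.half_time(p) / 3600)     # 4.370037636579258   (hours to f = 1/2)
print(amykin.lag_time(p) / 3600)      # 2.3698465938684294  (tangent lag, hours)
```

So for the lipid-free condition the combined growth rate is
*k* = 2.70×10⁻⁴ s⁻¹, the nucleation-to-growth ratio is ρ ≈ 0.014 (strongly
nucleation-limited), half the monomer pool is fibrillar after ≈ 4.4 h and
the tangent construction puts the lag phase at ≈ 2.4 h.

From the shell, comparing the packaged constants across conditions:

```sh
$ amykin compare --out cmp.json
$ amykin report --comparisons cmp.json --out report.json --text report.txt
$ cat report.txt
...
Fold changes:
  kn Chol vs alone: 1.36-fold decreased
  ke Chol vs alone: 1.65-fold increased
  kn Chol vs DOPC: 2.18-fold decreased
  ke Chol vs DOPC: 2.83-fold increased
  kn 7keto vs alone: 1.18-fold increased
  ke 7keto vs alone: 2.75-fold decreased
  kn 7keto vs Chol: 1.61-fold increased
  ke 7keto vs Chol: 4.54-fold decreased
```

Cholesterol-containing vesicles accelerate elongation and suppress
nucleation; 7-ketocholesterol vesicles do the opposite, which keeps the
peptide in intermediate (protofibrillar) states.

A full synthetic round trip — simulate a noisy triplicate ThT experiment,
then recover the generating constants:

```sh
amykin simulate --kn 3.73e-6 --ke 3.378 --points 25 --sigma-rel 0.02 --seed 1 --out tht.csv
amykin fit tht.csv --out fit.json
```

Morphology: `amykin simulate-particles --condition 7keto_24h -n 5000 --seed 1
--out afm.csv` followed by `amykin classify afm.csv --out species.json`
yields ≈ 85% protofibrils under the default joint length × height rules
(fibril: 200–1000 nm × 2–6 nm; protofibril: 50–250 nm × 1–4 nm; fibril wins
in the overlap).

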