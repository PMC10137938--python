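# acepep

Analysis toolkit for virtual screening of angiotensin-converting-enzyme
(ACE) inhibitory tetrapeptides. ACE is a zinc metallopeptidase central to
blood-pressure regulation, and short food-derived peptides that inhibit it
are attractive antihypertensive alternatives to drugs. `acepep` implements
the computational side of an exhaustive tetrapeptide screen: it enumerates
the complete 20⁴ = 160,000 sequence space, characterises which residues a
score-ranked library prefers at each position, mines association rules over
residue properties, assembles Molecular Mechanics / Generalized Born Surface
Area (MM/GBSA) binding free energies with an interaction-entropy estimate,
decomposes binding into per-residue hotspot contributions from alanine
scans, and fits IC50 values from enzyme-inhibition dose–response assays.

Docking engines and MD codes are deliberately **not** dependencies: their
outputs (score lists, per-frame energy tables, per-residue contribution
tables, peak areas) are consumed as plain CSV, and a synthetic-data module
generates statistically realistic versions of all of them so the whole
pipeline is testable and reproducible end to end.

## The core quantities

**MM/GBSA enthalpy.** For a protein–peptide complex,
ΔH = ΔE_vdW + ΔE_ele + ΔG_GB + ΔG_np, averaged over MD frames, with the
nonpolar solvation term ΔG_np = γ·SASA + β (γ = 0.005 kcal·mol⁻¹·Å⁻²,
β = 0).

**Interaction entropy (IE).** The entropic penalty is estimated from the
fluctuation ΔE_int of the protein–ligand interaction energy:

    −TΔS = kT · ln ⟨ e^{ΔE_int / kT} ⟩ ≥ 0,

computed in log space to avoid overflow. For Gaussian fluctuations of
standard deviation σ this converges to σ²/(2kT). The total binding free
energy is ΔG_bind = ΔH + (−TΔS).

**Alanine scanning.** Each receptor residue x near the peptide contributes
ΔΔG^{x→a} = ΔG_bind^x − ΔG_bind^a; contributions sum to ΔG_bind. Residues
favourable by ≥ 1 kcal/mol (contribution ≤ −1) in ≥ 50 % of complexes are
recurrent hotspots.

**Association rules.** Peptides are encoded as transactions of positional
property items (`P1:aromatic`, …); FP-growth mines itemsets with
support = count/N, and rules X→Y with confidence = Sup(X∪Y)/Sup(X).

**IC50.** ACE inhibition from hippuric-acid HPLC peak areas,
inhibition = ((b−c)−(a−c))/(b−c) × 100 %, fitted against concentration with
a four-parameter log-logistic curve.

## Worked example

```python
from acepep import BindingEnergyModel, DoseResponseModel
from acepep.synthetic import EnergySeriesConfig, gen_energy_series, gen_dose_response

frames = gen_energy_series(EnergySeriesConfig(seed=0, n_frames=10_000,
                                              complex_id="ACE-WFSW (synthetic)"))
print(BindingEnergyModel(frames, complex_id="ACE-WFSW (synthetic)").fit().summary())
```

```
MM/GBSA + interaction entropy — ACE-WFSW (synthetic)
  frames: 100 (enthalpy), 10000 (entropy); T = 300 K
  term          kcal/mol      sem
  dE_vdW          -36.54     0.31
  dE_ele          -43.47     0.50
  dG_GB            41.27     0.35
  dG_np            -2.88     0.03
  dH              -41.62
  -T dS             6.66
  dG_bind         -34.96
```

The component means recover the configured values (the defaults mimic a
strong Trp-containing binder) within their standard errors; the IE penalty
here reflects the configured 3 kcal/mol interaction-energy fluctuation.

```python
fit = DoseResponseModel.from_dataframe(gen_dose_response(seed=1, true_ic50=19.98)).fit()
print(fit.summary())
```

```
4PL dose-response fit
  n points        7
  IC50            21.21 uM (+/- 6.99, 95% CI half-width)
  hill slope      1.186
  bottom / top    7.14 / 95.68 %
  rmse            1.994 % inhibition
```

A seven-point 2× dilution series with 3 % inhibition noise recovers the
planted 19.98 μM IC50 within its confidence interval.

The same stages are scriptable from the shell via the `acepep` CLI
(`enumerate`, `simulate-scores`, `rank-stats`, `mine-rules`, `energetics`,
`alascan`, `ic50`, and `demo` for the full deterministic pipeline):

```bash
acepep demo --seed 7 --out-dir demo_out
```

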