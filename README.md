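# cotransport

Stoichiometry analysis of electrogenic Na⁺/Cl⁻-coupled substrate transport
from voltage-clamp and radiotracer measurements.

Secondary-active transporters of the SLC6 family (glycine, GABA, monoamine
transporters) move a fixed number of Na⁺ and Cl⁻ ions per substrate molecule
each cycle. That coupling stoichiometry — e.g. 3 Na⁺ : 1 Cl⁻ : 1 glycine for
GlyT2 versus 2 : 1 : 1 for GlyT1 — sets the concentrating power of the
transporter and is measured electrophysiologically. This package implements
the quantitative chain used for that measurement, for anyone analysing
two-electrode voltage-clamp and uptake data from oocytes or transfected
cells:

* **Thermodynamic reversal potential.** A cycle moving n_Na sodium ions,
  n_Cl chloride ions and one neutral substrate molecule (net charge
  z_T = n_Na − n_Cl) is at equilibrium at

  E_T = [2.3·R·T / (z_T·F)] · log₁₀( [Na⁺]ₒ^n_Na [Cl⁻]ₒ^n_Cl [S]ₒ /
  ([Na⁺]ᵢ^n_Na [Cl⁻]ᵢ^n_Cl [S]ᵢ) )

  so E_T shifts by 2.3·R·T·n_Na/(z_T·F) per tenfold change of external Na⁺.
  Fitting measured reversal potentials against log₁₀[Na⁺]ₒ and inverting the
  slope counts the coupled sodium ions.
* **Charge-to-flux ratio.** The time integral of the substrate-evoked
  current (in moles of elementary charge, |Q|/F) divided by the moles of
  radiolabelled substrate accumulated estimates z_T directly.
* **I/V analysis.** Evoked-current subtraction, normalization to a reference
  potential, reversal-potential interpolation, and rectification degree
  (ratio of hyperpolarized- to depolarized-limb slopes).
* **Uptake kinetics.** Hill fits of the sodium dependence (EC₅₀, Hill n) and
  Michaelis–Menten fits of chloride/substrate dependence (K_m, V_max,
  V_max/K_m), with mock-cell background subtraction.
* **Synthetic experiments.** Seeded generators that emulate each protocol
  with known ground truth, so the whole chain is testable end to end.

## Worked example

```python
from cotransport import *

stoich = Stoichiometry(n_na=3, n_cl=1)          # 3 Na+ : 1 Cl- : 1 substrate
print("predicted slope:", round(slope_per_decade(stoich, 18.0), 2))
print("n_Na from measured 86.49 mV/decade:",
      round(infer_n_na(86.49, z_t=2, temperature_c=18.0), 2))

# a synthetic reversal-potential assay: 8 oocytes, 5 Na+ levels, 5 mV noise
spec = SimulationSpec(
    stoichiometry=stoich,
    conditions=IonConditions(na_o=100, cl_o=106, gly_o=1, temperature_c=18.0),
    seed=1, noise_sd_erev=5.0,
)
series = gen_erev_series(spec, [20, 40, 60, 80, 100], n_oocytes=8)
fit = fit_reversal_series(series.points())
print(f"fitted slope: {fit.slope:.2f} ± {fit.slope_se:.2f} mV/decade")

# charge-to-flux: 1-min tracer application at -60 mV, zero noise
trace, counts = gen_charge_flux_experiment(spec, transport_rate_mol_per_s=1e-13)
q = integrate_charge(trace)
m = moles_from_tracer(counts.dpm_sample, counts.dpm_background,
                      counts.specific_activity_ci_per_mmol)
print(f"ratio: {charge_to_flux(q, m).ratio:.2f} charges/molecule")
```

prints

```
predicted slope: 86.55
n_Na from measured 86.49 mV/decade: 3.0
fitted slope: 84.30 ± 3.65 mV/decade
ratio: 2.00 charges/molecule
```

The predicted slope is the 18 °C theoretical shift of E_rev per decade of
external Na⁺ for a 3:1:1 cycle (z_T = 2); inverting a measured 86.49
mV/decade slope at z_T = 2 returns ≈3 coupled Na⁺ ions. The noisy synthetic
assay recovers a slope statistically consistent with that prediction, and
the noiseless charge-to-flux chain returns exactly the net charge of the
generating stoichiometry (2 charges per molecule).

A `cotransport` CLI wraps the same functions:

```
cotransport predict slope --stoichiometry 3:1 --temperature-c 18
cotransport simulate erev --stoichiometry 3:1 --seed 1 --out erev.csv
cotransport analyze erev-slope --in erev.csv --z-t 2
cotransport report --config config.yaml --out report/
```

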