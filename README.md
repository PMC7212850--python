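# pdtdose

Absorbed-photon dosimetry for interstitial photodynamic therapy (PDT),
built around the comparison of two photosensitizers in an orthotopic rat
glioma (RG-2) model: **Rutherrin** (the ruthenium complex TLD1433
formulated with apo-transferrin, activated at 530/808 nm) and
**ALA-induced PpIX** (protoporphyrin IX produced from 5-aminolevulinic
acid, activated at 635 nm).

Photosensitizers differ in extinction coefficient, tissue concentration
and activation wavelength, so joules or photons delivered are not
comparable across agents.  The package therefore expresses every dose as
the **absorbed photon density** — photons absorbed *by the
photosensitizer* per cm³ of tissue:

```
n_abs [hv cm^-3] = psi [hv cm^-2] * mu_a,ps,   mu_a,ps = ln(10) * eps * C
```

where `psi` is the areal photon density (radiant exposure divided by the
photon energy `h*c/lambda`), `eps` the decadic molar extinction
coefficient [M⁻¹ cm⁻¹] and `C` the photosensitizer concentration [M].
On this common axis the package computes:

- **In vitro LD50** — viability plates normalized against solvent/kill
  controls, four-parameter logistic fits on log₁₀ concentration, LD50
  converted to hv cm⁻³ (with the 8:1 ALA→PpIX stoichiometry for the
  pro-drug).
- **Light transport** — fluence around an interstitial isotropic emitter
  in turbid brain tissue by the diffusion closed form
  `phi(r) = P exp(-mu_eff r) / (4 pi D r)` and by a seeded voxel
  Monte Carlo (Henyey–Greenstein scattering, Russian roulette), plus
  dose–volume histograms.
- **Photodynamic thresholds** — the absorbed photon density at the
  observed necrosis/enhancement boundary radius, its inverse (predicted
  treatable radius), and the selectivity heuristic `log3(SUR)` effective
  penetration depths.
- **Biodistribution** — ICP-MS ruthenium ppb → TLD1433 tissue
  concentration → specific uptake ratio (SUR, tumor over normal brain).
- **Survival** — Kaplan–Meier estimation and the Mantel–Cox log-rank
  test, implemented from first principles.
- **Synthetic data** — seeded generators for every input (plates, uptake
  tables, boundary radii, survival arms) at the modeled study's
  conditions.

See `docs/methods.md` for models, parameter defaults and limitations.

## Worked example

```python
from pdtdose.pipeline import run_comparison, render_report
print(render_report(run_comparison(seed=1)))
```

prints (abridged):

```
In vitro LD50:
    agent  ld50_concentration_M  hill_slope  ld50_photon_density_hv_cm3
rutherrin          2.196662e-08    1.629560                2.274583e+16
      ala          3.187447e-04    1.484038                1.501829e+19

Selectivity (penetration depths = log3 SUR):
         condition       sur  penetration_depths  distance_cm
rutherrin_808_gray 20.141933            2.733270     2.735459
      ala_635_gray 10.600000            2.148942     1.806089

Photodynamic thresholds at the necrosis boundary:
       condition       tissue  threshold_hv_cm3  boundary_radius_cm
 rutherrin_tumor        tumor      8.457310e+18            0.428506
rutherrin_normal normal_brain      3.112767e+18            0.082270

Survival medians:
                 arm  n  median_days
             control  8     3.385697
             ala_pdt  8     8.437824
rutherrin_pdt_5mg_4h  8    14.131507
```

Reading it: killing half the RG-2 cells takes ~2.3×10¹⁶ absorbed photons
per cm³ with Rutherrin versus ~1.5×10¹⁹ with ALA-PpIX — roughly three
orders of magnitude less light dose for the same biological effect.  A
tumor-to-brain uptake ratio near 20 buys ~2.7 effective penetration
depths of selective margin (vs ~2.1 for PpIX), normal brain necroses at
a ~3× lower threshold than tumor, and the survival arms separate
(log-rank p < 0.05) with medians ordered control < ALA < Rutherrin.

The same stages are available as CLI subcommands operating on CSV files:

```sh
pdtdose generate --out scenario/ --seed 7
pdtdose fit-ld50 --plate scenario/plate_rutherrin.csv --ps rutherrin --light well_530
pdtdose compute-sur --samples scenario/uptake.csv --timepoint 4 --dose 5
pdtdose compare-survival --records scenario/survival.csv --arms control,rutherrin_pdt_5mg_4h
pdtdose run-all --seed 1 --out report/
```

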