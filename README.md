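# hydrashell

Analysis of protein hydration shells from two complementary directions:

* **Simulation side** — given molecular configurations (multi-model PDB or
  extended XYZ) of a protein in electrolyte solution, classify water
  molecules into the first solvation shell (water oxygen within 3.5 Å of a
  protein C or O atom) and bulk (farther than 10 Å from all protein C/O),
  enumerate hydrogen-bond geometries, and build normalized 2D probability
  densities p<sub>b,x</sub>(d, cos θ) of the donor–acceptor heavy-atom
  distance d and the hydrogen-centered angle θ for each bond population x
  at salt molality b.  Differences of these maps quantify how the shell
  perturbs the solvent structure:

      Δp_{b,x}  =  p_{b,x} − p_{b,bulk}            (shell vs. bulk, same b)
      ΔΔp_x     =  Δp_{b_high,x} − Δp_{b_low,x}    (high vs. low salt)

  A monotone distance→frequency calibration ν(d) = ν_free − A·e^{−(d−d0)/λ}
  projects any geometry density onto a simulated water OH-stretch spectrum.

* **Experiment side** — IR solvation-shell spectroscopy (IR-SSS) on
  ATR-FTIR spectra: linear baseline correction between two window-averaged
  anchor points, subtraction of the bulk-solvent reference scaled by the
  largest coefficient c that leaves no negative spectral features (the
  *least non-negative* residual; a solute occupying 1% of the volume gives
  c = 0.99), and normalization to the amide II band
  ([1500.1, 1550] cm⁻¹) as an internal concentration standard.  The result
  is the solute-correlated (SC) spectrum of the protein plus its perturbed
  hydration shell.

The intended users are researchers comparing hydration-shell structure
across proteins (e.g. halophilic vs. mesophilic variants) and salt
concentrations.  Because microsecond trajectories and wet-lab spectra are
not shippable test assets, the package includes synthetic generators that
produce frames with *known* hydrogen-bond geometry distributions and
spectra that are a *known* mixture of solvent, SC component, baseline
drift and noise — every pipeline stage is validated against that ground
truth.

## Worked example

Run the full synthetic demonstration (two molalities of frames, two KCl
concentrations of spectra):

```bash
hydrashell report --config run.yaml
```

with `run.yaml`:

```yaml
out_dir: demo
seed: 1
n_frames: 8
molalities: [0.15, 2.0]
concentrations: [0.15, 2.0]
```

Selected output from `demo/summary.json`:

```json
"simulation": {
  "per_molality": {
    "2.0": {"dp_regions": {"VERY_STRONG": 0.606, "MODERATE": -0.387}}
  },
  "ddp_regions": {"VERY_STRONG": 0.194, "MODERATE": -0.194}
},
"experiment": {
  "per_concentration": {
    "0.15": {"c_true": 0.97, "c_recovered": 0.9709},
    "2.0":  {"c_true": 0.97, "c_recovered": 0.9621}
  }
},
"transfer_cost_kJ_per_mol": 120.44
```

Reading the numbers: `dp_regions` are signed integrals of Δp over the two
standard regions of the difference map — very strong hydrogen bonds
(d < 2.8 Å) are *enriched* in the shell (+0.61) while moderately strong,
nearly linear bonds (d > 2.8 Å, −1 < cos θ < −0.75) are *depleted*
(−0.39); `ddp_regions` shows the enrichment growing with salt.  On the
experiment side the subtraction coefficient recovered from noisy synthetic
spectra is within 1% of the generating value 0.97.  The transfer cost is
the surface-tension estimate for moving 10,000 Å² of hydrophobic protein
surface from water (72 mN/m) into 2 mol/kg KCl (76 mN/m) with a
microscopic-to-macroscopic factor of 0.5: ≈120 kJ/mol.

Individual stages are also exposed (`hydrashell simulate-frames`,
`hbond-density`, `diff`, `regions`, `map-spectrum`, `simulate-spectra`,
`sss`, `transfer-cost`); see `--help` on each, or call the library
functions directly (`hydrashell.classify_waters`, `enumerate_hbonds`,
`accumulate_density`, `density_difference`, `run_sss`, ...).

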