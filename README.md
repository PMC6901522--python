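# mydgf-nmr

Analysis pipeline for the solution-state characterisation of human
myeloid-derived growth factor (hMYDGF): chemical-shift-perturbation (CSP)
mapping of ¹H,¹⁵N HSQC spectra, pH-titration pKa extraction, ¹⁵N
relaxation with rotational-correlation-time and mass estimation,
NMR-ensemble statistics, and CD/fluorescence/sequence utilities. It is
written for structural biologists who have assigned peak lists, coordinate
ensembles and optical scans and want the downstream numbers — perturbation
bins, pKa values, τc, ensemble RMSDs — reproducibly, from plain-text
inputs.

The quantities at the core:

* combined amide perturbation ΔδNH = √(ΔδH² + (ΔδN/5)²), binned with a
  first-bin width of Q3 + 1.5·IQR (Tukey fence) of a replicate-pair ΔδNH
  distribution, after aligning all spectra on a pH-insensitive reference
  amide (W77);
* pKa from titration curves by cubic inflection (pKa = −b/3a) with a
  Henderson–Hasselbalch fit δ(pH) = δ_acid + A/(1 + 10^(pKa−pH)) as
  cross-check;
* single-exponential relaxation fits I(t) = I₀e^(−t/T) and the rigid-rotor
  estimate τc = (4πνN)⁻¹ √(6T₁/T₂ − 7), mapped to apparent mass by an
  empirical ~0.6 ns/kDa calibration;
* ensemble RMSD of models 2..N against the lowest-energy conformer after
  Kabsch superposition over ordered residues; NOE restraint classes by
  sequence separation (short ≤ 1 < medium ≤ 5 < long);
* molar ellipticity conversion, Savitzky–Golay smoothing and polynomial
  emission-peak location.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

Everything runs on synthetic data out of the box. The numbered drivers
under `analysis/` execute the full pipeline and write tables under
`results/`:

```bash
python analysis/01_simulate.py           # seeded datasets + ground truth
python analysis/02_csp_binning.py
python analysis/03_titration_pka.py
python analysis/04_relaxation_tumbling.py
```

which prints, among other lines:

```
replicate Tukey fence (first bin bound): 0.0283 ppm
endpoint comparison: perturbed; 24/30 residues above the fence
200-curve recovery: HH median |error| 0.021, cubic median |error| 0.069
"tau_c_ns_600MHz": 9.4,
"tau_c_ns_800MHz": 7.0,
"mass_kda_from_tauc": 15.6,
```

Reading these: the replicate fence (0.028 ppm) is the reproducibility
scale of the simulated spectra, and the pH 5.5 → 8.0 comparison correctly
calls the titrating residues perturbed. The Henderson–Hasselbalch fit
recovers known pKa values to ~0.02 pH units (the cubic trendline to ~0.07,
its method bias on a truncated pH window). Chaining the study's mean
structured-residue relaxation times (T₁ = 763.6 ms, T₂ = 78.6 ms) through
the rigid-rotor closed form gives τc = 9.4 ns at the 600-MHz ¹⁵N Larmor
frequency — a ~15.7 kDa apparent mass under the default calibration, i.e.
a monomer — while the 800-MHz frequency gives 7.0 ns, pinning down which
field the closed form belongs with.

The same stages are available as a CLI for your own files:

```bash
mydgf-nmr simulate --seed 1 --out-dir sim
mydgf-nmr titrate sim/hsqc_ph*.list --ph 5.5 --ph 6 --ph 6.25 --ph 6.5 \
    --ph 7 --ph 7.4 --ph 8 --ref-peak A30N-H --out-dir titration
mydgf-nmr ensemble-stats ensemble.pdb --ranges 35-126,133-168 \
    --restraints restraints.upl
```

`analysis/07_deposited_validation.py` additionally checks the pipeline
against the deposited hMYDGF structure (PDB 6O6W), its restraints and the
UniProt Q969H8 sequence once those files are downloaded manually (URLs in
the script's docstring).

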