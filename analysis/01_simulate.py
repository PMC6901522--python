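#!/usr/bin/env python
"""Generate the synthetic study datasets every later stage consumes.

Writes, under results/simulated/: per-pH HSQC peak lists for a 30-residue
titration scenario (with ground-truth pKa table), two replicate pH-6 lists
for the chemical-shift-perturbation fence, T2 decay tables, a jittered
20-model coordinate ensemble, a restraint table with the study's class
sizes, and native/denatured emission scans.
"""

import sys
from pathlib import Path

import numpy as np

from mydgf_nmr.io_formats import Condition, write_ensemble, write_peaklist, write_restraint_table, write_xy_table
from mydgf_nmr.synthetic import (
    DecayScenario,
    EnsembleScenario,
    TitrationScenario,
    default_titration_scenario,
    make_base_coordinates,
    make_decay_dataset,
    make_emission_spectrum,
    make_ensemble,
    make_restraint_set,
    make_titration_dataset,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2026
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
OUT.mkdir(parents=True, exist_ok=True)

scenario = default_titration_scenario(n_residues=30, seed=SEED)
with open(OUT / "titration_truth.tsv", "w") as fh:
    fh.write("label\tpka\tamp_h\tamp_n\n")
    for r in scenario.residues:
        fh.write(
            f"{r.label.render()}\t{'' if r.pka is None else f'{r.pka:.4f}'}"
            f"\t{r.amp_h:.4f}\t{r.amp_n:.4f}\n"
        )
for pl in make_titration_dataset(scenario):
    with open(OUT / f"hsqc_ph{pl.condition.pH:g}.list", "w") as fh:
        write_peaklist(pl, fh)

# two replicate pH-6 spectra (same truth, noise only) for the Tukey fence
for rep in (1, 2):
    rep_scenario = TitrationScenario(
        residues=scenario.residues, ph_grid=(6.0,), noise_sd=scenario.noise_sd,
        seed=SEED + 100 + rep,
    )
    (pl,) = make_titration_dataset(rep_scenario)
    with open(OUT / f"hsqc_ph6_replicate{rep}.list", "w") as fh:
        write_peaklist(pl, fh)

rng = np.random.default_rng(SEED)
true_t2 = tuple(rng.uniform(60.0, 100.0, size=50))
with open(OUT / "t2_decays.tsv", "w") as fh:
    fh.write("label\tdelay_ms\tintensity\ttrue_T_ms\n")
    for series, T in zip(
        make_decay_dataset(DecayScenario(true_T_ms=true_t2, seed=SEED + 1)), true_t2
    ):
        for d, i in zip(series.delays_ms, series.intensities):
            fh.write(f"{series.label.render()}\t{d:g}\t{float(i)!r}\t{T:.4f}\n")

atoms, coords = make_base_coordinates(n_residues=125, seed=SEED + 2)
ens = make_ensemble(EnsembleScenario(atoms, coords, n_models=20, jitter_sd=0.5, seed=SEED + 3))
with open(OUT / "ensemble.pdb", "w") as fh:
    write_ensemble(ens, fh)

with open(OUT / "restraints.upl", "w") as fh:
    write_restraint_table(make_restraint_set(2932, 151, 620, seed=SEED + 4), fh)

for name, centre, width in (("native", 338.0, 25.0), ("denatured", 357.0, 30.0)):
    spec = make_emission_spectrum(centre, width, noise_frac=0.01, seed=SEED + 5)
    with open(OUT / f"emission_{name}.csv", "w") as fh:
        write_xy_table(spec, fh)

print(f"wrote synthetic datasets to {OUT} (seed {SEED})")
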