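#!/usr/bin/env python
"""Relaxation fits and the tumbling-time / mass chain.

Fits every simulated T2 decay to a single exponential, averages the fitted
time constants over a secondary-structure-like mask, and — taking the
study's printed mean T1 (763.6 ms) together with its printed mean T2
(78.6 ms) — chains the rigid-rotor closed form at the 600-MHz 15N Larmor
frequency to a rotational correlation time and apparent mass. Finding:
tau_c = 9.4 ns, apparent mass ~15.7 kDa under the 0.6 ns/kDa calibration —
a monomer-sized value; the same means at the 800-MHz frequency give 7.0 ns,
confirming which field the closed form belongs to. A 100-replicate
recovery run reports the fit error at 2 % noise.
"""

import json
from pathlib import Path

from mydgf_nmr.io_formats import parse_assignment_label
from mydgf_nmr.recovery import decay_recovery
from mydgf_nmr.relaxation import (
    NU_N_600MHZ,
    NU_N_800MHZ,
    DecaySeries,
    average_over_mask,
    estimate_tauc,
    expand_residue_ranges,
    fit_exponential,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "relaxation"
OUT.mkdir(parents=True, exist_ok=True)

rows: dict[str, list[tuple[float, float]]] = {}
truth: dict[str, float] = {}
for line in (ROOT / "simulated" / "t2_decays.tsv").read_text().splitlines()[1:]:
    label, delay, intensity, true_t = line.split("\t")
    rows.setdefault(label, []).append((float(delay), float(intensity)))
    truth[label] = float(true_t)

fits = []
for label, pts in rows.items():
    fits.append(
        fit_exponential(
            DecaySeries(parse_assignment_label(label), tuple(p[0] for p in pts),
                        tuple(p[1] for p in pts), "T2")
        )
    )
with open(OUT / "t2_fits.tsv", "w") as fh:
    fh.write("label\tT_ms\ttrue_T_ms\trel_error\tok\n")
    for f in fits:
        true = truth[f.label.render()]
        fh.write(f"{f.label.render()}\t{f.T_ms:.3f}\t{true:.3f}\t{abs(f.T_ms-true)/true:.4f}\t{f.ok}\n")

values = {f.label.residue_number: f.T_ms for f in fits if f.ok}
mask = expand_residue_ranges([(30, 54), (60, 79)])  # structured-like subset
mean_t2, n_used = average_over_mask(values, mask)

est_600 = estimate_tauc(763.6, 78.6, NU_N_600MHZ)
est_800 = estimate_tauc(763.6, 78.6, NU_N_800MHZ)
recovery = decay_recovery(n_residues=100, true_T_ms=78.6, noise_sd=0.02, seed=2026)

summary = {
    "simulated_mean_T2_ms": mean_t2,
    "n_residues_in_mask": n_used,
    "study_mean_T1_ms": 763.6,
    "study_mean_T2_ms": 78.6,
    "tau_c_ns_600MHz": est_600.tau_c_rounded,
    "tau_c_ns_800MHz": est_800.tau_c_rounded,
    "mass_kda_from_tauc": round(est_600.mw_estimate_kda, 1),
    "t2_recovery_median_rel_error": recovery["median_relative_error"],
}
(OUT / "tumbling.json").write_text(json.dumps(summary, indent=2))
print(json.dumps(summary, indent=2))
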