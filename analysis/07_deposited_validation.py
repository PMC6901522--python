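#!/usr/bin/env python
"""Validation against the deposited hMYDGF data (requires manual downloads).

This stage checks the pipeline against the deposited solution structure
and sequence rather than synthetic data. It needs network access once to
fetch, into analysis/data/:

  6O6W.pdb        https://files.rcsb.org/download/6O6W.pdb
  6O6W.mr         https://files.rcsb.org/download/6O6W.mr
                  (NOE upper-bound restraints; convert/extract the CYANA-
                  style table to 6O6W_restraints.upl, one record per line:
                  res_i resname_i atom_i res_j resname_j atom_j bound)
  Q969H8.fasta    https://rest.uniprot.org/uniprotkb/Q969H8.fasta

Expected outcomes: 20 models; backbone RMSD vs model 1 over ordered
residues 35-126 and 133-168 of ~0.7 Å and all-heavy of ~1.3 Å; restraint
classes 2932 short / 151 medium / 620 long of 3703 total (raw-record
convention; deviations are reported, not hidden); average mass of GSKGT +
mature residues 32-173 with one disulfide of ~16.25 kDa. The script exits
quietly when the files are absent.
"""

import json
import sys
from pathlib import Path

from mydgf_nmr.ensemble import RegionSet, classify_restraints, ensemble_rmsd, sequence_props
from mydgf_nmr.io_formats import read_ensemble, read_restraint_table

DATA = Path(__file__).resolve().parent / "data"
OUT = Path(__file__).resolve().parent.parent / "results" / "deposited"

summary = {}

pdb = DATA / "6O6W.pdb"
if pdb.exists():
    ens = read_ensemble(str(pdb))
    summary["n_models"] = ens.n_models
    for selection in ("backbone", "heavy"):
        region = RegionSet(ranges=((35, 126), (133, 168)), atom_selection=selection)
        mean, sd, _ = ensemble_rmsd(ens, region)
        summary[f"rmsd_{selection}_mean_A"] = round(mean, 3)
        summary[f"rmsd_{selection}_sd_A"] = round(sd, 3)

upl = DATA / "6O6W_restraints.upl"
if upl.exists():
    counts = classify_restraints(read_restraint_table(upl.read_text()))
    summary["restraints"] = {
        "total": counts.total,
        "short": counts.short,
        "medium": counts.medium,
        "long": counts.long,
    }

fasta = DATA / "Q969H8.fasta"
if fasta.exists():
    seq = "".join(
        line.strip() for line in fasta.read_text().splitlines() if not line.startswith(">")
    )
    construct = "GSKGT" + seq[31:173]  # cloning residues + mature V32-L173
    props = sequence_props(construct, n_disulfides=1)
    summary["construct_length"] = len(construct)
    summary["average_mass_kda"] = round(props.average_mass_kda, 2)
    summary["extinction_280"] = props.extinction_280

if not summary:
    print("no deposited data found under analysis/data/ — see this script's "
          "docstring for download instructions; nothing to validate")
    sys.exit(0)

OUT.mkdir(parents=True, exist_ok=True)
(OUT / "deposited_validation.json").write_text(json.dumps(summary, indent=2))
print(json.dumps(summary, indent=2))
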