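# Methods

This package reimplements, as tested library code, the quantitative
analyses used to characterise human myeloid-derived growth factor (hMYDGF)
in solution: chemical-shift-perturbation (CSP) mapping of ¹H,¹⁵N HSQC
spectra, pH-titration pKa extraction, ¹⁵N relaxation analysis with
rotational-correlation-time and mass estimation, multi-model ensemble
statistics, and the supporting CD/fluorescence/sequence arithmetic. All
stages run on plain-text inputs (Sparky-style peak lists, multi-MODEL PDB,
CYANA-style `.upl` restraint tables, two-column CSV/TSV spectra) and every
stage has a seeded synthetic generator that emits ground truth next to the
data, so the whole pipeline is validated closed-loop without downloads.

## Chemical-shift perturbation

The combined perturbation of a backbone amide between two conditions is

    ΔδNH = sqrt(ΔδH² + (ΔδN / 5)²)   [ppm]

with ΔδH and ΔδN the signed displacements in the ¹H and ¹⁵N dimensions;
the 1/5 factor compensates the wider ¹⁵N dispersion. Before comparison,
every spectrum is rigidly shifted (one constant ppm offset per dimension)
so that a designated pH-insensitive reference amide — W77 for hMYDGF —
coincides across conditions; alignment offsets are applied in ppm, which
is field-independent. The reference peak is pinned exactly, so its CSP is
identically zero rather than zero to rounding.

Perturbations are discretised into ten equal-width bins. The width of the
first bin is the Tukey upper fence, Q3 + 1.5·IQR, of the ΔδNH distribution
between two replicate spectra of nominally identical conditions — i.e. the
boundary between reproducibility noise and genuine movement. Quartiles use
linear interpolation on the sorted sample (numpy's default, the common
"type 7" convention); the method is configurable because fence values are
mildly convention-dependent. Bins are right-closed, zero falls in bin 1,
and the tenth bin is open-topped. Residues missing in either condition are
marked (rendered black / B-factor −1 when painted onto a structure).
`compare_conditions` calls a pair of spectra "unperturbed" iff every
common residue's ΔδNH falls below a threshold, defaulting to the fence
when one is available and to 0.02 ppm — a typical HSQC reproducibility
scale — otherwise.

## pH titration and pKa

Per-residue curves track ΔδNH relative to the lowest-pH spectrum across
the series; for the hMYDGF study grid this reference is pH 5.5 (the pH 4.0
sample precipitated) and the grid is {5.5, 6.0, 6.25, 6.5, 7.0, 7.4, 8.0},
the 7.4 point coming from the calcium-study buffer. Two extractors:

* **Cubic inflection** — unweighted least-squares third-order polynomial in
  pH; pKa at the inflection, −b/(3a), where the fitted second derivative is
  exactly zero. Needs ≥ 4 points and a non-flat curve; |a| within 1e-12 of
  the normalised problem is declared "no inflection" rather than returning
  an unbounded value. pKa is reported to one decimal.
* **Henderson–Hasselbalch (HH)** — nonlinear least squares of the
  single-site fast-exchange model δ(pH) = δ_acid + A/(1 + 10^(pKa−pH)),
  initialised at the observed half-transition point. This is the physical
  model and serves as the cross-check on the graphical cubic method.

An extracted pKa outside the sampled pH window is flagged
`in_range=False` and labelled an estimate; no extrapolation guard beyond
the flag. A known limitation of the cubic route: when the true pKa lies
below the window the sampled curve is a saturating tail, and the cubic's
inflection lands near the top of the window rather than below it — so the
out-of-window flag is trustworthy for the HH fit (which recovers a
below-window pKa by extrapolation and flags it) but not a reliable
detector of incomplete titrations for the cubic. On noiseless single-site
data over the truncated study window the cubic also carries a systematic
bias of roughly 0.1 pH units (a cubic is not a sigmoid); the recovery
experiments therefore quote separate error bands: median |error| ≤ 0.05
for HH, ≤ 0.2 for the cubic, over 200 synthetic curves with pKa in
[5.8, 7.0], combined amplitudes 0.1–0.5 ppm and 0.005 ppm shift noise.

## ¹⁵N relaxation and tumbling

Peak intensity vs relaxation delay is fit per residue to
I(t) = I₀·exp(−t/T) by Levenberg–Marquardt, initialised from a log-linear
regression on the positive intensities (deterministic, and exact at zero
noise). Delay schedules default to the study's grids — 10–210 ms in 20-ms
steps for T₂ and 80–2000 ms for T₁. A fitted T exceeding 100× the longest
delay means the data do not decay over the window and the fit is flagged
not-converged. Heteronuclear NOE is the ratio of saturated to unsaturated
peak intensity; duplicate experiment pairs are averaged at the intensity
level before ratioing (configurable).

Mean T₁ and T₂ over a user-supplied mask of residues in secondary
structure (an input of residue ranges; no secondary-structure computation
in scope) feed the isotropic rigid-rotor estimate

    τc = 1/(4π·νN) · sqrt(6·T₁/T₂ − 7)

valid for T₁/T₂ ≥ 7/6, with νN the ¹⁵N Larmor frequency. νN defaults to
60.83 MHz (¹⁵N at a 600-MHz spectrometer): the study recorded relaxation
at 600 and 800 MHz, and only the 600-MHz frequency chains the printed
means (763.6 ms, 78.6 ms) to the printed 9.4 ns — kept as a regression
test. Apparent mass uses an empirical linear calibration for rigid
monomers, default 0.6 ns/kDa with zero intercept, exposed in configuration
because published calibrations vary; 9.4 ns maps to ≈ 15.7 kDa under the
default, close to but not exactly the study's 15.5 kDa (whose calibration
coefficients are not printed).

## Ensemble statistics

Superposition is the classic Kabsch SVD solution over centred coordinates
with the reflection corrected to a proper rotation; it is implemented
directly (~15 lines of numpy) so the tests can cross-check it against two
independent routes — scipy's Wahba solver and a brute-force 10°-step Euler
rotation grid. Ensemble precision follows the deposition convention:
models 2..N are each superposed onto model 1 (the lowest-energy conformer)
over selected atoms of the ordered regions, and the mean ± sd of those
RMSDs is reported. The ordered regions for hMYDGF default to residues
35–126 and 133–168; backbone selection defaults to N, CA, C with carbonyl
O optional, since "backbone heavy atoms" is ambiguous on that point.

NOE restraints are classified by sequence separation — short |i−j| ≤ 1,
medium 1 < |i−j| ≤ 5, long |i−j| > 5 — counting one per record with no
deduplication or ambiguity expansion (the raw-record convention; the
deposited bookkeeping is not documented, so the simplest convention is the
default and any deviation is reported rather than absorbed). Interface
residues between docked partners are those with any heavy atom within a
cutoff (default 5 Å) of the partner's heavy atoms, computed with a k-d
tree and property-tested against the all-pairs scan; hydrogens are
excluded on both sides.

Sequence properties use standard residue mass tables (Biopython), one
water per chain, and −2 hydrogen atoms per disulfide; the 280-nm
extinction coefficient follows the ProtParam rule
ε = 5500·nTrp + 1490·nTyr + 125·n_cystine, and Beer's law inverts
absorbance to molar concentration.

## Optical spectra

CD scans are buffer-subtracted pointwise on an exactly matching grid (no
interpolation) and converted to molar ellipticity
[θ] = θ_mdeg/(10·c·l) in deg·cm²·dmol⁻¹; a mean-residue option divides by
(n_residues − 1). Smoothing is Savitzky–Golay (default window 11, order 3
— the study used an external tool without stating parameters) with
polynomial edge extension, which preserves any polynomial of degree ≤ the
filter order. Fluorescence maxima come from a least-squares polynomial
trendline (degree 6 by default) evaluated at its real critical points
inside the scanned window, with a dense-grid fallback and an explicit flag
when the maximum sits on the window edge; the x axis is centred and scaled
before fitting for conditioning. Replicate scans are averaged pointwise
before fitting.

## Synthetic generators

All generators are pure functions of a scenario object that includes the
seed, and they emit ground truth alongside the data:

* **Titration** — per-residue single-site logistic shift trajectories in
  each dimension with additive Gaussian shift noise (default σ =
  0.005 ppm, about HSQC digital resolution), on the study pH grid;
  pH-insensitive residues are generated flat. Default amplitudes (ΔδH up
  to 0.12 ppm, ΔδN up to 0.6 ppm) resemble the histidine-neighbourhood
  excursions of the study spectra.
* **Decays** — single exponentials with multiplicative Gaussian noise on
  either study delay grid.
* **Ensembles** — model 1 is an unjittered base structure; later models
  add i.i.d. Gaussian coordinate jitter of sd σ_j, giving a
  pre-superposition expected RMSD of σ_j·√3 and a Monte-Carlo-computable
  post-superposition expectation used as the oracle.
* **Restraints** — residue pairs drawn inside each requested
  sequence-separation class, so the classifier must reproduce the
  requested counts exactly.
* **Emission** — Gaussian peaks on the 305–400 nm, 0.5-nm-step grid.

What the generators do *not* emulate: peak overlap and lineshapes,
chemical-exchange broadening, assignment errors, baseline drift and
correlated noise, anisotropic tumbling, and real protein geometry
(ensembles are jittered random clouds). Passing the closed-loop tests
therefore demonstrates correctness of the estimators under their stated
statistical models, not robustness to every pathology of real spectra.

## Numerical choices and degenerate inputs

Duplicate peak labels, non-numeric fields, mismatched model compositions,
non-positive restraint bounds and duplicated wavelength points are hard
errors with located messages, never silently dropped. Readers and writers
round-trip losslessly (full-precision `repr` formatting). Degenerate fits
raise typed errors: flat titration curves, all-equal decay intensities,
a < 3-point or collinear superposition, an all-zero replicate fence (which
asks for an explicit bound override instead of producing zero-width bins).
Reported precision follows the study's: pKa and τc to one decimal, masses
to two.

## Analysis layout and problem sizes

The numbered drivers under `analysis/` are thin narratives over the
library: simulate → CSP binning → titration pKa → relaxation/tumbling →
ensemble statistics → optical spectra, writing under `results/`. Driver 07
validates against the deposited structure (PDB 6O6W), restraints and the
UniProt Q969H8 sequence when those files have been downloaded manually
(URLs in its docstring); everything else is download-free. Default
problem sizes — 30-residue titration scenarios (200 curves for recovery
scoring), 50–100 decay replicates, 20-model/500-atom ensembles — are
chosen so each stage completes in seconds while keeping Monte-Carlo
sampling error well below the tolerances being checked.
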