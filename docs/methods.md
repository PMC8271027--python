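# Methods

This note documents the models, the synthetic-data conditions, the numerical
choices and the known limitations of `pepxkit`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## FP association kinetics

The exchange of a fluorescent reporter peptide into a peptide-receptive
MHC-I groove is modelled as a single-exponential association,
Y(t) = Y0 − A·e^(−Kt), fitted by unweighted least squares (no weighting
scheme is standard for plate-reader FP exports). The observed rate K is an
apparent first-order constant; no attempt is made to decompose it into
on/off microscopic rates, and no anisotropy-to-fraction-bound conversion is
applied.

Fitting is multi-start Levenberg–Marquardt (trust-region-reflective with
bounds A > 0, K > 0): the starting rate is ln 2 / t_half from the first
half-range crossing, refined from {0.1, 1, 10}× that value, keeping the
lowest RSS. A trace whose range is below 3× a successive-difference noise
estimate is refused as "no association detected" rather than fitted.
Standard errors are asymptotic, s²(JᵀJ)⁻¹.

Baseline handling defaults to subtracting the mean of the matched
free-peptide (reporter-only) well; point-wise subtraction is available when
the grids match exactly.

Condition comparisons use the replicate-mean rates:

* fold change = mean K(cat) / mean K(−), with an SD from first-order error
  propagation of the two replicate SDs. Whether published ± values on fold
  changes are SDs of per-replicate ratios or propagated SDs of means is not
  decidable from summary data alone; propagation of means is this package's
  documented choice, not an inference about the source experiments.
* relative activity = (K_mut − K_−)/(K_WT − K_−), reported unclamped (a
  hyperactive mutant may exceed 1, a slightly inhibitory one may go
  negative).
* mutant-vs-WT comparisons use Welch's unequal-variance t test with
  Welch–Satterthwaite degrees of freedom; p-values are reported raw, with
  no multiplicity correction (star thresholds 0.05/0.01/0.001 are display
  conventions only).

## CPMG relaxation dispersion

Intensities convert to R2_eff(ν) = (1/T_CPMG)·ln(I0/I(ν)) with
T_CPMG = 40 ms and the 15-point schedule (0, 950, 50, 300, 150, 800, 100,
250, 400, 600, 200, 50, 500, 300, 700) Hz; the ν = 0 entry is the reference
scan and frequencies 50 and 300 Hz are measured twice. The per-profile
uncertainty is pooled over duplicate pairs, σ = √(Σ ΔR2² / 2m), and applied
uniformly — one σ per methyl, the standard duplicate-based convention.

A methyl is called *dispersing* when its amplitude — the mean R2_eff over
the two lowest distinct frequencies minus the mean over the two highest,
duplicates averaged within a frequency first — strictly exceeds 2 s⁻¹. The
threshold is interpreted as a dispersion *amplitude* rather than an absolute
R2_eff level, since an absolute threshold would flag rigid methyls with high
intrinsic relaxation.

Exchange is fitted with the fast-exchange (Luz–Meiboom) closed form; the
general two-site (Carver–Richards-type) expression and multiple-quantum-
specific equations are out of scope in v1. In the fast limit only
φ = p_a·p_b·Δω² and k_ex are identifiable, so populations and shift
differences are intentionally not reported. The fit is weighted least
squares in (R2,0, ln k_ex, ln φ) space, multi-started at
k_ex ∈ {200, 1000, 5000} s⁻¹, against a flat one-parameter alternative;
AICc (chi-square plus the small-sample penalty) selects the model, ties
resolving to the flat model for parsimony. Duplicate ν points enter the fit
as independent observations, consistent with their role in error
estimation.

Parameter-recovery envelopes were fixed by pre-build Monte-Carlo: at
σ ≈ 0.3 s⁻¹ and φ/k_ex = 10 s⁻¹ the population median of |k̂_ex − k_ex|/k_ex
over k_ex ∈ [500, 3000] s⁻¹ is ≈ 0.15 (300-profile run), so the 50-profile
regression test asserts a 0.20 envelope to absorb the sampling scatter of a
median of 50.

## HSQC intensity ratios

Ratios I/I0 are computed over residues quantified in both spectra; the
significance rule flags ratios strictly below mean − δ, where δ is one
*sample* standard deviation (ddof = 1) of the ratio distribution — the
"mean − δ" convention with δ read as an SD, a documented interpretation.
Peaks that vanish in the perturbed spectrum get ratio 0, stay in the
statistics, and are always flagged; a zero reference intensity cannot be
ratioed and is excluded. Fewer than 3 quantified residues make δ
meaningless and the flagging step refuses. CSPs use the conventional amide
weighting √(Δδ_H² + (Δδ_N/5)²) with the nitrogen axis down-weighted 5-fold.

## Structure mapping

Per-residue values are written into the B-factor column (fixed width
%6.2f, columns 61–66) of ATOM/HETATM records on a single chain, clamped to
the display range (e.g. 0.30–0.70, or 0-to-mean); unmapped residues of that
chain receive a −1.00 sentinel so viewers can color "unassigned"
distinctly. The file is edited at the line level: every byte outside the
rewritten B fields round-trips exactly, which is why the PDB handling is a
small fixed-width editor rather than an object-model parser. Matching is
by author residue number; insertion codes in the mapped chain are rejected
in v1, and mmCIF is unsupported.

## Thermal shift

Dye-based melt curves quench after the unfolding transition, while the
Boltzmann sigmoid is monotone; the data are therefore truncated after the
global fluorescence maximum and the rising limb fitted. Tm initializes at
the steepest rise (max ΔF/ΔT). Replicates are fitted independently and
averaged; ΔTm carries the propagated standard error. Tm is invariant under
affine rescaling of the fluorescence axis. Two-transition unfolding and
van't Hoff thermodynamics are out of scope.

## Synthetic-data conditions

The generator encodes the study conditions; its defaults are fixed and are
not tuned per run:

* **FP**: plateau 150 FP units, amplitude 150, free-peptide baseline 35,
  Gaussian noise 2 FP units, 3 replicates per condition, 40 points on an
  even grid. No raw K_on values or signal-to-noise figures are published,
  so absolute scales are conventions; only the *ratios* are calibrated.
  The uncatalyzed rate is fixed at 1e−4 s⁻¹; catalyzed rates multiply it by
  the published fold change and mutant rates invert the relative-activity
  formula. Published values encoded: wild-type conjugate fold changes
  10.89/5.83/3.83/1.31 (A\*03:01, B\*27:05, B\*27:09, A\*02:01), TAPBPR
  30.9/34.28/3.13/1.48 (A\*02:01, A\*03:01, B\*27:09, B\*27:05), and the
  scoop-loop mutant activities (L18G, K16G, GGGGG on three allotypes; K16L,
  L18K, GGGGL, GGGGK, GGLGG, GGKGG on A\*03:01 and B\*27:09), with
  qualitative statements ("no activity", "as efficient as wild type")
  encoded as 0.0 and 1.0. Measurement windows follow the 1–5 h plate-reader
  range with per-condition duration clip(8/k, 1 h, 5 h), since measuring
  times differed per allotype; fast catalyzed rises are thereby resolved
  without changing the noise model.
* **CPMG**: reference intensity 1e6, noise 1% of the reference, the
  duplicate schedule above; the demo methyl uses R2,0 = 12 s⁻¹,
  k_ex = 1500 s⁻¹, φ = 1.5e4 s⁻² (amplitude 10 s⁻¹ — a strong but
  physically plausible dispersion at 40 ms). ν > 0 points carry
  I = I0·e^(−T·R2(ν)); the ν = 0 rows carry the un-attenuated reference, as
  the reference scan contains no relaxation block. Duplicated frequencies
  receive independent noise so duplicate-based error estimation is
  genuinely exercised.
* **Peak lists**: positions drawn uniformly over amide ranges
  (6.5–10.5 / 105–130 ppm), intensities around 1e6; chosen residues carry
  true attenuations and shifts. Noise defaults to zero so constructed
  ratios are exact.
* **Melts**: 25–95 °C in 0.5 °C steps (a 2 °C/min ramp read every 15 s),
  transition from 1000 to 9000 fluorescence units, slope 1.5 °C, noise 1%
  of the transition height, 3 replicates; the demo condition pair is 6 °C
  apart, matching the published stability gap between the two
  photo-peptide complexes.

Noise streams are keyed by (seed, condition, replicate), so a fixed seed is
bit-reproducible, different replicates and conditions never share noise,
and different seeds change only the noise realization.

What passing recovery tests show — and what they do not: the synthetic
traces are ideal single-exponentials with homoscedastic Gaussian noise.
Real FP data add drifts, mixing transients and photobleaching; real
dispersion data add off-resonance effects and multiple-quantum artefacts;
real melts add pre-transition slopes. Recovery under the synthetic
conditions validates the estimators and the statistic definitions, not
robustness to those instrumental effects.

## Reproduction script

`scripts/acceptance.py` recomputes each calibrated statistic from scratch at
the study conditions (6 traces per fold change, 9 per relative activity) and
writes them as JSON keyed by short ids. Problem sizes match the replicate
counts above; a full run takes a few seconds on one CPU.

## Known limitations

* Fast-exchange-only dispersion model; no global multi-residue (shared
  k_ex) fits; no Δω sign information.
* FP fold-change SDs assume independent replicate means (no pairing
  information survives in summary exports).
* The flat-trace refusal is a range-vs-noise heuristic; near-threshold
  traces with pathological noise may still be fitted.
* PDB mapping targets one chain and ignores altLoc; files with insertion
  codes in the mapped chain are rejected rather than disambiguated.
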