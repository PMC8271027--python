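# pepxkit

Quantitative analysis of chaperone-catalyzed peptide exchange on MHC class I
molecules, for structural biologists and immunologists working with
fluorescence-polarization (FP) exchange assays, methyl-CPMG relaxation
dispersion, TROSY-HSQC titrations and dye-based thermal-shift (DSF) melts.

Peptide loading onto MHC-I is edited by the chaperones tapasin (assayed as an
ERp57-tapasin conjugate) and TAPBPR. `pepxkit` implements the four
quantitative readouts used to characterize that catalysis, each driven either
by plain-text experiment exports or by a built-in synthetic-data generator
with known ground truth:

**FP exchange kinetics** (`pepxkit.fpkinetics`). A baseline-subtracted
association trace is fitted with

    Y(t) = Y0 − A·e^(−K·t)

where Y0 is the plateau, A the FP range and K the observed association rate
(K_on). Conditions are compared by the catalyst **fold change**
K_on(cat)/K_on(−) and, for tapasin scoop-loop mutants, the **relative
catalytic activity**

    (K_on,mut − K_on,−) / (K_on,WT − K_on,−)

with replicate SDs, error propagation, and Welch's unequal-variance t test.

**Methyl-CPMG relaxation dispersion** (`pepxkit.cpmg`). Peak intensities at
refocusing frequency ν_CPMG convert to effective relaxation rates
R2_eff(ν) = (1/T_CPMG)·ln(I0/I(ν)), with uncertainties pooled from duplicated
ν points. Methyls whose dispersion amplitude exceeds 2 s⁻¹ are flagged as
exchanging and fitted with the fast-exchange (Luz–Meiboom) two-state model

    R2_eff(ν) = R2,0 + (φ/k_ex)·[1 − (4ν/k_ex)·tanh(k_ex/4ν)],  φ = p_a·p_b·Δω²

against a flat no-exchange alternative, selected by AICc.

**HSQC intensity ratios** (`pepxkit.hsqcratio`). Paired peak lists give
per-residue I/I0 and weighted amide CSPs √(Δδ_H² + (Δδ_N/5)²); residues with
I/I0 below mean − δ (δ = SD of the ratios) are flagged as significantly
line-broadened, and the table can be written onto a PDB structure's B-factor
column (`pepxkit.structmap`) for viewer coloring on, e.g., a 0.30–0.70 ramp.

**Thermal shift** (`pepxkit.thermoshift`). Melt curves are truncated after
the fluorescence maximum and fitted with the Boltzmann sigmoid
F(T) = F_min + (F_max − F_min)/(1 + e^((Tm−T)/s)) to estimate Tm and ΔTm
between conditions.

The three curve fitters are scikit-learn-style estimators
(`AssociationKinetics`, `TwoStateDispersion`, `BoltzmannMelt`) with
`fit`/`predict`/`get_params` and fitted attributes (`k_on_`, `kex_`, `tm_`,
…), so they compose with sklearn model-selection tooling; module functions
wrap them for dataclass-level convenience.

## Worked example

Generate a synthetic A\*03:01 exchange experiment (uncatalyzed, ERp57-Tsn^WT
and the L18G scoop-loop mutant, 3 replicates each, 2 FP units of noise),
fit it, and aggregate:

```sh
pepxkit synth --out run --seed 7
pepxkit fitfp --data run/fp_data.csv --layout run/fp_layout.tsv --out run
pepxkit cpmg  --data run/cpmg.tsv --out run
pepxkit ratio --reference run/peaks_ref.tsv --perturbed run/peaks_per.tsv --out run
pepxkit tm    --data run/melt.csv --out run
pepxkit report --run-dir run --out run
```

`run/report.json` then reads:

```json
{
  "attenuated_residues": ["D147", "V142"],
  "dispersing_methyls": ["I23-CD1"],
  "fold_changes": {
    "A*03:01/L18G": 4.639206,
    "A*03:01/Tsn-WT": 11.078185
  },
  "relative_activities": {
    "A*03:01/L18G": 0.361097
  },
  "tm": {
    "photoIF9": 65.0168,
    "photoRL9": 71.0013
  }
}
```

Reading: wild-type tapasin accelerates peptide association on A\*03:01
~11-fold (ground truth 10.89), the L18G mutant retains 36% of wild-type
catalytic activity (truth 0.36), the synthetic dispersion profile with
exchange is flagged while the flat one is not, the two residues attenuated
in the perturbed peak list are recovered by the mean − δ rule, and the two
melt conditions differ by the built-in 6 °C stability gap.

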