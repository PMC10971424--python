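# Methods

## Assay model

The discharge assay loads an E2 enzyme with ubiquitin via E1/ATP and
offers a small nucleophile; transfer of ubiquitin off the E2~Ub thioester
onto the nucleophile produces a covalent ubiquitin adduct whose mass
shift identifies the acceptor. All four linkage chemistries considered
(isopeptide to an amine, oxyester to a hydroxyl, thioester to a thiol,
amide to an α-amine) are condensations releasing one water, so the
adduct's expected m/z is always

    m/z(adduct) = m/z(Ub, (M+H)+) + M(nucleophile) − 18.015 Da

and the bond kind is carried as metadata only. Because linear-mode
MALDI-TOF of an 8.6 kDa protein resolves neither isotopes nor charge
states, all arithmetic uses **average** atomic weights (IUPAC 2021
conventional values, embedded as constants; ¹⁵N exact mass 15.0001086)
and the singly protonated (M+H)⁺ convention (+1.00728 Da). The computed
panel agrees with the instrument software's printed list within 0.05%
relative error; a printed-value override mode exists because that list
contains small (≤2 Da) internal inconsistencies — notably the glucose
adduct, whose printed value exceeds plain condensation arithmetic by
about 2 Da without a stated adduct structure. The default ±5 Da match
tolerance absorbs these discrepancies either way.

Quantification assumes **equal molar area response** across ubiquitin
species: the discharge equation ratios the adduct area against a
¹⁵N-ubiquitin standard spiked at known concentration, which is only a
concentration estimate if a mole of adduct ionizes like a mole of
standard. The simulator makes the same assumption, so recovery tests
validate the pipeline, not the response assumption itself.

## Peak processing

- **Baseline**: rolling minimum followed by rolling mean over a window
  (default 50 Da) much wider than a peak (σ ≈ 4 Da) and much narrower
  than the baseline decay length. For a decaying exponential baseline the
  estimator's relative bias is (1 − e^(−2r))/(2r) with r = half-window /
  decay-length, so the default window keeps bias at the few-percent level
  for decay lengths ≳ 300 Da.
- **Noise**: 1.4826 × median absolute deviation of the baseline-subtracted
  residual, iteratively masking points beyond 3× the current estimate so
  peaks do not inflate it.
- **Detection**: strict local maxima of the baseline-subtracted trace
  with apex ≥ S/N threshold × noise (threshold 5, the assay's gate). A
  maximum is absorbed into a taller accepted peak when the valley between
  them stays above half the smaller apex: such a maximum is a shoulder —
  in practice a noise ripple on the flank of a strong peak — and keeping
  it would fragment the integration region. On resolved peaks the rule
  never fires, so detection coincides exactly with brute-force
  local-maximum enumeration there (asserted against an independent
  oracle). Centroids are intensity-weighted means over the contiguous
  region above half-apex; areas are trapezoidal integrals between the
  minima separating a peak from its accepted neighbours, truncated to
  ±4σ̂ (σ̂ from the half-max width).
- **Calibration**: one internal anchor (the ¹⁵N peak) determines only an
  offset, so the model is a single additive shift; calibration is
  idempotent and leaves zero residual at the anchor. Wells without a
  detectable standard peak within ±20 Da are flagged
  `calibration_failed`, never silently dropped. Mutant mode (no standard
  spiked) uses the identity model.
- **Matching**: control entries claim peaks by globally ascending |Δm/z|
  within tolerance, one peak per entry; exact ties go to the lower-m/z
  entry with a warning. Unmatched entries report zero area, which is what
  makes zero-discharge wells read as 0%.

No deconvolution is attempted for partially overlapping peaks (e.g. the
29 Da Ub-glycerol / ¹⁵N-Ub gap at large σ): integration regions are
truncated at the valley minimum. This is a declared limitation.

## Synthetic data

The simulator emulates what the processing contract needs and nothing
more: symmetric Gaussian peaks (linear-mode intact-protein peaks are
broad and near-symmetric), a single-exponential matrix baseline,
additive white Gaussian noise, and a per-well additive calibration
offset. Defaults: grid 8000–9200 Da at 0.5 Da, σ = 4 Da, [Ub] = [¹⁵N] =
2 µM, detector response 500 intensity units/µM (standard apex ≈ 1000 ×
noise), noise SD 1, offsets drawn uniformly in ±5 Da, 23 E2s × 5
nucleophiles × 2 technical replicates, per-cell true discharge drawn
from {0, 0.1, 0.25, 0.5, 0.75, 0.9}. It does **not** model isotope fine
structure, detector saturation, matrix adducts, chemical (non-white)
noise, asymmetric peak tails, or ionization suppression — so passing
recovery tests demonstrate correctness of the processing chain under the
stated peak model, not robustness to every artifact of real spectra.

Recovery at these conditions: every well of a simulated full plate lands
within ±3 percentage points of truth (the suite asserts ≥95%), and
zero-truth wells stay below 1% because an absent adduct peak cannot pass
the S/N 5 gate.

## Aggregation

Replicates are combined by the arithmetic mean (cells with fewer than
two valid replicates are counted and warned about); time courses report
the sample SD (n−1 denominator), absent for single replicates. Values
above 100% — possible whenever response or concentration assumptions
fail — are reported and flagged, never clamped. QC flags replace any
silent row filtering.

## Interface contacts

Contacts are classified purely by distance on a PDB model: hydrophobic
when any side-chain carbon pair of two apolar residues is within 4.5 Å;
ionic when a cationic group atom (Lys NZ, Arg NE/NH1/NH2, His ND1/NE2)
and an anionic oxygen (Asp/Glu carboxylate, or the C-terminal backbone
carboxylate O/OXT — included so a histidine facing a chain's Gly
C-terminus reads as ionic) are within the same cutoff; cation-π when a
cation center (Lys NZ; Arg approximated by CZ, the guanidinium centroid)
lies within 6.0 Å of an aromatic ring centroid. Cutoffs are inclusive
("within X Å" read as ≤). Trp's five- and six-membered rings are tested
and reported separately since the relevant ring is not specified by the
convention. The 4.5 Å heavy-atom cutoff is a common literature
convention, configurable; only the 6.0 Å cation-π cutoff is fixed by the
assay's interpretive convention. Alternate locations keep the
highest-occupancy conformer; HETATM records are ignored. No energy
scoring or model building is attempted.

## Numerical choices and degenerate inputs

- Noise-free traces give noise SD 0; S/N is then reported as infinity
  and every positive local maximum passes the gate.
- Grids coarser than the peak width log a warning (undersampled peaks).
- Empty spectra, non-ascending grids, windows wider than the spectrum,
  fractions summing above 1, unsupported elements, and unknown residue
  letters are rejected eagerly with the offending item named.
- All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); identical configuration reproduces
  byte-identical plate output.

## Problem sizes

The test suite and examples run full simulated plates (230 spectra of
2401 points) plus ~250 randomized property-check spectra; the whole
suite completes in a few seconds on one core, so no scaling-down of the
study conditions was needed.
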