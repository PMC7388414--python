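# Methods

This note documents the models, parameter choices and numerical
conventions behind `venomics`, and what the synthetic-data generator
does and does not emulate.

## Mass model

A peptide's neutral monoisotopic mass is the sum of standard residue
masses plus one water (18.010565 Da), minus two hydrogen atoms
(2 × 1.0078250319 Da) per formed disulfide bond, plus the deltas of any
applied modifications. Only the *count* of disulfide bonds matters for
mass; pairing topology is never modelled because only counts are
observable from intact masses.

The modification catalog is deliberately minimal: carbamidomethyl
(C, +57.021464, fixed — applies only to reduced/alkylated digest
aliquots, never to native mature masses, since the native aliquot is
analysed without alkylation), oxidation (M, +15.994915), deamidation
(N/Q, +0.984016), N-terminal acetylation (+42.010565) and C-terminal
amidation (−0.984016). Amidation is annotation-driven and never
inferred. Secreted amidated peptides arise from glycine-extended
precursors processed by peptidylglycine alpha-amidating monooxygenase,
so when an amidation annotation is applied to a sequence that still ends
in the Gly donor, the Gly is removed before the amide delta is applied
(net −58.005480 Da versus the Gly-extended chain). This convention is
what reconciles the printed mass of U2-TRTX-Ar1a (4876.02 Da) with its
printed 43-residue sequence to ~4 ppm; likewise the printed mass of
U1-TRTX-Ar1b is its sequence mass plus N-terminal acetylation (~12 ppm).
One printed value, VLPPLKF at 812.40 Da, differs from the
sequence-derived 812.52 Da by ~143 ppm under every reading we tried; it
is treated as an open discrepancy — both values are reported, and no
parameter is tuned to force agreement.

m/z conversions use the proton mass 1.00727646 Da:
`mz = (M + z·m_p)/z` and its inverse. ppm errors are computed relative
to the *theoretical* mass; at the 10-ppm working tolerance the choice of
reference changes results by well under 0.01 ppm.

## Digestion

Cleavage rules are data (side, target residues, blocking residues), so
unusual specificities can be configured without code changes. Defaults:
trypsin after K/R not before P; chymotrypsin after F/W/Y/L not before P;
Glu-C after E *and* D (the broadened phosphate-buffer specificity, since
the Glu-C aliquot is digested in phosphate buffer; an E-only mode
exists); Asp-N before D; thermolysin before I/L/V/A/M/F. Proline
blocking for thermolysin and extended chymotrypsin targets (M/H) are
deliberately not assumed; these are conventions, and the defaults are
flagged as assumptions rather than measured specificities.

Missed-cleavage expansion enumerates spans of up to `max_missed + 1`
consecutive fully specific segments. Semi-specific expansion truncates
exactly one terminus of a fully specific peptide; the implementation is
tested for set equality against a brute-force oracle that enumerates all
substrings and classifies their termini.

## Coverage and maturation

The mature N-terminus is called as the smallest start position where
peptides from at least two distinct digestion channels (the five enzymes
plus "native" as its own channel) begin. Two is the default because the
multi-enzyme design makes shared *biological* termini the parsimonious
explanation of cross-enzyme agreement, while any single enzyme's
N-termini are mostly proteolytic.

"Fully sequenced" requires a chain of covering fragments in which
consecutive fragments overlap by at least one residue. Abutting-only
joins are rejected: two fragments meeting edge-to-edge cannot exclude an
insertion at the junction. The minimum overlap of one residue is itself
an assumption; it is the weakest criterion that still ties the two
fragments to a shared residue.

## Validation

Native precursor ions below 5.0×10⁵ intensity are excluded; an ion at
exactly the threshold is kept (the exclusion rule is strictly-below).
Redundant ions — repeated observations of one species, including across
charge states — are merged by single-linkage clustering on decharged
neutral mass at the 10-ppm working tolerance, with intensities summed
and the cluster mass taken as the intensity-weighted mean.
Single-linkage is chosen precisely because it merges charge-state chains
transitively. Merging keeps all signal; a `drop_redundant` flag
reproduces the alternative convention of keeping only the most intense
member. Unknown-charge ions cannot be decharged and pass through as
flagged singletons that never match.

A candidate mature toxin is validated when (a) its theoretical mass
matches a cluster within 10 ppm through at least one charge state in
the +2..+9 ladder window, and (b) its consensus sequence is supported by
MS/MS-derived coverage. Singly charged ions may cluster but cannot
trigger validation, mirroring acquisition settings in which +1 and
unassigned charge states are not fragmented.

## Physicochemistry

Net charge uses the Henderson–Hasselbalch closed form with termini
included. The default pKa set is the EMBOSS scale (N-term 8.6, C-term
3.6, K 10.8, R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1); a
Lehninger-style scale is selectable. For disulfide-bonded toxins
`exclude_cys` removes Cys from both the charge and the composition
calculations, since bridged thiols neither titrate nor behave as free
side chains. Under these defaults the computed values reproduce the four
published physiological-pH net charges (+5.94, +6.0, −0.96, −0.95 at
their printed precisions) and the published isoelectric points of the
two most basic toxins (10.60 and 10.52).

The isoelectric point is the unique root of the strictly decreasing
charge curve, found by Brent's method on pH 0–14 and reported to two
decimals; when the charge does not change sign (no basic or no acidic
group under the model) the pI is explicitly undefined rather than a
number. Composition percentages are rounded half-up to one decimal.
The class alphabets (tiny/small/aliphatic/aromatic/hydrophobic/
hydrophilic/charged/cationic/anionic) partition so that hydrophobic +
hydrophilic equals the considered length and charged = cationic +
anionic + His.

## Quantification

Hi3 abundance is the mean of the three most intense peptides (all of
them when fewer than three). The per-protein mean across replicates uses
only replicates where the protein was detected — missing is not zero in
data-independent acquisition. Proteins failing the ≥3-peptide /
≥2-replicate filters are reported with flags and excluded from the
relative-abundance denominator. Shared-peptide disambiguation between
homologous proteoforms is out of scope; peptides are assumed
pre-assigned by the identification software.

## Screening

Decision rules only: AMP significance is a strict `score > 0.8` per
activity, and the ACP label requires consensus of the two anticancer
predictors with both scores strictly `> 0.5`. The predictors themselves
are external; their scores are inputs.

## Synthetic data

The generator emulates the features the pipeline relies on: precursor
architecture (hydrophobic signal ~16–23 aa, acidic propeptide ending in
an Arg processing motif, mature region), CRPs with an even Cys count
(6–10) constrained to the 3–9 kDa mass window typical of tarantula
CRPs, short peptides under 1.5 kDa, per-peptide Bernoulli dropout
(default 0.15) on five-enzyme digest evidence, and ion maps with ±3 ppm
m/z jitter, weighted charge states over +2..+9, log-normal intensities
(meanlog 15.4, sdlog 1.2 on the natural-log scale — median ≈4.9×10⁶,
with a low tail below the 5×10⁵ filter threshold so filtering is
exercised), and 200 decoy ions kept at least 50 ppm (5× the matching
tolerance) from every true mass so decoys are unambiguous negatives.
The mature-region residue distribution is venom-like (elevated K/R) but
qualitative, not fitted. Evidence defaults to fully specific digest
products; semi-specific emission is available via the config.

What it does **not** emulate: isotope envelopes, chimeric or co-eluting
features, retention-time structure, charge-state-dependent intensity,
correlated (non-independent) peptide dropout, PTM heterogeneity, and
shared peptides between homologous proteoforms. Passing the synthetic
end-to-end tests therefore demonstrates correctness of the arithmetic
and the decision logic under the stated noise model, not robustness to
every artefact of real instrument data.

All randomness flows from a single integer seed through NumPy's
integer-state PCG64 generator, so runs are reproducible across
platforms. The end-to-end recovery check uses 20 seeded replicates at
the default generator settings (10 CRPs + 7 short peptides, 3 ions per
toxin, 200 decoys) and requires sensitivity ≥ 0.95 with zero false
validations from decoy-only ion sets.

## Numerical conventions and degenerate inputs

Peptide coordinates are 1-based inclusive in all tables; internal
cleavage positions are inter-residue 0..L. Ties in Hi3 are resolved by
sorting intensities descending before truncation, which makes the top-3
mean deterministic under permutation. Empty sequences, out-of-bounds
evidence, negative intensities, unknown residues, and disulfide counts
exceeding Cys capacity are rejected with explicit errors rather than
coerced. Pipeline outputs embed a hash of the configuration, and reruns
with identical inputs are byte-identical.

## Known limitations

* Printed reference masses mix observed and theoretical values; the
  package reports both and does not force agreement (VLPPLKF remains
  discrepant at ~143 ppm).
* Enzyme specificities beyond the defaults (e.g. thermolysin proline
  blocking) are assumptions, configurable but not validated against
  digest data.
* The ion-cluster mass is an intensity-weighted mean, which slightly
  favours intense charge states; at 10 ppm this is inconsequential but
  documented.
* Quantification does not attempt cross-run normalisation or
  differential abundance; it mirrors a single processed experiment.
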