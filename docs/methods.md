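# Methods

## The classification problem

Plant asparaginyl endopeptidases (AEPs) split functionally into
protease-type enzymes (hydrolysis after Asn/Asp) and ligase-type enzymes
(transpeptidation, e.g. backbone cyclisation of cyclotides). The two types
are close homologues; the discriminating signal is carried by a small
number of positions — the MLA loop (His294–His301, OaAEP1_b numbering),
the Gatekeeper pocket residue (Cys247-homologous), the poly-proline loop —
rather than by overall similarity. `ligasespace` therefore classifies via
(a) an unsupervised embedding of residue *biophysical properties* with a
supervised read-out, and (b) an explicit rule screen of the MLA.

## Property encoding

Each alignment cell contributes five features: side-chain mass (average
atomic masses, Da; glycine = 1.008), net formal charge at pH 7
(D/E −1, K/R +1, H +0.1, others 0), Kyte–Doolittle hydropathy, TOP-IDP
disorder propensity, and occupancy (1 residue / 0 gap). The scales ship as
`data/residue_properties.tsv` and can be substituted wholesale.

Choices made where convention leaves room:

- **His charge +0.1.** AEPs mature in the mildly acidic vacuole, where the
  imidazole is partially protonated; `with_his_charge(0.0)` restores the
  strict formal-charge convention.
- **Normalisation scope.** "Within each property" is implemented as
  *pooled across all columns* of that property (min-max to [0, 1] by
  default; z-score available). Column-wise scaling would erase
  between-column contrasts, which are exactly what the PCA should see.
- **Order of operations.** Normalise first, then impute each missing cell
  with the arithmetic mean of its own column's normalised observed values
  (global property mean for an all-gap column). Imputation therefore
  preserves every column's observed mean. Occupancy is never imputed.
- **`X` residues** are present (occupancy 1) but uncharacterised: missing
  on the four physical properties, hence imputed like gaps.

## Sequence-space model

PCA is computed by SVD of the column-centered feature matrix, without
variance scaling (features are already normalised to comparable ranges).
No more than `n_sequences − 1` components are kept. Determinism: component
signs are fixed so each loading column's largest-magnitude entry is
positive; ties in column ranking break toward the lower column index. The
decomposition satisfies, to tight tolerances checked in the tests:
orthonormal loadings, non-increasing explained variance, exact
reconstruction, and total-variance conservation.

**Component selection.** Each leading component (default: first 10) is
tested for ligase-vs-protease separation with the exact two-sided Wilcoxon
rank-sum test on its coordinates — distribution-free and exact at the
small labelled-class sizes this problem has (6 vs 12 in the motivating
data set). Selection applies Holm step-down adjustment at α = 0.05 by
default. The uncorrected variant is available
(`correction="none"`), but the default controls the family-wise chance of
selecting any component of a signal-free alignment — the property the
package's own null-simulation check demands — at a negligible cost in
power: a completely separating component at 6 vs 12 has raw
p = 2/C(18,6) ≈ 1.08 × 10⁻⁴ and survives the adjustment at any tested
family size. Both raw and adjusted p-values are reported.

**Profile extraction.** Per column, the aggregate weight sums |loading|
over the selected components and the column's five features (sum-pooling;
the simplest scale-respecting choice). The top k = 16 columns form the
profile. The ideal residue at a position is the modal residue among
labelled ligases, with a gap counted as a bona-fide state (reported `-`);
modal ties break toward the residue whose normalised property vector is
nearest (Euclidean) the ligase column mean, then alphabetically.

**Match score and call.** score = (matching positions)/k, deletion matches
deletion, all other columns ignored; ligase iff score ≥ 0.25 (closed
bound). Metrics over the labelled set report accuracy, sensitivity, the
standard specificity TN/(TN+FP), *and* the verbatim "printed-formula"
specificity TN/(TP+FN) carried by the original analysis definition —
the latter is not a rate (it can exceed 1) and is never silently
corrected, only labelled.

## MLA screen

Segments are the ungapped residues between the alignment columns of the
reference MLA boundaries, inclusive of insertion columns, so insertions
lengthen and deletions shorten a segment (possibly to length 0).

- **Minimality**: deficit ≥ δ = 3 residues against the protease-type
  reference length (known ligase truncations are 4–5 aa; δ configurable).
  When no reference length is supplied, the longest protease-labelled
  segment (else the longest overall) anchors the test. An empty segment is
  the extreme truncation: minimal, GRAVY undefined.
- **GRAVY**: arithmetic mean Kyte–Doolittle hydropathy; cutoff 0.0 strict.
- **Sequons**: canonical N-X-S/T with X ≠ P, scanned 1-based within the
  segment and up to two residues past its end so boundary-spanning motifs
  are caught.
- **Unaligned screening**: Smith–Waterman (BLOSUM62, gap open 11 /
  extend 1) of a 40-residue reference window centered on the MLA; the
  residues aligned to the window's MLA positions form the segment. A score
  floor of 45 (≈ 15 identities for a 40-mer query, far above chance)
  separates confident mappings from "unmapped" — reported, not raised.

## Synthetic data

The generator emulates the structure the pipeline assumes: per-column
background residue profiles drawn from a Dirichlet (concentration 0.5 —
moderately conserved columns); 16 diagnostic columns carrying
property-contrasting residue pairs (charge/hydropathy opposites, so the
encoding, not raw identity, carries the signal) at fidelity 0.9; a
12-column MLA span where ligase rows are truncated by 5 columns
(p = 0.7) or hydrophobic, and protease rows are hydrophilic-extended with
a planted sequon at p = 0.5; background gap rate 0.02. Defaults are 10
ligase / 30 protease / 60 unknown rows over 120 columns. `mla_mode =
"neutral"` gives every row a class-independent hydrophilic loop, used when
an experiment must isolate the diagnostic columns (profile recovery) or
remove all class signal (type-I null, together with fidelity 0).

What it does **not** emulate: phylogenetic correlation between sequences
(rows are exchangeable draws), insertion columns, alignment error, or the
length/composition heterogeneity of real C13 domains. Passing recovery
tests therefore demonstrate correctness of the machinery under the stated
statistical model, not performance on real alignments, where relatedness
between the labelled sequences can inflate apparent separation.

## Problem sizes and runtime choices

Recovery and classification checks run 20 alignments of 40 × 120
(no unknowns, neutral MLA); the null check runs 100 such alignments with
fidelity 0; the MLA-screen characteristics use 10 alignments of 100 × 120.
These sizes give the binomial resolution the asserted bounds need (e.g.
≥ 95/100 null passes) while keeping the whole suite fast. The exhaustive
GRAVY oracle covers all 3,368,420 segments of length ≤ 5.

## Known limitations

- The MLA boundary and Gatekeeper positions are expressed in reference
  numbering and require the reference row to be present and un-truncated
  at those positions.
- Greedy identity-based redundancy removal depends on input order (labelled
  sequences first by design); it is a filter, not a clustering.
- `pairwise_identity` excludes pair-gap columns from the denominator;
  identities from other conventions (e.g. shortest-sequence denominators)
  will differ.
- The ideal-residue definition is the ligase modal state; with very few
  labelled ligases it is sensitive to any single mislabelled sequence.
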