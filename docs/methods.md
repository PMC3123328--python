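# Methods

This note records the models, rules and numerical choices behind each
module, the parameters that matter, what the synthetic data does and
does not emulate, and the places where the design was genuinely open.

## Curation model

Membership calls are made from the protein sequence alone, in a fixed
filter order; a rejected gene carries the first failing reason so each
decision is reproducible:

1. **HXXXD** (`scan_hxxxd`): positions *i* with residue *i* = H and
   *i*+4 = D. The motif is treated as absolutely required. Ambiguity
   codes (X) never satisfy the H or D positions — membership is
   conservative in the face of unknown residues.
2. **DFGWG-like** (`score_dfgwg_like`): the maximum, over all 5-mer
   windows, of positional matches to DFGWG; accept at
   `dfgwg_min_match` ≥ 3 of 5 (the motif is highly but not absolutely
   conserved). Genes on the exemption list skip this test; the list is
   explicit input rather than a similarity computation because the
   known DFGWG-free loci are identified by manual comparison with
   reference proteins, a judgment step we deliberately do not encode.
3. **Length**: proteins < `min_protein_length` (300 aa) are rejected as
   likely pseudogenes.
4. **Scaffold redundancy**: a surviving candidate on an unanchored
   region shorter than `short_scaffold_max` (20 kb) is dropped iff its
   global identity to some anchored survivor reaches
   `scaffold_identity_min` (default 0.95); the match is recorded.
   The source screen used "high similarity" nucleotide searches without
   a numeric cutoff, so the threshold is a package choice and
   configurable. Identity is defined as the maximum number of
   identically aligned residues in a global alignment with no mismatch
   or gap penalty (equivalently the longest common subsequence) divided
   by the longer sequence length. This definition is invariant to the
   choice among co-optimal alignment paths, which makes it exactly
   testable against an independent dynamic-programming oracle; for the
   redundancy decision (identical or near-identical copies vs unrelated
   proteins, which score ≈ 0.4 under this measure) it is
   interchangeable with conventional alignment identity.

Monotonicity (relaxing a threshold never shrinks the accepted set) and
idempotence (re-curating the accepted set is a no-op) are tested
properties.

## Duplication typing

**Whole-genome (salicoid) duplicates** are read from a synteny-derived
ortholog-pair table; the classifier flags pairs whose two members are
both in the curated family. No synteny inference is performed here —
the pair table is the interface, mirroring how such surveys consume a
published homeolog file.

**Local (tandem) arrays**: two family genes on one region are linked
iff every annotated model whose span lies *strictly between* their
spans has status `family_partial` or `transposon`; arrays are connected
components of this relation. Defining "intervening" by interval
position rather than model count makes the rule robust to nested or
overlapping annotations. Strand is stored but ignored — inverted array
members still count, and the one published inversion case is handled by
override rather than a strand rule. Override rules (`force_merge`,
`force_split`, `exclude_from_cluster`) are applied after rule-based
clustering, in order, each with a free-text justification that is
logged; clusters falling below two members dissolve. No general
multi-gene-unit duplication detector is attempted: the two-gene-unit
case is expressed as a documented merge.

**Counting**: a gene in both a salicoid pair and a local array has
category `both` and is counted once in "recent duplication" (the union)
and once in each per-type row; the published table's per-clade
arithmetic (e.g. 10 + 13 salicoid/local but 21 recent in the largest
clade) is consistent with this union reading, which we adopt.
Percentages are integer, rounded half away from zero.

## Retroelement flanks

Flanks are `[start−10000, start−1]` and `[end+1, end+10000]` on genome
coordinates, clipped to the region; "upstream" is the lower-coordinate
side with no strand correction, since the window extraction is defined
on the assembly, not the transcript. Hit classification
(retrotransposon vs other) is an input column: the homology search
against a protein database is out of scope and its output is consumed
as a labelled table. A flank is positive with ≥ `flank_min_hits` (2)
retro-class hits at E ≤ `flank_evalue_max` (1e-10); "multiple hits" is
quantified as ≥ 2 because the source rule gives no number, and the
knob is exposed. Classification is monotone: tightening either filter
never moves a gene from `none` toward `both`.

## Clade operations

Trees are used as rooted, exactly as written in the newick input;
re-rooting is the caller's concern. `assign_clades` gives every tip the
label of the smallest clade containing the tip together with all of
that label's anchor tips (an MRCA rule); on a binary tree ties are
impossible, on polytomies they break alphabetically. Inconsistent
anchor nestings raise with the conflict named.
`find_taxon_specific_clades` enumerates maximal single-taxon clades of
size ≥ `min_size`; polytomies are clade candidates as-is, and
`min_support` (no default — published practice rarely states a numeric
cutoff) is read from the label on the clade's root node. The result is
an antichain, invariant under tip reordering, and is tested against
brute-force enumeration of all clades.

## Motif conservation

Per column, information content is IC = log2(20) − H over gap-excluded
residue frequencies (0 for an all-gap column; no small-sample
correction, matching standard logo conventions). The window score is
the mean over the window's columns of 1 − (column match probability),
where match probability is the sum of squared residue frequencies —
the frequency form keeps scores invariant under duplicating every
sequence. Columns with > 50% gaps (or < 2 residues) are masked.
Z-scores standardize window scores over all windows; strongly conserved
windows sit in the negative tail. The automatic threshold is the
largest z at which the expected number of null windows at or below it
stays under one (Φ⁻¹(1/n)), clamped to [−2.5, −1.5], the range in
which published scans of this kind operate; an explicit override is
available. Reported motifs are merged runs of qualifying windows with
a majority-rule consensus, suppressed unless some column exceeds
`logo_report_bits` (1.5), with a 25-column context in multi-clade mode
and 10 in clade-specific mode.

The original scan of this kind weights sequence pairs by phylogenetic
distance with an unpublished score; this package substitutes the
tree-free mean pairwise identity and documents the substitution. The
contract tested is the reporting behaviour — planted conserved windows
(including a planted DFGWG) are recovered, and nothing below the bits
floor is reported — not byte-equality with any external tool.

## Expression statistics

Presence requires a mean raw intensity ≥ `presence_intensity` (50) in
at least one experimental group. Probe deduplication keeps, per gene,
the single-gene probe with the highest median intensity across all
retained samples (ties to the smallest probe id) — "highest signal
consistently across samples" operationalized as a median because it is
robust and deterministic; multi-gene probes are kept and flagged but
excluded from per-gene correlations. Heatmap transforms are log10
abundance and log2 treatment/control group-mean ratios; the
below-quantitation flag uses the presence threshold (50) since no
separate limit is published.

Correlations are Spearman's ρ (tie-corrected, via average ranks) on
log10 intensities over all retained arrays. Pair relations: `local` if
the genes share an array; `salicoid` if they are partners *or* one is
the salicoid partner of any member of the other's array (so a lone
survivor is compared against the whole array it duplicated from);
otherwise `other`. Groups are compared by tie-corrected Kruskal–Wallis
(χ², k−1 df; identical data in all groups returns H = 0, p = 1) and
Dunn's z on mean ranks with pooled tie-corrected variance. Dunn
p-values are unadjusted by default with a Bonferroni option, since the
source analysis does not state its adjustment; a compact letter display
is derived at α.

ΔCt: relative expression = E^(−Ct_target) divided by the geometric mean
of E^(−Ct_ref) over housekeeping genes, with missing references
dropped. Efficiency defaults to 2 (per-reaction efficiency estimation
is out of scope) and is a parameter; with a single shared efficiency
the geometric mean on linear quantities equals the arithmetic mean on
Ct, so the two published readings coincide — with per-gene efficiencies
the linear-quantity form is used.

## Synthetic data

`SimulationSpec` declares, per clade: gene count, salicoid pair count,
cross pairs (pairs whose second member sits inside an array — the
lone-survivor configuration that produces `both`-category genes),
array size lists, retro flank categories, and whether the clade is
DFGWG-free (its members then enter the exemption list). Decoy counts
cover each rejection class; decoy constructions *guarantee* the
intended outcome (backgrounds excluding H, or excluding D/F/G/W so the
best DFGWG-like window scores ≤ 1, truncation to 250 aa, exact copies
on short scaffolds) rather than relying on chance. Layout places array
members contiguously — interleaving a partial family model or a
transposon inside some arrays, and one inverted member — and separates
all other neighbours with an `other` model so the tandem rule has
positive and negative cases everywhere. The shipped `table1` fixture
is a versioned spec file, not hard-coded outputs: reproducing the
reference summary exercises the real classifiers end to end.

Expression: genes in a duplication component share a latent Gaussian
factor with loading chosen by the copula identity
ρ_s = (6/π)·asin(r/2), i.e. r = 2·sin(π·ρ_s/6), so the planted value is
the Spearman estimand itself (exactly 1 at ρ_s = 1); a global factor
plants `rho_other` among unrelated genes. Intensities are log-normal,
10^(2.7 + 0.5·z) — a ≈ 500-unit baseline with half-a-decade spread, so
nearly all probes pass the presence filter while a few cells dip under
the quantitation limit. Defaults: 9 experimental groups × 2 replicates
(the array-study shape), ρ_local = ρ_salicoid = 0.8, ρ_other = 0.
The generator does **not** emulate sequence evolution (no
substitution/indel process, no codon structure), array normalization
artefacts, probe cross-hybridization noise, or correlated group
effects; passing tests therefore demonstrate correctness of the
classifiers and statistics under the planted model, not robustness to
real-data pathologies.

## Simulation sizes and calibration checks

The statistical guarantees are checked by simulation at sizes chosen to
make the estimates stable while keeping the default suite fast: the
relation test is calibrated on 7 clades × 15 genes (arrays [2,3], two
salicoid pairs each) with 20 arrays per dataset — type-I error over
1000 null datasets measured at 0.051, power over 200 datasets with
ρ_dup = 0.8 vs ρ_other = 0 measured at 1.00; copula recovery is checked
at 500 samples (|ρ̂ − 0.8| < 0.05) and the null at 1000 samples
(mean |ρ̂| < 0.1); motif recovery uses 100 seeded 30 × 100 alignments
(≥ 95 recovered; measured 100), and null alignments report nothing in
≥ 95 of 100 seeds.

## Known limitations

- The scaffold-redundancy screen compares proteins, not nucleotides;
  an unanchored copy of an anchored gene diverged only in silent sites
  scores 1.0 either way, but a frame-shifted copy would not.
- `assign_clades` labels every tip, including outgroup-like tips far
  from any anchor; callers who want "unassigned" must prune first.
- The Kruskal–Wallis test treats within-clade pairwise correlations as
  exchangeable observations; correlations sharing a gene are not
  independent. The calibration simulation shows the test holds its
  level under the planted null, but strong shared structure in real
  data could inflate it.
- Override rules are authoritative and unvalidated by construction:
  the advisory identity computations that motivate them (e.g. a < 40%
  similarity neighbour) are not re-checked at apply time.
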