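# Methods

This note records the models, parameter choices and numerical conventions
behind each stage, what the synthetic generators do and do not emulate, and
the known limitations.

## Candidate identification

The identification stage replaces an external BLAST + profile-HMM pipeline
with a single embedded-reference local-alignment scanner. The original
double criterion (a significant sequence hit AND a significant domain hit,
both at E ≤ 10⁻¹⁰) collapses to one test because the two thresholds are
identical; what remains is the decision boundary, which the scanner
preserves.

* **Scoring.** Smith–Waterman under BLOSUM62 with affine gaps, gap open 11
  and extension 1 (a gap of length L costs 11 + (L−1)). The ambiguity
  letter X scores 0 against everything, so ambiguous residues neither help
  nor hurt.
* **Significance.** Karlin–Altschul *E = K·m·n·e^(−λS)* with the gapped
  BLOSUM62 constants λ = 0.267, K = 0.041 held fixed rather than estimated
  per query. This is approximate — real search engines re-estimate the
  parameters per composition — but it is deterministic and desk-scale, and
  the threshold regime (E ≤ 10⁻¹⁰ needs a raw score around 110+ at these
  problem sizes) is far from the boundary for both true domains (scores in
  the hundreds even at 50% identity) and shuffled negatives (scores around
  30–40). A 1000-shuffle simulation in the test suite confirms a zero
  false-positive rate at the cutoff.
* **Repeated domains.** Best-hit-then-mask: record the best significant
  hit over all references, remove its span, rescan the flanking segments.
  Later hits may not overlap masked spans at all (the simplest reproducible
  overlap rule). Hits shorter than 40 aligned columns are discarded to
  stop spurious micro-hits in leftover segments. Ties between equally
  scoring references resolve by registry order and are logged.
* **Partial sequences.** Proteins shorter than 100 aa are filtered before
  scanning (`min_protein_len`, exposed as a flag); the completeness
  criterion behind such filtering is not standardised, so the value is a
  package default, not an assertion about any particular study.

**References.** The Cu/Zn reference is the curated human SOD1 polypeptide
(cf. UniProt P00441); the Fe/Mn reference is a curated human SOD2
polypeptide split into its N- and C-terminal domain halves at mature
residue 90. These are configuration data providing a coordinate system;
the SOD2 entry is a curated approximation whose ligand positions are
validated internally against their expected residue letters at import
time, not a verbatim database copy.

## Physicochemical panel

All descriptors are computed from sequence alone, on the full predicted
polypeptide (no signal-peptide trimming), with average (not monoisotopic)
masses — the scale on which family tables conventionally print "MW (kDa)"
column values that are actually daltons; the output reports daltons.
Formulas: mass = Σ residue masses (ExPASy table) + one water (18.01524 Da);
pI solves net charge = 0 under the Bjellqvist pKa set by bisection
(tolerance well below 0.005 pH); instability is the Guruprasad dipeptide
sum (10/L)·Σ DIWV; aliphatic index and GRAVY are the standard mole-percent
and Kyte–Doolittle means. The DIWV, hydropathy and pKa tables are taken
from Biopython's data modules; the formulas around them are implemented
here and cross-checked against Biopython's `ProteinAnalysis` in the tests
(GRAVY/instability to 4 decimals, pI to 0.01; molecular masses differ from
Biopython by ~0.001 Da/residue because Biopython ships the IUPAC table
rather than the ExPASy one). X residues are excluded from every sum with a
logged warning; the reported length includes them.

## Conserved-ligand classification

Each Cu/Zn domain hit (its hit span) is globally aligned to the Cu/Zn
reference (BLOSUM62, gap open 10, extension 0.5); Fe/Mn-family proteins
are aligned once against the full Fe/Mn reference, whose ligand columns
span both domain halves. A ligand column is conserved only when the
aligned query residue is exactly the expected one — no conservative
substitutions, no gaps — because in this family any ligand loss is treated
as loss of the corresponding metal site. The bridging histidine shared by
the Cu and Zn sites is assigned to the Cu set, so a complete domain scores
4 Cu + 3 Zn = 7.

Group rules per domain: 4/3 → complete Cu/Zn enzyme; 4/<3 → Cu-only;
<4/3 → Zn-only; otherwise metal-free. Fe/Mn proteins are Mn-SOD only when
the full His-His-Asp-His linkage and His-Tyr-Gln active-centre set is
conserved. A multi-domain protein takes its best per-domain label
(complete > Cu-only > Zn-only > metal-free). Classification is a pure
function of the profile vectors.

Known limitation: threading a short motif consensus into the human
reference by semi-global alignment spans the N-terminal Cu pair, the
bridging His and the first Zn His (4 ligand columns). Reports that such a
motif covers six ligand regions in molluscan sequences imply a shorter
Zn-loop than the human reference carries; with a human coordinate system
the computed span is 4, and the package reports what it computes.

## Genome context

"Similarity" in the 70/70 duplication rule is implemented as column
identity over aligned columns (gaps excluded), with a switch for the
BLOSUM62-positive fraction; coverage is aligned columns over the length of
the longer protein, and both thresholds are strict (> 0.70). The tandem
rule combines its two clauses with AND: at most 5 intervening genes (dense
rank difference − 1) and the pair's genomic span within 100 kb (span, not
start-to-start, is the windowed quantity; configurable). Arrays are
connected components of qualifying pairs, so every member participates in
at least one qualifying pair. Collinear blocks use
longest-increasing-subsequence chains over (rank, rank) anchors, run in
both orientations, reported greedily longest-first without anchor reuse;
`min_block` defaults to 3 rather than the 5 common for whole-genome tools
because fixture genomes are small (flagged in output metadata). Block
scoring refinements (inter-anchor gap penalties, block E-values) are out
of scope.

## Motif and promoter scanning

PWMs are built from aligned instance sets: counts + flat pseudocount,
normalised, log₂ odds against the background (uniform unless supplied).
De-novo discovery is a published-tool concern and is deliberately out of
scope; scanning is the reusable computation. Matches are the best
non-overlapping windows scoring at least a configured fraction of the
model's maximum (greedy by score, ties leftmost); the motif-combination
string joins motif ids in positional order. Promoters are the configured
length (default 2000 bp) upstream of the gene feature's 5′ end — the gene
start stands in for the translation start when no CDS features are
provided, and the anchor used is recorded. Promoter scans run on both
strands independently, so a palindromic site counts once per strand — a
documented consequence of the per-strand overlap rule. Transcription-factor
family assignment is user-provided metadata only; no database lookup is
performed.

## Phylogeny

Distances are Poisson-corrected global-alignment identities,
d = −ln(max(identity, 10⁻⁴)); the floor caps distances where identity
degenerates. Neighbour joining (canonical, via scikit-bio) is exact on
additive matrices — a property test over 50 random 6–10-leaf trees checks
tip-to-tip distances to 10⁻⁶. Bootstrap resamples alignment columns
(multiple alignment via biotite's progressive aligner, or user-supplied),
rebuilds the NJ tree per replicate, and scores each internal edge of the
base tree by the percentage of replicates containing its bipartition;
taxa are sorted internally so supports are invariant to input order.
Clades are maximal subtrees whose subtending edge meets the support
threshold; remaining taxa are singletons. This distance stand-in is
deliberately lighter than maximum-likelihood inference: clade labels are
qualitative groupings, and only family-level splits (e.g. the Cu/Zn vs
Fe/Mn bipartition, which bootstraps at 100% on the synthetic families) are
treated as meaningful.

## Expression response

FPKM = counts·10⁹/(library size · gene length); TPM rescales
length-normalised rates so each sample column sums to 10⁶ (asserted on
every fixture). The ANOVA/Duncan stage runs on log₂(x+1) abundances by
default — the scale used for family heatmaps, and variance-stabilising —
with a flag for the raw scale. Duncan's multiple range test uses the
studentized-range quantile at the stepwise protection level
1−(1−α)^(p−1) for a span of p ranked means, with the harmonic mean of
group sizes under unequal replication; non-significant ranges shield their
sub-ranges (the classical protected procedure), and letters label maximal
homogeneous stretches. With two equal-size groups the procedure reduces
exactly to the pooled-variance t test, which the suite checks, and the
type-I error on a 2000-gene Gaussian null calibrates to α (observed ≈
0.05). Directions against the control are only called when the condition
and control letter sets are disjoint. Negative-binomial differential
models are out of scope; the ANOVA operates on normalised abundances, so
strongly induced genes shift other genes' TPM slightly downward
(compositionality) — fold-change outputs use a pseudo-count of 1 on the
abundance scale.

## Synthetic data: what it emulates, and what it does not

The generators emulate the *structure* of a family survey: five functional
groups defined by ligand knockouts (ligand → Ala, chemically inert and
alignment-stable) on shared templates; 1–4 concatenated domain copies;
tandem arrays as 2%-diverged near-copies of a 10%-diverged array founder
(inside the 70/70 rule by construction) with shuffled-sequence decoys;
partner chromosomes sharing an ordered gene subset; promoters with planted
consensus sites at recorded coordinates; negative-binomial counts
(variance μ + φμ², default φ = 0.04, log-normal library factors, 3
replicates per condition, 4-fold planted inductions). Background
substitutions follow BLOSUM62-conditional probabilities and never touch
ligand columns except where a knockout instructs it; distinct planted
arrays are separated by more than the tandem window because they share
template ancestry and would otherwise merge.

They do **not** emulate: sequence-length variation and real indel
processes (knockout proteins are template-length), genuinely unrelated
gene families (decoys are shuffles, conserving composition), intergenic
sequence structure, isoform complexity, or read-level noise. Passing the
recovery suites therefore demonstrates that the *rules* are implemented
correctly and are recoverable under realistic divergence and counting
noise — not that the pipeline's sensitivity on real, fragmented,
isoform-rich annotations matches its sensitivity here.

## Problem sizes and determinism

The test suite and the acceptance script run on fixture-scale problems
chosen as representative desk-scale sizes: 50-protein families, 100
random-negative scans, 1000 shuffle simulations, 2000-gene null matrices,
12-gene collinearity instances with exhaustive oracles, 100 bootstrap
replicates over 10 taxa. All randomness flows through explicit
`numpy.random.default_rng` seeds; pipeline TSV outputs are byte-identical
across reruns of the same (inputs, config, seed).
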