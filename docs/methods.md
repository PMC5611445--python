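# Methods

## Coordinates and data model

All positions are 0-based, half-open, anchored so the A of the ATG start
codon sits at 0; upstream positions are negative (−1 is the base
immediately 5′ of the A). An `UpstreamRegion` is one species' sequence
with an `anchor_offset` giving the start codon's index; the offset travels
in FASTA headers as `anchor=<int>`, and a header without it means the
record is pure upstream sequence ending at the start codon. Only
`{A,C,G,T,N}` are kept; other IUPAC ambiguity letters are mapped to N with
a logged warning, because genome-mined contigs contain them and every
downstream scorer treats N as a mismatch. Some distances in the
literature are quoted from the transcriptional start site rather than the
ATG; the per-species TSS–ATG offset is generally unknown, so everything
here anchors to the ATG and treats TSS-quoted distances as approximate
windows.

## Dot-plot homology screen

`compute_dotplot` scores every aligned window pair of `window` bp
(default 25) with +5/match, −4/mismatch and records a hit at the window
midpoint when the sum reaches `threshold` (default 45). These defaults
mean at least 17 of 25 bases must match (5m − 4(25−m) ≥ 45 ⇒ m ≥ 16.2),
i.e. ≥ 68% local identity. The published screen used a GUI dot-plot tool
whose "high sensitivity" scoring matrix is unpublished; the +5/−4 scheme
is the standard nucleotide (EDNAFULL-style) stand-in for which the same
window/threshold values are meaningful. Only the forward strand is
scanned: upstream regions are compared in genomic orientation.

"A discernible conserved region" is operationalized as the longest
diagonal segment after merging same-diagonal hits separated by ≤ 10 bp
(`max_gap`, configurable); segment length is the covered span from the
first window's start to the last window's end. An element is **present**
when that length exceeds `min_conserved_length` (default 100 bp). The
>100 bp rule is applied to the enhancer as well as the PRR (the original
description states it only for the PRR); both are configurable.
**no_coverage** requires both that no qualifying segment exists and that
the covered part of the element's expected window is under 50% of it —
mirroring the treatment of short contigs as inconclusive rather than
negative. The search window is the expected element window padded by
±2 kb; the enhancer search extends to −10 kb because in some
afroinsectiphilians the enhancer sits near −7.5 kb.

`annotate_element_by_homology` mirrors iterative assembly at decreasing
stringency: one local alignment (affine gaps, open −10 / extend −1), then
the best hit is accepted at the first threshold of the schedule
0.85, 0.80, …, 0.60 that its percent identity meets. Identity is
identical non-gap columns over columns with at least one residue. A hit
must span ≥ 50% of the reference to count at all — under +5/−4 scoring a
long local alignment of unrelated sequence has negative score, so random
queries produce only short, rejected hits. Global alignments and the
Figure-style identity tracks use Biopython's `PairwiseAligner`; among
co-optimal alignments the aligner's first enumerated one is returned,
which is deterministic (the specific tie-break order differs from a
hand-rolled DP but never changes the optimum score or identity by more
than the tie itself).

## CpG islands

The Gardiner-Garden & Frommer statistic for a window of length L is
O/E = N_CpG · L / (N_C · N_G), zero when either count is zero; N counts
as neither C nor G and breaks CpG pairs. A 100 bp window sliding by 1
marks every position it covers when O/E > 0.6 **and** GC > 0.5; maximal
marked runs ≥ 200 bp are reported, trimmed to the outermost qualifying
window edges (union semantics, no smoothing). The original tool applies
a version-dependent 10-window average before thresholding; union
semantics is the deterministic reading of the stated criteria, and the
window/shift/thresholds are all exposed if a smoothed variant is wanted.
The default scan span is [−600, +200) around the start codon — the
island sits over the proximal promoter and may extend into exon 1 — and
can be widened when exon-1 length is known. The GC-rich but CpG-poor
repeat (GGGGGCCCCC)ₙ is the canonical negative: GC = 1.0 but O/E = 0.36.

## Motif catalog and classification

The catalog (`data/motif_catalog.yaml`, editable) holds each motif's
IUPAC consensus, layout offset within its element, orientation, and
critical-core positions traceable to site-directed mutagenesis:

* CRE-2/3/4 — core `CGTCA` (on the element strand for CRE-4, whose
  `TGACGCGC` is the reverse-complement orientation of the CRE);
* BRE-1/2 — core `TTCC` (mutation to `GTAC` abolishes enhancer activity);
* URE1 — positions 4, 5, 7 of `TCACCCTTGACCA`, the bases altered in the
  two mutants that fail to bind PPARγ-RXRα;
* upTRE/dnTRE — the 3′ hexamers `AGGCAA` / `AGGTCA` whose mutation
  eliminates T3-receptor interaction;
* RARE-1/2/3 — the AT-richness rule: only G/C→A/T changes (or deletions)
  inside a half-site count as core hits;
* TATA — loss of the A/T-rich frame: ≥ 3 core mismatches, or any G/C (or
  gap) at positions 1–4 of `TATAAAA`. Under this rule the walrus variant
  `TAAATAA` is a variant while `TACA…` variants classify as disrupted —
  the biology is debatable (TBP binds some TACA boxes weakly) and the
  thresholds are exposed rather than hidden.

Motifs without mutagenesis data (PPRE-2, NBRE, GCCCCT×3, CCAAT, DR-*)
carry no core and can never be called disrupted; their state space is
{intact, variant, deleted, not_found}. Classification is total over
`{A,C,G,T,N,-}^L`: no residues → not_found; gaps over ≥ 50% of the span
(configurable) → deleted; any core hit → disrupted; any other mismatch →
variant; else intact. Overlapping catalog entries (URE1/RARE-1,
BRE-1/RARE-2, dnTRE/NBRE) are both emitted, flagged `overlapping`, with
their consensus strings agreeing on shared bases.

Scanning a species works from the located element: each motif is searched
inside its layout offset ± 12 bp (tolerating small indel drift), the
fewest-mismatch (then leftmost, then forward-strand) instance is taken as
observed, and classified. Motifs whose window falls outside coverage are
not_found. Direct-repeat motifs (DR-1/3/4, TRE half-sites `AGGTMA`
separated by four nucleotides) are found positionlessly by
`find_direct_repeat`, which reports two half-site matches at an exact
spacer with per-half mismatch counts — the murid URE1 is recovered as a
degenerate DR-1 on its reverse complement at ≤ 2 mismatches per half.

## Consensus and conservation

The majority consensus takes, per column, the most frequent symbol among
included species if its frequency exceeds 50%, else `N` (deliberately not
an IUPAC ambiguity code: it marks failure of the majority rule). Each
species votes once; gaps are first-class symbols by default because
gap-majority columns are meaningful in the indel-rich PRR; a skip-gaps
mode is provided since the original description does not say which
convention was used. Pseudogene species are excluded from consensus by
the callers, matching the published procedure. Multiple-sequence
alignment itself is out of scope: alignments come from outside or from
the simulator's exact homology map. The conservation summary reports
per-motif state fractions split by gene status, dropping not_found
species from denominators.

## Presence matrix and Dollo gain/loss mapping

Calls assemble into a species × element matrix over {present, absent,
no_coverage}; missing pairs read as no_coverage. The packaged 139-species
table ships with the package, transcribed from the published survey, with
taxon group and *UCP1* status (pseudogene lineages: xenarthrans,
paenungulates, equids, cetaceans, suids, pangolins) as metadata — gene
status is input, not inferred.

Dollo parsimony fits the biology of a complex enhancer: gained once,
realistically never regained. The gain branch is the branch above the
MRCA of all present tips; a present tip outside a user-supplied gain
clade is an error. Losses are the maximal branches below the gain whose
subtree contains an absent tip and no present tip; tips without coverage
are compatible with either state and never force (or split) a loss. This
greedy maximal-subtree rule provably yields the minimum number of losses,
and the implementation is checked against exhaustive search over loss
subsets on random trees. When a loss subtree also contains missing-data
tips, deeper placements can be co-minimal; the count of alternative
optima is reported.

One curated reclassification is applied for event mapping
(`curated_species_matrix`): the two-toed sloth's enhancer "absent" cell
is treated as missing data, because the underlying genome search found no
*UCP1*-containing contig at all for that assembly and the sister sloth
lineage retains partial enhancer coverage. With it, the enhancer history
on the packaged tree is one stem-eutherian gain and exactly five
independent losses (armadillo, hyrax, sperm whale, and one stem loss each
for the delphinids and the pangolins), and seven species lack both the
enhancer and an intact gene. Without it, the raw table yields six losses;
both views are computable. Note the transcribed table's eutherian
enhancer-present count is 123 and its PRR coverage denominator 123; the
survey's prose summarises these as 121 and 125 while agreeing exactly on
every other tally — the table is taken as authoritative.

## Synthetic data generator

The simulator emulates the statistical structure the screen assumes. The
root is a 10.2 kb region ([−10 000, +200) around the start codon) of
background composition GC = 0.40 carrying the four synthetic element
templates: enhancer 200 bp at [−4000, −3800), PRR 678 bp at
[−2773, −2095), a CpG-qualifying 400 bp block at [−250, +150) built to
exceed O/E 0.6 and GC 0.5 by construction, and a 300 bp promoter at
[−300, 0) with TATA at ≈ −275, GCCCCT sites, CRE-4 and CCAAT. Templates
are deterministic: catalogued motif consensus strings (IUPAC letters
concretized) at their layout offsets in seeded filler. They are synthetic
stand-ins — the real human/rat/mouse sequences live in GenBank — so
passing tests demonstrate correctness of the machinery on data with this
structure, not agreement with any real genome.

Evolution is a single-parameter symmetric substitution model: on a branch
of t expected substitutions/site a site differs from its parent with
probability (3/4)(1 − e^{−4t/3}), new base uniform over the other three.
No across-site rate heterogeneity; the one rate contrast that matters to
the study — pseudogene lineages decaying faster — is a per-branch
multiplier (default ×2) inherited by descendants. Indels arrive at
`indel_rate` (default 0.01) events per site per unit branch length, 50:50
insertion:deletion, geometric lengths with mean 3 bp, suppressed when a
deletion would overlap a motif critical core so motif-state truth stays
well defined (substitutions are never suppressed). Element deletion
events remove exactly the template's residues on a configured branch.
Every residue carries a persistent homology key, giving exact per-tip
element intervals, per-motif true states (classified on the truly
homologous residues), and the induced true alignment — one column per
surviving key, ordered consistently across lineages.

The default tree is eight tips in two balanced clades (branch lengths
0.05–0.08, root-to-tip ≈ 0.18), small enough that the full pipeline runs
in ~2–3 s per replicate; the benchmark uses 20 replicates with an
enhancer deletion on one cherry's stem, a PRR deletion on a tip, and one
pseudogene tip at ×2 rate (effective 0.10 subs/site, within the ≤ 0.15
regime the recovery claims are scoped to). What the generator does not
emulate: real assembly artifacts (chimeric contigs, sequencing error),
composition heterogeneity beyond the element templates, selection, and
TSS/ATG offset variation.

## Numerical and degenerate-input choices

Sequences shorter than one window give an empty dot plot or CpG scan with
a warning, not an error. Empty alignment requests, empty include sets,
conflicting duplicate presence calls, unknown branch ids and present tips
outside a declared gain clade raise. Dot-plot hits use int32 accumulation
(no overflow below ~4 × 10⁸ bp windows). The element definition for the
CpG island extends 150 bp past the start codon — an intentional exception
to the "elements lie 5′ of the ATG" convention, since the island runs
into exon 1. All thresholds named above are keyword parameters with the
stated defaults.

## Known limitations

Motif-state calls on real (non-simulated) data inherit the located
element anchor; a long indel just 5′ of a motif can shift its search
window by more than the ±12 bp slack and demote an intact motif to
variant/disrupted via a mis-anchored observation (the benchmark's ~2%
motif-state disagreement is mostly this). The dot-plot scoring matrix is
a stand-in for an unpublished one, so presence calls near the 100 bp
boundary may differ from the original screen's visual judgement. Dollo
mapping reports minimum-loss histories only; likelihood-based
ancestral-state reconstruction and branch-length-aware models are out of
scope, as are multiple alignment, BLAST-style mining and weight-matrix
(TRANSFAC) scanning, which the explicit motif catalog replaces.
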