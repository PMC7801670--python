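# Methods

This note documents the models, conventions and numerical choices behind
each analysis, what the synthetic generator does and does not emulate,
and the known limitations.

## Coordinates and topology

All coordinates are 1-based with both ends inclusive, the dialect of
baculovirus annotation tables (`1>747` = sense ORF from 1 to 747;
`796<1518` = antisense). Genomes are circular by default; a circular
genome's origin can be moved with `normalize_origin`, which also returns
the coordinate remapping, so any numbering convention (e.g. granulin
start codon = nucleotide 1, the convention of the bundled reference
table) can be established after annotation. An origin-wrapping feature is
stored with `start > end` and a `wraps_origin` flag. N bases are allowed
in input; they are excluded from G+C content (numerator and denominator)
and any codon containing N terminates ORF extension — conservative and
testable behavior for draft sequence.

## ORF model

`enumerate_orfs` implements common ORF-finder semantics: per (stop codon,
frame, strand), the ORF is the stretch from the *first* ATG after the
previous stop to that stop; nested shorter ATG variants of the same stop
are not emitted (a `require_atg=False` mode starts ORFs at the first
codon after the previous stop instead). "≥ 50 codons" means ≥ 50 encoded
amino acids with the terminal stop excluded, so the nucleotide span is
`3*(aa+1)` and `aa = (end-start+1)/3 - 1` for non-wrapping ORFs — the
arithmetic that reproduces the printed lengths in the reference table.
Circularity is handled by scanning the doubled sequence; each stop is
emitted from the occurrence with complete upstream context and
deduplicated by its position modulo the genome length, with ORF length
capped at the genome length. The enumerator is checked against an
independent brute-force oracle (walk every ATG on every strand to its
first stop) on random circular and linear genomes.

Curation (`curate_overlaps`) is greedy: rank by homology evidence
(descending), then amino-acid length, then lower start, then sense
strand; walk down the ranking and discard any ORF completely contained
in a retained one or overlapping a retained one by more than
`max_overlap_frac` (default 0.5) of the shorter ORF's length. The
published curation of this genome family used database homology to decide
which overlapping ORFs are real; that evidence can be injected via
per-ORF scores without bundling a database. Ties break deterministically
so runs are reproducible. A fully database-free run therefore retains
the *longest* member of each overlap clique, which reproduces planted
truth on synthetic genomes but is not guaranteed to reproduce a
published, homology-informed 183-ORF list.

## Promoter classification

Scanned on the coding strand only, in the `window` (default 180) bases 5'
of the start codon, wrapping the origin on circles and truncating on
linear molecules. Early = literal TATA with a CAGT or CATT initiator
whose gap — counted as bases strictly *between* the motifs — lies in
[20, 40]; because the anchor convention is not universal, a
start-to-start anchor is available (`gap_anchor="start"`). Late = any of
ATAAG/TTAAG/GTAAG, overlapping occurrences included. Class is E, L, E/L
or none by which hit lists are non-empty. No masking of neighboring ORFs
is applied, and E/L scans are independent. Classification provably
depends only on the window, which the tests exercise.

## hr detection

The only fully specified signature of a granulovirus hr is the 10-bp
core TTAAT(G/A)TCGA, treated as two consensus 10-mers. `find_cores`
reports every position (both strands, circular wrap) within Hamming
distance `max_mismatch` (default 1: cores are highly conserved, repeats
imperfect; configurable 0–2, ≥ 5 rejected as degenerate). `cluster_hrs`
single-linkage clusters hit positions with linkage ≤ `max_gap` (default
400 bp, accommodating 2–5 repeats of ~120 bp with drift; first/last
clusters merge across the origin), sets region bounds to
[min core − flank, max core + 9 + flank] (flank default 60 bp ≈ the
~35-bp core offset within a repeat unit plus margin), labels majors
hr1..hrN in genome order and suffixes short (single-core) regions to the
preceding major (hr5a style). An optional AT-richness filter
(`min_at_fraction`) reflects that hrs are AT-rich, off by default. This
is deliberately a core-anchored detector, not a tandem-repeat finder:
region *bounds* are parameter-dependent and approximate; region count,
location and per-repeat core orientation are the reliable outputs.

## Comparative analyses

Percent identity: global alignment (end gaps penalized) under BLOSUM62
with gap open 10 / extend 1 — a fixed published matrix standing in for
the ClustalW dialect used historically, whose exact parameters the
original analyses did not pin; identity = identical aligned pairs over
the full alignment length including gap columns (a "shorter sequence"
denominator is available), reported as a rounded percentage. Arguments
are canonically ordered internally so the function is exactly symmetric
even under co-optimal alignments. Homolog tables keep each query's best
hit by score (ties to the lower ordinal) when identity ≥ `min_identity`
(default 20%), plus secondary hits scoring ≥ 0.9× the best — reproducing
the occasional double entries of published tables as a reporting choice.
Shared-count and mean-identity summaries use best hits only, the mean
rounded to integer percent. Duplicate genes are intra-proteome pairs at
≥ `min_identity` (default 95%). Gene parity uses post-curation ordinal
ranks (gene order, not genomic position); clusters are maximal runs where
i steps by +1 and j by a constant ±1, reported at `min_len ≥ 3` by
default (with `min_len=1` the runs partition the points). Because the
bundled reference table already fixes the published homolog assignments,
cross-genome summaries of that genome are computed from the table rather
than by re-aligning against proteomes this package does not ship.

## Proteome mapping

Input is the peptide-sequence level — the first point where
occlusion-body proteomics is reproducible without instruments and
search-engine scoring. A peptide matches a protein iff it is a substring
under I/L equivalence (isobaric residues; switchable). Matching is
monotone in observations; shared peptides count toward every matching
protein and are flagged, since no parsimony rule is assumed. Confidence
is the conventional ≥ 2 distinct peptides. `tryptic_digest` (cleave
after K/R except before P, ≤ `missed_cleavages` internal sites, length
≥ 6) supports generating realistic observations.

## Synthetic generator

`synthetic_data.generate(config, seed)` is fully deterministic from one
NumPy generator stream. Defaults emulate the study conditions of an
annotated granulovirus genome: background G+C 0.40 (generated genomes
verify within ±0.02 at ≥ 20 kb), 20 ORFs of 50–1300 codons on both
strands with promoter classes in proportions like an annotated genome
(L 41%, E 22%, E/L 18%, none the rest), 8 major hrs of 2–5 repeats of
120-bp imperfect units (8% unit noise) with the core at offset 35 and
≤ 1 mismatch per core, 1 short hr, 1 opposite-strand duplicate gene
pair, and peptide observations from up to 24 unique-protein sources
(4 with a single peptide, the rest with several) across 29 samples.
Features are laid out sequentially with random gaps (gaps around hrs kept
above the clustering linkage distance so planted hrs never merge);
coding sequences are sampled codon-wise from the background composition
with rejection of stops and core-like 10-mers (with backtracking where a
sampled suffix would force a rejection); promoter windows are built by
plant-then-scrub until a re-scan yields exactly the planted class; and a
global scrub removes accidental core-like hits outside planted cores.

With `no_decoys=True` the genome additionally contains no spurious start
codon: ATG/CAT trigrams are excluded outside planted starts, the early
initiator is restricted to CAGT (CATT contains CAT), the core is
restricted to the ATG-free TTAATATCGA variant, and an iterative pass
destroys any remaining decoy ORF start at a junction. This mode gives
sharp exact-recovery tests; the default mode keeps background decoys so
curation is exercised realistically.

What the generator does *not* emulate: real codon usage and amino-acid
composition (proteins are background-composition random, so alignment
identities between non-duplicate genes are uninformative), gene density
of real viral genomes (features never overlap, while real baculovirus
ORFs overlap promiscuously before curation), hr unit structure beyond
the core (no palindromes, no unit-boundary model), and peptide-level
noise (no missed identifications, no spectral false positives). Passing
synthetic tests therefore demonstrates algorithmic correctness on the
stated feature models, not end-to-end fidelity on biological data.

## Problem sizes and verification

The test suite validates each analysis against independent oracles
(brute-force ORF walks, sliding-window motif scans, exhaustive Hamming
scans, brute-force run finding) on randomized inputs of a few kb, and
against planted truth on synthetic genomes of ~10–60 kb; these sizes
exercise every code path, including origin wrap, within seconds.
`scripts/acceptance.py` recomputes the bundled-table summaries and the
synthetic end-to-end recoveries with a user-supplied seed. Checks that
need the real 176,677-bp sequence (genome length, G+C = 39.79%, the
372-ORF enumeration, the nine genomic hrs, ORF39/49 at 100% identity)
run only when a local copy of the NC_013772 FASTA is placed at
`data/NC_013772.fasta`; the sequence is too large to bundle as text.

## Known limitations

* The 183-ORF curated set of the reference genome is homology-informed;
  without that external evidence the curator reproduces only the
  enumeration (372 ORFs at ≥ 50 codons) and a longest-wins curation.
* hr boundaries are parameter-dependent; only count, location overlap
  and orientation are contractual.
* The reference table transcription carries its source's typesetting
  quirks; they are recorded in its `notes` column and the table's
  checksums are pinned, with one mean identity (CpGV) rounding to 43
  where the source prose says 44.
* Promoter tallies printed in prose for the reference genome are
  internally inconsistent with its own table; the per-ORF table column
  is taken as authoritative and no summary statistic is derived from the
  prose tallies.
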