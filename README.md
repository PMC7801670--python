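# gvannot

Annotation and comparative-genomics toolkit for circular granulovirus
(betabaculovirus) genomes, built around the analyses used to characterize
the *Mythimna unipuncta* granulovirus Hawaiian strain (MyunGV-A,
GenBank NC_013772): a 176,677-bp AT-rich circular dsDNA genome with 183
annotated ORFs, nine homologous regions and a characterized
occlusion-body proteome.

## Who it is for

Viral genomicists annotating a newly sequenced baculovirus and wanting
the field's standard desk analyses as tested, scriptable functions rather
than one-off web-tool runs:

* **ORF enumeration on a circular chromosome** — for each stop codon in
  each of the six reading frames, the ORF runs from the first ATG after
  the previous stop; ORFs encoding ≥ 50 amino acids are reported, frames
  continue across the origin, and origin-wrapping ORFs are reported once.
  Greedy curation discards ORFs contained in, or overlapping more than a
  configurable fraction of, better-supported ORFs, and the set is
  renumbered with the granulin gene's start codon as nucleotide 1.
* **Promoter motif classification** — the 180 bp upstream of each start
  codon is classed *early* (TATA with a CAGT/CATT initiator 20–40 nt
  downstream), *late* ((A/T/G)TAAG), *both*, or *none*.
* **Homologous-region (hr) detection** — hits to the conserved 10-bp core
  TTAAT(G/A)TCGA (within a Hamming-distance budget, both strands) are
  single-linkage clustered; clusters of ≥ 2 cores are major hrs built of
  ~120-bp imperfect direct repeats, isolated cores are short hrs (the
  *hr5a* convention), and per-repeat core orientation is summarized.
* **Cross-genome comparison** — global-alignment percent identity
  (BLOSUM62, affine gaps, identities over full alignment length),
  best-hit homolog tables with secondary hits, shared-ORF counts and mean
  identities, duplicate-gene detection by self-comparison, and gene
  parity plots: maximal collinear / reverse-collinear runs of homolog
  gene-order points.
* **Occlusion-body proteome mapping** — peptide identifications per
  gel-slice sample are matched to the putative proteome as substrings
  under I/L equivalence; proteins with ≥ 2 distinct peptides are
  confident detections.
* **Synthetic genomes with planted truth** — a deterministic generator
  that emulates the statistics above (G+C ≈ 0.40, ORFs of 50–1300 codons,
  planted promoter classes, 8 major + 1 short hr, opposite-strand
  duplicate genes, peptide observations over 29 samples), so every
  analysis is testable offline against known truth.

The package also bundles a machine-readable transcription of the
published MyunGV-A annotation table (183 ORF rows, 9 hr rows, homolog
identities against AcMNPV, XcGV, HearGV, TnGV, MyunGV-B and CpGV) under
`gvannot.fixtures`, with transcription notes and pinned checksums.

## Worked example

Simulate a genome with fully known truth, then annotate it:

```
$ gvannot simulate --seed 11 --n-orfs 12 --n-major-hrs 8 --n-short-hrs 1 \
    --no-decoys --out-prefix demo2
genome of 43717 bp with 12 ORFs and 9 hrs -> demo2.fasta, demo2_truth.tsv

$ gvannot annotate demo2.fasta --out-prefix demo2_ann
12 ORFs -> demo2_ann.tsv, demo2_ann.gff3

$ gvannot hrscan demo2.fasta --out demo2_hrs.tsv
32 core hits, 9 hr regions -> demo2_hrs.tsv
  hr1: mixed
  hr2: all_reverse
  ...
```

With `--no-decoys` the background is constructed free of spurious start
codons, so enumeration plus curation recovers exactly the 12 planted
ORFs; `hrscan` recovers the planted 8-major + 1-short hr architecture
(the short hr is labelled with a letter suffix on the preceding major hr)
and reports, per hr, whether its repeat cores point the same way or in
opposite directions. The annotation TSV uses the standard table dialect —
`2325<4808` is an antisense ORF of (4808−2325+1)/3 − 1 = 827 amino acids:

```
orf   name  position    aa_length  promoter
1     orf1  2325<4808   827        unset
```

Checking the bundled reference table:

```
$ gvannot fixture-check
183 ORF rows, 9 hr rows
orientation tally: 99 sense / 84 antisense
  acmnpv: 88 shared ORFs, mean identity 34%
  ...
  tngv: 169 shared ORFs, mean identity 98%
```

99 sense / 84 antisense is the orientation split of the 183 MyunGV-A
ORFs relative to the granulin-sense strand; the per-genome lines give how
many MyunGV-A ORFs have a homolog in each reference genome and the
rounded mean of the best-hit amino-acid identities — TnGV is the closest
relative at 98%.

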