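# asmgaps

Gap, break and multicoverage analysis of phased (haplotype-resolved) genome
assemblies aligned to a complete reference.

Modern diploid assemblies still carry a few hundred gaps per haplotype, and
those gaps are not random: they cluster at segmental duplications (SDs),
centromeric satellite DNA and low-complexity GA/TC and AT dinucleotide
tracts. `asmgaps` takes contig-to-reference alignments (minimap2-style PAF)
plus annotation tracks (BED) and quantifies where and why an assembly
breaks. It is aimed at people producing or evaluating human (or other
well-referenced) phased assemblies.

## What it computes

Starting from filtered alignments (mapq ≥ 10, alignment width ≥ 1 kbp,
contig size ≥ 100 kbp):

* **Contig-end alignments and assembly gaps** — terminal alignments ≥ 50 kbp
  delimit each contig against the reference; when a contig's reference span
  exceeds its length by > 5% it is split into pieces at the largest
  reference jumps, each with its own ends. Reference intervals between
  subsequent pieces of one haploid assembly are the *assembly gaps*.
* **Simple contig ends and feature enrichment** — the first/last alignment
  of each contig with ≥ 25 kbp aligned gives a point position per contig
  side. Each end gets exactly one annotation label by priority
  (chromosome end ≻ SD+GA/TC ≻ SD ≻ satellite ≻ GA/TC ≻ AT ≻ Poisson end ≻
  other; "within" means ≤ 10 kbp). Enrichment of ends near a track is
  tested against uniform random placement: fold = observed / median of the
  permuted counts, empirical *p* = (1 + #{random ≥ observed}) / (1 + N).
* **Alignment discontinuities** — a gap between query-adjacent alignments
  of one contig with target gap *g_t* < 1 Mbp and query gap *g_q*
  (unaligned bases) is a *contraction* if *g_t* > *g_q*, an *expansion* if
  *g_t* < *g_q*, with event size |*g_t* − *g_q*|; events within ±1 Mbp of
  centromeric satellites are flagged CENSAT; same-class events ≥ 100 bp in
  ≥ 5 assemblies form recurrent SV regions.
* **Multicoverage and CNV** — sweep-line detection of reference intervals
  covered by ≥ 2 contig alignments of one haplotype, embedded-contig
  detection, windowed read depth → diploid copy number
  (CN = 2·depth/mean control depth), and the four-way CNV call against the
  reference's k-mer copy number (noCN / CNV / more10CN / none), plus a
  loss-of-heterozygosity screen over contig overlaps.
* **Low-complexity tracts** — TA/TC/GA dinucleotide counts in 100-bp bins,
  Z ≥ 1.96 marks enriched bins, tract size = enriched-bin run × 100 bp;
  1-kbp windows with ≥ 80% GA/TC (or AT) dinucleotide content are flagged
  and merged.
* **Validation** — assembly gaps spanned by ≥ 10 long reads (mapq ≥ 10,
  full containment) are considered closable; phased assemblies are cut into
  1-Mbp blocks and assigned to truth haplotypes by majority vote to measure
  phasing concordance and locate large-scale switch errors.

A seeded synthetic-data module builds an annotated reference and a diploid
assembly with planted, ground-truthed gaps, inversions,
expansions/contractions, embedded contigs and copy-number gains — every
stage is testable with no download.

All intervals are 0-based half-open; every output embeds a
`## thresholds:` header with the complete parameterization.

## Worked example

```bash
asmgaps simulate --seed 3 --out demo
asmgaps all --paf demo/truth_h1.paf --paf demo/truth_h2.paf \
    --hap h1 --hap h2 --sample HG_demo \
    --fasta demo/reference.fa --sd demo/sd.bed --sat demo/sat.bed \
    --gatc demo/gatc.bed --at demo/at.bed --out run
```

`run/gaps.bed` lists the assembly gaps — for this seed, the 12 planted ones
at their exact coordinates, e.g.

```
chrom   start   end     left_piece      right_piece     sample  hap
chr1    297082  326819  h1_chr1_ctg1.1  h1_chr1_ctg2.1  HG_demo h1
chr1    744757  836137  h1_chr1_ctg2.1  h1_chr1_ctg3.1  HG_demo h1
```

(contig `h1_chr1_ctg1`, piece 1 ends at chr1:297,082 and the next contig
starts at 326,819: a 29.7-kbp gap). `run/discontinuities.tsv` classifies
intra-contig breaks:

```
sample  haplotype contig       chrom start   end     target_gap query_gap klass       event_size
HG_demo h1        h1_chr1_ctg3 chr1  1518920 1553733 34813      0         contraction 34813
HG_demo h1        h1_chr1_ctg3 chr1  3072707 3072707 0          29780     expansion   29780
```

— the first row is 34,813 reference bases absent from the contig, the
second is 29,780 contig bases with no reference counterpart.
`run/multicov.bed` shows the duplicated contigs (`embedded True` means one
contig's whole aligned span lies inside another's), and
`run/end_categories.tsv` gives the nonredundant end-label accounting whose
counts sum to the number of simple contig ends.

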