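# longsv

Structural-variant (SV) discovery and breakpoint analysis for noisy
long-read (nanopore-class) whole-genome sequencing, for researchers
studying germline SV polymorphism and somatic rearrangement in cancer.

Long reads span whole repeat elements and SV breakpoints, but carry
10–15% sequencing error. `longsv` implements an analysis chain built
around that trade-off:

* **Germline calling** — per-read SV *signatures* are extracted from
  gapped CIGARs (insertions/deletions ≥ 100 bp), split alignments
  (inversions, duplication-type junctions, translocations) and long soft
  clips. Signatures cluster by single linkage within 50 bp (indels) or
  100 bp (others); clusters with ≥ 2 reads at mapping quality ≥ 20 become
  candidates, merged across windows of 300 bp (insertions) / 1000 bp
  (others) when their intervals overlap reciprocally ≥ 80%. Support
  thresholds depend on size — deletions of 100–500 bp need ≥ 4 reads,
  501–1000 bp ≥ 3, larger ≥ 2; insertions ≤ 1000 bp need ≥ 3
  insertion-bearing reads, larger ones ≥ 2 (or ≥ 2 long-clipped reads on
  each side) — followed by artifact filters: support within the terminal
  10% of a read, deletions with a nearby insertion ≥ 10%/30% of their
  length, regions with ≥ 30% of reads below mapping quality 30, variant
  allele frequency < 0.03, ≥ 80% short-repeat cover, and segmental
  duplications. Per-sample calls merge into a population set with allele
  frequencies (carrier counts 1 or 2 by VAF).
* **Somatic calling** — tumor candidates minus matched-normal read
  evidence, a pooled normal panel, and loci where the normal has depth
  < 9; inter-chromosomal breakends merge within 500 bp. Virus
  integrations are found from chimeric reads: unmapped read fragments are
  mapped to a panel of viral genomes, the genome capturing the most reads
  is the per-sample reference, and clustered human/virus junctions with
  ≥ 2 reads become integration sites.
* **Consensus building** — for each SV, support-read segments spanning
  the event ± 500 bp are star-aligned and voted column-wise (majority
  ≥ 50%); the consensus is accepted only if it remaps to the call locus
  (within 100 bp for insertions, overlapping the call for deletions).
* **Repeat classification** — consensus insertions are classified from
  RepeatMasker `.out` / Tandem Repeat Finder `.dat` annotation:
  `single_SINE` / `single_LINE` (one element covers ≥ 80%),
  `multi_repeat`, `repeat_included`, `non_repeat`, or excluded when ≥ 50%
  short repeat; plus 5′ truncation, twin-priming (two inverted LINE
  segments), poly(A) tails, tandem duplications, templated insertions and
  processed pseudogenes.
* **Breakpoint mechanics** — junction homology and untemplated insertion
  are measured by aligning both reference flanks to the consensus;
  mechanisms follow homology/insertion bands (NAHR > 100 bp homology,
  alt-EJ 2–100 bp, FoSTeS/MMBIR ≥ 10 bp insertion, NHEJ otherwise).
  Ancestral events come from the outgroup/reference anchor-distance ratio
  r = (d_outgroup − 200)/(d_reference − 200): r ∈ [−0.3, 0.3] means the
  outgroup lacks the sequence, r ∈ [0.7, 1.3] that it carries it.
* **Benchmarking** — greedy one-to-one matching of calls to a truth set
  (same type, breakpoints < 500 bp), with precision, recall, F = 2PR/(P+R)
  and repeat-context strata.
* **Simulator** — fully self-contained fixtures: repeat-bearing
  references, donor genomes with spiked SVs of every class (including
  junction homology/insertions, twin-primed LINEs, viral integrations),
  noisy reads with exact truth SAM alignments, RepeatMasker/TRF-format
  annotation, truth VCFs and outgroup anchor tables.

## Worked example

The library is the primary interface; `examples/` holds one short script
per capability. The end-to-end germline example:

```bash
python examples/01_germline_calling.py
```

prints (abridged):

```
18 passing SV calls from 870 reads:
  INS       chr1:15749-15749  len=290  support=4  VAF=0.33
  DEL       chr1:23638-25792  len=2154  support=2  VAF=0.15
  TRA_INTRA chr1:42609-44486  len=1877  support=12  VAF=0.57
  ...
  INV       chr1:284131-286839  len=2708  support=16  VAF=0.70

vs truth (18 spiked SVs): recall=1.000 precision=1.000 F=1.000
```

Every spiked SV in the 300 kb / 15x simulation is recovered at its exact
breakpoints, and no spurious call is emitted; support is the number of
distinct reads carrying the SV signature after artifact filtering, and
VAF the support divided by the spanning depth.

A thin CLI wraps the same stages for shell use:

```bash
longsv simulate --outdir sim --seed 3 --length 300000 --coverage 12
longsv germline --bam sim/S1.sam --ref sim/ref.fa \
    --repeats sim/ref.rm.out --trf sim/ref.trf.dat --out calls.vcf
longsv evaluate --calls calls.vcf --truth sim/truth.vcf
```

Other subcommands: `somatic`, `consensus`, `annotate`, `mechanics`.

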