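# walkseq

Detection and characterization of (unauthorized) genetically modified
organisms from **DNA-walking amplicon libraries sequenced on long-read
nanopore platforms** — without a reference assembly of the GM event.

Enforcement and food-safety laboratories screen for GMOs with qPCR
assays targeting common transgenic elements (the CaMV 35S promoter
p35S, the nopaline-synthase terminator tNOS, the vector-derived t35S).
A positive screen says *something* transgenic is present, but proving
*which* event — authorized or not — requires the transgene flanking
regions: the junctions between the inserted cassette and the host
genome, whose sequence uniquely identifies the insertion event.
DNA walking amplifies outward from the known anchor elements into the
unknown flanking DNA, producing amplicons of roughly 200 bp – 4 kbp
that long-read sequencing covers end-to-end.  `walkseq` turns the
resulting noisy read set into delineated insertion sites, 100-bp
junction sequences and an authorization verdict.

## The pipeline

For reads with per-base error around 13%:

1. **Trim** sequencer adapters (internal hits split reads) and the
   57-bp walking-tag adapter (edit distance ≤ 0.30 × matched length,
   min match 5 bp, both orientations, iterated); keep reads ≥ 100 bp.
2. **Correct** errors by overlap pileup (overlaps ≥ 700 bp on both
   reads; majority vote per column, indels included; reads < 700 bp
   dropped), trim low-support ends — error falls to the low percents.
3. **Cluster** in two greedy rounds: global 95% identity at 99% length
   similarity, keeping clusters of ≥ 6 reads (this is what removes
   PCR/sequencing chimeras), then merge by local containment at 95%.
4. **Annotate** cluster representatives against local FASTA databases
   (plant/host genomes; vectors and constructs; transgenic elements)
   with a seed-and-extend search using exact 64-base words:
   class 1 = near-full-length plant hit (background), class 2A =
   partial plant hit explained by a transgenic element, class 2B =
   partial plant hit with vector evidence (junction candidate),
   class 3 = no plant hit (insert-internal).
5. **Characterize**: group junction-candidate breakpoints per contig,
   border side and locus; concordant groups (≥ 70% of breakpoints
   within ±5 bp, < 3 fusion partners) become delineated insertion
   sites, scattered-clip patterns are flagged as chimeric suspects;
   excise the 100-bp junction window and call its consensus
   (min coverage 2); reassemble flanks; tile insert fragments.
6. **Call status** of each junction against an authorized-junction
   database (and optionally a patent database): *known* at ≥ 90% window
   coverage, *unknown* at ≤ 50% or no hit, *ambiguous* between.

A bundled simulator generates the complete study scenario — transgenic
cassette (LB–t35S–hpt–p35S–pUBI–cry1B–tNOS–RB) inserted at two host
loci, bidirectional anchored amplicons, nanopore-like noise with
homopolymer bias, chimeras (including a planted scattered-clip chimera
family), time-stamped reads with a realistic accumulation profile —
with full ground truth, so the whole pipeline is testable offline.
See `docs/methods.md` for the model details and limitations.

## Worked example

Simulate the default scenario and run everything:

```bash
walkseq run --simulate --seed 1 --out runs/demo
```

which prints (seed 1):

```
delineated sites: 4
  contig1-LB@14186  clusters=10 reads=569 status=unknown
  contig1-RB@14186  clusters=1 reads=515 status=known
  contig2-LB@13253  clusters=12 reads=826 status=unknown
  contig2-RB@13251  clusters=11 reads=1528 status=known
```

Reading this: the two simulated cassette insertions produce four
transgene junctions (left and right border on each of two host
contigs); all four are recovered, each supported by several read
clusters at the true breakpoint.  The simulated authorized-junction
database contains only the two right-border junctions, so those come
back *known* (their 100-bp windows align nearly full-length to a
database entry) while the two left-border junctions are *unknown* —
exactly the signature of a GM event that is detected but not matched
by any authorized record.  The run directory holds the per-stage
artefacts: `run_stats.tsv` (the raw-tier mean error is ≈ 12.8% and the
processed tier ≈ 1.6–1.7%, over the 1/2/4/8/16/24 h time subsets),
`clusters.tsv`, `annotations.tsv`, `sites.bed`/`sites.tsv` (which also
lists one *chimeric_suspect* locus — the simulator plants a
PCR-recombination chimera family whose scattered clipping pattern the
delineation rule refuses to call as a site), `junctions.fasta`,
`flanks.fasta`, `insert_layout.tsv`, `status.tsv` and a `manifest.json`
with parameter and checksum provenance.

Every stage is also its own subcommand (`walkseq simulate`, `trim`,
`subset`, `correct`, `cluster`, `search`, `map`, `annotate`, `status`,
`report`) operating on plain FASTQ/FASTA/TSV/BED files.

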