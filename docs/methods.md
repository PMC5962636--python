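# Methods

`walkseq` re-implements, as a single reproducible pipeline, a desk-scale
workflow for detecting and characterizing transgene insertions from
DNA-walking amplicon libraries sequenced on a long-read nanopore
platform.  The design target is the published Bt rice case: a T-DNA
cassette (LB – t35S – hpt – p35S – pUBI – cry1B – tNOS – RB) present at
two genomic loci, amplified by walking PCR anchored bidirectionally on
the p35S, tNOS and t35S elements, and identified without a reference
assembly of the event itself.  This note records the models, the
numerical choices, and what the synthetic data can and cannot show.

## Pipeline model

1. **Adapter removal.**  Sequencer ("platform") adapters are removed
   with a minimum trim of 4 bp; an internal hit at normalized identity
   ≥ 0.75 splits the read (the published run lowered the middle
   threshold of its trimming tool to 0.75 for exactly this reason).
   The 57-bp walking-tag adapter
   `GGAAGCAGTGGTATCAACGCAGAGTGGCCATTACGGCCGAACACGCGTCGTTTACCT`
   is then removed wherever its edit distance is at most
   `floor(0.30 × matched length)` with a minimum match of 5 bp, in both
   orientations, iterating until no occurrence remains; reads shorter
   than 100 bp afterwards are dropped.  Partial adapters (shorter than
   the full 57-mer) are accepted only at read ends — internally a full
   occurrence must match, which prevents random 5-mers from shredding
   reads.  Removal order is fixed (full occurrences first, by edit
   distance, then leftmost; then the longest optimal end partial) so
   runs are byte-reproducible and oracle-checkable.  Whether the
   original study searched the reverse complement is not stated; both
   orientations are searched here because double-stranded ligation makes
   both possible.

2. **Error correction**, the correct-then-trim design of long-read
   correction tools such as Canu.
   Overlaps are detected by shared 2-bit-packed words (default k = 12;
   at 13 % per-base error the chance that a word is clean in both reads
   of a pair is ≈ (0.87²)¹² ≈ 3.5 % per position, dense enough for
   reliable candidate detection, which 15-mers are not), grouped per
   partner read, and verified by global alignment of the implied
   segments; overlaps under 700 bp on either read are dropped, matching
   the published minimum read and overlap lengths.  Candidate partners
   are ranked by shared-word count × implied overlap span so that true
   dovetail partners are not crowded out by the many reads sharing only
   a common cassette region.  Every read ≥ 700 bp is corrected
   (the published run forced this via corOutCoverage) by per-column
   majority vote over at most 16 overlapping reads, indels included via
   the verification alignment paths; ties keep the original base, so a
   base whose column majority agrees with the original is never
   changed.  Trimming removes end runs with support below 2 (the same
   threshold as the consensus coverage floor; the original does not
   quantify "low support"), drops reads under 700 bp and applies one
   more walking-adapter pass.  Qualities of corrected reads are
   recomputed from column support (a capped linear proxy), since the
   original qualities are invalidated.

3. **Two-round clustering** (a CD-HIT-like greedy procedure).  Round 1:
   reads sorted by length descending; each read joins the first cluster
   whose representative it matches at ≥ 95 % global identity with
   length ratio ≥ 0.99, else founds a cluster; only clusters with ≥ 6
   members are retained.  Round 2 merges retained clusters whose
   shorter representative aligns inside a longer one at ≥ 95 % identity
   over its whole length; all round-2 clusters are kept.  Identity is
   defined traceback-invariantly as `1 − editdist / max(len)` (global)
   and `1 − editdist_infix / len(shorter)` (containment): the
   conventional "matches / alignment length" depends on which co-optimal
   traceback an aligner happens to return and would make exact oracle
   comparisons ill-posed.  Both orientations are compared, since
   nanopore reads come from either strand.  The abundance filter is the
   chimera defence: a PCR/sequencing chimera joins two essentially
   random fragments, so it almost never recruits five like-minded
   companions.

4. **Annotation.**  Cluster representatives are searched against a
   plant/host genomic database and a non-host (vector/construct)
   database using a seed-and-extend engine with exact 64-base words —
   the stringent word size of the published BLAST runs — extended by an
   exact banded affine local DP (match +1, mismatch −2, a gap of length
   n costs 5 + 2(n−1)).  Because the banded pass is exact within the
   seeded window, the engine's best hit equals a full Smith–Waterman
   oracle whenever the true alignment contains one clean word; the
   price, as in the original study, is that short or very noisy
   homologies yield no hit at all.  Classes: ≥ 98 % query coverage
   against the plant DB → class 1 (host background, uninformative); no
   plant hit → class 3 (insert-internal if the non-host DB hits, else
   no information); otherwise class 2, split into 2A when ≥ 80 % of the
   plant-hit interval is explained by transgenic-element hits (the
   automated replacement for the published manual review; threshold
   configurable) and 2B otherwise.  Class 2B with a non-host hit is a
   junction candidate.  Representatives whose plant hit covers 90–98 %
   of the query get their overhangs searched against the vector DB at
   word size 16; vector-free overhangs reassign the cluster to class 1,
   generalizing the single ~92 %-coverage chloroplast case that the
   original authors resolved by hand (the exact review band is not
   stated in the source; [0.90, 0.98) is this package's choice).

5. **Characterization.**  For each junction-candidate representative
   the breakpoint is the host-hit boundary adjacent to the vector
   overhang, and the border side (LB/RB) follows from which cassette
   end the vector hit faces.  Breakpoints on one (contig, side) are
   first split into positional loci (gaps above 1 kb separate loci, so
   a chimeric hotspot elsewhere on a chromosome cannot poison a real
   site); a locus is a *delineated* site when ≥ 70 % of its breakpoints
   sit within ±5 bp of the modal position and fewer than 3 distinct
   insert-fusion partners are involved, otherwise it is emitted as a
   *chimeric suspect* (the scattered-clipping pattern seen at the
   published phantom locus on chromosome III; the constants quantify a
   qualitative description and are config keys).  Suspects are only
   flagged — resolving them needs wet-lab confirmation.  The
   per-cluster junction excision takes the 100 bp around the midpoint
   between the two hits in query coordinates, as published; the
   *site-level* window is instead centred on the delineated breakpoint
   projected into the modal representative (from the nearest hit
   boundary, avoiding internal indel drift), which removes the few-bp
   boundary noise that individual hits carry.  The window consensus is
   called across the supporting reads with a minimum coverage of 2 and
   is indel-aware: majority deletions emit nothing, majority insertions
   splice in the modal base — so errors local to the anchoring
   representative do not survive — while 50/50 columns emit N and
   uncalled columns fall back to the representative's base in the
   reported window.  Flanks are reassembled by greedy overlap merging
   (minimum overlap 40 bp at 94 % identity, the defaults of the
   assembler used in the original study), and insert-internal fragments
   are tiled after removing fragments contained in others.

6. **Authorization status.**  Each junction window is searched (word
   size 16; a 64-base exact word is unreasonable for a 100-bp query at
   ~1 % consensus error) against the authorized-junction database and,
   when supplied, a patent database.  Coverage ≥ 90 % of the window →
   *known*; ≤ 50 % or no hit → *unknown*; the band in between —
   undefined at the two published operating points — is reported as
   *ambiguous* and never auto-resolved.

7. **Run statistics.**  The "raw" tier is the adapter-trimmed,
   length-filtered read set and the "processed" tier the corrected one,
   each mapped to a reference of insert-plus-flanks and summarized per
   time subset (1/2/4/8/16/24 h).  Correction runs once on the full
   dataset; per-subset processed tiers filter on the source read's
   start time.  Re-running correction per subset, as the original study
   did, changes no tested property and would repeat the most expensive
   stage six times.

## Synthetic data

The generator builds the study conditions so that every stage is
testable without external downloads.  Defaults: two insertions on two
30-kb host contigs (order-3 Markov chains, with one deliberate
low-complexity tract planted near the last right-border junction);
amplicons of 200 bp – 4 kbp anchored at p35S/tNOS/t35S in both
directions (6 amplicons per anchor-direction per insertion, 90 reads
each, giving > 500 raw reads across each junction window plus a few
nonspecific host amplicons); per-base error 13 % split 45 % / 30 % /
25 % into substitutions / insertions / deletions (a long-read-like skew;
the source states only the total), doubled inside homopolymer runs ≥ 4;
2 % random chimeras joining two amplicon fragments tail-to-head; one
planted chimera *family* — one host locus fused to three distinct
cassette fragments at clip points tens of bp apart, each amplified past
the ≥ 6-read filter — to exercise the scattered-clip rule, which is why
that family is excluded from the random-chimera discard statistic; and
read start times drawn from a piecewise-linear cumulative profile with
knots at the six subset hours matching the published accumulation
(14.6 / 29.9 / 47.6 / 67.6 / 95.3 / 100 % — over half the reads before
8 h).  The mini-databases are: host contigs plus decoy plant contigs
(one embedding the pUBI element verbatim, to exercise class 2A); the
cassette plus a synthetic vector backbone; the elements themselves; and
an authorized-junction database seeded with the two right-border truth
windows (mirroring the published control, where only right-border
junctions were in public databases), so two junctions come out *known*
and two *unknown*.

What the simulation does not emulate: signal-level artefacts and
basecaller-specific error structure beyond the homopolymer multiplier,
primer thermodynamics and amplification bias (amplicon abundances are
uniform), barcode demultiplexing, and real plant-genome repeat
structure.  Passing tests therefore demonstrate the pipeline's logic
and its behaviour under calibrated nanopore-like noise, not performance
on any particular real flow cell.

## Numerical and engineering choices

* Edit distances come from edlib; the affine local DP and the pileup
  accumulators are numba kernels; the independent test oracles use
  hand-written DPs and biotite's optimal aligner, never the same code
  path.
* Scoring convention everywhere: match +1, mismatch −2, gap open −5
  charged on the first gapped base, −2 per further base; N mismatches
  everything.
* Seeds whose word is > 80 % one base (or contains N) are skipped;
  extension is never masked.
* Per-read error rate is (mismatches + inserted + deleted bases) /
  alignment length of the primary hit.
* All intervals are 0-based half-open internally; reports print 1-based
  positions.
* Determinism: every stage is seeded through the run configuration, all
  greedy orders and tie-breaks are fixed and documented, and the run
  manifest records parameters and output checksums — identical
  manifests imply identical outputs.
* Default problem size (≈ 7,000 reads, ≈ 15 Mb of sequence) is chosen
  so a full run finishes in minutes on one CPU while keeping > 500 raw
  reads per junction; depths beyond that change the measured quantities
  only marginally because consensus accuracy saturates.

## Known limitations

* The aligner is not BLAST: no e-values, no composition statistics;
  hits are ranked by raw score.  With word size 64, hits lacking a
  64-base exact word are invisible by design.
* Correction assumes amplicon-style redundancy; isolated reads are left
  uncorrected and then removed by the support trim, so singleton
  amplicons do not survive to clustering.
* The chimeric-suspect rule flags but cannot verify; the original study
  confirmed its three suspect combinations by PCR, and the output notes
  carry the same caveat.
* Insertions are simulated in forward orientation and without host-base
  deletion at the integration site; the delineation logic does not
  depend on either simplification, but they are untested territory.
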