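# Methods

## The accounting model

A pangenome graph represents many assemblies at once: nodes (GFA segments)
carry DNA, and each assembly's genome is an oriented path over nodes, so
sequence shared between assemblies is stored once on shared nodes. All
analyses here are *accounting* over that structure — no alignment is
performed; the graph's own segmentation defines the resolution.

**Coverage.** A sample covers a node if any of its paths traverses it, in
either orientation, any haplotype; multiplicity is ignored because a node is
one piece of sequence no matter how often it is visited. Sample names come
from W-line sample fields verbatim, or from P-line names split per PanSN
(`sample#haplotype#contig`), falling back to the first `.`-delimited field
and then to the whole name — assemblies aggregated from public archives
carry heterogeneous naming and all three conventions occur.

**Contribution ledger.** Novel-sequence attribution is a greedy set-cover
ordering: the reference assembly first claims every node it covers; then,
repeatedly, the sample whose remaining covered nodes hold the most base
pairs claims them, until all samples are evaluated (a sample can be
evaluated at 0 bp and is still reported). Nodes no path covers accumulate as
`unassigned_bp`, which makes the conservation identity
`reference + Σ samples + unassigned = total graph bp` exact and checkable on
every input. Ties on remaining bp are broken lexicographically by sample
name; the printed statistic is insensitive to the tie-break whenever the
tied sets are disjoint, and determinism matters more than any particular
choice. Mean degree is reported as edges/nodes (E/N), the convention behind
the published 1.4 for the 40-assembly chicken graph; 2E/N is exposed
separately as `mean_incident_degree`.

**SV classification.** Works on the multi-sample VCF the pipeline emits.
Subsetting to one sample emulates `bcftools view -a -s`: keep records where
the sample's genotype contains a non-reference, non-missing allele index,
drop alt alleles it does not carry, renumber genotype indices. Each carried
ref/alt pair is classified from lengths alone: with
`delta = len(alt) − len(ref)`, the pair is an SV when
`|delta| ≥ sv_min_delta` (default 50, inclusive in both directions — the
symmetric reading of the two published threshold sentences); length-changing
pairs are `indel` below `indel_max_len` (default 1000) and
`insertion`/`deletion` at or above it; `delta = 0` gives `snv` (1 bp) or
`mnv`. Allele trimming (strip the shared leading run, then the shared
trailing run) decides purity: if both trimmed alleles remain longer than one
base the pair is `complex`. Trimming strips the full shared leading run, not
just the single VCF anchor base, because a pure insertion written as
`REF=NNN…`, `ALT=REF+ins` must trim to an empty side to be recognized as
pure. Symbolic alleles (`<DEL>`) are rejected with a counted skip: the
pipeline's VCFs are sequence-resolved. Phased and unphased separators are
equivalent; a `1/2` genotype yields two classifications.

**MAF census.** hal2maf output includes reconstructed ancestral genomes
("Anc0") and the synthetic graph backbone ("MINIGRAPH"). A block is excluded
iff *any* row's genome (the `src` field up to the first `.`) is in the
exclusion set (default `{Anc0, MINIGRAPH, GRCg7b}`; never empty). Retained
blocks are censused by the s-line `size` field — ungapped sequence length,
exact integers, strand-independent — not alignment columns. Multiplicity
counts distinct genomes in a block, not rows; a genome with several rows
contributes all their sizes to its bp total but once to multiplicity. Blocks
are counted as serialized; blocks split at hal2maf chunk boundaries are not
merged.

**Assembly statistics.** N50/L50 accumulate sorted-descending lengths until
the cumulative sum first reaches `total/2`; `nx_stats` accepts an external
total so the statistics can be recomputed from a published per-chromosome
table even when unplaced scaffold lengths are unprinted — valid precisely
when every omitted scaffold is shorter than the crossing length (true for
the KLC table: ~15 Mb of unplaced sequence vs a 90.5 Mb N50), and an error
is raised when the listed lengths cannot reach half the total. GC is
`100·Σ(G+C)/Σ(A+C+G+T)`: Ns and IUPAC ambiguity codes count toward scaffold
length but are excluded from numerator and denominator. The bundled KLC
chromosome-length table reproduces the published N50/L50 and
percent-of-assembly values; note the published per-chromosome lengths sum to
1,011,440,124 bp, which matches neither the printed chromosome-scale total
(1,008,187,434) nor the genome size (1,023,165,347) — the package reports
from the inputs it is given and does not reconcile them.

## The synthetic pangenome generator

`simulate.generate` emulates the *statistical structure* the analyses
assume, not chicken biology: one chromosome consisting of a shared reference
core (default 24 kb, split into ~48 backbone segments) traversed by every
sample, with non-overlapping planted bubbles separated by at least one
backbone segment. Defaults: 6 assemblies (reference + 5), 2 unique
insertions per sample of 300–1500 bp (sample-exclusive novel sequence),
5 shared insertions of 30–1200 bp with carrier fraction 0.5 (at least one
carrier is forced), 5 deletions of 30–1200 bp, 12 SNVs. These sizes keep a
bundle around 100 nodes / 36 kb — large enough that greedy ordering, carrier
sharing and the exclusion filter are all exercised, small enough that a
20-seed sweep runs in about a second. Length ranges straddle both classifier
thresholds (50 and 1000 bp) so planted variants fall into every class.

Insertions add carrier-only nodes; deletions make carriers skip a reference
node (no new sequence); SNVs are 1-bp two-allele bubbles. The emitted GFA
uses a P line for the reference and W walks for samples, mirroring pipeline
output and exercising both dialects. The VCF uses the anchored-base
convention for indels and haploid genotypes (one path per assembly). The
MAF contains one gap-free block per planted insertion, rows for each
carrier with that carrier's own coordinates, plus three decoy blocks
(Anc0, MINIGRAPH, reference) so the exclusion filter always has work.

All randomness flows from a single numpy PCG64 stream seeded by
`SimParams.seed`; a given parameter set is byte-reproducible. Bubble
placement is constructive (events laid left-to-right with drawn spacers of
at least 30 bp), so overlaps are impossible by design; parameter sets whose
events cannot fit the core raise immediately rather than being re-drawn.

The truth tables are computed from the generator's own planted carrier sets,
not by calling the analysis modules: graph counts from the constructed
node/link lists, sample-exclusive novel bp directly from carrier sets, the
expected contribution ledger from a small independent greedy over those
sets, expected variant classes from the planted lengths, and the MAF census
from the planted insertion events. `verify()` therefore compares two
genuinely separate routes.

**What passing does not show.** The generator has no repeat families, no
nested or overlapping variation, no inversions or translocations, no
haplotype structure (one haploid path per sample), single-chromosome scale,
and identical inserted sequence across carriers of a shared event. Exact
truth recovery on these bundles validates the accounting logic, not
robustness to alignment artifacts, partial-node novelty, or the scale of
real graphs (~10^8 nodes), where only streaming behavior and the
conservation invariants carry over.

## Numerical and interface choices

- Degenerate inputs: empty GFA parses to an empty graph; mean degree of an
  empty graph is reported as 0 with a warning; N50 of an empty length list,
  GC with a zero denominator, and an empty MAF exclusion set are errors.
- Record order in GFA is not meaningful: referential integrity is checked
  after the whole stream is read, so S lines may follow the L/P/W lines
  that use them.
- Serialization round-trips the input dialect (walks stay W lines, P-line
  path names are preserved verbatim).
- Percent-of-assembly values are full-precision floats; report formatting
  uses 10 significant digits, matching published length tables.
- Sweep sizes in tests and the acceptance script (20 seeds for conservation
  and round-trip, 10 for per-sample SV/MAF truth) are the package's chosen
  balance between coverage of the randomized space and a fast default test
  run.
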