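# panledger

Accounting analyses over the outputs of graph-based pangenome pipelines
(Minigraph-Cactus style), built around the 40-assembly *Gallus gallus*
pangenome that integrates the Korean long-tailed chicken (KLC)
chromosome-level assembly:

- **`panledger.gfa`** — parse/validate/serialize path-covered GFA v1.1 graphs
  (S/L/P/W records, PanSN path names), node/edge/length statistics, and
  per-sample node-coverage sets.
- **`panledger.contribution`** — attribute graph sequence to assemblies:
  the reference claims every node it covers, then the assembly with the most
  *remaining* covered base pairs claims its nodes, iteratively, until all
  assemblies are evaluated. The ledger conserves
  `reference + Σ samples + unassigned = total graph bp`.
- **`panledger.sv`** — extract the variants one sample carries from a
  multi-sample VCF (allele trimming and genotype renumbering) and classify
  each ref/alt pair by length rules: a structural variant when
  `|len(alt) − len(ref)| ≥ 50`, an *indel* when the length change is below
  1 kb, *insertion*/*deletion* at ≥ 1 kb, *snv*/*mnv* for length-preserving
  changes, *complex* when substitution remains after allele trimming.
- **`panledger.maf`** — drop MAF alignment blocks containing ancestral
  (`Anc0`), synthetic (`MINIGRAPH`) or reference rows, then census the
  surviving non-reference blocks: total bp per assembly and a histogram of
  blocks by the number of distinct assemblies present.
- **`panledger.asmstats`** — streaming FASTA scan, N50/L50, GC over
  unambiguous bases, per-scaffold percent-of-assembly.
- **`panledger.simulate`** — seeded generator of miniature ground-truthed
  pangenome bundles (FASTA + GFA + VCF + MAF + truth tables) plus a
  `verify()` that runs every stage against the planted truth.

## Worked example

```sh
$ panledger simulate --out demo --seed 5
$ panledger gfa-stats demo/graph.gfa
node_count      106
edge_count      137
total_length    36080
mean_degree     1.2924528301886793
...
$ panledger contribute demo/graph.gfa --reference REF
rank    sample  bp      nodes   round
1       REF     24000   79      0
2       S1      4638    10      1
3       S4      2379    5       2
4       S2      2238    3       3
5       S5      1419    6       4
6       S3      1406    3       5
```

The reference claims its whole 24 kb genome; each later row is the sequence
an assembly adds that no earlier-evaluated assembly covered, in greedy
(largest-first) order — S1 contributes 4,638 bp of novel sequence, and the
per-round amounts are non-increasing. `panledger verify --seed 5` replays
all stages against the generator's planted truth.

The same statistics apply to published summary inputs. The 40 chromosome-level
scaffold lengths of the KLC assembly (`panledger.datasets`), with the full
genome size 1,023,165,347 bp as total, give:

```python
>>> from panledger.asmstats import nx_stats
>>> from panledger.datasets import KLC_CHROMOSOME_LENGTHS, KLC_GENOME_SIZE
>>> nx_stats(list(KLC_CHROMOSOME_LENGTHS.values()), total=KLC_GENOME_SIZE)
(90511606, 4)
```

i.e. scaffold N50 = 90,511,606 bp and L50 = 4, and chromosome 1 is
19.10081949 % of the assembly.

## Scope

The package consumes the pipeline's output formats; it does not build
graphs (Minigraph-Cactus), call consequences (VEP), or compute
completeness/misassembly metrics (BUSCO/QUAST). See `docs/methods.md` for
the model, parameter defaults and known limitations.
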