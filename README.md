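# refscaf

Reference-guided scaffolding and gap-closure primer design for draft
bacterial genomes.

`refscaf` maps draft contigs onto one or more finished reference replicons
(chromosome and plasmids), assigns each contig to **at most one** replicon,
builds an ordered/oriented N-gapped pseudocontig per replicon (splitting
contigs that span the origin of a circular molecule), designs
uniqueness-verified PCR primer pairs across the remaining gaps, and emits
ACT-compatible comparison files (crunch + EMBL feature tables) for
structural inspection. All stages are native Python — no external alignment
or primer binaries are invoked.

## Command line

```bash
refscaf \
    --contigs draft_contigs.fasta \
    --reference chromosome.fasta --reference plasmid.fasta \
    --ptt chromosome.ptt --ptt plasmid.ptt \
    --outdir out/ --protein-scan
```

One output directory per reference replicon:

| file | content |
|---|---|
| `Reference.fsa` | the reference replicon |
| `PseudoContig.fsa` | the N-gapped pseudocontig |
| `PseudoContig.crunch` | ACT comparison file (pseudocontig vs reference) |
| `PseudoContig.tab` | one feature per placed contig |
| `ReferenceHits.tab` | one feature per alignment hit on the reference |
| `PCRProducts.tab`, `PrimerPairs.tsv` | gap-closure primer pairs |
| `ReferenceProteinHits.tab` | protein hits in excluded contigs (needs `--ptt`) |

plus a top-level `UnMappedContigs.txt`, `summary.txt`/`summary.tsv` and
`run.log`. Load `Reference.fsa` + `PseudoContig.fsa` +
`PseudoContig.crunch` into the Artemis Comparison Tool and add the `.tab`
entries on the matching molecule.

Feature colours: mapped contig 4 (blue), origin-split part 5 (cyan),
reference hit 3 (green), PCR product 2 (red), protein hit 7 (yellow).

Useful flags: `--min-contig-length`, `--min-coverage`, `--min-hit-length`,
`--min-identity`, `--kmer`, `--linear`, `--no-primers`, `--window`,
`--tm-range`, `--gc-range`, `--product-max`, `--min-spacer`. Run
`refscaf --help` for the full list and defaults.

## Library layout

| module | role |
|---|---|
| `refscaf.io_formats` | FASTA, NCBI PTT, ACT crunch, EMBL `.tab` read/write |
| `refscaf.align` | seed-and-chain local aligner (k-mer seeds, maximal exact extension, sparse chaining) |
| `refscaf.profiling` | per-contig coverage profiling, mapped/excluded status, unique replicon assignment |
| `refscaf.scaffold` | orientation, anchoring, origin splitting, ordering, N-gap estimation, pseudocontig assembly |
| `refscaf.primers` | exhaustive gap-primer candidate enumeration, Tm/GC/homopolymer/3'-complementarity filters, genome-wide uniqueness |
| `refscaf.protein_scan` | six-frame translation + Smith-Waterman scan of excluded contigs with reference proteins |
| `refscaf.synthetic` | deterministic fixture engine: random genomes, fragmentation with ground truth, contaminants |
| `refscaf.cli` | pipeline wiring and all on-disk outputs |

Internal coordinates are 0-based half-open everywhere; on-disk formats are
1-based inclusive, converted exactly once at the write boundary.

Primer melting temperatures use the GC-count approximation
`Tm = 64.9 + 41*(nGC - 16.4)/len`; primer uniqueness is an exact
occurrence count of the primer and its reverse complement over **all**
input contigs (mapped and excluded alike) and must equal 1.

## Synthetic fixtures

```python
from refscaf.synthetic import generate_genome, fragment_genome

genome = generate_genome([150_000, 60_000], seed=1)
contigs, truth = fragment_genome(
    genome, n_contigs=40, gap_mean=300, inversion_prob=0.3,
    mutation_rate=0.01, n_contaminants=5, origin_spanner=True, seed=1,
)
```

`truth` records each contig's source replicon, interval, strand,
contaminant/origin-spanning flags and the true inter-fragment gaps, so
recovery of assignment, orientation, order and gap sizes is testable
end to end without any downloads.

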