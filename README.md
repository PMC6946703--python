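# crisprhgt

Analysis pipeline for CRISPR spacer-acquisition recording of horizontal gene
transfer (HGT): from raw CRISPR-array amplicon reads to identified
transferred mobile elements, plus a synthetic recording-experiment generator
that makes every stage testable offline.

A recording strain acquires short spacers from intracellular DNA into its
genomic CRISPR array. Sequencing the array and classifying the new spacers
against the recorder's own references reveals exogenous DNA — typically
conjugative plasmids — that entered the cell, without requiring selectable
markers or stable replication of the transferred element.

## Components

| module | what it does |
|---|---|
| `crisprhgt.simulate` | synthetic recordings: references, ground-truth acquisition events (expansion rate, exogenous fraction, AAG PAM bias, hotspots), amplicon reads with substitution errors, truth manifest |
| `crisprhgt.arrays` | parse reads into spacers between direct repeats (Hamming matching), call expanded arrays, per-sample expansion summaries |
| `crisprhgt.classify` | two-step endogenous filter against the recorder references (seed 8, then rescue at seed 5; endogenous = any hit with ≥80% identity AND ≥80% query coverage), exact dereplication |
| `crisprhgt.matching` | all-hits database matching at 95/95, scrambled-spacer null, threshold calibration, community unique-mapping filter |
| `crisprhgt.analytics` | normalized spacer mapping (spacers/kb/1000 exogenous spacers), 200-bp window coverage, sample-level HGT calls (≥10 unique exogenous spacers and ≥3× the 0.03% control rate), greedy/exact minimal covering plasmid sets, PAM summaries, GFF3 annotation categories, metagenome/plasmid provenance |
| `crisprhgt.align` | internal gapless seed-and-extend matcher (oracle-checked against exhaustive Smith–Waterman) |
| `crisprhgt.cli` / `crisprhgt.io` | CLI, FASTA/FASTQ/GFF3/TSV handling, run reports |

All coordinates in TSV outputs are 0-based half-open; GFF3's 1-based closed
convention is converted at the parsing boundary.

## CLI

```bash
# synthetic recording with ground truth
crisprhgt simulate --seed 1 --n-reads 10000 --expansion-rate 0.02 \
    --donor rp4_like:60000 --out-dir sim/

# spacer extraction + expansion calls
crisprhgt extract --reads sim/reads.fastq \
    --parental-spacer <SPACER1> --parental-spacer <SPACER2> --out-dir ext/

# endogenous/exogenous classification against the recorder
crisprhgt classify --spacers ext/spacers.tsv --recorder recorder.fasta --out-dir cls/

# scrambled-null threshold calibration and database matching
crisprhgt calibrate --spacers cls/exogenous.fasta --db plasmids.fasta \
    --seed 1 --out calibration.tsv
crisprhgt match --spacers cls/exogenous.fasta --db plasmids.fasta \
    --unique-only --out hits.tsv

# downstream analytics (profiles, coverage, calls, cover set, PAM)
crisprhgt analyze --hits hits.tsv --refs plasmids.fasta \
    --total-exogenous 2000 --out-dir out/

# end-to-end from a YAML config
crisprhgt run --config config.yaml --out-dir out/
```

A minimal end-to-end config:

```yaml
seed: 5
sample_id: demo
simulate:
  n_reads: 2000
  expansion_rate: 0.25
  exogenous_fraction: 0.6
  error_rate: 0.0
  donor_lengths: {donor_1: 5000}
```

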