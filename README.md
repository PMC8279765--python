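# pestiscan

Build curated profile HMMs of pesticidal-protein families from raw sequence
sets, calibrate per-model gathering cutoffs, detect and classify candidate
toxins in proteins and genomes, and compare the genomic context around
genomic hits.

The toolkit is self-contained: profile-HMM construction and Viterbi/forward
scoring, Smith–Waterman similarity graphs, native Markov clustering (MCL),
a built-in progressive aligner, gathering-cutoff calibration from score
distributions, GenBank flank extraction with uniform ORF re-annotation, and
an EasyFig-style identity-block SVG. A fixtures module generates synthetic
protein families and GenBank replicons with planted toxin cassettes, so no
external database is needed to exercise the full pipeline.

## Command line

```bash
# synthetic data (families + decoys + a planted GenBank replicon pair)
pestiscan fixtures --seed 1 --with-genome --out fix/

# dedup -> similarity graph -> MCL -> one model per family (>= 5 members)
pestiscan build --fasta fix/families.fasta --min-cluster-size 5 \
    --inflation 2.0 --seed 1 --out models/

# gathering cutoffs from positive/background score distributions
pestiscan calibrate --models models/ --positives fix/families.fasta \
    --negatives fix/decoys.fasta

# scan proteins (FASTA) or genomes (GenBank); --no-cutoff also reports
# sub-threshold matches for manual review
pestiscan scan --input fix/genome.gbk --models models/ --out scan/

# 5000 bp flanks around each genomic hit, ORF re-annotation, identity
# blocks between regions, stacked SVG comparison
pestiscan context --input fix/genome.gbk --models models/ --out ctx/

# sensitivity / specificity on labelled sets
pestiscan benchmark --models models/ --positives fix/families.fasta \
    --negatives fix/decoys.fasta
```

Models are stored in a plain-text native format (`.phmm`, bit-exact round
trip) with an additional HMMER3 ASCII export (`.hmm`) for interoperability.
Scores are full-sequence forward log-odds in bits (log2), local alignment
mode; gathering cutoffs gate on these.

## Layout

- `src/pestiscan/hmm_core.py` — profile construction, Viterbi/forward
  scoring, profile alignment, model serialization
- `src/pestiscan/model_builder.py` — dedup, similarity graph, MCL,
  per-family models, C-terminal model, cutoff calibration/validation
- `src/pestiscan/scanner.py` — protein/genome scanning, neighbour trees
- `src/pestiscan/context.py` — flank extraction, ORF re-annotation,
  identity blocks, SVG rendering
- `src/pestiscan/cli_io.py`, `src/pestiscan/cli.py` — fixtures, benchmark,
  file I/O, command line
- `tests/` — unit, property (hypothesis) and acceptance suites; the
  brute-force oracles live in `tests/oracles.py`
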