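# tcrmodels

Probabilistic sequence models for T-cell receptor (TRB CDR3) repertoires:

- **repertoire I/O** — clonotype TSV dialects (Adaptive/ImmunoSEQ-style,
  AIRR rearrangement, simple two-column), productive filtering with
  conserved C…F/V anchors, CDR3 collapsing, count-weighted training
  datasets;
- **CDR3 alignment** — fixed-width (default 19-column) multiple alignment of
  variable-length CDR3s via per-length PWMs, progressive profile–profile
  alignment (BLOSUM62, affine gaps) and a profile HMM with Viterbi decoding;
- **encodings** — aligned one-hot over 21 symbols, and the Left+Right binary
  encoding (19 × 20 × 2 = 760 features);
- **RBM** — Restricted Boltzmann Machine over aligned sequences with dReLU
  hidden units: closed-form marginal scoring, exact and AIS partition
  functions, weighted maximum-likelihood training by persistent contrastive
  divergence, Gibbs sampling, latent projection;
- **selection model** — SONIA-style independent-site selection factors over
  Left+Right features on top of a pluggable background distribution
  (three built-ins; external generation-probability providers can implement
  the `BackgroundModel` interface);
- **response scoring** — pseudo-counted fold change, expansion calling
  (one-sided Fisher's exact test + Storey q-values), response and
  specificity scores, midrank AUROC, correlation-vs-abundance curves,
  read-split and unique-clone cross-validation protocols;
- **diversity** — Levenshtein-kernel repertoire dissimilarity index;
- **synthetic data** — seeded repertoire simulator with planted responder
  motifs, log-normal clonal expansion, multinomial read sampling and
  technical replicates, so the whole stack is testable offline.

## CLI

All functionality is exposed under a single entry point:

```bash
tcrmodels simulate --config sim.yaml --seed 1 --out sim/
tcrmodels align --input cdr3s.txt --out msa.tsv
tcrmodels encode --input cdr3s.txt --mode left_right --out features.tsv
tcrmodels expand --day0 sim/day0.tsv --day21 sim/day21_A.tsv --out calls.tsv
tcrmodels train-rbm --input sim/day21_A.tsv --hidden 25 --l1sq 0.1 --seed 1 --out rbm/
tcrmodels train-sonia --input sim/day21_A.tsv --background positionwise_independent --out sonia/
tcrmodels score --day0 sim/day0.tsv --day21 A=sim/day21_A.tsv --day21 B=sim/day21_B.tsv --out scores/
tcrmodels specificity --report scores/score_report.tsv --focal A --out spec.tsv
tcrmodels evaluate --report scores/score_report.tsv --focal A --out eval.json
tcrmodels diversity pool.txt --delta 5.7
```

Every subcommand writes a manifest (config hash, seed, package version) next
to its outputs. Scores are computed in natural log and written in log base
10.

A minimal simulation config:

```yaml
n_clones: 2000
depth: 100000
antigens:
  - name: A
    motif: {3: V, 4: V, 5: V}
    responder_fraction: 0.1
```

## Layout

```
src/tcrmodels/
  io.py          clonotype tables, filtering, collapsing, count weighting
  align.py       PWMs, progressive profile alignment, profile HMM, Viterbi
  encoding.py    one-hot and Left+Right encodings
  rbm.py         dReLU RBM: scoring, partition function, training, sampling
  selection.py   background models and selection-factor training
  scoring.py     fold change, expansion calls, response/specificity, AUROC
  diversity.py   Levenshtein dissimilarity index
  simulate.py    synthetic repertoire experiments
  validation.py  end-to-end null and planted-specificity protocols
  cli.py         command-line interface
```
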