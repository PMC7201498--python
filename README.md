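# pssmloc

Protein subcellular-localization toolkit built on position-specific
scoring matrices (PSSMs). It provides:

- **PSSM I/O** — FASTA reading, PSI-BLAST `-out_ascii_pssm` parsing
  (log-odds block), sigmoid scaling into (0, 1), and an exact TSV
  round-trip dump (`pssmloc.pssm_io`).
- **Feature encoders** (`pssmloc.features`) — the classic pseudo-PSSM
  (20 column means + row-lagged squared differences, width `20 + 20*xi`),
  a column-lag family pairing *different* amino-acid columns
  (width `(20 + 20*xi) - xi*(xi+1)/2`; squared-difference, raw-product,
  and two mean-centred variants), a 400-entry cross-column correlation
  table per residue distance `S`, and fusion by concatenation.
- **Imbalance resampling** (`pssmloc.imbalance`) — SMOTE by convex
  interpolation toward same-class nearest neighbours, single-pass ENN
  editing with a 3-NN majority vote, and their composite
  (oversample, then edit), with full per-synthetic provenance.
- **Model + evaluation** (`pssmloc.model_eval`) — RBF-SVM with
  exhaustive `(c, gamma)` grid search, jackknife (leave-one-out)
  evaluation where synthetic rows are never test points, per-class
  Sn / Sp / F-measure / Mcc / G-mean and overall accuracy, and both
  resample-then-fuse and fuse-then-resample strategies.
- **Synthetic data** (`pssmloc.synthetic`) — labeled integer-scale PSSM
  collections with class-dependent column profiles, configurable
  imbalance, and Gaussian feature blobs, all seed-deterministic.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (dimension
identities, oracle equivalence against naive loop implementations,
resampler geometry, end-to-end parameter recovery, jackknife
determinism). Simulations there are scaled to run on one CPU in
seconds.

## CLI

```sh
# generate a labeled synthetic PSSM collection (4 classes, 43/30/13/12)
pssmloc simulate --classes 43,30,13,12 --seed 1 --out data/

# encode it (column-lag encoder at xi=13 -> 189 features per protein)
pssmloc encode --pssm-dir data/ --encoder IM_PSEPSSM --xi 13 --out features.csv

# end-to-end: encode + fuse + resample + jackknife SVM report
pssmloc evaluate --pssm-dir data/ --labels data/labels.csv \
    --xi 13 -S 1 --method SMOTEENN --k-neighbors 3 \
    --placement BEFORE_CV --out-dir results/

# OA as a function of xi (dimension column checks the closed form)
pssmloc sweep --pssm-dir data/ --labels data/labels.csv \
    --param xi --values 1:15 --out sweep.csv
```

Every subcommand writes its fully resolved configuration as JSON beside
its outputs; all randomness flows from the single `--seed`.

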