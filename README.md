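# pocketsig

Structure-based drug-target prediction from positive and negative pocket
signatures.

Given a set of protein structures known to bind a drug (positive set) and a
set known not to (negative set), `pocketsig`:

1. extracts binding pockets — from co-crystal ligand contacts, from a
   built-in grid/burial cavity finder, or from an external pocket table;
2. builds a **positive structural signature**: sequence-order-independent
   pairwise pocket alignment, average-linkage guide tree, progressive
   profile merging, re-registration refinement, and preservation-ratio
   pruning (every kept position is present in ≥ 50 % of the members, at
   most 100 positions);
3. builds a **negative signature** the same way from each non-target's
   pocket most similar to the binding pocket;
4. scores query proteins: each of the top-3 largest pockets is aligned to
   both signatures with the combined score
   `rmsd·N^(−1/3) + α·(1 − similarity/best_similarity)` (α = 1.2) and a
   protein is a predicted target when `score_positive − score_negative < 0`;
5. ranks predicted targets by externally computed docking scores and
   attaches an empirical significance (fraction of random-structure docking
   scores at least as good);
6. ships a sequence-similarity nearest-neighbor baseline and a synthetic
   benchmark generator so the full pipeline is testable offline.

## CLI

```bash
# synthetic benchmark: PDB files + labels.tsv + truth.json
pocketsig simulate --n-pos 15 --n-neg 15 --sigma 0.3 --dropout 0.2 \
    --confusability 0.5 --seed 7 --out bench/

# positive signature from co-crystals (ligand code STI) and apo structures
pocketsig build-sig --polarity pos --pdb-dir positives/ --ligand STI \
    --out pos_sig.json

# negative signature (reference binding pocket from a co-crystal)
pocketsig build-sig --polarity neg --pdb-dir negatives/ \
    --reference-pdb positives/complex.pdb --ligand STI --out neg_sig.json

# score queries, rank by docking scores, attach significance
pocketsig predict --pos-sig pos_sig.json --neg-sig neg_sig.json \
    --pdb-dir queries/ --docking-scores docking.tsv \
    --random-scores random_docking.tsv --out predictions.tsv

# cross-validated evaluation on a labeled directory
pocketsig evaluate --pdb-dir bench/ --labels bench/labels.tsv \
    --folds 5 --seed 0

# sequence nearest-neighbor baseline
pocketsig baseline --fasta seqs.fasta --labels labels.tsv --cutoff 0.6
```

`--pockets-from FILE` substitutes an external pocket TSV
(`structure_id  rank  volume  comma-separated-atom-serials`) for the
built-in cavity finder. A YAML config passed with `--config` can override
any scoring parameter (`alpha`, `match_distance`, `min_aligned`,
`positive_only_cutoff`, `top_k_pockets`, ...).

## Formats

* **Structures** — PDB (`ATOM`/`HETATM`, model 1, best-occupancy altlocs).
* **Signatures** — JSON (schema v1): per-position centroid, element and
  residue frequency tables, preservation ratio, plus the parameter snapshot.
* **Docking / random scores** — two-column TSV (id, score; lower = better).
* **Predictions** — TSV with columns
  `id, pocket_rank, score_pos, score_neg, delta, predicted, docking_score, significance`.

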