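# mhcbind

Pan-allele peptide–MHC binding prediction with a CNN–BiLSTM–CBAM
network, semi-supervised curation of immunopeptidomics data, and a
neoantigen candidate-peptide pipeline.

## The problem

MHC class I and II molecules present short peptides on the cell
surface; predicting which peptides an HLA allele binds underpins
T-cell epitope discovery and personalised cancer-vaccine design.  Two
complementary data types exist: **binding-affinity (BA)** assays give
quantitative IC50 values (nM) for peptide–allele pairs, and
**eluted-ligand (EL)** mass spectrometry gives large sets of peptides
known to be presented — but only positives, often from multi-allelic
cell lines where the presenting allele is unknown, with decoy negatives
sampled at random.

`mhcbind` is aimed at immunoinformaticians who want a transparent,
fully inspectable implementation of this modelling stack: every network
equation, curation rule and metric is plain NumPy/pandas, tested
against independent brute-force oracles.

## The model

A peptide is middle-padded to a fixed length, concatenated with the
allele's fixed-length pseudo-sequence (the peptide-contacting residues)
and one-hot encoded. The resulting matrix feeds three branches:

* a **2D-CNN** over the (length × alphabet) "image", followed by a
  **convolutional block attention module** (CBAM):
  channel attention `Mc(F) = σ(MLP(AvgPool(F)) + MLP(MaxPool(F)))`
  then spatial attention `Ms(F) = σ(Conv([AvgPool(F); MaxPool(F)]))`,
  each applied multiplicatively;
* a **1D-CNN → bidirectional LSTM** over the residue sequence
  (standard gate equations, last hidden states of both directions);
* a **BLOSUM62 skip branch**: the peptide's substitution-score encoding
  through one dense layer.

The branches are concatenated and reduced by an MLP to one output.
Regression pre-training uses MSE on the log-affinity score

    score = 1 − ln(IC50) / ln(50000)

(50000 nM → 0, 1 nM → 1); classification uses weighted cross-entropy on
binder labels (IC50 < 500 nM ⇒ 1). Training follows AdamW, learning
rate 1e-4 with cosine annealing (T_max = 30), 30 epochs, batch 40000
(class I) / 20000 (class II) by default; all sizes are configurable and
the bundled benchmarks use desk-scale values.

The **curation pipeline** turns raw EL data into a single-allele
classification set: a regression ensemble pre-trained on BA data
(1) assigns each multi-allele positive the candidate allele with the
highest predicted score, and (2) removes sampled decoy "negatives" the
model scores at or above the 500 nM score (≈0.4256) — likely true
binders. The curated EL sets and the threshold-labelled BA set are
merged, and a 5-fold classifier ensemble (fold-mean prediction, each
member checkpointed at its minimum held-out-fold loss) is trained on
the result. Evaluation uses ROC-AUC, PR-AUC and TOPk%-PPV (positive
fraction among the top ⌈k·N⌉ predictions; k = 0.20 by default).

The **neoantigen pipeline** takes a mutation table (mutant protein
sequences with the first altered position), extracts all 8–11-mer
windows containing an altered position (for frameshift/nonstop
mutations the whole downstream suffix counts as altered), scores them
against a 20-allele panel, selects peptides whose mean panel score
exceeds 0.2 / 0.5 / 0.7, and summarises selections as sequence-logo
information matrices (bits, `log2 20 − H`).

## Worked example

```python
import numpy as np
from mhcbind.simulate import make_world, sample_ba, sample_el, sample_eval_pairs
from mhcbind.benchmark import tiny_model_config
from mhcbind.curation import CurationConfig, run_curation
from mhcbind.train_eval import FoldEnsemble, evaluate

world = make_world(n_alleles=2, seed=1)          # 2 alleles, anchor motifs at P2 + C-term
ba = sample_ba(world, 20000, seed=2)             # IC50 table with log-normal noise
el, _ = sample_el(world, 2500, 2500, seed=3)     # eluted ligands + random decoys

cfg = CurationConfig(model_config=tiny_model_config("regression", epochs=6),
                     pseudo_sequences=world.alleles, seed=1)
table, report, _ = run_curation(ba, el, el.iloc[0:0], cfg)
print(len(table), report.n_negatives_removed)

ens = FoldEnsemble(config=tiny_model_config("classification", epochs=3),
                   pseudo_sequences=world.alleles, n_folds=5, seed=1)
ens.fit(table[["peptide", "allele"]], table["label"].to_numpy(float))

ev = sample_eval_pairs(world, 1000, 3000, seed=9)
scores = ens.predict(ev[["peptide", "allele"]])
print(evaluate(ev["label"].to_numpy(), scores).to_dict())
```

On this synthetic benchmark the curated table has ~25,000 rows (a
handful of decoys removed as predicted binders), and the 5-fold
ensemble separates held-out binders from non-binders with ROC-AUC and
PR-AUC well above 0.9 — a run of `scripts/acceptance.py --seed 1`
printed `e2e_roc_auc 0.9944`, `e2e_pr_auc 0.9786`, `e2e_top20_ppv
0.965` on 4,000 held-out pairs, with the permuted-label control at
`control_roc_auc 0.5732` — chance level, so the recovered signal comes
from the planted anchor motifs, not from leakage. The same run
recovered the hidden presenting allele for 96.7% of multi-allele
eluted ligands on a 3-allele world (`deconvolution_recovery 0.9673`).

The same stack is scriptable from the shell:

```
mhcbind simulate --world-seed 1 --out data/
mhcbind pretrain --ba data/ba.tsv --pseudo data/pseudo.tsv --out ckpt/reg
mhcbind curate   --ba data/ba.tsv --el-sa data/el.tsv --pseudo data/pseudo.tsv \
                 --checkpoints ckpt/reg --out curated/
mhcbind train    --training curated/training.tsv --pseudo data/pseudo.tsv --out ckpt/clf
mhcbind neoantigen --mutations data/mutations.tsv --panel data/pseudo.tsv \
                   --checkpoints ckpt/clf --out neo/
```

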