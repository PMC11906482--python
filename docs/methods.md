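# Methods

## Inputs and encodings

Peptides use the 20 canonical amino acids; anything else (selenocysteine,
ambiguity codes, lower-case artefacts other than case) is rejected rather
than remapped, keeping encodings injective. Class-I peptides are 8–15
residues (padded to `max_pep_len = 14`), class-II 9–25 (padded to 21).
Padding is *middle padding*: pads are inserted after position ⌈L/2⌉, so
the N-terminal anchors (P1–P⌈L/2⌉) and the C-terminal anchors keep fixed
indices across peptide lengths. This matters because class-I binding
specificity concentrates at P2 and the C-terminus; terminal-preserving
padding keeps those columns aligned for the convolutional filters.
The padding symbol encodes as an all-zero row in both the one-hot
(L × 21) and BLOSUM62 (L × 20) encodings, so padded positions carry no
signal. BLOSUM62 values come from biopython's published matrix.

The MHC molecule is represented by a NetMHCpan-style fixed-length
pseudo-sequence (34 contact residues for class I; a concatenated
α+β pseudo-sequence for class II), supplied as a two-column TSV. The
full-chain alternative was rejected because variable chain lengths would
force per-allele padding and ~10× longer inputs for no added contact
information. The bundled 20-allele class-I panel file carries real
common allele names with *synthetic* pseudo-sequences (the file and its
docstring say so); users substitute their own table for real work.

## Network

One (peptide, allele) pair becomes a (max_pep_len + pseudo_len) × 21
one-hot matrix processed by three branches:

* **2D-CNN trunk** (always on): valid convolution, ReLU, then 2×2 max
  pooling before attention. Pooling is a deliberate deviation from a
  bare conv→attention stack: it quarters the attention and head width
  with no measurable loss on the recovery benchmarks, which keeps the
  single-CPU budget honest.
* **CBAM**: channel attention then spatial attention, both sigmoid
  gates in (0,1) applied multiplicatively — so the module is a
  contraction (max|F″| ≤ max|F|), which the tests assert. The shared
  channel MLP uses reduction ratio 8 (2 in the desk-scale configs); the
  spatial convolution is 7×7, zero-padded to preserve shape. The order
  channel-then-spatial follows the module's published design and the
  architecture prose; the equation block in the source text repeats the
  spatial symbol for both steps, which we read as a typographical slip.
* **1D-CNN → BiLSTM**: valid 1D convolution (width 3, ReLU) over the
  same matrix read as a residue sequence; a forward and a backward LSTM
  pass with independent parameters; the two final hidden states are
  concatenated. Gates are the textbook equations; the per-equation
  reference functions in `network.py` are kept deliberately scalar so
  tests can pin the batched training graph against them.
* **BLOSUM62 skip branch**: the padded peptide's substitution-score
  matrix, flattened through one dense layer (the raw-flatten
  alternative was rejected to keep the fusion width independent of
  `max_pep_len`).

Branch outputs concatenate into a fusion vector reduced by an MLP to a
single output: linear for regression, a logit (sigmoid at predict time,
binder call at 0.5) for classification. Ablation flags (`use_cbam`,
`use_1dcnn_bilstm`, `use_blosum`) drop the named module; disabling the
1D or BLOSUM branch shrinks the fusion vector, disabling CBAM keeps the
width but removes the reweighting.

Convolution activations are ReLU (the defining equations leave σ
generic); sigmoids appear only where the gate equations require them.

## Training

AdamW (weight decay 0.01), learning rate 1e-4, cosine annealing with
T_max = 30, 30 epochs, batch 40000/20000 (class I/II) are the published
defaults and are recorded in `ModelConfig`; the synthetic benchmarks
override them with desk-scale values (batch 256, learning rate 1e-3,
3–6 epochs) because the desk problems are ~100× smaller than the
datasets those defaults were tuned for. Regression minimises MSE on
the score transform; classification minimises cross-entropy with
per-class weights inversely proportional to class counts — curation
removes only negatives, and the weights keep the threshold-labelled BA
majority class from drowning the EL positives. Every fold member is
checkpointed at its minimum held-out-fold loss; the ensemble prediction
is the arithmetic fold mean. All randomness (initialisation, batch
order, fold split) derives from one config seed; training is
single-threaded and bitwise reproducible.

The network and training loop are NumPy with a package-local
reverse-mode autodiff core (`_autodiff.py`). Gradients are verified by
finite differences (relative error < 1e-4) in float64; production runs
use float32 (training is memory-bandwidth bound, and the half-width
arrays roughly double throughput). Convolutions accumulate over kernel
offsets instead of materialising an im2col buffer — for these kernel
sizes the unfolded tensor would dominate memory traffic. Max-pool
gradients split equally among tied maxima.

## IC50 transform

`score = 1 − ln(IC50)/ln(50000)`, IC50 in nM. Scores outside [0,1]
(IC50 < 1 nM or > 50000 nM) are kept, not clipped: the transform is
unbounded and clipping would bias the regression target. Binder labels
use the conventional threshold: IC50 < 500 nM ⇒ 1, ≥ 500 nM ⇒ 0.

## Curation

The pipeline runs pretrain → deconvolve → filter → merge:

* **Deconvolution** assigns each multi-allele eluted positive the
  candidate allele with the highest regression-ensemble score; exact
  ties go to the lexicographically smallest allele name so results are
  order-independent. Regression scores (not classification
  probabilities) are used because deconvolution precedes any
  classification training.
* **Negative filtering** removes decoys whose predicted score is at or
  above the score of 500 nM (≈0.4256) — i.e. decoys the model itself
  considers binders at the standard positivity threshold. The
  threshold is configurable; removed decoys are not re-sampled
  (class-imbalance is handled by the loss weights instead, so the
  curated set never contains synthetic peptides the user didn't
  provide).
* **Merging** unions BA (threshold-labelled), single-allele EL and
  deconvolved multi-allele EL records; exact duplicates collapse with
  provenance union, and a BA/EL label conflict keeps the
  experimentally observed EL positive (logged).

`rounds > 1` repeats deconvolve→filter→merge, refitting the regressor
on the current curated table (binary labels as pseudo-score targets on
the same [0,1] scale, since post-merge rows no longer carry IC50s).
Default is one round: on the strongly separated synthetic worlds a
second round is a fixed point, and iterating on real data risks
progressively excluding borderline ligands.

## Evaluation

ROC-AUC is the Mann–Whitney pairwise probability; PR-AUC is the area
under the descending-score precision–recall step curve with tied scores
grouped (equal to average precision; both are computed via
scikit-learn and pinned against brute-force oracles in the tests).
TOPk%-PPV — not given a formula in the immunopeptidomics literature we
follow — is defined here as the positive fraction among the top
⌈k·N⌉ predictions, ties broken by stable input order, pooled across
alleles (a per-allele option exists). Pearson r is the standard
product-moment coefficient.

## Synthetic worlds

A world plants, per allele, a random pseudo-sequence and anchor motifs
at P2 and the C-terminus: 3 preferred residues per anchor, each match
lowering ln IC50 by 3.2 from a baseline of ln 25000, plus N(0, 0.4)
log-noise, clipped to [1, 50000] nM. With these defaults a
double-anchor match sits at ≈42 nM (binder), a single match at
≈1000 nM and a non-match at ≈25000 nM (non-binders), so binder status
is essentially determined by the motif and desk-scale models can
recover it; `hard_mode` weakens the separation (bonus 1.6, σ 0.9) for
robustness work. EL positives force anchor matches with probability
0.95 per anchor for a hidden true allele; multi-allele candidate sets
contain 2–6 alleles including the true one. Decoy negatives are
uniform random peptides, so ≈(3/20)² ≈ 2% are true binders — exactly
the contamination the filter must remove. Hidden truth (true allele,
noise-free binder status) lives in a sidecar frame that never reaches
the files the pipeline consumes.

What the generator does **not** emulate: real allele-specific length
distributions, proteasomal cleavage and transport biases,
mass-spectrometry detectability (hydrophobicity, charge), shared motifs
between related alleles, and assay-to-assay IC50 shifts. Passing the
recovery benchmarks therefore demonstrates that the pipeline's
machinery — encoding, optimisation, deconvolution, filtering,
ensembling, metrics — is correct and recovers planted structure; it
does not certify accuracy on real immunopeptidomes.

## Benchmarks and problem sizes

`benchmark.py` fixes the experiment scales: 2-allele recovery world
with 20,000 BA + 5,000 EL samples, 5-fold training of a tiny model
(4 2D-conv filters, 8 1D-conv filters, 8 LSTM units, one 32-unit MLP
layer), 4,000 held-out pairs with noise-free labels, a permuted-label
control; a 3-allele world with pairwise-disjoint anchor sets
(18,000 BA pairs, 1,500 multi-allele positives, 1,500 single-allele
decoys) for deconvolution recovery and contamination reduction; and
6,000-row ablation runs. Disjoint anchors matter for deconvolution:
when two alleles share preferred residues at an anchor, the presenting
allele is not identifiable from the peptide alone, so the recovery
experiment would measure motif overlap rather than model quality.
These sizes were chosen as the smallest at which the recovery signal
is comfortably away from its thresholds on a single CPU;
`scripts/acceptance.py` re-runs them end to end.

## Neoantigen pipeline

Mutation tables are filtered (missing fields, silent mutations, exact
duplicates), then every 8–11-mer window of the mutant protein
containing an altered position is emitted. For missense/nonsense/
splice/intron records the single recorded position is altered; for
frameshift and nonstop records everything from the first altered
position to the C-terminus is neo-sequence, so every window overlapping
that suffix qualifies. Window counts obey the closed form
min(p, N−L+1) − max(1, p−L+1) + 1. Candidates are scored against the
20-allele panel; selection keeps peptides with mean panel score
strictly above the threshold (0.2/0.5/0.7), so the selections nest.
The mean (not max) over alleles is used, read literally from the
procedure this follows; a max option exists. Motif matrices are
computed per window length (logo columns need equal lengths):
per-position information log2 20 − H with no pseudocount, per-residue
bar height = frequency × information.

## Known limitations

* CPU-only; the autodiff core is written for clarity and testability,
  not large-scale throughput.
* Class-II support is structural (lengths, pseudo-sequences, batch
  default) but untested against real class-II data.
* The default negative-filter threshold assumes regression scores on
  the log-affinity score scale; a recalibrated model needs a recalibrated
  threshold.
* No structural or physicochemical descriptor encodings, and no
  upstream variant calling — the neoantigen pipeline starts from a
  mutation table.
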