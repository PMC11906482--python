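"""Synthetic peptide-MHC worlds with planted, recoverable structure.

A :class:`SyntheticWorld` holds a small set of artificial alleles, each
with a random pseudo-sequence and an anchor motif: a few peptide
positions (by default position 2 and the C-terminus, where real class-I
binding specificity concentrates) at which a small set of preferred
residues lowers the peptide's log-IC50 by a fixed energy bonus.

Generators emulate the three experimental data types the training
pipeline consumes:

* ``sample_ba``    — binding-affinity pairs with a log-normal IC50 noise
  model, clipped to [1, 50000] nM;
* ``sample_el``    — eluted-ligand tables: positives drawn with
  anchor-matching residues for a hidden true allele (multi-allele mode
  hides it inside a candidate set of 2-6), negatives sampled uniformly
  so a small fraction are true binders — the contamination the curation
  pipeline must remove.  Hidden truth goes to a separate sidecar frame,
  never into the visible table;
* ``sample_mutations`` — mutant-protein tables with planted bad rows
  (missing fields, silent mutations, duplicates) at known rates;
* ``sample_eval_pairs`` — held-out labelled pairs with noise-free
  ground-truth labels for evaluation.

Defaults are strongly separable (anchor bonus well above the noise SD)
so desk-scale models can recover the planted structure; ``hard_mode``
weakens the separation for robustness testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import RESIDUES
from .neoantigen import SELECTED_MUTATION_TYPES, _SUFFIX_TYPES

_LN_500 = math.log(500.0)
_LN_50000 = math.log(50000.0)


@dataclass(frozen=True)
class AnchorMotif:
    """One anchor position with its preferred residues and energy bonus
    (reduction of ln IC50 when matched)."""

    position: int  # 1-based peptide position
    residues: tuple
    bonus: float


@dataclass
class SyntheticWorld:
    """Ground-truth generative model for one simulation run."""

    alleles: dict  # name -> pseudo-sequence
    motifs: dict  # name -> list[AnchorMotif]
    peptide_length: int
    baseline_ln_ic50: float
    noise_sd: float
    seed: int

    def true_ln_ic50(self, peptide: str, allele: str) -> float:
        """Noise-free ln IC50 of a peptide against an allele."""
        total = self.baseline_ln_ic50
        for anchor in self.motifs[allele]:
            if peptide[anchor.position - 1] in anchor.residues:
                total -= anchor.bonus
        return total

    def is_true_binder(self, peptide: str, allele: str) -> bool:
        """Noise-free binder call at the 500 nM threshold."""
        return self.true_ln_ic50(peptide, allele) < _LN_500


def make_world(n_alleles: int = 2, peptide_length: int = 9, seed: int = 0,
               pseudo_len: int = 34, anchor_bonus: float = 3.2,
               n_preferred: int = 3, baseline_ic50: float = 25000.0,
               noise_sd: float = 0.4, hard_mode: bool = False,
               disjoint_motifs: bool = False) -> SyntheticWorld:
    """Build a deterministic synthetic world.

    Each allele receives a random pseudo-sequence and anchors at
    position 2 and the C-terminus with ``n_preferred`` preferred
    residues each; motifs are redrawn until pairwise distinct.  With
    ``disjoint_motifs`` the preferred residue sets are pairwise
    disjoint at every anchor position (well-separated specificities, so
    multi-allele deconvolution has an unambiguous answer); requires
    ``n_alleles * n_preferred <= 20``.
    """
    if n_alleles < 1:
        raise ValueError("need at least one allele")
    if disjoint_motifs and n_alleles * n_preferred > len(RESIDUES):
        raise ValueError("disjoint motifs need n_alleles * n_preferred <= 20")
    if hard_mode:
        anchor_bonus, noise_sd = 1.6, 0.9
    rng = np.random.default_rng(seed)
    residues = np.array(list(RESIDUES))
    anchor_positions = (2, peptide_length)

    alleles, motifs = {}, {}
    used_motifs = set()
    pools = {pos: list(RESIDUES) for pos in anchor_positions}
    for i in range(n_alleles):
        name = f"SYN{i + 1:02d}"
        alleles[name] = "".join(str(r) for r in
                                rng.choice(residues, size=pseudo_len))
        while True:
            anchors = []
            for pos in anchor_positions:
                pool = pools[pos]
                pick = sorted(str(r) for r in
                              rng.choice(pool, size=n_preferred,
                                         replace=False))
                anchors.append(AnchorMotif(position=pos,
                                           residues=tuple(pick),
                                           bonus=anchor_bonus))
            anchors = tuple(anchors)
            key = tuple((a.position, a.residues) for a in anchors)
            if key not in used_motifs:
                used_motifs.add(key)
                break
        if disjoint_motifs:
            for a in anchors:
                pools[a.position] = [r for r in pools[a.position]
                                     if r not in a.residues]
        motifs[name] = list(anchors)
    return SyntheticWorld(
        alleles=alleles, motifs=motifs, peptide_length=peptide_length,
        baseline_ln_ic50=math.log(baseline_ic50), noise_sd=noise_sd,
        seed=seed,
    )


def _random_peptides(rng, n: int, length: int) -> list[str]:
    mat = rng.integers(0, 20, size=(n, length))
    res = np.array(list(RESIDUES))
    return ["".join(row) for row in res[mat]]


def sample_ba(world: SyntheticWorld, n: int, seed: int = 0) -> pd.DataFrame:
    """Binding-affinity table: peptide, allele, ic50_nM.

    ln IC50 = baseline - sum(matched anchor bonuses) + N(0, noise_sd),
    clipped to [1, 50000] nM.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    names = sorted(world.alleles)
    peptides = _random_peptides(rng, n, world.peptide_length)
    alleles = [names[i] for i in rng.integers(0, len(names), size=n)]
    ln = np.array([world.true_ln_ic50(p, a) for p, a in zip(peptides, alleles)])
    ln = ln + rng.normal(0.0, world.noise_sd, size=n)
    ic50 = np.clip(np.exp(np.clip(ln, 0.0, _LN_50000)), 1.0, 50000.0)
    return pd.DataFrame({"peptide": peptides, "allele": alleles,
                         "ic50_nM": ic50})


def _binder_peptide(rng, world: SyntheticWorld, allele: str,
                    match_prob: float = 0.95) -> str:
    pep = list(_random_peptides(rng, 1, world.peptide_length)[0])
    for anchor in world.motifs[allele]:
        if rng.random() < match_prob:
            pep[anchor.position - 1] = anchor.residues[
                rng.integers(0, len(anchor.residues))
            ]
    return "".join(pep)


def sample_el(world: SyntheticWorld, n_pos: int, n_neg: int,
              multi_allele: bool = False, seed: int = 0,
              match_prob: float = 0.95):
    """Eluted-ligand table plus a hidden-truth sidecar.

    Visible columns: peptide, alleles (comma-joined candidate set),
    label.  Sidecar columns: true_allele (positives), true_binder
    (noise-free binder call against the sampled allele).  In
    multi-allele mode the candidate set has 2-6 alleles and always
    contains the hidden true allele.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("sizes must be >= 0")
    rng = np.random.default_rng(seed)
    names = sorted(world.alleles)
    rows, truth = [], []

    def _candidate_set(true_name: str) -> str:
        if not multi_allele or len(names) == 1:
            return true_name
        k = int(rng.integers(2, min(6, len(names)) + 1))
        others = [a for a in names if a != true_name]
        pick = list(rng.choice(others, size=k - 1, replace=False))
        return ",".join(sorted(pick + [true_name]))

    for _ in range(n_pos):
        true_name = names[rng.integers(0, len(names))]
        pep = _binder_peptide(rng, world, true_name, match_prob)
        rows.append((pep, _candidate_set(true_name), 1))
        truth.append((true_name, world.is_true_binder(pep, true_name)))
    for _ in range(n_neg):
        a = names[rng.integers(0, len(names))]
        pep = _random_peptides(rng, 1, world.peptide_length)[0]
        rows.append((pep, _candidate_set(a), 0))
        truth.append((a, world.is_true_binder(pep, a)))

    el = pd.DataFrame(rows, columns=["peptide", "alleles", "label"])
    sidecar = pd.DataFrame(truth, columns=["true_allele", "true_binder"])
    return el, sidecar


def sample_eval_pairs(world: SyntheticWorld, n_pos: int, n_neg: int,
                      seed: int = 0) -> pd.DataFrame:
    """Held-out labelled pairs with deterministic ground-truth labels.

    Positives are anchor-matched binders for their allele; negatives
    are uniform random peptides resampled until they are noise-free
    non-binders.  Columns: peptide, allele, label.
    """
    rng = np.random.default_rng(seed)
    names = sorted(world.alleles)
    rows = []
    for _ in range(n_pos):
        a = names[rng.integers(0, len(names))]
        pep = _binder_peptide(rng, world, a, match_prob=1.0)
        if not world.is_true_binder(pep, a):  # guaranteed by full match
            continue
        rows.append((pep, a, 1))
    for _ in range(n_neg):
        a = names[rng.integers(0, len(names))]
        while True:
            pep = _random_peptides(rng, 1, world.peptide_length)[0]
            if not world.is_true_binder(pep, a):
                break
        rows.append((pep, a, 0))
    return pd.DataFrame(rows, columns=["peptide", "allele", "label"])


def sample_mutations(world: SyntheticWorld, n_proteins: int, seed: int = 0,
                     frac_missing: float = 0.10, frac_unchanged: float = 0.10,
                     frac_duplicate: float = 0.05):
    """Mutation table with planted bad rows at fixed rates.

    Returns ``(table, plan)`` where the plan records how many rows were
    planted clean/missing/unchanged/duplicated and the exact expected
    survivor count after preprocessing.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    res = np.array(list(RESIDUES))
    types = sorted(SELECTED_MUTATION_TYPES)
    clean_rows = []
    for i in range(n_proteins):
        length = int(rng.integers(50, 201))
        wt = "".join(rng.choice(res, size=length))
        mtype = types[rng.integers(0, len(types))]
        pos = int(rng.integers(1, length + 1))
        if mtype in _SUFFIX_TYPES:
            suffix = "".join(rng.choice(res, size=length - pos + 1))
            while wt[pos - 1 :] == suffix:
                suffix = "".join(rng.choice(res, size=length - pos + 1))
            mut = wt[: pos - 1] + suffix
        else:
            alt = str(rng.choice([r for r in RESIDUES if r != wt[pos - 1]]))
            mut = wt[: pos - 1] + alt + wt[pos:]
        clean_rows.append((f"PROT{i:04d}", wt, mut, mtype, pos))

    n_missing = int(round(frac_missing * n_proteins))
    n_unchanged = int(round(frac_unchanged * n_proteins))
    n_duplicate = int(round(frac_duplicate * n_proteins))
    rows = [dict(zip(("protein_id", "wildtype_seq", "mutant_seq",
                      "mutation_type", "altered_pos"), r)) for r in clean_rows]
    for j in range(n_missing):
        length = int(rng.integers(50, 201))
        wt = "".join(rng.choice(res, size=length))
        rows.append({"protein_id": f"MISS{j:04d}", "wildtype_seq": wt,
                     "mutant_seq": None,
                     "mutation_type": types[rng.integers(0, len(types))],
                     "altered_pos": int(rng.integers(1, length + 1))})
    for j in range(n_unchanged):
        length = int(rng.integers(50, 201))
        wt = "".join(rng.choice(res, size=length))
        rows.append({"protein_id": f"SAME{j:04d}", "wildtype_seq": wt,
                     "mutant_seq": wt,
                     "mutation_type": types[rng.integers(0, len(types))],
                     "altered_pos": int(rng.integers(1, length + 1))})
    dup_idx = rng.integers(0, n_proteins, size=n_duplicate)
    for j in dup_idx:
        rows.append(dict(zip(("protein_id", "wildtype_seq", "mutant_seq",
                              "mutation_type", "altered_pos"),
                             clean_rows[j])))
    order = rng.permutation(len(rows))
    table = pd.DataFrame([rows[i] for i in order])
    plan = {
        "n_total": len(rows),
        "n_clean": n_proteins,
        "n_missing": n_missing,
        "n_unchanged": n_unchanged,
        "n_duplicate": n_duplicate,
        "n_expected_survivors": n_proteins,
    }
    return table, plan
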