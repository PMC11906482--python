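"""Neoantigen candidate pipeline: mutation table -> windows -> panel
scores -> threshold selection -> motif information matrices.

From a table of mutant protein sequences, sliding windows of lengths
8-11 that contain a mutated position are extracted as candidate
peptides; each candidate is scored by a binder-classification ensemble
against a panel of 20 common HLA class-I alleles; peptides whose mean
panel score exceeds a threshold (0.2 / 0.5 / 0.7) are selected; and
per-length Shannon sequence-logo matrices summarise the selected
peptides' residue preferences.

For missense and nonsense mutations only the single altered position
counts as mutated; for frameshift and nonstop mutations every position
from the first altered residue to the C-terminus is neo-sequence, so
any window overlapping that suffix qualifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import RESIDUES
from .train_eval import ensemble_predict

#: Mutation classes retained for candidate generation.
SELECTED_MUTATION_TYPES = frozenset({
    "Missense", "Nonsense", "Frame_Shift_Del", "Frame_Shift_Ins",
    "Splice_Site", "Intron", "Nonstop",
})

#: Mutation types whose alteration extends to the C-terminus.
_SUFFIX_TYPES = frozenset({"Frame_Shift_Del", "Frame_Shift_Ins", "Nonstop"})

WINDOW_LENGTHS = (8, 9, 10, 11)


def preprocess_mutations(records: pd.DataFrame) -> pd.DataFrame:
    """Filter a mutation table: drop rows with missing fields, rows
    whose mutant sequence equals the wildtype, and exact duplicates.
    Row order is preserved; never raises."""
    df = records.copy()
    required = ["protein_id", "wildtype_seq", "mutant_seq",
                "mutation_type", "altered_pos"]
    for col in required:
        if col not in df.columns:
            df[col] = np.nan
    df = df.dropna(subset=required)
    df = df[(df["wildtype_seq"].astype(str) != "")
            & (df["mutant_seq"].astype(str) != "")]
    df = df[df["mutant_seq"] != df["wildtype_seq"]]
    df = df.drop_duplicates(subset=required, keep="first")
    return df.reset_index(drop=True)


@dataclass(frozen=True)
class CandidatePeptide:
    """A mutation-overlapping window of the mutant protein."""

    sequence: str
    protein_id: str
    window_start: int  # 1-based in the mutant protein
    contains_altered: bool = True


def window_count(n: int, p: int, length: int) -> int:
    """Closed-form number of length-``length`` windows of an n-residue
    protein that contain position p: min(p, n-L+1) - max(1, p-L+1) + 1
    when positive, else 0."""
    lo = max(1, p - length + 1)
    hi = min(p, n - length + 1)
    return max(hi - lo + 1, 0)


def generate_mutant_windows(record, lengths=WINDOW_LENGTHS) -> list[CandidatePeptide]:
    """All sliding windows over the mutant protein that contain an
    altered position, deduplicated on (sequence, start, length).

    ``record``: mapping with protein_id, mutant_seq, mutation_type,
    altered_pos (1-based, mutant coordinates).
    """
    seq = str(record["mutant_seq"])
    n = len(seq)
    p = int(record["altered_pos"])
    mtype = str(record["mutation_type"])
    pid = str(record["protein_id"])
    if not 1 <= p <= n:
        raise ValueError(
            f"altered position {p} outside mutant sequence of length {n}"
        )
    # inclusive 1-based span of altered positions
    alt_lo, alt_hi = (p, n) if mtype in _SUFFIX_TYPES else (p, p)
    out, seen = [], set()
    for L in lengths:
        for s in range(1, n - L + 2):
            e = s + L - 1
            if e < alt_lo or s > alt_hi:
                continue
            key = (seq[s - 1 : e], s, L)
            if key in seen:
                continue
            seen.add(key)
            out.append(CandidatePeptide(sequence=key[0], protein_id=pid,
                                        window_start=s))
    return out


@dataclass
class PanelScoreMatrix:
    """Candidate peptides x panel alleles score matrix."""

    scores: pd.DataFrame  # index: peptide sequences, columns: alleles

    @property
    def mean_score(self) -> pd.Series:
        return self.scores.mean(axis=1)

    @property
    def peptides(self) -> list[str]:
        return list(self.scores.index)


def score_against_panel(peptides, panel_alleles, model,
                        pseudo_sequences: dict) -> PanelScoreMatrix:
    """Score every (peptide, panel allele) combination with the
    (classification) ensemble; entry (i, j) = ensemble score."""
    peptides = [p.sequence if isinstance(p, CandidatePeptide) else str(p)
                for p in peptides]
    panel_alleles = list(panel_alleles)
    for a in panel_alleles:
        if a not in pseudo_sequences:
            raise KeyError(f"panel allele {a!r} has no pseudo-sequence")
    # dedupe peptides, keep first-seen order
    uniq = list(dict.fromkeys(peptides))
    flat = pd.DataFrame(
        [(p, a) for p in uniq for a in panel_alleles],
        columns=["peptide", "allele"],
    )
    members = getattr(model, "members_", None)
    if members is not None:
        scores = ensemble_predict(members, flat)
    else:
        scores = np.asarray(model.predict(flat), dtype=np.float64)
    mat = scores.reshape(len(uniq), len(panel_alleles))
    return PanelScoreMatrix(
        scores=pd.DataFrame(mat, index=uniq, columns=panel_alleles)
    )


def select_high_scoring(matrix: PanelScoreMatrix, threshold: float) -> list[str]:
    """Peptides whose mean panel score strictly exceeds *threshold*.

    Selections nest: the 0.7 set is a subset of 0.5, which is a subset
    of 0.2."""
    mean = matrix.mean_score
    return [p for p, m in mean.items() if m > threshold]


@dataclass
class MotifMatrix:
    """Shannon sequence-logo summary of equal-length peptides.

    ``heights``: positions x 20 residues, bar heights in bits
    (frequency x positional information); ``information``: per-position
    information content log2(20) - H, in [0, log2 20].
    """

    heights: pd.DataFrame
    information: np.ndarray


def motif_matrix(peptides) -> MotifMatrix:
    """Information-content matrix of equal-length peptides (no
    pseudocounts): info(pos) = log2(20) - H(residue frequencies);
    bar height(pos, r) = freq(pos, r) * info(pos)."""
    peptides = [str(p) for p in peptides]
    if not peptides:
        raise ValueError("need at least one peptide")
    L = len(peptides[0])
    if any(len(p) != L for p in peptides):
        raise ValueError("mixed peptide lengths; group by length first")
    n = len(peptides)
    counts = np.zeros((L, 20), dtype=np.float64)
    res_index = {r: i for i, r in enumerate(RESIDUES)}
    for pep in peptides:
        for pos, ch in enumerate(pep):
            counts[pos, res_index[ch]] += 1.0
    freqs = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    info = math.log2(20) - entropy
    heights = freqs * info[:, None]
    return MotifMatrix(
        heights=pd.DataFrame(heights, columns=list(RESIDUES),
                             index=np.arange(1, L + 1)),
        information=info,
    )


def run_neoantigen_pipeline(mutations: pd.DataFrame, panel_alleles, model,
                            pseudo_sequences: dict,
                            thresholds=(0.2, 0.5, 0.7),
                            lengths=WINDOW_LENGTHS) -> dict:
    """End-to-end candidate pipeline.

    Returns a dict with the preprocessed table, candidate list, panel
    matrix, per-threshold selections, and per-length motif matrices for
    the 0.5-threshold selection (and above).
    """
    clean = preprocess_mutations(mutations)
    clean = clean[clean["mutation_type"].isin(SELECTED_MUTATION_TYPES)]
    candidates: list[CandidatePeptide] = []
    for _, row in clean.iterrows():
        candidates.extend(generate_mutant_windows(row, lengths=lengths))
    result = {"mutations": clean, "candidates": candidates,
              "matrix": None, "selected": {}, "motifs": {}}
    if not candidates:
        return result
    matrix = score_against_panel(candidates, panel_alleles, model,
                                 pseudo_sequences)
    result["matrix"] = matrix
    for thr in thresholds:
        result["selected"][thr] = select_high_scoring(matrix, thr)
    for thr in [t for t in thresholds if t >= 0.5] or list(thresholds):
        by_len: dict[int, MotifMatrix] = {}
        sel = result["selected"].get(thr, [])
        for L in sorted({len(p) for p in sel}):
            by_len[L] = motif_matrix([p for p in sel if len(p) == L])
        result["motifs"][thr] = by_len
    return result
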