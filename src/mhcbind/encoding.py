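"""Numeric encodings of peptide and MHC pseudo-sequences.

Peptides and allele pseudo-sequences are turned into the fixed-shape
arrays the network consumes:

* one-hot: ``(L, 21)`` — 20 canonical residues plus a padding symbol
  (``-``) whose row is all-zero, so padded positions contribute nothing;
* BLOSUM62: ``(L, 20)`` — each residue replaced by its substitution-score
  row against the 20 canonical residues (padding rows are zero);
* the concatenated peptide+pseudo-sequence one-hot matrix, reinterpreted
  as a single-channel 2D image for the 2D-convolution branch.

Peptides are middle-padded to a fixed length (pads inserted after
position ``ceil(L/2)``) so that both the N- and C-terminal anchor
positions keep a stable index across peptide lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: The 20 canonical amino acids, alphabetical one-letter codes.
RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
#: Padding symbol; encoded as an all-zero row in every encoding.
PAD = "-"
#: Full 21-symbol alphabet valid after padding.
ALPHABET = RESIDUES + PAD

_RES_INDEX = {r: i for i, r in enumerate(RESIDUES)}

_blosum_rows = None


def _blosum62_rows() -> np.ndarray:
    """(21, 20) array: row i = BLOSUM62 scores of residue i vs the 20
    canonical residues; final (padding) row is zero."""
    global _blosum_rows
    if _blosum_rows is None:
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        rows = np.zeros((21, 20), dtype=np.float64)
        for i, a in enumerate(RESIDUES):
            for j, b in enumerate(RESIDUES):
                rows[i, j] = mat[a, b]
        _blosum_rows = rows
    return _blosum_rows


def validate_sequence(seq: str, allow_pad: bool = False) -> None:
    """Raise ``ValueError`` naming the first offending position if *seq*
    contains a character outside the allowed alphabet."""
    allowed = ALPHABET if allow_pad else RESIDUES
    for pos, ch in enumerate(seq):
        if ch not in allowed:
            raise ValueError(
                f"invalid residue {ch!r} at position {pos} in sequence {seq!r}"
            )


def pad_sequence(seq: str, target_length: int) -> str:
    """Middle-pad *seq* with ``-`` to *target_length*.

    Pads are inserted after position ``ceil(L/2)`` so both termini are
    preserved in place.
    """
    validate_sequence(seq)
    if len(seq) > target_length:
        raise ValueError(
            f"sequence of length {len(seq)} exceeds target length {target_length}"
        )
    n_pad = target_length - len(seq)
    cut = math.ceil(len(seq) / 2)
    return seq[:cut] + PAD * n_pad + seq[cut:]


def encode_one_hot(seq: str) -> np.ndarray:
    """One-hot encode a (possibly padded) sequence as ``(L, 21)``.

    Residue rows have a single 1; padding rows are all-zero (the 21st
    column is reserved for the pad symbol and never set).
    """
    validate_sequence(seq, allow_pad=True)
    out = np.zeros((len(seq), 21), dtype=np.float64)
    for i, ch in enumerate(seq):
        if ch != PAD:
            out[i, _RES_INDEX[ch]] = 1.0
    return out


def encode_blosum62(seq: str) -> np.ndarray:
    """BLOSUM62-encode a (possibly padded) sequence as ``(L, 20)``."""
    validate_sequence(seq, allow_pad=True)
    rows = _blosum62_rows()
    idx = np.array([20 if ch == PAD else _RES_INDEX[ch] for ch in seq])
    return rows[idx].copy()


def decode_one_hot(matrix: np.ndarray) -> str:
    """Inverse of :func:`encode_one_hot`; all-zero rows decode to ``-``."""
    chars = []
    for row in matrix:
        if row.sum() == 0:
            chars.append(PAD)
        else:
            chars.append(RESIDUES[int(np.argmax(row))])
    return "".join(chars)


@dataclass
class EncodedPair:
    """Fused numeric encoding of one peptide + allele pseudo-sequence."""

    onehot_pair: np.ndarray  # (max_pep_len + pseudo_len, 21)
    blosum_peptide: np.ndarray  # (max_pep_len, 20)

    @property
    def image_view(self) -> np.ndarray:
        """The one-hot pair matrix as a 1-channel 2D image (1, H, W)."""
        return self.onehot_pair[np.newaxis, :, :]


def build_pair_input(
    peptide: str, pseudo_sequence: str, max_pep_len: int
) -> EncodedPair:
    """Encode one (peptide, allele pseudo-sequence) pair.

    The peptide is middle-padded to *max_pep_len*, concatenated with the
    pseudo-sequence, and one-hot encoded; the BLOSUM62 block covers the
    padded peptide only.
    """
    validate_sequence(pseudo_sequence)
    padded = pad_sequence(peptide, max_pep_len)
    onehot = encode_one_hot(padded + pseudo_sequence)
    blosum = encode_blosum62(padded)
    return EncodedPair(onehot_pair=onehot, blosum_peptide=blosum)


def encode_dataset(
    peptides,
    alleles,
    pseudo_sequences: dict,
    max_pep_len: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised encoding of a whole dataset.

    Returns ``(onehot, blosum)`` with shapes ``(n, max_pep_len +
    pseudo_len, 21)`` and ``(n, max_pep_len, 20)``.  Identical
    (peptide, allele) rows are encoded once and broadcast.
    """
    peptides = list(peptides)
    alleles = list(alleles)
    if len(peptides) != len(alleles):
        raise ValueError("peptides and alleles must have equal length")
    if not peptides:
        raise ValueError("empty dataset")
    pseudo_lens = {len(v) for v in pseudo_sequences.values()}
    if len(pseudo_lens) != 1:
        raise ValueError("all pseudo-sequences must share one length")
    pseudo_len = pseudo_lens.pop()

    pep_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    allele_cache: dict[str, np.ndarray] = {}
    n = len(peptides)
    onehot = np.zeros((n, max_pep_len + pseudo_len, 21), dtype=np.float64)
    blosum = np.zeros((n, max_pep_len, 20), dtype=np.float64)
    for i, (pep, alle) in enumerate(zip(peptides, alleles)):
        if pep not in pep_cache:
            padded = pad_sequence(pep, max_pep_len)
            pep_cache[pep] = (encode_one_hot(padded), encode_blosum62(padded))
        if alle not in allele_cache:
            try:
                ps = pseudo_sequences[alle]
            except KeyError:
                raise KeyError(f"allele {alle!r} has no pseudo-sequence") from None
            allele_cache[alle] = encode_one_hot(ps)
        po, pb = pep_cache[pep]
        onehot[i, :max_pep_len] = po
        onehot[i, max_pep_len:] = allele_cache[alle]
        blosum[i] = pb
    return onehot, blosum
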