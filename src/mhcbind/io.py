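"""Readers and writers for the pipeline's table dialects.

All tables are tab-separated with a header row; lines starting with
``#`` and blank lines are skipped.  Peptides are upper-cased on read.
Schema violations raise with ``file:line:column`` context.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

#: column name -> required dtype caster, per schema
SCHEMAS = {
    "ba": {"peptide": str, "allele": str, "ic50_nM": float},
    "el": {"peptide": str, "alleles": str, "label": int},
    "pseudo": {"allele": str, "pseudo_sequence": str},
    "training": {"peptide": str, "allele": str, "label": int,
                 "provenance": str, "fold": int},
    "mutations": {"protein_id": str, "wildtype_seq": str, "mutant_seq": str,
                  "mutation_type": str, "altered_pos": int},
    "predictions": {"peptide": str, "allele": str, "score": float},
}

_PEPTIDE_COLUMNS = ("peptide", "pseudo_sequence", "wildtype_seq", "mutant_seq")


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a TSV table against a named schema."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    spec = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    header = None
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                missing = [c for c in spec if c not in header]
                if missing:
                    raise ValueError(
                        f"{path}:{lineno}: missing columns {missing}"
                    )
                continue
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}:{len(parts)}: expected "
                    f"{len(header)} columns, got {len(parts)}"
                )
            rec = {}
            for col, value in zip(header, parts):
                caster = spec.get(col, str)
                try:
                    value = caster(value)
                except ValueError:
                    colno = header.index(col) + 1
                    raise ValueError(
                        f"{path}:{lineno}:{colno}: cannot parse "
                        f"{value!r} as {caster.__name__} for column {col!r}"
                    ) from None
                if col in _PEPTIDE_COLUMNS and isinstance(value, str):
                    value = value.upper()
                rec[col] = value
            records.append(rec)
    if header is None:
        raise ValueError(f"{path}: empty table (no header)")
    return pd.DataFrame(records, columns=header)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a DataFrame as TSV (no index)."""
    df.to_csv(path, sep="\t", index=False)


def read_pseudo_table(path) -> dict:
    """Load an allele pseudo-sequence TSV into a dict; enforces unique
    allele names and a single pseudo-sequence length."""
    df = read_table(path, "pseudo")
    if df["allele"].duplicated().any():
        dup = df["allele"][df["allele"].duplicated()].iloc[0]
        raise ValueError(f"duplicate allele name {dup!r} in {path}")
    table = dict(zip(df["allele"], df["pseudo_sequence"]))
    if len({len(v) for v in table.values()}) > 1:
        raise ValueError(f"pseudo-sequences in {path} have mixed lengths")
    return table


def read_fasta(path) -> dict:
    """Read a protein FASTA (wrapped or unwrapped) as id -> sequence."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(s), id=str(name), description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def default_panel_path() -> Path:
    """Bundled 20-allele class-I panel (synthetic pseudo-sequences)."""
    return Path(__file__).parent / "data" / "panel_class1_synthetic.tsv"


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, seed: int, inputs=()) -> None:
    """Record config, seed, input checksums and versions for re-runs."""
    from . import __version__

    manifest = {
        "config": config,
        "seed": seed,
        "inputs": {str(p): file_checksum(p) for p in inputs},
        "versions": {
            "mhcbind": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
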