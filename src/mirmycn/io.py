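"""Readers and writers for the pipeline's plain-text formats.

Matrices travel as TSV (first column = feature id, header = sample ids),
plate tables as CSV, gene sets as GMT, sequences as FASTA.  Report
writers prepend a comment header with version, config hash and seed so
every artifact is self-describing.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO


def read_plate_table(path) -> pd.DataFrame:
    """Reporter-plate CSV: screen_id, replicate, mirna_id, firefly, renilla."""
    df = pd.read_csv(path, comment="#")
    required = {"screen_id", "replicate", "mirna_id", "firefly", "renilla"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_matrix(path) -> pd.DataFrame:
    """Feature x sample TSV matrix with the feature id in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_matrix(df: pd.DataFrame, path, header: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t")


def read_annotations(path) -> pd.DataFrame:
    """Sample sidecar TSV: sample_id, genotype, time_weeks[, group]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing sample_id column")
    return df.set_index("sample_id")


def read_fasta(path) -> dict[str, str]:
    """FASTA file as an id -> sequence mapping (uppercase)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")


def read_mapping(path) -> dict[str, str]:
    """Two-column TSV mapping murine assay id -> human miRNA id."""
    df = pd.read_csv(path, sep="\t", comment="#", header=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: mapping needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_json(obj, path, **meta) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(meta)
    payload.update(obj if isinstance(obj, dict) else {"result": obj})
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
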