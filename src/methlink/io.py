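"""Readers and writers for the plain-text formats shared by all stages.

Conventions
-----------
* genomic intervals are 0-based half-open, BED-style, everywhere;
* tables are tab-separated with a header row;
* sparse cell matrices are MatrixMarket triplets (1-based indices per the
  standard) with ``<name>.rows.txt`` / ``<name>.cols.txt`` sidecars;
* position weight matrices are JASPAR-style text plus a sidecar table for
  the log-odds score thresholds and background base frequencies.

Every reader raises ``FormatError`` with a line number on malformed input.
"""

from __future__ import annotations

import io as _stdio
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import networkx as nx
from scipy import sparse
from scipy.io import mmread, mmwrite
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------

def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise FormatError(f"{path}: {exc}") from exc


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# BED (0-based half-open; extra named columns allowed after the first three)
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, extra_cols: Iterable[str] = ()) -> pd.DataFrame:
    """Read a BED file into chrom/start/end plus ``extra_cols``.

    Lines whose interval is empty or inverted (end <= start) are rejected.
    """
    extra = list(extra_cols)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3 + len(extra):
                raise FormatError(f"{path}:{lineno}: expected >= {3 + len(extra)} columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise FormatError(f"{path}:{lineno}: zero-length or inverted interval [{start}, {end})")
            rows.append([parts[0], start, end, *parts[3 : 3 + len(extra)]])
    return pd.DataFrame(rows, columns=["chrom", "start", "end", *extra])


def write_bed(df: pd.DataFrame, path: str | Path, extra_cols: Iterable[str] = ()) -> None:
    cols = ["chrom", "start", "end", *extra_cols]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file; duplicate members within a set are collapsed,
    preserving first occurrence order."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT needs name, description and >= 1 member")
            name = parts[0]
            members = [g for g in parts[2:] if g]
            sets[name] = list(dict.fromkeys(members))
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path, description: str = "na") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# ---------------------------------------------------------------------------
# MatrixMarket triplets with row/column name sidecars
# ---------------------------------------------------------------------------

def write_mtx(matrix, rows: Iterable[str], cols: Iterable[str], out_dir: str | Path, name: str) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(np.asarray(matrix) if not sparse.issparse(matrix) else matrix)
    # integer field keeps count/binary matrices byte-stable across runs
    with open(out_dir / f"{name}.mtx", "wb") as fh:
        mmwrite(fh, mat.tocoo(), field="integer" if np.issubdtype(mat.dtype, np.integer) else None)
    (out_dir / f"{name}.rows.txt").write_text("\n".join(rows) + "\n")
    (out_dir / f"{name}.cols.txt").write_text("\n".join(cols) + "\n")


def read_mtx(out_dir: str | Path, name: str) -> pd.DataFrame:
    out_dir = Path(out_dir)
    mat = mmread(out_dir / f"{name}.mtx").tocsr()
    rows = (out_dir / f"{name}.rows.txt").read_text().splitlines()
    cols = (out_dir / f"{name}.cols.txt").read_text().splitlines()
    return pd.DataFrame(mat.toarray(), index=rows, columns=cols)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# JASPAR-style PWMs (+ sidecar with thresholds and background)
# ---------------------------------------------------------------------------

def write_motifs(motif_list, path: str | Path) -> None:
    """Write motifs as JASPAR text plus ``<path>.meta.tsv`` with the
    log-odds thresholds and background frequencies."""
    from .chromatin import Motif  # local import to avoid a cycle

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = []
    meta_rows = []
    for m in motif_list:
        counts = {base: list(np.round(m.pwm[i] * 1000, 3)) for i, base in enumerate("ACGT")}
        rec = bio_motifs.Motif(alphabet="ACGT", counts=counts)
        rec.matrix_id = m.name
        rec.name = m.name
        records.append(rec)
        meta_rows.append([m.name, m.threshold, *m.background])
    path.write_text(bio_motifs.write(records, "jaspar"))
    meta = pd.DataFrame(meta_rows, columns=["name", "threshold", "bg_A", "bg_C", "bg_G", "bg_T"])
    write_tsv(meta, str(path) + ".meta.tsv")


def read_motifs(path: str | Path):
    from .chromatin import Motif

    path = Path(path)
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    meta = read_tsv(str(path) + ".meta.tsv").set_index("name")
    out = []
    for rec in records:
        counts = np.array([rec.counts[b] for b in "ACGT"], dtype=float)
        pwm = counts / counts.sum(axis=0, keepdims=True)
        name = rec.name or rec.matrix_id
        row = meta.loc[name]
        out.append(
            Motif(
                name=name,
                pwm=pwm,
                background=np.array([row.bg_A, row.bg_C, row.bg_G, row.bg_T], dtype=float),
                threshold=float(row.threshold),
            )
        )
    return out


# ---------------------------------------------------------------------------
# GraphML + JSON helpers
# ---------------------------------------------------------------------------

def write_graphml(graph: nx.DiGraph, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(graph, str(path))


def read_graphml(path: str | Path) -> nx.DiGraph:
    return nx.read_graphml(str(path))


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
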