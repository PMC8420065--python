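"""Tabular I/O for every artifact the pipeline touches.

One dialect everywhere: tab-separated UTF-8 with a header line; empty cells
and the literal string ``NA`` denote missing values. Genomic coordinates are
1-based in input files (HM450K manifest / GENCODE convention) and converted
exactly once, here, to 0-based half-open internal coordinates. BED output is
0-based half-open as usual.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, InvariantError

MISSING_TOKENS = ("", "NA")


def _read_rows(path: str | Path, expected_columns: Sequence[str] | None = None):
    """Yield (line_number, dict) rows of a TSV file; validate the header."""
    path = Path(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header line")
        if expected_columns is not None:
            missing = [c for c in expected_columns if c not in header]
            if missing:
                raise FormatError(f"{path}: missing required column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            yield lineno, dict(zip(header, row))


def _parse_int(value: str, path, lineno: int, column: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: non-integer {column} {value!r}")


# ---------------------------------------------------------------------------
# probe manifests and gene models
# ---------------------------------------------------------------------------

PROBE_COLUMNS = ["probe_id", "chrom", "position", "is_enhancer"]
GENE_COLUMNS = ["gene_id", "gene_type", "chrom", "strand", "tss"]

_TRUE = {"1", "true", "True", "TRUE", "yes"}
_FALSE = {"0", "false", "False", "FALSE", "no"}


def read_probe_manifest(path: str | Path) -> pd.DataFrame:
    """Read a CpG probe manifest.

    Returns a DataFrame with columns probe_id, chrom, pos (0-based) and
    is_enhancer (bool). Duplicate probe ids are rejected.
    """
    records = []
    seen: set[str] = set()
    for lineno, row in _read_rows(path, PROBE_COLUMNS):
        pid = row["probe_id"]
        if pid in seen:
            raise FormatError(f"{path}:{lineno}: duplicate probe_id {pid!r}")
        seen.add(pid)
        if not row["chrom"]:
            raise FormatError(f"{path}:{lineno}: empty chrom")
        pos1 = _parse_int(row["position"], path, lineno, "position")
        if pos1 < 1:
            raise FormatError(f"{path}:{lineno}: position must be >= 1, got {pos1}")
        flag = row["is_enhancer"]
        if flag in _TRUE:
            enh = True
        elif flag in _FALSE:
            enh = False
        else:
            raise FormatError(f"{path}:{lineno}: bad is_enhancer value {flag!r}")
        records.append((pid, row["chrom"], pos1 - 1, enh))
    return pd.DataFrame(records, columns=["probe_id", "chrom", "pos", "is_enhancer"])


def write_probe_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    out = manifest.copy()
    out["position"] = out.pop("pos") + 1
    out["is_enhancer"] = out["is_enhancer"].map({True: "1", False: "0"})
    out[PROBE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Read gene models (id, type in {lncRNA, mRNA}, chrom, strand, 1-based TSS)."""
    records = []
    seen: set[str] = set()
    for lineno, row in _read_rows(path, GENE_COLUMNS):
        gid = row["gene_id"]
        if gid in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene_id {gid!r}")
        seen.add(gid)
        if row["gene_type"] not in ("lncRNA", "mRNA"):
            raise FormatError(f"{path}:{lineno}: bad gene_type {row['gene_type']!r}")
        if row["strand"] not in ("+", "-"):
            raise FormatError(f"{path}:{lineno}: bad strand {row['strand']!r}")
        tss1 = _parse_int(row["tss"], path, lineno, "tss")
        records.append((gid, row["gene_type"], row["chrom"], row["strand"], tss1 - 1))
    return pd.DataFrame(records, columns=["gene_id", "gene_type", "chrom", "strand", "tss"])


def write_gene_models(genes: pd.DataFrame, path: str | Path) -> None:
    out = genes.copy()
    out["tss"] = out["tss"] + 1
    out[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# numeric matrices
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a features x samples matrix; NaN marks missing cells.

    First column is the feature id, the header carries sample ids. Ragged
    rows and duplicate row/column ids are format errors.
    """
    path = Path(path)
    index = []
    data = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file")
        samples = header[1:]
        if len(set(samples)) != len(samples):
            raise FormatError(f"{path}: duplicate sample ids in header")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            index.append(row[0])
            values = []
            for col, cell in zip(samples, row[1:]):
                if cell in MISSING_TOKENS:
                    values.append(np.nan)
                else:
                    try:
                        values.append(float(cell))
                    except ValueError:
                        raise FormatError(f"{path}:{lineno}: non-numeric cell {cell!r}")
            data.append(values)
    if len(set(index)) != len(index):
        raise FormatError(f"{path}: duplicate row ids")
    return pd.DataFrame(data, index=pd.Index(index, name=header[0] or "feature"),
                        columns=samples, dtype=float)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA", index_label=matrix.index.name or "feature")


# ---------------------------------------------------------------------------
# edge lists, survival tables, sample groups
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, expected_columns: Sequence[str]) -> pd.DataFrame:
    """Read a TSV edge table with the named columns, de-duplicated on those
    columns preserving first occurrence."""
    records = [
        tuple(row[c] for c in expected_columns) for _, row in _read_rows(path, expected_columns)
    ]
    frame = pd.DataFrame(records, columns=list(expected_columns))
    return frame.drop_duplicates(keep="first").reset_index(drop=True)


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_survival(path: str | Path) -> pd.DataFrame:
    """Read per-sample follow-up records (sample_id, time, event)."""
    records = []
    for lineno, row in _read_rows(path, ["sample_id", "time", "event"]):
        try:
            t = float(row["time"])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric time {row['time']!r}")
        if t <= 0:
            raise FormatError(f"{path}:{lineno}: time must be > 0, got {t}")
        if row["event"] in _TRUE:
            ev = True
        elif row["event"] in _FALSE:
            ev = False
        else:
            raise FormatError(f"{path}:{lineno}: bad event flag {row['event']!r}")
        records.append((row["sample_id"], t, ev))
    frame = pd.DataFrame(records, columns=["sample_id", "time", "event"])
    if frame["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    return frame


def write_survival(surv: pd.DataFrame, path: str | Path) -> None:
    out = surv.copy()
    out["event"] = out["event"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_sample_groups(path: str | Path) -> pd.Series:
    records = {}
    for lineno, row in _read_rows(path, ["sample_id", "group"]):
        if row["group"] not in ("tumor", "normal"):
            raise FormatError(f"{path}:{lineno}: bad group {row['group']!r}")
        if row["sample_id"] in records:
            raise FormatError(f"{path}:{lineno}: duplicate sample {row['sample_id']!r}")
        records[row["sample_id"]] = row["group"]
    return pd.Series(records, name="group")


def write_sample_groups(groups: pd.Series, path: str | Path) -> None:
    frame = groups.rename("group").rename_axis("sample_id").reset_index()
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> members..."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, _desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set {name!r}")
            sets[name] = set(members)
    return sets


def write_gmt(sets: dict[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "."] + sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# regions (BED) and networks (edge-list TSV + GraphML)
# ---------------------------------------------------------------------------

def write_regions_bed(regions, path: str | Path) -> None:
    """Write merged enhancer regions as 4-column BED sorted by (chrom, start)."""
    rows = []
    for r in regions:
        if r.start >= r.end:
            raise InvariantError(f"region {r.region_id}: start {r.start} >= end {r.end}")
        rows.append((r.chrom, r.start, r.end, r.region_id))
    rows.sort(key=lambda t: (t[0], t[1]))
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, start, end, rid in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{rid}\n")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, path, named_key_ids=True)


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)
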