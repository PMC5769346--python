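"""Readers and writers: OTU tables (TSV / BIOM), taxonomy, networks, matrices.

TSV tables may have OTUs as rows (the QIIME convention, often with a
``#OTU ID`` header and an optional trailing ``taxonomy`` column) or samples
as rows; orientation is auto-detected from the header with an explicit
override. BIOM is supported in both common encodings: 1.0 (JSON) and 2.1
(HDF5). Networks round-trip through GraphML (node attributes ``domain``,
``phylum``, ``lineage``; edge attribute ``partial_correlation``) and a plain
edge-list TSV.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .inference import AssociationNetwork
from .preprocess import OtuTable

__all__ = [
    "read_otu_table",
    "read_taxonomy",
    "write_otu_table",
    "write_matrix",
    "write_network",
    "read_network",
    "write_edge_list",
]

def jsonify(obj):
    """Recursively make an object strict-JSON safe (NaN/inf -> null)."""
    if isinstance(obj, dict):
        return {k: jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonify(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        return float(obj) if np.isfinite(obj) else None
    return obj


_OTU_HEADER = re.compile(r"otu|feature|observation", re.IGNORECASE)
_SAMPLE_HEADER = re.compile(r"sample", re.IGNORECASE)
_TAXONOMY_COL = re.compile(r"taxonomy|lineage|consensus", re.IGNORECASE)


def _coerce_counts(df: pd.DataFrame, path: str) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=np.int64)
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (np.abs(numeric - np.round(numeric)) > 1e-9)
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-integer count at row {row!r}, column {col!r} in {path}"
            )
        out[col] = np.round(numeric).astype(np.int64)
    return out


def read_otu_table(
    path: str | Path,
    domain_label: str = "",
    orientation: str = "auto",
    taxonomy: dict[str, str] | None = None,
) -> OtuTable:
    """Read an OTU count table from TSV or BIOM (1.0 JSON / 2.1 HDF5).

    ``orientation`` applies to TSV only: ``"otus_as_rows"``,
    ``"samples_as_rows"``, or ``"auto"`` (header heuristic — an index header
    matching OTU/feature/observation means OTUs as rows, matching "sample"
    means samples as rows; otherwise the QIIME convention, OTUs as rows, is
    assumed). An embedded taxonomy column or BIOM observation metadata is
    attached automatically; an explicit ``taxonomy`` map takes precedence.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".biom":
        table = _read_biom(path, domain_label)
    else:
        table = _read_tsv(path, domain_label, orientation)
    if taxonomy:
        table.taxonomy.update(
            {k: v for k, v in taxonomy.items() if k in set(table.otu_ids)}
        )
    return table


def _read_tsv(path: Path, domain_label: str, orientation: str) -> OtuTable:
    # leading "# key: value" provenance lines are skipped; a "#OTU ID" header
    # (no space after the hash) is kept
    n_skip = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("# ") or line.strip() == "#":
                n_skip += 1
            else:
                break
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=n_skip, dtype=str)
    # QIIME files often start with a '# Constructed from biom file' line
    if str(df.index[0]).startswith("#") and df.iloc[0].isna().all():
        df = df.iloc[1:]
    df.index = df.index.astype(str)
    df.index.name = (df.index.name or "").lstrip("#").strip()

    tax_col = next((c for c in df.columns if _TAXONOMY_COL.fullmatch(str(c).strip())), None)
    embedded_tax: dict[str, str] = {}
    if tax_col is not None:
        embedded_tax = df[tax_col].dropna().to_dict()
        df = df.drop(columns=[tax_col])

    header = df.index.name or ""
    if orientation == "auto":
        if _OTU_HEADER.search(header):
            orientation = "otus_as_rows"
        elif _SAMPLE_HEADER.search(header):
            orientation = "samples_as_rows"
        else:
            orientation = "otus_as_rows"
    if orientation == "otus_as_rows":
        counts = _coerce_counts(df, str(path)).T  # -> samples x OTUs
    elif orientation == "samples_as_rows":
        counts = _coerce_counts(df, str(path))
        if embedded_tax:  # taxonomy column only makes sense with OTU rows
            embedded_tax = {}
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    return OtuTable(counts=counts, domain_label=domain_label, taxonomy=embedded_tax)


def _read_biom(path: Path, domain_label: str) -> OtuTable:
    with open(path, "rb") as fh:
        head = fh.read(8)
    if head.startswith(b"\x89HDF"):
        return _read_biom_hdf5(path, domain_label)
    return _read_biom_json(path, domain_label)


def _lineage_from_meta(meta) -> str | None:
    if meta is None:
        return None
    tax = meta.get("taxonomy") if isinstance(meta, dict) else None
    if tax is None:
        return None
    if isinstance(tax, (list, tuple)):
        return "; ".join(str(t) for t in tax)
    return str(tax)


def _read_biom_json(path: Path, domain_label: str) -> OtuTable:
    with open(path) as fh:
        doc = json.load(fh)
    n_rows, n_cols = doc["shape"]
    otu_ids = [str(r["id"]) for r in doc["rows"]]
    sample_ids = [str(c["id"]) for c in doc["columns"]]
    mat = np.zeros((n_rows, n_cols), dtype=np.int64)
    if doc.get("matrix_type") == "dense":
        mat = np.asarray(doc["data"], dtype=np.int64)
    else:
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = int(v)
    taxonomy = {}
    for r in doc["rows"]:
        lin = _lineage_from_meta(r.get("metadata"))
        if lin:
            taxonomy[str(r["id"])] = lin
    counts = pd.DataFrame(mat.T, index=sample_ids, columns=otu_ids)
    return OtuTable(counts=counts, domain_label=domain_label, taxonomy=taxonomy)


def _read_biom_hdf5(path: Path, domain_label: str) -> OtuTable:
    import h5py
    from scipy.sparse import csr_matrix

    with h5py.File(path, "r") as f:
        otu_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["observation/ids"][:]]
        sample_ids = [x.decode() if isinstance(x, bytes) else str(x) for x in f["sample/ids"][:]]
        data = f["observation/matrix/data"][:]
        indices = f["observation/matrix/indices"][:]
        indptr = f["observation/matrix/indptr"][:]
        mat = csr_matrix((data, indices, indptr), shape=(len(otu_ids), len(sample_ids))).toarray()
        taxonomy = {}
        if "observation/metadata/taxonomy" in f:
            tax = f["observation/metadata/taxonomy"][:]
            for oid, row in zip(otu_ids, tax):
                parts = [p.decode() if isinstance(p, bytes) else str(p) for p in np.atleast_1d(row)]
                taxonomy[oid] = "; ".join(parts)
    counts = pd.DataFrame(np.asarray(np.round(mat), dtype=np.int64).T,
                          index=sample_ids, columns=otu_ids)
    return OtuTable(counts=counts, domain_label=domain_label, taxonomy=taxonomy)


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read a two-column (OTU id, lineage) TSV; extra columns ignored."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", header=None)
    if df.shape[1] < 2:
        raise ValueError("taxonomy file needs at least two tab-separated columns")
    first = str(df.iloc[0, 0]).lower()
    if _OTU_HEADER.search(first) or first in ("id", "otu"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_otu_table(table: OtuTable, path: str | Path, provenance: dict | None = None) -> None:
    """Write counts as a QIIME-style TSV (OTUs as rows), with provenance comments."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        df = table.counts.T
        df.index.name = "#OTU ID"
        df.to_csv(fh, sep="\t")


def write_matrix(values: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> None:
    """Write a real-valued matrix (CLR, composition) as TSV with comments."""
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}: {val}\n")
        values.to_csv(fh, sep="\t", float_format="%.12g")


def write_network(net: AssociationNetwork, path: str | Path, fmt: str = "graphml") -> None:
    """Write a network as GraphML or an edge-list TSV.

    GraphML keeps node attributes (domain, phylum, lineage, otu_id) and edge
    attributes (partial_correlation, sign); edge lists store
    ``source  target  partial_correlation  sign``.
    """
    path = Path(path)
    if fmt == "graphml":
        g = nx.Graph()
        for n, d in net.graph.nodes(data=True):
            g.add_node(str(n), **{k: ("" if v is None else v) for k, v in d.items()})
        for u, v, d in net.graph.edges(data=True):
            g.add_edge(str(u), str(v), partial_correlation=float(d["partial_correlation"]),
                       weight=float(d.get("weight", d["partial_correlation"])),
                       sign=int(d.get("sign", 1 if d["partial_correlation"] > 0 else -1)))
        nx.write_graphml(g, path)
    elif fmt == "edgelist":
        write_edge_list(net, path)
    else:
        raise ValueError("fmt must be 'graphml' or 'edgelist'")


def write_edge_list(net: AssociationNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tpartial_correlation\tsign\n")
        for u, v, d in sorted(net.graph.edges(data=True)):
            rho = d["partial_correlation"]
            fh.write(f"{u}\t{v}\t{rho:.12g}\t{d.get('sign', 1 if rho > 0 else -1)}\n")


def read_network(path: str | Path) -> AssociationNetwork:
    """Read a GraphML network back into an :class:`AssociationNetwork`."""
    g = nx.read_graphml(Path(path))
    out = nx.Graph()
    for n, d in g.nodes(data=True):
        out.add_node(str(n), **d)
    for u, v, d in g.edges(data=True):
        rho = float(d.get("partial_correlation", d.get("weight", 0.0)))
        out.add_edge(str(u), str(v), partial_correlation=rho, weight=rho,
                     sign=int(d.get("sign", 1 if rho > 0 else -1)))
    return AssociationNetwork(graph=out)
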