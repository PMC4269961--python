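"""Readers and writers for every external format the toolkit touches.

Formats
-------
- gene annotation: headerless BED-like TSV ``chrom  start  end  symbol`` (extra
  columns ignored); 0-based half-open coordinates
- expression matrix: TSV with a header row of tissue names and gene symbols in
  the first column
- interaction network: 2-column TSV edge list; undirected; self-loops are
  dropped (with a logged count), duplicate edges collapsed
- pathway gene sets: GMT (``name<TAB>description<TAB>member...``)
- CNV calls: headerless TSV ``patient_id  chrom  start  end  dosage``
- benign-variant catalog: headerless TSV ``chrom  start  end  frequency``
- reports: JSON (full evidence) and flat TSV, byte-identical across reruns on
  identical inputs (sorted keys and records, no timestamps in the payload)

Every reader enforces the domain-type invariants and raises
:class:`~cytoprior.errors.ParseError` / :class:`~cytoprior.errors.ValidationError`
with a 1-based line number where applicable. Read -> write -> read is the
identity for every format (for networks, identity on the edge set: an edge
list cannot represent isolated nodes).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .errors import ParseError, ValidationError
from .types import (
    CNVCall,
    DOSAGE_TOKENS,
    ExpressionMatrix,
    GeneAnnotation,
    VariantCatalogEntry,
)

logger = logging.getLogger(__name__)


def _lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if line.strip():
                yield lineno, line


def _parse_int(token: str, what: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(
            f"line {lineno}: non-integer {what}: {token!r}"
        ) from None


def _parse_float(token: str, what: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"line {lineno}: non-numeric {what}: {token!r}") from None


# ---------------------------------------------------------------------------
# gene annotation


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read a BED-like annotation TSV, returning records sorted by
    (chrom, start). Symbols must be unique within the file."""
    records: list[GeneAnnotation] = []
    seen: dict[str, int] = {}
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"line {lineno}: expected 4+ tab-separated columns")
        chrom, start_s, end_s, symbol = fields[:4]
        start = _parse_int(start_s, "start coordinate", lineno)
        end = _parse_int(end_s, "end coordinate", lineno)
        if symbol in seen:
            raise ValidationError(
                f"line {lineno}: duplicate gene symbol {symbol!r} "
                f"(first seen on line {seen[symbol]})"
            )
        seen[symbol] = lineno
        try:
            records.append(GeneAnnotation(chrom, start, end, symbol))
        except ValidationError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from None
    records.sort(key=lambda g: (g.chrom, g.start, g.symbol))
    return records


def write_gene_annotation(records: Sequence[GeneAnnotation], path: str | Path) -> None:
    ordered = sorted(records, key=lambda g: (g.chrom, g.start, g.symbol))
    with open(path, "w", encoding="utf-8") as handle:
        for g in ordered:
            handle.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.symbol}\n")


# ---------------------------------------------------------------------------
# expression matrix


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x tissues TSV: header row = tissue names, first column =
    gene symbols. Order is preserved as in the file.

    A single-tissue matrix loads (with a logged warning) but specificity
    scoring will reject it downstream.
    """
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}: expression TSV needs a gene column and >= 1 tissue")
    tissues = header[1:]
    if len(set(tissues)) != len(tissues):
        dup = next(t for i, t in enumerate(tissues) if t in tissues[:i])
        raise ValidationError(f"duplicate tissue name in header: {dup!r}")
    try:
        frame = pd.read_csv(
            path, sep="\t", index_col=0, header=None, skiprows=1,
            names=[header[0]] + tissues, float_precision="round_trip",
        )
    except Exception as exc:  # pandas raises various subclasses
        raise ParseError(f"cannot parse expression TSV {path}: {exc}") from None
    frame.index = frame.index.astype(str)
    try:
        frame = frame.astype(float)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"non-numeric expression value in {path}: {exc}") from None
    matrix = ExpressionMatrix(frame)
    if matrix.n_tissues < 2:
        logger.warning(
            "expression matrix %s has a single tissue column; "
            "tissue-specificity scoring will be unavailable",
            path,
        )
    return matrix


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix with ``repr``-precision floats so numeric round-trips
    are bit-exact."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("gene\t" + "\t".join(matrix.tissues) + "\n")
        for gene in matrix.genes:
            vals = "\t".join(repr(float(v)) for v in matrix.row(gene))
            handle.write(f"{gene}\t{vals}\n")


# ---------------------------------------------------------------------------
# interaction network


def read_network(path: str | Path) -> nx.Graph:
    """Read a 2-column undirected edge list. Self-loops are dropped (count
    logged); duplicate edges collapse silently."""
    graph = nx.Graph()
    dropped = 0
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ParseError(f"line {lineno}: expected 2 tab-separated node names")
        a, b = fields[0], fields[1]
        if a == b:
            dropped += 1
            continue
        graph.add_edge(a, b)
    if dropped:
        logger.info("dropped %d self-loop(s) while reading %s", dropped, path)
    return graph


def write_network(graph: nx.Graph, path: str | Path) -> None:
    edges = sorted(tuple(sorted(e)) for e in graph.edges())
    with open(path, "w", encoding="utf-8") as handle:
        for a, b in edges:
            handle.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# pathway gene sets (GMT)


def read_genesets_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read GMT: ``name<TAB>description<TAB>member1<TAB>member2...``.
    Pathway names must be unique; member sets must be nonempty."""
    pathways: dict[str, frozenset[str]] = {}
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"line {lineno}: GMT needs name, description and >= 1 member"
            )
        name = fields[0]
        members = frozenset(m for m in fields[2:] if m)
        if not members:
            raise ValidationError(f"line {lineno}: pathway {name!r} has no members")
        if name in pathways:
            raise ValidationError(f"line {lineno}: duplicate pathway name {name!r}")
        pathways[name] = members
    return pathways


def write_genesets_gmt(pathways: dict[str, frozenset[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name in sorted(pathways):
            members = "\t".join(sorted(pathways[name]))
            handle.write(f"{name}\tna\t{members}\n")


# ---------------------------------------------------------------------------
# CNV calls and benign catalog


def read_cnv_calls(path: str | Path) -> list[CNVCall]:
    """Read a headerless segment TSV: patient_id, chrom, start, end, dosage."""
    calls: list[CNVCall] = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 5:
            raise ParseError(f"line {lineno}: expected 5 columns for a CNV call")
        patient, chrom, start_s, end_s, dosage = fields[:5]
        start = _parse_int(start_s, "start coordinate", lineno)
        end = _parse_int(end_s, "end coordinate", lineno)
        if dosage not in DOSAGE_TOKENS:
            raise ParseError(
                f"line {lineno}: unknown dosage token {dosage!r}; "
                f"expected one of {DOSAGE_TOKENS}"
            )
        try:
            calls.append(CNVCall(patient, chrom, start, end, dosage))
        except ValidationError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from None
    calls.sort(key=lambda c: (c.patient_id, c.chrom, c.start, c.end, c.dosage))
    return calls


def write_cnv_calls(calls: Sequence[CNVCall], path: str | Path) -> None:
    ordered = sorted(calls, key=lambda c: (c.patient_id, c.chrom, c.start, c.end, c.dosage))
    with open(path, "w", encoding="utf-8") as handle:
        for c in ordered:
            handle.write(f"{c.patient_id}\t{c.chrom}\t{c.start}\t{c.end}\t{c.dosage}\n")


def read_variant_catalog(path: str | Path) -> list[VariantCatalogEntry]:
    """Read a headerless catalog TSV: chrom, start, end, population frequency."""
    entries: list[VariantCatalogEntry] = []
    for lineno, line in _lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"line {lineno}: expected 4 columns for a catalog entry")
        chrom, start_s, end_s, freq_s = fields[:4]
        start = _parse_int(start_s, "start coordinate", lineno)
        end = _parse_int(end_s, "end coordinate", lineno)
        freq = _parse_float(freq_s, "frequency", lineno)
        try:
            entries.append(VariantCatalogEntry(chrom, start, end, freq))
        except ValidationError as exc:
            raise ValidationError(f"line {lineno}: {exc}") from None
    entries.sort(key=lambda e: (e.chrom, e.start, e.end))
    return entries


def write_variant_catalog(entries: Sequence[VariantCatalogEntry], path: str | Path) -> None:
    ordered = sorted(entries, key=lambda e: (e.chrom, e.start, e.end))
    with open(path, "w", encoding="utf-8") as handle:
        for e in ordered:
            handle.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.frequency!r}\n")


# ---------------------------------------------------------------------------
# reports


def write_report(results: dict, path: str | Path, format: str = "json") -> None:
    """Write a report document.

    ``format="json"`` dumps the full nested evidence with sorted keys;
    ``format="tsv"`` flattens ``results["genes"]`` and ``results["cnvs"]``
    record lists into one flat table. Output bytes depend only on ``results``.
    """
    path = Path(path)
    if format == "json":
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(results, handle, indent=2, sort_keys=True)
            handle.write("\n")
    elif format == "tsv":
        rows: list[dict] = []
        for section in ("genes", "cnvs"):
            for record in results.get(section, []):
                flat = {"record_type": section[:-1]}
                _flatten(record, flat)
                rows.append(flat)
        frame = pd.DataFrame(rows)
        frame.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as handle:
        return json.load(handle)


def _flatten(record: dict, out: dict, prefix: str = "") -> None:
    for key in sorted(record):
        value = record[key]
        name = f"{prefix}{key}"
        if isinstance(value, dict):
            _flatten(value, out, prefix=f"{name}.")
        elif isinstance(value, (list, tuple)):
            out[name] = ",".join(str(v) for v in value)
        else:
            out[name] = value
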