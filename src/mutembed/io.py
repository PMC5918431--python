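"""Readers and writers for the plain-text formats the pipeline touches.

Formats: two-column TSV mutation profiles (sample_id, gene), MAF-lite
(tab-delimited with a header naming Tumor_Sample_Barcode and Hugo_Symbol),
word2vec text vectors, two-column TSV edge lists, gene label tables and
GMT gene-set files.  TSV dialect throughout: no header unless stated,
tab-separated, lines starting with '#' skipped.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .containers import (
    VALID_LABELS,
    GeneSetCollection,
    GeneVectorTable,
    InteractionGraph,
    LabelTable,
    MutationProfileSet,
)
from .exceptions import EmptyInputError, FormatError, ValidationError

logger = logging.getLogger(__name__)


def _data_lines(path: str | Path) -> list[tuple[int, str]]:
    """(line_number, stripped_line) for non-blank, non-comment lines."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            out.append((lineno, line))
    return out


def read_profiles(path: str | Path, format: str = "tsv") -> MutationProfileSet:
    """Read per-sample mutated-gene profiles.

    ``format="tsv"``: two columns sample_id, gene symbol, no header.
    ``format="maf"``: tab-delimited with a header line containing at least
    Tumor_Sample_Barcode and Hugo_Symbol columns.

    Samples appear in first-appearance order; genes are deduplicated
    per sample and upper-cased.
    """
    if format not in ("tsv", "maf"):
        raise ValueError(f"unknown profile format {format!r}")
    order: list[str] = []
    genes_by_sample: dict[str, set[str]] = {}

    if format == "tsv":
        rows = _data_lines(path)
        if not rows:
            raise EmptyInputError(f"no mutation records in {path}")
        for lineno, line in rows:
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            sample, gene = fields[0].strip(), fields[1].strip()
            if not sample or not gene:
                raise FormatError(f"{path}:{lineno}: empty sample id or gene symbol")
            if sample not in genes_by_sample:
                order.append(sample)
                genes_by_sample[sample] = set()
            genes_by_sample[sample].add(gene.upper())
    else:
        with open(path, encoding="utf-8") as fh:
            header = None
            for raw in fh:
                line = raw.rstrip("\n")
                if line.startswith("#") or not line.strip():
                    continue
                header = line.split("\t")
                break
            if header is None:
                raise EmptyInputError(f"no header line in MAF file {path}")
            try:
                i_sample = header.index("Tumor_Sample_Barcode")
                i_gene = header.index("Hugo_Symbol")
            except ValueError as exc:
                raise FormatError(
                    f"{path}: MAF header must contain Tumor_Sample_Barcode "
                    f"and Hugo_Symbol"
                ) from exc
            for raw in fh:
                line = raw.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) <= max(i_sample, i_gene):
                    raise FormatError(f"{path}: truncated MAF record: {line[:60]!r}")
                sample, gene = fields[i_sample].strip(), fields[i_gene].strip()
                if sample not in genes_by_sample:
                    order.append(sample)
                    genes_by_sample[sample] = set()
                genes_by_sample[sample].add(gene.upper())
        if not order:
            raise EmptyInputError(f"no mutation records in {path}")

    return MutationProfileSet([(s, genes_by_sample[s]) for s in order])


def read_vectors(path: str | Path) -> GeneVectorTable:
    """Read vectors in word2vec text format ("count dim" header line)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError(f"{path}: expected 'count dim' header line")
        try:
            count, dim = int(header[0]), int(header[1])
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer vector header") from exc
        vocab: list[str] = []
        rows = np.empty((count, dim), dtype=np.float64)
        for i in range(count):
            line = fh.readline()
            if not line:
                raise FormatError(f"{path}: header promises {count} rows, found {i}")
            fields = line.split()
            if len(fields) != dim + 1:
                raise FormatError(
                    f"{path}: row {i + 1} has {len(fields) - 1} values, expected {dim}"
                )
            vocab.append(fields[0])
            try:
                rows[i] = [float(x) for x in fields[1:]]
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric value on row {i + 1}") from exc
    return GeneVectorTable(vocab, rows)


def write_vectors(table: GeneVectorTable, path: str | Path) -> None:
    """Write vectors in word2vec text format at 6-decimal precision."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(table.vocab)} {table.d}\n")
        for token, row in zip(table.vocab, table.matrix):
            coords = " ".join(f"{x:.6f}" for x in row)
            fh.write(f"{token} {coords}\n")


def read_edge_list(path: str | Path) -> InteractionGraph:
    """Read a two-column TSV of interacting gene pairs.

    Self-loops are dropped; duplicate and reversed pairs collapse.  An
    empty file yields an empty (valid) graph.
    """
    edges = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated gene symbols")
        edges.append((fields[0].strip(), fields[1].strip()))
    return InteractionGraph(edges)


def read_labels(path: str | Path) -> LabelTable:
    """Read a two-column TSV mapping gene symbol -> driver/passenger label.

    A duplicated gene keeps its last label (with a logged warning).
    """
    mapping: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
        gene, label = fields[0].strip().upper(), fields[1].strip()
        if label not in VALID_LABELS:
            raise ValidationError(
                f"{path}:{lineno}: unknown label {label!r}; "
                f"expected one of {sorted(VALID_LABELS)}"
            )
        if gene in mapping and mapping[gene] != label:
            logger.warning("%s:%d: duplicate label for %s, keeping last", path, lineno, gene)
        mapping[gene] = label
    return LabelTable(mapping)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets in GMT format: name, description, members per line."""
    sets: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        fields = [f for f in line.split("\t")]
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT lines need name, description and >= 1 gene"
            )
        name = fields[0].strip()
        if name in sets:
            raise ValidationError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        members = {g.strip().upper() for g in fields[2:] if g.strip()}
        if not members:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} has no members")
        sets[name] = members
    return GeneSetCollection(sets)


def write_profiles(profiles: MutationProfileSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sample_id, genes in profiles:
            for gene in sorted(genes):
                fh.write(f"{sample_id}\t{gene}\n")


def write_edge_list(graph: InteractionGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")


def write_labels(labels: LabelTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(labels.mapping):
            fh.write(f"{gene}\t{labels.mapping[gene]}\n")
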