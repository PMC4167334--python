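"""TSV readers/writers and run metadata for every pipeline artifact.

All artifacts are plain TSV (counts, sample sheets, truth tables, DE
tables, cluster memberships/centroids, annotation) with a JSON sidecar
recording the configuration and seed, so runs diff cleanly and are
reproducible.  Readers validate eagerly and name the offending line.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .de import CountMatrix

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed input file; the message names file and line."""


def read_counts(path, samples_path=None):
    """Read a counts TSV (gene id column + one integer column per sample).

    Validates cell-by-cell: duplicate gene ids, negative or non-integer
    counts are rejected with the file and line number.  With
    ``samples_path`` the sample sheet is read too and a validated
    :class:`CountMatrix` is returned; otherwise the counts DataFrame.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, no genes") from None
        if len(header) < 2:
            raise ParseError(f"{path}: header must name at least one sample")
        sample_names = header[1:]
        genes, rows = [], []
        seen = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            gene = row[0]
            if gene in seen:
                raise ParseError(f"{path}:{lineno}: duplicate gene id {gene!r}")
            seen.add(gene)
            vals = []
            for col, cell in zip(sample_names, row[1:]):
                try:
                    v = int(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}:{lineno}: non-integer count {cell!r} in "
                        f"column {col!r}"
                    ) from None
                if v < 0:
                    raise ParseError(
                        f"{path}:{lineno}: negative count {v} in column {col!r}"
                    )
                vals.append(v)
            genes.append(gene)
            rows.append(vals)
    if not genes:
        raise ParseError(f"{path}: no genes")
    counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64),
        index=pd.Index(genes, name="gene"),
        columns=sample_names,
    )
    if samples_path is None:
        return counts
    samples = read_sample_sheet(samples_path)
    missing = [c for c in counts.columns if c not in samples.index]
    if missing:
        raise ParseError(
            f"{samples_path}: samples missing from sheet: {missing}"
        )
    return CountMatrix(counts=counts, samples=samples)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_sample_sheet(path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t")
    required = {"sample", "genotype", "tissue", "time_days", "phase"}
    missing = required - set(samples.columns)
    if missing:
        raise ParseError(f"{path}: sample sheet lacks columns {sorted(missing)}")
    return samples.set_index("sample")


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample")


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index_label="gene")


def read_gene_set(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_gene_set(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_annotation(path) -> dict[str, set[str]]:
    """Annotation TSV: gene <tab> semicolon-joined term ids (may be empty)."""
    annot: dict[str, set[str]] = {}
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[0] != "gene":
            raise ParseError(f"{path}: first column must be 'gene'")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            gene = row[0]
            if gene in annot:
                raise ParseError(f"{path}:{lineno}: duplicate gene {gene!r}")
            terms = row[1] if len(row) > 1 else ""
            annot[gene] = {t for t in terms.split(";") if t}
    return annot


def write_annotation(annot: dict[str, set[str]], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene", "terms"])
        for gene in sorted(annot):
            writer.writerow([gene, ";".join(sorted(annot[gene]))])


def write_de_result(result, path) -> None:
    result.table.to_csv(path, sep="\t", index_label="gene", float_format="%.10g")


def write_table(df: pd.DataFrame, path, index_label=None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def write_metadata(meta: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
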