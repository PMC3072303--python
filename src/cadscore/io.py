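"""File formats and run-reproducibility helpers.

Conventions, enforced everywhere:

* expression matrices are tab-delimited, UTF-8, ``.`` decimal; gene ids in
  column 1 under the header ``gene``, sample ids across the header row; a
  single leading ``#`` comment line carries the scale/platform tags;
* sample sheets are CSV with the sample id in column ``sample_id``;
* floats are serialised at 9 significant digits so write/read round-trips
  are exact at that precision and output is byte-stable.

A read-only subset of the GEO series-matrix format is supported: ``!``-
prefixed metadata lines are skipped and the expression table between the
``!series_matrix_table_begin``/``!series_matrix_table_end`` markers is
parsed (ID_REF column = gene/probe id).
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import DataError, ExpressionMatrix, validate_samples

FLOAT_FORMAT = "%.9g"


def _format_float(x) -> str:
    if pd.isna(x):
        return "NA"
    return FLOAT_FORMAT % x


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def write_expression(matrix: ExpressionMatrix, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# cadscore expression scale={matrix.scale} platform={matrix.platform}\n")
        fh.write("gene\t" + "\t".join(str(s) for s in matrix.samples) + "\n")
        for gene, row in zip(matrix.genes, matrix.values):
            fh.write(str(gene) + "\t" + "\t".join(_format_float(v) for v in row) + "\n")


def read_expression(path, format: str = "tsv", scale: str | None = None,
                    platform: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from ``tsv`` or ``geo_series_matrix`` format."""
    path = Path(path)
    if format == "tsv":
        return _read_expression_tsv(path, scale, platform)
    if format == "geo_series_matrix":
        return _read_series_matrix(path, scale, platform)
    raise DataError(f"unknown expression format {format!r}")


def _read_expression_tsv(path: Path, scale, platform) -> ExpressionMatrix:
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise DataError(f"{path}: empty expression file")
    lines = text.splitlines()
    tags = {}
    start = 0
    if lines[0].startswith("#"):
        for tok in lines[0].lstrip("#").split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                tags[k] = v
        start = 1
    header = lines[start].split("\t")
    ncol = len(header)
    for lineno, line in enumerate(lines[start + 1:], start=start + 2):
        if line and len(line.split("\t")) != ncol:
            raise DataError(f"{path}:{lineno}: ragged row ({len(line.split(chr(9)))} fields, expected {ncol})")
    df = pd.read_csv(_io.StringIO("\n".join(lines[start:])), sep="\t",
                     index_col=0, na_values=["NA"])
    df.index.name = "gene"
    return ExpressionMatrix(
        df,
        scale=scale or tags.get("scale", "log2"),
        platform=platform or tags.get("platform", "microarray"),
    )


def _read_series_matrix(path: Path, scale, platform) -> ExpressionMatrix:
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise DataError(f"{path}: empty series-matrix file")
    table_lines: list[str] = []
    in_table = False
    for line in text.splitlines():
        low = line.strip().lower()
        if low.startswith("!series_matrix_table_begin"):
            in_table = True
            continue
        if low.startswith("!series_matrix_table_end"):
            in_table = False
            continue
        if in_table and line.strip():
            table_lines.append(line)
        # all other '!'-prefixed metadata lines are skipped
    if not table_lines:
        raise DataError(f"{path}: no series_matrix table found")
    df = pd.read_csv(_io.StringIO("\n".join(table_lines)), sep="\t",
                     index_col=0, na_values=["NA", "null"])
    df.index = df.index.map(lambda s: str(s).strip('"'))
    df.columns = [str(c).strip('"') for c in df.columns]
    df.index.name = "gene"
    return ExpressionMatrix(df, scale=scale or "log2",
                            platform=platform or "microarray")


# ---------------------------------------------------------------------------
# sample sheets
# ---------------------------------------------------------------------------

def write_samples(samples: pd.DataFrame, path) -> None:
    out = samples.copy()
    out.index.name = "sample_id"
    float_cols = out.select_dtypes(include=[float]).columns
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        out.to_csv(fh, float_format=FLOAT_FORMAT,
                   columns=[c for c in out.columns if c != "age_missing"])


def read_samples(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise DataError(f"{path}: sample sheet missing 'sample_id' column")
    df = df.set_index("sample_id")
    return validate_samples(df)


# ---------------------------------------------------------------------------
# association tables
# ---------------------------------------------------------------------------

ASSOC_COLUMNS = ["gene", "beta", "se", "p_unadjusted", "p_adjusted", "q_bh", "flag"]


def write_association(results: pd.DataFrame, path) -> None:
    """Write an association table with stable column order and formatting."""
    out = results.reset_index() if results.index.name == "gene" else results.copy()
    cols = [c for c in ASSOC_COLUMNS if c in out.columns]
    out = out[cols + [c for c in out.columns if c not in cols]]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        out.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_association(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("gene")


# ---------------------------------------------------------------------------
# run reproducibility
# ---------------------------------------------------------------------------

def file_digest(path) -> str:
    """SHA-256 hex digest of a file (for run logs)."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_config_echo(config: dict, path) -> None:
    """Write the resolved configuration of a run as sorted JSON."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(config, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def log(msg: str) -> None:
    """Log to stderr; results go to files/stdout only."""
    print(msg, file=sys.stderr)
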