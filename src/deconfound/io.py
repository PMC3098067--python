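"""Tab-separated readers and writers plus run logging.

All matrices travel as UTF-8 tab-separated text: first header cell
names the row-identifier column (``gene_id`` or ``cell_type``), the
remaining header cells are column identifiers; one row per gene (or
cell type); "." decimal separator; numeric output at 6 significant
digits.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DeconfoundingResult
from .markers import MarkerSet
from .matrices import (
    ConcentrationMatrix,
    DeconfoundError,
    ExpressionMatrix,
    SignatureMatrix,
    ValidationError,
)

__all__ = [
    "ParseError",
    "read_expression_tsv",
    "write_expression_tsv",
    "write_signature_tsv",
    "write_concentration_tsv",
    "read_markers_tsv",
    "write_markers_tsv",
    "write_result",
]

_FLOAT_FMT = "%.6g"


class ParseError(DeconfoundError):
    """Malformed tab-separated input."""


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}: header must name at least one data column")
        n_cols = len(header)
        ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_cols:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_cols} fields, got {len(fields)}"
                )
            ids.append(fields[0])
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if len(set(ids)) != len(ids):
        seen, dup = set(), None
        for i in ids:
            if i in seen:
                dup = i
                break
            seen.add(i)
        raise ParseError(f"{path}: duplicate row identifier {dup!r}")
    return pd.DataFrame(np.asarray(rows, dtype=float), index=ids, columns=header[1:])


def read_expression_tsv(path) -> ExpressionMatrix:
    """Parse a gene-by-sample expression matrix from tab-separated text."""
    frame = _read_table(path)
    try:
        return ExpressionMatrix.from_frame(frame)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _write_table(frame: pd.DataFrame, path, index_label: str):
    frame.to_csv(path, sep="\t", index_label=index_label, float_format=_FLOAT_FMT)


def write_expression_tsv(X: ExpressionMatrix, path):
    _write_table(X.to_frame(), path, "gene_id")


def write_signature_tsv(S: SignatureMatrix, path):
    _write_table(S.to_frame(), path, "gene_id")


def write_concentration_tsv(C: ConcentrationMatrix, path):
    _write_table(C.to_frame(), path, "cell_type")


def read_markers_tsv(path, cell_type: str = "CD3") -> MarkerSet:
    """Read a marker file: two tab-separated columns gene_id, role.

    ``role`` is "positive" or "negative"; a header line is optional.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    pos, neg = [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
            gene, role = fields[0].strip(), fields[1].strip().lower()
            if lineno == 1 and role not in ("positive", "negative"):
                continue  # header
            if role == "positive":
                pos.append(gene)
            elif role == "negative":
                neg.append(gene)
            else:
                raise ParseError(f"{path}:{lineno}: role must be positive or negative")
    try:
        return MarkerSet(cell_type, pos, neg)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_markers_tsv(markers: MarkerSet, path):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\trole\n")
        for g in markers.positive_markers:
            fh.write(f"{g}\tpositive\n")
        for g in markers.negative_markers:
            fh.write(f"{g}\tnegative\n")


def write_result(result: DeconfoundingResult, out_prefix, config=None, warnings=()) -> list:
    """Write a deconvolution result set and its run log.

    Produces ``<prefix>.signature.tsv``, ``<prefix>.concentration.tsv``,
    ``<prefix>.trace.tsv`` (deterministic given the result) and
    ``<prefix>.log`` (timestamped).  Returns the manifest of data files.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sig = prefix.with_suffix(prefix.suffix + ".signature.tsv")
    con = prefix.with_suffix(prefix.suffix + ".concentration.tsv")
    trc = prefix.with_suffix(prefix.suffix + ".trace.tsv")
    log = prefix.with_suffix(prefix.suffix + ".log")

    write_signature_tsv(result.S_hat, sig)
    write_concentration_tsv(result.C_hat, con)
    trace = pd.DataFrame(
        {"iteration": np.arange(1, len(result.residual_trace) + 1),
         "frobenius_residual": result.residual_trace}
    )
    trace.to_csv(trc, sep="\t", index=False, float_format=_FLOAT_FMT)

    manifest = [str(sig), str(con), str(trc)]
    with open(log, "w", encoding="utf-8") as fh:
        fh.write(f"timestamp\t{datetime.datetime.now().isoformat()}\n")
        if config is not None:
            for key, val in vars(config).items():
                fh.write(f"config.{key}\t{val}\n")
        fh.write(f"n_iterations\t{result.n_iterations}\n")
        fh.write(f"converged\t{result.converged}\n")
        fh.write(f"stop_reason\t{result.stop_reason}\n")
        fh.write(f"restart_index\t{result.restart_index}\n")
        fh.write(f"final_residual\t{result.final_residual:.6g}\n")
        for w in warnings:
            fh.write(f"warning\t{w}\n")
        for f in manifest:
            fh.write(f"output\t{f}\n")
    return manifest
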