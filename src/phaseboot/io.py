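"""Reading expression matrices and writing result tables.

The expected input layout is the common supplementary-text one: plain tab-
or whitespace-delimited rows, one gene per row, an optional leading
identifier column and an optional header line, followed by one numeric
column per timepoint (12 columns at 4-h spacing in the reference design).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .meboot import GENERATOR_NAME

__all__ = ["read_expression_matrix", "write_results", "write_matrix"]

logger = logging.getLogger(__name__)


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a genes-by-timepoints matrix from delimited text.

    Dialect is sniffed: a first line whose trailing fields are non-numeric is
    treated as a header and skipped; a non-numeric first field per row is the
    gene identifier, otherwise IDs gene_0001... are generated.  Duplicate IDs
    are suffixed. Ragged rows raise an error naming the offending line.
    """
    path = Path(path)
    rows: list[tuple[str | None, list[float]]] = []
    ncols = None
    with path.open() as fh:
        lines = [(i + 1, line.rstrip("\n")) for i, line in enumerate(fh)
                 if line.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")

    start = 0
    first_fields = lines[0][1].split()
    if not all(_is_number(tok) for tok in first_fields[1:]) or (
            len(first_fields) > 1 and not _is_number(first_fields[1])):
        start = 1  # header line
    if start == len(lines):
        raise ValueError(f"{path}: no data rows")

    for lineno, line in lines[start:]:
        fields = line.split()
        has_id = not _is_number(fields[0])
        gene_id = fields[0] if has_id else None
        numeric = fields[1:] if has_id else fields
        if not numeric or not all(_is_number(tok) for tok in numeric):
            raise ValueError(f"{path}:{lineno}: non-numeric expression value")
        values = [float(tok) for tok in numeric]
        if ncols is None:
            ncols = len(values)
        elif len(values) != ncols:
            raise ValueError(
                f"{path}:{lineno}: expected {ncols} columns, found {len(values)}")
        rows.append((gene_id, values))

    width = len(str(len(rows)))
    ids: list[str] = []
    seen: dict[str, int] = {}
    for i, (gene_id, _) in enumerate(rows):
        gid = gene_id if gene_id is not None else f"gene_{i + 1:0{max(width, 4)}d}"
        if gid in seen:
            seen[gid] += 1
            gid = f"{gid}.{seen[gid]}"
        else:
            seen[gid] = 0
        ids.append(gid)

    data = np.array([values for _, values in rows], dtype=float)
    columns = [f"t{4 * j:g}" for j in range(data.shape[1])]
    return pd.DataFrame(data, index=pd.Index(ids, name="gene_id"), columns=columns)


def write_matrix(matrix: pd.DataFrame, path, header: bool = True) -> None:
    """Write a matrix in the same delimited-text layout the reader accepts."""
    path = Path(path)
    matrix.to_csv(path, sep="\t", header=header, index=True)


def write_results(results: pd.DataFrame, summary, outdir, config: dict | None = None
                  ) -> dict[str, Path]:
    """Write per-gene table, run metadata, and (last) the per-bin summary.

    The summary is written last so a failure part-way leaves the per-gene
    table intact.  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    per_gene = outdir / "per_gene_results.tsv"
    results.to_csv(per_gene, sep="\t", index=False, float_format="%.6g")
    paths["per_gene"] = per_gene

    meta = dict(config or {})
    meta.setdefault("generator", GENERATOR_NAME)
    meta["n_genes"] = int(summary.n_genes)
    meta["n_skipped"] = int(summary.n_skipped)
    meta["total_circadian"] = int(summary.total_circadian)
    cfg_path = outdir / "run_config.yaml"
    with cfg_path.open("w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    paths["config"] = cfg_path

    summary_path = outdir / "summary.tsv"
    summary.to_frame().to_csv(summary_path, sep="\t", index=False)
    paths["summary"] = summary_path
    return paths
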