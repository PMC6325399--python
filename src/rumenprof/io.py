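"""Delimited-text I/O for peak tables, Ct tables and pipeline outputs.

Readers accept TSV or CSV (delimiter auto-detected unless fixed in the
config), reject malformed rows with a logged count instead of failing,
and never silently drop a sample.  All writers are atomic: content goes
to a temporary file in the target directory which is then renamed.
"""

from __future__ import annotations

import io as _stdio
import logging
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .qpcr import CtRecord
from .trflp import BinnedMatrix, PeakTable

__all__ = [
    "read_peak_tables",
    "read_ct_table",
    "read_fermentation_table",
    "read_meta",
    "read_binned_matrix",
    "write_table",
    "write_binned_matrix",
    "write_newick",
]

logger = logging.getLogger("rumenprof")


def _read_delimited(source, delimiter: str | None) -> pd.DataFrame:
    """Read a delimited table, sniffing tab vs comma when not configured."""
    if delimiter is not None:
        return pd.read_csv(source, sep=delimiter)
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    if not text.strip():
        return pd.DataFrame()
    header = text.splitlines()[0]
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    return pd.read_csv(_stdio.StringIO(text), sep=sep)


def _require_columns(frame: pd.DataFrame, needed: dict[str, str], what: str) -> None:
    for role, col in needed.items():
        if col not in frame.columns:
            raise ValueError(
                f"{what}: required column {col!r} (role: {role}) not found; "
                f"available: {list(frame.columns)}"
            )


def read_peak_tables(
    source, config: PipelineConfig | None = None
) -> dict[str, PeakTable]:
    """Read an instrument peak-table export into one PeakTable per sample.

    Rows with non-numeric or non-positive size/height are rejected with
    a logged count; row order within each sample is preserved.
    """
    config = config or PipelineConfig()
    frame = _read_delimited(source, config.delimiter)
    if frame.empty:
        logger.warning("peak table source is empty")
        return {}
    cols = {
        "sample id": config.peak_sample_col,
        "fragment size": config.peak_size_col,
        "peak height": config.peak_height_col,
    }
    _require_columns(frame, cols, "peak table")

    sizes = pd.to_numeric(frame[config.peak_size_col], errors="coerce")
    heights = pd.to_numeric(frame[config.peak_height_col], errors="coerce")
    valid = sizes.notna() & heights.notna() & (sizes > 0) & (heights > 0)
    n_rejected = int((~valid).sum())
    if n_rejected:
        logger.warning("peak table: rejected %d malformed row(s)", n_rejected)

    clean = frame.loc[valid].assign(_size=sizes[valid], _height=heights[valid])
    tables: dict[str, PeakTable] = {}
    for sid, group in clean.groupby(config.peak_sample_col, sort=False):
        tables[str(sid)] = PeakTable(
            str(sid), group["_size"].to_numpy(), group["_height"].to_numpy()
        )
    return tables


def read_ct_table(source, config: PipelineConfig | None = None) -> list[CtRecord]:
    """Read replicate Ct rows grouped into one record per (sample, taxon).

    Rows with Ct <= 0 or non-numeric are rejected with a warning;
    single-replicate records are flagged in the log.
    """
    config = config or PipelineConfig()
    frame = _read_delimited(source, config.delimiter)
    if frame.empty:
        logger.warning("Ct table source is empty")
        return []
    cols = {
        "sample id": config.ct_sample_col,
        "target taxon": config.ct_taxon_col,
        "Ct": config.ct_value_col,
    }
    _require_columns(frame, cols, "Ct table")

    cts = pd.to_numeric(frame[config.ct_value_col], errors="coerce")
    valid = cts.notna() & (cts > 0)
    n_rejected = int((~valid).sum())
    if n_rejected:
        logger.warning("Ct table: rejected %d row(s) with invalid Ct", n_rejected)

    clean = frame.loc[valid].assign(_ct=cts[valid])
    records = []
    for (sid, taxon), group in clean.groupby(
        [config.ct_sample_col, config.ct_taxon_col], sort=False
    ):
        reps = tuple(group["_ct"].tolist())
        if len(reps) == 1:
            logger.info("Ct table: single replicate for (%s, %s)", sid, taxon)
        records.append(CtRecord(str(sid), str(taxon), reps))
    return records


def read_fermentation_table(source, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Read tidy fermentation records (species, animal_id, diet, response, value)."""
    config = config or PipelineConfig()
    frame = _read_delimited(source, config.delimiter)
    needed = {c: c for c in ("species", "animal_id", "diet", "response", "value")}
    _require_columns(frame, needed, "fermentation table")
    frame = frame.copy()
    frame["value"] = pd.to_numeric(frame["value"], errors="coerce")
    n_rejected = int(frame["value"].isna().sum())
    if n_rejected:
        logger.warning("fermentation table: rejected %d non-numeric value(s)", n_rejected)
    return frame.dropna(subset=["value"]).reset_index(drop=True)


def read_meta(source, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Read sample metadata; sample_id must be unique."""
    config = config or PipelineConfig()
    frame = _read_delimited(source, config.delimiter)
    _require_columns(frame, {c: c for c in ("sample_id", "species", "animal_id", "diet")}, "meta")
    if frame["sample_id"].duplicated().any():
        raise ValueError("meta: duplicate sample_id entries")
    return frame


def _atomic_write(path: Path, content: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as handle:
            handle.write(content)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_table(frame: pd.DataFrame, path: str | Path, float_format: str = "%.12g") -> Path:
    """Write a DataFrame as TSV atomically (temp file + rename)."""
    path = Path(path)
    _atomic_write(path, frame.to_csv(sep="\t", index=False, float_format=float_format))
    return path


def write_binned_matrix(matrix: BinnedMatrix, path: str | Path) -> Path:
    """Write a binned matrix as TSV: first column bin_bp (2 dp), one column per sample."""
    path = Path(path)
    frame = pd.DataFrame(matrix.values, columns=matrix.sample_ids)
    frame.insert(0, "bin_bp", [f"{r:.2f}" for r in matrix.representatives])
    _atomic_write(path, frame.to_csv(sep="\t", index=False, float_format="%.17g"))
    return path


def read_binned_matrix(path: str | Path, standardized: bool = False) -> BinnedMatrix:
    """Re-read a binned-matrix TSV written by :func:`write_binned_matrix`."""
    frame = pd.read_csv(path, sep="\t")
    representatives = frame["bin_bp"].to_numpy(dtype=float)
    sample_ids = [c for c in frame.columns if c != "bin_bp"]
    values = frame[sample_ids].to_numpy(dtype=float)
    return BinnedMatrix(
        representatives,
        sample_ids,
        values,
        member_lengths=[[r] for r in representatives],
        standardized=standardized,
    )


def write_newick(newick: str, path: str | Path) -> Path:
    path = Path(path)
    _atomic_write(path, newick if newick.endswith("\n") else newick + "\n")
    return path
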