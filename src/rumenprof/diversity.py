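"""Alpha-diversity indices over standardized T-RF profiles.

Shannon entropy is computed in nats (natural log by default; the base is
configurable).  The inverse Simpson index ``1 / sum(p_i^2)`` is the
effective number of equally abundant fragment types.  Both are Hill
numbers (orders 1 and 2), so ``exp(H) >= D`` for every valid abundance
vector.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .trflp import BinnedMatrix

__all__ = ["shannon", "inverse_simpson", "diversity_table"]

_SUM_TOL = 1e-9


def _check_simplex(p: np.ndarray) -> np.ndarray | None:
    """Validate an abundance vector; return it, or None if all-zero."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("abundance vector must be 1-D")
    if np.any(p < 0):
        raise ValueError("abundances must be non-negative")
    total = p.sum()
    if total == 0:
        return None
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"abundances must sum to 1 (got {total!r})")
    return p


def shannon(p, base: float = math.e) -> float:
    """Shannon diversity ``H = -sum(p_i * log p_i)`` over nonzero entries.

    Returns NaN for an all-zero vector (diversity undefined without any
    observed fragment).
    """
    checked = _check_simplex(p)
    if checked is None:
        return float("nan")
    nz = checked[checked > 0]
    return float(-(nz * (np.log(nz) / math.log(base))).sum())


def inverse_simpson(p) -> float:
    """Inverse Simpson diversity ``D = 1 / sum(p_i^2)``.

    Returns NaN for an all-zero vector.
    """
    checked = _check_simplex(p)
    if checked is None:
        return float("nan")
    return float(1.0 / np.sum(checked**2))


def diversity_table(
    matrix: BinnedMatrix, meta: pd.DataFrame | None = None, base: float = math.e
) -> pd.DataFrame:
    """Per-sample richness, Shannon and inverse-Simpson from a standardized matrix.

    Parameters
    ----------
    matrix:
        A standardized :class:`~rumenprof.trflp.BinnedMatrix`.
    meta:
        Optional sample metadata with columns ``sample_id``, ``species``,
        ``diet`` to join onto the result.
    """
    if not matrix.standardized:
        raise ValueError("diversity requires a standardized matrix")
    rows = []
    for j, sid in enumerate(matrix.sample_ids):
        col = matrix.values[:, j]
        rows.append(
            {
                "sample_id": sid,
                "richness": int(np.count_nonzero(col)),
                "shannon": shannon(col, base=base),
                "inverse_simpson": inverse_simpson(col),
            }
        )
    table = pd.DataFrame(rows)
    if meta is not None:
        keep = [c for c in ("sample_id", "species", "animal_id", "diet") if c in meta.columns]
        table = table.merge(meta[keep], on="sample_id", how="left")
        order = ["sample_id"] + [c for c in ("species", "animal_id", "diet") if c in table.columns]
        order += ["richness", "shannon", "inverse_simpson"]
        table = table[order]
    return table
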