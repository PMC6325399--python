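"""Relative quantification of rumen bacteria from qPCR Ct values.

Abundance of a target taxon is expressed relative to the total-bacteria
assay under perfect-doubling amplification:

    abundance (% of total) = 100 * 2^-(Ct_target - Ct_total)

Replicate Ct values are aggregated by arithmetic mean; replicate
scatter above ``sd_threshold`` cycles raises a QC flag.  Abundances
above 100% (target amplifying earlier than the universal assay) are
flagged but never clamped, preserving the raw transform for QC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TOTAL_TAXON",
    "CtRecord",
    "aggregate_ct",
    "relative_abundance",
    "abundance_table",
    "group_fold_change",
    "present_fold",
]

TOTAL_TAXON = "total"


@dataclass(frozen=True)
class CtRecord:
    """Replicate quantification cycles for one sample x taxon assay."""

    sample_id: str
    taxon: str
    replicate_cts: tuple[float, ...]

    def __post_init__(self) -> None:
        cts = tuple(float(c) for c in self.replicate_cts)
        if len(cts) == 0:
            raise ValueError("CtRecord needs at least one replicate")
        if any(not math.isfinite(c) or c <= 0 for c in cts):
            raise ValueError("Ct values must be finite and positive")
        object.__setattr__(self, "replicate_cts", cts)


def aggregate_ct(record: CtRecord, sd_threshold: float = 0.5) -> tuple[float, str]:
    """Arithmetic mean of replicate Ct values with a scatter QC flag.

    Returns ``(mean_ct, flag)`` where flag is ``"ok"`` or
    ``"high_replicate_sd"`` when the replicate sample SD exceeds
    ``sd_threshold`` cycles.
    """
    cts = np.asarray(record.replicate_cts)
    mean_ct = float(cts.mean())
    sd = float(cts.std(ddof=1)) if len(cts) > 1 else 0.0
    flag = "high_replicate_sd" if sd > sd_threshold else "ok"
    return mean_ct, flag


def relative_abundance(ct_target: float, ct_total: float) -> float:
    """Percent of total bacteria from target and total-bacteria Ct values."""
    if not (math.isfinite(ct_target) and math.isfinite(ct_total)):
        raise ValueError("Ct values must be finite")
    if ct_target <= 0 or ct_total <= 0:
        raise ValueError("Ct values must be positive")
    return 100.0 * 2.0 ** (-(ct_target - ct_total))


def abundance_table(
    records: list[CtRecord], sd_threshold: float = 0.5
) -> pd.DataFrame:
    """Per sample x taxon relative abundances from replicate Ct records.

    The total-bacteria record of each sample (taxon ``"total"``) supplies
    the reference Ct.  Target taxa in samples lacking a total record are
    emitted with qc_flag ``missing_total`` and NaN abundance.

    Columns: sample_id, taxon, mean_ct, delta_ct, abundance_percent, qc_flag.
    """
    totals: dict[str, float] = {}
    for rec in records:
        if rec.taxon == TOTAL_TAXON:
            totals[rec.sample_id], _ = aggregate_ct(rec, sd_threshold)

    rows = []
    for rec in records:
        if rec.taxon == TOTAL_TAXON:
            continue
        mean_ct, flag = aggregate_ct(rec, sd_threshold)
        ct_total = totals.get(rec.sample_id)
        if ct_total is None:
            rows.append(
                {
                    "sample_id": rec.sample_id,
                    "taxon": rec.taxon,
                    "mean_ct": mean_ct,
                    "delta_ct": float("nan"),
                    "abundance_percent": float("nan"),
                    "qc_flag": "missing_total",
                }
            )
            continue
        delta = mean_ct - ct_total
        pct = relative_abundance(mean_ct, ct_total)
        if pct > 100 and flag == "ok":
            flag = "exceeds_total"
        rows.append(
            {
                "sample_id": rec.sample_id,
                "taxon": rec.taxon,
                "mean_ct": mean_ct,
                "delta_ct": delta,
                "abundance_percent": pct,
                "qc_flag": flag,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "taxon", "mean_ct", "delta_ct", "abundance_percent", "qc_flag"],
    )


def group_fold_change(
    abundances: pd.DataFrame,
    meta: pd.DataFrame,
    taxon: str,
    numerator_diet: str,
    denominator_diet: str,
    level: str = "across_species",
    method: str = "ratio_of_means",
):
    """Fold change of a taxon's abundance between two diet groups.

    Parameters
    ----------
    abundances:
        Table with columns ``sample_id``, ``taxon``, ``abundance_percent``
        (e.g. from :func:`abundance_table`).
    meta:
        Sample metadata with ``sample_id``, ``species``, ``diet`` (and
        ``animal_id`` for ``mean_of_ratios``).
    level:
        ``"per_species"`` returns a Series of folds indexed by species;
        ``"across_species"`` returns a single float: the fold of
        cross-species means of the per-species group means.
    method:
        ``"ratio_of_means"`` divides group mean abundances;
        ``"mean_of_ratios"`` averages per-animal HC/HF style ratios
        (per_species level only).

    A zero denominator mean yields ``inf`` so an unbounded fold is
    reported distinctly rather than erroring.
    """
    if level not in ("per_species", "across_species"):
        raise ValueError(f"unknown level {level!r}")
    if method not in ("ratio_of_means", "mean_of_ratios"):
        raise ValueError(f"unknown method {method!r}")

    sub = abundances[abundances["taxon"] == taxon].merge(meta, on="sample_id")
    if sub.empty:
        raise ValueError(f"no abundance records for taxon {taxon!r}")
    for diet in (numerator_diet, denominator_diet):
        if not (sub["diet"] == diet).any():
            raise ValueError(f"diet group {diet!r} is empty for taxon {taxon!r}")

    cell_means = sub.groupby(["species", "diet"])["abundance_percent"].mean().unstack("diet")

    if method == "mean_of_ratios":
        if level != "per_species":
            raise ValueError("mean_of_ratios is defined per species")
        wide = sub.pivot_table(
            index=["species", "animal_id"], columns="diet", values="abundance_percent"
        )
        with np.errstate(divide="ignore"):
            ratios = wide[numerator_diet] / wide[denominator_diet]
        return ratios.groupby(level="species").mean()

    with np.errstate(divide="ignore"):
        per_species = cell_means[numerator_diet] / cell_means[denominator_diet]
        if level == "per_species":
            return per_species
        num = cell_means[numerator_diet].mean()
        den = cell_means[denominator_diet].mean()
        return float("inf") if den == 0 else float(num / den)


def present_fold(fold: float) -> str:
    """Presentation rounding of a fold value, matching reporting style.

    Nearest integer up to 1,000; nearest hundred above that; ``"inf"``
    for unbounded folds.
    """
    if math.isinf(fold):
        return "inf"
    if fold > 1000:
        return f"{int(round(fold / 100.0) * 100):,}"
    return str(int(round(fold)))
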