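"""Species x diet split-plot analysis for fermentation-type responses.

The design: species is the whole-plot factor with animal nested within
species as the whole-plot (random) error, and diet is the sub-plot
factor varying within animal.  On a balanced layout (equal animals per
species, every animal observed under every diet, one observation per
animal x diet) the classic ANOVA decomposition gives the exact mixed-
model tests:

    F_species = MS_species / MS_animal(species)      (whole-plot stratum)
    F_diet    = MS_diet / MS_residual                (sub-plot stratum)
    F_int     = MS_species:diet / MS_residual

Variance components follow from the expected mean squares:
``sigma2_animal = (MS_animal - MS_residual) / n_diets`` (truncated at
zero) and ``sigma2_residual = MS_residual``.

Unbalanced layouts are rejected outright — the exact F-tests above do
not apply and a general mixed-model (REML) fit would be needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MeansTable",
    "AnovaTable",
    "summarize_means",
    "split_plot_anova",
    "tukey_pairwise",
    "significance_label",
]


@dataclass(frozen=True)
class MeansTable:
    """Species x diet cell means with the pooled sub-plot SEM."""

    response: str
    means: pd.DataFrame  # index species, columns diets
    sem: float
    n_per_cell: int


@dataclass(frozen=True)
class AnovaTable:
    """Split-plot ANOVA results for one response."""

    response: str
    table: pd.DataFrame  # index: effect; columns: ss, df, error_stratum, ms, F, p
    sigma2_animal: float
    sigma2_residual: float
    ss_total: float
    df_total: int

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])


def _pull_response(records: pd.DataFrame, response: str) -> pd.DataFrame:
    sub = records[records["response"] == response] if "response" in records.columns else records
    if sub.empty:
        raise ValueError(f"no records for response {response!r}")
    required = {"species", "animal_id", "diet", "value"}
    missing = required - set(sub.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    return sub


def _check_balanced(sub: pd.DataFrame) -> tuple[list[str], list[str], int]:
    """Return (species levels, diet levels, animals per species) or raise."""
    counts = sub.groupby(["species", "animal_id", "diet"], observed=True).size()
    if (counts != 1).any():
        raise ValueError(
            "unbalanced design: expected exactly one observation per animal x diet; "
            "use a general mixed-model tool for unbalanced data"
        )
    species = sorted(sub["species"].unique())
    diets = sorted(sub["diet"].unique())
    per_species = sub.groupby("species", observed=True)["animal_id"].nunique()
    if per_species.nunique() != 1:
        raise ValueError(
            "unbalanced design: unequal animals per species; "
            "use a general mixed-model tool for unbalanced data"
        )
    per_animal_diets = sub.groupby(["species", "animal_id"], observed=True)["diet"].nunique()
    if (per_animal_diets != len(diets)).any():
        raise ValueError(
            "unbalanced design: every animal must be observed under every diet"
        )
    return species, diets, int(per_species.iloc[0])


def summarize_means(records: pd.DataFrame, response: str) -> MeansTable:
    """Species x diet cell means with pooled SEM from the residual stratum.

    SEM = sqrt(MS_residual / n) with n animals per cell; NaN when the
    residual stratum has no degrees of freedom (single animal per cell).
    """
    sub = _pull_response(records, response)
    means = (
        sub.groupby(["species", "diet"], observed=True)["value"].mean().unstack("diet")
    )
    try:
        anova = split_plot_anova(records, response)
        n = sub.groupby(["species", "diet"], observed=True)["value"].size().iloc[0]
        df_resid = anova.table.loc["residual", "df"]
        sem = (
            math.sqrt(anova.sigma2_residual / n) if df_resid > 0 else float("nan")
        )
    except ValueError:
        sem = float("nan")
    return MeansTable(response, means, sem, int(sub.groupby(["species", "diet"], observed=True).size().iloc[0]))


def split_plot_anova(records: pd.DataFrame, response: str) -> AnovaTable:
    """Classic balanced split-plot ANOVA for one response.

    Raises ``ValueError`` on unbalanced input (see module docstring).
    Zero residual variance with a non-zero effect yields an infinite F
    and p = 0.
    """
    sub = _pull_response(records, response)
    species, diets, n = _check_balanced(sub)
    a, b = len(species), len(diets)
    if a < 2 or b < 2 or n < 2:
        raise ValueError("need >=2 species, >=2 diets and >=2 animals per species")

    y = sub.pivot_table(
        index=["species", "animal_id"], columns="diet", values="value", observed=True
    )  # (a*n) x b
    grand = float(y.values.mean())

    sp_means = y.mean(axis=1).groupby(level="species", observed=True).mean()  # a
    animal_means = y.mean(axis=1)  # a*n
    diet_means = y.mean(axis=0)  # b
    cell_means = (
        sub.groupby(["species", "diet"], observed=True)["value"].mean().unstack("diet")
    )  # a x b

    ss_species = n * b * float(((sp_means - grand) ** 2).sum())
    ss_animal = b * float(
        ((animal_means - sp_means.reindex(animal_means.index.get_level_values("species")).values) ** 2).sum()
    )
    ss_diet = a * n * float(((diet_means - grand) ** 2).sum())
    interaction_dev = (
        cell_means.sub(sp_means, axis=0).sub(diet_means, axis=1) + grand
    )
    ss_int = n * float((interaction_dev.values**2).sum())
    ss_total = float(((y.values - grand) ** 2).sum())
    ss_resid = ss_total - ss_species - ss_animal - ss_diet - ss_int
    ss_resid = max(ss_resid, 0.0)

    df_species = a - 1
    df_animal = a * (n - 1)
    df_diet = b - 1
    df_int = (a - 1) * (b - 1)
    df_total = a * b * n - 1
    df_resid = df_total - df_species - df_animal - df_diet - df_int

    ms_animal = ss_animal / df_animal
    ms_resid = ss_resid / df_resid

    def f_and_p(ss: float, df: int, ms_err: float, df_err: int) -> tuple[float, float]:
        ms = ss / df
        if ms_err == 0:
            return (math.inf, 0.0) if ms > 0 else (float("nan"), float("nan"))
        f = ms / ms_err
        return f, float(stats.f.sf(f, df, df_err))

    f_sp, p_sp = f_and_p(ss_species, df_species, ms_animal, df_animal)
    f_diet, p_diet = f_and_p(ss_diet, df_diet, ms_resid, df_resid)
    f_int, p_int = f_and_p(ss_int, df_int, ms_resid, df_resid)

    table = pd.DataFrame(
        {
            "ss": [ss_species, ss_animal, ss_diet, ss_int, ss_resid],
            "df": [df_species, df_animal, df_diet, df_int, df_resid],
            "error_stratum": ["animal(species)", "", "residual", "residual", ""],
            "ms": [
                ss_species / df_species,
                ms_animal,
                ss_diet / df_diet,
                ss_int / df_int,
                ms_resid,
            ],
            "F": [f_sp, float("nan"), f_diet, f_int, float("nan")],
            "p": [p_sp, float("nan"), p_diet, p_int, float("nan")],
        },
        index=["species", "animal(species)", "diet", "species:diet", "residual"],
    )
    sigma2_animal = max((ms_animal - ms_resid) / b, 0.0)
    return AnovaTable(response, table, sigma2_animal, ms_resid, ss_total, df_total)


def tukey_pairwise(
    cell_means: pd.DataFrame, ms_error: float, df_error: int, n_per_cell: int
) -> pd.DataFrame:
    """Tukey HSD adjusted p-values for all species x diet cell pairs.

    Uses the studentized-range distribution with ``k`` = number of
    cells and the supplied (sub-plot) error mean square.  For ``k = 2``
    this collapses to the unadjusted two-sample t-test from the same
    stratum.
    """
    if df_error <= 0:
        raise ValueError("df_error must be positive")
    if n_per_cell < 1 or ms_error < 0:
        raise ValueError("invalid error variance or cell size")

    cells = [
        (f"{sp}:{diet}", float(cell_means.loc[sp, diet]))
        for sp in cell_means.index
        for diet in cell_means.columns
    ]
    k = len(cells)
    se = math.sqrt(ms_error / n_per_cell)
    rows = []
    for (name_a, mean_a), (name_b, mean_b) in combinations(cells, 2):
        diff = mean_a - mean_b
        if se == 0:
            p_adj = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, df_error))
        rows.append(
            {"cell_a": name_a, "cell_b": name_b, "difference": diff, "p_adj": min(p_adj, 1.0)}
        )
    return pd.DataFrame(rows)


def significance_label(p: float) -> str:
    """Reporting convention: p<0.05 significant, 0.05<=p<0.1 a trend."""
    if math.isnan(p):
        return "na"
    if p < 0.05:
        return "significant"
    if p < 0.1:
        return "trend"
    return "ns"
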