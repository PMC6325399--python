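"""Reference group-mean tables from a cross-species acidosis feeding trial.

Three ruminant species (Hanwoo cattle, Holstein cattle, Korean native
goats; four animals each) were switched abruptly from a high-forage
ration (HF, 80:20 hay:concentrate) to concentrate only (HC).  The
published species x diet group means for rumen fermentation variables
and qPCR relative abundances (% of total bacteria) are reproduced here
as fixtures so that derived summaries — diet means, fold changes —
can be recomputed through the package's own operations.

Values are group means at printed precision; per-animal raw data were
not published.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "SPECIES",
    "DIETS",
    "fermentation_cell_means",
    "fermentation_sem",
    "abundance_cell_means",
    "abundance_sem",
    "cell_mean_records",
    "abundance_cell_records",
]

SPECIES = ("Hanwoo", "Holstein", "Goat")
DIETS = ("HF", "HC")

# response -> {(species, diet): mean}; units noted per response
_FERMENTATION = {
    # pH units
    "pH": [6.39, 5.56, 6.37, 5.14, 6.25, 5.90],
    # mg/dL
    "NH3-N": [1.27, 4.97, 2.56, 4.84, 5.19, 7.51],
    # mM
    "total_VFA": [74.3, 81.5, 63.1, 121.6, 59.4, 53.8],
    # mmol/mol of total VFA
    "acetate": [590, 470, 585, 464, 562, 478],
    "propionate": [175, 272, 170, 210, 218, 198],
    "butyrate": [123, 130, 118, 215, 88, 164],
    "isobutyrate": [59, 55, 68, 38, 71, 82],
    "valerate": [28, 46, 31, 55, 34, 44],
    "isovalerate": [25, 28, 29, 18, 27, 35],
    # unitless
    "A:P_ratio": [3.4, 1.8, 3.5, 2.5, 2.6, 2.5],
}

_FERMENTATION_SEM = {
    "pH": 0.121,
    "NH3-N": 1.890,
    "total_VFA": 6.81,
    "acetate": 13.2,
    "propionate": 23.4,
    "butyrate": 18.1,
    "isobutyrate": 6.3,
    "valerate": 4.2,
    "isovalerate": 3.3,
    "A:P_ratio": 0.29,
}

# taxon -> [Hanwoo HF, Hanwoo HC, Holstein HF, Holstein HC, Goat HF, Goat HC]
# relative abundance, % of total bacteria
_ABUNDANCE = {
    "Prevotella": [37.921, 40.747, 41.885, 37.905, 39.599, 51.827],
    "F_succinogenes": [0.774, 0.039, 0.819, 0.099, 2.187, 0.171],
    "R_flavefaciens": [0.010, 0.025, 0.016, 0.001, 0.008, 0.003],
    "S_bovis": [2.715, 0.020, 0.782, 0.011, 0.158, 0.015],
    "Lactobacillus": [0.016, 0.380, 0.040, 1.041, 0.002, 0.862],
    "S_ruminantium": [3.475, 3.037, 3.632, 3.169, 5.812, 3.902],
    "M_elsdenii": [0.001, 1.450, 0.002, 3.402, 0.001, 1.692],
}

_ABUNDANCE_SEM = {
    "Prevotella": 3.7177,
    "F_succinogenes": 0.3642,
    "R_flavefaciens": 0.0081,
    "S_bovis": 0.9344,
    "Lactobacillus": 0.3862,
    "S_ruminantium": 1.4698,
    "M_elsdenii": 0.7372,
}

_CELLS = [(sp, diet) for sp in SPECIES for diet in DIETS]


def _cell_frame(values: list[float]) -> pd.DataFrame:
    frame = pd.DataFrame(index=list(SPECIES), columns=list(DIETS), dtype=float)
    for (sp, diet), v in zip(_CELLS, values):
        frame.loc[sp, diet] = v
    return frame


def fermentation_cell_means(response: str) -> pd.DataFrame:
    """Species x diet mean table for one fermentation response."""
    return _cell_frame(_FERMENTATION[response])


def fermentation_sem(response: str) -> float:
    return _FERMENTATION_SEM[response]


def abundance_cell_means(taxon: str) -> pd.DataFrame:
    """Species x diet mean relative abundance (% of total) for one taxon."""
    return _cell_frame(_ABUNDANCE[taxon])


def abundance_sem(taxon: str) -> float:
    return _ABUNDANCE_SEM[taxon]


def cell_mean_records(response: str) -> pd.DataFrame:
    """One pseudo-record per species x diet cell, for summarize_means.

    Group means over these records reproduce the published cell means
    exactly, so diet-level and species-level summaries can be recomputed
    through the same code paths as raw data.
    """
    rows = []
    for (sp, diet), v in zip(_CELLS, _FERMENTATION[response]):
        rows.append(
            {
                "species": sp,
                "animal_id": f"{sp}-mean",
                "diet": diet,
                "response": response,
                "value": float(v),
            }
        )
    return pd.DataFrame(rows)


def abundance_cell_records() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(abundances, meta) with one pseudo-sample per species x diet cell.

    Shaped for :func:`rumenprof.qpcr.group_fold_change`: group means over
    these records equal the published cell means.
    """
    abundance_rows = []
    meta_rows = []
    for sp, diet in _CELLS:
        sid = f"{sp}-{diet}"
        meta_rows.append(
            {"sample_id": sid, "species": sp, "animal_id": f"{sp}-mean", "diet": diet}
        )
        for taxon, values in _ABUNDANCE.items():
            v = values[_CELLS.index((sp, diet))]
            abundance_rows.append(
                {"sample_id": sid, "taxon": taxon, "abundance_percent": float(v)}
            )
    return pd.DataFrame(abundance_rows), pd.DataFrame(meta_rows)
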