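"""End-to-end drivers: simulate a full study, run the T-RF chain, summarize.

These functions are the glue the analysis scripts and the CLI share;
all per-stage computation lives in the stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import datasets
from .config import PipelineConfig
from .qpcr import CtRecord
from .synthetic import (
    CommunityProfile,
    SimConfig,
    simulate_community,
    simulate_ct_table,
    simulate_electropherogram,
    simulate_fermentation,
)
from .trflp import (
    BinnedMatrix,
    PeakTable,
    TruePeakSet,
    bin_fragments,
    detect_true_peaks,
    filter_by_size,
    standardize,
)

__all__ = ["StudyData", "simulate_study", "trflp_chain"]


def _child_seed(seed: int | None, *key: int) -> int:
    """Deterministic sub-seed below 2^31 from a global seed and a stream key."""
    ss = np.random.SeedSequence(seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class StudyData:
    """A simulated study with its ground truth.

    ``peaks``/``ct``/``fermentation``/``meta`` are tidy frames in the
    same shapes the io readers produce; ``communities`` maps sample_id
    to its planted :class:`CommunityProfile` and ``planted_abundance``
    holds the planted qPCR % of total per sample x taxon.
    """

    meta: pd.DataFrame
    peak_tables: dict[str, PeakTable]
    ct_records: list[CtRecord]
    fermentation: pd.DataFrame
    communities: dict[str, CommunityProfile]
    planted_abundance: pd.DataFrame

    def peaks_frame(self) -> pd.DataFrame:
        return pd.concat([t.to_frame() for t in self.peak_tables.values()], ignore_index=True)

    def ct_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": r.sample_id, "taxon": r.taxon, "replicate": i + 1, "ct": ct}
            for r in self.ct_records
            for i, ct in enumerate(r.replicate_cts)
        ]
        return pd.DataFrame(rows)


def simulate_study(config: SimConfig | None = None, seed: int | None = None) -> StudyData:
    """Simulate the full crossed study: 3 species x n animals x 2 diets.

    Each species x diet cell gets its own community over a shared pool
    of fragment lengths (a geometric rank-abundance curve permuted per
    cell), with mild per-sample Dirichlet jitter, so community structure
    genuinely differs between cells.  Planted qPCR abundances are the
    reference trial's species x diet mean abundances; fermentation
    responses use the reference cell means with animal and residual
    variability scaled from the reported SEM.
    """
    config = config or SimConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))

    species = list(datasets.SPECIES)[: config.n_species]
    diets = list(datasets.DIETS)

    pool = simulate_community(
        config.n_taxa,
        "uniform",
        seed=_child_seed(seed, 1),
        size_window=config.size_window,
        min_spacing=2 * config.binning_tolerance,
    )
    base = 0.7 ** np.arange(config.n_taxa)
    base /= base.sum()

    meta_rows = []
    peak_tables: dict[str, PeakTable] = {}
    communities: dict[str, CommunityProfile] = {}
    ct_records: list[CtRecord] = []
    planted_rows = []

    taxa = list(datasets._ABUNDANCE)
    for si, sp in enumerate(species):
        for di, diet in enumerate(diets):
            cell_abund = rng.permutation(base)
            for j in range(config.n_animals):
                sid = f"{sp}{j + 1}{diet}"
                meta_rows.append(
                    {"sample_id": sid, "species": sp, "animal_id": f"{sp}-{j + 1}", "diet": diet}
                )
                jitter = rng.dirichlet(cell_abund * 200.0)
                community = CommunityProfile(pool.lengths, jitter)
                communities[sid] = community
                peak_tables[sid] = simulate_electropherogram(
                    community,
                    config,
                    seed=_child_seed(seed, 2, si, di, j),
                    sample_id=sid,
                )
                planted = {
                    taxon: float(datasets.abundance_cell_means(taxon).loc[sp, diet])
                    for taxon in taxa
                }
                ct_records.extend(
                    simulate_ct_table(
                        planted,
                        ct_total=config.ct_total,
                        ct_noise_sd=config.ct_noise_sd,
                        n_replicates=config.n_replicates,
                        seed=_child_seed(seed, 3, si, di, j),
                        sample_id=sid,
                    )
                )
                for taxon, pct in planted.items():
                    planted_rows.append({"sample_id": sid, "taxon": taxon, "planted_percent": pct})

    ferment_frames = []
    for ri, response in enumerate(datasets._FERMENTATION):
        sigma_e = datasets.fermentation_sem(response) * np.sqrt(config.n_animals)
        ferment_frames.append(
            simulate_fermentation(
                cell_means=datasets.fermentation_cell_means(response),
                species=tuple(species),
                diets=tuple(diets),
                n_animals=config.n_animals,
                sigma_animal=sigma_e,
                sigma_e=sigma_e,
                response=response,
                seed=_child_seed(seed, 4, ri),
            )
        )

    return StudyData(
        meta=pd.DataFrame(meta_rows),
        peak_tables=peak_tables,
        ct_records=ct_records,
        fermentation=pd.concat(ferment_frames, ignore_index=True),
        communities=communities,
        planted_abundance=pd.DataFrame(planted_rows),
    )


def trflp_chain(
    peak_tables: dict[str, PeakTable] | list[PeakTable],
    config: PipelineConfig | None = None,
) -> tuple[list[TruePeakSet], BinnedMatrix]:
    """Size filter -> true-peak calling -> binning -> standardization.

    Returns the per-sample true-peak sets and the standardized
    bins x samples matrix.
    """
    config = config or PipelineConfig()
    tables = list(peak_tables.values()) if isinstance(peak_tables, dict) else list(peak_tables)
    true_sets = [
        detect_true_peaks(
            filter_by_size(table, config.min_bp, config.max_bp), k_sd=config.k_sd
        )
        for table in tables
    ]
    matrix = bin_fragments(true_sets, tolerance_bp=config.binning_tolerance)
    return true_sets, standardize(matrix)
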