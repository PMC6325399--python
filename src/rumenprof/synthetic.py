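"""Synthetic electropherograms, Ct tables and fermentation records.

Every downstream stage of the pipeline is exercised against data with
known ground truth: a planted community of a few dominant fragments
over many low background peaks, Ct values consistent with planted
relative abundances under doubling-per-cycle amplification, and
fermentation responses built from additive species/diet/interaction
fixed effects with random animal intercepts.

A single global seed fans out to independent per-stream generators via
``numpy.random.SeedSequence`` spawn keys, so adding one stream never
perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qpcr import TOTAL_TAXON, CtRecord
from .trflp import PeakTable

__all__ = [
    "CommunityProfile",
    "SimConfig",
    "simulate_community",
    "simulate_electropherogram",
    "simulate_ct_table",
    "simulate_fermentation",
]

# fixed spawn-key offsets, one per random stream
_STREAM_COMMUNITY = 0
_STREAM_ELECTRO = 1
_STREAM_CT = 2
_STREAM_FERMENT = 3


def _rng(seed: int | None, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class CommunityProfile:
    """Planted ground truth: true T-RF lengths and their proportions."""

    lengths: np.ndarray  # bp, within the size window
    abundances: np.ndarray  # proportions summing to 1

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float)
        abund = np.asarray(self.abundances, dtype=float)
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "abundances", abund)
        if lengths.shape != abund.shape:
            raise ValueError("lengths and abundances must align")
        if np.any(abund < 0):
            raise ValueError("abundances must be non-negative")
        # empty profile (background-only simulation) is allowed
        if len(abund) and abs(abund.sum() - 1.0) > 1e-12:
            raise ValueError("abundances must sum to 1")

    @property
    def n_taxa(self) -> int:
        return len(self.lengths)


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    Heights are in RFU.  ``signal_scale`` is the summed height of a
    sample's true peaks, split among taxa by abundance; background peak
    heights are |N(0, background_scale)|, keeping the zero-anchored
    scale that the detection rule estimates.  The signal-to-background
    ratio must exceed 10 so planted peaks stay recoverable by the
    3-SD rule.

    The default community is a geometric rank-abundance curve (ratio
    0.9): a field of equally abundant taxa is both unrealistic and,
    beyond ~n_background/8 taxa, mathematically self-masking under the
    iterative threshold, whereas a decreasing series is peeled off top
    down.  With the defaults the rarest of 20 taxa still sits ~6x above
    the detection threshold.
    """

    n_taxa: int = 10
    community_model: str = "geometric"
    geometric_ratio: float = 0.9
    n_background: int = 150
    background_scale: float = 50.0
    signal_scale: float = 20_000.0
    height_cv: float = 0.02
    size_window: tuple[float, float] = (27.0, 520.0)
    binning_tolerance: float = 0.5
    ct_total: float = 20.0
    ct_noise_sd: float = 0.2
    n_replicates: int = 3
    n_species: int = 3
    n_animals: int = 4
    sigma_animal: float = 0.3
    sigma_e: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.background_scale > 0 and self.signal_scale <= 10 * self.background_scale:
            raise ValueError("signal_scale must exceed 10x background_scale")
        for name in ("background_scale", "height_cv", "ct_noise_sd", "sigma_animal", "sigma_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def simulate_community(
    n_taxa: int,
    model: str = "uniform",
    seed: int | None = None,
    *,
    geometric_ratio: float = 0.5,
    size_window: tuple[float, float] = (27.0, 520.0),
    min_spacing: float = 1.0,
) -> CommunityProfile:
    """Draw a planted community of ``n_taxa`` fragments.

    Abundance models: ``uniform`` (all equal), ``geometric``
    (proportional to ``geometric_ratio**i``), ``broken-stick`` (uniform
    stick breaking).  Fragment lengths are uniform in the size window
    with pairwise spacing at least ``min_spacing`` (rejection sampling),
    which should be at least twice the binning tolerance so the binning
    ground truth is unambiguous.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    rng = _rng(seed, _STREAM_COMMUNITY)

    lengths = np.empty(0)
    lo, hi = size_window
    while len(lengths) < n_taxa:
        candidate = rng.uniform(lo, hi)
        if lengths.size == 0 or np.min(np.abs(lengths - candidate)) >= min_spacing:
            lengths = np.append(lengths, candidate)
    lengths.sort()

    if model == "uniform":
        abund = np.full(n_taxa, 1.0 / n_taxa)
    elif model == "geometric":
        if not 0 < geometric_ratio < 1:
            raise ValueError("geometric_ratio must be in (0, 1)")
        raw = geometric_ratio ** np.arange(n_taxa)
        abund = raw / raw.sum()
    elif model == "broken-stick":
        cuts = np.sort(rng.uniform(0, 1, size=n_taxa - 1))
        abund = np.diff(np.concatenate(([0.0], cuts, [1.0])))
    else:
        raise ValueError(f"unknown abundance model {model!r}")
    # re-normalize defensively against accumulated float error
    abund = abund / abund.sum()
    return CommunityProfile(lengths, abund)


def simulate_electropherogram(
    community: CommunityProfile,
    config: SimConfig | None = None,
    seed: int | None = None,
    sample_id: str = "S1",
) -> PeakTable:
    """Planted true peaks plus half-normal background peaks.

    True peak heights are ``signal_scale * abundance`` with small
    multiplicative Gaussian noise (CV ``height_cv``); background peaks
    sit at uniform-random lengths in the size window with heights
    ``|N(0, background_scale)|``.  All emitted heights are positive.
    """
    config = config or SimConfig()
    rng = _rng(seed, _STREAM_ELECTRO)
    lo, hi = config.size_window

    true_heights = config.signal_scale * community.abundances
    if config.height_cv > 0 and community.n_taxa:
        noise = rng.normal(0.0, config.height_cv, size=community.n_taxa)
        true_heights = true_heights * np.clip(1.0 + noise, 0.05, None)

    bg_sizes = rng.uniform(lo, hi, size=config.n_background)
    bg_heights = np.abs(rng.normal(0.0, config.background_scale, size=config.n_background))
    # heights must be strictly positive; an exact zero has measure zero
    bg_heights = np.maximum(bg_heights, np.finfo(float).tiny)

    sizes = np.concatenate([community.lengths, bg_sizes])
    heights = np.concatenate([true_heights, bg_heights])
    if config.background_scale == 0:
        sizes, heights = community.lengths, true_heights
    order = np.argsort(sizes)
    return PeakTable(sample_id, sizes[order], heights[order])


def simulate_ct_table(
    abundances_percent: dict[str, float],
    ct_total: float = 20.0,
    ct_noise_sd: float = 0.2,
    n_replicates: int = 3,
    seed: int | None = None,
    sample_id: str = "S1",
) -> list[CtRecord]:
    """Replicate Ct values consistent with planted relative abundances.

    Inverts the 2^-dCt transform: a taxon at ``a``% of total bacteria
    amplifies ``log2(a/100)`` cycles after the total-bacteria assay,
    plus Gaussian cycle noise.  A total-bacteria record is always
    emitted.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = _rng(seed, _STREAM_CT)

    records = []
    total_cts = ct_total + rng.normal(0.0, ct_noise_sd, size=n_replicates)
    records.append(CtRecord(sample_id, TOTAL_TAXON, tuple(total_cts)))
    for taxon, pct in abundances_percent.items():
        if pct <= 0:
            raise ValueError(f"abundance for {taxon!r} must be positive (got {pct})")
        true_ct = ct_total - np.log2(pct / 100.0)
        cts = true_ct + rng.normal(0.0, ct_noise_sd, size=n_replicates)
        records.append(CtRecord(sample_id, taxon, tuple(cts)))
    return records


@dataclass(frozen=True)
class _Design:
    species: tuple[str, ...]
    diets: tuple[str, ...]
    n_animals: int


def simulate_fermentation(
    cell_means: pd.DataFrame | None = None,
    *,
    mu: float = 0.0,
    species_effects: dict[str, float] | None = None,
    diet_effects: dict[str, float] | None = None,
    interaction: dict[tuple[str, str], float] | None = None,
    species: tuple[str, ...] = ("Hanwoo", "Holstein", "Goat"),
    diets: tuple[str, ...] = ("HF", "HC"),
    n_animals: int = 4,
    sigma_animal: float = 0.3,
    sigma_e: float = 0.1,
    response: str = "pH",
    seed: int | None = None,
) -> pd.DataFrame:
    """Balanced species x animal x diet records with additive effects.

    The fixed part of each observation is either looked up from
    ``cell_means`` (index = species, columns = diets) or assembled as
    ``mu + species + diet + interaction``.  Animal intercepts are
    N(0, sigma_animal^2) and residuals N(0, sigma_e^2), matching a
    split-plot design in which diet varies within animal.

    Returns a tidy frame with columns species, animal_id, diet,
    response, value.
    """
    if n_animals < 2 and (sigma_animal > 0 or sigma_e > 0):
        raise ValueError("need at least 2 animals per species for a stochastic design")
    rng = _rng(seed, _STREAM_FERMENT)

    def fixed(sp: str, diet: str) -> float:
        if cell_means is not None:
            return float(cell_means.loc[sp, diet])
        val = mu
        val += (species_effects or {}).get(sp, 0.0)
        val += (diet_effects or {}).get(diet, 0.0)
        val += (interaction or {}).get((sp, diet), 0.0)
        return val

    rows = []
    for sp in species:
        animal_intercepts = rng.normal(0.0, sigma_animal, size=n_animals)
        for j in range(n_animals):
            animal_id = f"{sp}-{j + 1}"
            for diet in diets:
                value = fixed(sp, diet) + animal_intercepts[j] + rng.normal(0.0, sigma_e)
                rows.append(
                    {
                        "species": sp,
                        "animal_id": animal_id,
                        "diet": diet,
                        "response": response,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)
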