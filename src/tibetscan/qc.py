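"""Variant-level quality control and population-contrast filters.

The QC chain mirrors the study pipeline order: genotypes below the quality
threshold are masked to missing first, then sites exceeding the missingness
cap are removed, then sites discordant between duplicate callsets are
blacklisted. All filters are pure functions; thresholds default to the
published values (quality 30, 5% missingness, 5% discordance, 10%/1%
enrichment contrast, 5% archaic-mask MAF).
"""

from __future__ import annotations

import numpy as np

from .data_model import MISSING, SiteFrequencyTable

__all__ = [
    "mask_low_quality",
    "drop_high_missing",
    "drop_discordant_sites",
    "enriched_variant_filter",
    "archaic_like_mask",
]


def mask_low_quality(
    genotypes: np.ndarray, qualities: np.ndarray, threshold: float = 30.0
) -> np.ndarray:
    """Set genotypes with phred quality below ``threshold`` to missing.

    Shapes of ``genotypes`` and ``qualities`` must match; the input is not
    modified.
    """
    genotypes = np.asarray(genotypes)
    qualities = np.asarray(qualities)
    if genotypes.shape != qualities.shape:
        raise ValueError("genotypes and qualities must have identical shape")
    out = genotypes.copy()
    out[qualities < threshold] = MISSING
    return out


def drop_high_missing(
    genotypes: np.ndarray, max_missing_fraction: float = 0.05
) -> np.ndarray:
    """Keep-mask for sites whose missing fraction is <= the cap.

    ``genotypes`` is (sites, samples) with ``MISSING`` entries; order of the
    surviving sites is preserved by boolean masking.
    """
    genotypes = np.asarray(genotypes)
    miss = (genotypes == MISSING).mean(axis=1)
    return miss <= max_missing_fraction


def drop_discordant_sites(
    callset_a: np.ndarray,
    callset_b: np.ndarray,
    max_discordance: float = 0.05,
) -> np.ndarray:
    """Blacklist mask for sites with too many discordant duplicate calls.

    Both callsets are (sites, shared_samples) unphased genotype dosages
    aligned on the same samples and sites (phase-insensitive comparison:
    the two callsets were phased independently). Discordance at a site is
    the fraction of samples, among those called in both sets, with unequal
    genotypes. Returns True where the site is blacklisted.
    """
    a = np.asarray(callset_a)
    b = np.asarray(callset_b)
    if a.shape != b.shape:
        raise ValueError("callsets must be aligned (same sites x samples)")
    if a.shape[1] == 0:
        raise ValueError("no shared samples between callsets")
    both = (a != MISSING) & (b != MISSING)
    diff = (a != b) & both
    n_called = both.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disc = np.where(n_called > 0, diff.sum(axis=1) / n_called, 0.0)
    return disc > max_discordance


def enriched_variant_filter(
    freqs: SiteFrequencyTable,
    target_population: str,
    reference_populations: list[str],
    target_min: float = 0.10,
    reference_max: float = 0.01,
) -> np.ndarray:
    """Sites frequent in the target but rare in every reference population.

    A site passes iff derived frequency > ``target_min`` in the target AND
    < ``reference_max`` in each reference population separately (the
    conjunction over references is the strict reading of the published
    filter). Sites with no called chromosomes in a required population
    fail.
    """
    f_t = freqs.frequency(target_population)
    with np.errstate(invalid="ignore"):
        passing = f_t > target_min  # NaN (uncalled) compares False
        for pop in reference_populations:
            passing &= freqs.frequency(pop) < reference_max
    return passing


def archaic_like_mask(
    freqs: SiteFrequencyTable,
    archaic_track: str = "DEN",
    target_population: str = "TIB",
    reference_populations: list[str] | None = None,
    maf_max: float = 0.05,
) -> np.ndarray:
    """Archaic-like sites: derived allele carried by the archaic genome and
    by >= 1 target haplotype, but uncommon (folded MAF < ``maf_max``) in
    every listed reference population.

    "Carried by the archaic" means at least one archaic chromosome has the
    derived allele (het or hom); a missing archaic call never qualifies.
    """
    refs = reference_populations if reference_populations is not None else [
        p for p in freqs.populations if p != target_population
    ]
    d_arch, t_arch = freqs.archaic[archaic_track]
    mask = (t_arch > 0) & (d_arch > 0)
    mask &= freqs.derived[target_population] > 0
    with np.errstate(invalid="ignore"):
        for pop in refs:
            mask &= freqs.minor_allele_frequency(pop) < maf_max  # NaN -> False
    return mask
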