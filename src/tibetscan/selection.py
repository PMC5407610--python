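"""Component statistics of the composite selection scan.

Implements the five per-site statistics combined by the composite score —
iHS, XP-EHH, ΔiHH, F_ST and ΔDAF — plus the three-population PBS. EHH-based
statistics integrate over genetic distance (cM), falling back to physical
distance at 1 cM/Mb when no genetic map is attached, and truncate the
outward integration where EHH drops below 0.05 (the conventional cutoff in
the EHH literature).

Sign conventions: ``ihs_raw = ln(iHH_A / iHH_D)`` (ancestral over derived),
so long unbroken *derived* haplotypes give negative raw iHS;
``delta_daf = DAF_target - DAF_reference``; ``xpehh_raw =
ln(iHH_pop_A / iHH_pop_B)`` is positive when population A carries the
longer haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import MISSING, HaplotypePanel

__all__ = [
    "site_fst",
    "fst_terms",
    "genomewide_fst",
    "delta_daf",
    "ehh_profile",
    "haplotype_scores",
    "xpehh_raw",
    "normalize_scores",
    "pbs",
    "component_scan",
]


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


def fst_terms(
    count1: np.ndarray,
    size1: np.ndarray | float,
    count2: np.ndarray,
    size2: np.ndarray | float,
    estimator: str = "hudson",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (numerator, denominator) of the chosen F_ST estimator.

    ``hudson``: N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    D = p1(1-p2) + p2(1-p1). ``wc`` is the two-population Weir-Cockerham
    theta for haploid allele counts. Both are meant to be combined across
    sites as ratio-of-sums.
    """
    c1 = np.asarray(count1, dtype=float)
    c2 = np.asarray(count2, dtype=float)
    n1 = np.asarray(size1, dtype=float)
    n2 = np.asarray(size2, dtype=float)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("need >= 2 chromosomes per population")
    p1, p2 = c1 / n1, c2 / n2
    if estimator == "hudson":
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    elif estimator == "wc":
        r = 2.0
        nbar = (n1 + n2) / r
        nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
        pbar = (c1 + c2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2) / (nbar - 1))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2)
        num, den = a, a + b
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return num, den


def site_fst(
    count1: float, size1: float, count2: float, size2: float, estimator: str = "hudson"
) -> float:
    """Single-site F_ST; NaN when both samples are monomorphic for the same
    allele (no information about differentiation). May be negative."""
    num, den = fst_terms(count1, size1, count2, size2, estimator)
    den = float(den)
    if den == 0.0:
        return float("nan")
    return float(num) / den


def genomewide_fst(
    count1: np.ndarray,
    size1: np.ndarray | float,
    count2: np.ndarray,
    size2: np.ndarray | float,
    estimator: str = "hudson",
) -> float:
    """Ratio-of-sums F_ST over polymorphic sites (never mean-of-ratios)."""
    num, den = fst_terms(count1, size1, count2, size2, estimator)
    valid = den != 0
    total = den[valid].sum()
    if not np.any(valid) or total == 0:
        raise ValueError("no polymorphic sites: zero denominator sum")
    return float(num[valid].sum() / total)


def delta_daf(freq_target: np.ndarray, freq_reference: np.ndarray) -> np.ndarray:
    """Derived-allele frequency difference, target minus reference."""
    return np.asarray(freq_target, dtype=float) - np.asarray(freq_reference, dtype=float)


def pbs(fst_th: float, fst_te: float, fst_he: float) -> float:
    """Population branch statistic from the three pairwise F_ST values.

    Negative F_ST inputs are clamped to 0 before the log transform
    T = -ln(1 - F); any F_ST = 1 gives NaN (infinite branch).
    """
    fs = np.array([fst_th, fst_te, fst_he], dtype=float)
    if np.any(fs >= 1.0):
        return float("nan")
    fs = np.clip(fs, 0.0, None)
    t = -np.log(1.0 - fs)
    return float((t[0] + t[1] - t[2]) / 2.0)


# ---------------------------------------------------------------------------
# EHH family
# ---------------------------------------------------------------------------


def _ehh_steps(alleles: np.ndarray, cols: np.ndarray, stop_below: float) -> np.ndarray:
    """Partition-refinement EHH walk (pure-numpy reference implementation).

    Returns EHH at each visited site, stopping early once EHH drops below
    ``stop_below`` (pass a negative threshold to disable) or reaches 0.
    """
    n = alleles.shape[0]
    n_pairs = n * (n - 1) / 2.0
    group = np.zeros(n, dtype=np.int64)
    out = np.empty(cols.size, dtype=np.float64)
    for j in range(cols.size):
        key = group * 4 + (alleles[:, cols[j]] + 1)
        _, group = np.unique(key, return_inverse=True)
        counts = np.bincount(group)
        out[j] = (counts * (counts - 1) / 2.0).sum() / n_pairs
        if out[j] < stop_below or out[j] == 0.0:
            return out[: j + 1]
    return out


try:  # optional compiled kernel; identical semantics to _ehh_steps
    from numba import njit

    @njit(cache=False)
    def _ehh_steps_jit(alleles, cols, stop_below):  # pragma: no cover
        n = alleles.shape[0]
        n_pairs = n * (n - 1) / 2.0
        group = np.zeros(n, dtype=np.int64)
        key = np.empty(n, dtype=np.int64)
        out = np.empty(cols.size, dtype=np.float64)
        for j in range(cols.size):
            c = cols[j]
            for i in range(n):
                key[i] = group[i] * 4 + alleles[i, c] + 1
            order = np.argsort(key)
            g = 0
            prev = key[order[0]]
            group[order[0]] = 0
            for t in range(1, n):
                k2 = key[order[t]]
                if k2 != prev:
                    g += 1
                    prev = k2
                group[order[t]] = g
            counts = np.zeros(g + 1, dtype=np.float64)
            for i in range(n):
                counts[group[i]] += 1.0
            acc = 0.0
            for x in counts:
                acc += x * (x - 1.0) / 2.0
            out[j] = acc / n_pairs
            if out[j] < stop_below or out[j] == 0.0:
                return out[: j + 1]
        return out

    _EHH_IMPL = _ehh_steps_jit
except ImportError:  # pragma: no cover
    _EHH_IMPL = _ehh_steps


def _ehh_outward(
    alleles: np.ndarray, order: np.ndarray, stop_below: float | None = None
) -> np.ndarray:
    """EHH over a set of haplotypes at successive sites in ``order``.

    EHH at step j is the probability that two random haplotypes from the
    set are identical over all sites visited up to j (inclusive). Missing
    alleles count as a distinct state (they break homozygosity). With
    ``stop_below`` set, extension stops after the first value under the
    threshold (the returned profile includes that crossing value);
    otherwise the full-length profile is returned (zero-filled beyond the
    point where all haplotypes become distinct).
    """
    if order.size == 0 or alleles.shape[0] < 2:
        return np.zeros(order.size)
    cols = np.ascontiguousarray(order, dtype=np.int64)
    res = _EHH_IMPL(
        np.ascontiguousarray(alleles), cols,
        -1.0 if stop_below is None else float(stop_below),
    )
    if stop_below is None and res.size < order.size:
        res = np.concatenate([res, np.zeros(order.size - res.size)])
    return res


def ehh_profile(
    panel: HaplotypePanel, core_site: int, core_allele: int
) -> tuple[np.ndarray, np.ndarray]:
    """EHH of the carriers of ``core_allele`` at each flanking site.

    Returns ``(ehh_left, ehh_right)`` ordered outward from the core (the
    value at offset 0 corresponds to the site adjacent to the core; EHH at
    the core itself is 1 by definition). Requires >= 2 carriers.
    """
    carriers = np.flatnonzero(panel.alleles[:, core_site] == core_allele)
    if carriers.size < 2:
        raise ValueError("need >= 2 carrier haplotypes for EHH")
    sub = panel.alleles[carriers]
    left = np.arange(core_site - 1, -1, -1)
    right = np.arange(core_site + 1, panel.n_sites)
    return _ehh_outward(sub, left), _ehh_outward(sub, right)


def _ihh_one_side(
    ehh: np.ndarray, dist_cm: np.ndarray, truncation: float
) -> tuple[float, bool]:
    """Trapezoidal integral of one outward EHH branch over genetic distance.

    Integration starts at the core (EHH = 1, distance 0) and stops at the
    first site where EHH < ``truncation``; returns (integral, hit_edge)
    where hit_edge means the chromosome ended before EHH decayed.
    """
    ehh_full = np.concatenate(([1.0], ehh))
    d_full = np.concatenate(([0.0], dist_cm))
    below = np.flatnonzero(ehh_full < truncation)
    if below.size:
        stop = below[0] + 1  # include the crossing segment
        return float(np.trapezoid(ehh_full[:stop], d_full[:stop])), False
    return float(np.trapezoid(ehh_full, d_full)), True


@dataclass
class HaplotypeScores:
    ihh_ancestral: float
    ihh_derived: float
    ihs_raw: float
    delta_ihh_raw: float
    valid: bool
    reason: str = ""


def haplotype_scores(
    panel: HaplotypePanel,
    core_site: int,
    truncation: float = 0.05,
    min_carriers: int = 2,
    daf_range: tuple[float, float] = (0.05, 0.95),
) -> HaplotypeScores:
    """iHH for both core alleles, raw iHS and raw ΔiHH at one site.

    Invalid (flagged, not scored) when either allele has < ``min_carriers``
    carriers, the derived iHH is 0 (no infinite log ratios), or the derived
    frequency falls outside ``daf_range``.
    """
    col = panel.alleles[:, core_site]
    called = col != MISSING
    n_der = int((col == 1).sum())
    n_anc = int((col == 0).sum())
    n = n_der + n_anc
    if n == 0:
        return HaplotypeScores(np.nan, np.nan, np.nan, np.nan, False, "all missing")
    daf = n_der / n
    if not (daf_range[0] <= daf <= daf_range[1]):
        return HaplotypeScores(np.nan, np.nan, np.nan, np.nan, False, "daf out of range")
    if min(n_der, n_anc) < min_carriers:
        return HaplotypeScores(np.nan, np.nan, np.nan, np.nan, False, "too few carriers")
    cm = panel.cm_positions()
    d_left = cm[core_site] - cm[core_site - 1 :: -1] if core_site > 0 else np.empty(0)
    d_right = cm[core_site + 1 :] - cm[core_site]
    left = np.arange(core_site - 1, -1, -1)
    right = np.arange(core_site + 1, panel.n_sites)
    ihh = {}
    for allele in (0, 1):
        carriers = panel.alleles[panel.alleles[:, core_site] == allele]
        ehh_l = _ehh_outward(carriers, left, stop_below=truncation)
        ehh_r = _ehh_outward(carriers, right, stop_below=truncation)
        il, _ = _ihh_one_side(ehh_l, d_left[: ehh_l.size], truncation)
        ir, _ = _ihh_one_side(ehh_r, d_right[: ehh_r.size], truncation)
        ihh[allele] = il + ir
    if ihh[1] == 0.0 or ihh[0] == 0.0:
        return HaplotypeScores(ihh[0], ihh[1], np.nan, np.nan, False, "zero iHH")
    return HaplotypeScores(
        ihh_ancestral=ihh[0],
        ihh_derived=ihh[1],
        ihs_raw=float(np.log(ihh[0] / ihh[1])),
        delta_ihh_raw=ihh[0] - ihh[1],
        valid=True,
    )


def _population_ihh(
    alleles: np.ndarray,
    dist_left: np.ndarray,
    dist_right: np.ndarray,
    core_site: int,
    stop_left: int | None,
    stop_right: int | None,
) -> float:
    """Unconditional population iHH at a core site: integral of the
    probability that two random haplotypes of the population are identical
    from the core outward. ``stop_*`` give the truncation index determined
    on the pooled panel (shared between populations)."""
    left = np.arange(core_site - 1, -1, -1)
    right = np.arange(core_site + 1, alleles.shape[1])
    if stop_left is not None:
        left = left[:stop_left]
        dist_left = dist_left[:stop_left]
    if stop_right is not None:
        right = right[:stop_right]
        dist_right = dist_right[:stop_right]
    ehh_l = _ehh_outward(alleles, left)
    ehh_r = _ehh_outward(alleles, right)
    il = float(np.trapezoid(np.concatenate(([1.0], ehh_l)), np.concatenate(([0.0], dist_left))))
    ir = float(np.trapezoid(np.concatenate(([1.0], ehh_r)), np.concatenate(([0.0], dist_right))))
    return il + ir


def xpehh_raw(
    panel_a: HaplotypePanel,
    panel_b: HaplotypePanel,
    core_site: int,
    truncation: float = 0.05,
) -> float:
    """Raw cross-population EHH score ln(iHH_A / iHH_B) at a core site.

    Both panels must share the same site frame. Integration for both
    populations is truncated where the EHH of the pooled panel drops below
    ``truncation``, so the two integrals cover the same interval. NaN when
    either population's iHH is 0.
    """
    if panel_a.n_sites != panel_b.n_sites:
        raise ValueError("panels must share the same sites")
    pooled = np.vstack([panel_a.alleles, panel_b.alleles])
    cm = panel_a.cm_positions()
    d_left = cm[core_site] - cm[core_site - 1 :: -1] if core_site > 0 else np.empty(0)
    d_right = cm[core_site + 1 :] - cm[core_site]
    left = np.arange(core_site - 1, -1, -1)
    right = np.arange(core_site + 1, panel_a.n_sites)
    pooled_l = _ehh_outward(pooled, left, stop_below=truncation)
    pooled_r = _ehh_outward(pooled, right, stop_below=truncation)

    def _stop(ehh: np.ndarray) -> int | None:
        below = np.flatnonzero(ehh < truncation)
        return int(below[0] + 1) if below.size else None

    sl, sr = _stop(pooled_l), _stop(pooled_r)
    ihh_a = _population_ihh(panel_a.alleles, d_left, d_right, core_site, sl, sr)
    ihh_b = _population_ihh(panel_b.alleles, d_left, d_right, core_site, sl, sr)
    if ihh_a == 0.0 or ihh_b == 0.0:
        return float("nan")
    return float(np.log(ihh_a / ihh_b))


def normalize_scores(raw: np.ndarray, mean: float | None = None, sd: float | None = None) -> np.ndarray:
    """Genome-wide z-normalization over valid (finite) scores.

    When ``mean``/``sd`` are given (e.g. learned from a neutral ensemble)
    they are used instead of the in-sample moments.
    """
    raw = np.asarray(raw, dtype=float)
    finite = np.isfinite(raw)
    if finite.sum() < 2 and (mean is None or sd is None):
        raise ValueError("need >= 2 valid scores to normalize")
    mu = float(np.mean(raw[finite])) if mean is None else mean
    sigma = float(np.std(raw[finite], ddof=0)) if sd is None else sd
    if sigma == 0.0:
        raise ValueError("zero variance: cannot normalize")
    out = np.full(raw.shape, np.nan)
    out[finite] = (raw[finite] - mu) / sigma
    return out


# ---------------------------------------------------------------------------
# Per-site scan
# ---------------------------------------------------------------------------


def component_scan(
    panel: HaplotypePanel,
    target: str = "TIB",
    reference: str = "HAN",
    truncation: float = 0.05,
    daf_range: tuple[float, float] = (0.05, 0.95),
    sites: np.ndarray | None = None,
) -> pd.DataFrame:
    """Raw component statistics at every (or the given) site of a panel.

    Returns a DataFrame with one row per scanned site: position, the five
    raw statistics and their validity flags. Normalization and composite
    scoring are applied downstream so that the same neutral normalization
    can be reused across panels.
    """
    rows_t = panel.population_haplotypes(target)
    rows_r = panel.population_haplotypes(reference)
    sub_t = panel.subset(haplotypes=rows_t)
    sub_r = panel.subset(haplotypes=rows_r)
    der_t = (sub_t.alleles == 1).sum(axis=0)
    tot_t = (sub_t.alleles != MISSING).sum(axis=0)
    der_r = (sub_r.alleles == 1).sum(axis=0)
    tot_r = (sub_r.alleles != MISSING).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_t = np.where(tot_t > 0, der_t / tot_t, np.nan)
        f_r = np.where(tot_r > 0, der_r / tot_r, np.nan)
    num, den = fst_terms(der_t, tot_t.astype(float), der_r, tot_r.astype(float), "hudson")
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den != 0, num / den, np.nan)
    ddaf = delta_daf(f_t, f_r)

    scan_sites = np.arange(panel.n_sites) if sites is None else np.asarray(sites)
    recs = []
    for i in scan_sites:
        hs = haplotype_scores(sub_t, int(i), truncation=truncation, daf_range=daf_range)
        xp = (
            xpehh_raw(sub_t, sub_r, int(i), truncation=truncation)
            if 0 < f_t[i] + f_r[i] and (der_t[i] + der_r[i]) > 0 and (der_t[i] + der_r[i]) < (tot_t[i] + tot_r[i])
            else np.nan
        )
        recs.append(
            {
                "position": panel.positions[i],
                "site": int(i),
                "daf_target": f_t[i],
                "daf_reference": f_r[i],
                "fst": fst[i],
                "delta_daf": ddaf[i],
                "ihs_raw": hs.ihs_raw,
                "delta_ihh_raw": hs.delta_ihh_raw,
                "xpehh_raw": xp,
            }
        )
    return pd.DataFrame(recs)
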