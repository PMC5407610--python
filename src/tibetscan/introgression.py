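"""Archaic-introgression statistics.

``D`` is the ABBA-BABA statistic comparing derived-allele sharing with an
archaic genome between a case and a control population, polarized by an
outgroup allele. The orientation here is the narrative one: positive D
means *excess archaic sharing in the case population*. Per-site terms are

    term_case = p_case (1 - p_ctrl) p_arch (1 - p_out)
    term_ctrl = p_ctrl (1 - p_case) p_arch (1 - p_out)

and D = sum(term_case - term_ctrl) / sum(term_case + term_ctrl). ``U`` is
the denominator summed over a window — the weight of archaic-informative
sites — and D* is the window D divided by the standard deviation of D
within its U-group (20 near-equal groups by U rank), which calibrates the
heavy tails D has in windows with few archaic-informative sites.

The S*-style scan chains population-private derived alleles along each
target haplotype with a dynamic program, flagging windows whose best chain
is long and sufficiently archaic-matching. The Q-style estimator recovers
the archaic admixture fractions (m_D, m_N) by equating observed archaic
sharing with Monte-Carlo expectations under a calibration model and
intersecting the two implicit curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    MISSING,
    HaplotypePanel,
    IntervalCI,
    SiteFrequencyTable,
    assign_windows,
)
from .cms import fdr_qvalues

__all__ = [
    "abba_baba_terms",
    "d_statistic",
    "block_bootstrap_ci",
    "u_statistic",
    "window_d_u",
    "dstar_scores",
    "sstar_scan",
    "sstar_haplotype_score",
    "q_admixture",
    "QAdmixtureResult",
    "overlap_permutation_test",
]


# ---------------------------------------------------------------------------
# D / U / D*
# ---------------------------------------------------------------------------


def abba_baba_terms(
    freqs: SiteFrequencyTable,
    case: str,
    control: str,
    archaic: str = "DEN",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (term_case, term_ctrl). Sites with a missing archaic or
    outgroup call, or with the outgroup carrying the derived allele,
    contribute 0 through the p_arch (1 - p_out) weight."""
    p1 = freqs.frequency(case)
    p2 = freqs.frequency(control)
    p3 = freqs.archaic_frequency(archaic)
    p4 = freqs.outgroup_frequency()
    w = np.nan_to_num(p3, nan=0.0) * np.nan_to_num(1.0 - p4, nan=0.0)
    p1 = np.nan_to_num(p1, nan=0.0)
    p2 = np.nan_to_num(p2, nan=0.0)
    term_case = p1 * (1.0 - p2) * w
    term_ctrl = p2 * (1.0 - p1) * w
    return term_case, term_ctrl


def d_statistic(term_case: np.ndarray, term_ctrl: np.ndarray) -> float:
    """D from per-site terms; positive = excess archaic sharing in the case."""
    den = float(np.sum(term_case) + np.sum(term_ctrl))
    if den == 0.0:
        raise ValueError("no archaic-informative sites (zero denominator)")
    return float(np.sum(term_case) - np.sum(term_ctrl)) / den


def block_bootstrap_ci(
    positions: np.ndarray,
    term_case: np.ndarray,
    term_ctrl: np.ndarray,
    block_size: int = 1_000_000,
    replicates: int = 200,
    level: float = 0.95,
    seed: int | None = None,
) -> IntervalCI:
    """Percentile bootstrap CI for D over ``block_size``-bp blocks.

    Blocks are resampled with replacement (same number as observed), D is
    recomputed per replicate, and the CI is the (alpha/2, 1-alpha/2)
    percentile pair.
    """
    blocks = assign_windows(positions, block_size)
    uniq = np.unique(blocks)
    if uniq.size < 2:
        raise ValueError("need >= 2 blocks for the block bootstrap")
    num_b = np.array([term_case[blocks == b].sum() - term_ctrl[blocks == b].sum() for b in uniq])
    den_b = np.array([term_case[blocks == b].sum() + term_ctrl[blocks == b].sum() for b in uniq])
    rng = np.random.default_rng(seed)
    reps = np.empty(replicates)
    for r in range(replicates):
        take = rng.integers(0, uniq.size, size=uniq.size)
        den = den_b[take].sum()
        reps[r] = num_b[take].sum() / den if den > 0 else np.nan
    reps = reps[np.isfinite(reps)]
    alpha = 1.0 - level
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    point = d_statistic(term_case, term_ctrl)
    return IntervalCI(
        point=point,
        lower=min(float(lo), point),
        upper=max(float(hi), point),
        method="percentile-bootstrap",
    )


def u_statistic(term_case: np.ndarray, term_ctrl: np.ndarray) -> float:
    """U = sum of (term_case + term_ctrl): the denominator of D."""
    return float(np.sum(term_case) + np.sum(term_ctrl))


def window_d_u(
    freqs: SiteFrequencyTable,
    case: str,
    control: str,
    archaic: str = "DEN",
    width: int = 200_000,
) -> pd.DataFrame:
    """Per-window D and U values (windows indexed from the first base)."""
    tc, tt = abba_baba_terms(freqs, case, control, archaic)
    win = assign_windows(freqs.positions, width)
    rows = []
    for w in np.unique(win):
        sel = win == w
        u = u_statistic(tc[sel], tt[sel])
        d = np.nan
        if u > 0:
            d = d_statistic(tc[sel], tt[sel])
        rows.append(
            {
                "chrom": freqs.chromosome,
                "start": int(w) * width + 1,
                "end": (int(w) + 1) * width,
                "D": d,
                "U": u,
                "n_sites": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def dstar_scores(
    windows: pd.DataFrame,
    n_groups: int = 20,
    null_dstar: np.ndarray | None = None,
) -> pd.DataFrame:
    """Normalize window D values into D* by within-U-group SD.

    Windows are sorted by (U, chrom, start), split into ``n_groups``
    near-equal groups (size remainder assigned to the lowest-U groups) and
    each window's D is divided by the sample SD of D within its group.
    With a ``null_dstar`` ensemble (same pipeline on neutral
    equal-admixture simulations), one-sided empirical p-values and BH
    q-values are attached.
    """
    w = windows.copy()
    valid = np.isfinite(w["D"].to_numpy(dtype=float))
    if valid.sum() < n_groups:
        raise ValueError(f"need >= {n_groups} windows with finite D")
    sub = w.loc[valid].sort_values(["U", "chrom", "start"], kind="mergesort")
    n = len(sub)
    base, rem = divmod(n, n_groups)
    sizes = np.full(n_groups, base)
    sizes[:rem] += 1  # remainder to the lowest-U groups
    group = np.repeat(np.arange(n_groups), sizes)
    sub = sub.assign(u_group=group + 1)
    sd = sub.groupby("u_group")["D"].transform(lambda x: x.std(ddof=1))
    if np.any(np.isclose(sd, 0.0)) or np.any(~np.isfinite(sd)):
        raise ValueError("zero or undefined within-group SD; cannot normalize")
    sub = sub.assign(D_star=sub["D"] / sd)
    out = w.join(sub[["u_group", "D_star"]])
    if null_dstar is not None:
        null_sorted = np.sort(np.asarray(null_dstar, dtype=float))
        ds = out["D_star"].to_numpy(dtype=float)
        n_ge = null_sorted.size - np.searchsorted(null_sorted, ds, side="left")
        p = np.where(np.isfinite(ds), (1.0 + n_ge) / (1.0 + null_sorted.size), np.nan)
        out["p"] = p
        out["q"] = fdr_qvalues(p)
    return out


# ---------------------------------------------------------------------------
# S*-style scan
# ---------------------------------------------------------------------------


def _sstar_pair_score(distance: int, bonus: int, mismatch: int, min_spacing: int) -> int:
    return bonus + distance if distance >= min_spacing else mismatch


def sstar_haplotype_score(
    positions: np.ndarray,
    bonus: int = 5000,
    mismatch: int = -10_000,
    min_spacing: int = 10,
) -> tuple[float, list[int]]:
    """Best chain score over ordered candidate-site positions, with the
    optimal chain (site indices) by backtracking.

    Dynamic program: S(j) = max over i<j of score(i, j) + max(S(i), 0);
    a chain needs at least two sites to score.
    """
    pos = np.asarray(positions, dtype=np.int64)
    m = pos.size
    if m < 2:
        return float("-inf"), []
    S = np.full(m, -np.inf)
    back = np.full(m, -1, dtype=np.int64)
    for j in range(1, m):
        for i in range(j):
            sc = _sstar_pair_score(int(pos[j] - pos[i]), bonus, mismatch, min_spacing)
            cand = sc + (S[i] if S[i] > 0 else 0.0)
            if cand > S[j]:
                S[j] = cand
                back[j] = i if S[i] > 0 else -(i + 2)  # encode chain restart
    j = int(np.argmax(S))
    best = float(S[j])
    chain = [j]
    while True:
        b = int(back[j])
        if b == -1:
            break
        if b <= -2:  # chain started at site -(b+2)
            chain.append(-(b + 2))
            break
        chain.append(b)
        j = b
    return best, sorted(chain)


def sstar_scan(
    target_panel: HaplotypePanel,
    comparison_panel: HaplotypePanel,
    freqs: SiteFrequencyTable,
    archaic: str = "DEN",
    width: int = 50_000,
    bonus: int = 5000,
    mismatch: int = -10_000,
    min_spacing: int = 10,
    score_threshold: float = 50_000.0,
    archaic_match_min: float = 0.3,
) -> pd.DataFrame:
    """Window-level S* scores for the target panel.

    Candidate sites per haplotype are derived alleles carried by that
    haplotype and absent from the comparison panel. Per window the score is
    the best chain over any target haplotype; candidate windows must both
    exceed ``score_threshold`` and have an archaic-match fraction of the
    chained alleles >= ``archaic_match_min``.
    """
    if target_panel.n_sites != comparison_panel.n_sites:
        raise ValueError("panels must share the same site frame")
    comp_derived = (comparison_panel.alleles == 1).sum(axis=0)
    private = comp_derived == 0
    arch_freq = freqs.archaic_frequency(archaic)
    arch_has = np.nan_to_num(arch_freq, nan=0.0) > 0
    win = assign_windows(target_panel.positions, width)
    rows = []
    for w in np.unique(win):
        in_w = np.flatnonzero((win == w) & private)
        best = float("-inf")
        best_match = np.nan
        best_hap = None
        for h in range(target_panel.n_haplotypes):
            carried = in_w[target_panel.alleles[h, in_w] == 1]
            if carried.size < 2:
                continue
            score, chain_local = sstar_haplotype_score(
                target_panel.positions[carried], bonus, mismatch, min_spacing
            )
            if score > best:
                chain_sites = carried[chain_local]
                best = score
                best_match = float(arch_has[chain_sites].mean()) if len(chain_sites) else np.nan
                best_hap = str(target_panel.haplotype_individuals[h])
        rows.append(
            {
                "chrom": target_panel.chromosome,
                "start": int(w) * width + 1,
                "end": (int(w) + 1) * width,
                "s_star": best if np.isfinite(best) else np.nan,
                "archaic_match": best_match,
                "haplotype": best_hap,
                "candidate": bool(
                    np.isfinite(best)
                    and best >= score_threshold
                    and np.isfinite(best_match)
                    and best_match >= archaic_match_min
                ),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Q-style admixture-fraction estimation
# ---------------------------------------------------------------------------


def _sharing_weights(
    freqs: SiteFrequencyTable,
    archaic: str,
    other: str | None,
    control: str | None = None,
    control_max: float = 0.01,
) -> np.ndarray:
    """Per-site weight of archaic-specific informative sites: the archaic
    carries the derived allele, the outgroup the ancestral, and (when a
    second archaic track is available) the other archaic the ancestral.
    The last condition keeps the two sharing statistics from being nearly
    collinear — the archaics share most of their derived alleles. With a
    ``control`` population, sites where the control carries the derived
    allele above ``control_max`` are dropped: shared ancient polymorphism
    (incomplete lineage sorting) is usually present in both modern
    populations, while introgressed tracts are population-specific, so the
    conditioning suppresses the noisy baseline without losing the
    admixture signal."""
    p3 = freqs.archaic_frequency(archaic)
    p4 = freqs.outgroup_frequency()
    w = np.nan_to_num(p3, nan=0.0) * np.nan_to_num(1.0 - p4, nan=0.0)
    if other is not None and other in freqs.archaic:
        p_other = freqs.archaic_frequency(other)
        w = w * np.nan_to_num(1.0 - p_other, nan=0.0)
    if control is not None:
        with np.errstate(invalid="ignore"):
            pc = freqs.frequency(control)
        w = w * np.where(np.nan_to_num(pc, nan=1.0) < control_max, 1.0, 0.0)
    return w


def _sharing_statistic(
    freqs: SiteFrequencyTable,
    case: str,
    archaic: str,
    other: str | None = None,
    control: str | None = None,
) -> float:
    """Archaic-specific sharing mass per Mb: sum of case frequency times the
    archaic-specific weight, normalized by the spanned sequence.

    A per-site *mean* would not do: admixture adds many new low-frequency
    archaic-specific sites, so a mean responds non-monotonically to the
    admixture fraction, while the per-Mb sharing mass grows with every
    introgressed tract.
    """
    w = _sharing_weights(freqs, archaic, other, control)
    p1 = np.nan_to_num(freqs.frequency(case), nan=0.0)
    if w.sum() == 0:
        raise ValueError("no archaic-informative sites")
    span_mb = float(freqs.positions[-1] - freqs.positions[0] + 1) / 1e6
    return float((p1 * w).sum() / span_mb)


_OTHER = {"DEN": "NEA", "NEA": "DEN"}

#: archaic source branch feeding each sampled archaic track
_SOURCE = {"DEN": "DENI", "NEA": "NEA"}


def _control_for(scenario_template, archaic: str, control: str | None) -> str | None:
    """Control-conditioning is only valid for post-split admixture: pulses
    into the common ancestor ("ANC") leave tracts shared by both modern
    populations, which the absent-in-control condition would discard."""
    if control is None:
        return None
    for p in scenario_template.pulses:
        if p.source == _SOURCE[archaic] and p.destination == "ANC":
            return None
    return control


@dataclass
class QAdmixtureResult:
    m_d: float
    m_n: float
    ci_d: IntervalCI | None
    ci_n: IntervalCI | None
    coefficients: dict[str, tuple[float, float, float]]
    observed: dict[str, float]


def _fit_response_surface(
    model,
    scenario_template,
    case: str,
    anchors: list[tuple[float, float]],
    n_reps: int,
    sequence_length: float,
    seed: int,
    control: str | None = None,
) -> tuple[dict[str, tuple[float, float, float]], dict]:
    """Linear response of the sharing statistics to (m_D, m_N), fitted by
    Monte-Carlo at anchor fractions with shared seeds. Returns the fitted
    coefficients and the per-replicate anchor values (so downstream
    bootstraps can propagate calibration uncertainty)."""
    from .simulate import simulate_archaic  # local import to avoid cycle

    reps: dict[tuple[float, float], dict[str, list[float]]] = {}
    for md, mn in anchors:
        vals: dict[str, list[float]] = {"DEN": [], "NEA": []}
        for r in range(n_reps):
            scen = scenario_template.with_fractions(md, mn)
            _, sft, _ = simulate_archaic(
                model, scen, sequence_length=sequence_length,
                seed=seed + r,  # shared seeds across anchors
                track_tracts=False,
            )
            for a in ("DEN", "NEA"):
                ctrl = _control_for(scenario_template, a, control)
                vals[a].append(_sharing_statistic(sft, case, a, _OTHER[a], ctrl))
        reps[(md, mn)] = vals
    return _coef_from_anchor_values(anchors, reps), reps


def _coef_from_anchor_values(
    anchors: list[tuple[float, float]],
    reps: dict,
    take: dict | None = None,
) -> dict[str, tuple[float, float, float]]:
    """Least-squares plane fit through (optionally resampled) anchor means."""
    A = np.array([[1.0, md, mn] for md, mn in anchors])
    coef = {}
    for a in ("DEN", "NEA"):
        y = []
        for k in anchors:
            vals = np.asarray(reps[k][a])
            if take is not None:
                vals = vals[take[k]]
            y.append(vals.mean())
        beta, *_ = np.linalg.lstsq(A, np.array(y), rcond=None)
        coef[a] = (float(beta[0]), float(beta[1]), float(beta[2]))
    return coef


def _intersect_curves(
    coef: dict[str, tuple[float, float, float]],
    q_obs: dict[str, float],
    tol: float = 1e-10,
    clip: bool = True,
) -> tuple[float, float]:
    """Simultaneous (m_D, m_N) where both expected sharing statistics equal
    their observed values. The Denisovan curve gives m_D as a function of
    m_N; bisection on the Neanderthal curve's residual finds the crossing
    inside [0, 1]^2."""
    a_d, b_dd, b_dn = coef["DEN"]
    a_n, b_nd, b_nn = coef["NEA"]

    def m_d_given(m_n: float) -> float:
        if b_dd == 0:
            raise ValueError("Denisovan sharing does not respond to m_D")
        return (q_obs["DEN"] - a_d - b_dn * m_n) / b_dd

    def g(m_n: float) -> float:
        return a_n + b_nd * m_d_given(m_n) + b_nn * m_n - q_obs["NEA"]

    # bracket slightly beyond [0, 1]: Monte-Carlo noise in the calibration
    # pushes boundary-true fractions marginally outside; genuine failures
    # (no crossing, or a crossing far outside) still raise.
    margin = 0.1
    lo, hi = -margin, 1.0 + margin
    glo, ghi = g(lo), g(hi)
    if glo == 0.0:
        mn = lo
    elif np.sign(glo) == np.sign(ghi):
        raise ValueError(
            "admixture curves fail to intersect in [0, 1]^2 "
            f"(residuals {glo:.3g}, {ghi:.3g})"
        )
    else:
        while hi - lo > tol:
            mid = (lo + hi) / 2.0
            if np.sign(g(mid)) == np.sign(glo):
                lo = mid
            else:
                hi = mid
        mn = (lo + hi) / 2.0
    md = m_d_given(mn)
    if not (-margin <= md <= 1.0 + margin):
        raise ValueError(f"m_D estimate {md:.4f} outside [0, 1]")
    if clip:
        return float(np.clip(md, 0.0, 1.0)), float(np.clip(mn, 0.0, 1.0))
    return float(md), float(mn)


def q_admixture(
    freqs: SiteFrequencyTable,
    model,
    scenario_template,
    case: str = "TIB",
    control: str = "HAN",
    anchors: list[tuple[float, float]] | None = None,
    n_reps: int = 3,
    calibration_length: float = 5_000_000.0,
    seed: int = 0,
    bootstrap_replicates: int = 100,
    block_size: int = 1_000_000,
    level: float = 0.95,
) -> QAdmixtureResult:
    """Simultaneous estimate of Denisovan and Neanderthal admixture.

    Observed Denisovan- and Neanderthal-sharing statistics are equated with
    Monte-Carlo expectations under the calibration model evaluated on a
    linear response surface in (m_D, m_N); the curve intersection is found
    by bisection. CIs come from a moving-blocks bootstrap of the observed
    statistics over ``block_size``-bp blocks, with the calibration anchor
    replicates resampled alongside so calibration uncertainty propagates
    into the interval.
    """
    # anchors well away from 0: the response slopes are finite differences
    # of Monte-Carlo means, so small anchor fractions drown in noise
    anchors = anchors or [(0.0, 0.0), (0.05, 0.0), (0.0, 0.05)]
    coef, anchor_reps = _fit_response_surface(
        model, scenario_template, case, anchors, n_reps, calibration_length, seed,
        control=control,
    )
    q_obs = {
        a: _sharing_statistic(
            freqs, case, a, _OTHER[a], _control_for(scenario_template, a, control)
        )
        for a in ("DEN", "NEA")
    }
    m_d, m_n = _intersect_curves(coef, q_obs)

    ci_d = ci_n = None
    if bootstrap_replicates > 0:
        rng = np.random.default_rng(seed + 777)
        blocks = assign_windows(freqs.positions, block_size)
        uniq = np.unique(blocks)
        reps_d, reps_n = [], []
        p1 = np.nan_to_num(freqs.frequency(case), nan=0.0)
        weights = {
            a: _sharing_weights(
                freqs, a, _OTHER[a], _control_for(scenario_template, a, control)
            )
            for a in ("DEN", "NEA")
        }
        for _ in range(bootstrap_replicates):
            take = rng.integers(0, uniq.size, size=uniq.size)
            sel = np.concatenate([np.flatnonzero(blocks == uniq[b]) for b in take])
            resample = {k: rng.integers(0, n_reps, size=n_reps) for k in anchor_reps}
            coef_b = _coef_from_anchor_values(anchors, anchor_reps, resample)
            span_mb = uniq.size * block_size / 1e6
            try:
                qb = {
                    a: float((p1[sel] * weights[a][sel]).sum() / span_mb)
                    for a in ("DEN", "NEA")
                }
                # unclipped: percentile CIs need the raw sampling spread
                rd, rn = _intersect_curves(coef_b, qb, clip=False)
            except ValueError:
                continue
            reps_d.append(rd)
            reps_n.append(rn)
        if len(reps_d) >= max(10, bootstrap_replicates // 4):
            # t-interval on the bootstrap SE: with tens of blocks the plain
            # percentile interval undercovers
            from scipy import stats as _st

            tcrit = _st.t.ppf(1 - (1 - level) / 2, df=max(uniq.size - 1, 2))
            sd_d, sd_n = np.std(reps_d, ddof=1), np.std(reps_n, ddof=1)
            center_d, center_n = _intersect_curves(coef, q_obs, clip=False)
            lo_d, hi_d = center_d - tcrit * sd_d, center_d + tcrit * sd_d
            lo_n, hi_n = center_n - tcrit * sd_n, center_n + tcrit * sd_n
            ci_d = IntervalCI(m_d, min(lo_d, m_d), max(hi_d, m_d), "bootstrap-t")
            ci_n = IntervalCI(m_n, min(lo_n, m_n), max(hi_n, m_n), "bootstrap-t")
    return QAdmixtureResult(
        m_d=m_d, m_n=m_n, ci_d=ci_d, ci_n=ci_n, coefficients=coef, observed=q_obs
    )


# ---------------------------------------------------------------------------
# Overlap permutation test
# ---------------------------------------------------------------------------


def overlap_permutation_test(
    introgressed: np.ndarray,
    window_scores: np.ndarray,
    top_fraction: float = 0.002,
    replicates: int = 10_000,
    seed: int | None = None,
) -> tuple[int, float]:
    """Overlap between introgressed windows and the top CMS windows, with a
    permutation p-value.

    ``introgressed`` is a boolean flag per window; ``window_scores`` the
    per-window scan scores on the same partition. The observed statistic is
    the number of introgressed windows inside the top fraction by score;
    the null permutes scores across windows. p = (1 + #{null >= obs}) /
    (1 + replicates).
    """
    introgressed = np.asarray(introgressed, dtype=bool)
    scores = np.asarray(window_scores, dtype=float)
    if introgressed.shape != scores.shape:
        raise ValueError("window partitions do not match")
    scored = np.isfinite(scores)
    k = max(1, int(round(top_fraction * scored.sum())))
    order = np.argsort(np.where(scored, scores, -np.inf))[::-1][:k]
    top = np.zeros(scores.size, dtype=bool)
    top[order] = True
    observed = int((introgressed & top).sum())
    if observed == 0:
        return 0, 1.0
    rng = np.random.default_rng(seed)
    n_intro = int(introgressed.sum())
    null_ge = 0
    # permuting scores over windows == drawing which windows are "top";
    # count overlap of a random k-subset with the introgressed set
    for _ in range(replicates):
        perm_top = rng.choice(scores.size, size=k, replace=False)
        null_ge += int(introgressed[perm_top].sum() >= observed)
    p = (1.0 + null_ge) / (1.0 + replicates)
    return observed, float(p)
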