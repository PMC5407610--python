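"""Composite-of-signals selection score.

Per-statistic score densities are learned from simulations under a neutral
model and under a pooled grid of sweep scenarios (3 selection coefficients
x 5 onset times x 4 end frequencies, pooled with equal weight). At scan
time each statistic contributes a naive-Bayes posterior
``pi*f_sel / (pi*f_sel + (1-pi)*f_neut)`` and the composite score is the
sum of log posteriors, rescaled by 5/(number of valid components) so sites
with missing components stay comparable. Scores are therefore always
negative; higher (closer to zero) means stronger evidence of a sweep.

Significance is empirical: p-values compare observed scores with the score
distribution of fresh neutral simulations, and q-values are
Benjamini-Hochberg.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data_model import HaplotypePanel, WindowTable, assign_windows, merge_adjacent, partition_windows
from .selection import component_scan
from .simulate import DemographicModel, SweepScenario, simulate_neutral, simulate_sweep, sweep_grid

__all__ = [
    "STATISTICS",
    "ScoreDistributions",
    "train_distributions",
    "train_from_simulations",
    "cms_score",
    "empirical_pvalues",
    "fdr_qvalues",
    "region_cms",
    "top_regions",
]

#: Components of the composite, as normalized-score column names.
STATISTICS = ("ihs", "xpehh", "delta_ihh", "fst", "delta_daf")

#: Raw component-scan columns the normalized scores derive from.
_RAW = {
    "ihs": "ihs_raw",
    "xpehh": "xpehh_raw",
    "delta_ihh": "delta_ihh_raw",
    "fst": "fst",
    "delta_daf": "delta_daf",
}

#: Statistics that are z-normalized against the neutral ensemble. F_ST and
#: ΔDAF enter on their natural scale.
_NORMALIZED = ("ihs", "xpehh", "delta_ihh")


@dataclass
class ScoreDistributions:
    """Binned score densities under the null and the sweep alternative.

    Bin edges are shared between the null and alternative densities of a
    statistic; both densities sum to 1 after pseudo-count smoothing.
    ``normalization`` holds the neutral mean/SD applied to the raw
    EHH-family scores before binning.
    """

    edges: dict[str, np.ndarray]
    null_density: dict[str, np.ndarray]
    alt_density: dict[str, np.ndarray]
    normalization: dict[str, tuple[float, float]] = field(default_factory=dict)
    pseudocount: float = 1.0
    version: str = "1"

    def __post_init__(self) -> None:
        for stat in self.edges:
            for dens in (self.null_density[stat], self.alt_density[stat]):
                if len(dens) != len(self.edges[stat]) - 1:
                    raise ValueError(f"density/edge length mismatch for {stat!r}")
                if not np.isclose(dens.sum(), 1.0):
                    raise ValueError(f"density for {stat!r} must sum to 1")

    @property
    def statistics(self) -> list[str]:
        return list(self.edges)

    def density_at(self, stat: str, values: np.ndarray, which: str) -> np.ndarray:
        """Per-bin density mass at each value; out-of-range values fall in
        the terminal bins (the support learned in training is clipped, not
        extrapolated)."""
        edges = self.edges[stat]
        dens = self.null_density[stat] if which == "null" else self.alt_density[stat]
        idx = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, len(dens) - 1)
        out = dens[idx]
        out[~np.isfinite(np.asarray(values, dtype=float))] = np.nan
        return out

    def normalize(self, scores: pd.DataFrame) -> pd.DataFrame:
        """Attach normalized component columns to a raw component scan."""
        out = scores.copy()
        for stat in self.statistics:
            raw = out[_RAW[stat]].to_numpy(dtype=float)
            if stat in self.normalization:
                mu, sd = self.normalization[stat]
                out[stat] = (raw - mu) / sd
            else:
                out[stat] = raw
        return out

    # -- serialization --------------------------------------------------
    def to_json(self, path: str) -> None:
        payload = {
            "version": self.version,
            "pseudocount": self.pseudocount,
            "normalization": {k: list(v) for k, v in self.normalization.items()},
            "statistics": {
                stat: {
                    "edges": self.edges[stat].tolist(),
                    "null": self.null_density[stat].tolist(),
                    "alt": self.alt_density[stat].tolist(),
                }
                for stat in self.edges
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "ScoreDistributions":
        with open(path) as fh:
            payload = json.load(fh)
        edges = {s: np.array(d["edges"]) for s, d in payload["statistics"].items()}
        null = {s: np.array(d["null"]) for s, d in payload["statistics"].items()}
        alt = {s: np.array(d["alt"]) for s, d in payload["statistics"].items()}
        norm = {k: (v[0], v[1]) for k, v in payload["normalization"].items()}
        return cls(
            edges=edges, null_density=null, alt_density=alt,
            normalization=norm, pseudocount=payload["pseudocount"],
            version=payload["version"],
        )


def _smoothed_density(values: np.ndarray, edges: np.ndarray, pseudocount: float) -> np.ndarray:
    values = values[np.isfinite(values)]
    hist, _ = np.histogram(np.clip(values, edges[0], edges[-1]), bins=edges)
    dens = hist.astype(float) + pseudocount
    return dens / dens.sum()


def train_distributions(
    null_scores: pd.DataFrame,
    alt_scores: pd.DataFrame,
    bins: int = 60,
    pseudocount: float = 1.0,
    statistics: tuple[str, ...] = STATISTICS,
) -> ScoreDistributions:
    """Histogram densities from null and pooled-alternative component scans.

    Both inputs are raw component scans (one row per site/replicate);
    EHH-family statistics are normalized by the *null* moments before
    binning, and the common bin edges span the pooled finite support of
    both ensembles.
    """
    if len(null_scores) == 0 or len(alt_scores) == 0:
        raise ValueError("both simulation ensembles must be non-empty")
    normalization: dict[str, tuple[float, float]] = {}
    edges: dict[str, np.ndarray] = {}
    null_d: dict[str, np.ndarray] = {}
    alt_d: dict[str, np.ndarray] = {}
    for stat in statistics:
        raw_null = null_scores[_RAW[stat]].to_numpy(dtype=float)
        raw_alt = alt_scores[_RAW[stat]].to_numpy(dtype=float)
        if stat in _NORMALIZED:
            finite = raw_null[np.isfinite(raw_null)]
            if finite.size < 2:
                raise ValueError(f"too few valid null scores for {stat!r}")
            mu, sd = float(finite.mean()), float(finite.std(ddof=0))
            if sd == 0:
                raise ValueError(f"zero null variance for {stat!r}")
            normalization[stat] = (mu, sd)
            raw_null = (raw_null - mu) / sd
            raw_alt = (raw_alt - mu) / sd
        pooled = np.concatenate([raw_null[np.isfinite(raw_null)], raw_alt[np.isfinite(raw_alt)]])
        lo, hi = pooled.min(), pooled.max()
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        edges[stat] = np.linspace(lo, hi, bins + 1)
        null_d[stat] = _smoothed_density(raw_null, edges[stat], pseudocount)
        alt_d[stat] = _smoothed_density(raw_alt, edges[stat], pseudocount)
    return ScoreDistributions(
        edges=edges, null_density=null_d, alt_density=alt_d,
        normalization=normalization, pseudocount=pseudocount,
    )


def cms_score(
    scores: pd.DataFrame,
    distributions: ScoreDistributions,
    prior: float = 1e-4,
) -> np.ndarray:
    """Composite log-posterior score per site.

    ``scores`` is a raw component scan; normalization stored in the
    distributions is applied internally. A statistic that is invalid at a
    site (e.g. iHS at near-fixed cores) contributes the neutral posterior
    ``ln(prior)`` — the evidence-free likelihood ratio of 1 — so every
    scored site sits on the same 5-component scale without amplifying the
    remaining components. Sites with no valid component get NaN.
    """
    if not 0.0 < prior < 1.0:
        raise ValueError("prior must be in (0, 1)")
    normed = distributions.normalize(scores)
    stats = distributions.statistics
    n = len(normed)
    log_post = np.zeros((len(stats), n))
    valid = np.zeros((len(stats), n), dtype=bool)
    for k, stat in enumerate(stats):
        vals = normed[stat].to_numpy(dtype=float)
        f_sel = distributions.density_at(stat, vals, "alt")
        f_neut = distributions.density_at(stat, vals, "null")
        ok = np.isfinite(f_sel) & np.isfinite(f_neut) & ((f_sel + f_neut) > 0)
        post = np.full(n, np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            post[ok] = prior * f_sel[ok] / (prior * f_sel[ok] + (1 - prior) * f_neut[ok])
        log_post[k] = np.log(post)
        valid[k] = ok
    n_valid = valid.sum(axis=0)
    total = np.where(valid, log_post, np.log(prior)).sum(axis=0)
    return np.where(n_valid > 0, total, np.nan)


def empirical_pvalues(observed: np.ndarray, null_ensemble: np.ndarray) -> np.ndarray:
    """p = (1 + #{null >= observed}) / (1 + N): the proportion of null
    scores at least as high (closer to 0) as the observed score, with a
    pseudo-count so p is never 0."""
    null_sorted = np.sort(np.asarray(null_ensemble, dtype=float))
    if null_sorted.size == 0:
        raise ValueError("null ensemble must be non-empty")
    observed = np.asarray(observed, dtype=float)
    n_ge = null_sorted.size - np.searchsorted(null_sorted, observed, side="left")
    p = (1.0 + n_ge) / (1.0 + null_sorted.size)
    p = np.where(np.isfinite(observed), p, np.nan)
    return p


def fdr_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (NaN-aware)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def region_cms(
    score_table: pd.DataFrame,
    chromosome_length: int,
    width: int = 200_000,
    chromosome: str = "1",
    score_column: str = "cms",
) -> WindowTable:
    """Aggregate per-site composite scores into fixed windows.

    The window statistic is the highest (max) score among member sites;
    windows without scored sites get NaN.
    """
    wt = partition_windows(chromosome_length, width, chromosome)
    idx = assign_windows(score_table["position"].to_numpy(), width)
    scores = score_table[score_column].to_numpy(dtype=float)
    cms_max = np.full(len(wt), np.nan)
    n_sites = np.zeros(len(wt), dtype=int)
    for w in range(len(wt)):
        member = scores[idx == w]
        member = member[np.isfinite(member)]
        n_sites[w] = member.size
        if member.size:
            cms_max[w] = member.max()
    wt.table["cms_max"] = cms_max
    wt.table["n_sites"] = n_sites
    return wt


def top_regions(
    windows: WindowTable,
    top_fraction: float | None = None,
    top_n: int | None = None,
    score_column: str = "cms_max",
) -> pd.DataFrame:
    """Highest-scoring windows with adjacent top windows merged.

    ``top_fraction`` (e.g. 0.002 or 0.01) or ``top_n`` selects windows by
    descending score; merged intervals report the max member score and are
    returned best-first.
    """
    scores = windows.table[score_column].to_numpy(dtype=float)
    scored = np.isfinite(scores)
    n_scored = int(scored.sum())
    if top_n is None:
        if top_fraction is None:
            raise ValueError("give top_fraction or top_n")
        top_n = max(1, int(round(top_fraction * n_scored)))
    order = np.argsort(np.where(scored, scores, -np.inf))[::-1][:top_n]
    selected = np.zeros(len(windows), dtype=bool)
    selected[order] = True
    merged = merge_adjacent(windows, selected, score=score_column)
    return merged.sort_values("score", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Simulation-driven training
# ---------------------------------------------------------------------------


def train_from_simulations(
    model: DemographicModel,
    scenarios: list[SweepScenario] | None = None,
    n_null: int = 60,
    reps_per_cell: int = 5,
    samples: dict[str, int] | None = None,
    sequence_length: float = 300_000.0,
    seed: int | None = None,
    null_sites_per_rep: int = 40,
    bins: int = 60,
    pseudocount: float = 1.0,
    panel_size: int = 600,
) -> tuple[ScoreDistributions, np.ndarray, pd.DataFrame]:
    """Train score densities and a null composite ensemble by simulation.

    Null component scores come from ``n_null`` neutral replicates (a random
    subset of interior sites per replicate); alternative scores are the
    focal-site statistics of ``reps_per_cell`` sweeps per grid cell, pooled
    with equal weight. Returns ``(distributions, null_cms, null_scores)``
    where ``null_cms`` is the composite score of *held-out* null
    replicates (half the neutral simulations, not used for the densities):
    scoring the training sites against densities they themselves shaped is
    anticonservative for downstream empirical p-values.
    """
    rng = np.random.default_rng(seed)
    scenarios = scenarios if scenarios is not None else sweep_grid()
    null_frames = []
    for _ in range(n_null):
        pan = simulate_neutral(model, samples, sequence_length, int(rng.integers(1, 2**31 - 1)))
        interior = _interior_sites(pan, sequence_length)
        if interior.size == 0:
            continue
        take = interior if interior.size <= null_sites_per_rep else rng.choice(
            interior, size=null_sites_per_rep, replace=False
        )
        null_frames.append(component_scan(pan, sites=np.sort(take)))
    n_train = max(1, len(null_frames) // 2)
    null_scores = pd.concat(null_frames[:n_train], ignore_index=True)
    null_holdout = pd.concat(null_frames[n_train:] or null_frames, ignore_index=True)

    alt_frames = []
    for scen in scenarios:
        scen = SweepScenario(
            s=scen.s,
            onset_generations_ago=scen.onset_generations_ago,
            end_frequency=scen.end_frequency,
            population=scen.population,
            panel_size=panel_size,
        )
        for _ in range(reps_per_cell):
            pan, info = simulate_sweep(
                model, scen, samples, sequence_length, int(rng.integers(1, 2**31 - 1))
            )
            alt_frames.append(
                component_scan(pan, sites=np.array([info.focal_site_index]))
            )
    alt_scores = pd.concat(alt_frames, ignore_index=True)

    dists = train_distributions(null_scores, alt_scores, bins=bins, pseudocount=pseudocount)
    null_cms = cms_score(null_holdout, dists)
    return dists, null_cms[np.isfinite(null_cms)], null_scores


def _interior_sites(panel: HaplotypePanel, sequence_length: float, margin: float = 0.2) -> np.ndarray:
    """Sites away from the sequence edges (EHH integrals need flank room)."""
    lo, hi = margin * sequence_length, (1 - margin) * sequence_length
    return np.flatnonzero((panel.positions >= lo) & (panel.positions <= hi))
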