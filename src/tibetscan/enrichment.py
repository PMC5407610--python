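"""GO-term over-representation among top scan windows by window resampling.

Genes are assigned to every fixed-width window they overlap by at least one
base pair; the test statistic for a term is the number of *distinct* genes
annotated with it among the genes of the top windows. The null samples the
same number of windows without replacement from all windows, so the test
inherits the genomic clustering of genes rather than assuming gene-level
exchangeability. q-values are Benjamini-Hochberg over the tested terms.
Term-to-gene maps are taken as flat sets (no ontology-graph propagation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cms import fdr_qvalues
from .data_model import WindowTable

__all__ = ["window_gene_sets", "go_resampling_test"]


def window_gene_sets(
    windows: WindowTable, genes: pd.DataFrame
) -> list[set[str]]:
    """Genes overlapping each window (>= 1 bp, 1-based inclusive bounds).

    ``genes`` needs columns chrom, start, end, name on the same coordinate
    system as the windows. A gene spanning several windows is assigned to
    all of them.
    """
    out: list[set[str]] = [set() for _ in range(len(windows))]
    tab = windows.table
    for chrom, sub in genes.groupby("chrom"):
        sel = tab["chrom"] == chrom
        if not sel.any():
            continue
        w_start = tab.loc[sel, "start"].to_numpy()
        w_end = tab.loc[sel, "end"].to_numpy()
        w_idx = np.flatnonzero(sel.to_numpy())
        for g_start, g_end, name in zip(sub["start"], sub["end"], sub["name"]):
            hits = (g_start <= w_end) & (g_end >= w_start)
            for w in w_idx[hits]:
                out[w].add(str(name))
    return out


def go_resampling_test(
    top_windows: np.ndarray,
    window_genes: list[set[str]],
    term_genes: dict[str, set[str]],
    replicates: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-term over-representation p/q by window resampling.

    ``top_windows`` holds the indices of the selected windows; the null
    draws the same number of windows without replacement from all windows
    and recounts distinct term genes. p = (1 + #{null >= observed}) /
    (1 + replicates).
    """
    top_windows = np.asarray(top_windows, dtype=int)
    n_windows = len(window_genes)
    if top_windows.size > n_windows:
        raise ValueError("more top windows than windows")
    rng = np.random.default_rng(seed)
    terms = list(term_genes)
    for term in terms:
        if not term_genes[term]:
            raise ValueError(f"term {term!r} has no genes in the map")

    def _observed(idx: np.ndarray, genes: set[str]) -> int:
        hit: set[str] = set()
        for w in idx:
            hit |= window_genes[w] & genes
        return len(hit)

    obs = {t: _observed(top_windows, term_genes[t]) for t in terms}
    null_ge = {t: 0 for t in terms}
    k = top_windows.size
    for _ in range(replicates):
        draw = rng.choice(n_windows, size=k, replace=False)
        for t in terms:
            if _observed(draw, term_genes[t]) >= obs[t]:
                null_ge[t] += 1
    p = np.array([(1.0 + null_ge[t]) / (1.0 + replicates) for t in terms])
    out = pd.DataFrame(
        {
            "term": terms,
            "observed_genes": [obs[t] for t in terms],
            "genes": [
                ",".join(sorted(set().union(*[window_genes[w] for w in top_windows]) & term_genes[t]))
                if top_windows.size else ""
                for t in terms
            ],
            "p": p,
            "q": fdr_qvalues(p),
        }
    )
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)
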