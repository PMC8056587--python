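"""Methodological benchmarks: Pearson vs Spearman on co-functional gene pairs,
and top-K correlate overlap against an external reference list.

The Pearson/Spearman experiment repeatedly samples a gene set from a curated
collection of co-expressed, functionally related sets, then a random gene
pair within it, and computes both coefficients on the variance-stabilized
expression rows.  Because such pairs are expected to be genuinely
correlated, the paired one-tailed t-test of (pearson - spearman) > 0 probes
which coefficient is the more sensitive detector of these relationships;
sorting pairs by the difference surfaces the Pearson-specific extreme
(typically tissue-restricted linear relationships) and the Spearman-specific
extreme (monotone but non-linear patterns).

The overlap benchmark takes a gene's top-K co-expressed partners and scores
their intersection with an independent reference list (e.g. known protein
interactors) by the hypergeometric upper tail — the same kernel as
over-representation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ParameterError
from .gsea import GeneSetCollection, hypergeom_upper_tail
from .normalize import VstMatrix
from .store import CorrelationVector

DEFAULT_N_SIM = 2832
DEFAULT_TOP_K = 500


def pearson_vs_spearman(
    vst: VstMatrix,
    collection: GeneSetCollection,
    n_sim: int = DEFAULT_N_SIM,
    seed: int | None = None,
) -> tuple[pd.DataFrame, float]:
    """Paired Pearson/Spearman comparison over random within-set gene pairs.

    Each simulation draws a uniform random eligible set, then a uniform
    random unordered pair within it (with replacement across simulations).
    Returns the per-pair table sorted by delta = pearson - spearman
    (descending; both extremes identifiable) and the one-tailed paired
    t-test p-value for mean delta > 0.
    """
    gene_pos = {g: i for i, g in enumerate(vst.gene_ids)}
    eligible = []
    for name in collection.names():
        members = sorted(g for g in collection.sets[name] if g in gene_pos)
        if len(members) >= 2:
            eligible.append((name, members))
    if not eligible:
        raise AnalysisError("no gene set has >= 2 genes present in the expression matrix")

    rng = np.random.default_rng(seed)
    rank_cache: dict[int, np.ndarray] = {}

    def ranks(i: int) -> np.ndarray:
        if i not in rank_cache:
            rank_cache[i] = stats.rankdata(vst.values[i])
        return rank_cache[i]

    rows = []
    for _ in range(int(n_sim)):
        name, members = eligible[rng.integers(len(eligible))]
        ia, ib = rng.choice(len(members), size=2, replace=False)
        ga, gb = members[ia], members[ib]
        xa, xb = vst.values[gene_pos[ga]], vst.values[gene_pos[gb]]
        pr = float(np.corrcoef(xa, xb)[0, 1])
        sr = float(np.corrcoef(ranks(gene_pos[ga]), ranks(gene_pos[gb]))[0, 1])
        rows.append(
            {
                "set_name": name,
                "gene_a": ga,
                "gene_b": gb,
                "pearson_r": pr,
                "spearman_r": sr,
                "delta": pr - sr,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["delta", "gene_a", "gene_b"], ascending=[False, True, True], kind="stable"
    )
    table = table.reset_index(drop=True)
    res = stats.ttest_rel(table["pearson_r"], table["spearman_r"], alternative="greater")
    return table, float(res.pvalue)


@dataclass
class OverlapResult:
    overlap: int
    pval: float
    k: int
    reference_in_universe: int
    universe_size: int


def topk_overlap_test(
    vector: CorrelationVector,
    reference: list[str],
    k: int = DEFAULT_TOP_K,
    universe: list[str] | None = None,
) -> OverlapResult:
    """Hypergeometric test of top-k correlates against a reference gene list."""
    genes, r = vector.ranked(drop_query=True)
    if universe is not None:
        uni = {str(g).upper() for g in universe}
        keep = np.isin(genes, sorted(uni))
        genes, r = genes[keep], r[keep]
    if k > len(genes):
        raise ParameterError(f"k={k} exceeds the {len(genes)}-gene universe")
    ref = {str(g).upper() for g in reference} & set(genes)
    top = set(genes[:k])
    x = len(top & ref)
    p = hypergeom_upper_tail(x, len(genes), len(ref), k)
    return OverlapResult(
        overlap=x,
        pval=p,
        k=k,
        reference_in_universe=len(ref),
        universe_size=len(genes),
    )
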