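"""Preranked gene set enrichment driven by correlation vectors (corGSEA),
plus hypergeometric over-representation analysis.

corGSEA asks: which annotated gene sets concentrate at the extremes of a
gene's genome-wide co-expression ranking?  Genes are ordered by signed
Pearson r (descending) and the classic weighted Kolmogorov-Smirnov running
sum is walked down the list: set members ("hits") increment the sum by
``|r|^p / sum_hits |r|^p`` and non-members decrement it by ``1/(N - N_hits)``.
The enrichment score ES is the running sum's extremum by absolute value; a
positive ES means the set crowds the co-correlated top of the ranking, a
negative ES the anti-correlated bottom.  The leading edge is the subset of
hits at or before (ES > 0) / at or after (ES < 0) the extremum.

Significance comes from a gene-label permutation null: random sets of the
same size are drawn from the ranked universe, and

* ``NES = ES / mean(|null ES| of the same sign)`` (sides normalized
  separately; a set whose null has no same-sign values gets NES = NaN);
* ``pval = (1 + #{ |null ES| >= |ES| }) / (n_perm + 1)`` — the one-sided
  upper tail of the null |ES| distribution with a +1 pseudocount, so p is
  uniform under the null, never 0, and bounded below by 1/(n_perm+1);
* ``padj`` is Benjamini-Hochberg across all tested sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError, GmtError, ParameterError
from .store import CorrelationVector

DEFAULT_N_PERM = 1000
DEFAULT_MIN_SIZE = 15
DEFAULT_MAX_SIZE = 500
DEFAULT_WEIGHT = 1.0
MIN_RANKED_GENES = 100


@dataclass
class GeneSetCollection:
    """Named gene sets with uppercased symbols (GMT-backed)."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source_tag: str = ""

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return sorted(self.sets)

    @classmethod
    def from_dict(cls, sets: dict, source_tag: str = "") -> "GeneSetCollection":
        clean = {
            str(name): frozenset(str(g).upper() for g in members)
            for name, members in sets.items()
        }
        return cls(sets=clean, source_tag=source_tag)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (one set per line: name, description, genes...)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in sets:
                raise GmtError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(g.upper() for g in genes if g)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions, source_tag=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(collection.sets[name])]) + "\n")


def enrichment_score(
    scores: np.ndarray, is_hit: np.ndarray, weight_exponent: float = DEFAULT_WEIGHT
) -> tuple[float, np.ndarray]:
    """Weighted KS running-sum enrichment score for one set.

    ``scores`` must be sorted descending; ``is_hit`` marks set members.
    Returns (ES, indices of the leading-edge hits in ranking order).
    """
    scores = np.asarray(scores, dtype=float)
    is_hit = np.asarray(is_hit, dtype=bool)
    N = len(scores)
    m = int(is_hit.sum())
    if m == 0:
        raise AnalysisError("gene set has no members in the ranking")
    if m == N:
        raise AnalysisError("gene set covers the whole ranking (no misses to decrement)")
    if not np.all(np.isfinite(scores)):
        raise AnalysisError("ranking scores must be finite")
    w = np.abs(scores[is_hit]) ** weight_exponent
    tot = w.sum()
    if tot == 0:  # all hit scores exactly zero: fall back to unweighted steps
        w = np.ones(m)
        tot = float(m)
    # cumulate hits and misses separately with a single final division each,
    # so the unweighted statistic is exact (no drift on long tied runs)
    hit_steps = np.zeros(N)
    hit_steps[is_hit] = w
    run = np.cumsum(hit_steps) / tot - np.cumsum(~is_hit) / (N - m)
    # extremum by absolute value; exact ties (up to rounding) go to the
    # earliest position, so the result does not depend on accumulation order
    absrun = np.abs(run)
    i = int(np.argmax(absrun >= absrun.max() - 1e-12))
    es = float(np.clip(run[i], -1.0, 1.0))
    hit_idx = np.flatnonzero(is_hit)
    leading = hit_idx[hit_idx <= i] if es >= 0 else hit_idx[hit_idx >= i]
    return es, leading


def _batch_enrichment_scores(
    scores: np.ndarray, positions: np.ndarray, weight_exponent: float
) -> np.ndarray:
    """ES for many sets given their (row-wise) hit positions in one ranking.

    The running sum's maximum is attained at a hit and its minimum just
    before a hit (or at the start/end, where it is 0), so only 2m candidate
    values per set need evaluating.
    """
    N = len(scores)
    B, m = positions.shape
    pos = np.sort(positions, axis=1)
    w = np.abs(scores)[pos] ** weight_exponent
    tot = w.sum(axis=1, keepdims=True)
    zero = tot[:, 0] == 0
    if zero.any():
        w[zero] = 1.0
        tot[zero] = m
    H = np.cumsum(w, axis=1) / tot
    k = np.arange(1, m + 1)
    miss_before = (pos + 1 - k) / (N - m)  # misses seen before hit k
    at_hit = H - miss_before
    before_hit = np.concatenate([np.zeros((B, 1)), H[:, :-1]], axis=1) - miss_before
    top = at_hit.max(axis=1)
    bottom = np.minimum(before_hit.min(axis=1), 0.0)
    return np.clip(np.where(top >= -bottom, top, bottom), -1.0, 1.0)


def _null_es(
    scores: np.ndarray, size: int, n_perm: int, weight_exponent: float, rng
) -> np.ndarray:
    """Permutation null: ES of ``n_perm`` random same-size sets from the ranking."""
    N = len(scores)
    positions = np.argsort(rng.random((n_perm, N)), axis=1)[:, :size]
    return _batch_enrichment_scores(scores, positions, weight_exponent)


def corgsea(
    vector: CorrelationVector,
    collection: GeneSetCollection,
    n_perm: int = DEFAULT_N_PERM,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    weight_exponent: float = DEFAULT_WEIGHT,
    seed: int | None = None,
) -> pd.DataFrame:
    """Preranked GSEA on a gene's genome-wide correlation vector.

    The query gene and missing correlations are dropped before ranking (its
    self-correlation of 1 would distort the top).  Results are deterministic
    given ``seed``; sets outside the size bounds are recorded in
    ``result.attrs["skipped"]`` rather than raising.
    """
    genes, r = vector.ranked(drop_query=True)
    if len(genes) < MIN_RANKED_GENES:
        raise AnalysisError(
            f"corGSEA needs >= {MIN_RANKED_GENES} ranked genes, got {len(genes)}"
        )
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}

    rows = []
    skipped = []
    for name in collection.names():
        members = [gene_pos[g] for g in collection.sets[name] if g in gene_pos]
        m = len(members)
        if m < min_size or m > max_size:
            skipped.append((name, m, "size"))
            continue
        if m == len(genes):
            skipped.append((name, m, "covers_universe"))
            continue
        is_hit = np.zeros(len(genes), dtype=bool)
        is_hit[members] = True
        es, leading = enrichment_score(r, is_hit, weight_exponent)
        if m not in null_cache:
            null_cache[m] = _null_es(r, m, n_perm, weight_exponent, rng)
        null = null_cache[m]
        pval = (1.0 + np.sum(np.abs(null) >= abs(es))) / (n_perm + 1.0)
        same_sign = null[null > 0] if es > 0 else null[null < 0] if es < 0 else null
        if es == 0:
            nes = 0.0
        elif len(same_sign) == 0:
            nes = np.nan
        else:
            nes = es / float(np.mean(np.abs(same_sign)))
        rows.append(
            {
                "set": name,
                "size": m,
                "ES": es,
                "NES": nes,
                "pval": pval,
                "leading_edge": ",".join(genes[leading]),
            }
        )
    if not rows:
        import warnings

        warnings.warn("no gene sets within size bounds; empty corGSEA result", stacklevel=2)
        out = pd.DataFrame(columns=["set", "size", "ES", "NES", "pval", "padj", "leading_edge"])
        out.attrs["skipped"] = skipped
        return out
    out = pd.DataFrame(rows)
    out["padj"] = multipletests(out["pval"].to_numpy(), method="fdr_bh")[1]
    out = out[["set", "size", "ES", "NES", "pval", "padj", "leading_edge"]]
    out = out.sort_values(["pval", "set"], kind="stable").reset_index(drop=True)
    out.attrs["skipped"] = skipped
    return out


def hypergeom_upper_tail(overlap: int, population: int, successes: int, draws: int) -> float:
    """P[X >= overlap] for X ~ Hypergeom(population, successes, draws)."""
    return float(stats.hypergeom.sf(overlap - 1, population, successes, draws))


def over_representation(
    query: list[str], collection: GeneSetCollection, universe: list[str]
) -> pd.DataFrame:
    """Hypergeometric upper-tail over-representation of a gene list in each set.

    The query is intersected with the universe first; BH adjustment across
    all sets with a nonzero universe intersection.
    """
    uni = {str(g).upper() for g in universe}
    q = {str(g).upper() for g in query} & uni
    if not q:
        raise AnalysisError("query list is empty after intersecting with the universe")
    rows = []
    for name in collection.names():
        s = collection.sets[name] & uni
        if not s:
            continue
        x = len(q & s)
        rows.append(
            {
                "set": name,
                "set_size": len(s),
                "overlap": x,
                "pval": hypergeom_upper_tail(x, len(uni), len(s), len(q)),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["set", "set_size", "overlap", "pval", "padj"])
    out = pd.DataFrame(rows)
    out["padj"] = multipletests(out["pval"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values(["padj", "pval", "set"], kind="stable").reset_index(drop=True)
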