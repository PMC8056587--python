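"""Per-(tissue, disease) genome-wide correlation matrices and single-gene vectors.

Correlations are computed within sample strata so that a gene pair's
relationship in, say, bone cancer is not diluted by its behaviour in brain
tissue.  Each stored group holds a symmetric gene x gene Pearson (or
Spearman) matrix together with the sample count n used, which drives the
analytic p-value for any single coefficient: two-sided p from
``t = r*sqrt(n-2)/sqrt(1-r^2)`` on n-2 degrees of freedom.
Genes with zero variance within a group have undefined correlations; those
entries are stored as NaN and dropped before any downstream ranking.
"""

from __future__ import annotations

import difflib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ParameterError, StoreError
from .normalize import VstMatrix

GROUP_SEP = "__"


def group_key(tissue: str, disease: str) -> str:
    return f"{tissue}:{disease}"


def parse_group(selector: str) -> tuple[str, str]:
    """Parse a "tissue:disease" selector string."""
    parts = selector.split(":")
    if len(parts) != 2 or not all(parts):
        raise ParameterError(f"group selector must be 'tissue:disease', got {selector!r}")
    return parts[0], parts[1]


def correlation_matrix(values: np.ndarray, method: str = "pearson") -> np.ndarray:
    """Gene x gene correlation over samples (columns of ``values``).

    Zero-variance genes yield NaN rows/columns.  Requires >= 3 samples.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[1] < 3:
        raise AnalysisError(f"need >= 3 samples for correlations, got {values.shape[1]}")
    if method == "spearman":
        values = stats.rankdata(values, axis=1)
    elif method != "pearson":
        raise ParameterError(f"unknown correlation method {method!r}")
    sd = values.std(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mat = np.corrcoef(values)
    bad = sd == 0
    mat[bad, :] = np.nan
    mat[:, bad] = np.nan
    good = ~bad
    mat[good, good] = 1.0
    return np.clip(mat, -1.0, 1.0, out=mat)


def correlation_pvalue(r, n: int):
    """Two-sided p-value for a correlation coefficient at sample size n.

    Student-t convention: t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 df; |r| = 1
    maps to p = 0.  NaN correlations propagate to NaN p-values.
    """
    if n < 3:
        raise ParameterError(f"correlation p-value needs n >= 3, got {n}")
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return np.where(np.isnan(r), np.nan, p)


@dataclass
class CorrelationVector:
    """One gene's genome-wide correlations within one tissue-disease group."""

    query_gene: str
    tissue: str
    disease: str
    genes: np.ndarray
    r: np.ndarray
    p: np.ndarray
    n: int

    @property
    def group(self) -> tuple[str, str]:
        return (self.tissue, self.disease)

    def ranked(self, drop_query: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """(genes, r) sorted by descending r, NaNs dropped, ties broken by symbol."""
        keep = np.isfinite(self.r)
        if drop_query:
            keep &= self.genes != self.query_gene
        genes, r = self.genes[keep], self.r[keep]
        order = np.lexsort((genes, -r))
        return genes[order], r[order]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "r": self.r, "p": self.p})


@dataclass
class GroupData:
    matrix: np.ndarray  # float32, NaN for zero-variance genes
    n: int
    sample_ids: np.ndarray


class CorrelationStore:
    """Correlation matrices for every tissue-disease group over a shared gene universe.

    When built in memory the store also keeps the variance-stabilized
    expression matrix and the per-group sample columns, which the same-gene
    cancer-vs-normal expression contrast needs.
    """

    def __init__(
        self,
        gene_ids: np.ndarray,
        groups: dict[tuple[str, str], GroupData],
        expression: VstMatrix | None = None,
        method: str = "pearson",
    ):
        self.gene_ids = np.asarray(gene_ids)
        self.groups = groups
        self.expression = expression
        self.method = method
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def group_keys(self) -> list[tuple[str, str]]:
        return sorted(self.groups)

    def _gene_index(self, gene: str) -> int:
        gene = str(gene).upper()
        if gene not in self._index:
            close = difflib.get_close_matches(gene, list(self._index), n=5)
            raise StoreError(
                f"gene {gene!r} not in the correlation store"
                + (f"; nearest symbols: {', '.join(close)}" if close else "")
            )
        return self._index[gene]

    def has_gene(self, gene: str) -> bool:
        return str(gene).upper() in self._index

    def matrix(self, group: tuple[str, str]) -> GroupData:
        if tuple(group) not in self.groups:
            avail = ", ".join(group_key(*g) for g in self.group_keys())
            raise StoreError(f"group {group_key(*group)!r} not found; available: {avail}")
        return self.groups[tuple(group)]

    def get_vector(self, gene: str, group: tuple[str, str]) -> CorrelationVector:
        idx = self._gene_index(gene)
        gd = self.matrix(group)
        r = gd.matrix[idx].astype(float)
        p = correlation_pvalue(r, gd.n)
        if np.isfinite(r[idx]):
            r[idx], p[idx] = 1.0, 0.0
        return CorrelationVector(
            query_gene=self.gene_ids[idx],
            tissue=group[0],
            disease=group[1],
            genes=self.gene_ids.copy(),
            r=r,
            p=p,
            n=gd.n,
        )

    def get_correlations(
        self, gene: str, groups: list[tuple[str, str]] | None = None
    ) -> list[CorrelationVector]:
        """One CorrelationVector per requested group (all groups by default)."""
        if groups is None:
            groups = self.group_keys()
        return [self.get_vector(gene, g) for g in groups]

    # -- persistence --------------------------------------------------------

    def save(self, outdir, include_expression: bool = True) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest: dict = {"method": self.method, "gene_count": len(self.gene_ids), "groups": {}}
        np.savetxt(outdir / "genes.txt", self.gene_ids, fmt="%s")
        for (tissue, disease), gd in sorted(self.groups.items()):
            fname = f"{tissue}{GROUP_SEP}{disease}.npy"
            np.save(outdir / fname, gd.matrix.astype(np.float32))
            manifest["groups"][group_key(tissue, disease)] = {
                "n": int(gd.n),
                "file": fname,
                "gene_count": len(self.gene_ids),
                "sample_ids": [str(s) for s in gd.sample_ids],
            }
        if include_expression and self.expression is not None:
            self.expression.to_tsv(outdir / "vst.tsv")
            self.expression.write_sidecar(outdir / "vst_params.json")
            manifest["expression"] = "vst.tsv"
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, indir) -> "CorrelationStore":
        indir = Path(indir)
        with open(indir / "manifest.json") as fh:
            manifest = json.load(fh)
        gene_ids = np.loadtxt(indir / "genes.txt", dtype=str, ndmin=1)
        groups: dict[tuple[str, str], GroupData] = {}
        for key, info in manifest["groups"].items():
            tissue, disease = parse_group(key)
            groups[(tissue, disease)] = GroupData(
                matrix=np.load(indir / info["file"]),
                n=int(info["n"]),
                sample_ids=np.asarray(info["sample_ids"]),
            )
        expression = None
        if manifest.get("expression"):
            from .normalize import DispersionTrend

            df = pd.read_csv(indir / "vst.tsv", sep="\t", index_col=0)
            with open(indir / "vst_params.json") as fh:
                params = json.load(fh)
            expression = VstMatrix(
                values=df.to_numpy(),
                gene_ids=df.index.to_numpy(),
                sample_ids=df.columns.to_numpy(),
                size_factors=np.asarray(
                    [params["size_factors"][str(s)] for s in df.columns]
                ),
                trend=DispersionTrend(**{
                    "a0": params["trend_params"]["a0"],
                    "a1": params["trend_params"]["a1"],
                }),
            )
        return cls(gene_ids, groups, expression=expression, method=manifest["method"])


def build_store(
    vst: VstMatrix,
    records,
    method: str = "pearson",
    min_samples: int = 3,
) -> CorrelationStore:
    """Compute per-group correlation matrices from a VST matrix and a filtered catalog.

    Only retained (non-excluded) records with an assigned tissue contribute;
    genes are placed in a fixed sorted order shared by every group.
    """
    order = np.argsort(vst.gene_ids)
    gene_ids = vst.gene_ids[order]
    values = vst.values[order]
    sample_pos = {str(s): j for j, s in enumerate(vst.sample_ids)}

    members: dict[tuple[str, str], list[str]] = {}
    for rec in records:
        if rec.excluded or rec.tissue_label is None:
            continue
        if rec.sample_id not in sample_pos:
            raise StoreError(f"catalog sample {rec.sample_id!r} absent from the count matrix")
        members.setdefault((rec.tissue_label, rec.disease_label), []).append(rec.sample_id)

    groups: dict[tuple[str, str], GroupData] = {}
    for key, ids in sorted(members.items()):
        if len(ids) < min_samples:
            continue
        cols = [sample_pos[s] for s in ids]
        mat = correlation_matrix(values[:, cols], method=method).astype(np.float32)
        groups[key] = GroupData(matrix=mat, n=len(ids), sample_ids=np.asarray(ids))
    if not groups:
        raise StoreError("no tissue-disease group has enough retained samples")

    expr = VstMatrix(
        values=values,
        gene_ids=gene_ids,
        sample_ids=vst.sample_ids.copy(),
        size_factors=vst.size_factors.copy(),
        trend=vst.trend,
    )
    return CorrelationStore(gene_ids, groups, expression=expr, method=method)


def consensus_top_correlates(
    vectors: list[CorrelationVector], k: int, agg: str = "mean"
) -> pd.DataFrame:
    """Genes ranked by mean (or median) correlation across groups.

    The query gene is excluded; genes with a missing correlation in any group
    are dropped.  If k exceeds the universe it is truncated with a warning.
    """
    if len(vectors) < 2:
        raise AnalysisError("consensus ranking needs >= 2 group vectors")
    if k < 1:
        raise ParameterError("k must be >= 1")
    if agg not in ("mean", "median"):
        raise ParameterError(f"unknown aggregation {agg!r}")
    genes = vectors[0].genes
    for v in vectors[1:]:
        if not np.array_equal(v.genes, genes):
            raise AnalysisError("group vectors do not share a gene universe")
    R = np.stack([v.r for v in vectors])
    keep = np.all(np.isfinite(R), axis=0)
    for v in vectors:
        keep &= genes != v.query_gene
    genes_k, R_k = genes[keep], R[:, keep]
    score = np.mean(R_k, axis=0) if agg == "mean" else np.median(R_k, axis=0)
    if k > len(genes_k):
        warnings.warn(
            f"k={k} exceeds the {len(genes_k)}-gene universe; truncating", stacklevel=2
        )
        k = len(genes_k)
    order = np.lexsort((genes_k, -score))[:k]
    out = pd.DataFrame({"gene": genes_k[order], "consensus_r": score[order]})
    for v, row in zip(vectors, R_k):
        out[f"r:{group_key(*v.group)}"] = row[order]
    return out
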