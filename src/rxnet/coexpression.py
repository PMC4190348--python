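"""Co-expression networks and temporal clustering.

Edges connect gene pairs whose developmental expression profiles
correlate at |r| >= 0.95 (Pearson, on quantile-normalized,
replicate-averaged, log2 RPKM).  The cohesion of a gene set is its
connectivity score — the mean absolute pairwise correlation over all
C(n,2) pairs — tested against the scores of equally sized random gene
sets.  Temporal groups come from complete-linkage hierarchical
clustering of per-gene z-score profiles under Euclidean distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import pearsonr, spearmanr

from .expression import ExpressionMatrix, InvalidInputError


class UndefinedVarianceError(ValueError):
    """A correlation was requested between zero-variance variables."""


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null sample, and empirical p.

    p = #(null >= observed) / n_perm by default (the convention that
    yields p = 6/1000 granularity); the (count+1)/(n+1) estimator is
    available via ``estimator="add_one"``.
    """

    observed: float
    null_values: np.ndarray
    n_perm: int
    seed: int
    estimator: str = "count"

    @property
    def p(self) -> float:
        count = int(np.sum(self.null_values >= self.observed))
        if self.estimator == "add_one":
            return (count + 1) / (self.n_perm + 1)
        return count / self.n_perm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observed": [self.observed],
                "p": [self.p],
                "n_perm": [self.n_perm],
                "seed": [self.seed],
            }
        )


def correlation_matrix(m: ExpressionMatrix, method: str = "pearson") -> pd.DataFrame:
    """All-pairs gene correlation over stages.

    Requires quantile-normalized, replicate-averaged log2 RPKM and at
    least 3 stage columns.  Constant gene rows have undefined
    correlations; these are recorded as 0 with a warning.
    """
    m.require_units("log2rpkm", "zscore")
    if m.values.shape[1] < 3:
        raise InvalidInputError("need >= 3 stages for correlations")
    X = m.values.to_numpy(dtype=float)
    const = X.std(axis=1) == 0
    if method == "pearson":
        with np.errstate(invalid="ignore"):
            R = np.corrcoef(X)
    elif method == "spearman":
        with np.errstate(invalid="ignore"):
            R, _ = spearmanr(X, axis=1)
            R = np.atleast_2d(R)
    else:
        raise InvalidInputError(f"unknown correlation method {method!r}")
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant gene row(s): correlations set to 0",
            stacklevel=2,
        )
        R[const, :] = 0.0
        R[:, const] = 0.0
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=m.gene_ids, columns=m.gene_ids)


def build_network(
    corr: pd.DataFrame, genes=None, threshold: float = 0.95
) -> nx.Graph:
    """Threshold the correlation matrix into a signed co-expression graph.

    An edge joins every pair with |r| >= threshold (inclusive); genes
    with no such partner are excluded from the network.  Edge
    attributes: ``r`` (signed) and ``sign`` (+1/-1).
    """
    if genes is None:
        genes = list(corr.index)
    else:
        genes = list(genes)
        missing = set(genes) - set(corr.index)
        if missing:
            raise InvalidInputError(f"genes absent from corr: {sorted(missing)[:5]}")
    sub = corr.loc[genes, genes].to_numpy()
    g = nx.Graph()
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    hits = np.abs(sub[iu, ju]) >= threshold
    for a, b in zip(iu[hits], ju[hits]):
        r = float(sub[a, b])
        g.add_edge(genes[a], genes[b], r=r, sign=1 if r >= 0 else -1)
    return g


def connectivity_score(genes, corr: pd.DataFrame) -> float:
    """Mean |r| over all unordered pairs of the gene set."""
    genes = list(genes)
    if len(genes) < 2:
        raise InvalidInputError("connectivity needs >= 2 genes")
    sub = np.abs(corr.loc[genes, genes].to_numpy())
    iu, ju = np.triu_indices(len(genes), k=1)
    return float(sub[iu, ju].mean())


def permutation_connectivity(
    geneset,
    background,
    corr: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    estimator: str = "count",
) -> PermutationResult:
    """Permutation test of gene-set connectivity.

    The null samples the connectivity score of ``n_perm`` uniform
    random subsets of the background universe, each the size of the
    query set (drawn without replacement within a draw); p counts
    null scores >= the observed score.
    """
    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    geneset = list(geneset)
    background = list(background)
    if len(geneset) > len(background):
        raise InvalidInputError("gene set larger than background universe")
    observed = connectivity_score(geneset, corr)
    rng = np.random.default_rng(seed)
    absR = np.abs(corr.loc[background, background].to_numpy())
    k = len(geneset)
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = np.sort(rng.choice(len(background), size=k, replace=False))
        sub = absR[np.ix_(idx, idx)]
        iu, ju = np.triu_indices(k, k=1)
        null[i] = sub[iu, ju].mean()
    return PermutationResult(
        observed=observed, null_values=null, n_perm=n_perm, seed=seed,
        estimator=estimator,
    )


def degree_fc_correlation(net: nx.Graph, fc: dict | pd.Series):
    """Pearson correlation of node degree with |log2 fold change|.

    Returns (r, slope, intercept) of the fitted line for the dot-plot
    overlay.  Raises if either variable has zero variance.
    """
    fc = pd.Series(fc, dtype=float)
    nodes = sorted(net.nodes)
    missing = set(nodes) - set(fc.index)
    if missing:
        raise InvalidInputError(f"nodes without fold change: {sorted(missing)[:5]}")
    deg = np.array([net.degree[n] for n in nodes], dtype=float)
    vals = fc.loc[nodes].to_numpy()
    if deg.std() == 0 or vals.std() == 0:
        raise UndefinedVarianceError("degree or fold change has zero variance")
    r = float(pearsonr(deg, vals).statistic)
    slope, intercept = np.polyfit(deg, vals, 1)
    return r, float(slope), float(intercept)


def hierarchical_cluster(z: ExpressionMatrix, k: int = 3) -> pd.Series:
    """Complete-linkage Euclidean clustering of z-score profiles.

    The tree is cut into exactly ``k`` groups; group labels 1..k are
    ordered by the group-mean profile's peak stage (earliest peak =
    group 1) so labels are reportable across runs.
    """
    z.require_units("zscore")
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    n = z.values.shape[0]
    if k > n:
        raise InvalidInputError("more groups than genes")
    X = z.values.to_numpy(dtype=float)
    if n == 1:
        return pd.Series([1], index=z.gene_ids)
    Zl = linkage(X, method="complete", metric="euclidean")
    raw = fcluster(Zl, t=k, criterion="maxclust")
    # order groups by mean peak time for stable reporting
    peaks = {}
    for lab in np.unique(raw):
        peaks[lab] = float(np.mean(np.argmax(X[raw == lab], axis=1)))
    order = sorted(peaks, key=lambda lab: (peaks[lab], lab))
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    return pd.Series([remap[v] for v in raw], index=z.gene_ids, name="group")


def complete_linkage_heights(z: ExpressionMatrix) -> np.ndarray:
    """Merge heights of the complete-linkage dendrogram (ascending)."""
    z.require_units("zscore")
    Zl = linkage(z.values.to_numpy(dtype=float), method="complete",
                 metric="euclidean")
    return Zl[:, 2]


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def write_sif(net: nx.Graph, path: str) -> None:
    """Simple interaction format: 'gene1 <pos|neg> gene2' per edge."""
    with open(path, "w") as fh:
        for u, v, d in sorted(net.edges(data=True)):
            rel = "pos" if d["sign"] > 0 else "neg"
            fh.write(f"{u}\t{rel}\t{v}\n")
        for n in sorted(net.nodes):
            if net.degree[n] == 0:
                fh.write(f"{n}\n")


def write_edge_table(net: nx.Graph, path: str) -> None:
    rows = [
        {"gene1": u, "gene2": v, "r": d["r"], "sign": d["sign"]}
        for u, v, d in sorted(net.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["gene1", "gene2", "r", "sign"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def write_graphml(net: nx.Graph, path: str) -> None:
    nx.write_graphml(net, path)
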