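"""Species-level summaries and comparative statistics.

Implements phylogenetic generalized least squares (PGLS) under a Brownian
motion model of trait covariance, Spearman rank correlation with an exact
small-sample null, Wilcoxon rank tests, and the binned length/similarity
tables used to summarise NUMT complements.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import solve_triangular

__all__ = [
    "PhyloTree",
    "SpeciesSummary",
    "PGLSFit",
    "RankTestResult",
    "BinTable",
    "load_tree",
    "bm_covariance",
    "simulate_bm",
    "random_ultrametric_tree",
    "pgls_fit",
    "spearman",
    "rank_test",
    "bin_length_similarity",
    "summarize_species",
    "read_traits",
    "species_summary_frame",
]


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths plus the derived tip order."""

    tree: dendropy.Tree
    tips: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tips)


@dataclass(frozen=True)
class SpeciesSummary:
    species: str
    n_numts: int
    total_len: int
    pct_genome: float
    genome_size: int
    n_insertion: int
    n_duplicate: int
    n_complex_clusters: int
    mean_len: float


@dataclass
class PGLSFit:
    """A Brownian-motion GLS regression fit.

    ``beta`` is (intercept, slope); ``sigma2`` is the estimated BM rate;
    ``r2`` is computed on residuals whitened by the Cholesky factor of the
    BM covariance, with the total sum of squares taken about the GLS mean.
    """

    beta: np.ndarray
    sigma2: float
    r2: float
    p_value: float
    df: int
    covariance: np.ndarray
    lam: float = 1.0


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_value: float
    n: tuple[int, ...]
    test_name: str  # "signed-rank" | "rank-sum"
    sidedness: str
    degenerate: bool = False


@dataclass
class BinTable:
    length_edges: np.ndarray
    length_counts: np.ndarray
    length_props: np.ndarray
    identity_edges: np.ndarray
    identity_counts: np.ndarray
    identity_mean_len: np.ndarray


# ---------------------------------------------------------------------------
# trees and Brownian covariance


def load_tree(source: str | Path) -> PhyloTree:
    """Read a rooted Newick tree with branch lengths."""
    s = str(source)
    if "(" not in s and Path(s).exists():
        tree = dendropy.Tree.get(path=s, schema="newick")
    else:
        tree = dendropy.Tree.get(data=s, schema="newick")
    tips = tuple(leaf.taxon.label for leaf in tree.leaf_node_iter())
    return PhyloTree(tree=tree, tips=tips)


def bm_covariance(ptree: PhyloTree, taxa: Sequence[str] | None = None) -> np.ndarray:
    """Brownian-motion covariance: C[i, j] = root-to-MRCA path length.

    Computed as (d_i + d_j - dist(i, j)) / 2 where d is root distance and
    dist the patristic distance, which is exactly the shared path length.
    """
    taxa = tuple(taxa) if taxa is not None else ptree.tips
    tree = ptree.tree
    idx = {t: i for i, t in enumerate(taxa)}
    present = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = [t for t in taxa if t not in present]
    if missing:
        raise ValueError(f"taxa not in tree: {missing}")
    n = len(taxa)
    C = np.zeros((n, n))
    depth: dict = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depth[node] = (depth[parent] if parent is not None else 0.0) + (node.edge.length or 0.0)
    tipsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label in idx:
                i = idx[label]
                C[i, i] = depth[node]
                tipsets[node] = [i]
            else:
                tipsets[node] = []
        else:
            kids = [tipsets[c] for c in node.child_nodes()]
            d = depth[node]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for u in kids[a]:
                        for v in kids[b]:
                            C[u, v] = C[v, u] = d
            tipsets[node] = [x for k in kids for x in k]
    return C


def random_ultrametric_tree(n_tips: int, rng: np.random.Generator, prefix: str = "sp") -> PhyloTree:
    """A random ultrametric (coalescent-style) tree for simulations."""
    clades = [(f"{prefix}{i + 1}", 0.0) for i in range(n_tips)]
    height = 0.0
    while len(clades) > 1:
        height += float(rng.exponential(1.0 / len(clades)))
        i, j = rng.choice(len(clades), size=2, replace=False)
        (na, ha), (nb, hb) = clades[i], clades[j]
        merged = (f"({na}:{height - ha:.6f},{nb}:{height - hb:.6f})", height)
        clades = [c for k, c in enumerate(clades) if k not in (i, j)] + [merged]
    newick = clades[0][0] + ";"
    return load_tree(newick)


def simulate_bm(
    ptree: PhyloTree,
    rng: np.random.Generator,
    sigma2: float = 1.0,
    mean: float = 0.0,
    taxa: Sequence[str] | None = None,
) -> np.ndarray:
    """Simulate one Brownian-motion trait vector over the tips."""
    C = bm_covariance(ptree, taxa)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))
    return mean + math.sqrt(sigma2) * (L @ rng.standard_normal(len(C)))


# ---------------------------------------------------------------------------
# PGLS


def pgls_fit(
    y: Sequence[float],
    x: Sequence[float],
    ptree: PhyloTree,
    taxa: Sequence[str] | None = None,
    lam: float = 1.0,
    estimate_lambda: bool = False,
) -> PGLSFit:
    """GLS regression of y on x under Brownian covariance from the tree.

    beta = (X' C^-1 X)^-1 X' C^-1 y.  Pagel's lambda scales the off-diagonal
    covariances; it is fixed at 1 (pure BM) unless ``estimate_lambda`` is
    set, in which case it is chosen by maximum likelihood on [0, 1].
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("PGLS requires at least 3 tips")
    if len(x) != n:
        raise ValueError("x and y must have equal length")
    C0 = bm_covariance(ptree, taxa)
    if C0.shape[0] != n:
        raise ValueError("trait vectors do not match the tree tips")

    def scaled(l: float) -> np.ndarray:
        C = l * C0 + (1.0 - l) * np.diag(np.diag(C0))
        return C

    if estimate_lambda:
        from scipy.optimize import minimize_scalar

        def negll(l: float) -> float:
            C = scaled(l)
            try:
                L = np.linalg.cholesky(C)
            except np.linalg.LinAlgError:
                return np.inf
            X = np.column_stack([np.ones(n), x])
            Xw = solve_triangular(L, X, lower=True)
            yw = solve_triangular(L, y, lower=True)
            b, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
            r = yw - Xw @ b
            s2 = float(r @ r) / n
            return 0.5 * (n * math.log(2 * math.pi * s2) + 2 * np.log(np.diag(L)).sum() + n)

        res = minimize_scalar(negll, bounds=(0.0, 1.0), method="bounded")
        lam = float(res.x)

    C = scaled(lam)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular BM covariance (zero-length tree?)") from exc

    X = np.column_stack([np.ones(n), x])
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, y, lower=True)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)

    ones_w = Xw[:, 0]
    b0 = float(ones_w @ yw) / float(ones_w @ ones_w)
    tss = float(((yw - ones_w * b0) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss < 1e-12 else 0.0)

    df = n - 2
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    se_slope = math.sqrt(max(sigma2 * xtx_inv[1, 1], 0.0))
    if se_slope == 0:
        p = 0.0 if abs(beta[1]) > 0 else 1.0
    else:
        t = beta[1] / se_slope
        p = 2.0 * sps.t.sf(abs(t), df)
    return PGLSFit(beta=beta, sigma2=sigma2, r2=max(min(r2, 1.0), 0.0), p_value=p,
                   df=df, covariance=C, lam=lam)


# ---------------------------------------------------------------------------
# correlation and rank tests


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of (average) ranks.  For n <= 9 the
    p-value is exact, from full enumeration of rank permutations; otherwise
    the usual t approximation with n - 2 df is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("spearman requires n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)

    def _rho(a: np.ndarray, b: np.ndarray) -> float:
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / math.sqrt((a @ a) * (b @ b)))

    rho = _rho(rx, ry)
    if n <= 9:
        rxc = rx - rx.mean()
        denom_x = math.sqrt(float(rxc @ rxc))
        count = 0
        total = 0
        ryc = ry - ry.mean()
        denom_y = math.sqrt(float(ryc @ ryc))
        for perm in itertools.permutations(ryc):
            r = float(rxc @ np.asarray(perm)) / (denom_x * denom_y)
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        t = rho * math.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
        p = 2.0 * sps.t.sf(abs(t), n - 2)
    return rho, min(p, 1.0)


def _signed_rank(diffs: np.ndarray, alternative: str) -> RankTestResult:
    nz = diffs[diffs != 0]
    if len(nz) == 0:
        return RankTestResult(statistic=0.0, p_value=1.0, n=(len(diffs),),
                              test_name="signed-rank", sidedness=alternative, degenerate=True)
    no_ties = len(np.unique(np.abs(nz))) == len(nz)
    method = "exact" if (len(nz) <= 25 and no_ties) else "approx"
    res = sps.wilcoxon(diffs, alternative=alternative, zero_method="wilcox",
                       correction=True, method=method)
    return RankTestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                          n=(len(diffs),), test_name="signed-rank", sidedness=alternative)


def rank_test(
    a: Sequence[float],
    b: Sequence[float] | None = None,
    paired: bool = False,
    alternative: str = "two-sided",
) -> RankTestResult:
    """Wilcoxon rank test: signed-rank (paired) or rank-sum (two-sample).

    With ``b=None``, ``a`` is interpreted as paired differences.  Exact null
    distributions are used for small samples without ties, with a
    continuity-corrected normal approximation (tie correction included)
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    if len(a) == 0:
        raise ValueError("empty group")
    if b is None or paired:
        if b is not None:
            b = np.asarray(b, dtype=float)
            if len(b) != len(a):
                raise ValueError("paired samples must have equal length")
            diffs = a - b
        else:
            diffs = a
        return _signed_rank(diffs, alternative)
    b = np.asarray(b, dtype=float)
    if len(b) == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(a) + len(b) <= 30 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    return RankTestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                          n=(len(a), len(b)), test_name="rank-sum", sidedness=alternative)


# ---------------------------------------------------------------------------
# binned tables and species summaries

DEFAULT_LENGTH_EDGES = np.array([0.0, 500.0, 1000.0, 2000.0, 5000.0, np.inf])
DEFAULT_IDENTITY_EDGES = np.arange(0.70, 1.0001, 0.05)


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Left-closed right-open bins; the last bin is closed on the right."""
    if np.any(values < edges[0]) or np.any(values > edges[-1]):
        raise ValueError("values fall outside the bin edges")
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.minimum(idx, len(edges) - 2)


def bin_length_similarity(
    numts: Sequence,
    length_edges: Sequence[float] | None = None,
    identity_edges: Sequence[float] | None = None,
) -> BinTable:
    """Binned NUMT length proportions and per-identity-bin mean lengths."""
    le = np.asarray(length_edges if length_edges is not None else DEFAULT_LENGTH_EDGES, dtype=float)
    ie = np.asarray(identity_edges if identity_edges is not None else DEFAULT_IDENTITY_EDGES, dtype=float)
    for e in (le, ie):
        if np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing")
    lengths = np.array([n.nuc_interval[1] - n.nuc_interval[0] for n in numts], dtype=float)
    idents = np.array([n.identity for n in numts], dtype=float)

    nl = len(le) - 1
    ni = len(ie) - 1
    lc = np.zeros(nl, dtype=int)
    ic = np.zeros(ni, dtype=int)
    isum = np.zeros(ni)
    if len(numts):
        li = _bin_index(lengths, le)
        ii = _bin_index(idents, ie)
        np.add.at(lc, li, 1)
        np.add.at(ic, ii, 1)
        np.add.at(isum, ii, lengths)
    with np.errstate(invalid="ignore"):
        mean_len = np.where(ic > 0, isum / np.maximum(ic, 1), np.nan)
    props = lc / lc.sum() if lc.sum() else lc.astype(float)
    return BinTable(length_edges=le, length_counts=lc, length_props=props,
                    identity_edges=ie, identity_counts=ic, identity_mean_len=mean_len)


def summarize_species(
    numts: Sequence,
    clusters: Sequence,
    families: Sequence,
    genome_size: int,
    species: str = "",
) -> SpeciesSummary:
    """Per-species NUMT totals: counts, length, genome percentage, type split."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    n = len(numts)
    total = sum(x.nuc_interval[1] - x.nuc_interval[0] for x in numts)
    n_dup = sum(1 for x in numts if getattr(x, "type_label", "insertion") == "duplicate")
    return SpeciesSummary(
        species=species,
        n_numts=n,
        total_len=total,
        pct_genome=100.0 * total / genome_size,
        genome_size=genome_size,
        n_insertion=n - n_dup,
        n_duplicate=n_dup,
        n_complex_clusters=len(clusters),
        mean_len=total / n if n else 0.0,
    )


def read_traits(path: str | Path) -> pd.DataFrame:
    """Read a per-species trait table (TSV with a ``species`` column)."""
    df = pd.read_csv(path, sep="\t")
    if "species" not in df.columns:
        raise ValueError("trait table must have a 'species' column")
    return df


def species_summary_frame(summaries: Iterable[SpeciesSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "species": s.species,
                "genome_size": s.genome_size,
                "n_numts": s.n_numts,
                "total_len": s.total_len,
                "pct_genome": round(s.pct_genome, 3),
                "n_insertion": s.n_insertion,
                "n_duplicate": s.n_duplicate,
                "n_complex_clusters": s.n_complex_clusters,
                "mean_len": round(s.mean_len, 1),
            }
        )
    return pd.DataFrame(rows)
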