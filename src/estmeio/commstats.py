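"""Community-structure statistics.

Counts are normalised to percent reads per sample, reduced to
presence/absence over the metazoan target phyla, and compared with the
Sørensen coefficient (2a/(2a+b+c) on shared and unique presences).
Group-average (UPGMA) clustering with SIMPROF permutation tests finds
sample groups with genuine internal structure; non-metric
multidimensional scaling (Kruskal stress-1, isotonic regression inside
a SMACOF majorisation loop) ordinates the samples; richness tables and
Levene-gated two-sample t-tests compare the estuaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix
from sklearn.isotonic import IsotonicRegression

from .io import OtuTable

__all__ = [
    "METAZOAN_PHYLA",
    "reads_to_percent",
    "to_presence",
    "pool_replicates",
    "sorensen_dissimilarity",
    "upgma",
    "Dendrogram",
    "simprof",
    "SimprofResult",
    "nmds",
    "NmdsResult",
    "richness_by_group",
    "station_richness",
    "welch_levene_ttest",
]

#: The eleven metazoan target phyla used for presence/absence analyses.
METAZOAN_PHYLA = [
    "Nematoda",
    "Platyhelminthes",
    "Arthropoda",
    "Mollusca",
    "Annelida",
    "Gastrotricha",
    "Tardigrada",
    "Kinorhyncha",
    "Rotifera",
    "Cnidaria",
    "Bryozoa",
]


class NormalisationError(ValueError):
    pass


def reads_to_percent(table: OtuTable) -> pd.DataFrame:
    """Percent of reads per sample (each sample column sums to 100)."""
    totals = table.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise NormalisationError(
            f"all-zero samples cannot be normalised: {list(zero.index)}"
        )
    return 100.0 * table.counts / totals


def to_presence(table: OtuTable,
                phyla: list[str] | None = None) -> pd.DataFrame:
    """Sample × OTU binary matrix over a taxon filter.

    Default filter is the eleven metazoan target phyla; OTUs absent
    from every sample after filtering are dropped.
    """
    phyla = METAZOAN_PHYLA if phyla is None else phyla
    filtered = table.filter_phyla(phyla)
    P = (filtered.counts.T > 0).astype(np.int8)
    P = P.loc[:, P.any(axis=0)]
    if P.shape[1] == 0:
        raise NormalisationError(
            "presence matrix is empty after filtering"
        )
    return P


def pool_replicates(P: pd.DataFrame, samples: pd.DataFrame,
                    ) -> pd.DataFrame:
    """Station-level presence: an OTU is present if seen in any
    replicate core of the station."""
    station = samples.loc[P.index, "station"]
    pooled = (P.groupby(station.values).max()).astype(np.int8)
    pooled.index.name = "station"
    # preserve station order of first appearance
    order = station.drop_duplicates().tolist()
    return pooled.loc[order]


def _dice_condensed(M: np.ndarray) -> np.ndarray:
    """Condensed Sørensen dissimilarities of a binary sample × OTU
    matrix; pairs of empty samples get 0."""
    M = np.asarray(M, dtype=float)
    a = M @ M.T
    s = M.sum(axis=1)
    denom = s[:, None] + s[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - 2.0 * a / denom
    d[denom == 0] = 0.0
    iu = np.triu_indices(M.shape[0], k=1)
    return d[iu]


def sorensen_dissimilarity(P: pd.DataFrame) -> DistanceMatrix:
    """Sørensen (Dice) dissimilarity matrix among samples.

    d = 1 − 2a/(2a+b+c) with a = shared presences, b and c unique to
    either sample. A pair of empty samples is defined to have d = 0
    (with a warning) rather than the formula's 0/0.
    """
    if P.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    s = P.values.sum(axis=1)
    if (s == 0).sum() >= 2:
        warnings.warn(
            "pairs of empty samples assigned dissimilarity 0",
            stacklevel=2,
        )
    d = _dice_condensed(P.values)
    return DistanceMatrix(squareform(d), ids=list(P.index.astype(str)))


@dataclass
class Dendrogram:
    """UPGMA merge tree over a labelled distance matrix."""

    linkage: np.ndarray
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, height: float) -> list[list[str]]:
        """Groups obtained by cutting at a dissimilarity height."""
        assign = hierarchy.fcluster(
            self.linkage, t=height, criterion="distance"
        )
        groups: dict[int, list[str]] = {}
        for lab, g in zip(self.labels, assign):
            groups.setdefault(g, []).append(lab)
        return list(groups.values())

    def to_newick(self) -> str:
        """Newick string with branch lengths = height differences."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf()
                                      else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.labels[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            blen = parent_height - node.dist
            return f"({left},{right}):{blen:.6g}"

        root = tree
        left = rec(root.left, root.dist)
        right = rec(root.right, root.dist)
        return f"({left},{right});"


def upgma(D: DistanceMatrix) -> Dendrogram:
    """Unweighted group-average agglomeration.

    Merge heights equal the average inter-cluster dissimilarity; ties
    are broken deterministically by the input label order (scipy's
    ordering convention).
    """
    Z = hierarchy.linkage(D.condensed_form(), method="average")
    return Dendrogram(linkage=Z, labels=list(D.ids))


@dataclass
class SimprofNode:
    node_id: int
    n_samples: int
    pi: float | None
    p_value: float | None
    significant: bool
    tested: bool


@dataclass
class SimprofResult:
    nodes: list[SimprofNode]
    groups: list[list[str]]
    alpha: float
    n_profile_perms: int
    n_test_perms: int
    meta: dict = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def _simprof_pi(M: np.ndarray, n_profile: int, n_test: int,
                rng: np.random.Generator) -> tuple[float, float]:
    """One similarity-profile test on a binary sample × OTU block.

    The observed ordered dissimilarity profile is compared with the
    mean profile of ``n_profile`` within-OTU permutations; pi is the
    summed absolute departure. The null distribution of pi comes from
    ``n_test`` further permutations scored against the same mean
    profile; p = (b+1)/(m+1).
    """
    obs = np.sort(_dice_condensed(M))
    npairs = obs.size
    mean_profile = np.zeros(npairs)
    for _ in range(n_profile):
        Mp = rng.permuted(M, axis=0)
        mean_profile += np.sort(_dice_condensed(Mp))
    mean_profile /= n_profile
    pi_obs = np.abs(obs - mean_profile).sum()
    exceed = 0
    for _ in range(n_test):
        Mp = rng.permuted(M, axis=0)
        pi_k = np.abs(np.sort(_dice_condensed(Mp)) - mean_profile).sum()
        if pi_k >= pi_obs:
            exceed += 1
    p = (exceed + 1) / (n_test + 1)
    return pi_obs, p


def simprof(P: pd.DataFrame, n_profile_perms: int = 1000,
            n_test_perms: int = 999, alpha: float = 0.05,
            seed: int | None = None) -> SimprofResult:
    """Similarity-profile tests down a Sørensen/UPGMA dendrogram.

    Starting at the root, each node's samples are tested for internal
    multivariate structure by within-OTU permutation; significant
    nodes are split and their children tested in turn, non-significant
    (or < 3-sample) nodes become final groups. Permutation counts and
    alpha are recorded in the result metadata since they are analysis
    choices, not data.
    """
    rng = np.random.default_rng(seed)
    D = sorensen_dissimilarity(P)
    dend = upgma(D)
    tree = hierarchy.to_tree(dend.linkage)
    labels = dend.labels
    M_full = P.values.astype(float)

    nodes: list[SimprofNode] = []
    groups: list[list[str]] = []

    def visit(node) -> None:
        leaf_ids = node.pre_order(lambda v: v.id)
        leaf_labels = [labels[i] for i in leaf_ids]
        if len(leaf_ids) < 3:
            nodes.append(
                SimprofNode(node.id, len(leaf_ids), None, None,
                            significant=False, tested=False)
            )
            groups.append(leaf_labels)
            return
        M = M_full[leaf_ids]
        pi, p = _simprof_pi(M, n_profile_perms, n_test_perms, rng)
        sig = p <= alpha
        nodes.append(
            SimprofNode(node.id, len(leaf_ids), pi, p,
                        significant=sig, tested=True)
        )
        if sig:
            visit(node.left)
            visit(node.right)
        else:
            groups.append(leaf_labels)

    visit(tree)
    return SimprofResult(
        nodes=nodes,
        groups=groups,
        alpha=alpha,
        n_profile_perms=n_profile_perms,
        n_test_perms=n_test_perms,
        meta={"note": "permutation counts and alpha are defaults, "
                      "not observed quantities"},
    )


@dataclass
class NmdsResult:
    coords: pd.DataFrame
    stress: float
    n_restarts: int
    converged: bool
    stress_trace: list[float] = field(default_factory=list)


def _pcoa_init(d_sq: np.ndarray, dims: int) -> np.ndarray:
    """Classical-scaling (PCoA) starting configuration."""
    n = d_sq.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    Bm = -0.5 * J @ (d_sq ** 2) @ J
    w, v = np.linalg.eigh(Bm)
    order = np.argsort(w)[::-1][:dims]
    wpos = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(wpos)


def nmds(D: DistanceMatrix, dims: int = 2, restarts: int = 4,
         max_iter: int = 300, tol: float = 1e-7,
         seed: int | None = None) -> NmdsResult:
    """Non-metric MDS minimising Kruskal stress-1.

    Alternates isotonic (monotone) regression of configuration
    distances on the ranked dissimilarities with a Guttman-transform
    configuration update. Restart 0 starts from the classical-scaling
    solution, later restarts from random configurations; the best
    final stress wins. An iteration that would increase stress-1
    terminates its restart, so the stress trace is non-increasing by
    construction.
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    rng = np.random.default_rng(seed)
    d = D.condensed_form()
    n = len(D.ids)
    if n == 2:
        half = d[0] / 2.0
        coords = pd.DataFrame(
            np.array([[-half] + [0.0] * (dims - 1),
                      [half] + [0.0] * (dims - 1)]),
            index=list(D.ids),
            columns=[f"nmds{k + 1}" for k in range(dims)],
        )
        return NmdsResult(coords, 0.0, 1, True, [0.0])
    iu = np.triu_indices(n, k=1)
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")

    best = None
    for r in range(max(1, restarts)):
        if r == 0:
            X = _pcoa_init(squareform(d), dims)
        else:
            X = rng.normal(0.0, 1.0, (n, dims))
        trace: list[float] = []
        converged = False
        for _ in range(max_iter):
            diff = X[:, None, :] - X[None, :, :]
            dist_mat = np.sqrt((diff ** 2).sum(-1))
            dist = dist_mat[iu]
            dhat = iso.fit(d, dist).predict(d)
            denom = (dist ** 2).sum()
            stress = np.sqrt(((dist - dhat) ** 2).sum() / denom)
            if trace and stress > trace[-1] + 1e-12:
                break  # keep the previous (better) configuration
            if trace and trace[-1] - stress < tol:
                trace.append(stress)
                converged = True
                X_prev = X
                break
            trace.append(stress)
            X_prev = X
            # Guttman transform with disparities dhat
            W = np.zeros((n, n))
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist > 0, dhat / dist, 0.0)
            W[iu] = ratio
            W = W + W.T
            Bmat = -W
            np.fill_diagonal(Bmat, W.sum(axis=1))
            X = Bmat @ X / n
            X -= X.mean(axis=0)
        final_stress = trace[-1] if trace else np.inf
        if best is None or final_stress < best[0]:
            best = (final_stress, X_prev - X_prev.mean(axis=0),
                    converged, trace)

    stress, X, converged, trace = best
    coords = pd.DataFrame(
        X, index=list(D.ids),
        columns=[f"nmds{k + 1}" for k in range(dims)],
    )
    return NmdsResult(coords, float(stress), max(1, restarts),
                      converged, trace)


def richness_by_group(table: OtuTable, rank: str = "phylum",
                      ) -> pd.DataFrame:
    """Per-sample OTU richness per taxonomic group.

    Counts OTUs with >= 1 read in the sample, grouped by the given
    rank (phylum or family).
    """
    if rank not in ("phylum", "family"):
        raise ValueError("rank must be 'phylum' or 'family'")
    present = (table.counts > 0).astype(int)
    grouped = present.groupby(table.taxonomy[rank]).sum()
    return grouped.T  # samples × groups


def station_richness(table: OtuTable, rank: str = "phylum",
                     ) -> pd.DataFrame:
    """Station-level richness: OTUs present in any replicate core."""
    present = (table.counts > 0).astype(int)
    station = table.samples["station"]
    by_station = present.T.groupby(station).max().T
    grouped = by_station.groupby(table.taxonomy[rank]).sum()
    return grouped.T


@dataclass
class TTestResult:
    levene_p: float
    t: float
    df: float
    p: float
    pooled: bool


def welch_levene_ttest(x, y, alpha_levene: float = 0.05) -> TTestResult:
    """Two-sample t-test gated by Levene's variance test.

    Levene's statistic (absolute deviations from group means) decides
    between the pooled-variance t-test (equal variances not rejected)
    and Welch's test. Returns t, degrees of freedom and the two-sided
    p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    lev_stat, lev_p = stats.levene(x, y, center="mean")
    equal_var = lev_p >= alpha_levene
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    if equal_var:
        df = x.size + y.size - 2
    else:
        df = float(res.df)
    return TTestResult(
        levene_p=float(lev_p),
        t=float(res.statistic),
        df=float(df),
        p=float(res.pvalue),
        pooled=bool(equal_var),
    )
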