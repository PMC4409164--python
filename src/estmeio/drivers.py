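"""Driver inference linking community structure to the environment.

* **BIOENV** — exhaustive search over subsets of the (z-scored)
  environmental variables for the subset whose Euclidean inter-station
  distances best Spearman-rank-correlate with the biotic Sørensen
  dissimilarities; the ten best subsets are reported.
* **Mantel** — permutation test of the same matrix rank correlation.
* **CCA** — canonical correspondence analysis: the chi-square
  standardised community table is regressed (row-weighted) on the
  explanatory variables and the fitted table eigen-decomposed; a 0.7
  pairwise-correlation filter and a stepwise AIC search select the
  model.
* **PLS-VIP** — univariate partial least squares (NIPALS deflation)
  of a richness response on the standardised drivers, ranked by the
  variable-importance-in-projection score with the VIP > 1 pertinence
  rule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

__all__ = [
    "normalize_env",
    "spearman_matrix_corr",
    "bioenv",
    "BioenvResult",
    "mantel",
    "MantelResult",
    "filter_collinear",
    "cca",
    "cca_stepwise_aic",
    "CcaResult",
    "pls_vip",
    "PlsVipResult",
]


class DriverError(ValueError):
    pass


def normalize_env(E: pd.DataFrame,
                  subset: list[str] | None = None) -> pd.DataFrame:
    """Column z-scores (mean 0, sd 1, ddof=1) of the chosen variables."""
    cols = list(E.columns) if subset is None else list(subset)
    sub = E[cols]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise DriverError(f"missing values in variables: {bad}")
    sd = sub.std(ddof=1)
    const = sd[sd == 0].index.tolist()
    if const:
        raise DriverError(f"constant variables cannot be scaled: {const}")
    return (sub - sub.mean()) / sd


def _check_matching(D1: DistanceMatrix, D2: DistanceMatrix) -> None:
    if list(D1.ids) != list(D2.ids):
        raise DriverError("distance matrices have mismatched labels")


def spearman_matrix_corr(D_bio: DistanceMatrix,
                         D_env: DistanceMatrix) -> float:
    """Spearman rank correlation of the lower-triangle entries."""
    _check_matching(D_bio, D_env)
    rho, _ = stats.spearmanr(D_bio.condensed_form(),
                             D_env.condensed_form())
    return float(rho)


@dataclass
class BioenvResult:
    """Ranked variable subsets, shaped like the published tables
    (No. of variables, Correlation, Environmental variables)."""

    table: pd.DataFrame
    n_subsets_evaluated: int
    max_subset_size: int
    top_k: int

    @property
    def best_subset(self) -> tuple[str, ...]:
        return tuple(self.table.iloc[0]["variables"])

    @property
    def best_rho(self) -> float:
        return float(self.table.iloc[0]["correlation"])


def bioenv(D_bio: DistanceMatrix, E: pd.DataFrame,
           max_subset_size: int | None = None, top_k: int = 10,
           allow_large: bool = False) -> BioenvResult:
    """Exhaustive BIOENV subset search.

    Every non-empty subset of the environmental variables up to
    ``max_subset_size`` is standardised, turned into Euclidean
    inter-station distances and Spearman-correlated against the biotic
    dissimilarities; the ``top_k`` best subsets are returned in
    descending rho order.
    """
    ids = list(D_bio.ids)
    missing = [s for s in ids if s not in E.index]
    if missing:
        raise DriverError(f"stations absent from env matrix: {missing}")
    E = E.loc[ids]
    p = E.shape[1]
    size_cap = p if max_subset_size is None else min(max_subset_size, p)
    if p > 20 and size_cap > 6 and not allow_large:
        raise DriverError(
            f"{p} variables with subset size {size_cap} is a "
            "combinatorial explosion; pass allow_large=True to force"
        )
    Z = normalize_env(E).values
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    # squared pairwise differences per variable, shape (p, npairs)
    sq = np.stack(
        [((Z[:, j][:, None] - Z[:, j][None, :]) ** 2)[iu]
         for j in range(p)]
    )
    bio_rank = stats.rankdata(D_bio.condensed_form())
    bio_rank = bio_rank - bio_rank.mean()
    bio_norm = np.sqrt((bio_rank ** 2).sum())

    cols = list(E.columns)
    results = []
    count = 0
    for k in range(1, size_cap + 1):
        for combo in itertools.combinations(range(p), k):
            count += 1
            d_env = np.sqrt(sq[list(combo)].sum(axis=0))
            er = stats.rankdata(d_env)
            er = er - er.mean()
            denom = bio_norm * np.sqrt((er ** 2).sum())
            rho = float((bio_rank * er).sum() / denom) if denom else 0.0
            results.append((k, rho, tuple(cols[i] for i in combo)))
    results.sort(key=lambda r: (-r[1], r[0], r[2]))
    table = pd.DataFrame(
        results[:top_k],
        columns=["n_variables", "correlation", "variables"],
    )
    return BioenvResult(
        table=table,
        n_subsets_evaluated=count,
        max_subset_size=size_cap,
        top_k=top_k,
    )


@dataclass
class MantelResult:
    rho: float
    p_value: float
    n_perm: int
    alternative: str
    seed: int | None


def mantel(D1: DistanceMatrix, D2: DistanceMatrix, n_perm: int = 999,
           seed: int | None = None,
           alternative: str = "two-sided") -> MantelResult:
    """Mantel permutation test of matrix association.

    The null permutes the rows and columns of ``D2`` simultaneously;
    p = (b+1)/(m+1) where b counts permuted statistics at least as
    extreme as the observed (two-sided on \\|rho\\| by default).
    """
    _check_matching(D1, D2)
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    rng = np.random.default_rng(seed)
    rho_obs = spearman_matrix_corr(D1, D2)
    n = len(D1.ids)
    iu = np.triu_indices(n, k=1)
    d1 = stats.rankdata(D1.condensed_form())
    d1 = d1 - d1.mean()
    d1_norm = np.sqrt((d1 ** 2).sum())
    M2 = D2.data
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        d2 = M2[np.ix_(perm, perm)][iu]
        r2 = stats.rankdata(d2)
        r2 = r2 - r2.mean()
        rho_p = (d1 * r2).sum() / (d1_norm * np.sqrt((r2 ** 2).sum()))
        if alternative == "two-sided":
            hit = abs(rho_p) >= abs(rho_obs) - 1e-12
        elif alternative == "greater":
            hit = rho_p >= rho_obs - 1e-12
        else:
            hit = rho_p <= rho_obs + 1e-12
        exceed += bool(hit)
    p = (exceed + 1) / (n_perm + 1)
    return MantelResult(rho=rho_obs, p_value=float(p), n_perm=n_perm,
                        alternative=alternative, seed=seed)


def filter_collinear(E: pd.DataFrame, threshold: float = 0.7,
                     prefer: list[str] | None = None,
                     ) -> tuple[pd.DataFrame, list[dict]]:
    """Drop variables until all pairwise \\|r\\| <= threshold.

    Greedy: while any pair exceeds the threshold, remove from the
    worst pair the variable with the higher mean absolute correlation
    to everything else (keeping the more "independent" one). The
    retention priority is configurable: variables in ``prefer`` are
    kept over non-preferred partners regardless of mean correlation.
    Returns the reduced matrix and a removal log.
    """
    if E.shape[1] < 2:
        raise DriverError("need at least 2 variables")
    prefer = set(prefer or [])
    kept = list(E.columns)
    log: list[dict] = []
    while True:
        corr = E[kept].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        worst_r = corr.loc[worst]
        if worst_r <= threshold or len(kept) == 1:
            break
        a, b = worst
        if (a in prefer) != (b in prefer):
            drop = b if a in prefer else a
        else:
            mean_r = corr.mean()
            drop = a if mean_r[a] >= mean_r[b] else b
        kept.remove(drop)
        log.append(
            {"removed": drop, "pair": (a, b),
             "abs_r": float(worst_r)}
        )
    return E[kept], log


@dataclass
class CcaResult:
    eigenvalues: np.ndarray
    total_inertia: float
    constrained_inertia: float
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    variables: list[str]
    variable_p: dict[str, float] | None = None
    aic: float | None = None

    @property
    def proportion_constrained(self) -> float:
        return self.constrained_inertia / self.total_inertia

    @property
    def first_two_axes_fraction(self) -> float:
        """Share of the constrained inertia on the first two axes."""
        ev = self.eigenvalues
        if ev.size == 0 or ev.sum() == 0:
            return 0.0
        return float(ev[: 2].sum() / ev.sum())


def _chi_square_standardise(Y: np.ndarray,
                            ) -> tuple[np.ndarray, np.ndarray, float]:
    total = Y.sum()
    if total <= 0:
        raise DriverError("community table has zero grand total")
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r <= 0).any() or (c <= 0).any():
        raise DriverError("community table has empty rows or columns")
    expected = np.outer(r, c)
    Qbar = (P - expected) / np.sqrt(expected)
    return Qbar, r, float((Qbar ** 2).sum())


def _weighted_design(E: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Row-weight-centred, weight-standardised design, sqrt-weighted."""
    mean_w = (r[:, None] * E).sum(axis=0)
    Ec = E - mean_w
    var_w = (r[:, None] * Ec ** 2).sum(axis=0)
    if (var_w <= 1e-14).any():
        raise DriverError("constant explanatory variable in CCA design")
    Ec = Ec / np.sqrt(var_w)
    return np.sqrt(r)[:, None] * Ec


def cca(Y: pd.DataFrame, E: pd.DataFrame) -> CcaResult:
    """Canonical correspondence analysis.

    ``Y`` is a non-negative station × taxon table with positive row
    and column sums; ``E`` the explanatory variables at the same
    stations. Total inertia equals the Pearson chi-square statistic of
    ``Y`` divided by its grand total; the constrained inertia is the
    inertia of the row-weighted regression of the chi-square
    standardised table on ``E``.
    """
    if list(Y.index) != list(E.index):
        if set(Y.index) != set(E.index):
            raise DriverError("station labels of Y and E differ")
        E = E.loc[Y.index]
    Yv = Y.values.astype(float)
    if (Yv < 0).any():
        raise DriverError("community table must be non-negative")
    Qbar, r, total_inertia = _chi_square_standardise(Yv)
    Xw = _weighted_design(E.values.astype(float), r)
    if np.linalg.matrix_rank(Xw) < Xw.shape[1]:
        dep = [
            E.columns[j] for j in range(1, Xw.shape[1])
            if np.linalg.matrix_rank(Xw[:, : j + 1])
            == np.linalg.matrix_rank(Xw[:, :j])
        ]
        raise DriverError(f"rank-deficient design; dependent: {dep}")
    coef, *_ = np.linalg.lstsq(Xw, Qbar, rcond=None)
    fitted = Xw @ coef
    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    eig = s ** 2
    keep = eig > max(eig[0] if eig.size else 0.0, 1.0) * 1e-12
    eig = eig[keep]
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    naxes = min(2, eig.size)
    # weighted site scores (linear-combination scores) and species scores
    with np.errstate(divide="ignore", invalid="ignore"):
        site = (U[:, :naxes] * s[:naxes]) / np.sqrt(r)[:, None]
    ctot = Yv.sum(axis=0) / Yv.sum()
    species = Vt[:naxes].T / np.sqrt(ctot)[:, None]
    # biplot scores: weighted correlation of variables with site axes
    biplot = np.corrcoef(
        np.hstack([Xw, U[:, :naxes]]), rowvar=False
    )[: Xw.shape[1], Xw.shape[1]:]
    axes = [f"CCA{k + 1}" for k in range(naxes)]
    return CcaResult(
        eigenvalues=eig,
        total_inertia=total_inertia,
        constrained_inertia=float(eig.sum()),
        site_scores=pd.DataFrame(site, index=Y.index, columns=axes),
        species_scores=pd.DataFrame(species, index=Y.columns,
                                    columns=axes),
        biplot_scores=pd.DataFrame(biplot, index=E.columns,
                                   columns=axes),
        variables=list(E.columns),
    )


def _constrained_inertia(Qbar: np.ndarray, Xw: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(Xw, Qbar, rcond=None)
    return float(((Xw @ coef) ** 2).sum())


def _cca_aic(n: int, resid_inertia: float, k: int) -> float:
    """Deviance-style AIC on residual inertia (ecological heuristic)."""
    resid = max(resid_inertia, 1e-12)
    return n * np.log(resid / n) + 2.0 * k


def cca_stepwise_aic(Y: pd.DataFrame, E: pd.DataFrame,
                     n_perm: int = 999,
                     seed: int | None = None) -> CcaResult:
    """Forward-backward AIC selection over the explanatory variables.

    Starts from the intercept-only (unconstrained) model; at each step
    the single add or drop that most lowers the AIC
    ``n log(residual inertia / n) + 2k`` is taken. Per-variable
    significance on the final model is a marginal pseudo-F test with
    permutation of the reduced-model residuals.
    """
    if list(Y.index) != list(E.index):
        E = E.loc[Y.index]
    Yv = Y.values.astype(float)
    Qbar, r, total = _chi_square_standardise(Yv)
    n = Yv.shape[0]
    candidates = list(E.columns)
    selected: list[str] = []
    current_aic = _cca_aic(n, total, 0)

    def inertia_of(cols: list[str]) -> float:
        if not cols:
            return 0.0
        Xw = _weighted_design(E[cols].values.astype(float), r)
        return _constrained_inertia(Qbar, Xw)

    improved = True
    while improved:
        improved = False
        moves = []
        for v in candidates:
            if v in selected:
                trial = [c for c in selected if c != v]
            else:
                trial = selected + [v]
            try:
                ci = inertia_of(trial)
            except DriverError:
                continue
            moves.append((_cca_aic(n, total - ci, len(trial)), trial))
        if moves:
            best_aic, best_set = min(moves, key=lambda m: m[0])
            if best_aic < current_aic - 1e-9:
                current_aic, selected = best_aic, best_set
                improved = True

    if not selected:
        empty = pd.DataFrame(index=Y.index)
        return CcaResult(
            eigenvalues=np.array([]),
            total_inertia=total,
            constrained_inertia=0.0,
            site_scores=pd.DataFrame(index=Y.index),
            species_scores=pd.DataFrame(index=Y.columns),
            biplot_scores=pd.DataFrame(),
            variables=[],
            variable_p={},
            aic=current_aic,
        )

    result = cca(Y, E[selected])
    result.aic = current_aic

    # marginal permutation tests: permute reduced-model residuals
    rng = np.random.default_rng(seed)
    pvals: dict[str, float] = {}
    full_inertia = inertia_of(selected)
    for v in selected:
        reduced = [c for c in selected if c != v]
        Xw_full = _weighted_design(E[selected].values.astype(float), r)
        gain_obs = full_inertia - inertia_of(reduced)
        if reduced:
            Xw_red = _weighted_design(E[reduced].values.astype(float), r)
            coef_r, *_ = np.linalg.lstsq(Xw_red, Qbar, rcond=None)
            fit_red = Xw_red @ coef_r
        else:
            fit_red = np.zeros_like(Qbar)
        resid_red = Qbar - fit_red
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Qnull = fit_red + resid_red[perm]
            gain = (
                _constrained_inertia(Qnull, Xw_full)
                - _constrained_inertia(Qnull, Xw_red)
                if reduced
                else _constrained_inertia(Qnull, Xw_full)
            )
            exceed += gain >= gain_obs - 1e-12
        pvals[v] = (exceed + 1) / (n_perm + 1)
    result.variable_p = pvals
    return result


@dataclass
class PlsVipResult:
    """Per-predictor VIP table plus per-component explained variance."""

    table: pd.DataFrame            # vip1, vip, sign, pertinent, r2_uni
    r2_components: np.ndarray      # R² of y per component
    n_components: int
    weights: np.ndarray            # component × predictor (normalised)

    @property
    def pertinent(self) -> list[str]:
        return self.table.index[self.table["pertinent"]].tolist()


def _vip_scores(W: np.ndarray, ss: np.ndarray, A: int) -> np.ndarray:
    """VIP over the first A components.

    VIP_j = sqrt(p * sum_a ss_a * w_aj^2 / sum_a ss_a); the weight
    vectors are unit-norm so the mean squared VIP is exactly 1.
    """
    p = W.shape[1]
    ssA = ss[:A]
    contrib = (ssA[:, None] * W[:A] ** 2).sum(axis=0)
    return np.sqrt(p * contrib / ssA.sum())


def pls_vip(X: pd.DataFrame, y: pd.Series, n_components: int = 2,
            n_perm: int | None = 999,
            seed: int | None = None) -> PlsVipResult:
    """PLS1 regression with VIP ranking.

    X and y are z-scored; components are extracted by NIPALS
    deflation. The table reports the first-latent-variable VIP
    (``vip1``), the cumulative VIP over all components (``vip``), the
    association sign (sign of the first-component regression
    coefficient), the VIP > 1 pertinence flag (on ``vip1``), the
    univariate R² of each predictor against the response and, when
    ``n_perm`` is set, a permutation p-value for that univariate
    association (the basis for significance stars).
    """
    if y.std(ddof=1) == 0:
        raise DriverError("response has zero variance")
    cols = list(X.columns)
    p = len(cols)
    n_components = min(n_components, p, len(y) - 1)
    Z = normalize_env(X).values
    yv = ((y - y.mean()) / y.std(ddof=1)).values.astype(float)
    ss_y_total = float((yv ** 2).sum())

    Xc = Z.copy()
    yc = yv.copy()
    W = np.zeros((n_components, p))
    ss = np.zeros(n_components)
    q_first = 0.0
    for a in range(n_components):
        w = Xc.T @ yc
        norm = np.linalg.norm(w)
        if norm == 0:
            W = W[:a]
            ss = ss[:a]
            n_components = a
            break
        w /= norm
        t = Xc @ w
        tt = float(t @ t)
        p_load = Xc.T @ t / tt
        q = float(yc @ t / tt)
        if a == 0:
            q_first = q
            w_first = w.copy()
        ss[a] = q ** 2 * tt               # y-variance captured
        Xc = Xc - np.outer(t, p_load)
        yc = yc - q * t
        W[a] = w
    if n_components == 0:
        raise DriverError("response is orthogonal to all predictors")

    r2_components = ss / ss_y_total
    vip1 = _vip_scores(W, ss, 1)
    vip_all = _vip_scores(W, ss, n_components)
    signs = np.sign(w_first * q_first)

    r2_uni = np.array(
        [stats.pearsonr(Z[:, j], yv)[0] ** 2 for j in range(p)]
    )
    p_perm = np.full(p, np.nan)
    if n_perm:
        rng = np.random.default_rng(seed)
        r_obs = np.abs(
            np.array([stats.pearsonr(Z[:, j], yv)[0] for j in range(p)])
        )
        exceed = np.zeros(p)
        for _ in range(n_perm):
            yp = rng.permutation(yv)
            r_p = np.abs(Z.T @ yp) / (
                np.linalg.norm(yp) * np.sqrt((Z ** 2).sum(axis=0))
            )
            exceed += r_p >= r_obs - 1e-12
        p_perm = (exceed + 1) / (n_perm + 1)

    table = pd.DataFrame(
        {
            "vip1": vip1,
            "vip": vip_all,
            "sign": signs,
            "pertinent": vip1 > 1.0,
            "r2_uni": r2_uni,
            "p_perm": p_perm,
        },
        index=pd.Index(cols, name="predictor"),
    )
    return PlsVipResult(
        table=table,
        r2_components=r2_components,
        n_components=n_components,
        weights=W,
    )
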