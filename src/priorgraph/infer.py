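"""Network inference engines.

Four engines reconstruct an undirected network over locus-set nodes from a
samples x nodes data matrix:

* :class:`PriorGraphicalLasso` — L1-penalised precision estimation with a
  per-edge penalty matrix ``Lambda = (1 - P) * omega`` encoding edge priors,
  the global weight omega selected by k-fold cross-validated test BIC;
* :class:`ShrinkagePartialCorrelation` — analytic-shrinkage partial
  correlations with edge-wise local-FDR screening;
* :class:`BayesianStructureMCMC` — Metropolis search over graph structures
  with Bernoulli edge priors and a BIC marginal-likelihood approximation;
* :class:`TreeEnsembleNetwork` — tree-ensemble regulatory link ranking with a
  scale-free-topology cutoff.

All engines operate on rank-gaussianised data (a Gaussian-copula surrogate for
mixed dosage/continuous columns) and are deterministic given (data, prior,
seed). Module-level functions are thin wrappers over the estimators.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor

from ._glasso import duality_gap, glasso_kernel
from ._mcmc import mcmc_kernel
from .network import PriorMatrix, UndirectedNetwork
from .priors import estimate_lfdr
from .simulate import OmicsDataset

logger = logging.getLogger(__name__)

#: Default global-weight grid for the penalised engine: {0.01, 0.015, ..., 1}.
DEFAULT_OMEGA_GRID = tuple(np.round(np.arange(0.01, 1.0001, 0.005), 6))


# ---------------------------------------------------------------------------
# Gaussianisation
# ---------------------------------------------------------------------------

def gaussianize(data: OmicsDataset) -> OmicsDataset:
    """Per-column rank-based inverse-normal transform (copula surrogate).

    Ranks use averages for ties and the offset quantile ``(r - 0.5) / n``;
    dosage columns are transformed the same way. Constant columns raise.
    """
    x = data.values.to_numpy(dtype=float)
    n = x.shape[0]
    out = np.empty_like(x)
    for k, col in enumerate(data.values.columns):
        if np.nanstd(x[:, k]) == 0:
            raise ValueError(f"constant column {col!r} cannot be gaussianised")
        r = stats.rankdata(x[:, k], method="average")
        out[:, k] = stats.norm.ppf((r - 0.5) / n)
    df = pd.DataFrame(out, index=data.values.index, columns=data.values.columns)
    return OmicsDataset(df, {c: "continuous" for c in df.columns})


def _as_dataset(data) -> OmicsDataset:
    if isinstance(data, OmicsDataset):
        return data
    if isinstance(data, pd.DataFrame):
        return OmicsDataset(data)
    arr = np.asarray(data, dtype=float)
    cols = [f"x{i}" for i in range(arr.shape[1])]
    return OmicsDataset(pd.DataFrame(arr, columns=cols))


def _correlation(x: np.ndarray) -> np.ndarray:
    c = np.corrcoef(x, rowvar=False)
    return np.atleast_2d(c)


# ---------------------------------------------------------------------------
# Penalised maximum likelihood (graphical lasso with per-edge penalties)
# ---------------------------------------------------------------------------

def penalized_mle(
    S: np.ndarray,
    Lambda: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 200,
    inner_max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge-penalty graphical lasso on a covariance/correlation matrix.

    Returns ``(Theta, adjacency)`` with adjacency the nonzero off-diagonal
    pattern (|Theta_ij| > 1e-8). Raises on non-convergence with the
    primal-dual gap in the message.
    """
    S = np.asarray(S, dtype=float)
    L = np.asarray(Lambda, dtype=float)
    if S.shape != L.shape or S.shape[0] != S.shape[1]:
        raise ValueError("S and Lambda must be square and of equal shape")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    if np.any(L < 0):
        raise ValueError("penalties must be nonnegative")
    L = L.copy()
    np.fill_diagonal(L, 0.0)
    Theta, W, n_sweeps, converged = glasso_kernel(
        S, L, tol, max_iter, inner_max_iter
    )
    if not converged:
        gap = duality_gap(S, L, Theta)
        raise RuntimeError(
            f"graphical lasso did not converge in {max_iter} sweeps "
            f"(duality gap {gap:.3e})"
        )
    adj = np.abs(Theta) > 1e-8
    np.fill_diagonal(adj, False)
    return Theta, adj


def penalty_matrix(P: PriorMatrix | None, omega: float, p: int) -> np.ndarray:
    """``Lambda = (1 - P) * omega`` with priors, constant omega without."""
    if P is None:
        L = np.full((p, p), omega)
    else:
        L = (1.0 - P.values) * omega
    np.fill_diagonal(L, 0.0)
    return L


def _test_bic(Theta: np.ndarray, S_test: np.ndarray, n_test: int) -> float:
    sign, logdet = np.linalg.slogdet(Theta)
    if sign <= 0:
        return np.inf
    ll = 0.5 * n_test * (logdet - np.sum(S_test * Theta))
    n_edges = int((np.abs(np.triu(Theta, 1)) > 1e-8).sum())
    return -2.0 * ll + n_edges * np.log(n_test)


class PriorGraphicalLasso(BaseEstimator):
    """Graphical lasso with per-edge prior penalties and CV/BIC selection.

    For each global weight omega in ``omega_grid`` the model is fitted on each
    of ``cv`` training folds with ``Lambda = (1 - P) * omega`` (constant omega
    without priors) and scored by test-fold BIC; the omega with minimal mean
    test BIC is refitted on the full data.

    Parameters
    ----------
    prior : PriorMatrix or None
        Per-edge prior probabilities aligned with the data columns.
    omega_grid : sequence of float
    cv : int, number of folds (default 5)
    tol, max_iter : graphical-lasso convergence controls
    random_state : seed for the fold shuffle

    Attributes
    ----------
    network_ : UndirectedNetwork — selected adjacency
    precision_ : ndarray — refitted precision at the selected omega
    omega_ : float — selected global weight
    bic_path_ : ndarray — mean test BIC per grid point
    """

    def __init__(self, prior: PriorMatrix | None = None,
                 omega_grid=DEFAULT_OMEGA_GRID, cv: int = 5,
                 tol: float = 1e-6, max_iter: int = 200,
                 random_state: int | None = None):
        self.prior = prior
        self.omega_grid = omega_grid
        self.cv = cv
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        data = gaussianize(_as_dataset(X))
        x = data.values.to_numpy(dtype=float)
        n, p = x.shape
        if n < 2 * self.cv:
            raise ValueError(f"need at least {2 * self.cv} samples for {self.cv}-fold CV")
        nodes = list(data.values.columns)
        if self.prior is not None and tuple(self.prior.nodes) != tuple(nodes):
            raise ValueError("prior node order does not match data columns")
        rng = np.random.default_rng(self.random_state)
        perm = rng.permutation(n)
        folds = np.array_split(perm, self.cv)
        grid = np.asarray(sorted(self.omega_grid), dtype=float)

        fold_S: list[tuple[np.ndarray, np.ndarray, int]] = []
        for f in folds:
            test_mask = np.zeros(n, dtype=bool)
            test_mask[f] = True
            S_tr = _correlation(x[~test_mask])
            S_te = _correlation(x[test_mask])
            fold_S.append((S_tr, S_te, int(test_mask.sum())))

        mean_bic = np.empty(len(grid))
        for gi, omega in enumerate(grid):
            L = penalty_matrix(self.prior, omega, p)
            bics = []
            for S_tr, S_te, n_te in fold_S:
                try:
                    Theta, _ = penalized_mle(S_tr, L, tol=self.tol,
                                             max_iter=self.max_iter)
                    bics.append(_test_bic(Theta, S_te, n_te))
                except RuntimeError:
                    bics.append(np.inf)
            mean_bic[gi] = np.mean(bics)
        best = int(np.argmin(mean_bic))
        self.omega_ = float(grid[best])
        self.bic_path_ = mean_bic
        S_full = _correlation(x)
        L = penalty_matrix(self.prior, self.omega_, p)
        self.precision_, adj = penalized_mle(S_full, L, tol=self.tol,
                                             max_iter=self.max_iter)
        self.network_ = UndirectedNetwork.from_adjacency(adj, nodes)
        if self.network_.n_edges == 0:
            warnings.warn("selected network is empty across the omega grid")
        self.n_features_in_ = p
        return self

    def get_network(self) -> UndirectedNetwork:
        return self.network_


def penalized_cv(data, P: PriorMatrix | None = None,
                 omega_grid=DEFAULT_OMEGA_GRID, k: int = 5,
                 rng: np.random.Generator | int | None = None) -> UndirectedNetwork:
    """Functional wrapper over :class:`PriorGraphicalLasso`."""
    seed = rng if isinstance(rng, (int, np.integer)) or rng is None else \
        int(rng.integers(2**31))
    est = PriorGraphicalLasso(prior=P, omega_grid=omega_grid, cv=k,
                              random_state=seed)
    est.fit(data)
    return est.network_


# ---------------------------------------------------------------------------
# Shrinkage partial correlations
# ---------------------------------------------------------------------------

def shrinkage_correlation(x: np.ndarray) -> tuple[np.ndarray, float]:
    """Analytic-shrinkage correlation estimate toward the identity.

    Closed-form intensity ``lambda* = sum Var(r_ij) / sum r_ij^2`` clamped to
    [0, 1] (Ledoit-Wolf style for the correlation matrix).
    """
    n, p = x.shape
    xc = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    r = (xc.T @ xc) / (n - 1)
    np.fill_diagonal(r, 1.0)
    # Var(r_ij) from the empirical variance of the products w_kij
    w_mean = r * (n - 1) / n
    var_sum = 0.0
    r2_sum = 0.0
    for i in range(p):
        wi = xc[:, i]
        for j in range(i + 1, p):
            w = wi * xc[:, j]
            v = n / ((n - 1) ** 3) * np.sum((w - w_mean[i, j]) ** 2)
            var_sum += v
            r2_sum += r[i, j] ** 2
    lam = 1.0 if r2_sum == 0 else min(1.0, max(0.0, var_sum / r2_sum))
    r_shrunk = (1.0 - lam) * r
    np.fill_diagonal(r_shrunk, 1.0)
    return r_shrunk, lam


def partial_correlations(corr: np.ndarray) -> np.ndarray:
    theta = np.linalg.inv(corr)
    d = np.sqrt(np.diag(theta))
    pcor = -theta / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor


class ShrinkagePartialCorrelation(BaseEstimator):
    """Shrinkage partial-correlation network with local-FDR edge screening.

    Edges are kept when the lfdr of the partial-correlation null p-value is at
    most ``lfdr_cut`` (0.2, i.e. posterior edge probability >= 0.8).

    Attributes: ``network_``, ``pcor_``, ``lfdr_``, ``shrinkage_``.
    """

    def __init__(self, lfdr_cut: float = 0.2, min_pvalues: int = 30):
        self.lfdr_cut = lfdr_cut
        self.min_pvalues = min_pvalues

    def fit(self, X, y=None):
        data = _as_dataset(X)
        df = data.values.dropna(axis=1)
        if df.shape[1] < 3:
            raise ValueError("need at least 3 complete columns")
        data = gaussianize(OmicsDataset(df))
        x = data.values.to_numpy(dtype=float)
        n, p = x.shape
        if n < 3:
            raise ValueError("need at least 3 samples")
        nodes = list(df.columns)
        r_shrunk, lam = shrinkage_correlation(x)
        pcor = partial_correlations(r_shrunk)
        iu = np.triu_indices(p, 1)
        vals = np.clip(pcor[iu], -0.999999, 0.999999)
        kappa = max(n - (p - 2) - 3, 1)
        z = np.arctanh(vals) * np.sqrt(kappa)
        pvals = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
        est = estimate_lfdr(pvals, min_pvalues=min(self.min_pvalues, len(pvals)))
        adj = np.zeros((p, p), dtype=bool)
        keep = est.lfdr <= self.lfdr_cut
        adj[iu[0][keep], iu[1][keep]] = True
        adj |= adj.T
        self.pcor_ = pcor
        self.shrinkage_ = lam
        self.lfdr_ = est.lfdr
        self.network_ = UndirectedNetwork.from_adjacency(adj, nodes)
        self.n_features_in_ = p
        return self


def shrinkage_pcor_network(data) -> UndirectedNetwork:
    """Functional wrapper over :class:`ShrinkagePartialCorrelation`."""
    return ShrinkagePartialCorrelation().fit(data).network_


# ---------------------------------------------------------------------------
# Bayesian structure MCMC
# ---------------------------------------------------------------------------

@dataclass
class PosteriorEdgeProbs:
    nodes: tuple[str, ...]
    probs: np.ndarray  # symmetric p x p posterior inclusion probabilities
    acceptance_rate: float
    n_iter: int
    burnin: int
    n_pd_rejections: int = 0


class BayesianStructureMCMC(BaseEstimator):
    """Metropolis graph-structure search with Bernoulli edge priors.

    Single-edge toggle proposals are accepted with probability
    ``min(1, exp(-dBIC/2) * prior_odds)`` where the BIC uses the
    support-constrained Gaussian MLE (covariance selection via iterative
    proportional scaling) and the edge prior is Bernoulli(p_ij) (0.5
    everywhere when no prior is given). The chain starts from the incidence
    of priors > 0.5. Posterior inclusion probabilities are post-burn-in
    visit frequencies; the network keeps edges at probability >= ``cut``.

    Attributes: ``edge_probs_`` (PosteriorEdgeProbs), ``network_``.
    """

    def __init__(self, prior: PriorMatrix | None = None, n_iter: int = 10_000,
                 burnin: int = 5_000, cut: float = 0.9,
                 ips_tol: float = 1e-6, ips_max_sweeps: int = 50,
                 random_state: int | None = None):
        self.prior = prior
        self.n_iter = n_iter
        self.burnin = burnin
        self.cut = cut
        self.ips_tol = ips_tol
        self.ips_max_sweeps = ips_max_sweeps
        self.random_state = random_state

    def fit(self, X, y=None):
        data = gaussianize(_as_dataset(X))
        x = data.values.to_numpy(dtype=float)
        n, p = x.shape
        nodes = tuple(data.values.columns)
        if self.prior is not None and tuple(self.prior.nodes) != nodes:
            raise ValueError("prior node order does not match data columns")
        S = _correlation(x)
        if self.prior is None:
            prior = np.full((p, p), 0.5)
        else:
            prior = np.clip(self.prior.values, 1e-12, 1 - 1e-12)
        A0 = (prior > 0.5).astype(np.int8)
        np.fill_diagonal(A0, 0)
        seed = self.random_state if self.random_state is not None else 0
        counts, n_kept, n_accept, n_reject_pd, _ = mcmc_kernel(
            S, float(n), prior, int(self.n_iter), int(self.burnin),
            int(seed) % (2**31), self.ips_tol, int(self.ips_max_sweeps), A0,
        )
        probs = counts / max(n_kept, 1)
        probs = 0.5 * (probs + probs.T)
        np.fill_diagonal(probs, 0.0)
        self.edge_probs_ = PosteriorEdgeProbs(
            nodes=nodes, probs=probs,
            acceptance_rate=n_accept / max(self.n_iter, 1),
            n_iter=self.n_iter, burnin=self.burnin,
            n_pd_rejections=int(n_reject_pd),
        )
        self.network_ = select_posterior_network(self.edge_probs_, self.cut)
        self.n_features_in_ = p
        return self


def mcmc_structure_search(data, P: PriorMatrix | None = None,
                          iter: int = 10_000, burnin: int = 5_000,
                          rng: np.random.Generator | int | None = None
                          ) -> PosteriorEdgeProbs:
    """Functional wrapper over :class:`BayesianStructureMCMC`."""
    seed = rng if isinstance(rng, (int, np.integer)) or rng is None else \
        int(rng.integers(2**31))
    est = BayesianStructureMCMC(prior=P, n_iter=iter, burnin=burnin,
                                random_state=seed)
    est.fit(data)
    return est.edge_probs_


def select_posterior_network(probs: PosteriorEdgeProbs, cut: float = 0.9
                             ) -> UndirectedNetwork:
    """Edges with posterior inclusion probability >= cut."""
    adj = probs.probs >= cut
    np.fill_diagonal(adj, False)
    return UndirectedNetwork.from_adjacency(adj, probs.nodes)


# ---------------------------------------------------------------------------
# Tree-ensemble link ranking and scale-free cutoff
# ---------------------------------------------------------------------------

@dataclass
class RankedLinks:
    """Symmetrised regulatory links ordered by nonincreasing weight."""

    links: list[tuple[str, str, float]]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, _, w in self.links])


class TreeEnsembleNetwork(BaseEstimator):
    """Tree-ensemble regulatory link ranking (random-forest importances).

    Each column is regressed on all others; the link weight is the normalised
    feature importance, symmetrised by the maximum of the two directions.
    ``fit`` ranks the links; ``network_`` applies the scale-free cutoff.
    """

    def __init__(self, n_estimators: int = 100, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.random_state = random_state

    def fit(self, X, y=None):
        data = gaussianize(_as_dataset(X))
        x = data.values.to_numpy(dtype=float)
        n, p = x.shape
        if p < 3:
            raise ValueError("need at least 3 columns")
        nodes = list(data.values.columns)
        w = np.zeros((p, p))
        for t in range(p):
            others = [k for k in range(p) if k != t]
            rf = RandomForestRegressor(
                n_estimators=self.n_estimators, max_features="sqrt",
                random_state=(0 if self.random_state is None
                              else self.random_state + t) % (2**31),
            )
            rf.fit(x[:, others], x[:, t])
            w[others, t] = rf.feature_importances_
        sym = np.maximum(w, w.T)
        iu = np.triu_indices(p, 1)
        links = [(nodes[i], nodes[j], float(sym[i, j]))
                 for i, j in zip(*iu)]
        links.sort(key=lambda e: (-e[2], e[0], e[1]))
        self.links_ = RankedLinks(links)
        self.network_ = scale_free_cutoff(self.links_)
        self.n_features_in_ = p
        return self


def tree_ensemble_links(data, n_estimators: int = 100,
                        rng: np.random.Generator | int | None = None
                        ) -> RankedLinks:
    """Functional wrapper over :class:`TreeEnsembleNetwork`."""
    seed = rng if isinstance(rng, (int, np.integer)) or rng is None else \
        int(rng.integers(2**31))
    est = TreeEnsembleNetwork(n_estimators=n_estimators, random_state=seed)
    est.fit(data)
    return est.links_


def scale_free_fit_r2(degrees: np.ndarray, n_bins: int = 10) -> tuple[float, int]:
    """Scale-free topology fit: R^2 of log10 frequency vs log10 degree.

    Degrees are log-binned into ``n_bins`` bins; zero-frequency bins are
    dropped. Returns (R^2, number of usable bins); fewer than 3 usable bins
    yields (nan, n_usable) since a 2-point regression is always perfect.
    """
    deg = degrees[degrees > 0]
    if deg.size == 0:
        return np.nan, 0
    lo, hi = deg.min(), deg.max()
    if lo == hi:
        return np.nan, 1
    edges = np.logspace(np.log10(lo), np.log10(hi + 1e-9), n_bins + 1)
    counts, edges = np.histogram(deg, bins=edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    mask = counts > 0
    if mask.sum() < 3:
        return np.nan, int(mask.sum())
    lx = np.log10(centers[mask])
    ly = np.log10(counts[mask] / counts.sum())
    slope, intercept, r, _, _ = stats.linregress(lx, ly)
    return float(r**2), int(mask.sum())


def scale_free_cutoff(links: RankedLinks, n_quantiles: int = 200,
                      r2_threshold: float = 0.8) -> UndirectedNetwork:
    """Select the link-weight cutoff giving the most scale-free network.

    Candidate cutoffs are 200 weight quantiles (or all unique weights when
    fewer). Among candidates with fit R^2 above the threshold the one with the
    most edges wins, otherwise the highest-R^2 candidate; candidates with too
    few degree bins for a meaningful fit are used only as a last resort
    (largest candidate network).
    """
    if not links.links:
        return UndirectedNetwork(())
    nodes = sorted({n for a, b, _ in links.links for n in (a, b)})
    weights = links.weights
    uniq = np.unique(weights)
    if uniq.size > n_quantiles:
        cutoffs = np.unique(np.quantile(uniq, np.linspace(0, 1, n_quantiles)))
    else:
        cutoffs = uniq
    best_sf = None  # (edges, net) among R2 > threshold
    best_r2 = None  # (r2, edges, net) among measurable fits
    biggest = None
    for cut in cutoffs:
        kept = [(a, b) for a, b, w in links.links if w >= cut]
        if not kept:
            continue
        net = UndirectedNetwork(nodes, kept)
        deg = np.array(list(net.degree().values()))
        r2, nb = scale_free_fit_r2(deg)
        if biggest is None or net.n_edges > biggest.n_edges:
            biggest = net
        if np.isnan(r2):
            continue
        if r2 > r2_threshold and (best_sf is None or net.n_edges > best_sf[0]):
            best_sf = (net.n_edges, net)
        if best_r2 is None or r2 > best_r2[0]:
            best_r2 = (r2, net.n_edges, net)
    if best_sf is not None:
        return best_sf[1]
    if best_r2 is not None:
        return best_r2[2]
    if biggest is not None:
        return biggest
    return UndirectedNetwork(nodes)


# ---------------------------------------------------------------------------
# Benchmark method registry
# ---------------------------------------------------------------------------

def standard_method_registry(
    include=("glasso", "glasso_p", "mcmc", "mcmc_p"),
    omega_grid=DEFAULT_OMEGA_GRID,
    cv: int = 5,
    mcmc_iter: int = 10_000,
    mcmc_burnin: int = 5_000,
    posterior_cut: float = 0.9,
    n_estimators: int = 100,
):
    """Build the (name -> (callable, uses_prior)) mapping for run_benchmark.

    Names: ``glasso``/``glasso_p`` (penalised engine without/with priors),
    ``mcmc``/``mcmc_p`` (Bayesian engine), ``pcor`` (shrinkage partial
    correlations), ``trees`` (tree-ensemble ranking with scale-free cutoff).
    External engines can be added to the returned dict.
    """

    def _glasso(data, P, rng):
        return penalized_cv(data, P, omega_grid=omega_grid, k=cv, rng=rng)

    def _mcmc(data, P, rng):
        probs = mcmc_structure_search(data, P, iter=mcmc_iter,
                                      burnin=mcmc_burnin, rng=rng)
        return select_posterior_network(probs, posterior_cut)

    def _pcor(data, P, rng):
        return shrinkage_pcor_network(data)

    def _trees(data, P, rng):
        return scale_free_cutoff(tree_ensemble_links(data, n_estimators, rng))

    registry = {
        "glasso": (_glasso, False),
        "glasso_p": (_glasso, True),
        "mcmc": (_mcmc, False),
        "mcmc_p": (_mcmc, True),
        "pcor": (_pcor, False),
        "trees": (_trees, False),
    }
    return {k: v for k, v in registry.items() if k in include}
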