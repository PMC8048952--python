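"""Comparative models on phylogenies: logistic regression for a binary
persistence strategy, generalized least squares for continuous fire
variables, and a leaf-trait PCA.

Persistence strategy (0 = seeder, 1 = resprouter) is modelled as a Bernoulli
trait with logistic mean structure ``logit P(y_i = 1) = x_i' beta`` and
residual dependence inherited from shared evolutionary history.  The
dependence between tips i and j decays with their divergence time t_ij as

    corr(y_i, y_j) = exp(-2 * alpha * t_ij / T)

where T is the tree height and ``alpha >= 0`` is the phylogenetic-signal
parameter: alpha -> infinity (or a star phylogeny) removes all dependence
and the estimator reduces exactly to Firth-penalized logistic regression.
Coefficients solve Firth-type bias-reduced generalized estimating equations;
alpha is profiled by a Gaussian pseudo-likelihood of the Pearson residuals.
Confidence intervals come from a parametric bootstrap that re-simulates the
strategy vector on the same tree from the fitted model.

PGLS assumes Brownian residual covariance proportional to shared root-to-tip
branch length.  The leaf-trait PCA operates on centred-and-scaled traits with
a fixed sign convention (leaf N loads positively on dimension 1, SLA
positively on dimension 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from scipy.special import expit
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "load_tree",
    "normalize_name",
    "tree_matrices",
    "classify_strategy",
    "PhyloLogisticRegression",
    "phylo_logistic_mple",
    "bootstrap_ci",
    "PGLS",
    "pgls_fit",
    "LeafTraitPCA",
    "leaf_trait_pca",
    "simulate_correlated_binary",
]


def normalize_name(name: str) -> str:
    return str(name).strip().replace(" ", "_")


def load_tree(path_or_string) -> dendropy.Tree:
    """Read a rooted Newick tree (path or literal string)."""
    src = str(path_or_string)
    if src.lstrip().startswith("("):
        return dendropy.Tree.get(data=src, schema="newick")
    return dendropy.Tree.get(path=src, schema="newick")


def tree_matrices(tree: dendropy.Tree, species: list[str]):
    """Shared-path covariance and divergence-time matrices for given tips.

    Returns ``(vcv, div_time, height)`` where ``vcv[i, j]`` is the shared
    root-to-MRCA path length of tips i and j (the Brownian covariance up to
    a rate constant), ``div_time[i, j] = patristic(i, j) / 2`` and ``height``
    is the maximum tip depth.  Raises on tips absent from the tree, listing
    the mismatches.
    """
    tip_by_name = {}
    for leaf in tree.leaf_node_iter():
        label = normalize_name(leaf.taxon.label if leaf.taxon else "")
        tip_by_name[label] = leaf
    wanted = [normalize_name(s) for s in species]
    missing = sorted(set(wanted) - set(tip_by_name))
    if missing:
        raise KeyError(f"species not in tree: {missing}")

    depth = {}
    for node in tree.preorder_node_iter():
        edge = node.edge.length or 0.0
        depth[node] = (depth.get(node.parent_node, 0.0)) + (
            edge if node.parent_node is not None else 0.0
        )

    n = len(wanted)
    index = {tip_by_name[w]: i for i, w in enumerate(wanted)}
    vcv = np.zeros((n, n))
    # postorder sweep: tips in different child subtrees share the MRCA depth
    clade: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            clade[node] = [index[node]] if node in index else []
            continue
        groups = [clade.pop(ch, []) for ch in node.child_nodes()]
        merged = []
        d = depth[node]
        for gi, g in enumerate(groups):
            for h in groups[gi + 1 :]:
                if g and h:
                    vcv[np.ix_(g, h)] = d
                    vcv[np.ix_(h, g)] = d
            merged.extend(g)
        clade[node] = merged
    depths = np.zeros(n)
    for leaf, i in index.items():
        depths[i] = depth[leaf]
    np.fill_diagonal(vcv, depths)
    div = 0.5 * (depths[:, None] + depths[None, :]) - vcv
    np.fill_diagonal(div, 0.0)
    return vcv, div, float(depths.max())


def classify_strategy(mortality_pct_at_full_scorch: float):
    """Seeder/resprouter call from whole-plant mortality at 100% leaf scorch.

    Mortality below 30% -> resprouter (1); above 70% -> seeder (0);
    intermediate mortality is inconclusive (None).
    """
    m = float(mortality_pct_at_full_scorch)
    if not 0.0 <= m <= 100.0:
        raise ValueError(f"mortality must be in [0, 100], got {m}")
    if m < 30.0:
        return 1
    if m > 70.0:
        return 0
    return None


_RHO_MAX = 0.95  # cap keeps the working covariance invertible at near-twin tips


def _phylo_correlation(div_norm: np.ndarray, alpha: float) -> np.ndarray:
    """Working tip correlation min(exp(-2 alpha t), rho_max), unit diagonal."""
    if np.isinf(alpha):
        return np.eye(div_norm.shape[0])
    R = np.minimum(np.exp(-2.0 * alpha * div_norm), _RHO_MAX)
    np.fill_diagonal(R, 1.0)
    return R


def simulate_correlated_binary(mu, R_chol, rng) -> np.ndarray:
    """Draw a binary vector with exact marginal means ``mu`` and a Gaussian
    copula whose latent correlation has Cholesky factor ``R_chol``."""
    z = R_chol @ rng.standard_normal(len(mu))
    u = stats.norm.cdf(z)
    return (u < mu).astype(float)


def _solve_beta(X, y, R_inv, beta0, penalty=True, max_iter=100, tol=1e-10):
    """Damped Newton solve of the (Firth-adjusted) estimating equations.

    Returns ``(beta, M, mu, converged)``; any linear-algebra failure (the
    working information going singular, e.g. at extreme correlation) yields
    ``converged=False`` rather than an exception.
    """
    beta = beta0.copy()

    def score_and_info(b):
        mu = expit(X @ b)
        W = np.clip(mu * (1.0 - mu), 1e-12, None)
        S = np.sqrt(W)
        SX = S[:, None] * X
        C = R_inv @ SX
        M = SX.T @ C
        M = 0.5 * (M + M.T)
        U = C.T @ ((y - mu) / S)
        if penalty:
            M_inv = linalg.inv(M)
            h = np.einsum("ij,ij->i", X @ M_inv, C)
            U = U + X.T @ (h * 0.5 * S * (1.0 - 2.0 * mu))
        return U, M, mu

    try:
        U, M, mu = score_and_info(beta)
        for _ in range(max_iter):
            norm0 = np.max(np.abs(U))
            if norm0 < tol:
                break
            step = linalg.solve(M, U, assume_a="pos")
            if not np.all(np.isfinite(step)):
                return beta, M, mu, False
            lam = 1.0
            for _ in range(30):
                U_new, M_new, mu_new = score_and_info(beta + lam * step)
                if np.max(np.abs(U_new)) < norm0 or lam < 1e-6:
                    break
                lam *= 0.5
            beta = beta + lam * step
            U, M, mu = U_new, M_new, mu_new
    except (linalg.LinAlgError, np.linalg.LinAlgError):
        return beta, np.eye(X.shape[1]), expit(X @ beta), False
    converged = bool(np.max(np.abs(U)) < max(tol, 1e-6))
    return beta, M, mu, converged


@dataclass
class PhyloGLMFit:
    """Plain-record view of a phylogenetic logistic fit."""

    coef: np.ndarray
    names: list[str]
    alpha: float
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    ci_lower: np.ndarray | None
    ci_upper: np.ndarray | None
    n: int
    converged: bool


class PhyloLogisticRegression(BaseEstimator):
    """Phylogenetic logistic regression by bias-reduced estimating equations.

    Parameters
    ----------
    alpha : float or None
        Phylogenetic-signal parameter.  None (default) profiles alpha over
        ``alpha_grid`` (log-spaced on [alpha_min, alpha_max] plus infinity,
        i.e. full independence) with bounded local refinement.
    penalty : bool
        Apply the Firth-type bias-reduction adjustment (default True); this
        keeps estimates finite under complete separation.
    n_boot : int
        Parametric-bootstrap replicates for percentile confidence intervals
        (0 disables the bootstrap at fit time).
    random_state : int
        Seed for the bootstrap simulations.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
    intercept_ : float
    alpha_ : float
    se_, zvalues_, pvalues_ : ndarray (intercept first)
    ci_ : ndarray of shape (n_features + 1, 2), after bootstrapping
    converged_ : bool
    n_boot_failures_ : int
    """

    def __init__(
        self,
        alpha=None,
        alpha_min=0.05,
        alpha_max=30.0,
        n_alpha=12,
        penalty=True,
        n_boot=0,
        max_iter=100,
        tol=1e-10,
        random_state=0,
    ):
        self.alpha = alpha
        self.alpha_min = alpha_min
        self.alpha_max = alpha_max
        self.n_alpha = n_alpha
        self.penalty = penalty
        self.n_boot = n_boot
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- internal ---------------------------------------------------------

    def _prepare(self, X, y, tree, species):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = list(X.columns)
            if species is None:
                species = list(X.index)
            X = X.to_numpy(float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_in_ = [f"x{i}" for i in range(X.shape[1])]
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X and y have incompatible shapes")
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("complete cases required: X/y contain NaN")
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("y must be binary 0/1")
        const = np.ptp(X, axis=0) == 0
        if const.any():
            bad = [self.feature_names_in_[i] for i in np.flatnonzero(const)]
            raise ValueError(f"constant predictor(s), coefficient undefined: {bad}")
        if tree is None:
            raise ValueError("a phylogeny is required")
        if species is None:
            raise ValueError("species labels are required when X is an array")
        _, div, height = tree_matrices(tree, list(species))
        div_norm = div / max(height, np.finfo(float).tiny)
        Xd = np.column_stack([np.ones(len(y)), X])
        return Xd, y, div_norm

    def _solve_at(self, alpha, Xd, y, div_norm, beta0):
        n = len(y)
        R = _phylo_correlation(div_norm, alpha) + 1e-10 * np.eye(n)
        try:
            R_inv = linalg.inv(R)
        except linalg.LinAlgError:
            return None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", linalg.LinAlgWarning)
            beta, M, mu, ok = _solve_beta(
                Xd, y, R_inv, beta0, self.penalty, self.max_iter, self.tol
            )
        if not ok:
            return None
        return beta, R_inv, M, mu

    def _estimate_alpha(self, e, div_norm):
        """Least-squares fit of residual cross-products to exp(-2 alpha t).

        The upper-triangle products e_i e_j estimate the working correlation;
        alpha is the decay rate that matches them best, with full
        independence (alpha = inf) as a competing candidate.
        """
        iu = np.triu_indices(len(e), 1)
        prod = np.outer(e, e)[iu]
        t = div_norm[iu]
        # a star phylogeny has no variation in divergence time: the decay
        # rate is unidentifiable and there is no shared history to model
        if np.ptp(t) < 1e-10:
            return np.inf

        def sse(log_a):
            r = np.exp(-2.0 * np.exp(log_a) * t)
            return float(np.sum((prod - r) ** 2))

        res = optimize.minimize_scalar(
            sse,
            bounds=(np.log(self.alpha_min), np.log(self.alpha_max)),
            method="bounded",
            options={"xatol": 1e-4},
        )
        if float(np.sum(prod**2)) <= res.fun:
            return np.inf
        return float(np.exp(res.x))

    # -- API --------------------------------------------------------------

    def fit(self, X, y, tree=None, species=None):
        """Fit to trait vector ``y`` with predictors ``X`` on ``tree``.

        ``X`` may be a DataFrame indexed by species name (then ``species``
        is optional); its tip labels must all occur in the tree.
        """
        Xd, y, div_norm = self._prepare(X, y, tree, species)
        beta0 = np.zeros(Xd.shape[1])

        if self.alpha is not None:
            alpha_hat = float(self.alpha)
            solved = self._solve_at(alpha_hat, Xd, y, div_norm, beta0)
        else:
            # alternate beta-solve and moment estimation of alpha, starting
            # from full independence
            alpha_hat = np.inf
            solved = self._solve_at(alpha_hat, Xd, y, div_norm, beta0)
            for _ in range(5):
                if solved is None:
                    break
                beta, _, _, mu = solved
                e = (y - mu) / np.sqrt(np.clip(mu * (1 - mu), 1e-12, None))
                alpha_new = self._estimate_alpha(e, div_norm)
                same = (np.isinf(alpha_new) and np.isinf(alpha_hat)) or (
                    np.isfinite(alpha_new)
                    and np.isfinite(alpha_hat)
                    and abs(np.log(alpha_new) - np.log(alpha_hat)) < 1e-3
                )
                trial = self._solve_at(alpha_new, Xd, y, div_norm, beta)
                if trial is not None:
                    alpha_hat, solved = alpha_new, trial
                if same or trial is None:
                    break

        if solved is None:
            self.converged_ = False
            warnings.warn("phylogenetic logistic regression failed to converge")
            p = Xd.shape[1]
            self.coef_ = np.full(p - 1, np.nan)
            self.intercept_ = np.nan
            self.se_ = self.zvalues_ = self.pvalues_ = np.full(p, np.nan)
            self.alpha_ = np.nan
            return self

        beta, R_inv, M, mu = solved
        self.converged_ = True
        self.alpha_ = float(alpha_hat)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        cov = linalg.inv(M)
        self.se_ = np.sqrt(np.diag(cov))
        self.zvalues_ = beta / self.se_
        self.pvalues_ = 2.0 * stats.norm.sf(np.abs(self.zvalues_))
        self.n_ = len(y)
        self._Xd, self._y, self._div_norm = Xd, y, div_norm
        self._R_inv, self._mu, self._beta = R_inv, mu, beta
        self.ci_ = None
        if self.n_boot:
            self.bootstrap_ci(self.n_boot, self.random_state)
        return self

    def bootstrap_ci(self, n_boot=1000, seed=0, level=0.95):
        """Percentile CIs from a parametric bootstrap on the fitted model.

        Strategy vectors are re-simulated from the fitted means and the
        fitted tip-correlation structure (alpha held at its point estimate),
        the coefficients are re-estimated for each replicate, and percentile
        intervals taken over converged replicates.  More than 20% failed
        replicates raises a warning.
        """
        if not getattr(self, "converged_", False):
            raise RuntimeError("bootstrap requires a converged fit")
        if n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        rng = np.random.default_rng(seed)
        n = len(self._y)
        R = _phylo_correlation(self._div_norm, self.alpha_) + 1e-10 * np.eye(n)
        L = linalg.cholesky(R, lower=True)
        draws = []
        failures = 0
        for _ in range(int(n_boot)):
            y_star = simulate_correlated_binary(self._mu, L, rng)
            if y_star.min() == y_star.max():  # degenerate replicate
                failures += 1
                continue
            beta_b, _, _, ok = _solve_beta(
                self._Xd, y_star, self._R_inv, self._beta, self.penalty,
                self.max_iter, max(self.tol, 1e-8),
            )
            if ok:
                draws.append(beta_b)
            else:
                failures += 1
        if failures > 0.2 * n_boot:
            warnings.warn(f"{failures}/{n_boot} bootstrap replicates failed")
        draws = np.asarray(draws)
        tail = 0.5 * (1.0 - level)
        self.ci_ = np.column_stack(
            [np.quantile(draws, tail, axis=0), np.quantile(draws, 1.0 - tail, axis=0)]
        )
        self.boot_estimates_ = draws
        self.n_boot_failures_ = failures
        return self.ci_

    def predict_proba(self, X):
        X = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        p1 = expit(self.intercept_ + X @ self.coef_)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def summary(self) -> PhyloGLMFit:
        beta = np.concatenate([[self.intercept_], self.coef_])
        return PhyloGLMFit(
            coef=beta,
            names=["intercept"] + list(self.feature_names_in_),
            alpha=self.alpha_,
            se=self.se_,
            zvalues=self.zvalues_,
            pvalues=self.pvalues_,
            ci_lower=None if self.ci_ is None else self.ci_[:, 0],
            ci_upper=None if self.ci_ is None else self.ci_[:, 1],
            n=self.n_,
            converged=self.converged_,
        )


def phylo_logistic_mple(tree, predictors, strategy, **kwargs) -> PhyloGLMFit:
    """Functional wrapper: fit strategy ~ predictors on a tree, return a record."""
    est = PhyloLogisticRegression(**kwargs).fit(predictors, strategy, tree=tree)
    return est.summary()


def bootstrap_ci(fit: PhyloLogisticRegression, n_boot=1000, seed=0, level=0.95):
    """Percentile bootstrap CIs for a fitted :class:`PhyloLogisticRegression`."""
    return fit.bootstrap_ci(n_boot=n_boot, seed=seed, level=level)


@dataclass
class PGLSFit:
    slope: float
    intercept: float
    fstat: float
    r2: float
    n: int
    p: float
    coef: np.ndarray | None = None


class PGLS(BaseEstimator):
    """Phylogenetic generalized least squares under Brownian covariance.

    Residual covariance is proportional to shared root-to-tip branch length
    (lambda = 1, no transformation).  On a star phylogeny this reduces to
    ordinary least squares.
    """

    def fit(self, X, y, tree=None, species=None):
        if isinstance(X, pd.DataFrame):
            if species is None:
                species = list(X.index)
            X = X.to_numpy(float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 1:
            X = X.T
        y = np.asarray(y, dtype=float).ravel()
        if tree is None or species is None:
            raise ValueError("tree and species labels are required")
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("complete cases required")
        C, _, _ = tree_matrices(tree, list(species))
        n, p = X.shape
        try:
            L = linalg.cholesky(C, lower=True)
        except linalg.LinAlgError:
            # near-duplicate tips: regularize minimally before giving up
            ridge = 1e-10 * np.trace(C) / max(n, 1)
            try:
                L = linalg.cholesky(C + ridge * np.eye(n), lower=True)
            except linalg.LinAlgError as err:
                raise linalg.LinAlgError("singular phylogenetic covariance") from err
        Xd = np.column_stack([np.ones(n), X])
        Xw = linalg.solve_triangular(L, Xd, lower=True)
        yw = linalg.solve_triangular(L, y, lower=True)
        coef, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        if rank < Xd.shape[1]:
            raise linalg.LinAlgError("singular design in PGLS")
        resid = yw - Xw @ coef
        rss = float(resid @ resid)
        ones_w = Xw[:, 0]
        mu_gls = float(ones_w @ yw) / float(ones_w @ ones_w)
        tss = float(np.sum((yw - mu_gls * ones_w) ** 2))
        df_den = n - p - 1
        self.coef_ = coef[1:].copy()
        self.intercept_ = float(coef[0])
        self.rss_ = rss
        self.rsquared_ = 1.0 - rss / tss if tss > 0 else np.nan
        if df_den > 0 and rss > 0:
            self.fstat_ = ((tss - rss) / p) / (rss / df_den)
            self.pvalue_ = float(stats.f.sf(self.fstat_, p, df_den))
        else:
            self.fstat_, self.pvalue_ = np.inf, 0.0
        self.n_ = n
        return self

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 1:
            X = X.T
        return self.intercept_ + X @ self.coef_


def pgls_fit(tree, x, y, species) -> PGLSFit:
    """Functional wrapper: simple PGLS regression of y on x."""
    est = PGLS().fit(np.asarray(x, float).reshape(-1, 1), y, tree=tree, species=species)
    return PGLSFit(
        slope=float(est.coef_[0]),
        intercept=est.intercept_,
        fstat=float(est.fstat_),
        r2=float(est.rsquared_),
        n=est.n_,
        p=float(est.pvalue_),
        coef=est.coef_,
    )


class LeafTraitPCA(BaseEstimator, TransformerMixin):
    """PCA of centred-and-scaled leaf traits with a fixed sign convention.

    Expects columns ``sla``, ``leaf_n``, ``cn_ratio`` (or any >= 2 traits,
    in which case the convention applies to the named columns only when
    present).  Dimension 1 is oriented so leaf N loads positively; dimension
    2 so SLA loads positively.
    """

    def __init__(self, n_components=2):
        self.n_components = n_components

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            self.trait_names_ = list(X.columns)
            values = X.to_numpy(float)
        else:
            values = np.asarray(X, dtype=float)
            self.trait_names_ = [f"trait{i}" for i in range(values.shape[1])]
        if values.shape[0] < 3:
            raise ValueError("need at least 3 species for a PCA")
        if np.isnan(values).any():
            raise ValueError("no missing trait values allowed")
        sd = values.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = [self.trait_names_[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant trait column(s): {bad}")
        self.mean_ = values.mean(axis=0)
        self.scale_ = sd
        Z = (values - self.mean_) / self.scale_
        # full SVD so variance fractions cover all axes
        _, s, Vt = np.linalg.svd(Z, full_matrices=False)
        var = s**2 / values.shape[0]
        self.explained_variance_ratio_ = var / var.sum()
        components = Vt
        for dim, trait in ((0, "leaf_n"), (1, "sla")):
            if dim >= components.shape[0]:
                continue
            j = self.trait_names_.index(trait) if trait in self.trait_names_ else dim
            if components[dim, j] < 0:
                components[dim] *= -1.0
        self.components_ = components[: self.n_components]
        self._all_components = components
        return self

    def transform(self, X):
        values = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        Z = (values - self.mean_) / self.scale_
        return Z @ self.components_.T


def leaf_trait_pca(sla, leaf_n, cn_ratio):
    """Functional wrapper: scores (dims 1-2), loadings, variance fractions."""
    df = pd.DataFrame({"sla": sla, "leaf_n": leaf_n, "cn_ratio": cn_ratio})
    est = LeafTraitPCA(n_components=2).fit(df)
    return est.transform(df), est.components_, est.explained_variance_ratio_
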