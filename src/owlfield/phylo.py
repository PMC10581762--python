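"""Phylogenetic comparative statistics from first principles.

Brownian-motion (BM) tree covariances, Pagel's-lambda phylogenetic
generalised least squares (PGLS) by maximum likelihood, bidirectional AIC
stepwise model selection, simulation-based phylogenetic ANOVA, BM ancestral
state reconstruction and maximum clade credibility (MCC) trees.

Model
-----
Under BM with rate ``sigma^2`` on a rooted tree, tip values are multivariate
normal with covariance ``sigma^2 C``, where ``C[i, j]`` is the shared
root-to-MRCA path length of tips i and j.  Pagel's lambda multiplies the
off-diagonal entries of ``C`` by ``lambda in [0, 1]``: lambda = 0 is a star
phylogeny (independent tips), lambda = 1 is pure BM.  PGLS estimates the
regression coefficients by GLS with ``V = sigma^2 C_lambda`` and profiles
the full Gaussian likelihood over lambda.  The parameter count used for the
AIC is (number of betas) + 2, counting sigma^2 and lambda.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "Phylogeny",
    "lambda_transform",
    "PagelLambdaGLS",
    "pgls_fit",
    "phylo_signal_lambda",
    "SignalResult",
    "phylostep",
    "StepwiseResult",
    "phylo_anova",
    "PhyloANOVAResult",
    "asr_bm",
    "ASRResult",
    "mcc_tree",
    "REFERENCE_LEVELS",
    "LEVEL_ORDER",
    "build_design",
]

#: treatment-contrast reference levels for the study's categorical covariates
REFERENCE_LEVELS = {"diet": "invertebrate", "habitat": "dense"}
#: display order of factor levels (reference first)
LEVEL_ORDER = {
    "diet": ["invertebrate", "vertebrate"],
    "habitat": ["dense", "semi-open", "open"],
    "group": ["owl", "raptor"],
}


class Phylogeny:
    """Rooted tree with branch lengths and BM covariance machinery.

    A thin wrapper over a :class:`dendropy.Tree` that adds the shared-path
    length matrix ``C``, ultrametricity checks and a cached eigendecomposition
    used by the fast PGLS profile over lambda.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate tip labels")
        if len(labels) < 2:
            raise ValueError("tree must have at least 2 tips")
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None and nd.edge.length is not None and nd.edge.length < 0:
                raise ValueError("negative branch length")
        self._cache: dict = {}

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(data=text, schema="newick",
                                     preserve_underscores=True)
        except Exception as exc:  # dendropy raises several error types
            raise ValueError(f"malformed newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def list_from_newick(cls, text: str) -> list:
        try:
            trees = dendropy.TreeList.get(data=text, schema="newick",
                                          preserve_underscores=True)
        except Exception as exc:
            raise ValueError(f"malformed newick: {exc}") from exc
        return [cls(t) for t in trees]

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True,
                                   unquoted_underscores=True).strip()

    # -- structure ---------------------------------------------------------
    @property
    def tip_labels(self) -> list:
        return sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def _depths(self) -> None:
        for nd in self.tree.preorder_node_iter():
            el = nd.edge.length if nd.edge.length is not None else 0.0
            nd._depth = el if nd.parent_node is None else nd.parent_node._depth + el

    def vcv(self, order: Sequence[str] | None = None):
        """BM covariance (shared path length) matrix and its tip order."""
        order = list(order) if order is not None else self.tip_labels
        key = ("vcv", tuple(order))
        if key in self._cache:
            return self._cache[key]
        self._depths()
        index = {lab: i for i, lab in enumerate(order)}
        if len(index) != len(order):
            raise ValueError("duplicate labels in requested order")
        n = len(order)
        C = np.zeros((n, n))
        # postorder: tip index lists per node; cross-child pairs share the
        # node's depth as covariance
        for nd in self.tree.postorder_node_iter():
            if nd.is_leaf():
                lab = nd.taxon.label
                if lab not in index:
                    raise ValueError(f"tip {lab!r} missing from requested order")
                nd._tips = [index[lab]]
                C[nd._tips[0], nd._tips[0]] = nd._depth
            else:
                kids = [ch._tips for ch in nd.child_nodes()]
                for i in range(len(kids)):
                    for j in range(i + 1, len(kids)):
                        C[np.ix_(kids[i], kids[j])] = nd._depth
                        C[np.ix_(kids[j], kids[i])] = nd._depth
                nd._tips = [t for k in kids for t in k]
        self._cache[key] = (C, order)
        return C, order

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        self._depths()
        depths = np.array([lf._depth for lf in self.tree.leaf_node_iter()])
        return bool(np.ptp(depths) <= rel_tol * max(depths.max(), 1e-300))

    def eig(self, order: Sequence[str] | None = None):
        """Cached eigendecomposition of C (for the ultrametric fast path)."""
        C, order = self.vcv(order)
        key = ("eig", tuple(order))
        if key not in self._cache:
            d, U = np.linalg.eigh(C)
            self._cache[key] = (np.maximum(d, 0.0), U)
        return self._cache[key] + (C,)


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale the off-diagonal entries of a BM covariance by Pagel's lambda."""
    lam = float(lam)
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    C = np.asarray(C, dtype=float)
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def _align(y, X, tree: Phylogeny | None, C):
    """Return (y, X, C, labels, names) aligned to a common species order."""
    names = None
    labels = None
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
    if tree is not None:
        order = tree.tip_labels
        if isinstance(y, pd.Series):
            if set(y.index) != set(order):
                raise ValueError("species in y do not match the tree tips")
            y = y.reindex(order)
            if isinstance(X, pd.DataFrame):
                X = X.reindex(order)
        C, labels = tree.vcv(order)
    elif C is None:
        raise ValueError("either tree or C must be given")
    yv = np.asarray(y, dtype=float).ravel()
    Xv = None if X is None else np.asarray(X, dtype=float)
    if Xv is not None and Xv.ndim == 1:
        Xv = Xv[:, None]
    return yv, Xv, np.asarray(C, dtype=float), labels, names


class PagelLambdaGLS(RegressorMixin, BaseEstimator):
    """Phylogenetic GLS regression with Pagel's-lambda error structure.

    Parameters
    ----------
    lam : "ML" or float in [0, 1]
        Profile lambda by maximum likelihood (default) or fix it.
    fit_intercept : bool
        Prepend an intercept column (default True).
    grid_size : int
        Number of lambda grid points pre-scanned before the bounded scalar
        refinement, to avoid local optima of the profile likelihood.

    The full Gaussian likelihood (ML, not REML) is used; AIC counts the
    betas plus sigma^2 plus lambda.  Standard errors use the unbiased
    residual variance and Student-t with ``n - p`` degrees of freedom, so a
    star tree (or lambda = 0) reproduces OLS exactly.
    """

    def __init__(self, lam="ML", fit_intercept: bool = True, grid_size: int = 101):
        self.lam = lam
        self.fit_intercept = fit_intercept
        self.grid_size = grid_size

    # -- likelihood machinery ---------------------------------------------
    @staticmethod
    def _profile_eig(z, Z, d, t0, lam):
        g = lam * d + (1.0 - lam) * t0
        g = np.maximum(g, 1e-12 * t0)
        w = 1.0 / g
        Zw = Z * w[:, None]
        A = Zw.T @ Z
        beta = np.linalg.solve(A, Zw.T @ z)
        r = z - Z @ beta
        rss = float(w @ (r * r))
        n = z.size
        sigma2 = max(rss / n, 1e-300)
        ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + float(np.log(g).sum()) + n)
        return ll, beta, sigma2, rss, A

    @staticmethod
    def _profile_chol(y, X, C, diagC, lam):
        V = lam * C
        np.fill_diagonal(V, diagC)
        cf = linalg.cho_factor(V, lower=True)
        logdet = 2.0 * float(np.log(np.diag(cf[0])).sum())
        ViX = linalg.cho_solve(cf, X)
        Viy = linalg.cho_solve(cf, y)
        A = X.T @ ViX
        beta = np.linalg.solve(A, X.T @ Viy)
        r = y - X @ beta
        rss = float(r @ linalg.cho_solve(cf, r))
        n = y.size
        sigma2 = max(rss / n, 1e-300)
        ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
        return ll, beta, sigma2, rss, A

    def fit(self, X, y, tree: Phylogeny | None = None, C: np.ndarray | None = None,
            feature_names: Sequence[str] | None = None):
        yv, Xv, C, labels, names = _align(y, X, tree, C)
        n = yv.size
        if Xv is None:
            Xv = np.empty((n, 0))
        if self.fit_intercept:
            Xv = np.column_stack([np.ones(n), Xv])
            names = ["(intercept)"] + list(names or
                                           [f"x{i}" for i in range(Xv.shape[1] - 1)])
        else:
            names = list(names or [f"x{i}" for i in range(Xv.shape[1])])
        if feature_names is not None:
            names = (["(intercept)"] if self.fit_intercept else []) + list(feature_names)
        p = Xv.shape[1]
        if n <= p:
            raise ValueError("need more observations than parameters")
        if np.linalg.matrix_rank(Xv) < p:
            raise ValueError("singular design matrix")
        yc = yv - yv.mean()
        if float(yc @ yc) < 1e-24 * max(1.0, abs(yv.mean()) ** 2):
            raise ValueError("response has zero variance")
        diagC = np.diag(C).copy()
        t0 = float(diagC.mean())
        ultra = np.ptp(diagC) <= 1e-8 * max(t0, 1e-300)
        if not ultra:
            warnings.warn("non-ultrametric covariance: lambda transform applied "
                          "to off-diagonals as usual", RuntimeWarning)
        if ultra:
            if tree is not None:
                d, U, _ = tree.eig(labels)
            else:
                d, U = np.linalg.eigh(C)
                d = np.maximum(d, 0.0)
            z, Z = U.T @ yv, U.T @ Xv
            prof = lambda lam: self._profile_eig(z, Z, d, t0, lam)
        else:
            prof = lambda lam: self._profile_chol(yv, Xv, C, diagC, lam)

        if self.lam == "ML":
            grid = np.linspace(0.0, 1.0, self.grid_size)
            lls = np.array([prof(l)[0] for l in grid])
            i = int(np.argmax(lls))
            lo = grid[max(i - 1, 0)]
            hi = grid[min(i + 1, grid.size - 1)]
            res = optimize.minimize_scalar(lambda l: -prof(l)[0],
                                           bounds=(lo, hi), method="bounded",
                                           options={"xatol": 1e-8})
            lam_hat = float(res.x) if -res.fun >= lls[i] else float(grid[i])
        else:
            lam_hat = float(self.lam)
            if not 0.0 <= lam_hat <= 1.0:
                raise ValueError("fixed lambda must lie in [0, 1]")
        ll, beta, sigma2, rss, A = prof(lam_hat)
        dfr = n - p
        cov = rss / dfr * np.linalg.inv(A)
        se = np.sqrt(np.diag(cov))
        tval = beta / se
        pval = 2.0 * stats.t.sf(np.abs(tval), dfr)

        self.nobs_ = n
        self.feature_names_ = names
        self.params_ = beta
        self.coef_ = beta[1:] if self.fit_intercept else beta
        self.intercept_ = float(beta[0]) if self.fit_intercept else 0.0
        self.se_ = se
        self.tvalues_ = tval
        self.pvalues_ = pval
        self.lambda_ = lam_hat
        self.sigma2_ = sigma2
        self.loglik_ = ll
        self.aic_ = -2.0 * ll + 2.0 * (p + 2)
        self.df_resid_ = dfr
        self.vcov_ = cov
        self.species_order_ = labels
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.feature_names_,
            "estimate": self.params_,
            "se": self.se_,
            "t": self.tvalues_,
            "p": self.pvalues_,
        })

    def profile_loglik(self, lam: float, X, y, tree=None, C=None) -> float:
        """Profile log-likelihood at a given lambda (for diagnostics)."""
        fitted = PagelLambdaGLS(lam=lam, fit_intercept=self.fit_intercept,
                                grid_size=self.grid_size).fit(X, y, tree=tree, C=C)
        return fitted.loglik_


def pgls_fit(y, X, tree: Phylogeny | None = None, lam="ML", C=None,
             feature_names=None) -> PagelLambdaGLS:
    """Fit a Pagel's-lambda PGLS model (thin wrapper over the estimator)."""
    return PagelLambdaGLS(lam=lam).fit(X, y, tree=tree, C=C,
                                       feature_names=feature_names)


@dataclass
class SignalResult:
    lambda_: float
    loglik: float
    at_lower_bound: bool = False
    at_upper_bound: bool = False
    degenerate: bool = False


def phylo_signal_lambda(y, tree: Phylogeny) -> SignalResult:
    """ML Pagel's lambda of a trait (intercept-only PGLS)."""
    try:
        m = PagelLambdaGLS().fit(None, y, tree=tree)
    except ValueError as exc:
        if "zero variance" in str(exc):
            return SignalResult(float("nan"), float("nan"), degenerate=True)
        raise
    return SignalResult(m.lambda_, m.loglik_,
                        at_lower_bound=m.lambda_ < 1e-4,
                        at_upper_bound=m.lambda_ > 1 - 1e-4)


# ---------------------------------------------------------------------------
# stepwise AIC selection
# ---------------------------------------------------------------------------

def build_design(traits: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Design columns for a term list: treatment contrasts for factors.

    Categorical columns are expanded into dummies against the study's
    reference levels (diet = invertebrate, habitat = dense); numeric columns
    pass through.  Column names follow the report convention
    ``"term [level]"``.
    """
    cols = {}
    for term in terms:
        if term not in traits.columns:
            raise KeyError(f"unknown candidate {term!r}")
        col = traits[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = LEVEL_ORDER.get(term)
            if levels is None or not set(col.dropna().unique()) <= set(levels):
                uniq = sorted(col.dropna().unique())
                ref = REFERENCE_LEVELS.get(term, uniq[0])
                ref = ref if ref in uniq else uniq[0]
                levels = [ref] + [u for u in uniq if u != ref]
            for lev in levels[1:]:
                if (col == lev).any():
                    cols[f"{term} [{lev}]"] = (col == lev).astype(float)
        else:
            cols[term] = col.astype(float)
    return pd.DataFrame(cols, index=traits.index)


@dataclass
class StepwiseResult:
    model: PagelLambdaGLS
    terms: list
    trace: list = field(default_factory=list)
    collinear: list = field(default_factory=list)


def phylostep(traits: pd.DataFrame, response: str, candidates: Sequence[str],
              tree: Phylogeny, lam="ML") -> StepwiseResult:
    """Bidirectional stepwise PGLS selection by lowest AIC.

    Starts from the intercept-only model; at each step the single add or
    drop move with the lowest AIC is accepted while it lowers the AIC.
    Factors enter and leave as whole blocks.  Collinear moves are recorded
    and skipped.
    """
    order = tree.tip_labels
    if set(traits.index) != set(order):
        raise ValueError("traits index does not match the tree tips")
    traits = traits.reindex(order)
    y = traits[response]

    def fit_terms(terms):
        terms = [t for t in candidates if t in terms]  # canonical order
        X = build_design(traits, terms) if terms else None
        return pgls_fit(y, X, tree=tree, lam=lam)

    collinear = []
    current: list = []
    model = fit_terms(current)
    trace = [{"step": 0, "action": "start", "term": None, "aic": model.aic_,
              "accepted": True}]
    step = 0
    while True:
        step += 1
        moves = [("add", t) for t in candidates if t not in current]
        moves += [("drop", t) for t in current]
        best = None
        for action, term in moves:
            cand = (current + [term]) if action == "add" else \
                [t for t in current if t != term]
            try:
                m = fit_terms(cand)
            except ValueError as exc:
                if "singular" in str(exc):
                    collinear.append(term)
                    trace.append({"step": step, "action": action, "term": term,
                                  "aic": float("nan"), "accepted": False})
                    continue
                raise
            trace.append({"step": step, "action": action, "term": term,
                          "aic": m.aic_, "accepted": False})
            if best is None or m.aic_ < best[0]:
                best = (m.aic_, action, term, cand, m)
        if best is None or best[0] >= model.aic_ - 1e-10:
            break
        _, action, term, current, model = best
        for tr in trace:
            if tr["step"] == step and tr["term"] == term and tr["action"] == action:
                tr["accepted"] = True
    return StepwiseResult(model, list(current), trace, sorted(set(collinear)))


# ---------------------------------------------------------------------------
# phylogenetic ANOVA
# ---------------------------------------------------------------------------

@dataclass
class PhyloANOVAResult:
    F: float
    df_between: int
    df_within: int
    p_sim: float
    n_sims: int
    seed: int | None
    infinite: bool = False


def _oneway_F(Y: np.ndarray, codes: np.ndarray, k: int) -> np.ndarray:
    """Row-wise one-way ANOVA F for a (m, n) matrix of datasets."""
    n = Y.shape[1]
    counts = np.bincount(codes, minlength=k).astype(float)
    ind = np.zeros((n, k))
    ind[np.arange(n), codes] = 1.0
    sums = Y @ ind
    means = sums / counts
    grand = Y.mean(axis=1, keepdims=True)
    ssb = ((means - grand) ** 2 * counts).sum(axis=1)
    sst = ((Y - grand) ** 2).sum(axis=1)
    ssw = np.maximum(sst - ssb, 0.0)
    dfb, dfw = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    F = np.where(ssb <= 1e-30 * np.maximum(sst, 1e-300), 0.0, F)
    return F


def phylo_anova(y, groups, tree: Phylogeny, n_sims: int = 1000,
                seed: int | None = None, rng=None) -> PhyloANOVAResult:
    """Simulation-based phylogenetic ANOVA (aov.phylo-style).

    The F statistic is the standard one-way ANOVA F on the raw tip data (the
    tree plays no role in it); its null distribution is built from ``n_sims``
    BM simulations on the tree, with the BM rate estimated from the data by
    ML, re-using the observed group labels.  ``p = (#{F_sim >= F_obs} + 1) /
    (n_sims + 1)``.
    """
    if rng is None:
        if seed is None:
            raise ValueError("a seed (or rng) is required for reproducibility")
        rng = np.random.default_rng(seed)
    order = tree.tip_labels
    if isinstance(y, pd.Series) and set(y.index) == set(order):
        y = y.reindex(order)
        if isinstance(groups, pd.Series):
            groups = groups.reindex(order)
    yv = np.asarray(y, dtype=float)
    if yv.size != len(order):
        raise ValueError("y length does not match the tree tips")
    glabels = pd.Categorical(np.asarray(groups))
    k = len(glabels.categories)
    if k < 2:
        raise ValueError("need at least 2 groups")
    codes = np.asarray(glabels.codes)
    n = yv.size
    F_obs = float(_oneway_F(yv[None, :], codes, k)[0])
    infinite = not np.isfinite(F_obs)

    C, _ = tree.vcv(order)
    one = np.ones(n)
    Ci1 = np.linalg.solve(C, one)
    mu = float(Ci1 @ yv / (Ci1 @ one))
    r = yv - mu
    sigma2 = float(r @ np.linalg.solve(C, r)) / n
    L = np.linalg.cholesky(C + 1e-12 * np.eye(n) * np.trace(C) / n)
    sims = (L @ rng.standard_normal((n, n_sims))).T * math.sqrt(max(sigma2, 0.0))
    F_sim = _oneway_F(sims, codes, k)
    p = (int(np.count_nonzero(F_sim >= F_obs)) + 1) / (n_sims + 1)
    return PhyloANOVAResult(F_obs, k - 1, n - k, p, n_sims, seed, infinite)


# ---------------------------------------------------------------------------
# ancestral state reconstruction
# ---------------------------------------------------------------------------

@dataclass
class ASRResult:
    values: pd.Series            # node label -> state (tips included)
    clades: dict                 # node label -> frozenset of descendant tips
    root_label: str


def asr_bm(tree: Phylogeny, tip_values) -> ASRResult:
    """ML ancestral states under Brownian motion at every internal node.

    Equivalent to GLS: the joint ML states minimise the sum over branches of
    squared changes divided by branch lengths, a weighted-Laplacian linear
    system with tips clamped to their observed values.  The root state equals
    the GLS (lambda = 1) phylogenetic mean.
    """
    if isinstance(tip_values, Mapping):
        tip_values = pd.Series(tip_values)
    vals = {k: float(v) for k, v in tip_values.items()}
    missing = set(tree.tip_labels) - set(vals)
    if missing:
        raise ValueError(f"missing tip values: {sorted(missing)}")
    internal = [nd for nd in tree.tree.preorder_node_iter() if not nd.is_leaf()]
    idx = {id(nd): i for i, nd in enumerate(internal)}
    labels = []
    used = set(tree.tip_labels)
    for i, nd in enumerate(internal):
        lab = nd.label if (nd.label and nd.label not in used) else f"nd{i}"
        while lab in used:
            lab = f"nd{i}_{len(used)}"
        used.add(lab)
        labels.append(lab)
    m = len(internal)
    A = np.zeros((m, m))
    b = np.zeros(m)
    for nd in tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        bl = nd.edge.length if nd.edge.length is not None else 0.0
        w = 1.0 / max(bl, 1e-9)
        pi = idx[id(nd.parent_node)]
        if nd.is_leaf():
            A[pi, pi] += w
            b[pi] += w * vals[nd.taxon.label]
        else:
            ci = idx[id(nd)]
            A[pi, pi] += w
            A[ci, ci] += w
            A[pi, ci] -= w
            A[ci, pi] -= w
    states = np.linalg.solve(A, b)
    out = {}
    clades = {}
    for i, nd in enumerate(internal):
        out[labels[i]] = float(states[i])
        clades[labels[i]] = frozenset(
            lf.taxon.label for lf in nd.leaf_iter())
    for lab, v in vals.items():
        out[lab] = v
        clades[lab] = frozenset([lab])
    root_label = labels[idx[id(tree.tree.seed_node)]]
    return ASRResult(pd.Series(out), clades, root_label)


# ---------------------------------------------------------------------------
# maximum clade credibility tree
# ---------------------------------------------------------------------------

def _node_heights(tree: dendropy.Tree) -> dict:
    """Height above the tips (max distance to a descendant tip) per node."""
    h = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            h[id(nd)] = 0.0
        else:
            h[id(nd)] = max(
                h[id(ch)] + (ch.edge.length or 0.0) for ch in nd.child_nodes())
    return h


def _clades(tree: dendropy.Tree):
    """(clade tip-set, node) pairs over the internal nodes, root included."""
    tips = {}
    out = []
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            tips[id(nd)] = frozenset([nd.taxon.label])
        else:
            s = frozenset().union(*(tips[id(ch)] for ch in nd.child_nodes()))
            tips[id(nd)] = s
            out.append((s, nd))
    return out


def mcc_tree(trees: Sequence[Phylogeny]) -> Phylogeny:
    """Maximum clade credibility tree from a tree sample.

    Clade frequencies are tallied across the sample; the sampled tree
    maximising the sum of log clade frequencies (the log credibility
    product) is returned, with each internal node's height replaced by the
    mean height of its clade across the trees containing it.
    """
    if len(trees) == 0:
        raise ValueError("empty tree sample")
    tipset = frozenset(trees[0].tip_labels)
    for t in trees:
        if frozenset(t.tip_labels) != tipset:
            raise ValueError("all trees must share the same tip set")
    counts: Counter = Counter()
    heights: dict = {}
    per_tree = []
    for t in trees:
        h = _node_heights(t.tree)
        cl = _clades(t.tree)
        per_tree.append(cl)
        for s, nd in cl:
            counts[s] += 1
            acc = heights.setdefault(s, [0.0, 0])
            acc[0] += h[id(nd)]
            acc[1] += 1
    ntr = len(trees)
    best_i, best_score = 0, -math.inf
    for i, cl in enumerate(per_tree):
        score = sum(math.log(counts[s] / ntr) for s, _ in cl)
        if score > best_score + 1e-12:
            best_i, best_score = i, score
    winner = trees[best_i].tree.clone(depth=1)
    mean_h = {s: acc[0] / acc[1] for s, acc in heights.items()}
    node_h = {}
    for s, nd in _clades(winner):
        node_h[id(nd)] = mean_h[s]
    clamped = False
    for nd in winner.preorder_node_iter():
        h = 0.0 if nd.is_leaf() else node_h[id(nd)]
        if nd.parent_node is None:
            continue
        bl = node_h[id(nd.parent_node)] - h
        if bl < 0:
            clamped = True
            bl = 0.0
        nd.edge.length = bl
    if clamped:
        warnings.warn("negative branch implied by mean clade heights; "
                      "clamped to zero", RuntimeWarning)
    out = Phylogeny(winner)
    out.credibility_score_ = best_score
    return out
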