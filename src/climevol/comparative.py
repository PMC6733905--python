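"""Phylogenetic comparative statistics on a dated tree.

Implements the toolbox used to relate species traits (preferred temperature,
water loss, substitution-rate proxies) to niche metrics while accounting for
shared ancestry:

* generalized least squares regression with a fixed-root Ornstein-Uhlenbeck
  (OU) correlation structure, reducing to Brownian motion (BM) as the
  attraction strength alpha -> 0 (:class:`PhyloRegression`);
* Blomberg's K phylogenetic-signal statistic with a randomization P-value;
* Felsenstein's standardized independent contrasts and their regression on
  node ages;
* maximum-likelihood (GLS) ancestral states under BM with along-branch
  interpolation, and lineage-averaged trait trends through time;
* phylogenetic principal component analysis (eigenanalysis of the
  GLS-estimated evolutionary covariance matrix);
* disparity-through-time curves with a BM-simulated null envelope.

All operations drop (and log) species with missing data rather than impute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .treekit import Tree, TreeNode

logger = logging.getLogger(__name__)

__all__ = [
    "phylo_cov",
    "pic",
    "resolve_polytomies",
    "contrasts_vs_age",
    "blomberg_k",
    "phylosig_test",
    "SignalResult",
    "PhyloRegression",
    "PhyloRegressionResults",
    "pgls_ou",
    "bonferroni",
    "anc_states_bm",
    "branch_state",
    "lineage_trend",
    "phylo_pca",
    "PhyloPCAResult",
    "dtt_envelope",
    "dtt_curve",
    "DTTResult",
]


# ---------------------------------------------------------------------------
# covariance machinery
# ---------------------------------------------------------------------------

def _tip_order(tree: Tree) -> list[str]:
    return tree.tip_labels


def phylo_cov(tree: Tree, order: list[str] | None = None) -> pd.DataFrame:
    """BM phylogenetic covariance: C[i, j] = depth of the MRCA of tips i, j."""
    depths = tree.depths()
    tips = tree.tips()
    labels = [t.label for t in tips]
    idx = {lab: k for k, lab in enumerate(labels)}
    n = len(tips)
    C = np.zeros((n, n))
    below: dict[int, list[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = [idx[node.label]]
            C[idx[node.label], idx[node.label]] = depths[node]
        else:
            groups = [below[id(c)] for c in node.children]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        C[i, groups[b]] = depths[node]
                        C[np.asarray(groups[b]), i] = depths[node]
            below[id(node)] = [i for g in groups for i in g]
    df = pd.DataFrame(C, index=labels, columns=labels)
    if order is not None:
        df = df.loc[order, order]
    return df


def _align(tree: Tree, trait: dict[str, float] | pd.Series):
    trait = dict(trait)
    labels = tree.tip_labels
    missing = [lab for lab in labels if lab not in trait or pd.isna(trait[lab])]
    if missing:
        raise ValueError(f"trait values missing for tips: {sorted(missing)}")
    y = np.array([float(trait[lab]) for lab in labels])
    return labels, y


def _gls_mean(Ci: np.ndarray, y: np.ndarray) -> float:
    one = np.ones(len(y))
    return float(one @ Ci @ y / (one @ Ci @ one))


# ---------------------------------------------------------------------------
# independent contrasts
# ---------------------------------------------------------------------------

def resolve_polytomies(tree: Tree, seed: int = 0) -> Tree:
    """Randomly resolve polytomies with zero-length branches (seeded)."""
    rng = np.random.default_rng(seed)
    tree = tree.copy()
    n_resolved = 0
    for node in list(tree.preorder()):
        while len(node.children) > 2:
            picks = rng.choice(len(node.children), size=2, replace=False)
            a, b = (node.children[i] for i in sorted(picks))
            node.children.remove(a)
            node.children.remove(b)
            joint = TreeNode(length=0.0)
            joint.add_child(a)
            joint.add_child(b)
            node.add_child(joint)
            n_resolved += 1
    if n_resolved:
        logger.info("randomly resolved %d polytomies with zero-length branches", n_resolved)
    return tree


def pic(tree: Tree, trait: dict[str, float]) -> pd.DataFrame:
    """Felsenstein's standardized independent contrasts on a binary dated tree.

    Returns one row per internal node: the contrast (standardized by its
    expected SD, with the usual branch-length extension at internal nodes)
    and the node age (time before present).
    """
    if any(len(n.children) > 2 for n in tree.preorder()):
        raise ValueError("tree has polytomies; resolve them first (resolve_polytomies)")
    _align(tree, trait)  # raises on missing tips
    depths = tree.depths()
    total = tree.depth
    value: dict[int, float] = {}
    varlen: dict[int, float] = {}
    rows = []
    for node in tree.postorder():
        if node.is_leaf:
            value[id(node)] = float(trait[node.label])
            varlen[id(node)] = node.length
        else:
            a, b = node.children
            va, vb = varlen[id(a)], varlen[id(b)]
            xa, xb = value[id(a)], value[id(b)]
            contrast = (xa - xb) / np.sqrt(va + vb)
            rows.append({"contrast": contrast, "age": total - depths[node]})
            value[id(node)] = (xa / va + xb / vb) / (1 / va + 1 / vb) if va + vb > 0 else 0.5 * (xa + xb)
            varlen[id(node)] = node.length + va * vb / (va + vb) if va + vb > 0 else node.length
    return pd.DataFrame(rows)


def contrasts_vs_age(contrasts: pd.DataFrame):
    """OLS of |standardized contrast| on node age; two-sided t-test on the slope.

    A negative slope indicates recent divergences carry larger standardized
    trait change than old ones.  Returns (slope, r, P).
    """
    if len(contrasts) < 3:
        raise ValueError("need at least 3 contrasts")
    x = contrasts["age"].to_numpy(dtype=float)
    y = np.abs(contrasts["contrast"].to_numpy(dtype=float))
    if np.ptp(x) == 0:
        raise ValueError("node ages are constant; regression undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue), float(res.pvalue)


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------

@dataclass
class SignalResult:
    """Phylogenetic signal test result: Blomberg's K and a randomization P."""

    K: float
    P: float
    n_perm: int
    method: str = "permutation"


def _k_parts(tree: Tree, order: list[str]):
    C = phylo_cov(tree, order).to_numpy()
    Ci = np.linalg.inv(C)
    n = len(order)
    one = np.ones(n)
    w = Ci @ one / (one @ Ci @ one)
    expected = (np.trace(C) - n / (one @ Ci @ one)) / (n - 1)
    return Ci, w, expected


def _k_stat(Y: np.ndarray, Ci: np.ndarray, w: np.ndarray, expected: float) -> np.ndarray:
    """Blomberg's K for each column of Y (n x m)."""
    n = Y.shape[0]
    a = w @ Y
    dev = Y - a[None, :]
    mse0 = np.sum(dev * dev, axis=0) / (n - 1)
    mse = np.einsum("im,ij,jm->m", dev, Ci, dev) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k(tree: Tree, trait: dict[str, float]) -> float:
    """Blomberg's K: observed MSE0/MSE divided by its BM expectation on the tree.

    K = 1 is the BM expectation; K < 1 indicates less phylogenetic signal
    than BM, K > 1 more.
    """
    labels, y = _align(tree, trait)
    if len(labels) < 4:
        raise ValueError("need at least 4 tips")
    if np.ptp(y) == 0:
        raise ValueError("trait is constant; K undefined")
    Ci, w, expected = _k_parts(tree, labels)
    return float(_k_stat(y[:, None], Ci, w, expected)[0])


def phylosig_test(
    tree: Tree,
    trait: dict[str, float],
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "permutation",
) -> SignalResult:
    """Randomization test of phylogenetic signal.

    ``method='permutation'`` shuffles tip values across the tree;
    ``method='bm'`` draws the null from BM simulations rate-matched to the
    data.  P counts null statistics >= observed, including the observed
    draw itself, so P >= 1/(n_perm + 1).
    """
    labels, y = _align(tree, trait)
    if np.ptp(y) == 0:
        raise ValueError("trait is constant")
    Ci, w, expected = _k_parts(tree, labels)
    k_obs = float(_k_stat(y[:, None], Ci, w, expected)[0])
    rng = np.random.default_rng(seed)
    if method == "permutation":
        Y = np.empty((len(y), n_perm))
        for j in range(n_perm):
            Y[:, j] = rng.permutation(y)
    elif method == "bm":
        C = np.linalg.inv(Ci)
        a = _gls_mean(Ci, y)
        resid = y - a
        rate = float(resid @ Ci @ resid / len(y))
        L = np.linalg.cholesky(C)
        Y = a + np.sqrt(rate) * (L @ rng.standard_normal((len(y), n_perm)))
    else:
        raise ValueError(f"unknown method {method!r}")
    k_null = _k_stat(Y, Ci, w, expected)
    p = (1 + int(np.sum(k_null >= k_obs))) / (n_perm + 1)
    return SignalResult(K=k_obs, P=float(p), n_perm=n_perm, method=method)


# ---------------------------------------------------------------------------
# phylogenetic regression (fixed-root OU / BM)
# ---------------------------------------------------------------------------

def _ou_corr(C: np.ndarray, alpha: float) -> np.ndarray:
    """Fixed-root OU covariance (sigma^2 factored out).

    V_ij = exp(-alpha * d_ij) * (1 - exp(-2 alpha * t_ij)) / (2 alpha), where
    t_ij is the shared path length (depth of the MRCA) and d_ij the patristic
    distance.  alpha -> 0 recovers the BM covariance t_ij.
    """
    if alpha <= 0:
        return C.copy()
    T = np.diag(C)
    d = T[:, None] + T[None, :] - 2 * C
    scale = -np.expm1(-2 * alpha * C) / (2 * alpha)
    return np.exp(-alpha * d) * scale


@dataclass
class PhyloRegressionResults:
    """MLEs, uncertainties and fit diagnostics of a phylogenetic regression."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    alpha: float
    sigma2: float
    llf: float
    aic: float
    nobs: int
    df_resid: int
    model: str
    resid: pd.Series
    pvalues_bonferroni: pd.Series | None = None

    def summary(self) -> str:
        lines = [
            f"Phylogenetic GLS ({self.model.upper()} correlation), n = {self.nobs}",
            f"alpha = {self.alpha:.6g}   sigma2 = {self.sigma2:.6g}",
            f"logL = {self.llf:.4f}   AIC = {self.aic:.4f}",
            "",
            f"{'term':<16}{'coef':>12}{'std err':>12}{'t':>10}{'P>|t|':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<16}{self.params[name]:>12.5g}{self.bse[name]:>12.5g}"
                f"{self.tvalues[name]:>10.3f}{self.pvalues[name]:>10.4g}"
            )
        return "\n".join(lines)


class PhyloRegression:
    """Phylogenetic regression of a species trait on one or more predictors.

    GLS with the fixed-root OU correlation structure (``model='ou'``; the
    attraction strength alpha is profiled by maximum likelihood over a log
    grid on [1e-8, 50]/tree-depth, refined by bounded scalar minimization) or
    with the BM structure (``model='bm'``, alpha = 0).  Polynomial terms of
    degree 2 are supported via ``degree=2``.  Species with missing values are
    dropped with a logged count.
    """

    def __init__(
        self,
        tree: Tree,
        data: pd.DataFrame,
        response: str,
        predictors: list[str],
        model: str = "ou",
        degree: int = 1,
    ):
        if model not in ("ou", "bm"):
            raise ValueError("model must be 'ou' or 'bm'")
        if degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")
        self.model = model
        cols = [response] + list(predictors)
        tips = set(tree.tip_labels)
        present = [s for s in data.index if s in tips]
        sub = data.loc[present, cols].dropna()
        dropped = len(tips) - len(sub)
        if dropped:
            logger.info("dropped %d species with missing data or absent from the tree", dropped)
        if len(sub) == 0:
            raise ValueError("no overlap between tree tips and data rows")
        keep = set(sub.index)
        pruned = tree
        for lab in sorted(tips - keep):
            from .treekit import drop_tip

            pruned = drop_tip(pruned, lab)
        self.tree = pruned
        order = pruned.tip_labels
        sub = sub.loc[order]
        self.response = response
        y = sub[response].to_numpy(dtype=float)
        names = ["const"]
        Xcols = [np.ones(len(sub))]
        for p in predictors:
            Xcols.append(sub[p].to_numpy(dtype=float))
            names.append(p)
            if degree == 2:
                Xcols.append(sub[p].to_numpy(dtype=float) ** 2)
                names.append(f"{p}^2")
        X = np.column_stack(Xcols)
        if X.shape[0] <= X.shape[1]:
            raise ValueError(f"n = {X.shape[0]} too small for {X.shape[1]} coefficients")
        self.y, self.X, self.names, self.order = y, X, names, order
        self.C = phylo_cov(pruned, order).to_numpy()
        self.depth = pruned.depth

    # profile log-likelihood pieces ------------------------------------

    def _gls(self, alpha: float):
        V = _ou_corr(self.C, alpha)
        cf = linalg.cho_factor(V, lower=True)
        Vi_X = linalg.cho_solve(cf, self.X)
        Vi_y = linalg.cho_solve(cf, self.y)
        XtViX = self.X.T @ Vi_X
        beta = np.linalg.solve(XtViX, self.X.T @ Vi_y)
        resid = self.y - self.X @ beta
        rss = float(resid @ linalg.cho_solve(cf, resid))
        n = len(self.y)
        sigma2 = rss / n
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        # floor sigma2 so perfect fits give a large finite likelihood
        llf = -0.5 * (n * np.log(2 * np.pi * max(sigma2, 1e-300)) + logdet + n)
        return beta, resid, sigma2, llf, XtViX

    def fit(self, alpha: float | None = None) -> PhyloRegressionResults:
        if self.model == "bm":
            alpha_hat = 0.0
        elif alpha is not None:
            alpha_hat = float(alpha)
        else:
            lo, hi = 1e-8 / self.depth, 50.0 / self.depth
            grid = np.geomspace(lo, hi, 40)
            lls = np.array([self._gls(a)[3] for a in grid])
            k = int(np.argmax(lls))
            a_lo = grid[max(k - 1, 0)]
            a_hi = grid[min(k + 1, len(grid) - 1)]
            res = optimize.minimize_scalar(
                lambda la: -self._gls(np.exp(la))[3],
                bounds=(np.log(a_lo), np.log(a_hi)),
                method="bounded",
                options={"xatol": 1e-10},
            )
            alpha_hat = float(np.exp(res.x))
            if self._gls(alpha_hat)[3] < lls[k]:
                alpha_hat = float(grid[k])

        beta, resid, sigma2, llf, XtViX = self._gls(alpha_hat)
        n, p = self.X.shape
        df_resid = n - p
        s2_unbiased = sigma2 * n / df_resid
        cov_beta = s2_unbiased * np.linalg.inv(XtViX)
        bse = np.sqrt(np.diag(cov_beta))
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(bse > 0, beta / np.where(bse > 0, bse, 1.0), np.inf * np.sign(beta))
        pvals = 2 * stats.t.sf(np.abs(tvals), df_resid)
        k_params = p + 1 + (1 if self.model == "ou" else 0)
        return PhyloRegressionResults(
            params=pd.Series(beta, index=self.names),
            bse=pd.Series(bse, index=self.names),
            tvalues=pd.Series(tvals, index=self.names),
            pvalues=pd.Series(pvals, index=self.names),
            alpha=alpha_hat,
            sigma2=sigma2,
            llf=llf,
            aic=2 * k_params - 2 * llf,
            nobs=n,
            df_resid=df_resid,
            model=self.model,
            resid=pd.Series(resid, index=self.order),
        )


def pgls_ou(
    tree: Tree,
    y: dict[str, float] | pd.Series,
    X: pd.DataFrame,
    model: str = "ou",
    degree: int = 1,
) -> PhyloRegressionResults:
    """Convenience wrapper: phylogenetic GLS of ``y`` on the columns of ``X``."""
    data = X.copy()
    data["__y__"] = pd.Series(dict(y))
    reg = PhyloRegression(tree, data, "__y__", list(X.columns), model=model, degree=degree)
    return reg.fit()


def bonferroni(results: list[PhyloRegressionResults]) -> None:
    """Family-wise Bonferroni adjustment across a declared regression family
    (multiplies each p-value by the family size, capped at 1; in place)."""
    m = len(results)
    for r in results:
        r.pvalues_bonferroni = (r.pvalues * m).clip(upper=1.0)


# ---------------------------------------------------------------------------
# ancestral states and lineage trends
# ---------------------------------------------------------------------------

def anc_states_bm(tree: Tree, trait: dict[str, float]) -> dict[TreeNode, float]:
    """ML (GLS) ancestral states under BM, for every node of the tree.

    The root state equals the GLS grand mean; internal states follow the
    conditional-normal formula using covariances between each node and the
    tips.  Tip states are the observed values.
    """
    labels, y = _align(tree, trait)
    idx = {lab: k for k, lab in enumerate(labels)}
    C = phylo_cov(tree, labels).to_numpy()
    Ci = np.linalg.inv(C)
    a = _gls_mean(Ci, y)
    w = Ci @ (y - a)
    depths = tree.depths()

    below: dict[int, set[str]] = {}
    for node in tree.postorder():
        below[id(node)] = (
            {node.label} if node.is_leaf else set().union(*(below[id(c)] for c in node.children))
        )

    states: dict[TreeNode, float] = {}
    n = len(labels)
    for node in tree.preorder():
        if node.is_leaf:
            states[node] = float(trait[node.label])
            continue
        if node is tree.root:
            states[node] = a
            continue
        c = np.empty(n)
        assigned = set()
        anc = node
        while anc is not None:
            members = below[id(anc)] - assigned
            for lab in members:
                c[idx[lab]] = depths[anc]
            assigned |= members
            anc = anc.parent
        states[node] = float(a + c @ w)
    return states


def branch_state(states: dict[TreeNode, float], node: TreeNode, frac: float) -> float:
    """Linear in-time interpolation along the branch above ``node``
    (``frac=0`` at the parent, 1 at the node)."""
    if node.parent is None:
        return states[node]
    return (1 - frac) * states[node.parent] + frac * states[node]


def lineage_trend(tree: Tree, states: dict[TreeNode, float], times: np.ndarray) -> pd.DataFrame:
    """Average trait value over all lineages existing at each query time.

    Each branch's value is the mean of its two endpoint states.  Times are
    measured from the root; a branch spanning (t_parent, t_child] is counted
    at time t iff t_parent <= t < t_child (at a speciation event the parent
    branch is excluded and both daughters included); terminal branches are
    also counted at the present.
    """
    depths = tree.depths()
    total = tree.depth
    times = np.asarray(times, dtype=float)
    if np.any(times < 0) or np.any(times > total * (1 + 1e-12)):
        raise ValueError(f"query times must lie in [0, {total}]")
    branches = []
    for node in tree.preorder():
        if node.parent is None:
            continue
        branches.append(
            (depths[node.parent], depths[node], 0.5 * (states[node.parent] + states[node]))
        )
    rows = []
    for t in times:
        vals = [
            v
            for (d0, d1, v) in branches
            if (d0 <= t < d1) or (t >= d1 and np.isclose(d1, total) and np.isclose(t, total))
        ]
        rows.append({"time": t, "mean_value": float(np.mean(vals)) if vals else np.nan, "n_lineages": len(vals)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phylogenetic PCA
# ---------------------------------------------------------------------------

@dataclass
class PhyloPCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fractions: np.ndarray
    evolutionary_cov: pd.DataFrame


def phylo_pca(tree: Tree, traits: pd.DataFrame) -> PhyloPCAResult:
    """Phylogenetic PCA: eigenanalysis of the evolutionary covariance matrix
    estimated by GLS under the BM covariance; scores are phylogenetically
    centred projections."""
    if traits.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    tips = tree.tip_labels
    sub = traits.loc[[s for s in tips if s in traits.index]].dropna()
    if len(sub) < len(tips):
        raise ValueError(
            f"traits missing for tips: {sorted(set(tips) - set(sub.index))}"
        )
    sub = sub.loc[tips]
    X = sub.to_numpy(dtype=float)
    C = phylo_cov(tree, tips).to_numpy()
    Ci = np.linalg.inv(C)
    one = np.ones(len(tips))
    a = (one @ Ci @ X) / (one @ Ci @ one)
    dev = X - a[None, :]
    R = dev.T @ Ci @ dev / (len(tips) - 1)
    if np.linalg.matrix_rank(R) == 0:
        raise ValueError("evolutionary covariance is singular")
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0, None)
    scores = dev @ eigvec
    pcs = [f"PC{i + 1}" for i in range(len(eigval))]
    return PhyloPCAResult(
        scores=pd.DataFrame(scores, index=tips, columns=pcs),
        loadings=pd.DataFrame(eigvec, index=traits.columns, columns=pcs),
        variance_fractions=eigval / eigval.sum(),
        evolutionary_cov=pd.DataFrame(R, index=traits.columns, columns=traits.columns),
    )


# ---------------------------------------------------------------------------
# disparity through time
# ---------------------------------------------------------------------------

def _avg_sq_dist(X: np.ndarray) -> float:
    """Mean squared pairwise Euclidean distance among rows (0 for < 2 rows)."""
    m = X.shape[0]
    if m < 2:
        return 0.0
    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * (X @ X.T)
    iu = np.triu_indices(m, 1)
    return float(np.mean(np.maximum(d2[iu], 0.0)))


def dtt_curve(tree: Tree, X: np.ndarray, tip_index: dict[str, int], _cache=None):
    """Relative subclade disparity at each internal-node height.

    At the root the value is 1 (whole-tree disparity, normalized); at each
    later node height it is the mean relative disparity over the clades of
    all branches crossing that height.
    """
    if _cache is None:
        _cache = _dtt_cache(tree, tip_index)
    heights, crossing = _cache
    total = _avg_sq_dist(X)
    if total == 0:
        raise ValueError("whole-tree disparity is zero")
    values = [1.0]
    for clades in crossing:
        rel = [
            _avg_sq_dist(X[members]) / total for members in clades
        ]
        values.append(float(np.mean(rel)))
    return np.asarray(heights), np.asarray(values)


def _dtt_cache(tree: Tree, tip_index: dict[str, int]):
    depths = tree.depths()
    below: dict[int, list[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = [tip_index[node.label]]
        else:
            below[id(node)] = [i for c in node.children for i in below[id(c)]]
    internal = [n for n in tree.preorder() if not n.is_leaf and n is not tree.root]
    node_heights = sorted(depths[n] for n in internal)
    branches = [
        (depths[n.parent], depths[n], np.asarray(below[id(n)]))
        for n in tree.preorder()
        if n.parent is not None
    ]
    heights = [0.0] + node_heights
    crossing = []
    for h in node_heights:
        crossing.append([members for (d0, d1, members) in branches if d0 <= h < d1])
    return heights, crossing


@dataclass
class DTTResult:
    """Observed DTT curve with a BM null median and 95% envelope."""

    heights: np.ndarray  # node heights from the root, Ma
    relative_heights: np.ndarray  # heights / tree depth
    observed: np.ndarray
    null_median: np.ndarray
    envelope_lo: np.ndarray
    envelope_hi: np.ndarray
    n_sim: int

    @property
    def inside_fraction(self) -> float:
        inside = (self.observed >= self.envelope_lo) & (self.observed <= self.envelope_hi)
        return float(np.mean(inside))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "height": self.heights,
                "relative_height": self.relative_heights,
                "observed": self.observed,
                "null_median": self.null_median,
                "lo": self.envelope_lo,
                "hi": self.envelope_hi,
            }
        )

    def plot(self, ax=None):  # pragma: no cover - exercised manually
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(self.relative_heights, self.envelope_lo, self.envelope_hi, alpha=0.3, color="grey")
        ax.plot(self.relative_heights, self.null_median, "--", color="black", label="BM median")
        ax.plot(self.relative_heights, self.observed, color="C3", label="observed")
        ax.set_xlabel("relative time from root")
        ax.set_ylabel("relative disparity")
        ax.legend()
        return ax


def dtt_envelope(
    tree: Tree,
    traits: pd.DataFrame | dict[str, float],
    n_sim: int = 1000,
    seed: int = 0,
    envelope: tuple[float, float] = (2.5, 97.5),
) -> DTTResult:
    """Disparity-through-time with a BM null envelope.

    The BM simulations are rate-matched to the data (evolutionary covariance
    estimated by GLS); the envelope spans the 2.5–97.5 percentiles of the
    simulated curves at each node height.
    """
    if isinstance(traits, dict):
        traits = pd.DataFrame({"trait": pd.Series(traits)})
    tips = tree.tip_labels
    sub = traits.loc[[s for s in tips if s in traits.index]].dropna()
    if len(sub) < len(tips):
        raise ValueError(f"traits missing for tips: {sorted(set(tips) - set(sub.index))}")
    X = sub.loc[tips].to_numpy(dtype=float)
    n, p = X.shape
    tip_index = {lab: i for i, lab in enumerate(tips)}
    cache = _dtt_cache(tree, tip_index)
    heights, observed = dtt_curve(tree, X, tip_index, cache)

    C = phylo_cov(tree, tips).to_numpy()
    Ci = np.linalg.inv(C)
    one = np.ones(n)
    a = (one @ Ci @ X) / (one @ Ci @ one)
    dev = X - a[None, :]
    R = dev.T @ Ci @ dev / n
    Lc = np.linalg.cholesky(C)
    # guard rank-deficient trait covariance
    Lr = np.linalg.cholesky(R + 1e-12 * np.eye(p) * max(np.trace(R), 1.0))
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sim, len(heights)))
    for s in range(n_sim):
        Z = rng.standard_normal((n, p))
        Xs = a[None, :] + Lc @ Z @ Lr.T
        _, sims[s] = dtt_curve(tree, Xs, tip_index, cache)
    lo, hi = np.percentile(sims, envelope, axis=0)
    return DTTResult(
        heights=np.asarray(heights),
        relative_heights=np.asarray(heights) / tree.depth,
        observed=observed,
        null_median=np.median(sims, axis=0),
        envelope_lo=lo,
        envelope_hi=hi,
        n_sim=n_sim,
    )
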