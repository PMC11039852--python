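"""Independent brute-force oracles used only by the test suite.

Deliberately naive: explicit matrix inverses, per-pair graph walks,
exhaustive enumeration, dense multivariate-normal densities.  They share
no code path with the package implementation they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---- tree walks -----------------------------------------------------------

def newick_adjacency(dtree):
    """Edge list (node -> parent, length) from a dendropy tree."""
    edges = {}
    for node in dtree.preorder_node_iter():
        if node.parent_node is not None:
            edges[node] = (node.parent_node, node.edge.length)
    return edges


def covariance_by_mrca_walk(dtree, taxa):
    """C_ij = root-to-MRCA depth by walking ancestor paths per pair."""
    leaves = {leaf.taxon.label: leaf for leaf in dtree.leaf_node_iter()}
    edges = newick_adjacency(dtree)

    def ancestors(node):
        path = [node]
        while node in edges:
            node = edges[node][0]
            path.append(node)
        return path

    def depth(node):
        d = 0.0
        while node in edges:
            node, ln = edges[node][0], edges[node][1]
            d += ln
        return d

    n = len(taxa)
    C = np.zeros((n, n))
    for i, a in enumerate(taxa):
        anc_a = ancestors(leaves[a])
        C[i, i] = depth(leaves[a])
        for j in range(i + 1, n):
            anc_b = set(ancestors(leaves[taxa[j]]))
            mrca = next(nd for nd in anc_a if nd in anc_b)
            C[i, j] = C[j, i] = depth(mrca)
    return C


def patristic_by_graph_walk(dtree, taxa):
    """D_ij = sum of branch lengths on the tip-to-tip path (via networkx)."""
    import networkx as nx

    G = nx.Graph()
    for node, (parent, length) in newick_adjacency(dtree).items():
        G.add_edge(id(node), id(parent), weight=length)
    leaves = {leaf.taxon.label: id(leaf) for leaf in dtree.leaf_node_iter()}
    n = len(taxa)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = nx.shortest_path_length(G, leaves[taxa[i]], leaves[taxa[j]],
                                    weight="weight")
        D[i, j] = D[j, i] = d
    return D


# ---- Blomberg's K ---------------------------------------------------------

def blomberg_k_dense(C, x):
    """K via explicit matrix inverse, transcribing the defining formulas."""
    n = len(x)
    Ci = np.linalg.inv(C)
    ones = np.ones(n)
    a = (ones @ Ci @ x) / (ones @ Ci @ ones)
    r = x - a
    mse0 = (r @ r) / (n - 1)
    mse = (r @ Ci @ r) / (n - 1)
    expected = (np.trace(C) - n / (ones @ Ci @ ones)) / (n - 1)
    return (mse0 / mse) / expected


def gls_mse_dense(C, x):
    n = len(x)
    Ci = np.linalg.inv(C)
    ones = np.ones(n)
    a = (ones @ Ci @ x) / (ones @ Ci @ ones)
    r = x - a
    return (r @ Ci @ r) / (n - 1)


def exhaustive_permutation_p(C, x):
    """Exact one-tailed permutation P over all n! tip relabelings."""
    obs = gls_mse_dense(C, x)
    perms = list(itertools.permutations(x))
    n_le = sum(gls_mse_dense(C, np.array(p)) <= obs + 1e-12 for p in perms)
    return n_le / len(perms)


# ---- Gaussian model likelihoods ------------------------------------------

def mvn_logpdf(x, mean, Sigma):
    from scipy.stats import multivariate_normal

    return float(multivariate_normal(mean=mean, cov=Sigma).logpdf(x))


def profile_mvn_loglik(x, structure):
    """max_{mu, s2} log N(x; mu 1, s2 * structure) by direct 2-D search."""
    from scipy.optimize import minimize

    n = len(x)

    def nll(theta):
        mu, log_s2 = theta
        return -mvn_logpdf(x, np.full(n, mu), math.exp(log_s2) * structure)

    best = None
    for mu0 in (x.mean(), np.median(x)):
        for ls0 in (-1.0, 0.0, 1.0):
            r = minimize(nll, [mu0, ls0], method="Nelder-Mead",
                         options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
            if best is None or r.fun < best.fun:
                best = r
    return -best.fun


def ou_grid_loglik(C, D, x, alphas):
    """OU profile logL maximized over an explicit alpha grid."""
    best = (-math.inf, None)
    for a in alphas:
        W = np.exp(-a * D) * (1 - np.exp(-2 * a * C)) / (2 * a)
        n = len(x)
        Wi = np.linalg.inv(W)
        ones = np.ones(n)
        mu = (ones @ Wi @ x) / (ones @ Wi @ ones)
        r = x - mu
        s2 = (r @ Wi @ r) / n
        sign, logdet = np.linalg.slogdet(W)
        ll = -0.5 * n * math.log(2 * math.pi * s2) - 0.5 * logdet - 0.5 * n
        if ll > best[0]:
            best = (ll, a)
    return best


# ---- regression -----------------------------------------------------------

def ols_r2(y, X):
    """R^2 of y ~ [1, X] via normal equations with explicit inverse."""
    n = len(y)
    A = np.column_stack([np.ones(n), X])
    beta = np.linalg.inv(A.T @ A) @ (A.T @ y)
    resid = y - A @ beta
    tss = np.sum((y - y.mean()) ** 2)
    return 1.0 - np.sum(resid**2) / tss


def gls_fit_dense(y, X, V):
    """(beta, se, t) by the textbook GLS formulas with explicit inverses."""
    Vi = np.linalg.inv(V)
    XtVi = X.T @ Vi
    cov_beta = np.linalg.inv(XtVi @ X)
    beta = cov_beta @ XtVi @ y
    resid = y - X @ beta
    n, p = X.shape
    s2 = (resid @ Vi @ resid) / (n - p)
    se = np.sqrt(np.diag(s2 * cov_beta))
    return beta, se, beta / se
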