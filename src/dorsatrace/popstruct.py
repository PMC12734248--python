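"""Population structure from genotype likelihoods.

Implements the low-depth evidence stream: a sample-by-sample covariance
matrix estimated by iteratively inferring individual allele frequencies
from genotype likelihoods (so uncertain genotypes contribute their
posterior expectation rather than a hard call), principal components of
that covariance, and a neighbour-joining tree built from the covariance-
derived distance matrix.

The covariance iteration follows the individual-allele-frequency scheme
used for low-coverage sequencing panels:

1. estimate per-site allele frequencies f_j from the GLs by EM;
2. compute posterior expected dosages E[g_ij | GL, π_ij] under a
   Binomial(2, π_ij) prior, starting from π_ij = f_j;
3. form the standardized residuals R_ij = (E[g_ij] − 2 f_j) / √(2 f_j (1 − f_j))
   and the covariance C = R Rᵀ / n_sites;
4. refresh π from the top-k SVD reconstruction of R mapped back to the
   frequency scale, truncated to [ε, 1−ε];
5. repeat until the covariance stabilizes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import skbio

from .formats import GenotypeLikelihoods

logger = logging.getLogger("dorsatrace")

_EPS = 1e-4  # truncation bound for individual allele frequencies


@dataclass
class CovarianceResult:
    """Covariance matrix, principal components and iteration diagnostics."""

    cov: np.ndarray
    pcs: np.ndarray
    explained: np.ndarray
    iterations_run: int
    converged: bool
    individuals: list[str]


def _site_frequencies(gl: np.ndarray, n_iter: int = 50, tol: float = 1e-8) -> np.ndarray:
    """EM estimate of per-site allele frequencies from GL triples."""
    n, m, _ = gl.shape
    f = np.full(m, 0.5)
    dos = np.array([0.0, 1.0, 2.0])
    for _ in range(n_iter):
        prior = np.stack(
            [(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1
        )  # HWE prior per site
        post = gl * prior[None, :, :]
        post /= post.sum(axis=2, keepdims=True)
        f_new = (post @ dos).mean(axis=0) / 2.0
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    return np.clip(f, _EPS, 1 - _EPS)


def _expected_dosage(gl: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Posterior mean dosage under per-individual Binomial(2, π) priors."""
    prior = np.stack([(1 - pi) ** 2, 2 * pi * (1 - pi), pi**2], axis=-1)
    post = gl * prior
    post /= post.sum(axis=2, keepdims=True)
    return post[..., 1] + 2.0 * post[..., 2]


def gl_covariance(
    gls: GenotypeLikelihoods,
    n_components: int = 10,
    max_iter: int = 100,
    tol: float = 1e-5,
) -> CovarianceResult:
    """Estimate the sample covariance matrix from genotype likelihoods.

    Parameters
    ----------
    gls : GenotypeLikelihoods
        Normalized likelihood triples; uninformative (1/3,1/3,1/3)
        triples mark missing data and contribute their posterior
        expectation under the current frequency model.
    n_components : int
        Number of SVD components used for the individual-allele-
        frequency update, and of principal components returned.
    max_iter, tol : int, float
        Iteration cap and convergence tolerance on max |ΔC|.

    Raises
    ------
    ValueError
        On fewer than 2 individuals or no polymorphic sites.
    """
    gl = gls.gl
    n, m, _ = gl.shape
    if n < 2:
        raise ValueError("need at least 2 individuals")

    f = _site_frequencies(gl)
    poly = (f > _EPS) & (f < 1 - _EPS)
    # frequencies at the truncation bound indicate monomorphic sites
    e0 = _expected_dosage(gl, np.broadcast_to(f, (n, m)))
    poly &= e0.std(axis=0) > 0
    if not poly.any():
        raise ValueError("no polymorphic sites in input")
    if not poly.all():
        logger.info("dropping %d monomorphic site(s)", int((~poly).sum()))
        gl = gl[:, poly, :]
        f = f[poly]
        m = int(poly.sum())

    k = min(n_components, n - 1, m)
    scale = np.sqrt(2.0 * f * (1.0 - f))
    pi = np.broadcast_to(f, (n, m)).copy()
    cov_prev = None
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        e = _expected_dosage(gl, pi)
        r = (e - 2.0 * f) / scale
        cov = (r @ r.T) / m
        if cov_prev is not None and np.max(np.abs(cov - cov_prev)) < tol:
            converged = True
            break
        cov_prev = cov
        u, s, vt = np.linalg.svd(r, full_matrices=False)
        r_hat = (u[:, :k] * s[:k]) @ vt[:k]
        pi = np.clip(f + r_hat * scale / 2.0, _EPS, 1 - _EPS)
    if not converged:
        warnings.warn(
            f"gl_covariance did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )

    cov = (cov + cov.T) / 2.0
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = evals[evals > 0].sum()
    n_pc = min(n_components, n)
    pcs = evecs[:, :n_pc] * np.sqrt(np.maximum(evals[:n_pc], 0.0))
    explained = np.maximum(evals[:n_pc], 0.0) / total if total > 0 else np.zeros(n_pc)
    return CovarianceResult(
        cov=cov,
        pcs=pcs,
        explained=explained,
        iterations_run=iterations,
        converged=converged,
        individuals=list(gls.individuals),
    )


def cov_to_distance(cov: np.ndarray) -> np.ndarray:
    """Euclidean-style distance from a covariance matrix.

    d_ij = sqrt(c_ii + c_jj − 2 c_ij); zero diagonal, symmetric.
    """
    c = np.asarray(cov, dtype=float)
    diag = np.diag(c)
    d2 = diag[:, None] + diag[None, :] - 2.0 * c
    d2 = np.maximum(d2, 0.0)
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def nj_tree(dist: np.ndarray, names: list[str]) -> skbio.TreeNode:
    """Neighbour-joining tree (Saitou–Nei) from a distance matrix.

    Classic Q-matrix agglomeration with standard branch-length
    formulas.  Negative branch lengths are clamped to zero with the
    deficit shifted to the sister edge, so path lengths between joined
    tips are preserved.  Exact on additive distance matrices.

    Raises
    ------
    ValueError
        On asymmetric input, non-zero diagonal or duplicate names.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n < 2:
        raise ValueError("distance matrix must be square with n >= 2")
    if len(names) != n or len(set(names)) != n:
        raise ValueError("names must be unique and match matrix size")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-9):
        raise ValueError("distance matrix must have zero diagonal")
    if np.any(d < -1e-12):
        raise ValueError("distances must be non-negative")

    nodes = [skbio.TreeNode(name=nm) for nm in names]
    if n == 2:
        root = skbio.TreeNode()
        for node in nodes:
            node.length = d[0, 1] / 2.0
            root.append(node)
        return root

    d = d.copy()
    active = list(range(n))
    while len(active) > 3:
        sub = d[np.ix_(active, active)]
        na = len(active)
        r = sub.sum(axis=1)
        q = (na - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_s, j_s = np.unravel_index(np.argmin(q), q.shape)
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        gi, gj = active[i_s], active[j_s]
        dij = sub[i_s, j_s]
        bi = 0.5 * dij + (r[i_s] - r[j_s]) / (2.0 * (na - 2))
        bj = dij - bi
        # clamp negatives, shifting the deficit to the sister edge
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        parent = skbio.TreeNode()
        nodes[gi].length = max(bi, 0.0)
        nodes[gj].length = max(bj, 0.0)
        parent.append(nodes[gi])
        parent.append(nodes[gj])

        du = 0.5 * (sub[i_s, :] + sub[j_s, :] - dij)
        d_new = np.append(d, np.zeros((1, d.shape[1])), axis=0)
        d_new = np.append(d_new, np.zeros((d_new.shape[0], 1)), axis=1)
        new_idx = d.shape[0]
        for t, gt_ in enumerate(active):
            d_new[new_idx, gt_] = d_new[gt_, new_idx] = du[t]
        d_new[new_idx, new_idx] = 0.0
        d = d_new
        nodes.append(parent)
        active = [g for g in active if g not in (gi, gj)] + [new_idx]

    # resolve the final three nodes around an unrooted center
    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    root = skbio.TreeNode()
    lengths = {
        a: 0.5 * (dab + dac - dbc),
        b: 0.5 * (dab + dbc - dac),
        c: 0.5 * (dac + dbc - dab),
    }
    for g in (a, b, c):
        nodes[g].length = max(lengths[g], 0.0)
        root.append(nodes[g])
    return root
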