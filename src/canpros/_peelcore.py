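"""Low-level contraction kernels for pedigree peeling.

The joint transmission tensor over the factored state space is never
materialised: ``T(c|f,m) = prod_i T_i(c_i|f_i, m_i)`` and the two directions
of the Elston-Stewart recursion are sequences of per-factor tensor
contractions (each reducible to a matrix product).  Both kernels accept an
arbitrary leading batch shape so that many nuclear families can be peeled in
one call.
"""

from __future__ import annotations

import numpy as np


def transmit_up(vec, factor_trans):
    """``M[..., f, m] = sum_c T(c|f,m) vec[..., c]``.

    ``vec`` has shape ``batch + (S,)``; the result ``batch + (S, S)`` with
    flat parental-state axes.
    """
    dims = tuple(t.shape[0] for t in factor_trans)
    S = int(np.prod(dims))
    batch = vec.shape[:-1]
    R = vec.reshape(batch + dims)
    nb = len(batch)
    for T in factor_trans:
        # contract the leading state axis; tensordot appends (f_i, m_i)
        R = np.tensordot(R, T, axes=([nb], [0]))
    # axes now: batch, f1, m1, f2, m2, ...
    k = len(dims)
    perm = list(range(nb)) + [nb + 2 * i for i in range(k)] + [nb + 2 * i + 1 for i in range(k)]
    R = np.transpose(R, perm)
    return np.ascontiguousarray(R).reshape(batch + (S, S))


def transmit_down(mat, factor_trans):
    """``v[..., c] = sum_{f,m} T(c|f,m) mat[..., f, m]``.

    ``mat`` has shape ``batch + (S, S)``; result ``batch + (S,)``.
    """
    dims = tuple(t.shape[0] for t in factor_trans)
    batch = mat.shape[:-2]
    nb = len(batch)
    k = len(dims)
    R = mat.reshape(batch + dims + dims)
    # interleave to (batch, f1, m1, f2, m2, ...)
    perm = list(range(nb))
    for i in range(k):
        perm += [nb + i, nb + k + i]
    R = np.transpose(R, perm)
    for T in factor_trans:
        # contract (f_i, m_i) at the current leading positions; the child
        # axis c_i is appended at the end
        R = np.tensordot(R, T, axes=([nb, nb + 1], [1, 2]))
    return np.ascontiguousarray(R).reshape(batch + (int(np.prod(dims)),))


def parent_child_kernels(factor_trans, factor_priors):
    """Per-factor kernels ``K_i[c, f] = sum_m T_i(c|f,m) prior_i(m)``.

    Marginalises an uninformative mother, leaving the child distribution
    given the father's factor state.
    """
    return [np.einsum("cfm,m->cf", T, p) for T, p in zip(factor_trans, factor_priors)]


def sibling_kernels(factor_trans, factor_priors):
    """Per-factor joint sibling distributions with parents integrated out:
    ``P_i[b, c] = sum_{f,m} prior(f) prior(m) T(b|f,m) T(c|f,m)``."""
    return [np.einsum("bfm,cfm,f,m->bc", T, T, p, p)
            for T, p in zip(factor_trans, factor_priors)]


def contract_kernels(w, kernels):
    """``v[..., c] = sum_s w[..., s] prod_i K_i[c_i, s_i]`` (factored).

    Contracts a non-factorised state vector against a Kronecker-structured
    kernel without materialising the joint matrix.
    """
    dims = tuple(k.shape[1] for k in kernels)
    batch = w.shape[:-1]
    nb = len(batch)
    R = w.reshape(batch + dims)
    for K in kernels:
        R = np.tensordot(R, K, axes=([nb], [1]))  # contract s_i, append c_i
    return np.ascontiguousarray(R).reshape(batch + (int(np.prod(dims)),))


def nuclear_loglik(lf, lm, children, factor_trans, prior):
    """Log-likelihood of independent nuclear families, batched.

    ``lf``/``lm``: (B, S) parental likelihood vectors (founder priors NOT yet
    applied); ``children``: (B, n_c, S) child likelihood vectors; returns
    (B,) log-likelihoods ``log sum_{fs,ms} prior(fs) lf(fs) prior(ms) lm(ms)
    prod_c sum_cs T(cs|fs,ms) child_c(cs)``.
    """
    B, nc, S = children.shape
    acc = None
    for c in range(nc):
        M = transmit_up(children[:, c, :], factor_trans)
        acc = M if acc is None else acc * M
    pf = prior[None, :] * lf
    pm = prior[None, :] * lm
    if acc is None:
        return np.log(pf.sum(axis=1)) + np.log(pm.sum(axis=1))
    tot = np.einsum("bf,bfm,bm->b", pf, acc, pm)
    return np.log(tot)


def nuclear_message(lf, lm, siblings, factor_trans, prior):
    """Transmission message onto one child of a nuclear family, batched.

    ``lf``/``lm``: (B, S) parental likelihoods (founder priors applied
    here); ``siblings``: (B, n_s, S) likelihoods of the other children (or
    None).  Returns (B, S): ``sum_{f,m} prior(f) lf(f) prior(m) lm(m)
    prod_j [sum_b T(b|f,m) sib_j(b)] T(c|f,m)``.
    """
    B, S = lf.shape
    acc = np.ones((B, S, S))
    if siblings is not None and siblings.shape[1] > 0:
        for c in range(siblings.shape[1]):
            acc *= transmit_up(siblings[:, c, :], factor_trans)
    acc *= (prior[None, :] * lf)[:, :, None]
    acc *= (prior[None, :] * lm)[:, None, :]
    return transmit_down(acc, factor_trans)


def nuclear_posterior(lf, lm, siblings, target_lik, factor_trans, prior):
    """Posterior state distribution of one child per nuclear family, batched.

    ``target_lik``: (B, S) the target child's own likelihood (its prior is
    supplied by the transmission).  Returns (B, S) normalised posteriors.
    """
    msg = nuclear_message(lf, lm, siblings, factor_trans, prior)
    post = msg * target_lik
    tot = post.sum(axis=1, keepdims=True)
    return post / tot
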