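"""Independent brute-force oracles for pedigree likelihoods.

These enumerate the full joint state space directly from the factor priors
and per-factor transmission tables, deliberately sharing no code with the
peeling recursion they are used to check.  Suitable for small pedigrees on
reduced state spaces (cost S**n_members).
"""

import math

import numpy as np


def joint_transmission(space, sf, sm):
    """P(child = . | father sf, mother sm) by direct per-factor products."""
    f = np.unravel_index(sf, space.dims)
    m = np.unravel_index(sm, space.dims)
    out = np.ones(1)
    for i, T in enumerate(space.factor_trans):
        out = np.kron(out, T[:, f[i], m[i]])
    return out


def _dense_joint_transmission(space):
    S = space.n_states
    T = np.empty((S, S, S))
    for sf in range(S):
        for sm in range(S):
            T[:, sf, sm] = joint_transmission(space, sf, sm)
    return T


def _joint_terms(ped, space, liks):
    """(n_combos,) joint probability x likelihood for every state combo."""
    ids = [ind.id for ind in ped]
    n = len(ids)
    S = space.n_states
    pos = {id_: i for i, id_ in enumerate(ids)}
    idx = np.indices((S,) * n).reshape(n, -1)
    T = _dense_joint_transmission(space)
    p = np.ones(idx.shape[1])
    for ind in ped:
        s = idx[pos[ind.id]]
        if ind.is_founder:
            p = p * space.prior[s]
        else:
            p = p * T[s, idx[pos[ind.father_id]], idx[pos[ind.mother_id]]]
        p = p * np.asarray(liks[ind.id])[s]
    return idx, p


def enumerate_loglik(ped, space, liks):
    """Exact log-likelihood by summation over all members' joint states."""
    _, p = _joint_terms(ped, space, liks)
    total = p.sum()
    return math.log(total) if total > 0 else -math.inf


def enumerate_posterior(ped, space, liks, target):
    """Exact posterior over the target's states by enumeration."""
    ids = [ind.id for ind in ped]
    idx, p = _joint_terms(ped, space, liks)
    t = ids.index(target)
    post = np.bincount(idx[t], weights=p, minlength=space.n_states)
    return post / post.sum()
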