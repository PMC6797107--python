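"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the transportation
problem is solved as an explicit linear program, and single-event Bayes
posteriors are recomputed by direct enumeration over hand-held histograms.
"""

import numpy as np
from scipy.optimize import linprog


def transport_lp(p, q, cost):
    """Optimal-transport cost between mass vectors p, q for a cost matrix.

    Solves  min sum_ij c_ij f_ij  s.t. row sums = p, column sums = q, f >= 0
    with the HiGHS LP solver.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    n, m = p.size, q.size
    c = np.asarray(cost, float).reshape(n * m)
    a_eq = np.zeros((n + m, n * m))
    for i in range(n):
        a_eq[i, i * m:(i + 1) * m] = 1.0
    for j in range(m):
        a_eq[n + j, j::m] = 1.0
    b_eq = np.concatenate([p, q])
    res = linprog(c, A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    assert res.status == 0, res.message
    return float(res.fun)


def emd_lp_1d(p_mass, q_mass, centers):
    """1-D EMD via the transportation LP with |center_i - center_j| costs."""
    cost = np.abs(centers[:, None] - centers[None, :])
    return transport_lp(p_mass, q_mass, cost)


def brute_force_posterior(bin_indices, masses, prior):
    """Single-event Bayes posterior by direct enumeration.

    ``masses[r][o]`` is the per-bin mass array of relation r, observable o;
    ``bin_indices[o]`` the event's bin per observable.  Returns the
    normalized posterior, or the uniform vector when all likelihoods vanish.
    """
    n_rel = len(masses)
    like = np.ones(n_rel)
    for r in range(n_rel):
        for o, k in enumerate(bin_indices):
            like[r] *= masses[r][o][k]
    unnorm = like * np.asarray(prior, float)
    if unnorm.sum() == 0:
        return np.full(n_rel, 1.0 / n_rel)
    return unnorm / unnorm.sum()
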