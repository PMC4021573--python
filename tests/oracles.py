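"""Independent brute-force oracles used to cross-check the implementation.

Everything here works directly from the multivariate-normal formulation of
Brownian motion (dense covariance matrices, explicit inverses) or from
exhaustive enumeration, deliberately avoiding the recursive/rerooting code
paths under test.
"""

from itertools import combinations

import numpy as np

from copynorm.signal import brownian_covariance


def gls_root_state(tree, traits):
    """ML root state under Brownian motion via generalized least squares."""
    C, labels = brownian_covariance(tree)
    x = np.array([traits[l] for l in labels])
    Ci = np.linalg.inv(C)
    one = np.ones(len(labels))
    return float(one @ Ci @ x / (one @ Ci @ one))


def gls_tip_prediction(tree, traits, query):
    """Conditional expectation of an unobserved tip under Brownian motion.

    Uses the full-tree covariance: mu + c' C_oo^{-1} (x - mu 1), with mu the
    GLS mean over the observed tips and c the covariances between the query
    and the observed tips.
    """
    C, labels = brownian_covariance(tree)
    qi = labels.index(query)
    obs = [i for i, l in enumerate(labels) if l in traits]
    x = np.array([traits[labels[i]] for i in obs])
    Coo = C[np.ix_(obs, obs)]
    c = C[qi, obs]
    Ci = np.linalg.inv(Coo)
    one = np.ones(len(obs))
    mu = float(one @ Ci @ x / (one @ Ci @ one))
    return float(mu + c @ Ci @ (x - mu))


def exact_mannwhitney_p(x, y, alternative="less"):
    """Exact Mann-Whitney p-value by enumerating all group assignments.

    Valid for untied data; counts, over all C(n+m, n) ways of labelling the
    pooled values, how extreme the observed U is.
    """
    x, y = list(x), list(y)
    pooled = x + y
    n = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    us = [u_stat([pooled[i] for i in idx],
                 [pooled[i] for i in range(len(pooled)) if i not in idx])
          for idx in combinations(range(len(pooled)), n)]
    us = np.array(us)
    if alternative == "less":
        return float(np.mean(us <= u_obs))
    if alternative == "greater":
        return float(np.mean(us >= u_obs))
    p = 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return float(min(1.0, p))


def grid_lambda(tree, traits, step=0.01):
    """Grid-search ML estimate of Pagel's lambda (brute force)."""
    C, labels = brownian_covariance(tree)
    x = np.array([traits[l] for l in labels])
    n = len(x)
    best = (None, -np.inf)
    for lam in np.arange(0.0, 1.0 + step / 2, step):
        V = lam * C
        np.fill_diagonal(V, np.diag(C))
        Vi = np.linalg.inv(V)
        one = np.ones(n)
        mu = one @ Vi @ x / (one @ Vi @ one)
        r = x - mu
        s2 = r @ Vi @ r / n
        _, logdet = np.linalg.slogdet(V)
        ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
        if ll > best[1]:
            best = (lam, ll)
    return best
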