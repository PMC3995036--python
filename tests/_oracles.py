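"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the likelihood is
maximized by a generic numerical optimizer over an unconstrained
reparameterization, and the rank statistic is computed straight from its
textbook formula.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm, rankdata


def two_component_nll(theta, z):
    """Negative pooled log-likelihood of the equal-variance 2-component mixture.

    theta = (mu1, mu2, log sigma, logit tau1); labels unconstrained.
    """
    mu1, mu2, ls, lt = theta
    sigma = np.exp(ls)
    t1 = expit(lt)
    a = np.stack(
        [
            np.log(t1) + norm.logpdf(z, mu1, sigma),
            np.log1p(-t1) + norm.logpdf(z, mu2, sigma),
        ],
        axis=1,
    )
    return -float(logsumexp(a, axis=1).sum())


def direct_mle_loglik(z, n_starts=10, seed=0):
    """Best 2-component equal-variance mixture log-likelihood found by a
    generic optimizer from multiple random starts."""
    rng = np.random.default_rng(seed)
    z = np.asarray(z, dtype=float)
    s = z.std() if z.std() > 0 else 1.0
    best = -np.inf
    for i in range(n_starts):
        if i == 0:
            x0 = np.array([z.mean() - s, z.mean() + s, np.log(s), 0.0])
        else:
            x0 = np.array(
                [
                    rng.choice(z),
                    rng.choice(z),
                    np.log(s) + rng.normal(0, 0.5),
                    rng.normal(0, 1.5),
                ]
            )
        res = minimize(
            two_component_nll, x0, args=(z,), method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12},
        )
        best = max(best, -res.fun)
    return best


def kruskal_wallis_hand(values, labels):
    """Tie-corrected Kruskal-Wallis H from the textbook rank formula."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    n = values.size
    ranks = rankdata(values)
    H = 0.0
    for g in np.unique(labels):
        r = ranks[labels == g]
        H += r.sum() ** 2 / r.size
    H = 12.0 / (n * (n + 1)) * H - 3.0 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return H / tie
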