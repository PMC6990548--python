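"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: a direct
Cox-de Boor recursion for B-spline evaluation and a dense 2-D grid
quadrature of the exact logistic posterior.
"""

import numpy as np


def cox_de_boor(x, t, i, k):
    """B_{i,k}(x) on knot vector t by the textbook recursion (0/0 := 0)."""
    if k == 0:
        if t[i] <= x < t[i + 1]:
            return 1.0
        if x == t[-1] and t[i] < t[i + 1] and t[i + 1] == t[-1]:
            return 1.0
        return 0.0
    left = 0.0
    if t[i + k] != t[i]:
        left = (x - t[i]) / (t[i + k] - t[i]) * cox_de_boor(x, t, i, k - 1)
    right = 0.0
    if t[i + k + 1] != t[i + 1]:
        right = (t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1]) * cox_de_boor(x, t, i + 1, k - 1)
    return left + right


def bspline_matrix_recursive(x_values, knots, degree):
    """Dense design matrix with clamped boundary knots via cox_de_boor."""
    t = np.r_[np.full(degree, knots[0]), knots, np.full(degree, knots[-1])]
    n_basis = len(t) - degree - 1
    return np.array(
        [[cox_de_boor(x, t, i, degree) for i in range(n_basis)] for x in x_values]
    )


def logistic_posterior_grid(y, x, prior_var=1000.0, half_width=5.0, n_grid=401):
    """Exact posterior moments of (b0, b1) for y ~ Bernoulli(logit = b0 + b1 x)
    under independent N(0, prior_var) priors, by dense grid quadrature."""
    b0 = np.linspace(-half_width, half_width, n_grid)
    b1 = np.linspace(-half_width, half_width, n_grid)
    B0, B1 = np.meshgrid(b0, b1, indexing="ij")
    eta = B0[..., None] + B1[..., None] * x
    log_post = (y * eta - np.logaddexp(0.0, eta)).sum(-1) - (B0**2 + B1**2) / (2 * prior_var)
    w = np.exp(log_post - log_post.max())
    w /= w.sum()
    m0, m1 = (w * B0).sum(), (w * B1).sum()
    s0 = np.sqrt((w * (B0 - m0) ** 2).sum())
    s1 = np.sqrt((w * (B1 - m1) ** 2).sum())
    return np.array([m0, m1]), np.array([s0, s1])
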