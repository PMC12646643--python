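"""Independent oracles for the telegraph model, sharing no code with the
package's solver path.

- ``beta_poisson_pmf``: the analytic stationary law (Poisson mixed over a
  Beta(kon, koff) promoter-activity density with intensity ksyn*b), computed
  by Gauss-Jacobi quadrature whose weight function absorbs the Beta density
  endpoint singularities.
- ``ssa_samples``: Gillespie stochastic simulation of the reaction system,
  sampled at decorrelated times after burn-in.
- ``enumerate_rate_matrix``: dense generator built by looping over every
  state and firing each reaction individually.
"""

import numpy as np
from numba import njit
from scipy.special import betaln, gammaln, roots_jacobi


def beta_poisson_pmf(kon, koff, ksyn, K, order=400):
    """P(x) for x in 0..K-1 of the telegraph stationary law.

    Moderate shapes use Gauss-Jacobi quadrature; large shapes (where the
    Jacobi recurrence loses accuracy) use the exact confluent-hypergeometric
    form in arbitrary precision.
    """
    if max(kon, koff) > 50:
        return _beta_poisson_hyp1f1(kon, koff, ksyn, K)
    t, w = roots_jacobi(order, koff - 1.0, kon - 1.0)
    b = (t + 1.0) / 2.0
    lam = ksyn * b
    x = np.arange(K)[:, None]
    logpois = (
        x * np.log(np.maximum(lam[None, :], 1e-300)) - lam[None, :] - gammaln(x + 1)
    )
    const = -(kon + koff - 1) * np.log(2.0) - betaln(kon, koff)
    return np.exp(const) * (np.exp(logpois) @ w)


def _beta_poisson_hyp1f1(kon, koff, ksyn, K):
    import mpmath as mp

    with mp.workdps(30):
        out = np.empty(K)
        for x in range(K):
            v = (
                mp.gamma(kon + x) / mp.gamma(kon)
                * mp.gamma(kon + koff) / mp.gamma(kon + koff + x)
                * mp.power(ksyn, x) / mp.factorial(x)
                * mp.hyp1f1(kon + x, kon + koff + x, -ksyn)
            )
            out[x] = float(v)
    return out


@njit(cache=False)
def ssa_samples(kon, koff, ksyn, n_samples, burn_in, spacing, seed):
    """mRNA copy numbers sampled every ``spacing`` time units at steady state."""
    np.random.seed(seed)
    g = 0  # 0 inactive, 1 active
    x = 0
    t = 0.0
    next_sample = burn_in
    out = np.empty(n_samples, dtype=np.int64)
    filled = 0
    while filled < n_samples:
        a_switch = kon if g == 0 else koff
        a_syn = ksyn if g == 1 else 0.0
        a_deg = float(x)
        a_tot = a_switch + a_syn + a_deg
        dt = -np.log(np.random.random()) / a_tot
        # record the state that holds across any sampling times in (t, t+dt)
        while filled < n_samples and next_sample <= t + dt:
            out[filled] = x
            filled += 1
            next_sample += spacing
        t += dt
        u = np.random.random() * a_tot
        if u < a_switch:
            g = 1 - g
        elif u < a_switch + a_syn:
            x += 1
        else:
            x -= 1
    return out


def enumerate_rate_matrix(kon, koff, ksyn, M):
    """Dense generator by explicit reaction enumeration over all states.

    State index = promoter * (M + 1) + x, promoter 0 = inactive.
    """
    n = M + 1
    A = np.zeros((2 * n, 2 * n))

    def fire(src, dst, rate):
        A[dst, src] += rate
        A[src, src] -= rate

    for g in (0, 1):
        for x in range(n):
            s = g * n + x
            # promoter switch
            fire(s, (1 - g) * n + x, kon if g == 0 else koff)
            # synthesis (active only, reflecting at x = M)
            if g == 1 and x < M:
                fire(s, s + 1, ksyn)
            # degradation
            if x > 0:
                fire(s, s - 1, float(x))
    return A
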