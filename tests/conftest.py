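import numpy as np
import pytest

from admixsel.popdata import AdmixtureMatrix, PopulationCounts


@pytest.fixture(scope="session")
def m_pooled():
    """k=1: every population is the same source (pooled-frequency null)."""
    return AdmixtureMatrix(M=[[1.0], [1.0]])


@pytest.fixture(scope="session")
def m_two_source():
    """Two pure populations plus a 50/50 admixed one."""
    return AdmixtureMatrix(M=[[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])


@pytest.fixture(scope="session")
def m_five_pop():
    """Five populations over two sources, the default synthetic region."""
    return AdmixtureMatrix(
        M=[[1, 0], [0, 1], [0.7, 0.3], [0.3, 0.7], [0.5, 0.5]],
        population_labels=("P1", "P2", "P3", "P4", "P5"),
    )


@pytest.fixture(scope="session")
def counts_37():
    return PopulationCounts("v1", x=[3, 7], N=[10, 10])


def grid_fit_null(x, N, M, coarse=41, fine=21):
    """Independent brute-force oracle for the constrained null fit.

    Two-stage dense grid search over the box [0,1]^k: a coarse lattice
    followed by a fine lattice around the coarse optimum.  Uses only
    direct evaluation of the binomial log-likelihood.
    """
    x = np.asarray(x, float)
    N = np.asarray(N, float)
    M = np.asarray(M, float)
    k = M.shape[1]

    def ll_of(Q):
        F = Q @ M.T
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(x > 0, x * np.log(F), 0.0)
            t2 = np.where(N - x > 0, (N - x) * np.log(1 - F), 0.0)
        ll = np.sum(np.where(N > 0, t1 + t2, 0.0), axis=1)
        return np.where(np.isfinite(ll), ll, -np.inf)

    axes = [np.linspace(0, 1, coarse)] * k
    Q = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, k)
    ll = ll_of(Q)
    best = Q[np.argmax(ll)]
    best_ll = float(np.max(ll))
    # pattern-search refinement: a local lattice of span +-h around the
    # incumbent; re-center while the optimum sits on the lattice edge
    # (ridge following), shrink once it is interior
    h = 1.0 / (coarse - 1)
    for _ in range(200):
        if h < 1e-6:
            break
        axes = [np.linspace(max(b - h, 0.0), min(b + h, 1.0), fine) for b in best]
        Q = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, k)
        ll = ll_of(Q)
        i = int(np.argmax(ll))
        cand = Q[i]
        on_edge = any(
            not np.isclose(c, 0.0) and not np.isclose(c, 1.0)
            and (np.isclose(c, ax[0]) or np.isclose(c, ax[-1]))
            for c, ax in zip(cand, axes)
        )
        if ll[i] > best_ll:
            best, best_ll = cand, float(ll[i])
        if not on_edge:
            h = 2.0 * h / (fine - 1)
    return best, best_ll
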