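import numpy as np
import pytest

import dissipy as d


@pytest.fixture
def chain20():
    return d.synth_structure(20, "chain")


@pytest.fixture
def chain20_net(chain20):
    return d.build_network(chain20, cutoff=4.0, stiffness=1.0)


@pytest.fixture
def globule60():
    return d.synth_structure(60, "globule", seed=5)


@pytest.fixture
def globule60_net(globule60):
    return d.build_network(globule60, cutoff=8.0, stiffness=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_curve(response_times, grid):
    """Independent oracle: direct enumeration of NR(t)."""
    out = []
    for t in grid:
        out.append(sum(1 for dt in response_times
                       if np.isfinite(dt) and dt <= t))
    return np.array(out)


def naive_verlet(masses, springs, x0, v0, dt, n_steps):
    """Independent brute-force velocity-Verlet integrator (pure loops).

    springs: list of (i, j, k_kcal, r0).  Returns final (x, v) plus the
    trajectory of positions saved every step.
    """
    from dissipy.units import KCAL_MOL_TO_INTERNAL

    x = [list(map(float, p)) for p in x0]
    v = [list(map(float, p)) for p in v0]
    n = len(x)

    def forces():
        f = [[0.0, 0.0, 0.0] for _ in range(n)]
        for (i, j, k, r0) in springs:
            dvec = [x[j][c] - x[i][c] for c in range(3)]
            r = sum(c * c for c in dvec) ** 0.5
            coef = k * KCAL_MOL_TO_INTERNAL * (r - r0) / r
            for c in range(3):
                f[i][c] += coef * dvec[c]
                f[j][c] -= coef * dvec[c]
        return f

    f = forces()
    traj = [np.array(x)]
    for _ in range(n_steps):
        for i in range(n):
            for c in range(3):
                v[i][c] += 0.5 * dt * f[i][c] / masses[i]
                x[i][c] += dt * v[i][c]
        f = forces()
        for i in range(n):
            for c in range(3):
                v[i][c] += 0.5 * dt * f[i][c] / masses[i]
        traj.append(np.array(x))
    return np.array(x), np.array(v), traj
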