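"""Synthetic fixtures: toy structures, model curves with known truth,
and block annotations.

Every generator is a pure function of its arguments (seed included), so
fixtures are bit-reproducible and never need to be shipped as files.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import GenerationError, SpecError
from .fitting import boltzmann_nr, lorentz_delta
from .modules import DifferenceCurve
from .response import DissipationCurve
from .structures import ProteinStructure, RegionAnnotation, Residue

#: Default residue spacing for the straight-chain fixture, Angstrom.
CHAIN_SPACING = 3.8

# ideal alpha-helix C-alpha trace geometry
HELIX_RISE = 1.5      # Angstrom per residue
HELIX_TWIST = 100.0   # degrees per residue
HELIX_RADIUS = 2.3    # Angstrom

# self-avoiding globule: minimum bead separation and nominal packing
GLOBULE_MIN_SEP = 3.5
GLOBULE_PACKING = 0.3


def _make_structure(positions: np.ndarray, source_id: str) -> ProteinStructure:
    residues = [
        Residue(index=i + 1, name="ALA", chain_id="A", mass=110.0, position=p)
        for i, p in enumerate(positions)
    ]
    return ProteinStructure(residues=residues, source_id=source_id)


def synth_structure(n: int, kind: str = "chain", *, spacing: float = CHAIN_SPACING,
                    seed: int = 0) -> ProteinStructure:
    """Generate a toy structure: "chain", "helix" or "globule".

    chain: collinear beads along x at `spacing`.  helix: ideal
    alpha-helical C-alpha trace.  globule: self-avoiding random
    placement (minimum separation 3.5 A) inside a sphere; deterministic
    under `seed`.
    """
    if n < 2:
        raise SpecError("need n >= 2 residues")
    if kind == "chain":
        pos = np.zeros((n, 3))
        pos[:, 0] = spacing * np.arange(n)
    elif kind == "helix":
        theta = np.deg2rad(HELIX_TWIST) * np.arange(n)
        pos = np.column_stack([
            HELIX_RADIUS * np.cos(theta),
            HELIX_RADIUS * np.sin(theta),
            HELIX_RISE * np.arange(n),
        ])
    elif kind == "globule":
        pos = _globule_positions(n, seed)
    else:
        raise SpecError(f"unknown structure kind {kind!r}")
    return _make_structure(pos, source_id=f"synth-{kind}-{n}")


def _globule_positions(n: int, seed: int, max_retries: int = 20000) -> np.ndarray:
    rng = np.random.default_rng(seed)
    # sphere radius for the nominal packing fraction with beads of
    # radius min_sep/2 (random sequential addition saturates near 0.38,
    # so the nominal packing must stay well below that)
    radius = 0.5 * GLOBULE_MIN_SEP * (n / GLOBULE_PACKING) ** (1.0 / 3.0)
    placed: list[np.ndarray] = []
    tries = 0
    while len(placed) < n:
        if tries >= max_retries:
            raise GenerationError(
                f"could not place {n} beads at min separation "
                f"{GLOBULE_MIN_SEP} A within radius {radius:.1f} A "
                f"after {max_retries} tries"
            )
        tries += 1
        p = rng.uniform(-radius, radius, size=3)
        if p @ p > radius * radius:
            continue
        if placed and np.min(np.linalg.norm(np.array(placed) - p, axis=1)) < GLOBULE_MIN_SEP:
            continue
        placed.append(p)
    return np.array(placed)


def synth_boltzmann_curve(nr1: float, nr2: float, t0: float, dt: float, *,
                          n_points: int = 200,
                          t_range: tuple[float, float] = (0.0, 1000.0),
                          noise_sd: float = 0.0, integerize: bool = False,
                          seed: int = 0) -> DissipationCurve:
    """Sample the sigmoid on a uniform grid, with optional noise.

    With `integerize` the samples are rounded, clamped to [NR1, NR2] and
    monotonized by cumulative max (a count curve must be non-decreasing).
    The generating truth is kept in `meta["truth"]`.
    """
    if n_points < 5:
        raise SpecError("need at least 5 points")
    t = np.linspace(t_range[0], t_range[1], n_points)
    y = boltzmann_nr(t, nr1, nr2, t0, dt)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=n_points)
    if integerize:
        y = np.maximum.accumulate(np.clip(np.rint(y), nr1, nr2))
    return DissipationCurve(
        times=t, nr=y,
        meta={"truth": {"nr1": nr1, "nr2": nr2, "t0": t0, "dt": dt,
                        "noise_sd": noise_sd, "integerize": integerize,
                        "seed": seed}},
    )


def synth_lorentz_curve(nr0: float, tc: float, w: float, a: float, *,
                        n_points: int = 200,
                        t_range: tuple[float, float] = (0.0, 1000.0),
                        noise_sd: float = 0.0, seed: int = 0) -> DifferenceCurve:
    """Sample the Lorentzian peak on a uniform grid, with optional noise."""
    if n_points < 6:
        raise SpecError("need at least 6 points")
    t = np.linspace(t_range[0], t_range[1], n_points)
    y = lorentz_delta(t, nr0, tc, w, a)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=n_points)
    return DifferenceCurve(
        times=t, delta_nr=y,
        meta={"truth": {"nr0": nr0, "tc": tc, "w": w, "a": a,
                        "noise_sd": noise_sd, "seed": seed}},
    )


def synth_annotation(n: int, boundaries: list[float],
                     labels: list[str]) -> RegionAnnotation:
    """Contiguous block annotation from cumulative fractions.

    boundaries are increasing fractions in (0, 1]; block k ends at
    residue round(n * boundaries[k]) with half-down tie breaking.
    """
    if len(boundaries) != len(labels):
        raise SpecError("boundaries and labels must have equal length")
    if not boundaries:
        raise SpecError("need at least one boundary")
    prev = 0.0
    for b in boundaries:
        if not (prev < b <= 1.0):
            raise SpecError("boundaries must be increasing and in (0, 1]")
        prev = b
    mapping: dict[int, str] = {}
    start = 1
    for frac, label in zip(boundaries, labels):
        end = int(math.ceil(n * frac - 0.5))  # nearest integer, half rounds down
        end = min(max(end, start - 1), n)
        for i in range(start, end + 1):
            mapping[i] = label
        start = end + 1
    order = list(dict.fromkeys(labels))
    return RegionAnnotation(labels=mapping, n_residues=n, label_order=order)


def synth_variant_network(network, residues, stiffness_factor: float = 0.5):
    """Mutant surrogate: scale the stiffness of all springs incident on
    the given residues (1-based) by `stiffness_factor`.

    Returns a new network; the input is untouched.
    """
    from dataclasses import replace

    idx0 = {int(i) - 1 for i in residues}
    if any(i < 0 or i >= network.n_beads for i in idx0):
        raise SpecError("variant residue index outside the network")
    k = network.stiffness.copy()
    touched = np.fromiter(
        ((i in idx0 or j in idx0)
         for i, j in zip(network.spring_i, network.spring_j)),
        dtype=bool, count=network.n_springs,
    )
    k[touched] *= stiffness_factor
    return replace(network, stiffness=k)
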