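"""Response-time detection and the cumulative dissipation curve.

The perturbed-minus-reference energy difference is scanned residue by
residue: a residue "responds" at the earliest frame where |dE| stays at
or above an effective threshold for a run of consecutive frames.
Perturbed residues respond at t = 0 by definition.  The dissipation
curve NR(t) counts responded residues over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, PolicyError
from .enm import EnergyTrace
from .structures import RegionAnnotation

NONRESPONSIVE = float("nan")


@dataclass
class DeltaEnergyTrace:
    """Perturbed minus reference per-residue energies."""

    times: np.ndarray   # (F,) fs
    delta: np.ndarray   # (N, F) kcal/mol

    @property
    def n_residues(self) -> int:
        return self.delta.shape[0]


@dataclass
class DetectionPolicy:
    """Threshold-and-sustain response criterion.

    mode "absolute": a residue responds when |dE| >= threshold for
    `sustain` consecutive saved frames.  mode "relative": the threshold
    for residue i is `noise_multiplier` times that residue's null-noise
    scale (population SD of its row in a control f=1 delta trace).
    """

    threshold: float = 0.1       # kcal/mol (absolute mode)
    sustain: int = 3             # consecutive frames
    mode: str = "absolute"       # "absolute" | "relative"
    noise_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "relative"):
            raise PolicyError(f"unknown detection mode {self.mode!r}")
        if self.sustain < 1:
            raise PolicyError("sustain must be >= 1")
        if self.mode == "absolute" and self.threshold <= 0:
            raise PolicyError("threshold must be > 0")
        if self.mode == "relative" and self.noise_multiplier <= 0:
            raise PolicyError("noise_multiplier must be > 0")

    def describe(self) -> dict:
        return {
            "mode": self.mode,
            "threshold": self.threshold,
            "sustain": self.sustain,
            "noise_multiplier": self.noise_multiplier,
        }


@dataclass
class ResponseProfile:
    """Response time per residue (NaN = nonresponsive), plus the perturbed set."""

    response_times: np.ndarray        # (N,) fs; NaN for nonresponsive
    perturbed: frozenset[int]         # 1-based indices
    policy: dict = field(default_factory=dict)

    @property
    def n_residues(self) -> int:
        return len(self.response_times)

    def is_responsive(self) -> np.ndarray:
        return np.isfinite(self.response_times)

    @property
    def n_responsive(self) -> int:
        return int(self.is_responsive().sum())


@dataclass
class DissipationCurve:
    """NR(t): cumulative count of responded residues on a time grid."""

    times: np.ndarray
    nr: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.nr = np.asarray(self.nr)
        if self.times.shape != self.nr.shape:
            raise AlignmentError("times and NR must have equal length")


def delta_energy(perturbed: EnergyTrace,
                 reference: EnergyTrace) -> DeltaEnergyTrace:
    """Elementwise perturbed - reference; grids must match exactly."""
    if perturbed.energies.shape != reference.energies.shape:
        raise AlignmentError(
            f"trace shapes differ: {perturbed.energies.shape} vs "
            f"{reference.energies.shape}"
        )
    if not np.array_equal(perturbed.times, reference.times):
        raise AlignmentError("trace time grids differ")
    return DeltaEnergyTrace(times=perturbed.times.copy(),
                            delta=perturbed.energies - reference.energies)


def _first_sustained(exceed: np.ndarray, m: int) -> np.ndarray:
    """Per row: first column t with exceed[t:t+m] all True, else -1."""
    n_res, n_frames = exceed.shape
    if m > n_frames:
        return np.full(n_res, -1, dtype=int)
    cs = np.cumsum(exceed, axis=1, dtype=int)
    pad = np.concatenate([np.zeros((n_res, 1), dtype=int), cs], axis=1)
    window = pad[:, m:] - pad[:, :-m]   # (N, F-m+1) counts in [t, t+m)
    hit = window == m
    first = np.argmax(hit, axis=1)
    first[~hit.any(axis=1)] = -1
    return first


def detect_response_times(delta: DeltaEnergyTrace, policy: DetectionPolicy,
                          perturbed_set,
                          control: DeltaEnergyTrace | None = None
                          ) -> ResponseProfile:
    """Assign each residue its response time under the given policy.

    `perturbed_set` residues (1-based) get dt = 0 regardless.  In
    relative mode a `control` delta trace (from an f = 1 pair or an
    external null) supplies the per-residue noise scale.
    """
    n = delta.n_residues
    perturbed = frozenset(int(i) for i in perturbed_set)
    for i in perturbed:
        if not 1 <= i <= n:
            raise AlignmentError(f"perturbed index {i} outside 1..{n}")

    if policy.mode == "absolute":
        theta = np.full(n, policy.threshold)
    else:
        if control is None:
            raise PolicyError("relative mode requires a control delta trace")
        if control.n_residues != n:
            raise AlignmentError("control trace residue count mismatch")
        noise = control.delta.std(axis=1)
        theta = policy.noise_multiplier * noise
        if np.any(theta <= 0):
            raise PolicyError(
                "relative mode: zero noise scale for some residues "
                "(a deterministic null control has no noise; use absolute mode)"
            )

    first = _first_sustained(np.abs(delta.delta) >= theta[:, None],
                             policy.sustain)
    times = np.where(first >= 0, delta.times[np.maximum(first, 0)],
                     NONRESPONSIVE)
    for i in perturbed:
        times[i - 1] = 0.0
    return ResponseProfile(response_times=times, perturbed=perturbed,
                           policy=policy.describe())


def dissipation_curve(profile: ResponseProfile,
                      grid: np.ndarray) -> DissipationCurve:
    """NR(t) = #{i : dt_i <= t}; nonresponsive residues never counted."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise AlignmentError("grid must be 1-D strictly increasing")
    dts = profile.response_times[profile.is_responsive()]
    nr = np.searchsorted(np.sort(dts), grid, side="right")
    return DissipationCurve(times=grid, nr=nr,
                            meta={"policy": profile.policy,
                                  "n_perturbed": len(profile.perturbed),
                                  "n_residues": profile.n_residues})


def region_mean_response(profile: ResponseProfile,
                         annotation: RegionAnnotation):
    """Per-region mean and population SD of response time.

    Returns a pandas DataFrame with one row per region plus an "All"
    row; nonresponsive residues are excluded from the statistics and
    counted in the `n_nonresponsive` column.
    """
    import pandas as pd

    if annotation.n_residues != profile.n_residues:
        raise AlignmentError("annotation does not cover the profile's residues")
    rows = []
    groups: dict[str, list[float]] = {lab: [] for lab in annotation.region_labels}
    nonresp: dict[str, int] = {lab: 0 for lab in annotation.region_labels}
    for i in range(1, profile.n_residues + 1):
        lab = annotation.label_of(i)
        dt = profile.response_times[i - 1]
        if np.isfinite(dt):
            groups[lab].append(dt)
        else:
            nonresp[lab] += 1

    def stats(vals: list[float], n_non: int, label: str) -> dict:
        if vals:
            arr = np.asarray(vals)
            mean, sd = float(arr.mean()), float(arr.std(ddof=0))
        else:
            mean = sd = float("nan")
        return {"region": label, "mean": mean, "sd": sd,
                "n_responsive": len(vals), "n_nonresponsive": n_non}

    all_vals = [v for vals in groups.values() for v in vals]
    rows.append(stats(all_vals, sum(nonresp.values()), "All"))
    for lab in annotation.region_labels:
        rows.append(stats(groups[lab], nonresp[lab], lab))
    return pd.DataFrame(rows)
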