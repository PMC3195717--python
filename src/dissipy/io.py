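"""Plain-text serialization of traces, profiles and curves.

All formats are tab-separated with ``# key: <json>`` comment headers, so
files are self-describing, diffable and loadable without the package.
"""

from __future__ import annotations

import json

import numpy as np

from .errors import FormatError
from .enm import EnergyTrace
from .modules import DifferenceCurve
from .response import DissipationCurve, ResponseProfile


def _meta_lines(meta: dict) -> list[str]:
    return [f"# {k}: {json.dumps(v)}" for k, v in meta.items()]


def _parse_meta(lines: list[str]) -> dict:
    meta = {}
    for line in lines:
        if not line.startswith("#"):
            continue
        body = line[1:].strip()
        if ":" not in body:
            continue
        key, _, val = body.partition(":")
        try:
            meta[key.strip()] = json.loads(val.strip())
        except json.JSONDecodeError:
            meta[key.strip()] = val.strip()
    return meta


def dump_trace(trace: EnergyTrace) -> str:
    """EnergyTrace -> TSV: meta comments, a time header row, one row per residue."""
    out = _meta_lines(trace.meta)
    out.append("residue\t" + "\t".join(f"{t:.10g}" for t in trace.times))
    for i in range(trace.n_residues):
        row = "\t".join(f"{e:.10g}" for e in trace.energies[i])
        out.append(f"{i + 1}\t{row}")
    return "\n".join(out) + "\n"


def load_trace(text: str) -> EnergyTrace:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    meta = _parse_meta([ln for ln in lines if ln.startswith("#")])
    data = [ln for ln in lines if not ln.startswith("#")]
    if not data or not data[0].startswith("residue"):
        raise FormatError("trace text lacks the 'residue' header row")
    times = np.array([float(x) for x in data[0].split("\t")[1:]])
    rows = []
    for ln in data[1:]:
        parts = ln.split("\t")
        rows.append([float(x) for x in parts[1:]])
    energies = np.array(rows)
    if energies.ndim != 2 or energies.shape[1] != len(times):
        raise FormatError("trace rows do not match the time header")
    return EnergyTrace(times=times, energies=energies, meta=meta)


def dump_curve(curve: DissipationCurve) -> str:
    """DissipationCurve -> 2-column TSV (t, NR)."""
    out = _meta_lines(curve.meta)
    out.append("t\tNR")
    for t, nr in zip(curve.times, curve.nr):
        out.append(f"{t:.10g}\t{nr:.10g}")
    return "\n".join(out) + "\n"


def load_curve(text: str) -> DissipationCurve:
    times, nr, meta = _load_two_column(text, "NR")
    return DissipationCurve(times=times, nr=nr, meta=meta)


def dump_difference(diff: DifferenceCurve) -> str:
    out = _meta_lines(diff.meta)
    out.append("t\tdNR")
    for t, d in zip(diff.times, diff.delta_nr):
        out.append(f"{t:.10g}\t{d:.10g}")
    return "\n".join(out) + "\n"


def load_difference(text: str) -> DifferenceCurve:
    times, d, meta = _load_two_column(text, "dNR")
    return DifferenceCurve(times=times, delta_nr=d, meta=meta)


def _load_two_column(text: str, value_name: str):
    lines = [ln for ln in text.splitlines() if ln.strip()]
    meta = _parse_meta([ln for ln in lines if ln.startswith("#")])
    data = [ln for ln in lines if not ln.startswith("#")]
    if not data:
        raise FormatError("empty curve text")
    start = 1 if data[0].split("\t")[0] in ("t", "time") else 0
    t_vals, y_vals = [], []
    for ln in data[start:]:
        parts = ln.split("\t")
        if len(parts) < 2:
            raise FormatError(f"expected 2 columns, got: {ln!r}")
        t_vals.append(float(parts[0]))
        y_vals.append(float(parts[1]))
    return np.array(t_vals), np.array(y_vals), meta


def dump_profile(profile: ResponseProfile) -> str:
    """ResponseProfile -> 2-column TSV (residue, dt or NA)."""
    out = _meta_lines({"perturbed": sorted(profile.perturbed),
                       "policy": profile.policy})
    out.append("residue\tresponse_time_fs")
    for i, dt in enumerate(profile.response_times, start=1):
        val = "NA" if not np.isfinite(dt) else f"{dt:.10g}"
        out.append(f"{i}\t{val}")
    return "\n".join(out) + "\n"


def load_profile(text: str) -> ResponseProfile:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    meta = _parse_meta([ln for ln in lines if ln.startswith("#")])
    data = [ln for ln in lines if not ln.startswith("#")]
    times = []
    for ln in data:
        parts = ln.split("\t")
        if parts[0] == "residue":
            continue
        times.append(float("nan") if parts[1] == "NA" else float(parts[1]))
    return ResponseProfile(
        response_times=np.array(times),
        perturbed=frozenset(meta.get("perturbed", [])),
        policy=meta.get("policy", {}),
    )
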