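"""Brute-force tick-expansion oracle for the EPG parameter battery.

Independent reference implementation: a recording is expanded to one
waveform code per 10 ms sample (100 Hz), the early-G rule and every
parameter are then computed by linear scans over the sample array.  It
shares no code with the interval-arithmetic engine and is deliberately
naive; durations are sample counts divided by the sampling rate.
"""

from __future__ import annotations

import numpy as np

CODES = ("np", "C", "pd", "G", "E1", "E2", "F")
IDX = {c: i for i, c in enumerate(CODES)}
NP, C, PD, G, E1, E2, F = (IDX[c] for c in CODES)
RATE = 100  # samples per second


def expand(rec) -> np.ndarray:
    """Per-sample waveform code for the whole recording."""
    n = round(rec.duration_s * RATE)
    arr = np.empty(n, dtype=np.int8)
    for ev in rec.events:
        arr[round(ev.start * RATE): round(ev.end * RATE)] = IDX[ev.code]
    return arr


def runs(arr: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs as (code, start_sample, end_sample)."""
    out = []
    change = np.flatnonzero(np.diff(arr)) + 1
    bounds = np.concatenate(([0], change, [arr.size]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        out.append((int(arr[a]), int(a), int(b)))
    return out


def reclassify_ticks(arr: np.ndarray, early_g_threshold_s: float = 600.0) -> np.ndarray:
    """Relabel G runs beginning < threshold into their probe as F."""
    arr = arr.copy()
    thresh = round(early_g_threshold_s * RATE)
    probe_start = None
    for code, a, b in runs(arr):
        if code == NP:
            probe_start = None
            continue
        if probe_start is None:
            probe_start = a
        if code == G and a - probe_start < thresh:
            arr[a:b] = F
    return arr


def _merged_events(rr: list[tuple[int, int, int]]):
    """Effective events: C (pd C)* collapsed to one C (summed C time);
    pd events kept individually.  Returns (code, start, n_samples)."""
    out = []
    i = 0
    while i < len(rr):
        code, a, b = rr[i]
        if code != C:
            out.append((code, a, b - a))
            i += 1
            continue
        c_samples = b - a
        pds = []
        j = i + 1
        while j + 1 < len(rr) and rr[j][0] == PD and rr[j + 1][0] == C:
            pds.append((PD, rr[j][1], rr[j][2] - rr[j][1]))
            c_samples += rr[j + 1][2] - rr[j + 1][1]
            j += 2
        out.append((C, a, c_samples))
        out.extend(pds)
        i = j
    return out


def oracle_parameters(rec, cfg) -> dict:
    """Full parameter battery, computed from the sample expansion.

    `rec` is the *unreclassified* recording; the early-G rule is
    applied at sample level.  Keys and units match the engine's.
    """
    arr = reclassify_ticks(expand(rec), cfg.early_g_threshold_s)
    total = arr.size
    vals: dict[str, float] = {}
    nan = float("nan")

    counts = np.bincount(arr, minlength=7)
    rr = runs(arr)
    if cfg.merge_c_across_pd:
        eff = _merged_events(rr)
    else:
        eff = [(code, a, b - a) for code, a, b in rr]

    for c, name in enumerate(CODES):
        evs = [e for e in eff if e[0] == c]
        vals[f"n_{name}"] = len(evs)
        vals[f"total_{name}_s"] = counts[c] / RATE
        vals[f"mean_{name}_s"] = counts[c] / RATE / len(evs) if evs else nan

    # probes: maximal non-np sample runs
    probes = []
    start = None
    for code, a, b in rr:
        if code == NP:
            if start is not None:
                probes.append((start, a))
                start = None
        elif start is None:
            start = a
    if start is not None:
        probes.append((start, total))
    vals["n_probes"] = len(probes)
    vals["mean_probe_dur_s"] = (
        sum(b - a for a, b in probes) / len(probes) / RATE if probes else nan
    )
    vals["first_probe_dur_s"] = (probes[0][1] - probes[0][0]) / RATE if probes else nan
    vals["second_probe_dur_s"] = (
        (probes[1][1] - probes[1][0]) / RATE if len(probes) > 1 else nan
    )

    if cfg.short_unit == "c_event":
        vals["n_short_C"] = sum(
            1 for e in eff if e[0] == C and e[2] < cfg.short_c_threshold_s * RATE
        )
    else:
        vals["n_short_C"] = sum(
            1 for a, b in probes if b - a < cfg.short_c_threshold_s * RATE
        )

    e1_ticks = np.flatnonzero(arr == E1)
    e2_ticks = np.flatnonzero(arr == E2)

    def containing_probe_start(sample: int) -> int:
        return next(a for a, b in probes if a <= sample < b)

    vals["t_first_probe_s"] = probes[0][0] / RATE if probes else nan
    if e1_ticks.size:
        t1 = int(e1_ticks[0])
        vals["t_first_E1_s"] = t1 / RATE
        vals["t_first_probe_to_first_E1_s"] = (t1 - probes[0][0]) / RATE
        vals["t_probe_with_first_E1_to_E1_s"] = (
            (t1 - containing_probe_start(t1)) / RATE
        )
    else:
        vals["t_first_E1_s"] = nan
        vals["t_first_probe_to_first_E1_s"] = nan
        vals["t_probe_with_first_E1_to_E1_s"] = nan
    if e2_ticks.size:
        t2 = int(e2_ticks[0])
        vals["t_probe_with_first_E2_to_E2_s"] = (
            (t2 - containing_probe_start(t2)) / RATE
        )
    else:
        vals["t_probe_with_first_E2_to_E2_s"] = nan

    sus = round(cfg.sustained_threshold_s * RATE)
    e2_runs = [(a, b) for code, a, b in rr if code == E2]
    g_runs = [(a, b) for code, a, b in rr if code == G]
    vals["n_sustained_E2"] = sum(1 for a, b in e2_runs if b - a > sus)
    vals["n_sustained_G"] = sum(1 for a, b in g_runs if b - a > sus)
    vals["longest_E2_s"] = (
        max(b - a for a, b in e2_runs) / RATE if e2_runs else nan
    )

    vals["dur_E1_before_first_sustained_E2_s"] = nan
    sus_e2 = [(a, b) for a, b in e2_runs if b - a > sus]
    if sus_e2:
        a0 = sus_e2[0][0]
        pos = next(i for i, (code, a, b) in enumerate(rr) if a == a0)
        if pos > 0 and rr[pos - 1][0] == E1:
            _, pa, pb = rr[pos - 1]
            vals["dur_E1_before_first_sustained_E2_s"] = (pb - pa) / RATE

    phloem = counts[E1] + counts[E2]
    vals["pct_E1_of_phloem"] = 100.0 * counts[E1] / phloem if phloem else nan

    if cfg.censor_policy == "max_time":
        for name in ("t_first_probe_s", "t_first_E1_s",
                     "t_first_probe_to_first_E1_s"):
            if np.isnan(vals[name]):
                vals[name] = rec.duration_s
    return vals
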