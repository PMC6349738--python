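"""The per-insect EPG parameter battery and cohort summaries.

For each annotated recording the engine computes, on the reclassified
event sequence:

* per waveform (np, C, pd, G, E1, E2, F): total duration, number of
  events, mean event duration — counts and means on *effective* events
  (pd interruptions do not split a pathway event);
* probe-level: number of probes, mean probe duration, durations of the
  first and second probe, number of short C events;
* time-to-event: time from recording start to the first probe and to
  the first phloem salivation ("1st E" = first E1 onset, the entry into
  phloem phase), time from the first probe to the first E1, time from
  the start of the probe containing the first E1 (resp. E2) to that
  onset, and the duration of the E1 event immediately preceding the
  first sustained E2;
* sustained-event parameters: numbers of sustained (> 10 min) E2 and G
  events, duration of the longest E2 event;
* percent contribution of E1 to the phloem phase,
  ``100 * total E1 / (total E1 + total E2)`` — high values mean the
  insect salivates into sieve elements without committing to ingestion,
  the signature of phloem-level rejection.

All values are stored in seconds; display conversion (minutes
generally, pd and E1 means in seconds, first-probe-to-phloem also in
hours) happens only in :func:`parameters_to_table`.  A parameter whose
triggering waveform never occurs is missing (NaN) and flagged censored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import WAVEFORM_CODES, Event, Recording
from .model import ModelConfig, effective_events, has_early_g, segment_probes

__all__ = [
    "ParameterRecord",
    "CohortSummary",
    "compute_insect_parameters",
    "sustained_events",
    "compute_cohort",
    "parameters_to_table",
    "PARAMETER_NAMES",
    "TIME_TO_EVENT_PARAMS",
]

#: Parameters carrying a censoring flag when their trigger never occurs.
TIME_TO_EVENT_PARAMS = (
    "t_first_probe_s",
    "t_first_E1_s",
    "t_first_probe_to_first_E1_s",
    "t_probe_with_first_E1_to_E1_s",
    "t_probe_with_first_E2_to_E2_s",
    "dur_E1_before_first_sustained_E2_s",
)

PARAMETER_NAMES: tuple[str, ...] = tuple(
    [f"n_{w}" for w in WAVEFORM_CODES]
    + [f"total_{w}_s" for w in WAVEFORM_CODES]
    + [f"mean_{w}_s" for w in WAVEFORM_CODES]
    + [
        "n_probes",
        "mean_probe_dur_s",
        "first_probe_dur_s",
        "second_probe_dur_s",
        "n_short_C",
        *TIME_TO_EVENT_PARAMS,
        "n_sustained_E2",
        "n_sustained_G",
        "longest_E2_s",
        "pct_E1_of_phloem",
    ]
)


@dataclass
class ParameterRecord:
    """One insect's parameter vector; NaN marks a missing value."""

    insect_id: str
    values: dict[str, float]
    censored: set[str] = field(default_factory=set)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def is_missing(self, name: str) -> bool:
        v = self.values[name]
        return isinstance(v, float) and math.isnan(v)


def sustained_events(
    rec: Recording, code: str, threshold_s: float = 600.0,
    cfg: ModelConfig = ModelConfig(),
) -> list[Event]:
    """Effective events of `code` strictly longer than `threshold_s`."""
    return [
        e for e in effective_events(rec, cfg)
        if e.code == code and e.duration > threshold_s
    ]


def compute_insect_parameters(
    rec: Recording, cfg: ModelConfig = ModelConfig()
) -> ParameterRecord:
    """Compute the full parameter battery for one recording.

    The recording must already have the early-G reclassification rule
    applied (see :func:`epgkit.model.reclassify_early_g`); an
    unreclassified recording raises ``ValueError``.
    """
    rec.validate()
    if has_early_g(rec, cfg):
        raise ValueError(
            f"{rec.insect_id}: recording contains early-probe G events; "
            "apply reclassify_early_g() before computing parameters"
        )

    eff = effective_events(rec, cfg)
    raw = rec.events
    vals: dict[str, float] = {}
    censored: set[str] = set()

    for w in WAVEFORM_CODES:
        evs = [e for e in eff if e.code == w]
        total = rec.total_duration(w)
        vals[f"n_{w}"] = len(evs)
        vals[f"total_{w}_s"] = total
        vals[f"mean_{w}_s"] = total / len(evs) if evs else math.nan

    probes = segment_probes(rec)
    vals["n_probes"] = len(probes)
    vals["mean_probe_dur_s"] = (
        sum(p.duration for p in probes) / len(probes) if probes else math.nan
    )
    vals["first_probe_dur_s"] = probes[0].duration if probes else math.nan
    vals["second_probe_dur_s"] = probes[1].duration if len(probes) > 1 else math.nan

    if cfg.short_unit == "c_event":
        vals["n_short_C"] = sum(
            1 for e in eff if e.code == "C" and e.duration < cfg.short_c_threshold_s
        )
    else:
        vals["n_short_C"] = sum(
            1 for p in probes if p.duration < cfg.short_c_threshold_s
        )

    first_e1 = next((e for e in raw if e.code == "E1"), None)
    first_e2 = next((e for e in raw if e.code == "E2"), None)

    def probe_containing(t: float):
        return next(p for p in probes if p.start <= t < p.end)

    if probes:
        vals["t_first_probe_s"] = probes[0].start
    else:
        vals["t_first_probe_s"] = math.nan
        censored.add("t_first_probe_s")

    if first_e1 is not None:
        vals["t_first_E1_s"] = first_e1.start
        vals["t_first_probe_to_first_E1_s"] = first_e1.start - probes[0].start
        vals["t_probe_with_first_E1_to_E1_s"] = (
            first_e1.start - probe_containing(first_e1.start).start
        )
    else:
        for name in ("t_first_E1_s", "t_first_probe_to_first_E1_s",
                     "t_probe_with_first_E1_to_E1_s"):
            vals[name] = math.nan
            censored.add(name)

    if first_e2 is not None:
        vals["t_probe_with_first_E2_to_E2_s"] = (
            first_e2.start - probe_containing(first_e2.start).start
        )
    else:
        vals["t_probe_with_first_E2_to_E2_s"] = math.nan
        censored.add("t_probe_with_first_E2_to_E2_s")

    sus_e2 = sustained_events(rec, "E2", cfg.sustained_threshold_s, cfg)
    vals["n_sustained_E2"] = len(sus_e2)
    vals["n_sustained_G"] = len(
        sustained_events(rec, "G", cfg.sustained_threshold_s, cfg)
    )
    e2_eff = [e for e in eff if e.code == "E2"]
    vals["longest_E2_s"] = max((e.duration for e in e2_eff), default=math.nan)

    vals["dur_E1_before_first_sustained_E2_s"] = math.nan
    if sus_e2:
        first_sus_start = sus_e2[0].start
        idx = next(
            i for i, e in enumerate(raw)
            if e.code == "E2" and e.start == first_sus_start
        )
        if idx > 0 and raw[idx - 1].code == "E1":
            vals["dur_E1_before_first_sustained_E2_s"] = raw[idx - 1].duration
    if math.isnan(vals["dur_E1_before_first_sustained_E2_s"]):
        censored.add("dur_E1_before_first_sustained_E2_s")

    tot_e1 = vals["total_E1_s"]
    tot_e2 = vals["total_E2_s"]
    phloem = tot_e1 + tot_e2
    vals["pct_E1_of_phloem"] = 100.0 * tot_e1 / phloem if phloem > 0 else math.nan

    if cfg.censor_policy == "max_time":
        for name in ("t_first_probe_s", "t_first_E1_s",
                     "t_first_probe_to_first_E1_s"):
            if name in censored:
                vals[name] = rec.duration_s

    return ParameterRecord(insect_id=rec.insect_id, values=vals, censored=censored)


@dataclass
class CohortSummary:
    """Group-level summary: per-parameter n, mean and variance on the
    original (untransformed) scale, plus the share of insects that
    reached phloem ingestion at all."""

    group: str
    n: int
    stats: pd.DataFrame  # index parameter; columns n, mean, variance
    percent_with_E2: float


def compute_cohort(records: list[ParameterRecord], group: str = "") -> CohortSummary:
    """Summarize a list of per-insect records for one experimental group.

    Means and variances are over non-missing values only; an insect
    lacking a waveform simply does not contribute to that parameter.
    """
    if not records:
        raise ValueError("compute_cohort requires at least one record")
    df = parameters_to_table(records)
    stats = pd.DataFrame(
        {
            "n": df.notna().sum(),
            "mean": df.mean(),
            "variance": df.var(ddof=1),
        }
    )
    pct_e2 = 100.0 * (df["n_E2"] >= 1).sum() / len(records)
    return CohortSummary(group=group, n=len(records), stats=stats,
                         percent_with_E2=float(pct_e2))


# display-unit policy: minutes generally; pd and E1 event means in
# seconds; the first-probe-to-phloem latency additionally in hours
_SECONDS_DISPLAY = {"mean_pd_s", "mean_E1_s", "total_pd_s", "total_E1_s"}


def parameters_to_table(
    records: list[ParameterRecord], display_units: bool = False
) -> pd.DataFrame:
    """Tabulate records: one row per insect, one column per parameter.

    With ``display_units=False`` (default) everything stays in storage
    units (seconds).  With ``display_units=True`` durations are shown in
    minutes except pd and E1 (seconds); the first-probe-to-first-E1
    latency is additionally exposed in hours; column names carry the
    unit suffix.
    """
    if not records:
        return pd.DataFrame(columns=list(PARAMETER_NAMES))
    df = pd.DataFrame(
        [r.values for r in records], index=[r.insect_id for r in records]
    )[list(PARAMETER_NAMES)]
    df.index.name = "insect_id"
    if not display_units:
        return df

    out = {}
    for col in df.columns:
        if not col.endswith("_s"):
            out[col] = df[col]
        elif col in _SECONDS_DISPLAY:
            out[col] = df[col]
        else:
            out[col[:-2] + "_min"] = df[col] / 60.0
    out["t_first_probe_to_first_E1_h"] = df["t_first_probe_to_first_E1_s"] / 3600.0
    return pd.DataFrame(out, index=df.index)
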