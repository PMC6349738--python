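"""Behavioral structure on top of an annotated recording.

A *probe* is one continuous stylet penetration: a maximal interval of
non-np waveforms flanked by non-probing (np) periods or a recording
boundary.  Probes are the unit of analysis for probe-level parameters
(number of probes, first/second probe duration, time to first probe).

Two conventions shape every downstream parameter:

* **Early-G reclassification.**  A waveform with the appearance of
  xylem ingestion (G) but beginning less than 10 min after the start of
  its probe is treated as derailed stylet mechanics (F): the stylet
  cannot plausibly reach xylem that fast.  The rule is applied before
  any parameter computation.

* **pd-embedded-in-pathway.**  A potential drop (pd) is an intracellular
  puncture *during* pathway; it interrupts the C signal but not the C
  event.  For event counting, a maximal run ``C (pd C)*`` collapses to
  one C event whose duration is the summed C time; the pds remain
  events of their own.  This is the convention under which pathway event
  counts and mean durations are internally consistent with totals.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import Event, Recording, merge_adjacent

__all__ = ["Probe", "ModelConfig", "segment_probes", "reclassify_early_g",
           "effective_events"]


@dataclass(frozen=True)
class Probe:
    """A maximal non-np interval; ``censored`` marks truncation by the
    recording end (the probe was still in progress at cutoff)."""

    index: int  # ordinal from 1
    start: float
    end: float
    events: tuple[Event, ...]
    censored: bool = False

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class ModelConfig:
    """Thresholds of the feeding model, all in seconds.

    early_g_threshold_s
        G beginning strictly less than this far into its probe is
        relabeled F (default 600 s = 10 min).
    sustained_threshold_s
        An event strictly longer than this is "sustained" (default
        600 s), the criterion for committed phloem/xylem ingestion.
    short_c_threshold_s
        A (merged) C event strictly shorter than this is a "short C
        event" (default 180 s).
    merge_c_across_pd
        Whether pd interruptions leave the enclosing C event intact.
    short_unit
        What "short C" counts: merged C events (``c_event``) or probes
        shorter than the threshold (``probe``).
    censor_policy
        How insects lacking a waveform enter group statistics for the
        corresponding time-to-event parameter: ``exclude`` (missing) or
        ``max_time`` (assigned the recording length).
    """

    early_g_threshold_s: float = 600.0
    sustained_threshold_s: float = 600.0
    short_c_threshold_s: float = 180.0
    merge_c_across_pd: bool = True
    short_unit: str = "c_event"
    censor_policy: str = "exclude"

    def __post_init__(self) -> None:
        for name in ("early_g_threshold_s", "sustained_threshold_s",
                     "short_c_threshold_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.short_unit not in ("c_event", "probe"):
            raise ValueError(f"short_unit must be c_event|probe, got {self.short_unit}")
        if self.censor_policy not in ("exclude", "max_time"):
            raise ValueError(f"censor_policy must be exclude|max_time")


def segment_probes(rec: Recording) -> list[Probe]:
    """Split a recording into probes (maximal non-np runs), in order.

    A probe truncated by the recording end is still a probe, flagged
    censored.  An all-np recording yields no probes.
    """
    rec.validate()
    probes: list[Probe] = []
    run: list[Event] = []
    for ev in rec.events:
        if ev.code == "np":
            if run:
                probes.append(_make_probe(len(probes) + 1, run, rec.duration_s))
                run = []
        else:
            run.append(ev)
    if run:
        probes.append(_make_probe(len(probes) + 1, run, rec.duration_s))
    return probes


def _make_probe(index: int, run: list[Event], duration_s: float) -> Probe:
    return Probe(
        index=index,
        start=run[0].start,
        end=run[-1].end,
        events=tuple(run),
        censored=run[-1].end == duration_s,
    )


def reclassify_early_g(rec: Recording, cfg: ModelConfig = ModelConfig()) -> Recording:
    """Relabel early-probe G events as F.

    Every G event whose onset lies strictly less than
    ``cfg.early_g_threshold_s`` after the start of its containing probe
    becomes F; adjacent same-code events are re-merged.  Total time is
    conserved and the operation is idempotent.
    """
    rec.validate()
    probe_start: dict[float, float] = {}
    for probe in segment_probes(rec):
        for ev in probe.events:
            probe_start[ev.start] = probe.start
    new_events = []
    for ev in rec.events:
        if ev.code == "G" and ev.start - probe_start[ev.start] < cfg.early_g_threshold_s:
            ev = Event("F", ev.start, ev.end)
        new_events.append(ev)
    out = rec.with_events(merge_adjacent(new_events))
    out.validate()
    return out


def has_early_g(rec: Recording, cfg: ModelConfig = ModelConfig()) -> bool:
    """True if the recording still contains G events the rule would relabel."""
    for probe in segment_probes(rec):
        for ev in probe.events:
            if ev.code == "G" and ev.start - probe.start < cfg.early_g_threshold_s:
                return True
    return False


def effective_events(rec: Recording, cfg: ModelConfig = ModelConfig()) -> list[Event]:
    """Event list used for counting and mean-duration statistics.

    With ``merge_c_across_pd`` (the default), each maximal run
    ``C (pd C)*`` collapses to one C event carrying the summed C
    duration (pd time excluded); its interval spans the run but the
    reported ``duration`` attribute would then disagree with
    ``end - start``, so the merged C event is represented with
    ``end = start + summed C duration`` for arithmetic consistency and
    the original span is irrelevant to every downstream parameter.
    pd events are returned unchanged, in place.  With the flag off, the
    raw segments are returned.
    """
    rec.validate()
    if not cfg.merge_c_across_pd:
        return list(rec.events)
    out: list[Event] = []
    i = 0
    events = rec.events
    n = len(events)
    while i < n:
        ev = events[i]
        if ev.code != "C":
            out.append(ev)
            i += 1
            continue
        # extend across the maximal C (pd C)* run
        c_total = ev.duration
        pds: list[Event] = []
        j = i + 1
        while j + 1 < n and events[j].code == "pd" and events[j + 1].code == "C":
            pds.append(events[j])
            c_total += events[j + 1].duration
            j += 2
        out.append(Event("C", ev.start, ev.start + c_total))
        out.extend(pds)
        i = j
    return out
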