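"""Semi-Markov simulator of whitefly feeding behavior.

Generates grammar-valid, 12-hour annotated EPG recordings so the whole
analysis chain (parsing, probe segmentation, parameter battery,
statistics) can be exercised and tested without access to raw insect
recordings.

Model
-----
Feeding is a first-order semi-Markov process over six macro states
(np, C, G, E1, E2, F): the insect jumps between behaviors according to
an embedded Markov chain and stays in each behavior for a lognormal
sojourn time (strictly positive and right-skewed, like behavioral
durations).  Potential drops (pd) are not a chain state: they are brief
intracellular punctures *during* pathway, modeled as a marked point
process inside C sojourns (a Poisson number of pd insertions per minute
of pathway), which preserves the pd-embedded-in-pathway convention and
the pathway merge rule downstream.

Grammar is enforced by construction: phloem ingestion (E2) is reachable
only from phloem salivation (E1); probes open from np into pathway; pd
insertions keep at least one sample of C on each side.  Event
boundaries are quantized to the 10 ms acquisition grid (100 Hz), so a
sample-level expansion of any simulated recording is exact.

Built-in profiles emulate the magnitude contrasts between the
experimental groups of a whitefly host-suitability study: a fully
host-adapted population (long committed phloem ingestion), phloem-level
rejection on a non-host (salivation without sustained ingestion),
delayed acceptance (very late first probe), and a thick-wire tethering
artifact (many short probes, elevated derailed-stylet time).  Profile
numbers are emulation targets for group means, not claims about any
real dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from .io import WAVEFORM_CODES, Event, Recording, merge_adjacent

__all__ = [
    "SimulationProfile",
    "SimulationTrace",
    "simulate_recording",
    "simulate_cohort",
    "builtin_profiles",
]

#: Chain states (pd is a burst process inside C, not a chain state).
CHAIN_STATES = ("np", "C", "G", "E1", "E2", "F")

#: Ticks per second of the acquisition grid.
TICKS_PER_S = 100

# transitions that would break the waveform grammar; probability must be 0
_FORBIDDEN = [
    ("np", "E2"), ("C", "E2"), ("G", "E2"), ("F", "E2"),  # E2 only after E1
    ("E1", "G"), ("E1", "F"),                             # E1 resolves to E2/C/np
]


def _median_from_mean(mean_s: float, log_sd: float) -> float:
    """Median of a lognormal with the given arithmetic mean and log-sd."""
    return mean_s * math.exp(-0.5 * log_sd**2)


@dataclass
class SimulationProfile:
    """Semi-Markov specification for one experimental group.

    ``transition[a][b]`` is the embedded-chain probability of jumping
    from state ``a`` to ``b``; rows are stochastic and grammar-forbidden
    entries are zero.  ``duration_median_s`` / ``duration_log_sd`` give
    each state's lognormal sojourn distribution (median seconds,
    log-scale sd).  pd bursts are controlled by ``pd_rate_per_min_c``
    (expected insertions per minute of pathway) and a lognormal pd
    duration.  ``first_np_median_s`` optionally overrides the median of
    the very first np sojourn, for groups whose hallmark is a delayed
    first probe.
    """

    name: str
    transition: dict[str, dict[str, float]]
    duration_median_s: dict[str, float]
    duration_log_sd: dict[str, float]
    pd_rate_per_min_c: float = 0.2
    pd_median_s: float = 5.5
    pd_log_sd: float = 0.35
    duration_s: float = 43_200.0
    init_state: str = "np"
    first_np_median_s: float | None = None
    first_np_log_sd: float | None = None

    def validate(self) -> None:
        if self.init_state not in CHAIN_STATES:
            raise ValueError(f"init_state {self.init_state!r} not a chain state")
        for s in CHAIN_STATES:
            row = self.transition.get(s)
            if row is None:
                raise ValueError(f"transition row missing for state {s}")
            if any(p < 0 for p in row.values()):
                raise ValueError(f"negative transition probability in row {s}")
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError(f"transition row {s} does not sum to 1")
            if self.duration_median_s.get(s, 0) <= 0:
                raise ValueError(f"duration median for {s} must be > 0")
            if self.duration_log_sd.get(s, -1) < 0:
                raise ValueError(f"duration log-sd for {s} must be >= 0")
        for a, b in _FORBIDDEN:
            if self.transition[a].get(b, 0.0) != 0.0:
                raise ValueError(f"grammar-forbidden transition {a}->{b} has p > 0")
        if self.pd_rate_per_min_c < 0 or self.pd_median_s <= 0:
            raise ValueError("pd burst parameters must be non-negative / positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")

    def analytic_mean_s(self, state: str) -> float:
        """Arithmetic mean of the state's sojourn distribution."""
        if state == "pd":
            return self.pd_median_s * math.exp(0.5 * self.pd_log_sd**2)
        m, s = self.duration_median_s[state], self.duration_log_sd[state]
        return m * math.exp(0.5 * s**2)

    def to_yaml(self) -> str:
        payload = {
            "name": self.name,
            "transition": self.transition,
            "duration_median_s": self.duration_median_s,
            "duration_log_sd": self.duration_log_sd,
            "pd_rate_per_min_c": self.pd_rate_per_min_c,
            "pd_median_s": self.pd_median_s,
            "pd_log_sd": self.pd_log_sd,
            "duration_s": self.duration_s,
            "init_state": self.init_state,
            "first_np_median_s": self.first_np_median_s,
            "first_np_log_sd": self.first_np_log_sd,
        }
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationProfile":
        return cls(**yaml.safe_load(text))


@dataclass
class SimulationTrace:
    """Raw sojourn draws behind one simulated recording.

    ``sojourns_s[state]`` holds every drawn duration for that state, in
    draw order, *before* grid quantization and end-of-recording
    truncation — including the final draw that the recording cuts
    short.  This is the right object for checking the generator against
    its analytic sojourn distribution, free of censoring bias.
    """

    sojourns_s: dict[str, list[float]] = field(default_factory=dict)

    def add(self, state: str, dur_s: float) -> None:
        self.sojourns_s.setdefault(state, []).append(dur_s)


def simulate_recording(
    profile: SimulationProfile,
    seed: int | np.random.SeedSequence,
    insect_id: str | None = None,
    return_trace: bool = False,
) -> Recording | tuple[Recording, SimulationTrace]:
    """Draw one annotated recording from a feeding profile.

    The same seed always yields a bit-identical recording (PCG64
    generator, integer seeding).  Output satisfies all Recording
    invariants and passes grammar validation with zero errors.
    """
    profile.validate()
    rng = np.random.default_rng(seed)
    if insect_id is None:
        insect_id = f"{profile.name}_sim"

    states = list(CHAIN_STATES)
    index = {s: i for i, s in enumerate(states)}
    P = np.array(
        [[profile.transition[a].get(b, 0.0) for b in states] for a in states]
    )
    trace = SimulationTrace()
    total_ticks = round(profile.duration_s * TICKS_PER_S)

    # 1. draw the macro-state sequence with tick-quantized sojourns
    segs: list[tuple[str, int]] = []  # (code, n_ticks)
    t = 0
    state = profile.init_state
    first = True
    while t < total_ticks:
        if first and state == "np" and profile.first_np_median_s is not None:
            med = profile.first_np_median_s
            sd = (profile.first_np_log_sd
                  if profile.first_np_log_sd is not None
                  else profile.duration_log_sd["np"])
        else:
            med = profile.duration_median_s[state]
            sd = profile.duration_log_sd[state]
        first = False
        dur = float(rng.lognormal(mean=math.log(med), sigma=sd))
        trace.add(state, dur)
        ticks = max(1, round(dur * TICKS_PER_S))
        ticks = min(ticks, total_ticks - t)  # truncate at the recording end
        segs.append((state, ticks))
        t += ticks
        state = states[rng.choice(len(states), p=P[index[state]])]

    # merge adjacent same-state sojourns before pd insertion
    merged: list[tuple[str, int]] = []
    for code, ticks in segs:
        if merged and merged[-1][0] == code:
            merged[-1] = (code, merged[-1][1] + ticks)
        else:
            merged.append((code, ticks))

    # 2. insert pd bursts inside C segments, keeping >=1 tick of C
    #    around every pd so pd is never adjacent to np
    final: list[tuple[str, int]] = []
    for code, ticks in merged:
        if code != "C" or profile.pd_rate_per_min_c == 0:
            final.append((code, ticks))
            continue
        lam = profile.pd_rate_per_min_c * ticks / (60 * TICKS_PER_S)
        n_pd = int(rng.poisson(lam))
        pd_ticks: list[int] = []
        for _ in range(n_pd):
            d = float(rng.lognormal(math.log(profile.pd_median_s),
                                    profile.pd_log_sd))
            trace.add("pd", d)
            pd_ticks.append(max(1, round(d * TICKS_PER_S)))
        # shed insertions that cannot fit with their C margins
        while pd_ticks and sum(pd_ticks) + len(pd_ticks) + 1 > ticks:
            pd_ticks.pop()
        if not pd_ticks:
            final.append((code, ticks))
            continue
        n = len(pd_ticks)
        spare = ticks - sum(pd_ticks) - (n + 1)
        gaps = 1 + rng.multinomial(spare, [1.0 / (n + 1)] * (n + 1))
        for k in range(n):
            final.append(("C", int(gaps[k])))
            final.append(("pd", pd_ticks[k]))
        final.append(("C", int(gaps[n])))

    # 3. ticks -> events in seconds on the 10 ms grid
    events: list[Event] = []
    t = 0
    for code, ticks in final:
        events.append(Event(code, t / TICKS_PER_S, (t + ticks) / TICKS_PER_S))
        t += ticks
    rec = Recording(
        insect_id=insect_id,
        events=merge_adjacent(events),
        duration_s=profile.duration_s,
    )
    rec.validate()
    return (rec, trace) if return_trace else rec


def simulate_cohort(
    profile: SimulationProfile,
    n: int,
    seed: int,
    id_prefix: str | None = None,
    return_traces: bool = False,
):
    """Simulate `n` independent recordings from one profile.

    Per-insect streams are spawned from a single seed sequence, so the
    cohort is reproducible as a whole and insects are independent.
    """
    prefix = id_prefix if id_prefix is not None else profile.name
    root = np.random.SeedSequence(seed)
    out, traces = [], []
    for i, child in enumerate(root.spawn(n)):
        rec, tr = simulate_recording(
            profile, child, insect_id=f"{prefix}_{i + 1:03d}", return_trace=True
        )
        out.append(rec)
        traces.append(tr)
    return (out, traces) if return_traces else out


def _profile(name, means_s, log_sds, transition, **kw) -> SimulationProfile:
    """Build a profile from target *mean* sojourn seconds per state."""
    medians = {s: _median_from_mean(means_s[s], log_sds[s]) for s in CHAIN_STATES}
    return SimulationProfile(
        name=name,
        transition=transition,
        duration_median_s=medians,
        duration_log_sd=dict(log_sds),
        **kw,
    )


_LOG_SD = {"np": 0.9, "C": 0.8, "G": 0.8, "E1": 0.6, "E2": 0.8, "F": 0.8}


def builtin_profiles() -> dict[str, SimulationProfile]:
    """The four built-in feeding profiles.

    ======================  =================================================
    name                    emulates
    ======================  =================================================
    host_adapted            adapted population on its true host: pathway
                            events ~10 min, xylem ~37 min, E1 ~66 s, very
                            long committed phloem ingestion (mean event
                            ~260 min), short np bouts
    phloem_rejection        non-host phloem rejection: frequent pathway and
                            pd activity, much salivation relative to
                            ingestion, short and rare E2 (~41 min events,
                            often none sustained)
    delayed_acceptance      host accepted only after a long pre-probe delay
                            (first np ~99 min); once probing, phloem is
                            reached and used
    thick_wire              tethering artifact of a stiff wire: many short
                            probes, elevated derailed-stylet (F) time,
                            drastically reduced phloem ingestion
    ======================  =================================================
    """
    profiles = {}
    profiles["host_adapted"] = _profile(
        "host_adapted",
        # target mean sojourns (s): C 10.3 min, G 37 min, E1 65.6 s,
        # E2 260 min, F 19.3 min, np 5 min
        {"np": 300.0, "C": 618.0, "G": 2220.0, "E1": 65.6, "E2": 15_600.0,
         "F": 1158.0},
        _LOG_SD,
        {
            "np": {"C": 1.0},
            "C": {"E1": 0.20, "G": 0.10, "F": 0.10, "np": 0.60},
            "E1": {"E2": 0.60, "C": 0.25, "np": 0.15},
            "E2": {"np": 0.70, "C": 0.30},
            "G": {"C": 0.40, "np": 0.60},
            "F": {"C": 0.40, "np": 0.60},
        },
        pd_rate_per_min_c=0.22,
        pd_median_s=_median_from_mean(6.0, 0.35),
    )
    profiles["phloem_rejection"] = _profile(
        "phloem_rejection",
        # C 8.9 min, G 15.2 min, E1 96.9 s, E2 ~41 min, F 10.9 min, np 5.2 min
        {"np": 312.0, "C": 534.0, "G": 912.0, "E1": 96.9, "E2": 2460.0,
         "F": 654.0},
        _LOG_SD,
        {
            "np": {"C": 1.0},
            "C": {"E1": 0.12, "G": 0.08, "F": 0.08, "np": 0.72},
            "E1": {"E2": 0.25, "C": 0.45, "np": 0.30},
            "E2": {"np": 0.60, "C": 0.40},
            "G": {"C": 0.40, "np": 0.60},
            "F": {"C": 0.40, "np": 0.60},
        },
        pd_rate_per_min_c=0.17,
        pd_median_s=_median_from_mean(5.0, 0.35),
    )
    profiles["delayed_acceptance"] = _profile(
        "delayed_acceptance",
        # C 5.6 min, G 57.6 min, E1 91.1 s, E2 35.8 min, F 23.3 min,
        # np 20.2 min; first probe delayed ~99 min
        {"np": 1212.0, "C": 336.0, "G": 3456.0, "E1": 91.1, "E2": 2148.0,
         "F": 1398.0},
        _LOG_SD,
        {
            "np": {"C": 1.0},
            "C": {"E1": 0.32, "G": 0.03, "F": 0.06, "np": 0.59},
            "E1": {"E2": 0.60, "C": 0.30, "np": 0.10},
            "E2": {"np": 0.55, "C": 0.45},
            "G": {"C": 0.50, "np": 0.50},
            "F": {"C": 0.50, "np": 0.50},
        },
        pd_rate_per_min_c=0.20,
        pd_median_s=_median_from_mean(4.4, 0.35),
        first_np_median_s=_median_from_mean(5946.0, 0.8),
        first_np_log_sd=0.8,
    )
    profiles["thick_wire"] = _profile(
        "thick_wire",
        # many short probes: C 4.5 min, G 56 min, E1 42 s, E2 64 min,
        # F 18.2 min, np 4.1 min
        {"np": 246.0, "C": 270.0, "G": 3366.0, "E1": 42.0, "E2": 3852.0,
         "F": 1092.0},
        _LOG_SD,
        {
            "np": {"C": 1.0},
            "C": {"E1": 0.03, "G": 0.01, "F": 0.07, "np": 0.89},
            "E1": {"E2": 0.55, "C": 0.30, "np": 0.15},
            "E2": {"np": 0.70, "C": 0.30},
            "G": {"C": 0.30, "np": 0.70},
            "F": {"C": 0.30, "np": 0.70},
        },
        pd_rate_per_min_c=0.09,
        pd_median_s=_median_from_mean(6.0, 0.35),
    )
    for p in profiles.values():
        p.validate()
    return profiles
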