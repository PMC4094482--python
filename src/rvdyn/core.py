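"""Shared data model for paced right-ventricular electrophysiology analysis.

This module holds the containers every other stage consumes — uniformly
sampled voltage traces, the 24-electrode layout on an idealised RV shell,
the realised S1S2 extrastimulus schedule — together with the deterministic
protocol logic that derives the ventricular effective refractory period
(VERP) from a capture oracle.

Conventions
-----------
* All times are milliseconds.  Within a pacing train, t = 0 is the S2
  (premature) stimulus; the last S1 stimulus sits at ``-coupling_ms``.
* Sample indexing is 0-based; intervals are closed on the left, open on
  the right.
* The VERP is the longest *tested* S2 coupling interval that fails to
  capture after 2 ms refinement; the "pre-VERP" measurement beat is the
  shortest capturing S2 (refine-step milliseconds above the VERP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

REGIONS = ("apex", "mid", "outflow_tract")
GROUPS = ("normal", "rvot_ectopy", "definite_arvc", "probable_arvc")
LIMB_LEADS = ("I", "II", "III", "aVR", "aVL", "aVF")
ECG_STATES = ("steady", "pre_erp")


class ProtocolError(ValueError):
    """Raised when the S1S2 schedule cannot be resolved consistently."""


class NoVerpError(ProtocolError):
    """Raised when no capture failure is reached above the pacing floor."""


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


@dataclass
class SignalTrace:
    """One channel's uniformly sampled voltage trace.

    Parameters
    ----------
    channel_id : str
        Channel label (electrode id or ECG lead name).
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in ms (relative to the epoch's reference
        stimulus).
    samples : ndarray
        Voltages in mV.
    """

    channel_id: str
    fs: float
    t0: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError("samples must be a non-empty 1-D array")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.fs

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) * self.dt_ms

    @property
    def t_end(self) -> float:
        return self.t0 + (self.samples.size - 1) * self.dt_ms

    def index_of(self, t_ms: float) -> int:
        """Index of the first sample at or after ``t_ms``."""
        return int(np.ceil((t_ms - self.t0) * self.fs / 1000.0 - 1e-9))

    def shifted(self, delta_ms: float) -> "SignalTrace":
        return SignalTrace(self.channel_id, self.fs, self.t0 + delta_ms,
                           self.samples.copy())

    def scaled(self, k: float) -> "SignalTrace":
        return SignalTrace(self.channel_id, self.fs, self.t0,
                           self.samples * k)


@dataclass(frozen=True)
class Electrode:
    electrode_id: str
    column: int          # 1..4 around the shell
    row: int             # 1 (apex) .. 6 (outflow tract)
    position_mm: tuple[float, float, float]
    region: str          # apex | mid | outflow_tract
    segment: int         # 1..16


@dataclass
class ElectrodeMap:
    """24 virtual electrodes in 4 columns of 6 rows covering the RV shell."""

    electrodes: list[Electrode]

    def __post_init__(self) -> None:
        if len(self.electrodes) != 24:
            raise ValidationError(
                f"expected 24 electrodes, got {len(self.electrodes)}")
        counts = {r: 0 for r in REGIONS}
        for e in self.electrodes:
            if e.region not in REGIONS:
                raise ValidationError(f"unknown region {e.region!r}")
            if not 1 <= e.segment <= 16:
                raise ValidationError(f"segment {e.segment} outside 1..16")
            counts[e.region] += 1
        if counts != {"apex": 8, "mid": 8, "outflow_tract": 8}:
            raise ValidationError(f"bad region counts {counts}")

    @property
    def ids(self) -> list[str]:
        return [e.electrode_id for e in self.electrodes]

    def positions(self) -> np.ndarray:
        return np.array([e.position_mm for e in self.electrodes])

    def by_id(self, electrode_id: str) -> Electrode:
        for e in self.electrodes:
            if e.electrode_id == electrode_id:
                return e
        raise KeyError(electrode_id)

    def adjacent_pairs(self) -> list[tuple[str, str]]:
        """Pairs of electrodes adjacent in the row/column lattice."""
        idx = {(e.column, e.row): e.electrode_id for e in self.electrodes}
        pairs = []
        for (c, r), eid in idx.items():
            if (c, r + 1) in idx:
                pairs.append((eid, idx[(c, r + 1)]))
            nc = c % 4 + 1  # wrap around the shell
            if (nc, r) in idx:
                pairs.append((eid, idx[(nc, r)]))
        return pairs


def build_electrode_map(geometry_spec: Sequence[dict] | None = None,
                        radius_mm: float = 15.0,
                        row_spacing_mm: float = 13.0) -> ElectrodeMap:
    """Construct the 24-electrode layout.

    With no ``geometry_spec`` an idealised cylinder-like shell is used:
    4 columns at 90 degree spacing, 6 rows along the long axis, apex rows
    1-2, mid rows 3-4, outflow-tract rows 5-6.  Apex and outflow tract each
    map onto 4 segments (2 electrodes per segment); the mid-ventricle maps
    onto 8 single-electrode segments, giving 16 segments in total.

    ``geometry_spec`` may give explicit electrodes as dicts with keys
    ``electrode_id, column, row, position_mm`` (region/segment are derived
    from the row/column if absent).
    """
    def region_segment(column: int, row: int) -> tuple[str, int]:
        if row <= 2:
            return "apex", column
        if row <= 4:
            return "mid", 4 + (row - 3) * 4 + column
        return "outflow_tract", 12 + column

    electrodes: list[Electrode] = []
    if geometry_spec is None:
        for col in range(1, 5):
            theta = (col - 1) * np.pi / 2.0
            for row in range(1, 7):
                region, seg = region_segment(col, row)
                pos = (radius_mm * np.cos(theta), radius_mm * np.sin(theta),
                       (row - 1) * row_spacing_mm)
                electrodes.append(Electrode(f"E{col}{row}", col, row, pos,
                                            region, seg))
    else:
        for item in geometry_spec:
            col, row = int(item["column"]), int(item["row"])
            region, seg = region_segment(col, row)
            electrodes.append(Electrode(
                str(item["electrode_id"]), col, row,
                tuple(float(v) for v in item["position_mm"]),
                item.get("region", region), int(item.get("segment", seg))))
    return ElectrodeMap(electrodes)


@dataclass(frozen=True)
class ProtocolEvent:
    train: int
    coupling_ms: float
    captured: bool


@dataclass
class StimulusProtocol:
    """The realised S1S2 schedule: tested coupling intervals and outcomes."""

    events: list[ProtocolEvent]
    verp_ms: float
    pre_verp_ci_ms: float
    s1_cycle_ms: float = 400.0
    s1_per_train: int = 8
    inter_train_gap_ms: float = 2000.0  # metadata only

    def __post_init__(self) -> None:
        if self.pre_verp_ci_ms <= self.verp_ms:
            raise ProtocolError("pre-VERP interval must exceed the VERP")

    @property
    def captured_intervals(self) -> list[float]:
        return sorted({e.coupling_ms for e in self.events if e.captured},
                      reverse=True)

    @property
    def tested_intervals(self) -> list[float]:
        return sorted({e.coupling_ms for e in self.events}, reverse=True)


def generate_s2_schedule(capture_oracle: Callable[[float], bool],
                         start_ms: float = 400.0,
                         coarse_step: float = 20.0,
                         coarse_floor: float = 300.0,
                         fine_step: float = 5.0,
                         bump_ms: float = 8.0,
                         refine_step: float = 2.0,
                         abort_floor: float = 150.0,
                         s1_cycle_ms: float = 400.0,
                         s1_per_train: int = 8) -> StimulusProtocol:
    """Realise the S1S2 extrastimulus schedule against a capture oracle.

    The coupling interval is reduced from ``start_ms`` in ``coarse_step``
    decrements until ``coarse_floor``, then in ``fine_step`` decrements until
    the first capture failure.  The interval is then increased by ``bump_ms``
    and walked back down in ``refine_step`` decrements; the VERP is the
    coupling interval of the final (refined) failure and the pre-VERP
    interval is ``verp + refine_step``.

    The oracle must be monotone (capture at a coupling interval implies
    capture at every longer interval); a non-monotone oracle raises
    :class:`ProtocolError`.  If no failure occurs above ``abort_floor`` a
    :class:`NoVerpError` is raised.
    """
    events: list[ProtocolEvent] = []
    outcomes: dict[float, bool] = {}

    def test(ci: float) -> bool:
        cap = bool(capture_oracle(ci))
        if ci in outcomes and outcomes[ci] != cap:
            raise ProtocolError(
                f"oracle is not deterministic at ci={ci} ms")
        outcomes[ci] = cap
        events.append(ProtocolEvent(len(events), float(ci), cap))
        return cap

    first_fail: float | None = None
    ci = float(start_ms)
    while ci >= coarse_floor - 1e-9:
        if not test(ci):
            first_fail = ci
            break
        ci -= coarse_step
    if first_fail is None:
        ci = coarse_floor - fine_step
        while ci >= abort_floor - 1e-9:
            if not test(ci):
                first_fail = ci
                break
            ci -= fine_step
    if first_fail is None:
        raise NoVerpError(
            f"no capture failure above the {abort_floor} ms pacing floor")

    if not any(outcomes.values()):
        raise ProtocolError("stimulation never captured at any tested "
                            "interval; VERP is above the drive interval")

    # Bump above the failure, then refine downwards on the fine grid.
    bump = first_fail + bump_ms
    while not test(bump):
        bump += bump_ms
        if bump > start_ms + bump_ms:
            raise ProtocolError("bump phase exceeded the drive interval "
                                "without capture")
    ci = bump - refine_step
    verp: float | None = None
    while ci >= abort_floor - 1e-9:
        if not test(ci):
            verp = ci
            break
        ci -= refine_step
    if verp is None:
        raise NoVerpError("refinement reached the pacing floor while "
                          "still capturing")

    for c_cap, cap in outcomes.items():
        if cap:
            for c_fail, fail_cap in outcomes.items():
                if not fail_cap and c_fail > c_cap:
                    raise ProtocolError(
                        "non-monotone capture oracle: captured at "
                        f"{c_cap} ms but failed at {c_fail} ms")

    return StimulusProtocol(events=events, verp_ms=float(verp),
                            pre_verp_ci_ms=float(verp + refine_step),
                            s1_cycle_ms=s1_cycle_ms,
                            s1_per_train=s1_per_train)


@dataclass
class BeatMeasurement:
    """Per-electrode, per-beat timing measurements (ms from the stimulus)."""

    electrode_id: str
    s2_coupling_ms: float
    at_ms: float
    rt_ms: float
    di_ms: float | None = None
    fractionation_index: int | None = None

    def __post_init__(self) -> None:
        if self.rt_ms <= self.at_ms:
            raise ValidationError("repolarization must follow activation")
        if self.fractionation_index is not None \
                and self.fractionation_index < 0:
            raise ValidationError("fractionation index must be >= 0")

    @property
    def ari_ms(self) -> float:
        return self.rt_ms - self.at_ms


@dataclass
class RestitutionCurve:
    """Per-electrode restitution points with steady-state references.

    ``points`` is a structured array-like list of dicts with keys
    ``coupling_ms, at_ms, rt_ms, ari_ms, di_ms`` sorted by descending
    coupling interval.
    """

    electrode_id: str
    points: list[dict]
    steady_at_ms: float
    steady_rt_ms: float
    steady_ari_ms: float

    def __post_init__(self) -> None:
        cis = [p["coupling_ms"] for p in self.points]
        if any(b > a for a, b in zip(cis, cis[1:])):
            self.points = sorted(self.points,
                                 key=lambda p: -p["coupling_ms"])

    def column(self, key: str) -> np.ndarray:
        return np.array([p[key] for p in self.points], dtype=float)


@dataclass
class PatientRecord:
    """All recorded epochs for one patient.

    Trace dictionaries are keyed as:

    * ``train_traces[(train_index, electrode_id)]`` — last S1 + S2 window,
      t = 0 at the S2 stimulus.
    * ``steady_traces[(repeat, electrode_id)]`` — one steady-pacing beat.
    * ``sinus_traces[(repeat, electrode_id)]`` — one sinus beat, t = 0 at
      the earliest RV activation onset.
    * ``ecg_traces[(lead, state, repeat)]`` — one paced limb-lead complex,
      t = 0 at the pacing stimulus.
    """

    patient_id: str
    group: str
    electrode_map: ElectrodeMap
    protocol: StimulusProtocol
    train_traces: dict = field(default_factory=dict)
    steady_traces: dict = field(default_factory=dict)
    sinus_traces: dict = field(default_factory=dict)
    ecg_traces: dict = field(default_factory=dict)
    train_couplings: dict = field(default_factory=dict)  # train -> ci
    truth: object | None = None  # generator bookkeeping, when synthetic

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        reps: dict[tuple, int] = {}
        for lead, state, rep in self.ecg_traces:
            reps[(lead, state)] = reps.get((lead, state), 0) + 1
        if any(n > 3 for n in reps.values()):
            raise ValidationError("at most 3 ECG repeats per lead/state")
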