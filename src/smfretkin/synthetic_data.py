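"""Trace simulator with the kinetic and photophysical structure the
analysis assumes: first-order state transitions, alternating-excitation
emission, fluorophore arrival/photobleaching, end-of-recording truncation,
and a refractory subpopulation that never leaves its starting state.

The simulator provides full ground truth so every downstream stage can be
validated by parameter recovery rather than against archived raw data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from smfretkin._types import StatePath
from smfretkin.trace_io import (
    DEFAULT_FRAME_INTERVAL_S,
    EXCITATION_ACCEPTOR,
    EXCITATION_DONOR,
    IntensityTrace,
    TraceSet,
)


class SimulationConfigError(ValueError):
    """Invalid kinetic scheme or emission configuration."""


@dataclass
class KineticScheme:
    """First-order kinetic scheme among ``n_states`` states.

    ``rate_matrix[i, j]`` is the transition rate constant k_ij (s^-1) from
    state i to state j; the diagonal is ignored.  ``initial_fractions`` is
    the time-zero state distribution for the responsive subpopulation; a
    ``refractory_fraction`` of records instead start in ``refractory_state``
    (which must have zero exit rates) and never leave it.
    """

    rate_matrix: np.ndarray
    initial_fractions: np.ndarray
    refractory_fraction: float = 0.0
    refractory_state: int | None = None

    def __post_init__(self) -> None:
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        self.initial_fractions = np.asarray(self.initial_fractions, dtype=float)
        K = self.rate_matrix.shape[0]
        if self.rate_matrix.shape != (K, K) or K < 2:
            raise SimulationConfigError("rate_matrix must be square, K >= 2")
        off = self.rate_matrix[~np.eye(K, dtype=bool)]
        if np.any(off < 0):
            raise SimulationConfigError("off-diagonal rates must be >= 0")
        if self.initial_fractions.shape != (K,):
            raise SimulationConfigError("initial_fractions length must equal K")
        if np.any(self.initial_fractions < 0) or abs(self.initial_fractions.sum() - 1.0) > 1e-12:
            raise SimulationConfigError("initial_fractions must sum to 1 within 1e-12")
        if not 0.0 <= self.refractory_fraction <= 1.0:
            raise SimulationConfigError("refractory_fraction must be in [0, 1]")
        if self.refractory_fraction > 0:
            if self.refractory_state is None:
                self.refractory_state = K - 1
            if self.exit_rates()[self.refractory_state] != 0.0:
                raise SimulationConfigError(
                    "refractory_state must have all exit rates zero"
                )

    @property
    def n_states(self) -> int:
        return self.rate_matrix.shape[0]

    def exit_rates(self) -> np.ndarray:
        K = self.n_states
        k = self.rate_matrix.copy()
        k[np.eye(K, dtype=bool)] = 0.0
        return k.sum(axis=1)

    def generator(self) -> np.ndarray:
        """Infinitesimal generator Q (rows sum to zero)."""
        K = self.n_states
        Q = self.rate_matrix.copy()
        Q[np.eye(K, dtype=bool)] = 0.0
        Q[np.eye(K, dtype=bool)] = -Q.sum(axis=1)
        return Q


@dataclass
class EmissionConfig:
    """Emission model mapping states to alternating-excitation intensities.

    On donor-excitation frames with both fluorophores active the acceptor
    channel reads ``total_intensity * E`` and the donor channel
    ``total_intensity * (1 - E)`` for the occupied state's E_FRET level,
    inverting E = I_A / (I_A + I_D).  Acceptor-excitation frames report
    acceptor presence directly.
    """

    efret_levels: np.ndarray
    total_intensity: float = 100.0
    noise_sd: float = 0.0
    baseline_offset: float = 0.0
    donor_bleach_rate: float = 0.0
    acceptor_bleach_rate: float = 0.0
    frame_interval: float = DEFAULT_FRAME_INTERVAL_S

    def __post_init__(self) -> None:
        self.efret_levels = np.asarray(self.efret_levels, dtype=float)
        if np.any((self.efret_levels < 0) | (self.efret_levels > 1)):
            raise SimulationConfigError("efret_levels must lie in [0, 1]")
        if self.noise_sd < 0:
            raise SimulationConfigError("noise_sd must be >= 0")
        if self.frame_interval <= 0:
            raise SimulationConfigError("frame_interval must be > 0")
        if self.donor_bleach_rate < 0 or self.acceptor_bleach_rate < 0:
            raise SimulationConfigError("bleach rates must be >= 0")


@dataclass
class SimulationConfig:
    scheme: KineticScheme
    emission: EmissionConfig
    n_records: int = 100
    max_duration: float = 1200.0  # ~20 min recording
    arrival_spread: float = 30.0  # mean of exponential arrival delays (s)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise SimulationConfigError("n_records must be >= 1")
        if self.max_duration <= self.emission.frame_interval:
            raise SimulationConfigError("max_duration must exceed frame_interval")
        if len(self.emission.efret_levels) != self.scheme.n_states:
            raise SimulationConfigError("efret_levels length must equal n_states")


@dataclass
class RecordTruth:
    """Ground truth for a single simulated record."""

    record_id: str
    path: StatePath  # states on donor frames from t0 to record end
    donor_arrival: float
    acceptor_arrival: float
    donor_loss: float
    acceptor_loss: float
    t0: float
    t_end: float
    end_cause: str  # 'bleach_or_loss' | 'recording_end'
    refractory: bool


@dataclass
class GroundTruth:
    records: list[RecordTruth]
    scheme: KineticScheme
    emission: EmissionConfig

    def __len__(self) -> int:
        return len(self.records)

    def to_json(self) -> str:
        payload = {
            "scheme": {
                "rate_matrix": self.scheme.rate_matrix.tolist(),
                "initial_fractions": self.scheme.initial_fractions.tolist(),
                "refractory_fraction": self.scheme.refractory_fraction,
                "refractory_state": self.scheme.refractory_state,
            },
            "emission": {
                "efret_levels": self.emission.efret_levels.tolist(),
                "total_intensity": self.emission.total_intensity,
                "noise_sd": self.emission.noise_sd,
                "baseline_offset": self.emission.baseline_offset,
                "donor_bleach_rate": self.emission.donor_bleach_rate,
                "acceptor_bleach_rate": self.emission.acceptor_bleach_rate,
                "frame_interval": self.emission.frame_interval,
            },
            "records": [
                {
                    "record_id": r.record_id,
                    "path_rle": r.path.run_lengths(),
                    "t0": r.t0,
                    "t_end": r.t_end,
                    "donor_arrival": r.donor_arrival,
                    "acceptor_arrival": r.acceptor_arrival,
                    "donor_loss": r.donor_loss,
                    "acceptor_loss": r.acceptor_loss,
                    "end_cause": r.end_cause,
                    "refractory": r.refractory,
                }
                for r in self.records
            ],
        }
        return json.dumps(payload, indent=1)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def simulate_state_path(
    scheme: KineticScheme,
    duration: float,
    frame_interval: float,
    rng: np.random.Generator | int,
    initial_state: int | None = None,
) -> StatePath:
    """Sample a continuous-time Markov chain and discretize it per frame.

    Exponential waiting times with each state's total exit rate; the
    reported per-frame state is the one occupied at the frame start, which
    keeps discretized dwell distributions geometric.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if duration < frame_interval:
        raise SimulationConfigError("duration must be >= frame_interval")
    exit_rates = scheme.exit_rates()
    K = scheme.n_states
    if initial_state is None:
        state = int(rng.choice(K, p=scheme.initial_fractions))
    else:
        state = int(initial_state)

    n_frames = int(np.floor(duration / frame_interval))
    frame_times = frame_interval * np.arange(n_frames)
    states = np.empty(n_frames, dtype=int)

    t = 0.0
    i = 0
    while i < n_frames:
        kx = exit_rates[state]
        dwell = np.inf if kx == 0.0 else rng.exponential(1.0 / kx)
        t_next = t + dwell
        while i < n_frames and frame_times[i] < t_next:
            states[i] = state
            i += 1
        if i >= n_frames:
            break
        probs = scheme.rate_matrix[state].copy()
        probs[state] = 0.0
        probs /= probs.sum()
        state = int(rng.choice(K, p=probs))
        t = t_next
    return StatePath(states=states, frame_interval=frame_interval)


def emit_intensities(
    path: StatePath,
    emission: EmissionConfig,
    rng: np.random.Generator | int,
    record_id: str = "rec0",
    t0: float | None = None,
    n_cycles: int | None = None,
    donor_span: tuple[float, float] | None = None,
    acceptor_span: tuple[float, float] | None = None,
) -> IntensityTrace:
    """Emit an alternating-excitation intensity trace for a state path.

    Each 2.67 s cycle holds one donor-excitation frame (at the cycle start,
    where the state path is sampled) and one acceptor-excitation frame (half
    a cycle later).  ``donor_span``/``acceptor_span`` are [on, off) windows
    of active fluorophore signal in absolute seconds; outside them the
    corresponding emissions fall to ``baseline_offset`` plus noise.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if len(path) == 0:
        raise SimulationConfigError("state path must be non-empty")
    dt = emission.frame_interval
    t0 = path.t0 if t0 is None else t0
    path_end = t0 + len(path) * dt
    if n_cycles is None:
        n_cycles = int(np.ceil(path_end / dt))
    if donor_span is None:
        donor_span = (t0, path_end)
    if acceptor_span is None:
        acceptor_span = (t0, path_end)

    cyc = np.arange(n_cycles)
    t_d = cyc * dt  # donor-excitation frames
    t_a = cyc * dt + dt / 2.0  # acceptor-excitation frames

    d_on = (t_d >= donor_span[0]) & (t_d < donor_span[1])
    a_on_d = (t_d >= acceptor_span[0]) & (t_d < acceptor_span[1])
    a_on_a = (t_a >= acceptor_span[0]) & (t_a < acceptor_span[1])

    # state per donor frame (frames outside the path window have no FRET pair)
    idx = np.floor((t_d - t0) / dt + 1e-9).astype(int)
    in_path = (idx >= 0) & (idx < len(path))
    E = np.zeros(n_cycles)
    E[in_path] = emission.efret_levels[path.states[idx[in_path]]]

    total = emission.total_intensity
    both = d_on & a_on_d & in_path
    I_A_d = np.where(both, total * E, 0.0)
    I_D_d = np.where(both, total * (1.0 - E), np.where(d_on, total, 0.0))
    I_A_a = np.where(a_on_a, total, 0.0)

    def noisy(x):
        out = x + emission.baseline_offset
        if emission.noise_sd > 0:
            out = out + rng.normal(0.0, emission.noise_sd, size=len(x))
        return out

    n = 2 * n_cycles
    time_s = np.empty(n)
    time_s[0::2] = t_d
    time_s[1::2] = t_a
    excitation = np.empty(n, dtype=object)
    excitation[0::2] = EXCITATION_DONOR
    excitation[1::2] = EXCITATION_ACCEPTOR
    I_donor_em = np.empty(n)
    I_acceptor_em = np.empty(n)
    I_donor_em[0::2] = noisy(I_D_d)
    I_acceptor_em[0::2] = noisy(I_A_d)
    I_donor_em[1::2] = noisy(np.zeros(n_cycles))
    I_acceptor_em[1::2] = noisy(I_A_a)

    return IntensityTrace(
        record_id=record_id,
        frame_index=np.arange(n),
        time_s=time_s,
        excitation=excitation,
        I_donor_em=I_donor_em,
        I_acceptor_em=I_acceptor_em,
        frame_interval=dt,
    )


def simulate_dataset(config: SimulationConfig) -> tuple[TraceSet, GroundTruth]:
    """Simulate ``n_records`` independent records with full ground truth.

    Donor- and acceptor-labeled complex arrivals are drawn independently
    (exponential with mean ``arrival_spread``); time zero of each record is
    the later arrival.  Records end at the first fluorophore loss
    (exponential bleaching clocks) or at the end of the recording.
    """
    rng = np.random.default_rng(config.rng_seed)
    scheme, emission = config.scheme, config.emission
    dt = emission.frame_interval
    n_cycles = int(np.floor(config.max_duration / dt))

    traces: list[IntensityTrace] = []
    truths: list[RecordTruth] = []
    for r in range(config.n_records):
        rid = f"rec{r:04d}"
        d_arr = rng.exponential(config.arrival_spread)
        a_arr = rng.exponential(config.arrival_spread)
        d_loss = d_arr + (
            rng.exponential(1.0 / emission.donor_bleach_rate)
            if emission.donor_bleach_rate > 0
            else np.inf
        )
        a_loss = a_arr + (
            rng.exponential(1.0 / emission.acceptor_bleach_rate)
            if emission.acceptor_bleach_rate > 0
            else np.inf
        )
        recording_end = n_cycles * dt
        t0_raw = max(d_arr, a_arr)
        # snap t0 to the next donor-excitation frame so the path sits on the grid
        t0 = np.ceil(t0_raw / dt - 1e-9) * dt
        t_end = min(d_loss, a_loss, recording_end)
        end_cause = "recording_end" if t_end >= recording_end else "bleach_or_loss"
        t_end = min(t_end, recording_end)

        refractory = bool(rng.random() < scheme.refractory_fraction)
        duration = max(t_end - t0, dt)
        if refractory:
            path = simulate_state_path(
                scheme, duration, dt, rng, initial_state=scheme.refractory_state
            )
        else:
            path = simulate_state_path(scheme, duration, dt, rng)
        path.t0 = t0

        trace = emit_intensities(
            path,
            emission,
            rng,
            record_id=rid,
            t0=t0,
            n_cycles=n_cycles,
            donor_span=(d_arr, min(d_loss, recording_end)),
            acceptor_span=(a_arr, min(a_loss, recording_end)),
        )
        traces.append(trace)
        truths.append(
            RecordTruth(
                record_id=rid,
                path=path,
                donor_arrival=d_arr,
                acceptor_arrival=a_arr,
                donor_loss=d_loss,
                acceptor_loss=a_loss,
                t0=t0,
                t_end=t_end,
                end_cause=end_cause,
                refractory=refractory,
            )
        )
    return (
        TraceSet(traces=traces, frame_interval=dt),
        GroundTruth(records=truths, scheme=scheme, emission=emission),
    )


# ---------------------------------------------------------------------------
# presets and E_FRET-level simulation helpers
# ---------------------------------------------------------------------------

def wt_like_scheme(
    k_pre_to_dh: float = 0.15,
    initial_pre: float = 0.50,
    initial_dh: float = 0.15,
    refractory_fraction: float = 0.35,
) -> KineticScheme:
    """Three-state scheme (pre, high, never-high) with an irreversible
    low-to-high step and a refractory never-high subpopulation."""
    K = 3
    rates = np.zeros((K, K))
    rates[0, 1] = k_pre_to_dh
    resp = initial_pre + initial_dh
    return KineticScheme(
        rate_matrix=rates,
        initial_fractions=np.array([initial_pre / resp, initial_dh / resp, 0.0]),
        refractory_fraction=refractory_fraction,
        refractory_state=2,
    )


def mutant_like_scheme(
    k_entry: float = 0.13,
    k_exit: float = 0.052,
    initial_pre: float = 0.62,
    initial_high: float = 0.13,
    refractory_fraction: float = 0.25,
) -> KineticScheme:
    """Three-state scheme with a transient high state: low -> high -> low
    (no re-formation), plus a refractory subpopulation."""
    K = 3
    rates = np.zeros((K, K))
    rates[0, 1] = k_entry
    rates[1, 2] = k_exit
    resp = initial_pre + initial_high
    return KineticScheme(
        rate_matrix=rates,
        initial_fractions=np.array([initial_pre / resp, initial_high / resp, 0.0]),
        refractory_fraction=refractory_fraction,
        refractory_state=2,
    )


def simulate_efret_cohort(
    scheme: KineticScheme,
    efret_levels: np.ndarray,
    n_records: int,
    efret_sd: float,
    rng: np.random.Generator | int,
    frame_interval: float = DEFAULT_FRAME_INTERVAL_S,
    mean_duration: float = 290.0,
    max_duration: float = 1200.0,
):
    """Simulate records directly on the E_FRET level (state path plus
    Gaussian E_FRET noise), bypassing the intensity/emission layer.

    Record lengths are exponential with the given mean, truncated at
    ``max_duration``.  Returns (list of EfretRecord, list of RecordTruth).
    """
    from smfretkin.preprocess import EfretRecord  # local import avoids cycle at module load

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    efret_levels = np.asarray(efret_levels, dtype=float)
    records, truths = [], []
    for r in range(n_records):
        rid = f"rec{r:04d}"
        dur = min(rng.exponential(mean_duration), max_duration)
        dur = max(dur, 2 * frame_interval)
        refractory = bool(rng.random() < scheme.refractory_fraction)
        if refractory:
            path = simulate_state_path(
                scheme, dur, frame_interval, rng, initial_state=scheme.refractory_state
            )
        else:
            path = simulate_state_path(scheme, dur, frame_interval, rng)
        efret = efret_levels[path.states] + (
            rng.normal(0.0, efret_sd, size=len(path)) if efret_sd > 0 else 0.0
        )
        end_cause = "recording_end" if dur >= max_duration else "bleach_or_loss"
        records.append(
            EfretRecord(
                record_id=rid,
                t0=0.0,
                efret=efret,
                frame_interval=frame_interval,
                end_cause=end_cause,
            )
        )
        truths.append(
            RecordTruth(
                record_id=rid,
                path=path,
                donor_arrival=0.0,
                acceptor_arrival=0.0,
                donor_loss=dur,
                acceptor_loss=dur,
                t0=0.0,
                t_end=dur,
                end_cause=end_cause,
                refractory=refractory,
            )
        )
    return records, truths
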