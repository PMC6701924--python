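"""Tabular I/O for intensity traces, configuration and result tables.

The portable on-disk interface is a delimiter-separated text table with one
row per (record, frame, excitation channel) and the exact header::

    record_id, frame_index, time_s, excitation, I_donor_em, I_acceptor_em

All other modules consume the in-memory types defined here
(:class:`IntensityTrace`, :class:`TraceSet`, :class:`AnalysisConfig`).
"""

from __future__ import annotations

import configparser
import io
import logging
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Exact column names of the trace table dialect.
TRACE_COLUMNS = [
    "record_id",
    "frame_index",
    "time_s",
    "excitation",
    "I_donor_em",
    "I_acceptor_em",
]

EXCITATION_DONOR = "donor"
EXCITATION_ACCEPTOR = "acceptor"

DEFAULT_FRAME_INTERVAL_S = 2.67


class TraceParseError(ValueError):
    """Raised when a trace table violates the dialect contract."""


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration keys."""


@dataclass
class IntensityTrace:
    """Per-frame emission intensities for one DNA-colocalized record.

    Frames alternate between donor and acceptor excitation.  ``I_donor_em``
    and ``I_acceptor_em`` are the donor- and acceptor-channel emissions for
    whichever excitation the frame used; acceptor emission under acceptor
    excitation (I_AA) is therefore ``I_acceptor_em`` on acceptor frames.
    """

    record_id: str
    frame_index: np.ndarray  # 0-based, int
    time_s: np.ndarray
    excitation: np.ndarray  # str array, 'donor' | 'acceptor'
    I_donor_em: np.ndarray
    I_acceptor_em: np.ndarray
    frame_interval: float = DEFAULT_FRAME_INTERVAL_S

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.excitation = np.asarray(self.excitation, dtype=object)
        self.I_donor_em = np.asarray(self.I_donor_em, dtype=float)
        self.I_acceptor_em = np.asarray(self.I_acceptor_em, dtype=float)
        n = len(self.frame_index)
        for name in ("time_s", "excitation", "I_donor_em", "I_acceptor_em"):
            if len(getattr(self, name)) != n:
                raise TraceParseError(
                    f"record {self.record_id!r}: column {name} has length "
                    f"{len(getattr(self, name))}, expected {n}"
                )
        if n < 2:
            raise TraceParseError(
                f"record {self.record_id!r}: needs >= 2 frames, got {n}"
            )
        if self.frame_interval <= 0:
            raise TraceParseError(
                f"record {self.record_id!r}: frame_interval must be > 0"
            )
        if np.any(np.diff(self.time_s) <= 0):
            raise TraceParseError(
                f"record {self.record_id!r}: frame times not strictly increasing"
            )
        bad = set(np.unique(self.excitation)) - {EXCITATION_DONOR, EXCITATION_ACCEPTOR}
        if bad:
            raise TraceParseError(
                f"record {self.record_id!r}: unknown excitation labels {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.frame_index)

    @property
    def donor_mask(self) -> np.ndarray:
        return self.excitation == EXCITATION_DONOR

    @property
    def acceptor_mask(self) -> np.ndarray:
        return self.excitation == EXCITATION_ACCEPTOR

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "record_id": self.record_id,
                "frame_index": self.frame_index,
                "time_s": self.time_s,
                "excitation": self.excitation,
                "I_donor_em": self.I_donor_em,
                "I_acceptor_em": self.I_acceptor_em,
            }
        )


@dataclass
class TraceSet:
    """A collection of records sharing acquisition metadata."""

    traces: list[IntensityTrace]
    frame_interval: float = DEFAULT_FRAME_INTERVAL_S
    variant: str = "wt"

    def __post_init__(self) -> None:
        ids = [t.record_id for t in self.traces]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise TraceParseError(f"duplicate record_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def to_frame(self) -> pd.DataFrame:
        if not self.traces:
            return pd.DataFrame(columns=TRACE_COLUMNS)
        return pd.concat([t.to_frame() for t in self.traces], ignore_index=True)


def write_traces(trace_set: TraceSet, path: str | Path, sep: str = "\t") -> None:
    """Serialize a :class:`TraceSet` losslessly to a delimited text table.

    Non-finite intensities are refused: they cannot round-trip unambiguously
    and always indicate an upstream bug.
    """
    df = trace_set.to_frame()
    for col in ("I_donor_em", "I_acceptor_em"):
        if len(df) and not np.all(np.isfinite(df[col].to_numpy())):
            bad = df.loc[~np.isfinite(df[col].to_numpy()), "record_id"].iloc[0]
            raise ValueError(
                f"non-finite intensity in column {col}, record {bad!r}; refusing to write"
            )
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_traces(
    path: str | Path,
    sep: str = "\t",
    frame_interval: float = DEFAULT_FRAME_INTERVAL_S,
    variant: str = "wt",
) -> TraceSet:
    """Read and validate a trace table.

    Rows are grouped by ``record_id`` and sorted by frame; unsorted input is
    normalized with a warning.  Duplicate (record, frame, excitation) rows
    are an error naming the offending record.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: missing columns {missing}")
    traces = []
    for rid, grp in df.groupby("record_id", sort=True):
        if not grp["frame_index"].is_monotonic_increasing:
            logger.warning("record %r: frames unsorted on disk; sorting", rid)
            warnings.warn(f"record {rid!r}: frames unsorted; sorted on read")
            grp = grp.sort_values("frame_index")
        dup = grp.duplicated(subset=["frame_index", "excitation"])
        if dup.any():
            raise TraceParseError(
                f"{path}: duplicated (frame, excitation) row in record {rid!r}"
            )
        traces.append(
            IntensityTrace(
                record_id=str(rid),
                frame_index=grp["frame_index"].to_numpy(),
                time_s=grp["time_s"].to_numpy(),
                excitation=grp["excitation"].to_numpy(),
                I_donor_em=grp["I_donor_em"].to_numpy(),
                I_acceptor_em=grp["I_acceptor_em"].to_numpy(),
                frame_interval=frame_interval,
            )
        )
    return TraceSet(traces=traces, frame_interval=frame_interval, variant=variant)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Validated pipeline configuration with documented defaults."""

    # acquisition / simulation
    frame_interval: float = DEFAULT_FRAME_INTERVAL_S
    variant: str = "wt"
    n_records: int = 100
    max_duration: float = 1200.0
    # preprocessing
    threshold_sd: float = 4.0
    min_dwell_frames: int = 3
    smooth_window_frames: int = 15
    outlier_low: float = -0.25
    outlier_high: float = 0.85
    max_outliers: int = 10
    # histograms
    bandwidth_t: float = 5.0
    bandwidth_e: float = 0.05
    grid_dt: float = 1.0
    grid_de: float = 0.01
    # HMM
    n_states: int = 3
    prior_means: tuple[float, ...] = (0.06, 0.06, 0.57)
    prior_beta: tuple[float, ...] = (1000.0, 1000.0, 1000.0)
    significance_floor: float = 1e-4
    n_restarts: int = 5
    # bookkeeping
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be > 0")
        if self.n_states < 2:
            raise ConfigError("n_states must be >= 2")
        if self.outlier_low >= self.outlier_high:
            raise ConfigError("outlier_low must be < outlier_high")
        if self.bandwidth_t <= 0 or self.bandwidth_e <= 0:
            raise ConfigError("bandwidths must be > 0")
        if len(self.prior_means) != self.n_states or len(self.prior_beta) != self.n_states:
            raise ConfigError("prior_means / prior_beta length must equal n_states")


_TUPLE_FIELDS = {"prior_means", "prior_beta"}


def load_config(path: str | Path | None = None, text: str | None = None) -> AnalysisConfig:
    """Load a plain-text ``key = value`` configuration (optionally sectioned).

    Missing keys take the documented defaults; unknown keys are rejected.
    Section headers are organizational only — keys are matched by name.
    """
    parser = configparser.ConfigParser()
    if text is None:
        if path is None:
            return AnalysisConfig()
        text = Path(path).read_text()
    # allow sectionless key=value files
    if text.strip() and not text.lstrip().startswith("["):
        text = "[analysis]\n" + text
    parser.read_file(io.StringIO(text))

    known = {f.name: f for f in fields(AnalysisConfig)}
    values: dict = {}
    for section in parser.sections():
        for key, raw in parser.items(section):
            if key not in known:
                raise ConfigError(f"unknown configuration key: {key!r}")
            values[key] = _coerce(key, raw)
    return AnalysisConfig(**values)


def _coerce(key: str, raw: str):
    defaults = AnalysisConfig()
    current = getattr(defaults, key)
    if key in _TUPLE_FIELDS:
        return tuple(float(v) for v in raw.replace(",", " ").split())
    if isinstance(current, bool):
        return raw.strip().lower() in {"1", "true", "yes", "on"}
    if isinstance(current, int):
        return int(raw)
    if isinstance(current, float):
        return float(raw)
    return raw.strip()


def config_with(config: AnalysisConfig, **overrides) -> AnalysisConfig:
    """Return a copy of ``config`` with the given fields replaced."""
    return replace(config, **overrides)


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a result table (generic delimiter-separated output)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)
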