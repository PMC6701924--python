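"""Semantic state labels, dwell segments, rastergram ordering and cohort
statistics on top of a fitted population model.

State semantics: the single high-E_FRET state is the paired ("DH"-like)
state — called ``DH`` for the wild-type variant and ``pseudo-DH`` for the
mutant.  Of the two low states, the one predominantly occupied before the
first high-state entry is ``pre-DH``; the other is ``non-DH`` when a record
never goes high and ``post-DH`` after a high segment has ended.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from smfretkin._types import StatePath
from smfretkin.ebhmm.population import PopulationFit, decode_states

LABEL_PRE = "pre-DH"
LABEL_HIGH_WT = "DH"
LABEL_HIGH_MUTANT = "pseudo-DH"
LABEL_NON = "non-DH"
LABEL_POST = "post-DH"

#: minimal mean separation for a state to count as the high-FRET state
HIGH_GAP = 0.15


class StateLabelError(ValueError):
    """Model misfit: the high-FRET state is not uniquely identifiable."""


@dataclass
class StateLabels:
    high_state: int
    pre_state: int
    other_state: int
    variant: str = "wt"

    @property
    def high_label(self) -> str:
        return LABEL_HIGH_WT if self.variant == "wt" else LABEL_HIGH_MUTANT


def label_states(
    fit: PopulationFit,
    variant: str = "wt",
    paths: list[StatePath] | None = None,
) -> StateLabels:
    """Map fitted state indices to semantic labels.

    Requires exactly one state whose posterior mean clears the others by
    ``HIGH_GAP``.  The pre state is the low state predominantly occupied
    before the first high-state entry across decoded paths.
    """
    if paths is None:
        paths = decode_states(fit)
    return label_states_from_means(fit.state_means, paths, variant)


def label_states_from_means(
    means: np.ndarray,
    paths: list[StatePath],
    variant: str = "wt",
) -> StateLabels:
    """As :func:`label_states`, from raw state means and decoded paths."""
    means = np.asarray(means, dtype=float)
    if len(means) != 3:
        raise StateLabelError(f"semantic labeling expects K=3, got K={len(means)}")
    order = np.argsort(means)
    if means[order[2]] - means[order[1]] < HIGH_GAP:
        raise StateLabelError(
            f"no unique high-E_FRET state: sorted means {means[order]}"
        )
    high = int(order[2])
    low_a, low_b = int(order[0]), int(order[1])

    pre_counts = {low_a: 0, low_b: 0}
    for p in paths:
        s = p.states
        hits = np.nonzero(s == high)[0]
        if len(hits) == 0:
            continue
        before = s[: hits[0]]
        pre_counts[low_a] += int((before == low_a).sum())
        pre_counts[low_b] += int((before == low_b).sum())
    if pre_counts[low_a] >= pre_counts[low_b]:
        pre, other = low_a, low_b
    else:
        pre, other = low_b, low_a
    return StateLabels(high_state=high, pre_state=pre, other_state=other, variant=variant)


@dataclass
class SegmentTable:
    """Labeled half-open dwell segments per record."""

    table: pd.DataFrame  # record_id, label, t_start_s, t_end_s, censored_end, flagged_short
    frame_interval: float

    def records(self) -> list[str]:
        return list(dict.fromkeys(self.table["record_id"]))

    def onsets(self, high_label: str | None = None) -> dict[str, float | None]:
        """First high-segment start per record (None if never high)."""
        highs = {LABEL_HIGH_WT, LABEL_HIGH_MUTANT} if high_label is None else {high_label}
        out: dict[str, float | None] = {}
        for rid, grp in self.table.groupby("record_id", sort=False):
            hi = grp[grp["label"].isin(highs)]
            out[rid] = float(hi["t_start_s"].iloc[0]) if len(hi) else None
        return out

    def durations(self) -> dict[str, float]:
        return {
            rid: float(grp["t_end_s"].max())
            for rid, grp in self.table.groupby("record_id", sort=False)
        }


def segment_paths(
    paths: list[StatePath],
    labels: StateLabels,
    record_ids: list[str] | None = None,
    end_causes: list[str] | None = None,
) -> SegmentTable:
    """Run-length encode decoded paths into labeled time segments.

    Times are seconds since each record's t0, half-open [t_start, t_end).
    The final segment is censored when the record ended with the recording.
    Single-frame high-state segments are kept but flagged.
    """
    if record_ids is None:
        record_ids = [f"rec{i:04d}" for i in range(len(paths))]
    if end_causes is None:
        end_causes = ["bleach_or_loss"] * len(paths)
    rows = []
    for path, rid, cause in zip(paths, record_ids, end_causes):
        dt = path.frame_interval
        rle = path.run_lengths()
        seen_high = False
        t = 0.0
        for i, (state, n) in enumerate(rle):
            if state == labels.high_state:
                lab = labels.high_label
                seen_high = True
            elif state == labels.pre_state:
                lab = LABEL_PRE
            else:
                lab = LABEL_POST if seen_high else LABEL_NON
            t_end = t + n * dt
            rows.append(
                {
                    "record_id": rid,
                    "label": lab,
                    "t_start_s": t,
                    "t_end_s": t_end,
                    "censored_end": (i == len(rle) - 1) and cause == "recording_end",
                    "flagged_short": (n == 1) and state == labels.high_state,
                }
            )
            t = t_end
    table = pd.DataFrame(
        rows,
        columns=[
            "record_id", "label", "t_start_s", "t_end_s", "censored_end", "flagged_short",
        ],
    )
    return SegmentTable(table=table, frame_interval=paths[0].frame_interval if paths else 0.0)


def build_rastergram(segments: SegmentTable) -> pd.DataFrame:
    """Deterministic rastergram row order.

    Records with a high-state onset sort ascending by onset, ties broken by
    descending record length; never-high records follow, by descending
    length.  Record id is the final tie-break so permuting the input leaves
    the output unchanged.
    """
    onsets = segments.onsets()
    lengths = segments.durations()
    rids = segments.records()
    with_onset = sorted(
        [r for r in rids if onsets[r] is not None],
        key=lambda r: (onsets[r], -lengths[r], r),
    )
    never = sorted(
        [r for r in rids if onsets[r] is None], key=lambda r: (-lengths[r], r)
    )
    ordered = with_onset + never
    return pd.DataFrame(
        {
            "row": np.arange(len(ordered)),
            "record_id": ordered,
            "onset_s": [onsets[r] if onsets[r] is not None else np.nan for r in ordered],
            "length_s": [lengths[r] for r in ordered],
        }
    )


@dataclass
class CohortStats:
    n_records: int
    n_ever_high: int  # decoded path visits the high state (incl. already-high)
    n_already_high: int  # high state at the first frame
    n_never_high: int
    n_reentries: int  # records with >= 2 disjoint high segments
    frac_ever_high: float
    frac_ever_high_ci: tuple[float, float]
    frac_never_high: float
    frac_never_high_ci: tuple[float, float]
    mean_duration_s: float
    sem_duration_s: float
    mean_duration_ever_high_s: float
    sem_duration_ever_high_s: float
    mean_duration_never_high_s: float
    sem_duration_never_high_s: float

    def to_frame(self) -> pd.DataFrame:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["frac_ever_high_ci_low"], d["frac_ever_high_ci_high"] = d.pop("frac_ever_high_ci")
        d["frac_never_high_ci_low"], d["frac_never_high_ci_high"] = d.pop(
            "frac_never_high_ci"
        )
        return pd.DataFrame([d])


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    if len(x) == 0:
        return float("nan"), float("nan")
    sem = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
    return float(np.mean(x)), sem


def cohort_statistics(segments: SegmentTable) -> CohortStats:
    """Counts, fractions (with 95% binomial CIs) and duration statistics.

    Durations are observed (possibly right-censored) times from t0 to
    record end, averaged without censoring correction.
    """
    rids = segments.records()
    if not rids:
        raise ValueError("no records")
    onsets = segments.onsets()
    durations = segments.durations()
    highs = {LABEL_HIGH_WT, LABEL_HIGH_MUTANT}

    ever, already, reentries = [], [], []
    for rid, grp in segments.table.groupby("record_id", sort=False):
        high_segs = grp[grp["label"].isin(highs)]
        ever.append(len(high_segs) > 0)
        already.append(len(grp) > 0 and grp["label"].iloc[0] in highs)
        reentries.append(len(high_segs) >= 2)

    n = len(rids)
    n_ever = int(np.sum(ever))
    n_never = n - n_ever
    ci_ever = tuple(proportion_confint(n_ever, n, alpha=0.05, method="wilson"))
    ci_never = tuple(proportion_confint(n_never, n, alpha=0.05, method="wilson"))

    durs = np.array([durations[r] for r in rids])
    ever_arr = np.array(ever)
    mean_all, sem_all = _mean_sem(durs)
    mean_e, sem_e = _mean_sem(durs[ever_arr])
    mean_n, sem_n = _mean_sem(durs[~ever_arr])
    return CohortStats(
        n_records=n,
        n_ever_high=n_ever,
        n_already_high=int(np.sum(already)),
        n_never_high=n_never,
        n_reentries=int(np.sum(reentries)),
        frac_ever_high=n_ever / n,
        frac_ever_high_ci=ci_ever,
        frac_never_high=n_never / n,
        frac_never_high_ci=ci_never,
        mean_duration_s=mean_all,
        sem_duration_s=sem_all,
        mean_duration_ever_high_s=mean_e,
        sem_duration_ever_high_s=sem_e,
        mean_duration_never_high_s=mean_n,
        sem_duration_never_high_s=sem_n,
    )
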