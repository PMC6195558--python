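"""Detachment-event detection and stepwise annotation.

Two layers:

``classify_states``
    Per-frame closed/open/transient labels from a center-of-mass distance
    series. A frame is *open* when the smoothed distance exceeds
    baseline + ``open_offset`` (default 5 Angstrom, the magnitude of the
    observed nSH2-helical separation). Sub-threshold excursions between
    two open stretches shorter than the dwell parameter are *transient*
    re-attachments.

``annotate_steps``
    The four-step detachment mechanism, operationalized as:

    * Step 1 - first sustained drop of the total inter-domain hydrogen-bond
      count (two-window mean comparison against a count threshold);
    * Step 2 - first open-state onset with the designated critical residue
      pair (default R340-E542) broken;
    * Step 3 - first transient re-attachment with that pair re-formed;
    * Step 4 - permanent loss of the critical pair while the timeline
      remains open thereafter (the complete dissociation).

    Steps must be strictly ordered in time; later steps are omitted when
    their signals never occur.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError
from .geometry import TimeSeries
from .hbond import OccupancyTable

__all__ = [
    "StepAnnotation",
    "EventTimeline",
    "classify_states",
    "annotate_steps",
    "DEFAULT_KEY_PAIRS",
]

CLOSED, OPEN, TRANSIENT = "closed", "open", "transient"

#: Critical residue pairs of the nSH2(p85alpha, chain B)-helical(p110alpha,
#: chain A) interface, in priority order: (chain, resnum, chain, resnum).
DEFAULT_KEY_PAIRS: tuple[tuple[str, int, str, int], ...] = (
    ("B", 340, "A", 542),  # R340-E542 critical salt bridge
    ("B", 358, "A", 542),  # R358-E542
    ("B", 380, "A", 545),  # L380-E/K545
    ("B", 382, "A", 546),  # K382-Q546
)


@dataclass
class StepAnnotation:
    step: int
    time_ns: float
    signal: str
    detail: str = ""


@dataclass
class EventTimeline:
    """Per-frame state labels plus step annotations."""

    times_ns: np.ndarray
    states: np.ndarray  # array of {'closed','open','transient'}
    steps: list[StepAnnotation] = field(default_factory=list)
    baseline: float = float("nan")
    threshold: float = float("nan")

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.states = np.asarray(self.states, dtype=object)
        if len(self.times_ns) != len(self.states):
            raise InputError("times and states must have equal length")
        bad = set(self.states.tolist()) - {CLOSED, OPEN, TRANSIENT}
        if bad:
            raise InputError(f"unknown state labels: {bad}")
        onsets = [s.time_ns for s in self.steps]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise InputError("step onsets must be strictly increasing")

    def segments(self) -> list[tuple[str, float, float]]:
        """Run-length segments as (state, start_ns, end_ns) with end exclusive."""
        out = []
        if len(self.states) == 0:
            return out
        start = 0
        for i in range(1, len(self.states) + 1):
            if i == len(self.states) or self.states[i] != self.states[start]:
                end_t = (
                    self.times_ns[i]
                    if i < len(self.states)
                    else self.times_ns[-1]
                    + (self.times_ns[-1] - self.times_ns[-2] if len(self.times_ns) > 1 else 0.0)
                )
                out.append((str(self.states[start]), float(self.times_ns[start]), float(end_t)))
                start = i
        return out

    def state_at(self, time_ns: float) -> str:
        idx = int(np.clip(np.searchsorted(self.times_ns, time_ns, side="right") - 1, 0, len(self.states) - 1))
        return str(self.states[idx])

    def to_json(self, path) -> None:
        payload = {
            "baseline_A": None if np.isnan(self.baseline) else self.baseline,
            "threshold_A": None if np.isnan(self.threshold) else self.threshold,
            "segments": [
                {"state": s, "start_ns": a, "end_ns": b} for s, a, b in self.segments()
            ],
            "steps": [
                {
                    "step": s.step,
                    "time_ns": s.time_ns,
                    "signal": s.signal,
                    "detail": s.detail,
                }
                for s in self.steps
            ],
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=1)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"time_ns": self.times_ns, "state": self.states})


def classify_states(
    com_series: TimeSeries,
    baseline_window: tuple[float, float] = (0.0, 100.0),
    open_offset: float = 5.0,
    smoothing_ns: float = 5.0,
    dwell_ns: float = 50.0,
) -> EventTimeline:
    """Closed/open/transient labels from a COM-distance series.

    baseline = mean distance over ``baseline_window`` (ns); frames whose
    smoothed distance is >= baseline + ``open_offset`` are open. Closed
    stretches strictly between two open stretches shorter than ``dwell_ns``
    are relabelled transient (brief re-attachments).
    """
    if open_offset <= 0:
        raise ConfigurationError("open_offset must be positive")
    t = com_series.times_ns
    b0, b1 = baseline_window
    base_mask = (t >= b0) & (t < b1)
    if not base_mask.any():
        raise ConfigurationError(
            f"baseline window {baseline_window} contains no frames"
        )
    baseline = float(com_series.values[base_mask].mean())
    threshold = baseline + open_offset
    smoothed = com_series.smoothed(smoothing_ns).values
    is_open = smoothed >= threshold - 1e-9

    states = np.array([OPEN if o else CLOSED for o in is_open], dtype=object)
    # transient relabelling: closed runs bracketed by open runs, shorter than dwell
    n = len(states)
    i = 0
    while i < n:
        if states[i] == CLOSED:
            j = i
            while j < n and states[j] == CLOSED:
                j += 1
            bracketed = i > 0 and j < n  # open on both sides
            dt = np.median(np.diff(t)) if n > 1 else 0.0
            duration = (t[j - 1] - t[i]) + dt if j > i else 0.0
            if bracketed and duration < dwell_ns:
                states[i:j] = TRANSIENT
            i = j
        else:
            i += 1
    return EventTimeline(t, states, [], baseline=baseline, threshold=threshold)


def _detect_level_drop(
    series: TimeSeries, window_ns: float, min_drop: float
) -> tuple[float, float] | None:
    """First sustained level drop: time and magnitude, or None.

    Adjacent sliding windows of width ``window_ns`` are compared; the first
    boundary where the trailing mean falls below the leading mean by at
    least ``min_drop`` is refined to the locally largest drop.
    """
    t, v = series.times_ns, series.values
    n = len(v)
    if n < 4:
        return None
    dt = np.median(np.diff(t))
    w = max(2, int(round(window_ns / dt)))
    if 2 * w > n:
        w = n // 2
    csum = np.concatenate([[0.0], np.cumsum(v)])
    before = (csum[w : n - w + 1] - csum[: n - 2 * w + 1]) / w
    after = (csum[2 * w :] - csum[w : n - w + 1]) / w
    drop = before - after  # positive = level decrease at boundary i+w
    crossing = np.flatnonzero(drop >= min_drop)
    if len(crossing) == 0:
        return None
    first = crossing[0]
    lo = max(0, first - w)
    hi = min(len(drop), first + w)
    best = lo + int(np.argmax(drop[lo:hi]))
    boundary_frame = best + w
    return float(t[boundary_frame]), float(drop[best])


def _pair_window_states(
    table: OccupancyTable, key_pairs
) -> tuple[str, np.ndarray] | None:
    """Window-resolved formed/broken states for the first key pair present."""
    for chain_a, num_a, chain_b, num_b in key_pairs:
        row = table.row(chain_a, num_a, chain_b, num_b)
        if row is not None:
            label = table.pair_labels[row]
            return label, table.occupancy[row] >= 0.5
    return None


def annotate_steps(
    timeline: EventTimeline,
    hbond_series: TimeSeries,
    pair_table: OccupancyTable,
    key_pairs=DEFAULT_KEY_PAIRS,
    drop_threshold: float = 1.0,
    drop_window_ns: float = 25.0,
) -> EventTimeline:
    """Annotate the four-step detachment mechanism onto a timeline.

    Returns a new timeline carrying the step annotations (annotation is
    idempotent: previous steps are replaced). When no key pair is present
    in the occupancy table a warning is issued and only the count-signal
    step (Step 1) is reported.
    """
    import warnings

    steps: list[StepAnnotation] = []

    drop = _detect_level_drop(hbond_series, drop_window_ns, drop_threshold)
    if drop is not None:
        t1, magnitude = drop
        steps.append(
            StepAnnotation(
                1,
                t1,
                "hbond_count_drop",
                f"total count drops by {magnitude:.2f}",
            )
        )

    key = _pair_window_states(pair_table, key_pairs)
    if key is None:
        if pair_table.n_pairs or key_pairs:
            warnings.warn(
                "no key residue pair found in occupancy table; "
                "annotating from the count signal only",
                stacklevel=2,
            )
        return EventTimeline(
            timeline.times_ns,
            timeline.states,
            steps,
            timeline.baseline,
            timeline.threshold,
        )
    pair_label, formed = key
    edges = pair_table.window_edges_ns

    def pair_formed_at(time_ns: float) -> bool:
        w = int(np.clip(np.searchsorted(edges, time_ns, side="right") - 1, 0, len(formed) - 1))
        return bool(formed[w])

    segments = timeline.segments()
    last_time = float(timeline.times_ns[-1])

    def after(t_min: float | None) -> float:
        return -np.inf if t_min is None else t_min

    t1 = steps[0].time_ns if steps else None

    # Step 2: first open onset with the key pair broken
    t2 = None
    for state, start, _end in segments:
        if state == OPEN and start > after(t1) and not pair_formed_at(start):
            t2 = start
            steps.append(
                StepAnnotation(2, t2, "open_onset", f"{pair_label} broken")
            )
            break

    # Step 3: first transient re-attachment with the pair re-formed
    t3 = None
    if t2 is not None:
        for state, start, _end in segments:
            if state == TRANSIENT and start > t2 and pair_formed_at(start):
                t3 = start
                steps.append(
                    StepAnnotation(3, t3, "transient_reattachment", f"{pair_label} re-formed")
                )
                break

    # Step 4: permanent loss of the key pair while the timeline stays open
    if t3 is not None:
        broken_windows = np.flatnonzero(~formed)
        t4 = None
        for w in broken_windows:
            if edges[w] <= t3:
                continue
            if formed[w:].any():
                continue  # re-forms later: not permanent
            t4 = float(edges[w])
            break
        if t4 is not None and timeline.state_at(min(t4, last_time)) == OPEN:
            steps.append(
                StepAnnotation(
                    4, t4, "permanent_pair_loss", f"{pair_label} lost, complete dissociation"
                )
            )

    steps.sort(key=lambda s: s.step)
    # enforce strict temporal ordering; omit later steps that violate it
    kept: list[StepAnnotation] = []
    for s in steps:
        if kept and s.time_ns <= kept[-1].time_ns:
            continue
        kept.append(s)
    return EventTimeline(
        timeline.times_ns, timeline.states, kept, timeline.baseline, timeline.threshold
    )
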