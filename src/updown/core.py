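"""Shared data containers for population spike trains and UP/DOWN intervals.

Conventions used throughout the package:

* spike times, interval onsets/offsets and durations are in **seconds**;
* neuronal/synaptic time constants and bin sizes are in **milliseconds**;
* rates are in **Hz**.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PopulationSpikeData", "StateIntervals"]


@dataclass
class PopulationSpikeData:
    """Per-unit spike time lists with recording duration and unit labels.

    Parameters
    ----------
    spikes
        List of 1-D float arrays, one per unit, of strictly increasing spike
        times in seconds.
    duration
        Recording duration in seconds; all spikes fall in ``[0, duration]``.
    unit_labels
        Optional per-unit labels (e.g. ``"E"``/``"I"``); defaults to empty
        strings.
    """

    spikes: list[np.ndarray]
    duration: float
    unit_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spikes = [np.asarray(s, dtype=float) for s in self.spikes]
        if not self.unit_labels:
            self.unit_labels = [""] * len(self.spikes)
        if len(self.unit_labels) != len(self.spikes):
            raise ValueError("unit_labels length must match number of units")
        if self.duration <= 0 and self.n_units > 0 and self.n_spikes > 0:
            raise ValueError("duration must be positive for non-empty data")

    @property
    def n_units(self) -> int:
        return len(self.spikes)

    @property
    def n_spikes(self) -> int:
        return int(sum(len(s) for s in self.spikes))

    def merged(self) -> np.ndarray:
        """All spike times pooled across units, sorted."""
        if not self.spikes:
            return np.empty(0)
        return np.sort(np.concatenate(self.spikes))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns unit_id, population, spike_time_s."""
        rows = []
        for uid, (times, lab) in enumerate(zip(self.spikes, self.unit_labels)):
            rows.append(
                pd.DataFrame(
                    {"unit_id": uid, "population": lab, "spike_time_s": times}
                )
            )
        if not rows:
            return pd.DataFrame(
                columns=["unit_id", "population", "spike_time_s"]
            )
        return pd.concat(rows, ignore_index=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, duration: float | None = None) -> "PopulationSpikeData":
        df = pd.read_csv(path, sep="\t")
        if df.empty:
            return cls(spikes=[], duration=duration or 0.0)
        n = int(df["unit_id"].max()) + 1
        spikes = [np.empty(0)] * n
        labels = [""] * n
        for uid, grp in df.groupby("unit_id"):
            spikes[int(uid)] = np.sort(grp["spike_time_s"].to_numpy(float))
            lab = grp["population"].iloc[0]
            labels[int(uid)] = "" if pd.isna(lab) else str(lab)
        if duration is None:
            duration = float(df["spike_time_s"].max())
        return cls(spikes=spikes, duration=duration, unit_labels=labels)

    def subset(self, unit_ids) -> "PopulationSpikeData":
        return PopulationSpikeData(
            spikes=[self.spikes[i] for i in unit_ids],
            duration=self.duration,
            unit_labels=[self.unit_labels[i] for i in unit_ids],
        )


@dataclass
class StateIntervals:
    """Alternating UP/DOWN segments as ``(state, onset, offset)`` triples.

    The intervals tile the analyzed span without overlap, states strictly
    alternate between ``"U"`` and ``"D"``, and ``offset > onset`` for every
    interval.
    """

    states: list[str]
    onsets: np.ndarray
    offsets: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        n = len(self.states)
        if len(self.onsets) != n or len(self.offsets) != n:
            raise ValueError("states, onsets, offsets must have equal length")
        if np.any(self.offsets <= self.onsets):
            raise ValueError("every interval must have offset > onset")
        for a, b in zip(self.states[:-1], self.states[1:]):
            if a == b:
                raise ValueError("states must strictly alternate")
        if n > 1 and not np.allclose(self.offsets[:-1], self.onsets[1:]):
            raise ValueError("intervals must tile the span without gaps")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def total_duration(self) -> float:
        if len(self) == 0:
            return 0.0
        return float(self.offsets[-1] - self.onsets[0])

    def durations_of(self, state: str) -> np.ndarray:
        mask = np.array([s == state for s in self.states])
        return (self.offsets - self.onsets)[mask]

    def state_at(self, t: np.ndarray) -> np.ndarray:
        """State label for each time in ``t`` (``""`` outside the span)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.onsets, t, side="right") - 1
        out = np.full(t.shape, "", dtype=object)
        ok = (idx >= 0) & (t < self.offsets[np.clip(idx, 0, len(self) - 1)])
        out[ok] = np.array(self.states, dtype=object)[idx[ok]]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"state": self.states, "onset_s": self.onsets, "offset_s": self.offsets}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StateIntervals":
        df = pd.read_csv(path)
        return cls(
            states=[str(s) for s in df["state"]],
            onsets=df["onset_s"].to_numpy(float),
            offsets=df["offset_s"].to_numpy(float),
        )


def intervals_from_labels(
    labels: np.ndarray, t_edges: np.ndarray, min_duration_s: float = 0.0
) -> StateIntervals:
    """Build alternating intervals from a per-bin boolean UP label series.

    Runs of equal labels are merged; runs shorter than ``min_duration_s`` are
    absorbed into their neighbors, iterated to a fixed point (shortest first).

    Parameters
    ----------
    labels
        Boolean array, True for UP, one entry per bin.
    t_edges
        Bin edges, length ``len(labels) + 1`` (seconds).
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.size == 0:
        raise ValueError("empty label series")
    # run-length encode
    change = np.flatnonzero(np.diff(labels.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    run_state = labels[starts].astype(np.int8)
    onsets = t_edges[starts].astype(float)
    offsets = t_edges[ends].astype(float)

    if min_duration_s > 0:
        onsets, offsets, run_state = _merge_short_runs(
            onsets, offsets, run_state, min_duration_s
        )
    states = ["U" if s else "D" for s in run_state]
    return StateIntervals(states=states, onsets=onsets, offsets=offsets)


def _merge_short_runs(onsets, offsets, run_state, min_dur):
    """Repeatedly absorb the shortest sub-minimum run into its neighbors."""
    onsets = list(onsets)
    offsets = list(offsets)
    st = list(run_state)
    while len(st) > 1:
        durs = [b - a for a, b in zip(onsets, offsets)]
        order = int(np.argmin(durs))
        if durs[order] >= min_dur:
            break
        i = order
        if i == 0:
            # absorb into the right neighbor
            onsets[1] = onsets[0]
            del onsets[0], offsets[0], st[0]
        elif i == len(st) - 1:
            offsets[-2] = offsets[-1]
            del onsets[-1], offsets[-1], st[-1]
        else:
            # merging the middle run fuses its two neighbors (same state)
            offsets[i - 1] = offsets[i + 1]
            del onsets[i : i + 2], offsets[i : i + 2], st[i : i + 2]
    return np.array(onsets), np.array(offsets), np.array(st)
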