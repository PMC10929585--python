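"""Core containers and on-disk formats.

The raw material of every analysis stage is a :class:`TraceSet`: a dense
neurons x frames matrix of relative fluorescence changes (dF/F) sampled at
a fixed interval (0.1 s for the miniscope recordings this package targets).
TraceSets round-trip through a plain CSV layout: first column neuron id,
one column per frame, header row carrying frame times in seconds.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["TraceSet", "load_traces", "save_traces"]


@dataclasses.dataclass
class TraceSet:
    """A per-condition matrix of fluorescence traces.

    Parameters
    ----------
    values
        Array of shape ``(n_neurons, n_frames)``. dF/F values are
        non-negative by construction of the indicator signal; forecast
        trajectories reuse this container and may carry negative values.
    dt
        Sampling interval in seconds (0.1 s at 10 frames/s).
    condition
        Label for the experimental condition ("before" | "after" |
        "synthetic").
    neuron_ids
        Identifiers for the rows; defaults to ``0..n_neurons-1``.
    """

    values: np.ndarray
    dt: float = 0.1
    condition: str = "synthetic"
    neuron_ids: Sequence[int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (neurons x frames) array")
        if self.values.shape[1] < 2:
            raise ValueError("a TraceSet needs at least 2 frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.neuron_ids is None:
            self.neuron_ids = list(range(self.values.shape[0]))
        else:
            self.neuron_ids = list(self.neuron_ids)
            if len(self.neuron_ids) != self.values.shape[0]:
                raise ValueError("neuron_ids length must match the number of rows")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds."""
        return np.arange(self.n_frames) * self.dt

    def copy(self, **updates) -> "TraceSet":
        fields = dict(
            values=self.values.copy(),
            dt=self.dt,
            condition=self.condition,
            neuron_ids=list(self.neuron_ids),
        )
        fields.update(updates)
        return TraceSet(**fields)


def save_traces(traces: TraceSet, path: str | Path) -> Path:
    """Write a TraceSet to CSV (first column neuron id, columns = frames)."""
    path = Path(path)
    df = pd.DataFrame(
        traces.values,
        index=pd.Index(traces.neuron_ids, name="neuron"),
        columns=[f"{t:.3f}" for t in traces.times],
    )
    df.to_csv(path)
    return path


def load_traces(path: str | Path, dt: float | None = None, condition: str = "synthetic") -> TraceSet:
    """Read a TraceSet CSV written by :func:`save_traces`.

    ``dt`` is normally recovered from the header times; pass it explicitly to
    override. Malformed numeric cells raise a :class:`ValueError` naming the
    file and offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy(dtype=float, na_value=np.nan)
    if np.isnan(values).any():
        row = int(np.argwhere(np.isnan(values))[0, 0])
        raise ValueError(f"{path}: non-numeric or missing value in row {df.index[row]!r}")
    if dt is None:
        try:
            times = df.columns.astype(float)
            dt = float(times[1] - times[0]) if len(times) > 1 else 0.1
        except (TypeError, ValueError):
            dt = 0.1
    return TraceSet(values=values, dt=dt, condition=condition, neuron_ids=list(df.index))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"cannot serialize {type(obj)!r}")


def dump_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")
    return path
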