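"""Time-series containers, standardization, differentiation and file I/O.

The universal input to every connectivity estimator is a multivariate
recording: ``n_nodes`` simultaneously sampled signals on a uniform time grid.
This module holds that container (:class:`TimeSeries`), the spike-train
container used by the cross-correlogram estimator (:class:`SpikeTrains`), and
the three numerical primitives every estimator is built from:

* per-node z-scoring (population convention, divisor ``n_time``),
* the symmetric difference quotient ``(x[t+1] - x[t-1]) / (2 dt)``,
* the time-averaged outer product ``<a, b> = (1/T) sum_t a_t b_t^T``.

Derivative endpoints are dropped rather than padded; the matching interior
(and trailing) state series are retrievable so that cross-products can be
formed on consistently indexed samples.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "TimeSeries",
    "SpikeTrains",
    "zscore",
    "numerical_derivative",
    "interior",
    "trailing",
    "time_average_outer",
    "read_timeseries",
    "write_timeseries",
    "read_spike_trains",
    "write_spike_trains",
]


def _default_node_ids(n: int) -> tuple[str, ...]:
    return tuple(f"n{i}" for i in range(n))


@dataclass(frozen=True)
class TimeSeries:
    """A ``(n_nodes, n_time)`` real-valued recording on a uniform grid.

    Parameters
    ----------
    values
        Real matrix, rows are nodes, columns are samples.
    dt
        Sampling interval in seconds, strictly positive.
    node_ids
        Unique ordered labels, one per node.
    """

    values: np.ndarray
    dt: float
    node_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D (n_nodes, n_time), got shape {values.shape}")
        if values.shape[1] < 2:
            raise ValueError("a time series needs at least 2 samples")
        if not np.all(np.isfinite(values)):
            raise ValueError("values contain non-finite entries")
        if not (float(self.dt) > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")
        node_ids = tuple(self.node_ids) or _default_node_ids(values.shape[0])
        if len(node_ids) != values.shape[0]:
            raise ValueError(
                f"{len(node_ids)} node_ids for {values.shape[0]} nodes"
            )
        if len(set(node_ids)) != len(node_ids):
            raise ValueError("node_ids must be unique")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "dt", float(self.dt))
        object.__setattr__(self, "node_ids", node_ids)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_time * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_time) * self.dt

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        return replace(self, values=values)


@dataclass(frozen=True)
class SpikeTrains:
    """Per-neuron sorted spike times (seconds) over a recording of ``duration``."""

    spike_times: tuple[np.ndarray, ...]
    duration: float

    def __post_init__(self) -> None:
        if not (float(self.duration) > 0):
            raise ValueError("duration must be positive")
        trains = []
        for i, t in enumerate(self.spike_times):
            t = np.asarray(t, dtype=float)
            if t.ndim != 1:
                raise ValueError(f"spike train {i} is not 1-D")
            if t.size and (t.min() < 0 or t.max() > self.duration):
                raise ValueError(f"spike train {i} has times outside [0, duration]")
            if t.size > 1 and np.any(np.diff(t) <= 0):
                raise ValueError(f"spike train {i} is not strictly increasing")
            trains.append(t)
        object.__setattr__(self, "spike_times", tuple(trains))
        object.__setattr__(self, "duration", float(self.duration))

    @property
    def n_neurons(self) -> int:
        return len(self.spike_times)

    def rates(self) -> np.ndarray:
        """Mean firing rate per neuron in Hz."""
        return np.array([t.size for t in self.spike_times]) / self.duration


# ---------------------------------------------------------------------------
# numerical primitives
# ---------------------------------------------------------------------------

def zscore(ts: TimeSeries) -> TimeSeries:
    """Standardize each node to mean 0 and population (divisor n) sd 1."""
    mean = ts.values.mean(axis=1, keepdims=True)
    sd = ts.values.std(axis=1, keepdims=True)  # population convention
    bad = np.flatnonzero(sd[:, 0] == 0)
    if bad.size:
        names = ", ".join(ts.node_ids[i] for i in bad)
        raise ValueError(f"zero-variance node(s) cannot be z-scored: {names}")
    return ts.with_values((ts.values - mean) / sd)


def numerical_derivative(ts: TimeSeries) -> TimeSeries:
    """Symmetric difference quotient ``(x[t+1] - x[t-1]) / (2 dt)``.

    The result has ``n_time - 2`` samples, indexed like the interior of the
    input (sample ``k`` of the output is the derivative at input sample
    ``k + 1``). Use :func:`interior` or :func:`trailing` to obtain state
    series with matching sample counts.
    """
    if ts.n_time < 3:
        raise ValueError("numerical derivative needs at least 3 samples")
    d = (ts.values[:, 2:] - ts.values[:, :-2]) / (2.0 * ts.dt)
    return ts.with_values(d)


def interior(ts: TimeSeries) -> TimeSeries:
    """State samples aligned with the derivative stencil center (drop endpoints)."""
    if ts.n_time < 3:
        raise ValueError("interior trimming needs at least 3 samples")
    return ts.with_values(ts.values[:, 1:-1])


def trailing(ts: TimeSeries) -> TimeSeries:
    """State samples at the trailing edge of the derivative stencil.

    Sample ``k`` is the state at input time ``k`` while the derivative sample
    ``k`` refers to time ``k + 1``; for stochastic dynamics this pairing keeps
    the state independent of the noise increments inside the stencil.
    """
    if ts.n_time < 3:
        raise ValueError("trailing trimming needs at least 3 samples")
    return ts.with_values(ts.values[:, :-2])


def time_average_outer(a: TimeSeries | np.ndarray, b: TimeSeries | np.ndarray) -> np.ndarray:
    """Time-averaged outer product ``(1/T) sum_t a_t b_t^T`` of shape (n_a, n_b)."""
    av = a.values if isinstance(a, TimeSeries) else np.asarray(a, float)
    bv = b.values if isinstance(b, TimeSeries) else np.asarray(b, float)
    if av.shape[1] != bv.shape[1]:
        raise ValueError(
            f"time-length mismatch: {av.shape[1]} vs {bv.shape[1]} samples"
        )
    return av @ bv.T / av.shape[1]


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_TEXT_FORMATS = {"csv": ",", "tsv": "\t"}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _TEXT_FORMATS or suffix == "npz":
        return suffix
    raise ValueError(f"cannot infer format from extension {path.suffix!r}; pass format=")


def write_timeseries(ts: TimeSeries, path: str | Path, format: str | None = None) -> None:
    """Write a recording as delimited text (``csv``/``tsv``) or binary ``npz``.

    Text layout: a ``# dt=<seconds>`` comment line, then one row per node with
    the node id in the first field. Binary stores values, dt and node ids and
    round-trips bit-exactly.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "npz":
        np.savez(path, values=ts.values, dt=ts.dt, node_ids=np.array(ts.node_ids))
        return
    if fmt not in _TEXT_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected csv, tsv or npz")
    delim = _TEXT_FORMATS[fmt]
    buf = io.StringIO()
    buf.write(f"# dt={ts.dt:.17g}\n")
    for node_id, row in zip(ts.node_ids, ts.values):
        buf.write(node_id + delim + delim.join(f"{v:.17g}" for v in row) + "\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_timeseries(path: str | Path, format: str | None = None,
                    dt: float | None = None) -> TimeSeries:
    """Read a recording written by :func:`write_timeseries`.

    ``dt`` may be supplied explicitly when the text file lacks the
    ``# dt=`` header line.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "npz":
        with np.load(path, allow_pickle=False) as data:
            return TimeSeries(
                values=data["values"],
                dt=float(data["dt"]),
                node_ids=tuple(str(s) for s in data["node_ids"]),
            )
    text = path.read_text(encoding="utf-8")
    file_dt = dt
    rows: list[list[float]] = []
    node_ids: list[str] = []
    width: int | None = None
    delim = "\t" if fmt == "tsv" else ","
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("dt="):
                file_dt = float(body[3:]) if dt is None else dt
            continue
        # autodetect delimiter on the first data line
        if not rows and fmt == "csv" and "\t" in line and "," not in line:
            delim = "\t"
        fields = line.split(delim)
        if len(fields) < 2:
            raise ValueError(f"line {lineno}: expected node id plus samples")
        node_ids.append(fields[0])
        row = []
        for col, cell in enumerate(fields[1:], start=2):
            try:
                row.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"non-numeric cell at row {lineno}, column {col}: {cell!r}"
                ) from None
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise ValueError(
                f"ragged rows: row {lineno} has {len(row)} samples, expected {width}"
            )
        rows.append(row)
    if file_dt is None:
        raise ValueError(f"{path}: no '# dt=' header and no dt argument given")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return TimeSeries(values=np.array(rows), dt=file_dt, node_ids=tuple(node_ids))


def write_spike_trains(spikes: SpikeTrains, path: str | Path) -> None:
    """Write spike trains as two-column text: ``neuron_id spike_time_s``."""
    path = Path(path)
    lines = [f"# duration={spikes.duration:.17g} n_neurons={spikes.n_neurons}"]
    for i, train in enumerate(spikes.spike_times):
        lines.extend(f"{i}\t{t:.17g}" for t in train)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_spike_trains(path: str | Path) -> SpikeTrains:
    path = Path(path)
    duration = None
    n_neurons = None
    per_neuron: dict[int, list[float]] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for token in line.lstrip("#").split():
                if token.startswith("duration="):
                    duration = float(token[9:])
                elif token.startswith("n_neurons="):
                    n_neurons = int(token[10:])
            continue
        fields = line.split()
        if len(fields) != 2:
            raise ValueError(f"line {lineno}: expected 'neuron_id spike_time'")
        per_neuron.setdefault(int(fields[0]), []).append(float(fields[1]))
    if duration is None:
        raise ValueError(f"{path}: missing '# duration=' header")
    n = n_neurons if n_neurons is not None else (max(per_neuron) + 1 if per_neuron else 0)
    trains = tuple(np.array(sorted(per_neuron.get(i, []))) for i in range(n))
    return SpikeTrains(spike_times=trains, duration=duration)
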