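"""In-memory containers shared across the analysis modules.

The recordings this package analyses come in two flavours: sharp-electrode
current clamp (voltages in mV, minis and evoked responses positive-going)
and two-electrode voltage clamp (TEVC; currents in nA, synaptic currents
inward/negative at a -70 mV holding potential).  Containers carry the
recording mode so downstream code can apply the right sign convention.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

CURRENT_CLAMP = "current_clamp"
TEVC = "tevc"
MODES = (CURRENT_CLAMP, TEVC)


@dataclass
class TraceRecording:
    """One uniformly sampled sweep plus its acquisition metadata.

    Parameters
    ----------
    samples : ndarray
        Recorded values, mV (current clamp) or nA (TEVC).
    sampling_rate : float
        Samples per second (Hz).
    stim_times : ndarray
        Stimulus onset times in seconds, sorted, within the trace span.
    mode : {"current_clamp", "tevc"}
    metadata : dict
        Free-form condition labels (genotype, muscle, ca_mM, cell_id, ...).
    """

    samples: np.ndarray
    sampling_rate: float
    stim_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    mode: str = CURRENT_CLAMP
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.stim_times = np.atleast_1d(np.asarray(self.stim_times, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.stim_times.size and (
            np.any(np.diff(self.stim_times) < 0)
            or self.stim_times[0] < 0
            or self.stim_times[-1] > self.duration
        ):
            raise ValueError("stim_times must be sorted and lie within the trace")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate

    @property
    def sign(self) -> float:
        """+1 if synaptic events deflect positive, -1 if negative (TEVC)."""
        return -1.0 if self.mode == TEVC else 1.0

    # ---- round-trippable serialization --------------------------------
    def to_text(self, path) -> None:
        """Two-column (time_s, value) text with '#'-prefixed metadata header."""
        header = _meta_header(self)
        data = np.column_stack([self.times, self.samples])
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, data, fmt="%.9g", delimiter="\t",
                       header="time_s\tvalue", comments="# ")

    @classmethod
    def from_text(cls, path) -> "TraceRecording":
        meta = _read_meta_header(path)
        data = np.loadtxt(path, delimiter="\t", comments="#")
        data = np.atleast_2d(data)
        return cls(samples=data[:, 1], **meta)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("time_s", data=self.times)
            fh.create_dataset("value", data=self.samples)
            fh.attrs["sampling_rate"] = self.sampling_rate
            fh.attrs["mode"] = self.mode
            fh.attrs["stim_times"] = self.stim_times
            fh.attrs["metadata"] = json.dumps(self.metadata)

    @classmethod
    def from_hdf5(cls, path) -> "TraceRecording":
        with h5py.File(path, "r") as fh:
            return cls(
                samples=fh["value"][:],
                sampling_rate=float(fh.attrs["sampling_rate"]),
                stim_times=np.asarray(fh.attrs["stim_times"], dtype=float),
                mode=str(fh.attrs["mode"]),
                metadata=json.loads(fh.attrs["metadata"]),
            )


def _meta_header(trace: TraceRecording) -> str:
    lines = [
        f"# sampling_rate: {float(trace.sampling_rate)!r}",
        f"# mode: {trace.mode}",
        "# stim_times: " + ",".join(f"{float(t)!r}" for t in trace.stim_times),
        "# metadata: " + json.dumps(trace.metadata),
    ]
    return "\n".join(lines) + "\n"


def _read_meta_header(path) -> dict:
    meta = {"sampling_rate": None, "mode": CURRENT_CLAMP,
            "stim_times": np.empty(0), "metadata": {}}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" not in body:
                continue
            key, _, value = body.partition(":")
            key, value = key.strip(), value.strip()
            if key == "sampling_rate":
                meta["sampling_rate"] = float(value)
            elif key == "mode":
                meta["mode"] = value
            elif key == "stim_times":
                meta["stim_times"] = (
                    np.array([float(v) for v in value.split(",") if v])
                )
            elif key == "metadata":
                meta["metadata"] = json.loads(value) if value else {}
    if meta["sampling_rate"] is None:
        raise ValueError(f"{path}: missing sampling_rate header")
    return meta


@dataclass
class TrainResponse:
    """Per-stimulus evoked amplitudes of a high-frequency train (magnitudes)."""

    amplitudes: np.ndarray
    freq: float
    ca_mM: float | None = None
    cell_id: str | None = None

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.freq <= 0:
            raise ValueError("freq must be positive")

    @property
    def stimulus_times(self) -> np.ndarray:
        """t_k = (k - 1)/freq: the first stimulus defines time zero."""
        return np.arange(self.amplitudes.size) / self.freq

    @property
    def n_stimuli(self) -> int:
        return int(self.amplitudes.size)


@dataclass
class VarianceMeanPoint:
    """Across-sweep mean and unbiased variance of evoked amplitude at one Ca level."""

    ca_mM: float
    mean_amp: float
    variance: float
    n_sweeps: int
    cell_id: str | None = None
    theoretical: bool = False  # the Ca-free origin point

    def __post_init__(self):
        if self.variance < 0:
            raise ValueError("variance must be nonnegative")
        if not self.theoretical and self.n_sweeps < 2:
            raise ValueError("measured points need at least 2 sweeps")


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Tidy delimited export with '#'-prefixed metadata header lines."""
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def asdict_shallow(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
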