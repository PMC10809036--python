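"""File readers and writers for the detection pipeline.

Calcium input follows the Suite2p array convention (``F.npy``, ``Fneu.npy``,
``iscell.npy`` and either ``positions.npy`` in micrometers or ``stat.npy``
with ``med`` centroids); EEG is read from a two-column CSV or an EDF file
(EDF requires the optional ``pyedflib`` dependency).  Outputs are plain CSV
and JSON tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ..cell_recruitment import RecruitmentResult
from ..eeg_events import EEGRecording
from ..population_events import EventSeeds
from ..signal_core import CalciumRecording

__all__ = [
    "load_suite2p",
    "load_eeg_csv",
    "load_eeg_edf",
    "load_labels_csv",
    "write_events_csv",
    "write_recruitment_csv",
    "read_recruitment_csv",
]


def load_suite2p(
    directory: str | Path,
    frame_rate: float | None = None,
    t0_offset: float | None = None,
    um_per_pixel: float = 1.0,
    use_iscell: bool = True,
) -> CalciumRecording:
    """Load a Suite2p-convention directory into a :class:`CalciumRecording`.

    ``meta.json`` (if present) supplies ``frame_rate`` and ``t0_offset``;
    explicit arguments override it.  Positions are read from
    ``positions.npy`` (micrometers) or, failing that, from ``stat.npy``
    ``med`` fields ([y, x] pixels) scaled by ``um_per_pixel`` with the y
    axis flipped to a standard math convention.
    """
    d = Path(directory)
    soma = np.load(d / "F.npy")
    neuropil = np.load(d / "Fneu.npy")

    meta = {}
    if (d / "meta.json").exists():
        meta = json.loads((d / "meta.json").read_text())
    frame_rate = frame_rate if frame_rate is not None else meta.get("frame_rate")
    if frame_rate is None:
        raise ValueError("frame_rate not given and not found in meta.json")
    t0_offset = t0_offset if t0_offset is not None else meta.get("t0_offset", 0.0)

    if (d / "positions.npy").exists():
        positions = np.load(d / "positions.npy")
    elif (d / "stat.npy").exists():
        stat = np.load(d / "stat.npy", allow_pickle=True)
        med = np.array([s["med"] for s in stat], dtype=float)  # [y, x] pixels
        positions = np.column_stack([med[:, 1], -med[:, 0]]) * um_per_pixel
    else:
        raise FileNotFoundError("neither positions.npy nor stat.npy found")

    if use_iscell and (d / "iscell.npy").exists():
        iscell = np.load(d / "iscell.npy")
        keep = iscell[:, 0].astype(bool)
        soma, neuropil, positions = soma[keep], neuropil[keep], positions[keep]

    return CalciumRecording(
        soma_raw=soma,
        neuropil_raw=neuropil,
        positions=positions,
        frame_rate=float(frame_rate),
        t0_offset=float(t0_offset),
    )


def load_eeg_csv(path: str | Path, bandpass: tuple[float, float] = (0.5, 300.0)) -> EEGRecording:
    """Read a two-column (time_s, value) CSV into an :class:`EEGRecording`."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError("EEG CSV must have two columns (time, value)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("EEG CSV time column must be uniformly sampled")
    return EEGRecording(samples=v, fs=1.0 / float(dt[0]), bandpass=bandpass, t0=float(t[0]))


def load_eeg_edf(
    path: str | Path, channel: int | str = 0, bandpass: tuple[float, float] = (0.5, 300.0)
) -> EEGRecording:
    """Read one channel of an EDF file (requires ``pyedflib``)."""
    try:
        import pyedflib
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF support requires the optional 'pyedflib' package; "
            "use a two-column CSV otherwise"
        ) from exc
    with pyedflib.EdfReader(str(path)) as f:  # pragma: no cover
        if isinstance(channel, str):
            channel = f.getSignalLabels().index(channel)
        samples = f.readSignal(channel)
        fs = f.getSampleFrequency(channel)
    return EEGRecording(samples=samples, fs=float(fs), bandpass=bandpass)


def load_labels_csv(path: str | Path) -> pd.DataFrame:
    """Manual event labels: columns ``event_type,time_s`` and optional ``cell``."""
    df = pd.read_csv(path)
    required = {"event_type", "time_s"}
    if not required <= set(df.columns):
        raise ValueError(f"labels CSV must contain columns {sorted(required)}")
    if "cell" not in df.columns:
        df["cell"] = "population"
    return df


def write_events_csv(seeds: EventSeeds, path: str | Path) -> None:
    rows = [
        {"event_type": "pis", "time_s": t, "provenance": prov}
        for t, prov in zip(seeds.pis_times, seeds.pis_provenance)
    ]
    if seeds.seizure_time is not None:
        rows.append({"event_type": "seizure", "time_s": seeds.seizure_time, "provenance": "half_max"})
    if seeds.terminal_time is not None:
        rows.append({"event_type": "terminal", "time_s": seeds.terminal_time, "provenance": "half_max"})
    pd.DataFrame(rows, columns=["event_type", "time_s", "provenance"]).to_csv(path, index=False)


def write_recruitment_csv(results: list[RecruitmentResult], path: str | Path) -> None:
    rows = [
        {
            "cell": r.cell_index,
            "event_type": r.event_type,
            "seed_time_s": r.event_seed_time,
            "recruited": r.recruited,
            "time_s": r.recruitment_time if r.recruitment_time is not None else np.nan,
            "feature": r.feature if r.feature is not None else np.nan,
        }
        for r in results
    ]
    pd.DataFrame(
        rows, columns=["cell", "event_type", "seed_time_s", "recruited", "time_s", "feature"]
    ).to_csv(path, index=False)


def read_recruitment_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
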