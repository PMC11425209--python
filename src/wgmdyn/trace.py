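"""In-memory containers and text I/O for sensor traces and spectra.

A trace is two synchronously sampled channels: the resonance-wavelength
shift Δλ(t) and the linewidth (FWHM) δλ(t). On disk it is a delimited text
file with header ``time_s  dlambda_m  fwhm_m``; the simulation ground truth
travels in a JSON sidecar ``<name>.truth.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

TRACE_COLUMNS = ("time_s", "dlambda_m", "fwhm_m")


@dataclass
class TimeTrace:
    """Uniformly sampled Δλ(t) and δλ(t) channels (SI units)."""

    t: np.ndarray  # s, strictly increasing, uniform
    dlambda: np.ndarray  # m
    fwhm: np.ndarray  # m

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.dlambda = np.asarray(self.dlambda, dtype=float)
        self.fwhm = np.asarray(self.fwhm, dtype=float)
        n = self.t.size
        if n < 2 or self.dlambda.size != n or self.fwhm.size != n:
            raise ValueError("trace channels must share a common length >= 2")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("sample times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
            raise ValueError("sample times must be uniformly spaced")

    @property
    def dt(self) -> float:
        """Sample interval (s)."""
        return float(self.t[1] - self.t[0])

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.dt

    def __len__(self) -> int:
        return self.t.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.t, "dlambda_m": self.dlambda, "fwhm_m": self.fwhm}
        )


@dataclass
class GroundTruth:
    """Injected-signal sidecar for simulated traces.

    ``events`` are (onset ω [s], duration τ [s], amplitude A [m]) triples,
    non-overlapping and sorted by onset; ``binding_steps`` are (time [s],
    amplitude [m]) pairs of permanent shifts.
    """

    events: list[tuple[float, float, float]] = field(default_factory=list)
    binding_steps: list[tuple[float, float]] = field(default_factory=list)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.events = [tuple(map(float, e)) for e in self.events]
        self.binding_steps = [tuple(map(float, b)) for b in self.binding_steps]
        onsets = [e[0] for e in self.events]
        if onsets != sorted(onsets):
            raise ValueError("ground-truth events must be sorted by onset")
        for (w0, tau0, _), (w1, _, _) in zip(self.events, self.events[1:]):
            if w0 + tau0 > w1:
                raise ValueError("ground-truth events must not overlap")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "events": [list(e) for e in self.events],
            "binding_steps": [list(b) for b in self.binding_steps],
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            events=[tuple(e) for e in payload["events"]],
            binding_steps=[tuple(b) for b in payload["binding_steps"]],
            seed=payload.get("seed"),
        )


@dataclass
class TransmissionSpectrum:
    """Normalized cavity transmission versus wavelength: a Lorentzian dip."""

    wavelength: np.ndarray  # m
    transmission: np.ndarray  # [0, 1]
    S_i: float  # dip depth (coupling efficiency)
    dlambda_i: float  # FWHM (m)

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.transmission = np.asarray(self.transmission, dtype=float)
        if self.wavelength.size != self.transmission.size:
            raise ValueError("wavelength and transmission grids differ in length")


def truth_sidecar_path(trace_path: str | Path) -> Path:
    p = Path(trace_path)
    return p.with_suffix(p.suffix + ".truth.json").with_name(p.stem + ".truth.json")


def write_trace(
    trace: TimeTrace,
    path: str | Path,
    truth: Optional[GroundTruth] = None,
    sep: str = "\t",
) -> None:
    """Write a trace as delimited text; optionally write the truth sidecar."""
    trace.to_frame().to_csv(path, sep=sep, index=False, float_format="%.17g")
    if truth is not None:
        truth.to_json(truth_sidecar_path(path))


def read_trace(path: str | Path) -> TimeTrace:
    """Read a delimited-text trace (tab or comma; header required).

    Raises
    ------
    ValueError
        On missing columns, malformed rows, or a non-monotone time column.
    """
    try:
        with open(path) as fh:
            header = fh.readline()
        sep = "," if "," in header else r"\s+"
        # round_trip parsing so written doubles read back bit-identically
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except OSError:
        raise
    except Exception as exc:
        raise ValueError(f"could not parse trace file {path}: {exc}") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file {path} lacks required columns {missing}")
    sub = df.loc[:, list(TRACE_COLUMNS)]
    if sub.isna().any().any():
        raise ValueError(f"trace file {path} contains malformed/missing values")
    return TimeTrace(
        t=sub["time_s"].to_numpy(),
        dlambda=sub["dlambda_m"].to_numpy(),
        fwhm=sub["fwhm_m"].to_numpy(),
    )


def read_truth(path: str | Path) -> GroundTruth:
    """Read the ground-truth sidecar belonging to ``path`` (or a .json path)."""
    p = Path(path)
    if p.suffix != ".json":
        p = truth_sidecar_path(p)
    return GroundTruth.from_json(p)


def events_to_frame(events: Sequence) -> pd.DataFrame:
    """Tabulate detected events (see :class:`wgmdyn.detect.Event`)."""
    return pd.DataFrame(
        [
            {
                "onset_s": e.onset,
                "duration_s": e.duration,
                "amplitude_m": e.amplitude,
                "dnu_hz": e.dnu,
                "kind": e.kind,
                "dwell_s": e.dwell,
            }
            for e in events
        ]
    )
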