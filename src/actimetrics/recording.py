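"""Raw tri-axial recording container and its CSV contract."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RawRecording:
    """Timestamped tri-axial samples in gravitational units (g).

    ``truth`` holds per-sample behaviour labels when the recording is
    synthetic; ``calib_truth`` the injected (offset g, scale) sensor
    error, if any.
    """

    sample_rate: float
    t0: np.datetime64
    samples: np.ndarray  # (n, 3) in g
    truth: np.ndarray | None = None
    calib_truth: tuple | None = None

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        self.t0 = np.datetime64(self.t0, "s")
        if self.truth is not None and len(self.truth) != len(self.samples):
            raise ValueError("truth labels must match sample count")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(pd.Timestamp(self.t0), periods=self.n_samples,
                             freq=pd.Timedelta(seconds=1 / self.sample_rate))

    def to_csv(self, path, include_truth: bool = False) -> None:
        """Write the `timestamp,x,y,z[,label]` CSV contract."""
        df = pd.DataFrame(self.samples, columns=["x", "y", "z"])
        df.insert(0, "timestamp", self.timestamps().strftime("%Y-%m-%dT%H:%M:%S.%f"))
        if include_truth and self.truth is not None:
            df["label"] = self.truth
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RawRecording":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        ts = df["timestamp"]
        if len(df) < 2:
            raise ValueError("recording CSV needs at least two samples")
        dt = (ts.iloc[1] - ts.iloc[0]).total_seconds()
        truth = df["label"].to_numpy() if "label" in df.columns else None
        return cls(
            sample_rate=1.0 / dt,
            t0=np.datetime64(ts.iloc[0]).astype("datetime64[s]"),
            samples=df[["x", "y", "z"]].to_numpy(),
            truth=truth,
        )


def read_diary(path) -> pd.DataFrame:
    """Read the diary CSV contract: start,end,type with type in
    {sleep, offbody}."""
    df = pd.read_csv(path, parse_dates=["start", "end"])
    bad = set(df["type"]) - {"sleep", "offbody"}
    if bad:
        raise ValueError(f"unknown diary interval types: {sorted(bad)}")
    return df
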