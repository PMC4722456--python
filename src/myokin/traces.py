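"""Time-resolved kinetic trace container and plain-text round trip.

A :class:`KineticTrace` is one optical transient — flash-photolysis light
scattering (acto-S1 dissociation), intrinsic tryptophan fluorescence (ATP
binding/hydrolysis by S1) or coumarin-ADP displacement — together with the
experimental conditions it was recorded under.  Traces serialize to CSV with
``# key: value`` metadata header lines followed by ``time_s,signal_au``
columns, so that a trace file regenerates the exact container.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SIGNAL_TYPES = ("light_scattering", "trp_fluorescence", "coumarin_fluorescence")


@dataclass(frozen=True)
class KineticTrace:
    """One time-resolved signal with its conditions and noise metadata.

    time in s (strictly increasing, ≥ 50 points), signal in arbitrary
    units; ``atp``/``adp`` are post-mixing concentrations in μM.
    """

    time: np.ndarray
    signal: np.ndarray
    signal_type: str
    atp: float = 0.0
    adp: float = 0.0
    genotype: str = ""
    noise_sd: float = 0.0
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "signal", np.asarray(self.signal, dtype=float))
        if self.signal_type not in SIGNAL_TYPES:
            raise ValueError(f"unknown signal_type {self.signal_type!r}")
        if self.time.size < 50:
            raise ValueError(f"trace needs >= 50 points, got {self.time.size}")
        if self.time.size != self.signal.size:
            raise ValueError("time and signal length mismatch")
        if self.time[0] < 0:
            raise ValueError("time must start at or after 0")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.atp < 0 or self.adp < 0:
            raise ValueError("conditions must be non-negative")

    @property
    def n_points(self) -> int:
        return int(self.time.size)

    def to_csv(self, path_or_buf) -> None:
        header = {
            "signal_type": self.signal_type,
            "atp_uM": self.atp,
            "adp_uM": self.adp,
            "genotype": self.genotype,
            "noise_sd": self.noise_sd,
            "seed": "" if self.seed is None else self.seed,
        }
        lines = "".join(f"# {k}: {v}\n" for k, v in header.items())
        body = pd.DataFrame({"time_s": self.time, "signal_au": self.signal}).to_csv(index=False)
        text = lines + body
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_csv(cls, path_or_buf) -> "KineticTrace":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        meta: dict = {}
        body_lines = []
        for line in text.splitlines():
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
            elif line.strip():
                body_lines.append(line)
        frame = pd.read_csv(io.StringIO("\n".join(body_lines)))
        seed = meta.get("seed", "")
        return cls(
            time=frame["time_s"].to_numpy(),
            signal=frame["signal_au"].to_numpy(),
            signal_type=meta.get("signal_type", "light_scattering"),
            atp=float(meta.get("atp_uM", 0.0)),
            adp=float(meta.get("adp_uM", 0.0)),
            genotype=meta.get("genotype", ""),
            noise_sd=float(meta.get("noise_sd", 0.0)),
            seed=None if seed == "" else int(seed),
        )
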