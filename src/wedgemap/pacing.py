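"""Pacing protocols for wedge optical-mapping experiments.

Two protocol families are supported: *dynamic* restitution pacing
(incremental trains at fixed frequencies, typically 1-5 Hz) and the
*extrastimulus* (S1-S2) protocol used to measure the effective
refractory period.  A protocol is a declarative description; the
explicit stimulus schedule is derived from it.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator


class PacingProtocol(BaseModel):
    """Declarative pacing schedule.

    Parameters
    ----------
    kind:
        ``"dynamic"`` for incremental fixed-frequency trains or
        ``"extrastimulus"`` for an S1-S2 protocol.
    frequencies_hz:
        Pacing frequencies for the dynamic protocol, in the order they
        are applied.  The study protocol ramps from 1 to 5 Hz.
    beats_per_frequency:
        Number of S1 stimuli delivered at each dynamic frequency.
    s1_interval_ms, s1_count:
        S1 drive-train settings for the extrastimulus protocol.
    s2_intervals_ms:
        S1-S2 coupling intervals tested, one block per interval
        (conventionally descending).
    block_gap_ms:
        Rest period inserted after each S2 before the next S1 train.
    stimulus_site:
        (row, col) pixel of the pacing electrode.
    start_ms:
        Time of the first stimulus.
    """

    kind: Literal["dynamic", "extrastimulus"] = "dynamic"
    frequencies_hz: list[float] = Field(default_factory=lambda: [1.0])
    beats_per_frequency: int = 8
    s1_interval_ms: float = 600.0
    s1_count: int = 4
    s2_intervals_ms: list[float] = Field(default_factory=list)
    block_gap_ms: float = 1500.0
    stimulus_site: tuple[int, int] = (50, 50)
    start_ms: float = 100.0

    @model_validator(mode="after")
    def _check(self) -> "PacingProtocol":
        if self.kind == "dynamic":
            if not self.frequencies_hz:
                raise ValueError("dynamic protocol requires at least one frequency")
            if any(f <= 0 for f in self.frequencies_hz):
                raise ValueError("pacing frequencies must be positive")
            if self.beats_per_frequency < 1:
                raise ValueError("beats_per_frequency must be >= 1")
        else:
            if not self.s2_intervals_ms:
                raise ValueError("extrastimulus protocol requires s2_intervals_ms")
            if self.s1_interval_ms <= 0 or self.s1_count < 1:
                raise ValueError("invalid S1 train settings")
            if any(c <= 0 for c in self.s2_intervals_ms):
                raise ValueError("S2 coupling intervals must be positive")
        return self

    # ------------------------------------------------------------------
    def stimulus_table(self) -> pd.DataFrame:
        """Explicit stimulus schedule.

        Returns a frame with columns ``time_ms``, ``label`` (``s1`` or
        ``s2``), ``frequency_hz`` (NaN for S1-S2 blocks), and
        ``coupling_ms`` (NaN except on S2 stimuli).
        """
        rows: list[tuple[float, str, float, float]] = []
        t = float(self.start_ms)
        if self.kind == "dynamic":
            for f in self.frequencies_hz:
                bcl = 1000.0 / f
                for _ in range(self.beats_per_frequency):
                    rows.append((t, "s1", f, np.nan))
                    t += bcl
        else:
            for coupling in self.s2_intervals_ms:
                for _ in range(self.s1_count):
                    rows.append((t, "s1", np.nan, np.nan))
                    t += self.s1_interval_ms
                t_s2 = rows[-1][0] + coupling
                rows.append((t_s2, "s2", np.nan, coupling))
                t = t_s2 + self.block_gap_ms
        df = pd.DataFrame(rows, columns=["time_ms", "label", "frequency_hz", "coupling_ms"])
        if not df["time_ms"].is_monotonic_increasing:
            raise ValueError("stimulus times are not strictly increasing")
        return df

    def stimulus_times(self) -> np.ndarray:
        """Stimulus times in ms, strictly increasing."""
        return self.stimulus_table()["time_ms"].to_numpy()

    @property
    def last_stimulus_ms(self) -> float:
        return float(self.stimulus_times()[-1])


def dynamic_protocol(
    frequencies_hz=(1.0,),
    beats_per_frequency: int = 8,
    stimulus_site: tuple[int, int] = (50, 50),
    start_ms: float = 100.0,
) -> PacingProtocol:
    """Convenience constructor for a dynamic restitution protocol."""
    return PacingProtocol(
        kind="dynamic",
        frequencies_hz=list(frequencies_hz),
        beats_per_frequency=beats_per_frequency,
        stimulus_site=stimulus_site,
        start_ms=start_ms,
    )


def s1s2_protocol(
    s2_intervals_ms,
    s1_interval_ms: float = 600.0,
    s1_count: int = 4,
    stimulus_site: tuple[int, int] = (50, 50),
    block_gap_ms: float = 1500.0,
    start_ms: float = 100.0,
) -> PacingProtocol:
    """Convenience constructor for an S1-S2 (extrastimulus) protocol."""
    return PacingProtocol(
        kind="extrastimulus",
        s2_intervals_ms=list(s2_intervals_ms),
        s1_interval_ms=s1_interval_ms,
        s1_count=s1_count,
        stimulus_site=stimulus_site,
        block_gap_ms=block_gap_ms,
        start_ms=start_ms,
    )
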