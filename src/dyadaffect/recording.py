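"""Containers for dyadic physiological recordings.

A :class:`DyadRecording` holds the four raw autonomic signals (ECG,
electrodermal activity, respiration airflow, peripheral skin temperature)
for both members of a dyad, together with the six-segment structure of a
session: a 4-min initial baseline, four 4-min conversation scenarios in
randomized order, and a 4-min final baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labels import SCENARIOS, SIGNALS

PARTICIPANTS = ("p1", "p2")


@dataclass(frozen=True)
class Segment:
    """One contiguous session segment, [start_sample, end_sample) at ``fs``.

    ``label`` is the scenario label for conversation segments and ``None``
    for the two baselines.
    """

    name: str
    start_sample: int
    end_sample: int
    label: str | None = None

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


@dataclass
class DyadRecording:
    """Raw signals plus segment metadata for one dyad.

    Parameters
    ----------
    dyad_id : str
        Identifier used for grouping in cross-validation.
    fs : float
        Sampling rate in Hz (all eight channels share it).
    signals : dict
        ``signals[participant][signal]`` -> full-session 1-D array;
        participants are ``"p1"``/``"p2"``, signals ``ecg`` (mV),
        ``eda`` (µS), ``resp`` (arbitrary airflow units), ``temp`` (°C).
    segments : list of Segment
        Exactly six, ordered, non-overlapping, within series length.
    truth : dict, optional
        Generator ground truth (beat/breath/SCR event times in absolute
        session seconds and the latent instantaneous-rate series), kept for
        oracle tests; absent for recordings loaded from disk.
    """

    dyad_id: str
    fs: float
    signals: dict[str, dict[str, np.ndarray]]
    segments: list[Segment]
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.segments) != 6:
            raise ValueError(f"expected 6 segments, got {len(self.segments)}")
        n = None
        for p in PARTICIPANTS:
            if p not in self.signals:
                raise ValueError(f"missing participant {p!r}")
            for sig in SIGNALS:
                arr = self.signals[p][sig]
                if n is None:
                    n = len(arr)
                elif len(arr) != n:
                    raise ValueError("all channels must have equal length")
        prev_end = 0
        for seg in self.segments:
            if seg.start_sample < prev_end or seg.end_sample <= seg.start_sample:
                raise ValueError("segments must be ordered and non-overlapping")
            if seg.end_sample > n:
                raise ValueError("segment extends past series length")
            prev_end = seg.end_sample
        labels = [s.label for s in self.segments if s.label is not None]
        if sorted(labels) != sorted(SCENARIOS):
            raise ValueError(
                "conversation segments must carry the four distinct scenario labels"
            )

    @property
    def n_samples(self) -> int:
        return len(self.signals["p1"]["ecg"])

    @property
    def conversation_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.label is not None]

    def segment_by_name(self, name: str) -> Segment:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(name)

    def slice(self, participant: str, signal: str, segment: Segment) -> np.ndarray:
        """Samples of one channel within a segment (half-open indexing)."""
        return self.signals[participant][signal][
            segment.start_sample : segment.end_sample
        ]

    def swapped(self) -> "DyadRecording":
        """The same recording with participants p1/p2 exchanged.

        Used by exchange-symmetry tests: all dyad-level features must be
        invariant under this operation.
        """
        sw = {"p1": self.signals["p2"], "p2": self.signals["p1"]}
        truth = None
        if self.truth is not None:
            truth = dict(self.truth)
            t1, t2 = truth.get("p1"), truth.get("p2")
            truth["p1"], truth["p2"] = t2, t1
        return DyadRecording(
            dyad_id=self.dyad_id,
            fs=self.fs,
            signals=sw,
            segments=list(self.segments),
            truth=truth,
        )
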