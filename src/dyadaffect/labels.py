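"""Scenario labels and the valence/arousal factorization.

The four conversation scenarios occupy the quadrants of the circumplex
affect model: positive/negative valence crossed with high/low arousal.
All modules use the canonical label order defined here, including
confusion-matrix row/column order and prediction tie-breaking.
"""

from __future__ import annotations

SCENARIOS: tuple[str, ...] = ("PV-HA", "PV-LA", "NV-HA", "NV-LA")

VALENCE: dict[str, str] = {"PV-HA": "P", "PV-LA": "P", "NV-HA": "N", "NV-LA": "N"}
AROUSAL: dict[str, str] = {"PV-HA": "H", "PV-LA": "L", "NV-HA": "H", "NV-LA": "L"}

SEGMENT_NAMES: tuple[str, ...] = (
    "baseline1",
    "conversation1",
    "conversation2",
    "conversation3",
    "conversation4",
    "baseline2",
)

CONVERSATION_SEGMENTS: tuple[str, ...] = SEGMENT_NAMES[1:5]

SIGNALS: tuple[str, ...] = ("ecg", "eda", "resp", "temp")


def label_from_axes(valence: str, arousal: str) -> str:
    """Map a (valence, arousal) pair back to the 4-class scenario label."""
    for lab in SCENARIOS:
        if VALENCE[lab] == valence and AROUSAL[lab] == arousal:
            return lab
    raise ValueError(f"unknown valence/arousal pair: {valence!r}/{arousal!r}")
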