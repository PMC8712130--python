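"""Electrode montage, channel aliases and analysis cluster definitions.

The recording montage is the 20-channel ambulatory layout used for the
child cohort: a prefrontal blink-monitoring channel (Fpz) plus 19 scalp
channels referenced to linked earlobes.  Clusters are named sets of
channels whose band powers are averaged before statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Recording montage, in amplifier order.
CHANNELS: tuple[str, ...] = (
    "Fpz", "Fz", "F3", "F4", "F7", "F8",
    "Cz", "C3", "C4", "T7", "T8",
    "Pz", "P3", "P4", "P7", "P8",
    "Cp5", "Cp6", "O1", "O2",
)

#: Channel used for blink detection/removal; excluded from analysis clusters.
BLINK_CHANNEL = "Fpz"

#: Old 10-20 temporal/posterior names mapped onto the modern labels
#: actually recorded (T3/T4 -> T7/T8, T5/T6 -> P7/P8).
CHANNEL_ALIASES: dict[str, str] = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}


def resolve_channel(name: str, apply_aliases: bool = True) -> str:
    """Map a channel label onto the montage, applying the alias table."""
    if name in CHANNELS:
        return name
    if apply_aliases and name in CHANNEL_ALIASES:
        return CHANNEL_ALIASES[name]
    raise KeyError(f"channel {name!r} not in montage {CHANNELS}")


@dataclass(frozen=True)
class ClusterDef:
    """A named set of scalp channels averaged together before statistics."""

    name: str
    channels: tuple[str, ...]

    def resolved(self, apply_aliases: bool = True) -> tuple[str, ...]:
        return tuple(resolve_channel(c, apply_aliases) for c in self.channels)


#: The 19 analysis channels (everything except the blink channel).
EI_CHANNELS: tuple[str, ...] = tuple(c for c in CHANNELS if c != BLINK_CHANNEL)

#: Default cluster table.  ``parietal`` follows the methods definition
#: {P3, P4, P7, P8}; ``parietal_pz`` is the alternative with Pz substituted
#: for P4 that appears in the results table.  The right-hemisphere set is
#: written with the legacy "T4" label and resolved through the alias map.
CLUSTERS: dict[str, ClusterDef] = {
    "frontal": ClusterDef("frontal", ("F3", "F4", "F7", "F8", "Fz")),
    "parietal": ClusterDef("parietal", ("P3", "P4", "P7", "P8")),
    "parietal_pz": ClusterDef("parietal_pz", ("Pz", "P3", "P7", "P8")),
    "occipital": ClusterDef("occipital", ("O1", "O2")),
    "midline": ClusterDef("midline", ("Fz", "Cz", "Pz")),
    "left_hemisphere": ClusterDef("left_hemisphere", ("F3", "C3", "T7", "P3", "O1")),
    "right_hemisphere": ClusterDef("right_hemisphere", ("F4", "C4", "T4", "P4", "O2")),
    "ei_set": ClusterDef("ei_set", EI_CHANNELS),
}

#: Posterior channels used by default for individual-alpha-frequency
#: estimation from the eyes-closed segment.
IAF_CHANNELS: tuple[str, ...] = ("O1", "O2", "Pz")
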