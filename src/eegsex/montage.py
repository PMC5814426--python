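"""The 26-channel 10-20 recording montage.

Channel order follows the acquisition montage of the study cohort
(NuAmps Quikcap, averaged-mastoid reference).  2-D positions are a
schematic projection of the 10-20 layout onto the unit disc (nose up,
left ear at x < 0) and are used only for topographic rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MontageError

#: Acquisition channel order.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC3", "FCz", "FC4", "T3", "C3", "Cz", "C4", "T4",
    "CP3", "CPz", "CP4", "T5", "P3", "Pz", "P4", "T6",
    "O1", "Oz", "O2",
)

#: Channels kept for the network input (O2 and Oz dropped so the channel
#: axis factorizes as 3 x 2 x 2 x 2, allowing maximal pooling depth).
DEFAULT_KEEP: tuple[str, ...] = tuple(
    ch for ch in DEFAULT_CHANNELS if ch not in ("O2", "Oz")
)

LEFT_CHANNELS: tuple[str, ...] = tuple(
    ch for ch in DEFAULT_CHANNELS if ch[-1].isdigit() and int(ch[-1]) % 2 == 1
)
RIGHT_CHANNELS: tuple[str, ...] = tuple(
    ch for ch in DEFAULT_CHANNELS if ch[-1].isdigit() and int(ch[-1]) % 2 == 0
)

# Schematic unit-disc coordinates (x, y), outer 10-20 ring at radius 0.95.
_R = 0.95
_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.309 * _R, 0.951 * _R), "Fp2": (0.309 * _R, 0.951 * _R),
    "F7": (-0.809 * _R, 0.588 * _R), "F8": (0.809 * _R, 0.588 * _R),
    "F3": (-0.42, 0.43), "Fz": (0.0, 0.45), "F4": (0.42, 0.43),
    "FC3": (-0.46, 0.22), "FCz": (0.0, 0.22), "FC4": (0.46, 0.22),
    "T3": (-_R, 0.0), "C3": (-0.48, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.48, 0.0), "T4": (_R, 0.0),
    "CP3": (-0.46, -0.22), "CPz": (0.0, -0.22), "CP4": (0.46, -0.22),
    "T5": (-0.809 * _R, -0.588 * _R), "T6": (0.809 * _R, -0.588 * _R),
    "P3": (-0.42, -0.43), "Pz": (0.0, -0.45), "P4": (0.42, -0.43),
    "O1": (-0.309 * _R, -0.951 * _R), "Oz": (0.0, -_R),
    "O2": (0.309 * _R, -0.951 * _R),
}


def _group(label: str) -> str:
    if label.endswith(("z", "Z")):
        return "midline"
    return "left" if int(label[-1]) % 2 == 1 else "right"


@dataclass(frozen=True)
class MontageSpec:
    """Ordered channel set with schematic scalp positions.

    Parameters
    ----------
    channel_names
        Ordered channel labels.
    positions
        ``(n_channels, 2)`` array of unit-disc coordinates, nose up.
    groups
        Per-channel hemisphere tag: ``left`` / ``right`` / ``midline``.
    """

    channel_names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.channel_names)) != len(self.channel_names):
            raise MontageError("duplicate channel labels in montage")
        if self.positions.shape != (len(self.channel_names), 2):
            raise MontageError("positions must be (n_channels, 2)")
        r = np.hypot(self.positions[:, 0], self.positions[:, 1])
        if np.any(r > 1.0 + 1e-9):
            raise MontageError("electrode positions must lie within the unit disc")
        if set(self.groups) - {"left", "right", "midline"}:
            raise MontageError("groups must be left/right/midline")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, label: str) -> int:
        try:
            return self.channel_names.index(label)
        except ValueError:
            raise MontageError(f"unknown channel label {label!r}") from None

    def subset(self, labels) -> "MontageSpec":
        """Montage restricted to ``labels``, in the requested order."""
        idx = [self.index(lab) for lab in labels]
        return MontageSpec(
            channel_names=tuple(labels),
            positions=self.positions[idx].copy(),
            groups=tuple(self.groups[i] for i in idx),
        )


def default_montage() -> MontageSpec:
    """The 26-channel acquisition montage in recording order."""
    pos = np.array([_POSITIONS[ch] for ch in DEFAULT_CHANNELS], dtype=float)
    groups = tuple(_group(ch) for ch in DEFAULT_CHANNELS)
    return MontageSpec(DEFAULT_CHANNELS, pos, groups)
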