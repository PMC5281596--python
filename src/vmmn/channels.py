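"""Electrode montage and canonical component topographies.

The recording montage is 37 scalp electrodes from the extended 10-20
system plus two bipolar ocular channels (horizontal and vertical EOG).
Topographies are plain ``{channel: gain}`` maps with gains in [0, 1];
channels absent from a map contribute nothing.  The visual mismatch
response is maximal over parieto-occipital sites (PO7/PO9 on the left,
PO8/PO10 on the right), which is also where the analysis ROIs sit.
"""

from __future__ import annotations

from .exceptions import LabelError

#: 37 scalp positions of the extended 10-20 system used throughout.
SCALP_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8", "P9", "P10",
    "PO7", "PO3", "POz", "PO4", "PO8", "PO9", "PO10",
    "O1", "Oz", "O2",
)

#: Bipolar ocular channels (recorded alongside the scalp montage).
EOG_CHANNELS: tuple[str, ...] = ("HEOG", "VEOG")

#: Full recording montage: scalp + EOG.
ALL_CHANNELS: tuple[str, ...] = SCALP_CHANNELS + EOG_CHANNELS

#: The four channels entering the two analysis ROIs.
ROI_CHANNELS: tuple[str, ...] = ("PO7", "PO9", "PO8", "PO10")


def validate_channels(labels) -> None:
    """Raise :class:`LabelError` if any label is not in the montage."""
    unknown = [c for c in labels if c not in ALL_CHANNELS]
    if unknown:
        raise LabelError(f"unknown channel label(s): {unknown}")


# Gain maps for the simulated evoked components.  Values are relative
# weights of the component peak amplitude per electrode; the layout is a
# broad parieto-occipital field with a slight right-hemisphere dominance
# for the early positivity (P1) and the mismatch response.

P1_TOPOGRAPHY: dict[str, float] = {
    "O2": 1.0, "Oz": 0.9, "O1": 0.85,
    "PO8": 0.95, "PO10": 0.9, "PO4": 0.7, "POz": 0.65,
    "PO7": 0.8, "PO9": 0.75, "PO3": 0.6,
    "P8": 0.5, "P10": 0.45, "P4": 0.35,
    "P7": 0.4, "P9": 0.35, "P3": 0.3, "Pz": 0.3,
}

N1_TOPOGRAPHY: dict[str, float] = {
    "PO8": 1.0, "PO7": 0.95, "PO10": 0.95, "PO9": 0.9,
    "O2": 0.9, "O1": 0.85, "Oz": 0.8,
    "PO4": 0.7, "PO3": 0.65, "POz": 0.65,
    "P8": 0.55, "P7": 0.5, "P10": 0.5, "P9": 0.45,
    "P4": 0.35, "P3": 0.3, "Pz": 0.3,
}

VMMN_TOPOGRAPHY: dict[str, float] = {
    "PO8": 1.0, "PO10": 0.95, "PO7": 0.9, "PO9": 0.85,
    "O2": 0.75, "Oz": 0.7, "O1": 0.7,
    "PO4": 0.65, "POz": 0.6, "PO3": 0.55,
    "P8": 0.45, "P10": 0.5, "P7": 0.4, "P9": 0.45,
    "P4": 0.3, "Pz": 0.25, "P3": 0.25,
}

#: Frontal field of an ocular (blink) artifact, used by the optional injector.
BLINK_TOPOGRAPHY: dict[str, float] = {
    "VEOG": 1.0, "Fp1": 0.6, "Fp2": 0.6, "F3": 0.25, "Fz": 0.25, "F4": 0.25,
    "F7": 0.15, "F8": 0.15,
}
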