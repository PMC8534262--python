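"""Standard 10/20-extended montage used by the 32-channel recordings.

Coordinates are a schematic top-view 2D layout (nose up), adequate for
rendering connectivity graphs; they are not digitized electrode positions.
"""

from __future__ import annotations

# 32-channel layout commonly shipped with 32-electrode clinical caps.
CHANNELS_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
]

FRONTAL = {"Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"}

# (x, y) in [-1, 1]^2; y > 0 is anterior.
LAYOUT_2D = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.42, 0.52), "Fz": (0.0, 0.50),
    "F4": (0.42, 0.52), "F8": (0.81, 0.59),
    "FC5": (-0.67, 0.27), "FC1": (-0.22, 0.25), "FC2": (0.22, 0.25), "FC6": (0.67, 0.27),
    "T7": (-1.0, 0.0), "C3": (-0.5, 0.0), "Cz": (0.0, 0.0), "C4": (0.5, 0.0), "T8": (1.0, 0.0),
    "TP9": (-1.05, -0.33), "CP5": (-0.67, -0.27), "CP1": (-0.22, -0.25),
    "CP2": (0.22, -0.25), "CP6": (0.67, -0.27), "TP10": (1.05, -0.33),
    "P7": (-0.81, -0.59), "P3": (-0.42, -0.52), "Pz": (0.0, -0.50),
    "P4": (0.42, -0.52), "P8": (0.81, -0.59),
    "PO9": (-0.55, -0.85), "O1": (-0.31, -0.95), "Oz": (0.0, -1.0),
    "O2": (0.31, -0.95), "PO10": (0.55, -0.85),
}


def default_channel_names(n: int) -> list[str]:
    """First ``n`` labels of the 32-channel montage (or EEG### beyond 32)."""
    if n <= len(CHANNELS_32):
        return CHANNELS_32[:n]
    extra = [f"EEG{i:03d}" for i in range(len(CHANNELS_32), n)]
    return CHANNELS_32 + extra
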