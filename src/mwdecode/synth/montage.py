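"""Spherical 10-20 sensor montage for the 32-channel recording system.

Coordinates come from the idealized spherical standard montages shipped
with MNE-Python (the Biosemi 32-channel layout plus the M1/M2 mastoids
from the 10-05 set), re-projected onto the scalp shell of the head model
and symmetrized so that left/right homologous electrodes are exact mirror
images across the midsagittal plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SensorMontage", "build_montage", "HOMOLOGOUS_PAIRS", "MIDLINE"]

#: left/right homologous electrode pairs of the 32-channel 10-20 layout
HOMOLOGOUS_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "Fp2"), ("AF3", "AF4"), ("F7", "F8"), ("F3", "F4"),
    ("FC1", "FC2"), ("FC5", "FC6"), ("T7", "T8"), ("C3", "C4"),
    ("CP1", "CP2"), ("CP5", "CP6"), ("P7", "P8"), ("P3", "P4"),
    ("PO3", "PO4"), ("O1", "O2"), ("M1", "M2"),
)

MIDLINE: tuple[str, ...] = ("Fz", "Cz", "Pz", "Oz")

MASTOIDS: tuple[str, str] = ("M1", "M2")


@dataclass(frozen=True)
class SensorMontage:
    """Electrode labels and Cartesian positions on the scalp sphere.

    Head frame: +x right, +y anterior, +z superior, origin at the sphere
    center; positions in meters, all on the scalp radius.  The two mastoid
    channels are flagged as reference candidates and excluded from the
    analysis channel set.
    """

    labels: tuple[str, ...]
    positions: np.ndarray  # (n, 3), read-only
    radius: float
    reference_labels: tuple[str, str] = MASTOIDS

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        self.positions.setflags(write=False)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def analysis_labels(self) -> tuple[str, ...]:
        return tuple(l for l in self.labels if l not in self.reference_labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def get_positions(self, labels: "list[str] | tuple[str, ...]") -> np.ndarray:
        return self.positions[[self.index(l) for l in labels]]

    @property
    def analysis_positions(self) -> np.ndarray:
        return self.get_positions(self.analysis_labels)


def _standard_directions() -> dict[str, np.ndarray]:
    """Unit direction of every electrode from the MNE standard montages."""
    import mne

    biosemi = mne.channels.make_standard_montage("biosemi32")
    pos = biosemi.get_positions()["ch_pos"]
    dirs = {name: p / np.linalg.norm(p) for name, p in pos.items()}
    try:
        std = mne.channels.make_standard_montage("colin27_1005")
    except ValueError:  # older MNE naming
        std = mne.channels.make_standard_montage("standard_1005")
    std_pos = std.get_positions()["ch_pos"]
    for name in MASTOIDS:
        p = std_pos[name]
        dirs[name] = p / np.linalg.norm(p)
    return dirs


def build_montage(n_scalp: int = 32, radius: float = 0.092) -> SensorMontage:
    """Deterministic 32-channel 10-20 montage plus two mastoids.

    All positions are projected radially onto the sphere of ``radius``
    meters and homologous pairs are symmetrized, so the montage is exactly
    mirror-symmetric across the midsagittal plane.
    """
    if n_scalp != 32:
        raise ValueError("only the 32-channel 10-20 layout is supported")
    dirs = _standard_directions()

    # enforce exact mirror symmetry
    mirror = np.array([-1.0, 1.0, 1.0])
    for left, right in HOMOLOGOUS_PAIRS:
        d = dirs[left] + mirror * dirs[right]
        d /= np.linalg.norm(d)
        dirs[left] = d
        dirs[right] = mirror * d
    for name in MIDLINE:
        d = dirs[name].copy()
        d[0] = 0.0
        dirs[name] = d / np.linalg.norm(d)

    import mne

    scalp = list(mne.channels.make_standard_montage("biosemi32").ch_names)
    labels = tuple(scalp + list(MASTOIDS))
    positions = np.array([dirs[name] * radius for name in labels])
    return SensorMontage(labels=labels, positions=positions, radius=radius)


def write_montage(montage: SensorMontage, path) -> None:
    """ASCII ``label x y z`` (meters), one electrode per line."""
    with open(path, "w") as fh:
        for label, (x, y, z) in zip(montage.labels, montage.positions):
            fh.write(f"{label} {x:.9f} {y:.9f} {z:.9f}\n")


def read_montage(path) -> SensorMontage:
    labels, rows = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, x, y, z = line.split()
            labels.append(name)
            rows.append([float(x), float(y), float(z)])
    positions = np.array(rows)
    radius = float(np.linalg.norm(positions, axis=1).mean())
    return SensorMontage(tuple(labels), positions, radius)
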