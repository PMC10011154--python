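"""16-channel sensorimotor montage (10-20 system subset).

The montage covers the fronto-centro-parietal strip over both sensorimotor
cortices.  Positions are 2-D head-plane coordinates (x toward the right ear,
y toward the nasion, unit head radius) used for source-gain kernels,
channel adjacency, and topographic summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical channel order of the recording setup.
CHANNELS: tuple[str, ...] = (
    "F3", "FC3", "C5", "C3", "C1", "CP3", "P3", "FCz", "Cz",
    "F4", "FC4", "C6", "C4", "C2", "CP4", "P4",
)

# Head-plane lattice: rows F/FC/C/CP/P at y = .5/.25/0/-.25/-.5,
# lateral index 1/3/5 at |x| = .2/.4/.6.  Left hemisphere x < 0.
_POSITIONS: dict[str, tuple[float, float]] = {
    "F3": (-0.4, 0.5), "F4": (0.4, 0.5),
    "FC3": (-0.4, 0.25), "FCz": (0.0, 0.25), "FC4": (0.4, 0.25),
    "C5": (-0.6, 0.0), "C3": (-0.4, 0.0), "C1": (-0.2, 0.0),
    "Cz": (0.0, 0.0),
    "C2": (0.2, 0.0), "C4": (0.4, 0.0), "C6": (0.6, 0.0),
    "CP3": (-0.4, -0.25), "CP4": (0.4, -0.25),
    "P3": (-0.4, -0.5), "P4": (0.4, -0.5),
}


@dataclass(frozen=True)
class Montage:
    """Electrode labels with 2-D head-plane positions."""

    labels: tuple[str, ...] = CHANNELS
    positions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_POSITIONS)
    )

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        missing = [lb for lb in self.labels if lb not in self.positions]
        if missing:
            raise ValueError(f"positions missing for {missing}")
        coords = self.coords()
        if not np.all(np.isfinite(coords)):
            raise ValueError("montage positions must be finite")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def coords(self) -> np.ndarray:
        """(n_channels, 2) array of positions in canonical label order."""
        return np.asarray([self.positions[lb] for lb in self.labels], float)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def mirrored(self, label: str) -> str:
        """Label of the channel mirrored across the midline (x -> -x)."""
        x, y = self.positions[label]
        for other in self.labels:
            ox, oy = self.positions[other]
            if np.isclose(ox, -x) and np.isclose(oy, y):
                return other
        raise KeyError(f"no mirror for {label}")

    def distance_matrix(self) -> np.ndarray:
        c = self.coords()
        return np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)

    def neighbor_matrix(self, scale: float = 1.3) -> np.ndarray:
        """Boolean channel adjacency.

        Two channels are neighbors when their head-plane distance is at most
        ``scale`` times the minimal inter-electrode distance; this recovers
        the nearest-neighbor lattice of the montage.
        """
        d = self.distance_matrix()
        off = d[~np.eye(self.n_channels, dtype=bool)]
        thresh = scale * off.min()
        adj = (d <= thresh) & ~np.eye(self.n_channels, dtype=bool)
        return adj | adj.T


DEFAULT_MONTAGE = Montage()
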