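"""Electrode montage: the 19-channel 10-20 layout and its neighbor relation.

The montage carries the ordered channel labels used to index every
adjacency matrix in the pipeline, plus approximate 2-D scalp positions
(unit-circle projection of the standard 10-20 coordinates) from which a
symmetric neighbor map is derived for bad-channel interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 19 electrodes of the 10-20 system in fixed pipeline order.
STANDARD_1020_LABELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

# Normalized 2-D positions (x: left-right, y: posterior-anterior) on the
# unit disc, the conventional flattened 10-20 layout.
_POS_2D: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.40, 0.51), "Fz": (0.0, 0.50),
    "F4": (0.40, 0.51), "F8": (0.81, 0.59),
    "T3": (-1.00, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T4": (1.00, 0.0),
    "T5": (-0.81, -0.59), "P3": (-0.40, -0.51), "Pz": (0.0, -0.50),
    "P4": (0.40, -0.51), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

#: Default normalized-distance cutoff for the neighbor relation.
NEIGHBOR_CUTOFF = 0.75


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels plus a symmetric channel -> neighbors map."""

    labels: tuple[str, ...]
    neighbors: dict[str, frozenset[str]] = field(compare=False)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        for ch, nbrs in self.neighbors.items():
            if not nbrs:
                raise ValueError(f"channel {ch!r} has no neighbors")
            for other in nbrs:
                if ch not in self.neighbors.get(other, frozenset()):
                    raise ValueError(
                        f"neighbor relation not symmetric for ({ch!r}, {other!r})"
                    )

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def positions_2d(labels: tuple[str, ...] = STANDARD_1020_LABELS) -> np.ndarray:
    """Flattened scalp positions (n, 2) for the given 10-20 labels."""
    try:
        return np.array([_POS_2D[lab] for lab in labels])
    except KeyError as exc:
        raise KeyError(f"no 10-20 position for channel {exc.args[0]!r}") from exc


def neighbors_from_positions(
    labels: tuple[str, ...], pos: np.ndarray, cutoff: float = NEIGHBOR_CUTOFF
) -> dict[str, frozenset[str]]:
    """Neighbor map from pairwise distance below `cutoff` (normalized units).

    Guarantees at least one neighbor per channel by falling back to the
    nearest channel when the cutoff leaves a channel isolated.
    """
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    nbrs: dict[str, set[str]] = {lab: set() for lab in labels}
    for i, lab in enumerate(labels):
        close = np.where(d[i] < cutoff)[0]
        if close.size == 0:
            close = np.array([int(np.argmin(d[i]))])
        for j in close:
            nbrs[lab].add(labels[j])
            nbrs[labels[j]].add(lab)
    return {lab: frozenset(v) for lab, v in nbrs.items()}


def standard_montage(cutoff: float = NEIGHBOR_CUTOFF) -> Montage:
    """The 19-channel 10-20 montage with distance-derived neighbors."""
    pos = positions_2d(STANDARD_1020_LABELS)
    return Montage(
        labels=STANDARD_1020_LABELS,
        neighbors=neighbors_from_positions(STANDARD_1020_LABELS, pos, cutoff),
    )
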