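"""Electrode montages for multichannel EEG.

A :class:`ChannelMontage` is a named, ordered set of scalp electrodes with
schematic 2-D coordinates on the unit head circle (nose up, right ear at
positive x).  Two montages from the extended 10-10 system ship with the
package: a 61-channel set typical of high-density clinical recordings and a
48-channel subset of it.  Coordinates are an azimuthal-equidistant projection
of idealised spherical 10-10 positions, scaled so the outermost electrode
lies on the head circle; they are unitless and intended for topographic
display and channel bookkeeping, not for source analysis.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = ["ChannelMontage", "load_montage", "BUILTIN_MONTAGES"]

BUILTIN_MONTAGES = {
    "dataset1": "montage61.csv",
    "dataset2": "montage48.csv",
}


@dataclass(frozen=True)
class ChannelMontage:
    """Ordered electrode labels with 2-D head-circle coordinates."""

    names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)  # (n_channels, 2)

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate channel labels: {dupes}")
        if pos.shape != (len(names), 2):
            raise ValueError(
                f"positions shape {pos.shape} does not match {len(names)} labels"
            )
        radii = np.hypot(pos[:, 0], pos[:, 1])
        if np.any(radii > 1.0 + 1e-9):
            bad = [names[i] for i in np.nonzero(radii > 1.0 + 1e-9)[0]]
            raise ValueError(f"positions outside unit head circle: {bad}")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, label: str) -> int:
        try:
            return self.names.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def subset(self, labels: list[str]) -> "ChannelMontage":
        """Montage restricted to ``labels``, in the order given."""
        idx = [self.index(label) for label in labels]
        return ChannelMontage(tuple(labels), self.positions[idx])

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["label", "x", "y"])
            for name, (x, y) in zip(self.names, self.positions):
                writer.writerow([name, f"{x:.4f}", f"{y:.4f}"])


def _read_montage_csv(fh) -> ChannelMontage:
    reader = csv.DictReader(fh)
    if reader.fieldnames is None or {"label", "x", "y"} - set(reader.fieldnames):
        raise ValueError("montage CSV must have columns: label, x, y")
    names, pos = [], []
    for row in reader:
        names.append(row["label"])
        pos.append((float(row["x"]), float(row["y"])))
    return ChannelMontage(tuple(names), np.array(pos))


def load_montage(name_or_path: str | Path) -> ChannelMontage:
    """Load a built-in montage (``"dataset1"``/``"dataset2"``) or a CSV file.

    The CSV schema is ``label,x,y`` with coordinates inside the unit circle.
    """
    key = str(name_or_path)
    if key in BUILTIN_MONTAGES:
        ref = resources.files("hfdeeg.data") / BUILTIN_MONTAGES[key]
        with ref.open("r") as fh:
            return _read_montage_csv(fh)
    path = Path(name_or_path)
    if not path.exists():
        raise FileNotFoundError(
            f"{name_or_path!r} is neither a built-in montage "
            f"({sorted(BUILTIN_MONTAGES)}) nor an existing CSV file"
        )
    with open(path) as fh:
        return _read_montage_csv(fh)
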