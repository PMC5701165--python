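"""Electrode layouts: a 128-channel super-Nyquist-density (SND) patch and
its four Nyquist-density (ND1-ND4) sublattices.

The SND array is a ~14 mm-spacing grid of 128 electrodes covering an
occipitotemporal patch; the four ND arrays are the interleaved parity
sublattices of that grid, each with ~28 mm spacing, pairwise disjoint, and
jointly exhausting the SND electrodes.  Coordinates are in millimetres with
the origin at the occipital pole, x rightward, y upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ElectrodeLayout", "make_layout", "ARRAY_NAMES"]

ARRAY_NAMES = ("SND", "ND1", "ND2", "ND3", "ND4")


@dataclass
class ElectrodeLayout:
    """Positions of the SND electrodes and the ND subset partition.

    Attributes
    ----------
    positions : (n, 3) ndarray
        Electrode coordinates in mm.
    nd_subsets : list of 4 int ndarrays
        Disjoint index sets ND1..ND4 whose union is all electrodes.
    """

    positions: np.ndarray
    nd_subsets: list = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.nd_subsets = [np.asarray(s, dtype=int) for s in self.nd_subsets]

    @property
    def n_electrodes(self) -> int:
        return self.positions.shape[0]

    @property
    def snd_indices(self) -> np.ndarray:
        return np.arange(self.n_electrodes)

    def array_indices(self, name: str) -> np.ndarray:
        """Electrode indices of one array ('SND' or 'ND1'..'ND4')."""
        if name == "SND":
            return self.snd_indices
        if name in ARRAY_NAMES:
            return self.nd_subsets[int(name[2]) - 1]
        raise KeyError(f"unknown array {name!r}; expected one of {ARRAY_NAMES}")

    def median_spacing(self, name: str = "SND") -> float:
        """Median nearest-neighbour distance within one array, in mm."""
        pos = self.positions[self.array_indices(name)]
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        return float(np.median(d.min(axis=1)))

    def side_mask(self, side: str) -> np.ndarray:
        """Boolean mask of electrodes on the left (x<0) or right (x>0)."""
        if side == "left":
            return self.positions[:, 0] < 0
        if side == "right":
            return self.positions[:, 0] > 0
        raise ValueError("side must be 'left' or 'right'")

    def to_frame(self) -> pd.DataFrame:
        subset = np.empty(self.n_electrodes, dtype=object)
        for i, idx in enumerate(self.nd_subsets):
            subset[idx] = f"ND{i + 1}"
        return pd.DataFrame(
            {
                "electrode": np.arange(self.n_electrodes),
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "subset": subset,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ElectrodeLayout":
        df = pd.read_csv(path, sep="\t")
        pos = df[["x", "y", "z"]].to_numpy()
        subsets = [
            df.index[df["subset"] == f"ND{i + 1}"].to_numpy() for i in range(4)
        ]
        return cls(positions=pos, nd_subsets=subsets)


def make_layout(
    geometry: str = "flat_patch",
    seed: int = 0,
    spacing_mm: float = 14.0,
    n_cols: int = 16,
    n_rows: int = 8,
    jitter_mm: float = 0.5,
    head_radius_mm: float = 95.0,
) -> ElectrodeLayout:
    """Build the SND electrode layout and its four ND sublattices.

    ``flat_patch`` places ``n_cols x n_rows`` electrodes on a rectangular
    grid with ``spacing_mm`` pitch (plus a small seeded placement jitter
    mimicking cap irregularity); ``spherical_cap`` wraps the same patch onto
    a sphere of ``head_radius_mm``.  The ND subsets are the four parity
    classes of the grid (even/odd row x even/odd column), each a 2x-pitch
    lattice.

    Deterministic given ``seed``.
    """
    if geometry not in ("flat_patch", "spherical_cap"):
        raise ValueError("geometry must be 'flat_patch' or 'spherical_cap'")
    rng = np.random.default_rng(seed)
    cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    cols, rows = cols.ravel(), rows.ravel()
    x = (cols - (n_cols - 1) / 2.0) * spacing_mm
    y = rows * spacing_mm
    x = x + rng.normal(0.0, jitter_mm, x.shape)
    y = y + rng.normal(0.0, jitter_mm, y.shape)

    if geometry == "flat_patch":
        pos = np.column_stack([x, y, np.zeros_like(x)])
    else:
        # azimuthal-equidistant inverse: arc lengths on the sphere
        R = head_radius_mm
        rho = np.hypot(x, y)
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(rho > 0, x / rho, 0.0)
            uy = np.where(rho > 0, y / rho, 0.0)
        c = rho / R
        pos = np.column_stack(
            [R * np.sin(c) * ux, R * np.sin(c) * uy, R * (np.cos(c) - 1.0)]
        )

    # parity sublattices: ND1=(even row, even col) ... ND4=(odd row, odd col)
    subset_id = (rows % 2) * 2 + (cols % 2)
    subsets = [np.flatnonzero(subset_id == k) for k in range(4)]
    return ElectrodeLayout(positions=pos, nd_subsets=subsets)
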