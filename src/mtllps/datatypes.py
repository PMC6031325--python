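"""Shared data containers for the microtubule LLPS analysis pipeline.

Conventions used throughout the package:

* images are 2D ``numpy`` arrays indexed ``[row, col]`` (row = y, col = x),
  0-based, with coordinates referring to pixel *centers*;
* arc positions along filaments are expressed in micrometers (µm);
* intensities are arbitrary fluorescence units (photons/pixel for
  simulated data before noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TwoChannelImage",
    "FilamentPath",
    "ProfilePair",
    "Roi",
]


@dataclass
class TwoChannelImage:
    """A registered pair of fluorescence channels.

    ``ch1`` conventionally holds the GFP-tagged RBP1 signal and ``ch2`` the
    RFP-tagged RBP2 signal.  An optional third channel (``ch_mrna``) holds an
    mRNA / FISH image used for colocalization scoring.
    """

    ch1: np.ndarray
    ch2: np.ndarray
    pixel_size_nm: float = 30.0
    ch_mrna: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ch1 = np.asarray(self.ch1, dtype=float)
        self.ch2 = np.asarray(self.ch2, dtype=float)
        if self.ch1.ndim != 2 or self.ch1.shape != self.ch2.shape:
            raise ValueError(
                f"channel shapes differ: {self.ch1.shape} vs {self.ch2.shape}"
            )
        if self.ch_mrna is not None:
            self.ch_mrna = np.asarray(self.ch_mrna, dtype=float)
            if self.ch_mrna.shape != self.ch1.shape:
                raise ValueError("mRNA channel shape differs from ch1/ch2")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ch1.shape


@dataclass
class FilamentPath:
    """A sub-pixel polyline along one microtubule.

    ``vertices`` is an (N, 2) float array of (row, col) pixel coordinates;
    ``arc_um`` the cumulative arc length at each vertex in µm (``arc_um[0]``
    is 0).  Arc length is strictly increasing, i.e. consecutive vertices are
    distinct.
    """

    path_id: int
    vertices: np.ndarray
    pixel_size_nm: float = 30.0
    arc_um: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array of (row, col)")
        if len(self.vertices) < 2:
            raise ValueError(
                f"path {self.path_id}: a filament path needs >= 2 vertices"
            )
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.arc_um is None:
            seg = np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)
            self.arc_um = np.concatenate(
                [[0.0], np.cumsum(seg) * self.pixel_size_nm / 1000.0]
            )
        else:
            self.arc_um = np.asarray(self.arc_um, dtype=float)
        if np.any(np.diff(self.arc_um) <= 0):
            raise ValueError(
                f"path {self.path_id}: arc length must be strictly increasing "
                "(repeated vertices?)"
            )

    @property
    def length_um(self) -> float:
        return float(self.arc_um[-1])

    def reversed(self) -> "FilamentPath":
        return FilamentPath(
            path_id=self.path_id,
            vertices=self.vertices[::-1].copy(),
            pixel_size_nm=self.pixel_size_nm,
        )

    def point_at(self, s_um: np.ndarray) -> np.ndarray:
        """Interpolate (row, col) positions at arc positions ``s_um``."""
        s = np.asarray(s_um, dtype=float)
        r = np.interp(s, self.arc_um, self.vertices[:, 0])
        c = np.interp(s, self.arc_um, self.vertices[:, 1])
        return np.stack([r, c], axis=-1)

    def check_in_bounds(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        v = self.vertices
        bad = (
            (v[:, 0] < 0) | (v[:, 0] > rows - 1) | (v[:, 1] < 0) | (v[:, 1] > cols - 1)
        )
        if np.any(bad):
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"path {self.path_id}: vertex {i} at {tuple(v[i])} lies outside "
                f"image of shape {shape}"
            )


@dataclass
class ProfilePair:
    """Paired intensity profiles sampled along one filament path.

    Both channels are sampled at the same uniform arc grid; at each position
    the intensity is the mean over a perpendicular band of physical width
    ``line_thickness_nm`` (120 nm, i.e. 4 samples at 30 nm/px, by default).
    ``clipped`` flags positions whose band extended beyond the image border.
    """

    path_id: int
    positions_um: np.ndarray
    i_rbp1: np.ndarray
    i_rbp2: np.ndarray
    step_um: float
    line_thickness_nm: float = 120.0
    clipped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.i_rbp1 = np.asarray(self.i_rbp1, dtype=float)
        self.i_rbp2 = np.asarray(self.i_rbp2, dtype=float)
        n = len(self.positions_um)
        if not (len(self.i_rbp1) == len(self.i_rbp2) == n):
            raise ValueError("profile vectors must have equal length")
        if not self.step_um > 0:
            raise ValueError("step_um must be positive")
        if np.any(self.i_rbp1 < 0) or np.any(self.i_rbp2 < 0):
            raise ValueError("profile intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.positions_um)

    @property
    def extent_um(self) -> float:
        """Arc length covered by this profile (one step per sample)."""
        return len(self) * self.step_um


@dataclass
class Roi:
    """A region of interest given as a boolean mask (e.g. "cytoplasm")."""

    mask: np.ndarray
    label: str = "roi"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2D")
        if not self.mask.any():
            raise ValueError(f"ROI '{self.label}' is empty")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())
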