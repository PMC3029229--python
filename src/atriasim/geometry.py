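"""Cell geometry: cylinder, junctional subspace and annular shell volumes.

The myocyte is a cylinder of length ``l_cell`` and total radius
``r_bulk + d_junct``.  The outermost ``d_junct`` = 0.02 um annulus is the
junctional subspace; the remaining radius ``r_bulk`` = 6.5 um is divided
into ``n_bulk`` annular shells of width ``dr``.  The SR occupies 2.25% of
the bulk-cytosol volume, shell by shell.  Only 50% of every cytosolic/SR
volume (and of the junctional<->bulk exchange area) is accessible to Ca2+.

Shell indexing: internal arrays are ordered from the cell axis outward
(index 0 = innermost/central shell, index ``n_bulk-1`` = outermost shell,
adjacent to the subspace).  Reporting helpers expose both the radial
coordinate and the depth measured from the membrane, where "shell 1" in
depth order is the outermost shell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class CellGeometry:
    """Discretized cell geometry (volumes in nL, lengths in um)."""

    l_cell: float
    r_bulk: float
    d_junct: float
    n_bulk: int
    dr: float
    C_m: float              # membrane capacitance, nF
    f_access: float         # accessible volume/area fraction
    sr_fraction: float      # SR volume as fraction of bulk-cytosol volume
    V_ss: float             # accessible subspace volume, nL
    V_bulk: np.ndarray      # accessible bulk shell volumes, axis->membrane, nL
    V_sr: np.ndarray        # accessible SR shell volumes, nL
    r_centers: np.ndarray   # shell-centre radii, um (axis->membrane)
    r_faces: np.ndarray     # interface radii between shells, um (n_bulk-1,)
    A_faces: np.ndarray     # accessible interface areas between shells, um^2
    A_ss_bulk: float        # accessible junctional<->bulk exchange area, um^2
    x_ss_bulk: float        # centre-to-centre junctional<->bulk distance, um

    @property
    def depth_centers(self) -> np.ndarray:
        """Shell-centre depths from the membrane, outermost shell first."""
        total_r = self.r_bulk + self.d_junct
        return (total_r - self.r_centers)[::-1]

    @property
    def V_bulk_total(self) -> float:
        return float(self.V_bulk.sum())

    @property
    def V_cytosol(self) -> float:
        """Total accessible cytosolic volume (bulk + subspace), nL."""
        return self.V_bulk_total + self.V_ss

    @property
    def V_sr_total(self) -> float:
        return float(self.V_sr.sum())


def build_geometry(
    l_cell: float = 122.051,
    r_bulk: float = 6.5,
    d_junct: float = 0.02,
    n_bulk: int = 4,
    C_m: float = 0.05,
    f_access: float = 0.5,
    sr_fraction: float = 0.0225,
) -> CellGeometry:
    """Build the cylindrical shell geometry.

    Volumes are exact cylindrical annuli scaled by the accessible fraction;
    1 um^3 = 1e-6 nL.  Raises ``ValueError`` for non-positive dimensions.
    """
    if l_cell <= 0 or r_bulk <= 0 or d_junct <= 0:
        raise ValueError("cell dimensions must be positive")
    if n_bulk < 1:
        raise ValueError("n_bulk must be >= 1")
    if not (0 < f_access <= 1):
        raise ValueError("f_access must be in (0, 1]")

    dr = r_bulk / n_bulk
    edges = np.linspace(0.0, r_bulk, n_bulk + 1)
    r_centers = 0.5 * (edges[:-1] + edges[1:])
    r_faces = edges[1:-1]

    annulus = math.pi * (edges[1:] ** 2 - edges[:-1] ** 2) * l_cell  # um^3
    V_bulk = annulus * 1e-6 * f_access
    V_sr = V_bulk * sr_fraction

    r_out = r_bulk + d_junct
    V_ss = math.pi * (r_out**2 - r_bulk**2) * l_cell * 1e-6 * f_access

    A_faces = 2.0 * math.pi * r_faces * l_cell * f_access
    A_ss_bulk = 2.0 * math.pi * r_bulk * l_cell * f_access
    # centre of subspace annulus to centre of outermost bulk shell
    x_ss_bulk = d_junct / 2.0 + dr / 2.0

    return CellGeometry(
        l_cell=l_cell,
        r_bulk=r_bulk,
        d_junct=d_junct,
        n_bulk=n_bulk,
        dr=dr,
        C_m=C_m,
        f_access=f_access,
        sr_fraction=sr_fraction,
        V_ss=V_ss,
        V_bulk=V_bulk,
        V_sr=V_sr,
        r_centers=r_centers,
        r_faces=r_faces,
        A_faces=A_faces,
        A_ss_bulk=A_ss_bulk,
        x_ss_bulk=x_ss_bulk,
    )


def release_unit_mask(geom: CellGeometry) -> np.ndarray:
    """Boolean mask of bulk shells that carry an SR release/uptake unit.

    The outermost bulk shell has no release unit of its own: the SR shell at
    that radial position serves the junctional subspace instead, so the
    outermost bulk shell receives Ca2+ only by diffusion.  With the default
    four shells this puts release units in the three inner shells (plus the
    junctional unit handled separately).
    """
    mask = np.ones(geom.n_bulk, dtype=bool)
    mask[-1] = False
    return mask
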