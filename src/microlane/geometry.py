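"""Micropattern geometry: rasterized adhesive microlanes and reversal regions.

A microlane is a stripe-shaped adhesive (fibronectin) island of length ``L``
(tip-to-tip) and width ``W``, surrounded by a cell-repellent surface.  The cell
is strictly confined to the adhesive raster.  Four tip shapes are supported at
constant width, and :func:`equalize_area` adjusts the length so that different
tip shapes enclose the same total adhesive area.

Coordinate convention (used everywhere in this package): the continuous
long-axis coordinate ``koor`` is measured in micrometers from the lane center,
increasing along the long axis.  The raster uses 0-based site indices with site
centers at symmetric positions around ``koor = 0``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

TIP_SHAPES = ("round", "blunt", "sharp", "concave")

#: 4-neighborhood structuring element for connectivity checks.
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class PatternSpec:
    """Parametric description of a single microlane.

    Parameters
    ----------
    length : float
        Tip-to-tip extent L in micrometers.
    width : float
        Lane width W in micrometers.
    tip_shape : str
        One of ``round``, ``blunt``, ``sharp``, ``concave``.
    spacing : float
        Lattice spacing in micrometers per site (default 2, i.e. a 20 um lane
        is 10 sites wide).
    sharp_half_angle_deg : float
        Half opening angle of the triangular cap of a sharp tip (default 45).
    concave_radius : float or None
        Radius of the circular arc cut into each flat end of a concave lane.
        ``None`` means W/2.
    """

    length: float
    width: float = 20.0
    tip_shape: str = "round"
    spacing: float = 2.0
    sharp_half_angle_deg: float = 45.0
    concave_radius: float | None = None

    def __post_init__(self) -> None:
        if self.tip_shape not in TIP_SHAPES:
            raise ValueError(f"tip_shape must be one of {TIP_SHAPES}, got {self.tip_shape!r}")
        if not (self.length > self.width > 0):
            raise ValueError("require length > width > 0")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        n_across = self.width / self.spacing
        if abs(n_across - round(n_across)) > 1e-9:
            raise ValueError("lattice spacing must divide the lane width evenly")
        if round(n_across) < 4:
            raise ValueError("lane width must span at least 4 lattice sites to resolve the tip")
        if not (0 < self.sharp_half_angle_deg < 90):
            raise ValueError("sharp_half_angle_deg must lie in (0, 90)")
        r = self.concave_r
        if r <= 0 or r > self.width / 2 + 1e-9:
            raise ValueError("concave_radius must lie in (0, width/2]")
        if self.tip_shape == "sharp" and 2 * self.sharp_cap_length >= self.length:
            raise ValueError("sharp caps longer than the lane itself")
        if self.tip_shape == "concave" and 2 * r >= self.length:
            raise ValueError("concave cut deeper than the lane allows")

    @property
    def concave_r(self) -> float:
        return self.width / 2 if self.concave_radius is None else self.concave_radius

    @property
    def sharp_cap_length(self) -> float:
        """Axial length of one triangular cap of a sharp tip."""
        return (self.width / 2) / math.tan(math.radians(self.sharp_half_angle_deg))

    def analytic_area(self) -> float:
        """Exact enclosed area in um^2 of the continuous (un-rasterized) shape."""
        L, W = self.length, self.width
        if self.tip_shape == "round":
            return (L - W) * W + math.pi * (W / 2) ** 2
        if self.tip_shape == "blunt":
            return L * W
        if self.tip_shape == "sharp":
            return L * W - W * self.sharp_cap_length
        # concave: half-disc of radius r removed from each flat end
        return L * W - math.pi * self.concave_r**2


@dataclass(frozen=True, eq=False)
class PatternMask:
    """Rasterized admissible domain of a microlane.

    ``grid[iy, ix]`` is True where the substrate is adhesive.  ``x_centers``
    and ``y_centers`` give the site-center coordinates in the ``koor`` frame
    (lane center at 0 on both axes).
    """

    grid: np.ndarray
    spacing: float
    x_centers: np.ndarray
    y_centers: np.ndarray
    spec: PatternSpec

    @property
    def n_sites(self) -> int:
        return int(self.grid.sum())

    def area(self) -> float:
        """Raster area in um^2 (site count times site area)."""
        return self.n_sites * self.spacing**2


@dataclass(frozen=True)
class ReversalRegion:
    """The two tip intervals within ``xi0`` of each lane end (``koor`` frame)."""

    xi0: float
    lane_length: float
    #: ((lo, hi) at the left tip, (lo, hi) at the right tip); empty if xi0 == 0
    tip_intervals: tuple[tuple[float, float], ...]

    def in_left(self, koor: np.ndarray) -> np.ndarray:
        if not self.tip_intervals:
            return np.zeros(np.shape(koor), dtype=bool)
        return np.asarray(koor) <= self.tip_intervals[0][1]

    def in_right(self, koor: np.ndarray) -> np.ndarray:
        if not self.tip_intervals:
            return np.zeros(np.shape(koor), dtype=bool)
        return np.asarray(koor) >= self.tip_intervals[1][0]


def _inside(spec: PatternSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Continuous inclusion test for site centers (x, y) in the koor frame."""
    L, W = spec.length, spec.width
    half_l, half_w = L / 2, W / 2
    in_band = np.abs(y) <= half_w + 1e-12
    if spec.tip_shape == "blunt":
        return in_band & (np.abs(x) <= half_l + 1e-12)
    if spec.tip_shape == "round":
        body = np.abs(x) <= half_l - half_w
        d = np.abs(x) - (half_l - half_w)
        cap = (d >= 0) & (d**2 + y**2 <= half_w**2 + 1e-9)
        return in_band & (body | cap)
    if spec.tip_shape == "sharp":
        c = spec.sharp_cap_length
        body = np.abs(x) <= half_l - c
        d = half_l - np.abs(x)  # distance from the apex along the axis
        tan = math.tan(math.radians(spec.sharp_half_angle_deg))
        cap = (d >= 0) & (np.abs(y) <= d * tan + 1e-9)
        return in_band & (body | cap)
    # concave
    r = spec.concave_r
    cut = (np.abs(x) - half_l) ** 2 + y**2 < r**2 - 1e-9
    return in_band & (np.abs(x) <= half_l + 1e-12) & ~cut


def make_mask(spec: PatternSpec) -> PatternMask:
    """Rasterize ``spec`` by a center-of-site inclusion test.

    The raster is mirror-symmetric about both midlines by construction (site
    centers are placed symmetrically around the lane center).
    """
    a = spec.spacing
    nx = int(np.ceil(spec.length / a - 1e-9))
    ny = int(round(spec.width / a))
    x_centers = (np.arange(nx) - (nx - 1) / 2) * a
    y_centers = (np.arange(ny) - (ny - 1) / 2) * a
    X, Y = np.meshgrid(x_centers, y_centers)
    grid = _inside(spec, X, Y)
    n_comp = ndimage.label(grid, structure=_CROSS)[1]
    if n_comp != 1:
        raise ValueError(f"rasterized mask is not a single 4-connected component ({n_comp} parts)")
    return PatternMask(grid=grid, spacing=a, x_centers=x_centers, y_centers=y_centers, spec=spec)


def equalize_area(shape: str, reference: PatternSpec) -> PatternSpec:
    """Spec of tip shape ``shape`` whose analytic area matches ``reference``.

    Only the length is adjusted; width, spacing and cap parameters are kept.
    All supported shapes have area = W*L - k(shape), so the solution is exact.
    """
    if shape not in TIP_SHAPES:
        raise ValueError(f"unknown tip shape {shape!r}")
    target = reference.analytic_area()
    probe = dataclasses.replace(reference, tip_shape=shape)
    # area(L) = W*L - k  =>  k = W*L_probe - area(probe)
    k = reference.width * probe.length - probe.analytic_area()
    new_length = (target + k) / reference.width
    out = dataclasses.replace(reference, tip_shape=shape, length=new_length)
    if abs(out.analytic_area() - target) > 0.005 * target:
        raise ValueError("area equalization failed for the requested geometry")
    return out


def reversal_region(spec_or_length: PatternSpec | float, xi0: float) -> ReversalRegion:
    """Reversal region: the two intervals within ``xi0`` of each lane tip.

    Raises if ``xi0 >= L/2`` — then the two regions meet and the whole lane is
    "tip", the regime in which no directional run phase exists (the shortest
    experimental lanes).  ``xi0 == 0`` yields empty intervals and therefore no
    reversal events downstream.
    """
    L = spec_or_length.length if isinstance(spec_or_length, PatternSpec) else float(spec_or_length)
    if xi0 < 0:
        raise ValueError("xi0 must be non-negative")
    if xi0 >= L / 2:
        raise ValueError(
            f"xi0 = {xi0} um >= L/2 = {L / 2} um: reversal regions cover the whole lane "
            "(no run phase; lane too short for directional migration)"
        )
    if xi0 == 0:
        return ReversalRegion(xi0=0.0, lane_length=L, tip_intervals=())
    ivals = ((-L / 2, -L / 2 + xi0), (L / 2 - xi0, L / 2))
    return ReversalRegion(xi0=float(xi0), lane_length=L, tip_intervals=ivals)


def save_mask(mask: PatternMask, path: str) -> None:
    """Export the mask as an 8-bit PNG (0 forbidden / 255 adhesive) + sidecar.

    The sidecar text file (``<path>.txt``) records spacing, origin and the
    generating spec so that :func:`load_mask` can reconstruct the object.
    """
    from PIL import Image

    img = Image.fromarray((mask.grid.astype(np.uint8)) * 255, mode="L")
    img.save(path)
    s = mask.spec
    with open(str(path) + ".txt", "w") as fh:
        fh.write(
            "# microlane mask sidecar\n"
            f"spacing_um={mask.spacing}\n"
            "origin=lane center (koor=0), site centers symmetric\n"
            f"length_um={s.length}\nwidth_um={s.width}\ntip_shape={s.tip_shape}\n"
            f"sharp_half_angle_deg={s.sharp_half_angle_deg}\n"
            f"concave_radius_um={s.concave_r}\n"
        )


def load_mask(path: str) -> PatternMask:
    """Reconstruct a :class:`PatternMask` from a PNG + sidecar written by :func:`save_mask`."""
    kv: dict[str, str] = {}
    with open(str(path) + ".txt") as fh:
        for line in fh:
            if "=" in line and not line.startswith("#"):
                key, val = line.split("=", 1)
                kv[key.strip()] = val.strip()
    spec = PatternSpec(
        length=float(kv["length_um"]),
        width=float(kv["width_um"]),
        tip_shape=kv["tip_shape"],
        spacing=float(kv["spacing_um"]),
        sharp_half_angle_deg=float(kv.get("sharp_half_angle_deg", 45.0)),
        concave_radius=float(kv["concave_radius_um"]) if "concave_radius_um" in kv else None,
    )
    mask = make_mask(spec)
    from PIL import Image

    grid = np.asarray(Image.open(path)) > 127
    if grid.shape != mask.grid.shape or not np.array_equal(grid, mask.grid):
        raise ValueError(f"mask raster {path} does not match its sidecar spec")
    return mask
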