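"""Speckle-realistic OCT phantoms of layered mucosal tissue with vessels.

The phantom emulates the features of an endoscopic OCT scan of the vaginal
wall that the analysis pipeline relies on:

* a bright surface-reflection line at the air-tissue interface,
* a dark epithelium band of known thickness directly beneath it,
* a bright lamina propria below,
* fully developed speckle (complex circular-Gaussian field, hence
  Rayleigh-distributed amplitude) everywhere in tissue,
* 3-D vessel tubes whose speckle decorrelates between repeated frames
  while static tissue keeps the same speckle realization,
* optionally a grid-like pattern of decorrelating spots emulating the
  appearance of fractional laser treatment in en-face angiograms.

Every generated object carries the parameters that produced it, so
recovery tests can compare against ground truth without re-inference.

No physical light propagation, attenuation or probe motion is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import PhantomGeometry
from .ibdv import FrameSequence

__all__ = [
    "TissueScene",
    "AcquisitionVolume",
    "make_tissue_scene",
    "render_frame_sequence",
    "make_segmentation_dataset",
    "RAYLEIGH_MEAN_SD_RATIO",
]

# amplitude mean/SD ratio of fully developed speckle: sqrt(pi / (4 - pi))
RAYLEIGH_MEAN_SD_RATIO = float(np.sqrt(np.pi / (4.0 - np.pi)))

# relative backscatter of the rendered layers (arbitrary units of E[A^2]);
# the surface reflection is two pixels with the first much brighter, so
# boundary trackers localize it to the first tissue pixel
SURFACE_REFLECTIVITY = 16.0
SUBSURFACE_REFLECTIVITY = 4.0
EPITHELIUM_REFLECTIVITY = 0.25
LAMINA_REFLECTIVITY = 1.0


@dataclass
class TissueScene:
    """Geometric ground truth of one phantom volume.

    Arrays are indexed laterally ``(x, y)``; the vessel mask is ``(x, y, z)``.
    The epithelium band of a column at surface depth ``s`` (pixels) and
    thickness ``t`` (pixels, ``t = round(thickness_um / axial_pixel_um)``)
    spans ``z in [s, s + t)``; the surface-reflection line overlays its
    first pixel and the lamina propria starts at ``s + t``.
    """

    geometry: PhantomGeometry
    surface_depth: np.ndarray          # (x, y) float pixels
    epi_thickness_um: np.ndarray       # (x, y) float micrometres
    vessel_mask: np.ndarray            # (x, y, z) bool
    ablation_grid: np.ndarray | None = None   # (x, y) bool
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.geometry
        if np.any(self.epi_thickness_um < 0):
            raise ValueError("epithelial thickness must be >= 0 everywhere")
        if self.vessel_mask.shape != (g.n_fast, g.n_slow, g.n_depth):
            raise ValueError("vessel_mask must have shape (n_fast, n_slow, n_depth)")

    @property
    def surface_index(self) -> np.ndarray:
        """Rounded surface depth per column, (x, y) int."""
        return np.rint(self.surface_depth).astype(int)

    @property
    def thickness_px(self) -> np.ndarray:
        """Rasterized epithelium thickness per column, (x, y) int."""
        return np.rint(self.epi_thickness_um / self.geometry.axial_pixel_um).astype(int)

    @property
    def enface_vessel_fraction(self) -> float:
        """Fraction of (x, y) columns containing at least one vessel voxel."""
        return float(self.vessel_mask.any(axis=2).mean())

    @property
    def enface_vessel_mask(self) -> np.ndarray:
        """(x, y) bool — the ground-truth en-face vessel footprint."""
        return self.vessel_mask.any(axis=2)

    def reflectivity_volume(self) -> np.ndarray:
        """Mean-backscatter volume (x, y, z): air 0, layered tissue below."""
        g = self.geometry
        z = np.arange(g.n_depth)[None, None, :]
        s = self.surface_index[:, :, None]
        t = self.thickness_px[:, :, None]
        refl = np.zeros((g.n_fast, g.n_slow, g.n_depth))
        refl[(z >= s) & (z < s + t)] = EPITHELIUM_REFLECTIVITY
        refl[z >= s + t] = LAMINA_REFLECTIVITY
        # surface line overlays the top of the epithelium band
        refl[z == s] = SURFACE_REFLECTIVITY
        refl[z == s + 1] = SUBSURFACE_REFLECTIVITY
        return refl

    def epithelium_mask_bscan(self, y: int) -> np.ndarray:
        """Ground-truth epithelium mask of B-scan y as an image (z, x)."""
        g = self.geometry
        z = np.arange(g.n_depth)[:, None]
        s = self.surface_index[:, y][None, :]
        t = self.thickness_px[:, y][None, :]
        return (z >= s) & (z < s + t)


@dataclass
class AcquisitionVolume:
    """Rendered repeated-frame amplitude data for a whole volume.

    ``frames`` is indexed ``(y, frame, x, z)``: for each slow-axis position
    y there are ``n_repeats`` repeated B-scans.
    """

    frames: np.ndarray
    geometry: PhantomGeometry
    scene: TissueScene | None = None
    params: dict = field(default_factory=dict)

    @property
    def n_slow(self) -> int:
        return self.frames.shape[0]

    def sequence(self, y: int) -> FrameSequence:
        """The repeated-frame sequence at slow-axis position y."""
        return FrameSequence(self.frames[y].astype(np.float64), geometry=self.geometry)

    def sequences(self):
        """Iterate over FrameSequence objects in slow-axis order."""
        for y in range(self.n_slow):
            yield self.sequence(y)

    def structural_bscan(self, y: int) -> np.ndarray:
        """Temporal-mean amplitude B-scan at position y as an image (z, x)."""
        return self.frames[y].mean(axis=0).T.astype(np.float64)


def _smooth_surface(geometry: PhantomGeometry, base_px: float, rng: np.random.Generator) -> np.ndarray:
    """Gently undulating surface height field, slope < 1 px per column."""
    x = np.arange(geometry.n_fast)
    y = np.arange(geometry.n_slow)
    phx, phy = rng.uniform(0, 2 * np.pi, size=2)
    sx = 2.0 * np.sin(2 * np.pi * x / max(geometry.n_fast, 64) + phx)
    sy = 1.5 * np.sin(2 * np.pi * y / max(geometry.n_slow, 32) + phy)
    return base_px + sx[:, None] + sy[None, :]


def _rasterize_tubes(
    geometry: PhantomGeometry,
    surface_idx: np.ndarray,
    thickness_px: np.ndarray,
    vessel_fraction: float,
    rng: np.random.Generator,
    vessel_band_px: int = 40,
) -> np.ndarray:
    """Grow random 3-D tube centerlines until the en-face footprint hits
    the target area fraction, then trim the most recently added columns.

    Returns the (x, y, z) boolean vessel mask.  The en-face fraction of the
    result is within one footprint column of the target.
    """
    nx, ny, nz = geometry.n_fast, geometry.n_slow, geometry.n_depth
    mask = np.zeros((nx, ny, nz), dtype=bool)
    if vessel_fraction <= 0:
        return mask

    footprint = np.zeros((nx, ny), dtype=bool)
    total = nx * ny
    target_cols = int(round(vessel_fraction * total))
    # columns recorded in the order their footprint pixel was first set,
    # together with the z-extent stamped there (for trimming)
    added: list[tuple[int, int]] = []

    # vessels live in the subepithelial plexus: a shallow band of the
    # lamina propria starting just below the epithelium
    z_top = int(np.max(surface_idx + thickness_px)) + 4
    z_top = min(z_top, nz - 8)
    z_bot = min(z_top + vessel_band_px, nz - 4)

    max_tubes = 20000
    n_tubes = 0
    while footprint.sum() < target_cols and n_tubes < max_tubes:
        n_tubes += 1
        # random centerline: start anywhere, random heading, gentle wiggle
        cx = rng.uniform(0, nx)
        cy = rng.uniform(0, ny)
        theta = rng.uniform(0, 2 * np.pi)
        radius = int(rng.integers(1, 5))       # en-face radius 1-4 px
        zc = int(rng.integers(z_top, max(z_top + 1, z_bot)))
        length = int(rng.uniform(0.5, 1.5) * max(nx, ny))
        zr = radius                            # roughly isotropic tube section
        for _ in range(length):
            theta += rng.normal(0.0, 0.15)
            cx += np.cos(theta)
            cy += np.sin(theta)
            if not (0 <= cx < nx and 0 <= cy < ny):
                break
            ix, iy = int(cx), int(cy)
            x_lo, x_hi = max(0, ix - radius), min(nx, ix + radius + 1)
            y_lo, y_hi = max(0, iy - radius), min(ny, iy + radius + 1)
            z_lo, z_hi = max(z_top, zc - zr), min(nz, zc + zr + 1)
            for px in range(x_lo, x_hi):
                for py in range(y_lo, y_hi):
                    if (px - cx) ** 2 + (py - cy) ** 2 <= radius ** 2:
                        if not footprint[px, py]:
                            footprint[px, py] = True
                            added.append((px, py))
                        mask[px, py, z_lo:z_hi] = True
            if footprint.sum() >= target_cols:
                break

    # trim the most recently added footprint columns back to the target
    excess = footprint.sum() - target_cols
    for _ in range(max(0, excess)):
        px, py = added.pop()
        footprint[px, py] = False
        mask[px, py, :] = False
    return mask


def make_tissue_scene(
    geometry: PhantomGeometry | None = None,
    thickness_um: float | np.ndarray = 150.0,
    vessel_fraction: float = 0.2,
    seed: int = 0,
    surface_depth_px: float = 30.0,
    ablation_grid_pitch_px: int | None = None,
    vessel_band_px: int = 40,
) -> TissueScene:
    """Build a layered-tissue scene with embedded vessel tubes.

    Parameters
    ----------
    geometry
        Scan geometry; defaults to `PhantomGeometry()`.
    thickness_um
        True epithelial thickness, scalar or per-(x, y) field (micrometres).
    vessel_fraction
        Target en-face vessel area fraction in [0, 0.9].  The rasterized
        tube mask is trimmed/grown to land within 0.02 of this value
        (in practice within one footprint column).
    seed
        RNG seed; identical seeds give bit-identical scenes.
    surface_depth_px
        Mean depth of the air-tissue interface in pixels.
    ablation_grid_pitch_px
        If given, adds a grid of decorrelating treatment spots with this
        pitch to the scene (rendered as flow-like signal by the renderer).
    vessel_band_px
        Depth extent (pixels) of the subepithelial plexus band in which
        vessel tubes are placed.
    """
    if geometry is None:
        geometry = PhantomGeometry()
    if not (0.0 <= vessel_fraction <= 0.9):
        raise ValueError("vessel_fraction must lie in [0, 0.9]")

    rng = np.random.default_rng(seed)
    thickness = np.broadcast_to(
        np.asarray(thickness_um, dtype=float), (geometry.n_fast, geometry.n_slow)
    ).copy()
    if np.any(thickness < 0):
        raise ValueError("thickness_um must be >= 0")

    surface = _smooth_surface(geometry, surface_depth_px, rng)
    surface_idx = np.rint(surface).astype(int)
    t_px = np.rint(thickness / geometry.axial_pixel_um).astype(int)

    # the lamina propria and vessels need headroom below the epithelium
    margin_px = 12
    max_bottom = int(np.max(surface_idx + t_px))
    if max_bottom > geometry.n_depth - margin_px:
        max_um = (geometry.n_depth - margin_px - int(surface_idx.max())) * geometry.axial_pixel_um
        raise ValueError(
            f"epithelial thickness exceeds the imaging depth; the maximum "
            f"representable thickness for this geometry is {max_um:.0f} um"
        )

    vessel_mask = _rasterize_tubes(geometry, surface_idx, t_px, vessel_fraction, rng,
                                   vessel_band_px=vessel_band_px)

    grid = None
    if ablation_grid_pitch_px is not None:
        p = int(ablation_grid_pitch_px)
        if p < 2:
            raise ValueError("ablation_grid_pitch_px must be >= 2")
        gx = (np.arange(geometry.n_fast) % p) < max(1, p // 6)
        gy = (np.arange(geometry.n_slow) % p) < max(1, p // 6)
        grid = gx[:, None] | gy[None, :]

    return TissueScene(
        geometry=geometry,
        surface_depth=surface,
        epi_thickness_um=thickness,
        vessel_mask=vessel_mask,
        ablation_grid=grid,
        params={
            "thickness_um": float(np.mean(thickness)),
            "vessel_fraction_target": vessel_fraction,
            "seed": seed,
            "surface_depth_px": surface_depth_px,
            "ablation_grid_pitch_px": ablation_grid_pitch_px,
            "vessel_band_px": vessel_band_px,
        },
    )


def render_frame_sequence(
    scene: TissueScene,
    geometry: PhantomGeometry | None = None,
    decorrelation: float = 1.0,
    noise_floor: float = 0.05,
    seed: int = 0,
) -> AcquisitionVolume:
    """Render repeated-frame speckle amplitude data for a scene.

    Static tissue keeps one complex circular-Gaussian speckle field across
    all repeated frames (plus additive detection noise); voxels inside the
    vessel mask (and under ablation-grid spots, in a shallow sub-surface
    band) evolve between frames as

        g_{j+1} = sqrt(1 - d) * g_j + sqrt(d) * (independent draw)

    so that ``d = 0`` reproduces static speckle and ``d = 1`` gives fully
    independent realizations frame to frame.  Amplitude is the field
    magnitude, hence Rayleigh-distributed in tissue.

    Parameters
    ----------
    decorrelation
        Inter-frame speckle decorrelation ``d`` inside vessels, in [0, 1].
    noise_floor
        Scale of the additive complex detection noise (E[|n|^2] equals
        ``noise_floor**2``); with 0 and ``d = 0`` all frames are identical.
    """
    if geometry is None:
        geometry = scene.geometry
    if not (0.0 <= decorrelation <= 1.0):
        raise ValueError("decorrelation must lie in [0, 1]")
    if noise_floor < 0:
        raise ValueError("noise_floor must be >= 0")

    rng = np.random.default_rng(seed)
    nx, ny, nz = geometry.n_fast, geometry.n_slow, geometry.n_depth
    n_rep = geometry.n_repeats
    refl = scene.reflectivity_volume()

    dyn = scene.vessel_mask.copy()
    if scene.ablation_grid is not None:
        # treatment spots decorrelate in a shallow band below the surface
        s = scene.surface_index
        z = np.arange(nz)[None, None, :]
        band = (z >= s[:, :, None] + 1) & (z <= s[:, :, None] + 6)
        dyn |= band & scene.ablation_grid[:, :, None]

    d = float(decorrelation)
    frames = np.empty((ny, n_rep, nx, nz), dtype=np.float32)

    def cgauss(shape, scale):
        return (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) * (scale / np.sqrt(2.0))

    for y in range(ny):
        amp_scale = np.sqrt(refl[:, y, :])        # (x, z), E[|g|^2] = refl
        g = cgauss((nx, nz), amp_scale)
        dyn_y = dyn[:, y, :]
        for j in range(n_rep):
            if j > 0 and d > 0 and dyn_y.any():
                fresh = cgauss((nx, nz), amp_scale)
                g = np.where(dyn_y, np.sqrt(1.0 - d) * g + np.sqrt(d) * fresh, g)
            signal = g
            if noise_floor > 0:
                signal = signal + cgauss((nx, nz), noise_floor)
            frames[y, j] = np.abs(signal).astype(np.float32)

    return AcquisitionVolume(
        frames=frames,
        geometry=geometry,
        scene=scene,
        params={"decorrelation": d, "noise_floor": noise_floor, "seed": seed},
    )


def make_segmentation_dataset(
    n_pairs: int,
    geometry: PhantomGeometry | None = None,
    thickness_range_um: tuple[float, float] = (70.0, 250.0),
    noise_floor: float = 0.05,
    seed: int = 0,
):
    """Generate (B-scan, epithelium-mask) training pairs for segmentation.

    Each pair is a structural B-scan (temporal-mean amplitude, image
    orientation (z, x)) of a single-position phantom with random surface
    height and random epithelial thickness, plus its ground-truth band
    mask.  Images are max-normalized to [0, 1].

    Returns
    -------
    images : (n_pairs, n_depth, n_fast) float32
    masks : (n_pairs, n_depth, n_fast) bool
    thicknesses_um : (n_pairs,) float — the generating thickness values
    """
    if geometry is None:
        geometry = PhantomGeometry(n_depth=64, n_fast=64, n_slow=8, n_repeats=2)
    rng = np.random.default_rng(seed)
    images = np.empty((n_pairs, geometry.n_depth, geometry.n_fast), dtype=np.float32)
    masks = np.empty((n_pairs, geometry.n_depth, geometry.n_fast), dtype=bool)
    thicknesses = np.empty(n_pairs)

    max_thick = (geometry.n_depth - 14 - 14) * geometry.axial_pixel_um
    lo, hi = thickness_range_um
    hi = min(hi, max_thick)
    for i in range(n_pairs):
        t = rng.uniform(lo, hi)
        surf = rng.uniform(6.0, geometry.n_depth * 0.2 + 6.0)
        scene = make_tissue_scene(
            geometry,
            thickness_um=t,
            vessel_fraction=0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
            surface_depth_px=surf,
        )
        vol = render_frame_sequence(
            scene, decorrelation=0.0, noise_floor=noise_floor,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        y = geometry.n_slow // 2
        img = vol.structural_bscan(y)
        images[i] = (img / max(img.max(), 1e-12)).astype(np.float32)
        masks[i] = scene.epithelium_mask_bscan(y)
        thicknesses[i] = t
    return images, masks, thicknesses
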