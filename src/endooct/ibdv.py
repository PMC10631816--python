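"""Intensity-based Doppler variance (IBDV) angiography.

The flow-contrast statistic computed here is the amplitude-only Doppler
variance

    sigma^2 = 1 - sum_j A_j A_{j+1} / sum_j (A_j^2 + A_{j+1}^2) / 2

where ``A_j`` is the OCT amplitude of the j-th member of a set of repeated
measurements of the same voxel and the sum runs over the J consecutive
pairs (and optionally over a small lateral averaging window).  For static
tissue the repeated amplitudes are identical and sigma^2 = 0; where moving
scatterers decorrelate the speckle between repeats, sigma^2 rises toward
the fully-decorrelated Rayleigh limit 1 - pi/4.

By AM-GM, ``A_j A_{j+1} <= (A_j^2 + A_{j+1}^2)/2`` for non-negative
amplitudes, so sigma^2 always lies in [0, 1].

Two pairing modes are provided:

* ``"inter"`` (default) — pairs the same A-line across repeated B-scans
  acquired at one slow-axis position.  The long inter-frame time interval
  gives high sensitivity to slow microvascular flow.
* ``"intra"`` — pairs neighbouring A-lines within each frame (short time
  interval; sensitive only to fast flow).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .geometry import PhantomGeometry

__all__ = [
    "FrameSequence",
    "VarianceVolume",
    "EnFaceMap",
    "compute_ibdv",
    "compute_ibdv_volume",
    "enface_project",
]


@dataclass
class FrameSequence:
    """Repeated amplitude B-scans acquired at one slow-axis position.

    ``amplitude`` has shape ``(n_frames, n_fast, n_depth)`` = (J+1, x, z),
    all values non-negative.
    """

    amplitude: np.ndarray
    geometry: PhantomGeometry | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitude, dtype=np.float64)
        if a.ndim != 3:
            raise ValueError(f"amplitude must be 3-D (frame, x, z), got shape {a.shape}")
        if a.shape[0] < 2:
            raise ValueError("inter-frame variance needs >=2 frames")
        if np.any(a < 0):
            raise ValueError("amplitudes must be non-negative")
        self.amplitude = a

    @property
    def n_frames(self) -> int:
        return self.amplitude.shape[0]

    @property
    def n_pairs(self) -> int:
        """J — the number of consecutive-frame pairs entering the variance."""
        return self.n_frames - 1

    def mean_amplitude(self) -> np.ndarray:
        """Temporal mean amplitude, shape (x, z) — the structural B-scan."""
        return self.amplitude.mean(axis=0)


@dataclass
class VarianceVolume:
    """Doppler-variance values in [0, 1] per voxel, indexed (x, y, z)."""

    sigma2: np.ndarray
    geometry: PhantomGeometry | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma2, dtype=np.float64)
        if s.ndim != 3:
            raise ValueError(f"sigma2 must be 3-D (x, y, z), got shape {s.shape}")
        if s.size and (s.min() < -1e-9 or s.max() > 1 + 1e-9):
            raise ValueError("sigma2 values must lie in [0, 1]")
        self.sigma2 = np.clip(s, 0.0, 1.0)


@dataclass
class EnFaceMap:
    """Depth-projected angiogram on the lateral (x, y) grid."""

    values: np.ndarray
    z_bounds: tuple[int, int] | None = None
    geometry: PhantomGeometry | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError(f"en-face values must be 2-D (x, y), got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("en-face values must be finite")
        self.values = v


def _pair_sums_inter(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # a: (frames, x, z); consecutive-frame products at fixed (x, z)
    num = (a[:-1] * a[1:]).sum(axis=0)
    den = ((a[:-1] ** 2 + a[1:] ** 2) / 2.0).sum(axis=0)
    return num, den


def _pair_sums_intra(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # neighbouring A-lines within each frame, summed over frames
    num = (a[:, :-1, :] * a[:, 1:, :]).sum(axis=0)
    den = ((a[:, :-1, :] ** 2 + a[:, 1:, :] ** 2) / 2.0).sum(axis=0)
    # pad the last column so the output keeps the lateral grid size
    num = np.concatenate([num, num[-1:, :]], axis=0)
    den = np.concatenate([den, den[-1:, :]], axis=0)
    return num, den


def compute_ibdv(
    seq: FrameSequence | np.ndarray,
    lateral_window: int = 3,
    mode: str = "inter",
) -> np.ndarray:
    """Doppler-variance image sigma^2(x, z) of one repeated-frame sequence.

    Parameters
    ----------
    seq
        `FrameSequence` or raw array of shape (J+1, x, z) with J >= 1.
    lateral_window
        Odd number of neighbouring A-lines over which numerator and
        denominator are additionally summed before taking the ratio
        (denoising; 1 disables lateral averaging).
    mode
        ``"inter"`` (same A-line across repeated frames, default) or
        ``"intra"`` (neighbouring A-lines within each frame).

    Returns
    -------
    ndarray
        sigma^2 in [0, 1], shape (x, z).  Voxels with zero denominator
        (no backscattered signal at all) are defined as 0 so that
        background stays dark.
    """
    if not isinstance(seq, FrameSequence):
        seq = FrameSequence(np.asarray(seq))
    if lateral_window < 1 or lateral_window % 2 == 0:
        raise ValueError("lateral_window must be a positive odd integer")
    if mode not in ("inter", "intra"):
        raise ValueError(f"unknown pairing mode {mode!r}")

    a = seq.amplitude
    if mode == "inter":
        num, den = _pair_sums_inter(a)
    else:
        num, den = _pair_sums_intra(a)

    if lateral_window > 1:
        # box sum over the lateral window (axis 0 is x); nearest-edge padding
        num = uniform_filter1d(num, size=lateral_window, axis=0, mode="nearest")
        den = uniform_filter1d(den, size=lateral_window, axis=0, mode="nearest")

    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = 1.0 - num / den
    sigma2[den == 0] = 0.0
    # AM-GM guarantees [0,1] analytically; clip only float round-off
    return np.clip(sigma2, 0.0, 1.0)


def compute_ibdv_volume(
    sequences,
    lateral_window: int = 3,
    mode: str = "inter",
    geometry: PhantomGeometry | None = None,
) -> VarianceVolume:
    """Apply :func:`compute_ibdv` at every slow-axis position.

    Parameters
    ----------
    sequences
        Iterable of `FrameSequence` (or (J+1, x, z) arrays), one per
        slow-axis position, or a 4-D array (y, J+1, x, z).

    Returns
    -------
    VarianceVolume
        sigma^2 indexed (x, y, z).
    """
    if isinstance(sequences, np.ndarray) and sequences.ndim == 4:
        seq_list = [sequences[i] for i in range(sequences.shape[0])]
    else:
        seq_list = list(sequences)
    if not seq_list:
        raise ValueError("no frame sequences given")

    planes = []
    shape = None
    for s in seq_list:
        fs = s if isinstance(s, FrameSequence) else FrameSequence(np.asarray(s))
        if geometry is None and fs.geometry is not None:
            geometry = fs.geometry
        if shape is None:
            shape = fs.amplitude.shape
        elif fs.amplitude.shape != shape:
            raise ValueError(
                f"inconsistent frame-sequence shapes: {fs.amplitude.shape} vs {shape}"
            )
        planes.append(compute_ibdv(fs, lateral_window=lateral_window, mode=mode))

    sigma2 = np.stack(planes, axis=1)  # (x, y, z)
    return VarianceVolume(
        sigma2,
        geometry=geometry,
        provenance={"J": shape[0] - 1, "mode": mode, "lateral_window": lateral_window},
    )


def enface_project(vol: VarianceVolume, z_lo: int, z_hi: int) -> EnFaceMap:
    """Average-project a depth slab of a variance volume to an en-face map.

    The slab is half-open: z in [z_lo, z_hi).
    """
    n_depth = vol.sigma2.shape[2]
    if not (0 <= z_lo < z_hi <= n_depth):
        raise ValueError(
            f"empty or out-of-range depth slab [{z_lo}, {z_hi}) for n_depth={n_depth}"
        )
    values = vol.sigma2[:, :, z_lo:z_hi].mean(axis=2)
    return EnFaceMap(values, z_bounds=(z_lo, z_hi), geometry=vol.geometry)
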