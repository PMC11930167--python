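"""Seeded synthetic SMLM point-cloud generator (disk / nanofocus pattern).

The generator emulates, directly at the point-cloud level, the standard
disk-pattern test structure used to benchmark SMLM cluster analyses: nine
circular disks on a 3x3 grid, each disk filled with randomly placed
*nanofoci* (point-like epitopes), each nanofocus decorated with fluorescent
labels sitting on a spherical linker shell around the epitope.  Imaging is
emulated by a stochastic detection/blinking/precision chain rather than an
optical simulation:

1. each label is detected with probability ``detect_eff`` (dye duty cycle,
   filtering and frame-budget losses collapsed into one efficiency);
2. a detected label emits ``k >= 1`` localizations, ``k`` geometric with
   mean ``mean_blinks`` (re-blinking of the same molecule);
3. every localization is displaced by isotropic Gaussian noise of standard
   deviation ``loc_sigma`` per axis (localization precision);
4. nonspecific background molecules are placed uniformly in a slab volume
   (pattern bounding rectangle x ``axial_range``) at ``bg_density`` and sent
   through the same detection chain, projected to the xy plane.

Everything is reproducible bit-for-bit from ``PatternConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np

from .localization_io import LocalizationTable

__all__ = ["PatternConfig", "GroundTruth", "generate_ground_truth", "simulate_localizations", "simulate_pattern"]


@dataclass(frozen=True)
class PatternConfig:
    """Parameters of the disk/nanofocus pattern and the emulated imaging chain.

    Lengths are nm, densities as annotated.  Defaults reproduce the standard
    benchmark pattern: nine 560 nm disks on a 3x3 grid with 2500 nm spacing,
    4 nanofoci/um^2, 150 labels per nanofocus (variance 5) on a 99 nm linker
    shell, no background.
    """

    grid_shape: Tuple[int, int] = (3, 3)
    spacing: float = 2500.0            # nm, grid pitch of the disk centers
    disk_radius: float = 560.0         # nm
    nanofocus_density: float = 4.0     # 1/um^2 within each disk
    labels_mean: float = 150.0         # labels per nanofocus
    labels_var: float = 5.0            # variance of the label count
    linker_length: float = 99.0        # nm, radius of the label shell
    bg_density: float = 0.0            # 1/um^3, nonspecific molecules
    axial_range: float = 1000.0        # nm, slab thickness for background
    mean_blinks: float = 2.0           # localizations per detected label
    detect_eff: float = 0.2            # fraction of labels ever localized
    loc_sigma: float = 5.0             # nm, localization precision per axis
    seed: int = 0

    def __post_init__(self):
        gx, gy = self.grid_shape
        if gx < 1 or gy < 1:
            raise ValueError("grid_shape entries must be >= 1")
        for name in ("spacing", "disk_radius", "linker_length", "axial_range", "loc_sigma"):
            if getattr(self, name) < 0 or (name in ("spacing", "disk_radius", "linker_length", "axial_range") and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be > 0")
        if self.nanofocus_density < 0 or self.bg_density < 0:
            raise ValueError("densities must be >= 0")
        if self.labels_mean <= 0 or self.labels_var < 0:
            raise ValueError("labels_mean must be > 0 and labels_var >= 0")
        if self.mean_blinks < 1:
            raise ValueError("mean_blinks must be >= 1")
        if not (0 < self.detect_eff <= 1):
            raise ValueError("detect_eff must be in (0, 1]")
        if self.disk_radius >= self.spacing / 2 and (gx > 1 or gy > 1):
            raise ValueError("disks must not overlap: disk_radius < spacing/2")

    @property
    def disk_centers(self) -> np.ndarray:
        gx, gy = self.grid_shape
        xs, ys = np.meshgrid(
            np.arange(gx) * self.spacing, np.arange(gy) * self.spacing, indexing="ij"
        )
        return np.column_stack([xs.ravel(), ys.ravel()])

    @property
    def pattern_bounds(self) -> tuple[float, float, float, float]:
        """Bounding rectangle (xmin, xmax, ymin, ymax) of the disk pattern, nm."""
        c = self.disk_centers
        r = self.disk_radius
        return (
            float(c[:, 0].min() - r), float(c[:, 0].max() + r),
            float(c[:, 1].min() - r), float(c[:, 1].max() + r),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PatternConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """Ground-truth structure: nanofocus centers, label positions, background.

    ``nanofocus_parent`` maps each nanofocus to its disk;
    ``label_parent`` maps each label to its nanofocus.
    """

    nanofocus_centers: np.ndarray   # (k, 2) nm
    nanofocus_parent: np.ndarray    # (k,) disk index
    label_positions: np.ndarray     # (m, 2) nm, xy projection of shell points
    label_parent: np.ndarray        # (m,) nanofocus index
    background_positions: np.ndarray  # (b, 2) nm


def _uniform_in_disk(rng: np.random.Generator, center, radius, n) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    phi = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([center[0] + r * np.cos(phi), center[1] + r * np.sin(phi)])


def _sphere_shell_xy(rng: np.random.Generator, n, radius) -> np.ndarray:
    """xy projection of points uniform on a sphere surface of given radius."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return radius * v[:, :2]


def generate_ground_truth(config: PatternConfig) -> GroundTruth:
    """Draw the ground-truth pattern for a configuration.

    Per-disk nanofocus counts are Poisson(density x disk area); nanofocus
    centers are uniform in their disk; per-nanofocus label counts follow a
    rounded Normal(labels_mean, labels_var) truncated at 1; labels sit
    uniformly on a sphere of radius ``linker_length`` around the (2D, z=0)
    epitope, projected to the xy plane.  Background molecule positions are
    drawn uniformly over the pattern bounding rectangle with a Poisson count
    set by the slab volume.  Fully reproducible from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.Generator(np.random.PCG64(ss.spawn(2)[0]))

    disk_area_um2 = np.pi * (config.disk_radius / 1000.0) ** 2
    centers = config.disk_centers
    nano_centers, nano_parent = [], []
    for d, c in enumerate(centers):
        k = rng.poisson(config.nanofocus_density * disk_area_um2)
        if k:
            nano_centers.append(_uniform_in_disk(rng, c, config.disk_radius, k))
            nano_parent.append(np.full(k, d, dtype=int))
    if nano_centers:
        nano_centers = np.concatenate(nano_centers)
        nano_parent = np.concatenate(nano_parent)
    else:
        nano_centers = np.empty((0, 2))
        nano_parent = np.empty(0, dtype=int)

    n_labels = np.maximum(
        1,
        np.rint(rng.normal(config.labels_mean, np.sqrt(config.labels_var), size=nano_centers.shape[0])),
    ).astype(int) if nano_centers.shape[0] else np.empty(0, dtype=int)
    label_pos, label_parent = [], []
    for i, (c, m) in enumerate(zip(nano_centers, n_labels)):
        label_pos.append(c + _sphere_shell_xy(rng, m, config.linker_length))
        label_parent.append(np.full(m, i, dtype=int))
    if label_pos:
        label_pos = np.concatenate(label_pos)
        label_parent = np.concatenate(label_parent)
    else:
        label_pos = np.empty((0, 2))
        label_parent = np.empty(0, dtype=int)

    xmin, xmax, ymin, ymax = config.pattern_bounds
    slab_um3 = ((xmax - xmin) / 1000.0) * ((ymax - ymin) / 1000.0) * (config.axial_range / 1000.0)
    n_bg = rng.poisson(config.bg_density * slab_um3)
    bg = np.column_stack([
        rng.uniform(xmin, xmax, size=n_bg),
        rng.uniform(ymin, ymax, size=n_bg),
    ]) if n_bg else np.empty((0, 2))

    return GroundTruth(
        nanofocus_centers=nano_centers,
        nanofocus_parent=nano_parent,
        label_positions=label_pos,
        label_parent=label_parent,
        background_positions=bg,
    )


def _blink_and_localize(rng, positions, config, n_frames=8000):
    """Detection thinning, geometric blinking and precision noise for molecules."""
    n = positions.shape[0]
    if n == 0:
        return np.empty((0, 2)), np.empty(0, dtype=int)
    detected = rng.uniform(size=n) < config.detect_eff
    pos = positions[detected]
    if pos.shape[0] == 0:
        return np.empty((0, 2)), np.empty(0, dtype=int)
    k = rng.geometric(1.0 / config.mean_blinks, size=pos.shape[0])
    locs = np.repeat(pos, k, axis=0)
    locs = locs + rng.normal(scale=config.loc_sigma, size=locs.shape)
    frames = rng.integers(0, n_frames, size=locs.shape[0])
    return locs, frames


def simulate_localizations(truth: GroundTruth, config: PatternConfig) -> LocalizationTable:
    """Emulate imaging of a ground-truth pattern, returning the point cloud.

    Signal labels and background molecules go through the same chain:
    Bernoulli(detect_eff) detection, geometric(mean_blinks) localization
    multiplicity, isotropic Gaussian displacement of ``loc_sigma`` per axis.
    Row order: signal localizations first, then background.
    """
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.Generator(np.random.PCG64(ss.spawn(2)[1]))
    sig, sig_frames = _blink_and_localize(rng, truth.label_positions, config)
    bg, bg_frames = _blink_and_localize(rng, truth.background_positions, config)
    xy = np.concatenate([sig, bg]) if sig.size or bg.size else np.empty((0, 2))
    frames = np.concatenate([sig_frames, bg_frames])
    precision = np.full(xy.shape[0], float(config.loc_sigma))
    return LocalizationTable(x=xy[:, 0], y=xy[:, 1], frame=frames, precision=precision)


def simulate_pattern(config: PatternConfig) -> tuple[LocalizationTable, GroundTruth]:
    """Convenience: ground truth + localization table in one call."""
    truth = generate_ground_truth(config)
    return simulate_localizations(truth, config), truth
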