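"""Synthetic dual-energy root phantoms with known ground truth.

Generates paired reconstructed volumes (below-edge 16.5 keV, above-edge
17.2 keV, voxel values in cm⁻¹) of a root-like object:

* organic tissue whose attenuation decreases slightly with energy,
* high-Z mineral inclusions in the vascular core (attenuation also
  decreasing slightly with energy) acting as segmentation distractors,
* yttria inclusions whose attenuation jumps by the K-edge factor of ~5,
  placed preferentially at the primary/lateral root junction and along
  the outer epidermis as aggregated blobs,
* optional inter-scan shrinkage/shift applied to the below-edge volume,
  additive or counting noise, and a projection/FBP round-trip.

On yttria voxels the construction identity
``µ_above − µ_below = C·Δ(µ/ρ)/1000`` holds exactly (before noise and
shrinkage), so the generator doubles as the oracle for the downstream
segmentation and concentration-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from kescan.attenuation import KEDGE_DELTA_MU_RHO_CALIBRATED
from kescan.registration import RigidScaleTransform, resample

__all__ = [
    "ConfigurationError",
    "ParticlePopulation",
    "NoiseModel",
    "PhantomSpec",
    "GroundTruth",
    "sample_particles",
    "build_root_phantom",
    "apply_shrinkage",
    "add_noise",
    "fbp_roundtrip",
]


class ConfigurationError(ValueError):
    """Inconsistent phantom specification."""


@dataclass(frozen=True)
class ParticlePopulation:
    """Nanoparticle size statistics: (mean, sd) in nm, truncated at > 0."""

    nanotube_diameter_nm: tuple[float, float] = (31.3, 8.6)
    nanotube_length_nm: tuple[float, float] = (206.3, 77.3)
    irregular_size_nm: tuple[float, float] = (64.9, 16.9)
    nanotube_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.nanotube_fraction <= 1.0:
            raise ValueError("nanotube_fraction must be in [0, 1]")


@dataclass(frozen=True)
class NoiseModel:
    """``none``, ``gaussian`` (additive N(0, sigma) on µ) or ``poisson``
    (count statistics on transmission through ``path_cm`` at intensity i0,
    converted back to µ)."""

    kind: str = "none"
    sigma: float = 0.0
    i0: float = 1e6
    path_cm: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "poisson"):
            raise ConfigurationError(f"unknown noise model {self.kind!r}")
        if self.sigma < 0 or self.i0 <= 0 or self.path_cm <= 0:
            raise ConfigurationError("invalid noise parameters")


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 256, 256)
    voxel_size_mm: float = 0.00319
    tissue_mu_range: tuple[float, float] = (0.5, 1.5)
    #: µ_below = factor · µ_above for tissue ("slight decrease with energy").
    tissue_energy_factor: float = 1.02
    mineral_mu_above: float = 12.5
    mineral_mu_below: float = 13.1
    n_minerals: int = 3
    yttria_concentration_range: tuple[float, float] = (90.0, 130.0)
    n_yttria_junction: int = 4
    n_yttria_epidermis: int = 6
    delta_mu_rho: float = KEDGE_DELTA_MU_RHO_CALIBRATED
    edge_jump_ratio: float = 5.0
    #: linear factor from particle diameter (nm) to aggregate blob diameter
    aggregate_scale: float = 600.0
    shrinkage_scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    shrinkage_shift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise: NoiseModel = field(default_factory=NoiseModel)
    use_fbp: bool = False
    fbp_projections: int = 512
    display_window: tuple[float, float] = (0.2, 17.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ConfigurationError("voxel size must be positive")
        lo, hi = self.yttria_concentration_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError("concentration range must be positive")
        if any(not (0.9 < s < 1.1) for s in self.shrinkage_scale):
            raise ConfigurationError("shrinkage scale factors must lie in (0.9, 1.1)")
        if self.edge_jump_ratio <= 1:
            raise ConfigurationError("edge jump ratio must exceed 1")
        if self.delta_mu_rho <= 0:
            raise ConfigurationError("delta_mu_rho must be positive")
        if self.tissue_energy_factor < 1.0:
            raise ConfigurationError(
                "tissue_energy_factor must be >= 1 (attenuation decreases with energy)"
            )

    @property
    def shrinkage_transform(self) -> RigidScaleTransform:
        return RigidScaleTransform(
            translation=self.shrinkage_shift, scale=self.shrinkage_scale
        )


@dataclass(frozen=True)
class GroundTruth:
    yttria_mask: np.ndarray
    mineral_mask: np.ndarray
    tissue_mask: np.ndarray
    concentration: np.ndarray
    transform: RigidScaleTransform

    def __post_init__(self) -> None:
        if (self.yttria_mask & self.mineral_mask).any() or (
            self.yttria_mask & self.tissue_mask
        ).any() or (self.mineral_mask & self.tissue_mask).any():
            raise ValueError("ground-truth masks must be mutually disjoint")
        if (self.concentration[~self.yttria_mask] != 0).any():
            raise ValueError("concentration must be zero outside the yttria mask")


def sample_particles(
    n: int,
    pop: ParticlePopulation | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw ``n`` particle dimension records from the size distributions.

    Normal draws are truncated at zero by rejection; reproducible for a
    fixed seed.  Columns: ``kind`` ('nanotube' | 'irregular'),
    ``diameter_nm``, ``length_nm`` (NaN for irregular particles),
    ``size_nm`` (characteristic size: diameter or irregular size).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pop = pop or ParticlePopulation()
    rng = np.random.default_rng(seed)

    def truncated_normal(mean: float, sd: float, size: int) -> np.ndarray:
        out = rng.normal(mean, sd, size)
        bad = out <= 0
        while bad.any():
            out[bad] = rng.normal(mean, sd, int(bad.sum()))
            bad = out <= 0
        return out

    is_tube = rng.random(n) < pop.nanotube_fraction
    diameter = np.full(n, np.nan)
    length = np.full(n, np.nan)
    size = np.empty(n)
    n_tube = int(is_tube.sum())
    diameter[is_tube] = truncated_normal(*pop.nanotube_diameter_nm, n_tube)
    length[is_tube] = truncated_normal(*pop.nanotube_length_nm, n_tube)
    size[is_tube] = diameter[is_tube]
    size[~is_tube] = truncated_normal(*pop.irregular_size_nm, n - n_tube)
    return pd.DataFrame(
        {
            "kind": np.where(is_tube, "nanotube", "irregular"),
            "diameter_nm": diameter,
            "length_nm": length,
            "size_nm": size,
        }
    )


def apply_shrinkage(volume: np.ndarray, transform: RigidScaleTransform) -> np.ndarray:
    """Resample a volume under the inter-scan shrinkage/shift transform.

    Applied to the below-edge (second) scan only, simulating sample motion
    between acquisitions.  Linear interpolation, zero fill outside the
    field of view; exact for pure integer translations.
    """
    return resample(volume, transform)


def add_noise(volume: np.ndarray, model: NoiseModel, seed: int = 0) -> np.ndarray:
    """Apply the configured noise model; ``none`` returns a copy."""
    volume = np.asarray(volume, dtype=np.float32)
    rng = np.random.default_rng(seed)
    if model.kind == "none":
        return volume.copy()
    if model.kind == "gaussian":
        if model.sigma == 0:
            return volume.copy()
        return volume + rng.normal(0.0, model.sigma, volume.shape).astype(np.float32)
    # poisson: counts on the transmitted intensity, inverted back to µ
    expected = model.i0 * np.exp(-np.clip(volume, 0, None) * model.path_cm)
    counts = rng.poisson(expected).astype(np.float64)
    counts = np.maximum(counts, 1.0)
    noisy = -np.log(counts / model.i0) / model.path_cm
    # preserve sign convention for (rare) negative inputs
    noisy = np.where(volume < 0, volume, noisy)
    return noisy.astype(np.float32)


def fbp_roundtrip(
    slice2d: np.ndarray,
    n_projections: int = 512,
    angular_range: float = 180.0,
) -> np.ndarray:
    """Parallel-beam forward projection followed by filtered back projection.

    Optional stage that imparts realistic reconstruction texture onto a
    phantom slice.  The slice must be square.
    """
    from skimage.transform import iradon, radon

    slice2d = np.asarray(slice2d, dtype=np.float64)
    if slice2d.ndim != 2 or slice2d.shape[0] != slice2d.shape[1]:
        raise ValueError("slice must be 2D and square")
    if n_projections < 8:
        raise ValueError("need at least 8 projections")
    theta = np.linspace(0.0, angular_range, n_projections, endpoint=False)
    sino = radon(slice2d, theta=theta, circle=False)
    recon = iradon(
        sino,
        theta=theta,
        filter_name="ramp",
        circle=False,
        output_size=slice2d.shape[0],
    )
    return recon.astype(np.float32)


def _sphere_mask(shape, center, radius) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    return (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _geometry(shape: tuple[int, int, int]) -> dict:
    nz, ny, nx = shape
    cy, cx = ny // 2, nx // 2
    radius = int(0.27 * min(ny, nx))
    yy, xx = np.ogrid[:ny, :nx]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    primary_2d = r2 <= radius**2
    epi_width = max(2, radius // 8)
    epidermis_2d = primary_2d & (r2 > (radius - epi_width) ** 2)
    vascular_radius = max(3, radius // 5)
    vascular_2d = r2 <= vascular_radius**2

    primary = np.broadcast_to(primary_2d, shape).copy()
    epidermis = np.broadcast_to(epidermis_2d, shape).copy()
    vascular = np.broadcast_to(vascular_2d, shape).copy()

    # lateral root: horizontal cylinder along +x at mid-height
    z_lat = nz // 2
    lat_radius = max(3, radius // 5)
    zz, yy3, xx3 = np.ogrid[:nz, :ny, :nx]
    lateral = (
        ((zz - z_lat) ** 2 + (yy3 - cy) ** 2 <= lat_radius**2)
        & (xx3 >= cx)
        & (xx3 <= nx - 2)
    )
    root = primary | lateral
    junction = (z_lat, cy, cx + radius)
    return {
        "root": root,
        "primary": primary,
        "epidermis": epidermis & ~lateral,
        "vascular": vascular,
        "lateral": lateral & ~primary,
        "radius": radius,
        "center": (cy, cx),
        "z_lateral": z_lat,
        "lat_radius": lat_radius,
        "junction": junction,
    }


def build_root_phantom(
    spec: PhantomSpec | None = None,
    pop: ParticlePopulation | None = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Generate a dual-energy phantom pair plus ground truth.

    Returns ``(volume_below, volume_above, truth)`` in cm⁻¹.  The ground
    truth describes the object before shrinkage and noise; the applied
    shrinkage transform is recorded on the truth object.
    """
    spec = spec or PhantomSpec()
    pop = pop or ParticlePopulation()
    nz, ny, nx = spec.shape
    if nz < 8 or min(ny, nx) < 32:
        raise ConfigurationError("grid too small for a root with a lateral branch")

    ratio = spec.edge_jump_ratio
    c_lo, c_hi = spec.yttria_concentration_range
    dmu_hi = c_hi * spec.delta_mu_rho / 1000.0
    dmu_lo = c_lo * spec.delta_mu_rho / 1000.0
    win_lo, win_hi = spec.display_window
    mu_above_hi = dmu_hi * ratio / (ratio - 1.0)
    mu_above_lo = dmu_lo * ratio / (ratio - 1.0)
    if mu_above_hi > win_hi or mu_above_lo < win_lo:
        raise ConfigurationError(
            "yttria attenuation outside the display window "
            f"[{win_lo}, {win_hi}]: µ_above spans [{mu_above_lo:.2f}, {mu_above_hi:.2f}]"
        )

    rng = np.random.default_rng(spec.seed)
    geo = _geometry(spec.shape)
    root = geo["root"]

    # tissue attenuation at 17.2 keV: compartment base + smooth texture
    mu_above = np.zeros(spec.shape, dtype=np.float32)
    t_lo, t_hi = spec.tissue_mu_range
    span = t_hi - t_lo
    mu_above[root] = t_lo + 0.3 * span
    mu_above[geo["lateral"]] = t_lo + 0.35 * span
    mu_above[geo["epidermis"]] = t_lo + 0.55 * span
    mu_above[geo["vascular"]] = t_lo + 0.75 * span
    texture = ndi.gaussian_filter(rng.standard_normal(spec.shape), sigma=3.0)
    texture *= 0.08 * span / max(texture.std(), 1e-9)
    mu_above[root] = np.clip(mu_above[root] + texture[root].astype(np.float32), t_lo, t_hi)

    # mineral inclusions inside the vascular core
    mineral_mask = np.zeros(spec.shape, dtype=bool)
    vr = max(3, geo["radius"] // 5)
    cy, cx = geo["center"]
    for _ in range(spec.n_minerals):
        r = int(rng.integers(2, max(3, vr - 1)))
        cz = int(rng.integers(r + 1, nz - r - 1))
        jitter = rng.integers(-max(1, vr - r), max(2, vr - r), 2)
        mineral_mask |= _sphere_mask(
            spec.shape, (cz, cy + int(jitter[0]), cx + int(jitter[1])), r
        )
    mineral_mask &= root

    # yttria aggregate blobs: junction cluster + outer epidermis
    voxel_nm = spec.voxel_size_mm * 1e6
    n_blobs = spec.n_yttria_junction + spec.n_yttria_epidermis
    yttria_mask = np.zeros(spec.shape, dtype=bool)
    concentration = np.zeros(spec.shape, dtype=np.float32)
    if n_blobs:
        particles = sample_particles(
            max(n_blobs, 1), pop, seed=int(rng.integers(2**31))
        )
        r_max = min(6.0, (nz - 4) / 2.0, geo["radius"] / 3.0)
        radii = np.clip(
            particles["size_nm"].to_numpy() * spec.aggregate_scale / voxel_nm / 2.0,
            2.0,
            max(2.0, r_max),
        )
        centers = []
        jz, jy, jx = geo["junction"]
        for k in range(spec.n_yttria_junction):
            r = radii[k]
            off = rng.normal(0, 2.0, 3)
            centers.append(
                (
                    int(np.clip(jz + off[0], r + 1, nz - r - 2)),
                    int(np.clip(jy + off[1], r + 1, ny - r - 2)),
                    int(np.clip(jx + off[2] - r, r + 1, nx - r - 2)),
                )
            )
        R = geo["radius"]
        for k in range(spec.n_yttria_junction, n_blobs):
            r = radii[k]
            theta = rng.uniform(0, 2 * np.pi)
            rad = R - r - 1
            cz = int(rng.integers(int(r) + 1, nz - int(r) - 1))
            centers.append(
                (
                    cz,
                    int(np.clip(cy + rad * np.sin(theta), r + 1, ny - r - 2)),
                    int(np.clip(cx + rad * np.cos(theta), r + 1, nx - r - 2)),
                )
            )
        for (blob_center, r) in zip(centers, radii):
            blob = _sphere_mask(spec.shape, blob_center, r) & root & ~mineral_mask
            c_blob = rng.uniform(c_lo, c_hi)
            newly = blob & ~yttria_mask
            concentration[newly] = c_blob
            yttria_mask |= blob

    mineral_mask &= ~yttria_mask
    tissue_mask = root & ~yttria_mask & ~mineral_mask

    mu_below = (mu_above * spec.tissue_energy_factor).astype(np.float32)
    mu_above[mineral_mask] = spec.mineral_mu_above
    mu_below[mineral_mask] = spec.mineral_mu_below
    # yttria: exact construction identity Δµ = C·Δ(µ/ρ)/1000, ratio above/below = ratio
    dmu = concentration[yttria_mask] * spec.delta_mu_rho / 1000.0
    mu_below[yttria_mask] = dmu / (ratio - 1.0)
    mu_above[yttria_mask] = dmu * ratio / (ratio - 1.0)
    mu_above[~root] = 0.0
    mu_below[~root] = 0.0

    truth = GroundTruth(
        yttria_mask=yttria_mask,
        mineral_mask=mineral_mask,
        tissue_mask=tissue_mask,
        concentration=concentration,
        transform=spec.shrinkage_transform,
    )

    if spec.use_fbp:
        for volume in (mu_above, mu_below):
            for z in range(nz):
                volume[z] = fbp_roundtrip(volume[z], spec.fbp_projections)

    if not spec.shrinkage_transform.is_identity:
        mu_below = apply_shrinkage(mu_below, spec.shrinkage_transform)

    if spec.noise.kind != "none":
        seeds = rng.integers(2**31, size=2)
        mu_above = add_noise(mu_above, spec.noise, seed=int(seeds[0]))
        mu_below = add_noise(mu_below, spec.noise, seed=int(seeds[1]))

    return mu_below, mu_above, truth
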