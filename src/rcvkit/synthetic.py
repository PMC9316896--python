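"""Synthetic coupons and FTIR-like spectra for cleaning-verification studies.

This module generates the raw material every downstream stage consumes:
stainless-steel coupons carrying an inhomogeneous film of active
pharmaceutical ingredient (API), circular spot samples of the kind a
hand-held specular-reflectance FTIR takes, and scan-averaged mid-IR
spectra with additive noise and a coupon-roughness baseline.

The deposition model mirrors a microdot printer: up to 5200 droplets of
4-10 nL placed 0.5-1 mm apart, each droplet spreading into a uniform
disc.  Mass is conserved exactly: the sum of droplet masses equals the
area integral of the resulting surface-density field.  A regular grid
emulates printed coupons; a two-level clustered placement (cluster
centres, then local scatter) emulates deposition by hand, which is what
drives spot-to-spot relative standard deviations into the tens of
percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

MM2_PER_CM2 = 100.0

__all__ = [
    "InstrumentProfile",
    "DepositionProfile",
    "DropletPattern",
    "CouponSurface",
    "ApiSpectralSignature",
    "Spectrum",
    "DepositionInfeasibleError",
    "SpotOutOfBoundsError",
    "generate_coupon",
    "sample_spot",
    "sample_random_spots",
    "simulate_measurement",
    "generate_calibration_set",
    "generate_pseudo_blank_replicates",
    "default_signature",
    "circle_overlap_area",
]


class DepositionInfeasibleError(ValueError):
    """Target density cannot be deposited within droplet-count/volume limits."""


class SpotOutOfBoundsError(ValueError):
    """Requested spot footprint crosses the coupon edge."""


# ---------------------------------------------------------------------------
# Instrument and deposition configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InstrumentProfile:
    """Hand-held mid-IR instrument configuration.

    Defaults follow a specular-reflectance unit with a 1.76 mm^2 spot,
    a 650-4000 cm^-1 range, and 16 co-added scans per reported spectrum.
    Scan averaging is modelled as averaging independent noise
    realisations, so the effective channel noise SD is
    ``noise_sd_per_scan / sqrt(scans_per_spectrum)``.

    Parameters
    ----------
    wavenumber_min, wavenumber_max : float
        Spectral range in cm^-1.
    grid_step : float
        Sampling interval of the wavenumber grid in cm^-1.
    spot_area : float
        Area of the circular measurement footprint in mm^2.
    scans_per_spectrum : int
        Number of scans averaged into each reported spectrum.
    noise_sd_per_scan : float
        Per-channel absorbance noise SD of a single scan.
    baseline_shift_sd : float
        SD of the random baseline offset (and edge tilt) that models
        coupon-to-coupon surface roughness.
    """

    wavenumber_min: float = 650.0
    wavenumber_max: float = 4000.0
    grid_step: float = 2.0
    spot_area: float = 1.76
    scans_per_spectrum: int = 16
    noise_sd_per_scan: float = 0.004
    baseline_shift_sd: float = 0.01

    def __post_init__(self) -> None:
        if not self.wavenumber_min < self.wavenumber_max:
            raise ValueError("wavenumber_min must be < wavenumber_max")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.spot_area <= 0:
            raise ValueError("spot_area must be positive")
        if self.scans_per_spectrum < 1:
            raise ValueError("scans_per_spectrum must be >= 1")
        if self.noise_sd_per_scan < 0 or self.baseline_shift_sd < 0:
            raise ValueError("noise/baseline SDs must be non-negative")

    @property
    def wavenumbers(self) -> np.ndarray:
        """Ascending wavenumber grid in cm^-1."""
        n = int(math.floor((self.wavenumber_max - self.wavenumber_min) / self.grid_step)) + 1
        return self.wavenumber_min + self.grid_step * np.arange(n)

    @property
    def spot_radius_mm(self) -> float:
        return math.sqrt(self.spot_area / math.pi)

    @property
    def effective_noise_sd(self) -> float:
        return self.noise_sd_per_scan / math.sqrt(self.scans_per_spectrum)


@dataclass(frozen=True)
class DepositionProfile:
    """Microdot-deposition parameters for one coupon.

    ``inhomogeneity`` is the dial controlling spatial variability:
    0 produces a regular printed grid; positive values switch to
    clustered hand-style placement (cluster size grows with the dial,
    ~40 droplets per cluster per unit), so larger values give higher
    spot-to-spot %RSD.  The default of 0.1 (clusters of ~4 droplets)
    puts spot sampling of a 0.6 ug/cm^2 coupon in the middle of the
    27-53 %RSD regime observed for hand-deposited coupons.
    """

    coupon_width: float = 25.0  # mm
    coupon_height: float = 25.0  # mm
    solution_concentration: float = 2.0e-4  # ug per nL of deposited solution
    volume_range: tuple[float, float] = (4.0, 10.0)  # nL
    pitch_range: tuple[float, float] = (0.5, 1.0)  # mm, grid mode
    max_droplets: int = 5200
    droplet_diameter: float = 0.4  # mm, uniform-disc footprint
    inhomogeneity: float = 0.1
    cluster_spread: float = 1.0  # mm, scatter SD around a cluster centre
    droplets_per_cluster_scale: float = 40.0

    def __post_init__(self) -> None:
        if self.coupon_width <= 0 or self.coupon_height <= 0:
            raise ValueError("coupon dimensions must be positive")
        if self.solution_concentration <= 0:
            raise ValueError("solution_concentration must be positive")
        lo, hi = self.volume_range
        if not 0 < lo <= hi:
            raise ValueError("invalid volume_range")
        lo, hi = self.pitch_range
        if not 0 < lo <= hi:
            raise ValueError("invalid pitch_range")
        if self.max_droplets < 1:
            raise ValueError("max_droplets must be >= 1")
        if self.droplet_diameter <= 0:
            raise ValueError("droplet_diameter must be positive")
        if self.inhomogeneity < 0:
            raise ValueError("inhomogeneity must be >= 0")


@dataclass(frozen=True)
class DropletPattern:
    """Concrete droplet layout: positions (mm), volumes (nL), and limits."""

    positions: np.ndarray  # (n, 2)
    volumes: np.ndarray  # (n,)
    solution_concentration: float  # ug/nL
    pitch_range: tuple[float, float] = (0.5, 1.0)
    volume_range: tuple[float, float] = (4.0, 10.0)
    max_droplets: int = 5200
    droplet_diameter: float = 0.4

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        vol = np.asarray(self.volumes, dtype=float).reshape(-1)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "volumes", vol)
        if len(pos) != len(vol):
            raise ValueError("positions and volumes must have equal length")
        if len(pos) > self.max_droplets:
            raise ValueError("droplet count exceeds max_droplets")

    @property
    def masses(self) -> np.ndarray:
        """Per-droplet deposited mass in ug."""
        return self.volumes * self.solution_concentration

    @property
    def total_mass(self) -> float:
        return float(np.sum(self.masses))


@dataclass(frozen=True)
class CouponSurface:
    """A coupon with a deposited residue field.

    The density field is implied by the droplet pattern: each droplet's
    mass is spread uniformly over a disc of ``pattern.droplet_diameter``.
    ``mean_density`` is exact (total mass over coupon area), so mass
    conservation holds by construction.
    """

    width: float  # mm
    height: float  # mm
    pattern: DropletPattern
    target_density: float  # ug/cm^2
    inhomogeneity: float = 0.0
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("coupon dimensions must be positive")
        pos = self.pattern.positions
        if len(pos) and (
            (pos[:, 0] < 0).any()
            or (pos[:, 1] < 0).any()
            or (pos[:, 0] > self.width).any()
            or (pos[:, 1] > self.height).any()
        ):
            raise ValueError("droplet positions outside coupon bounds")

    @property
    def area_cm2(self) -> float:
        return self.width * self.height / MM2_PER_CM2

    @property
    def mean_density(self) -> float:
        """Area-averaged surface density in ug/cm^2 (exact)."""
        return self.pattern.total_mass / self.area_cm2

    def _images(self) -> tuple[np.ndarray, np.ndarray]:
        """Droplet positions plus mirror images across nearby edges.

        A droplet disc overhanging the coupon edge has the overhanging
        mass folded back inside (liquid stays on the coupon).  The
        folded mass seen by a spot equals the spot's overlap with the
        droplet's mirror image, so sampling works on the augmented set.
        This keeps mass conservation exact and the expected density
        field uniform right up to the edge.
        """
        pos = self.pattern.positions
        mass = self.pattern.masses
        r = self.pattern.droplet_diameter / 2
        all_pos = [pos]
        all_mass = [mass]
        near = {
            "left": pos[:, 0] < r,
            "right": pos[:, 0] > self.width - r,
            "bottom": pos[:, 1] < r,
            "top": pos[:, 1] > self.height - r,
        }

        def mirror(p: np.ndarray, axes: tuple[str, ...]) -> np.ndarray:
            q = p.copy()
            for ax in axes:
                if ax == "left":
                    q[:, 0] = -q[:, 0]
                elif ax == "right":
                    q[:, 0] = 2 * self.width - q[:, 0]
                elif ax == "bottom":
                    q[:, 1] = -q[:, 1]
                else:
                    q[:, 1] = 2 * self.height - q[:, 1]
            return q

        for ax in near:
            sel = near[ax]
            if sel.any():
                all_pos.append(mirror(pos[sel], (ax,)))
                all_mass.append(mass[sel])
        for ax_x in ("left", "right"):
            for ax_y in ("bottom", "top"):
                sel = near[ax_x] & near[ax_y]
                if sel.any():
                    all_pos.append(mirror(pos[sel], (ax_x, ax_y)))
                    all_mass.append(mass[sel])
        return np.vstack(all_pos), np.concatenate(all_mass)

    def _kdtree(self) -> tuple[cKDTree, np.ndarray, np.ndarray]:
        if self._tree is None:
            pos, mass = self._images()
            object.__setattr__(self, "_tree", (cKDTree(pos), pos, mass))
        return self._tree


# ---------------------------------------------------------------------------
# Coupon generation
# ---------------------------------------------------------------------------


def _feasible_droplet_count(total_mass: float, profile: DepositionProfile) -> int:
    """Droplet count whose mean volume sits mid-range, or raise if impossible."""
    conc = profile.solution_concentration
    v_lo, v_hi = profile.volume_range
    n_min = max(1, math.ceil(total_mass / (conc * v_hi)))
    n_max = math.floor(total_mass / (conc * v_lo))
    if n_min > profile.max_droplets or n_max < 1 or n_min > n_max:
        raise DepositionInfeasibleError(
            f"cannot deposit {total_mass:.4g} ug with <= {profile.max_droplets} "
            f"droplets of {v_lo}-{v_hi} nL at {conc} ug/nL"
        )
    v_mid = 0.5 * (v_lo + v_hi)
    n = int(round(total_mass / (conc * v_mid)))
    return min(max(n, n_min), min(n_max, profile.max_droplets))


def _reflect_into(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates into [lo, hi] by reflection (triangle wave)."""
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return lo + y


def generate_coupon(
    target_density: float,
    profile: DepositionProfile | None = None,
    seed: int | None = 0,
) -> CouponSurface:
    """Deposit droplets on a coupon to reach ``target_density`` ug/cm^2.

    Droplet volumes are drawn uniformly within the profile's volume
    range, then rescaled so the area-averaged density equals the target
    exactly.  Placement is a regular grid when ``profile.inhomogeneity``
    is 0 (printer emulation) and clustered otherwise (hand emulation).

    Raises
    ------
    DepositionInfeasibleError
        If the target cannot be reached within droplet count and volume
        limits, or the rescaled volumes would leave the allowed range.
    """
    profile = profile or DepositionProfile()
    if target_density < 0:
        raise ValueError("target_density must be >= 0")
    rng = np.random.default_rng(seed)
    w, h = profile.coupon_width, profile.coupon_height
    margin = profile.droplet_diameter / 2  # keep discs fully on the coupon

    if target_density == 0:
        pattern = DropletPattern(
            positions=np.empty((0, 2)),
            volumes=np.empty(0),
            solution_concentration=profile.solution_concentration,
            pitch_range=profile.pitch_range,
            volume_range=profile.volume_range,
            max_droplets=profile.max_droplets,
            droplet_diameter=profile.droplet_diameter,
        )
        return CouponSurface(w, h, pattern, 0.0, profile.inhomogeneity)

    total_mass = target_density * (w * h / MM2_PER_CM2)

    if profile.inhomogeneity == 0:
        positions, volumes = _grid_layout(total_mass, profile, margin)
    else:
        n = _feasible_droplet_count(total_mass, profile)
        volumes = rng.uniform(*profile.volume_range, size=n)
        volumes = _adjust_volumes(volumes, total_mass / profile.solution_concentration,
                                  profile.volume_range)
        # hand placement covers the full coupon; overhanging disc mass is
        # folded back across the edge at sampling time
        positions = _clustered_layout(n, profile, 0.0, rng)

    pattern = DropletPattern(
        positions=positions,
        volumes=volumes,
        solution_concentration=profile.solution_concentration,
        pitch_range=profile.pitch_range,
        volume_range=profile.volume_range,
        max_droplets=profile.max_droplets,
        droplet_diameter=profile.droplet_diameter,
    )
    surface = CouponSurface(w, h, pattern, target_density, profile.inhomogeneity)
    assert abs(surface.mean_density - target_density) <= 0.02 * target_density
    return surface


def _adjust_volumes(
    volumes: np.ndarray, target_volume: float, volume_range: tuple[float, float]
) -> np.ndarray:
    """Shift volumes by a common offset (clipping at the range edges) so
    they sum exactly to ``target_volume``."""
    v_lo, v_hi = volume_range
    n = len(volumes)
    if not n * v_lo <= target_volume <= n * v_hi:
        raise DepositionInfeasibleError(
            "target volume not reachable with volumes inside the allowed range"
        )
    vols = volumes.copy()
    for _ in range(100):
        residual = target_volume - vols.sum()
        if abs(residual) <= 1e-12 * max(target_volume, 1.0):
            return vols
        free = (vols > v_lo + 1e-15) if residual < 0 else (vols < v_hi - 1e-15)
        if not free.any():  # pragma: no cover - guarded by the range check above
            raise DepositionInfeasibleError("volume adjustment ran out of headroom")
        vols[free] = np.clip(vols[free] + residual / free.sum(), v_lo, v_hi)
    return vols


def _grid_layout(
    total_mass: float, profile: DepositionProfile, margin: float
) -> tuple[np.ndarray, np.ndarray]:
    """Regular grid at a pitch from the allowed range; equal volumes."""
    conc = profile.solution_concentration
    v_lo, v_hi = profile.volume_range
    w, h = profile.coupon_width, profile.coupon_height
    # Prefer coarse pitches (fewest droplets); take the first pitch whose
    # per-site volume is feasible.
    for pitch in np.linspace(profile.pitch_range[1], profile.pitch_range[0], 101):
        nx = int(math.floor((w - 2 * margin) / pitch)) + 1
        ny = int(math.floor((h - 2 * margin) / pitch)) + 1
        count = nx * ny
        if count > profile.max_droplets:
            break
        vol = total_mass / (count * conc)
        if v_lo <= vol <= v_hi:
            x0 = (w - (nx - 1) * pitch) / 2
            y0 = (h - (ny - 1) * pitch) / 2
            xs = x0 + pitch * np.arange(nx)
            ys = y0 + pitch * np.arange(ny)
            gx, gy = np.meshgrid(xs, ys)
            positions = np.column_stack([gx.ravel(), gy.ravel()])
            return positions, np.full(count, vol)
    raise DepositionInfeasibleError(
        "no pitch in range yields a feasible per-droplet volume for a grid"
    )


def _clustered_layout(
    n: int, profile: DepositionProfile, margin: float, rng: np.random.Generator
) -> np.ndarray:
    """Two-level placement: uniform cluster centres, Gaussian local scatter."""
    w, h = profile.coupon_width, profile.coupon_height
    per_cluster = max(1, int(round(profile.droplets_per_cluster_scale * profile.inhomogeneity)))
    n_clusters = max(1, int(round(n / per_cluster)))
    centres = np.column_stack(
        [rng.uniform(margin, w - margin, n_clusters), rng.uniform(margin, h - margin, n_clusters)]
    )
    assign = rng.integers(0, n_clusters, size=n)
    scatter = rng.normal(0.0, profile.cluster_spread, size=(n, 2))
    pos = centres[assign] + scatter
    pos[:, 0] = _reflect_into(pos[:, 0], margin, w - margin)
    pos[:, 1] = _reflect_into(pos[:, 1], margin, h - margin)
    return pos


# ---------------------------------------------------------------------------
# Spot sampling
# ---------------------------------------------------------------------------


def circle_overlap_area(d: float, r1: float, r2: float) -> float:
    """Area of intersection of two discs with centre distance ``d``."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return math.pi * r * r
    d2, r12, r22 = d * d, r1 * r1, r2 * r2
    alpha = math.acos(max(-1.0, min(1.0, (d2 + r12 - r22) / (2 * d * r1))))
    beta = math.acos(max(-1.0, min(1.0, (d2 + r22 - r12) / (2 * d * r2))))
    kite = 0.5 * math.sqrt(
        max(0.0, (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2))
    )
    return r12 * alpha + r22 * beta - kite


def sample_spot(
    surface: CouponSurface,
    center: tuple[float, float],
    spot_area: float = 1.76,
) -> float:
    """Local surface density (ug/cm^2) seen by a circular footprint.

    Deterministic: mass of all droplet-disc material inside the
    footprint divided by the footprint area.  Raises
    :class:`SpotOutOfBoundsError` when the footprint crosses the coupon
    edge.
    """
    if spot_area <= 0:
        raise ValueError("spot_area must be positive")
    r_spot = math.sqrt(spot_area / math.pi)
    cx, cy = center
    if (
        cx - r_spot < 0
        or cy - r_spot < 0
        or cx + r_spot > surface.width
        or cy + r_spot > surface.height
    ):
        raise SpotOutOfBoundsError(
            f"spot at ({cx:.2f}, {cy:.2f}) with radius {r_spot:.3f} mm crosses the coupon edge"
        )
    pattern = surface.pattern
    if len(pattern.positions) == 0:
        return 0.0
    r_drop = pattern.droplet_diameter / 2
    tree, pos, masses = surface._kdtree()
    idx = tree.query_ball_point([cx, cy], r_spot + r_drop)
    if not idx:
        return 0.0
    idx = np.asarray(idx)
    d = np.linalg.norm(pos[idx] - np.array([cx, cy]), axis=1)
    drop_area = math.pi * r_drop * r_drop
    frac = np.array([circle_overlap_area(di, r_spot, r_drop) for di in d]) / drop_area
    mass = float(np.sum(masses[idx] * frac))
    return mass / (spot_area / MM2_PER_CM2)


def sample_random_spots(
    surface: CouponSurface,
    n_spots: int,
    spot_area: float = 1.76,
    seed: int | None = 0,
) -> np.ndarray:
    """Densities at ``n_spots`` uniform random in-bounds spot centres."""
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    rng = np.random.default_rng(seed)
    r_spot = math.sqrt(spot_area / math.pi)
    xs = rng.uniform(r_spot, surface.width - r_spot, n_spots)
    ys = rng.uniform(r_spot, surface.height - r_spot, n_spots)
    return np.array([sample_spot(surface, (x, y), spot_area) for x, y in zip(xs, ys)])


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ApiSpectralSignature:
    """Gaussian-peak absorptivity model of one API.

    ``amplitudes`` are peak absorbances per unit surface density
    (AU per ug/cm^2); the clean spectrum at density d is
    ``sum_k a_k * d * exp(-(nu - c_k)^2 / (2 s_k^2))``.
    """

    centers: tuple[float, ...]
    widths: tuple[float, ...]  # Gaussian sigma, cm^-1
    amplitudes: tuple[float, ...]  # AU per (ug/cm^2)

    def __post_init__(self) -> None:
        if not (len(self.centers) == len(self.widths) == len(self.amplitudes)):
            raise ValueError("centers, widths, amplitudes must have equal length")
        if len(self.centers) == 0:
            raise ValueError("signature needs at least one peak")
        if any(w <= 0 for w in self.widths):
            raise ValueError("peak widths must be positive")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("peak amplitudes must be >= 0")

    def clean_absorbance(self, wavenumbers: np.ndarray, density: float) -> np.ndarray:
        wn = np.asarray(wavenumbers, dtype=float)
        out = np.zeros_like(wn)
        for c, s, a in zip(self.centers, self.widths, self.amplitudes):
            out += a * density * np.exp(-0.5 * ((wn - c) / s) ** 2)
        return out


def default_signature() -> ApiSpectralSignature:
    """Synthetic stand-in for a real API: one strong band near 1230 cm^-1
    (inside the default calibration window) plus two weaker bands."""
    return ApiSpectralSignature(
        centers=(1230.0, 1700.0, 2930.0),
        widths=(10.0, 15.0, 20.0),
        amplitudes=(0.05, 0.02, 0.035),
    )


@dataclass(frozen=True)
class Spectrum:
    """A wavenumber/absorbance pair.

    ``true_density`` carries the simulator's ground truth (ug/cm^2) and
    is ``None`` for spectra read from files.  ``n_scans_averaged``
    records how many scans went into the reported trace.
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    true_density: float | None = None
    n_scans_averaged: int = 1

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbance", ab)
        if wn.shape != ab.shape or wn.ndim != 1:
            raise ValueError("wavenumbers and absorbance must be equal-length 1-D arrays")
        if len(wn) > 1 and not (np.diff(wn) > 0).all():
            raise ValueError("wavenumbers must be strictly increasing")
        if self.n_scans_averaged < 1:
            raise ValueError("n_scans_averaged must be >= 1")


def _baseline(rng: np.random.Generator, instrument: InstrumentProfile) -> np.ndarray:
    """One coupon-roughness baseline realisation: offset plus mild tilt."""
    wn = instrument.wavenumbers
    mid = 0.5 * (instrument.wavenumber_min + instrument.wavenumber_max)
    half_span = 0.5 * (instrument.wavenumber_max - instrument.wavenumber_min)
    offset = rng.normal(0.0, instrument.baseline_shift_sd)
    tilt = rng.normal(0.0, instrument.baseline_shift_sd / half_span)
    return offset + tilt * (wn - mid)


def _scan_noise(rng: np.random.Generator, instrument: InstrumentProfile) -> np.ndarray:
    """Noise of the scan-averaged trace (SD = per-scan SD / sqrt(scans))."""
    return rng.normal(0.0, instrument.effective_noise_sd, size=len(instrument.wavenumbers))


def simulate_measurement(
    density: float,
    signature: ApiSpectralSignature,
    instrument: InstrumentProfile | None = None,
    seed: int | None = 0,
    *,
    rng: np.random.Generator | None = None,
    baseline: np.ndarray | None = None,
) -> Spectrum:
    """One scan-averaged FTIR measurement of a spot at the given density.

    The absorbance is the clean signature (linear in density) plus one
    baseline realisation per measurement plus scan-averaged noise.
    ``rng`` and ``baseline`` let callers share a random stream or a
    fixed baseline across replicate measurements.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    instrument = instrument or InstrumentProfile()
    if rng is None:
        rng = np.random.default_rng(seed)
    clean = signature.clean_absorbance(instrument.wavenumbers, density)
    if baseline is None:
        baseline = _baseline(rng, instrument)
    absorbance = clean + baseline + _scan_noise(rng, instrument)
    return Spectrum(
        wavenumbers=instrument.wavenumbers,
        absorbance=absorbance,
        true_density=density,
        n_scans_averaged=instrument.scans_per_spectrum,
    )


def generate_calibration_set(
    levels: Sequence[float],
    replicates: int,
    signature: ApiSpectralSignature,
    instrument: InstrumentProfile | None = None,
    seed: int | None = 0,
) -> list[Spectrum]:
    """Simulated calibration standards: ``replicates`` spectra per level.

    Returns spectra in level-major order with ``true_density`` labels.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("levels must be non-empty")
    if any(lv < 0 for lv in levels):
        raise ValueError("levels must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    instrument = instrument or InstrumentProfile()
    rng = np.random.default_rng(seed)
    return [
        simulate_measurement(lv, signature, instrument, rng=rng)
        for lv in levels
        for _ in range(replicates)
    ]


def generate_pseudo_blank_replicates(
    density: float,
    n: int,
    signature: ApiSpectralSignature,
    instrument: InstrumentProfile | None = None,
    seed: int | None = 0,
) -> list[Spectrum]:
    """Repeat measurements at a fixed point for LOQ estimation.

    The instrument and sample do not move between replicates, so all n
    spectra share one true density and one baseline realisation; only
    the scan-averaged noise differs.
    """
    if n < 2:
        raise ValueError("need at least 2 replicates")
    if density < 0:
        raise ValueError("density must be >= 0")
    instrument = instrument or InstrumentProfile()
    rng = np.random.default_rng(seed)
    shared_baseline = _baseline(rng, instrument)
    return [
        simulate_measurement(density, signature, instrument, rng=rng, baseline=shared_baseline)
        for _ in range(n)
    ]
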