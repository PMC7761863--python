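"""Synthetic spherical-head forward models and simulated evoked data.

Stand-in for an FEM forward pipeline: sensor arrays, volumetric source
spaces with Cartesian orientation triples, analytic EEG/MEG lead fields for
a spherically symmetric conductor, and simulated single-time-slice evoked
measurements.  Coordinates are head-centered Cartesian in millimeters;
dipole moments are in Am; lead-field entries are V/Am (EEG) or T/Am (MEG)
before amplitude normalization.

EEG forward model
-----------------
Potential of a current dipole q at r0 inside a homogeneous conducting sphere
of radius R (insulated outside), evaluated at a surface point r.  Summing the
interior Neumann-series solution

    V = (1/4 pi sigma) sum_{n>=1} (2n+1)/n * r0^(n-1)/R^(n+1)
        * [ n P_n(c) (q.r0_hat) + P_n'(c) (q.(r_hat - c r0_hat)) ],

with c = r_hat . r0_hat, in closed form (generating-function identities
sum f^n P_n = 1/g - 1, sum n f^n P_n = f(c-f)/g^3, sum f^n P_n' = f/g^3,
sum (f^n/n) P_n' = f(1+g)/(g(1-f c+g)), with f = r0/R and
g = sqrt(1 - 2 f c + f^2) = |r - r0|/R) gives

    V(r) = (1/(4 pi sigma R^2)) * [ (q.r0_hat) * (2(c-f)/g^3 + (2c-f)/(g(1+g)))
                                  + (q.T) * (2/g^3 + (1+g)/(g(1-f c+g))) ],

with T = r_hat - c r0_hat.  The r0 -> 0 limit is the classical central-dipole
potential 3 (q.r_hat)/(4 pi sigma R^2).  The truncated multipole series above
serves as the independent test oracle for this closed form.

MEG forward model
-----------------
The magnetic field outside a spherically symmetric conductor depends only on
the primary dipole (volume currents contribute through the geometry alone)
and has the closed form of Sarvas:

    B(r) = (mu0 / (4 pi F^2)) * (F (q x r0) - ((q x r0).r) grad F),

with a = r - r0, F = a (r a + r^2 - r0.r) and the standard grad F.  Radial
dipoles are exactly silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .constants import BRAIN_CONDUCTIVITY_S_PER_M, MU0
from .parametrization import NoiseModel

__all__ = [
    "GeometryConfig", "SensorArray", "SourceSpace", "LeadField",
    "TruthSource", "SimulatedDataset", "Scenario",
    "make_sensor_array", "build_source_space",
    "leadfield_eeg_sphere", "leadfield_meg_sphere",
    "simulate_measurement", "scenario_p20n20_like",
]

_MM = 1.0e-3  # millimeters -> meters


@dataclass(frozen=True)
class GeometryConfig:
    """Spherical-head geometry (all radii in mm, head-centered).

    The cortical shell is a band of radii [cortical_inner, cortical_outer]
    inside the conductor sphere; the deep region is a central ball.  The
    boundary margin keeps sources away from the conductor surface (the
    analytic model loses nothing there, but FEM pipelines exclude a boundary
    layer and the stand-in emulates that contract).
    """

    conductor_radius: float = 90.0
    cortical_inner: float = 70.0
    cortical_outer: float = 78.0
    deep_radius: float = 25.0
    boundary_margin: float | None = None  # default: one nominal source spacing
    eeg_sensor_radius: float | None = None  # default: conductor surface
    meg_sensor_radius: float = 110.0
    conductivity: float = BRAIN_CONDUCTIVITY_S_PER_M

    def __post_init__(self):
        if not (0 < self.cortical_inner < self.cortical_outer
                < self.conductor_radius):
            raise ValueError("need 0 < cortical_inner < cortical_outer "
                             "< conductor_radius")
        if not (0 < self.deep_radius < self.cortical_inner):
            raise ValueError("deep region must lie inside the cortical shell")

    def shell_volume_mm3(self) -> float:
        return 4.0 / 3.0 * np.pi * (self.cortical_outer**3
                                    - self.cortical_inner**3)


@dataclass(frozen=True)
class SensorArray:
    """EEG electrodes or MEG magnetometers on a spherical cap."""

    modality: Literal["EEG", "MEG"]
    positions: np.ndarray        # (m, 3) mm
    orientations: np.ndarray | None = None  # (m, 3) unit, MEG only
    names: tuple[str, ...] | None = None

    @property
    def count(self) -> int:
        return len(self.positions)

    def __post_init__(self):
        if self.modality == "MEG":
            if self.orientations is None:
                raise ValueError("MEG array requires magnetometer orientations")
            norms = np.linalg.norm(self.orientations, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("MEG orientations must be unit vectors")


@dataclass
class SourceSpace:
    """N dipole positions, each carrying a Cartesian orientation triple.

    Cortical positions have outward (radial) unit normals; deep positions
    have no preferred orientation but carry the radial direction for
    bookkeeping.  ``region`` holds per-position labels 'cortical'/'deep'.
    """

    positions: np.ndarray  # (N, 3) mm
    normals: np.ndarray    # (N, 3) unit
    region: np.ndarray     # (N,) str
    density: Literal["dense", "sparse"]
    geometry: GeometryConfig
    _area_cache: np.ndarray | None = field(default=None, repr=False,
                                           compare=False)

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def cortical_mask(self) -> np.ndarray:
        return self.region == "cortical"

    @property
    def nominal_spacing_mm(self) -> float:
        """Uniform-density spacing estimate (V_shell / N_cortical)^(1/3)."""
        n_cort = int(self.cortical_mask.sum())
        return (self.geometry.shell_volume_mm3() / max(n_cort, 1)) ** (1.0 / 3.0)

    def subsample(self, factor: int, rng: np.random.Generator) -> "SourceSpace":
        """Sparse space: floor(N/factor) positions drawn from this space."""
        n_sub = self.n_positions // factor
        if n_sub < 1:
            raise ValueError("subsampling factor too large for this space")
        # keep at least one deep position if any exist
        idx = np.sort(rng.choice(self.n_positions, size=n_sub, replace=False))
        if np.any(self.region == "deep") and not np.any(self.region[idx] == "deep"):
            deep_idx = rng.choice(np.flatnonzero(self.region == "deep"))
            idx[-1] = deep_idx
            idx = np.sort(idx)
        return SourceSpace(self.positions[idx], self.normals[idx],
                           self.region[idx], "sparse", self.geometry)


@dataclass(frozen=True)
class LeadField:
    """Sensor x (3N) gain matrix bound to a source space and sensor array.

    Column block i (3 columns) is position i's Cartesian triple.  EEG rows
    are average-referenced.  ``amplitude_norm`` is the amplitude A the matrix
    has been divided by (1.0 = raw SI units).
    """

    matrix: np.ndarray
    source_space: SourceSpace
    sensor_array: SensorArray
    amplitude_norm: float = 1.0

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[0]

    def normalized(self, amplitude: float) -> "LeadField":
        """Lead field consistent with data divided by ``amplitude``."""
        return replace(self, matrix=self.matrix / amplitude,
                       amplitude_norm=self.amplitude_norm * amplitude)


def _fibonacci_cap(count: int, radius: float, coverage: float) -> np.ndarray:
    """Deterministic Fibonacci-spiral points on a spherical cap.

    ``coverage`` is the covered fraction of the full sphere area, measured
    from the vertex (north pole).
    """
    i = np.arange(count, dtype=float)
    z = 1.0 - 2.0 * coverage * (i + 0.5) / count
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def make_sensor_array(modality: str, count: int = 128,
                      radius: float | None = None,
                      geometry: GeometryConfig = GeometryConfig(),
                      coverage: float = 0.65) -> SensorArray:
    """Sensor cap covering the upper part of the head sphere.

    EEG electrodes sit on the conductor surface; MEG magnetometers sit on a
    larger helmet sphere with radially oriented pickup axes.
    """
    modality = modality.upper()
    if modality == "EEG":
        r = radius if radius is not None else (
            geometry.eeg_sensor_radius or geometry.conductor_radius)
        if r < geometry.conductor_radius:
            raise ValueError("EEG electrodes must sit on the conductor surface")
        pos = _fibonacci_cap(count, r, coverage)
        return SensorArray("EEG", pos, None)
    if modality == "MEG":
        r = radius if radius is not None else geometry.meg_sensor_radius
        if r <= geometry.conductor_radius:
            raise ValueError("MEG sensors must lie outside the conductor")
        pos = _fibonacci_cap(count, r, coverage)
        ori = pos / np.linalg.norm(pos, axis=1, keepdims=True)
        return SensorArray("MEG", pos, ori)
    raise ValueError(f"unknown modality {modality!r}")


def _uniform_shell(rng: np.random.Generator, n: int, r_in: float,
                   r_out: float) -> np.ndarray:
    u = rng.uniform(size=n)
    r = (u * (r_out**3 - r_in**3) + r_in**3) ** (1.0 / 3.0)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return r[:, None] * v


def build_source_space(geometry: GeometryConfig = GeometryConfig(),
                       density: str = "dense", n_dense: int = 4000,
                       deep_fraction: float = 0.1,
                       sparse_factor: int = 100,
                       seed: int | np.random.Generator = 0) -> SourceSpace:
    """Uniform random source positions in the cortical shell and deep ball.

    ``n_dense`` positions are split between the cortical shell (radial
    outward normals) and the central deep region.  The sparse density
    subsamples the dense space 1:``sparse_factor`` with the same seed, so the
    sparse positions are a strict subset of the dense ones.  A boundary
    margin (default: one nominal source spacing) keeps cortical sources away
    from the conductor surface.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if not 0.0 <= deep_fraction < 1.0:
        raise ValueError("deep_fraction must be in [0, 1)")
    n_deep = int(round(n_dense * deep_fraction))
    n_cort = n_dense - n_deep
    if n_cort < 1:
        raise ValueError("infeasible geometry/config: no cortical sources")

    margin = geometry.boundary_margin
    if margin is None:
        # one nominal source spacing, but never more than the gap the
        # configured band already leaves to the conductor surface
        margin = min((geometry.shell_volume_mm3() / n_cort) ** (1.0 / 3.0),
                     geometry.conductor_radius - geometry.cortical_outer)
    outer = min(geometry.cortical_outer, geometry.conductor_radius - margin)
    if outer <= geometry.cortical_inner:
        raise ValueError("boundary margin leaves an empty cortical shell")

    pos_c = _uniform_shell(rng, n_cort, geometry.cortical_inner, outer)
    normals_c = pos_c / np.linalg.norm(pos_c, axis=1, keepdims=True)
    if n_deep:
        pos_d = _uniform_shell(rng, n_deep, 0.0, geometry.deep_radius)
        normals_d = pos_d / np.maximum(
            np.linalg.norm(pos_d, axis=1, keepdims=True), 1e-12)
        positions = np.vstack([pos_c, pos_d])
        normals = np.vstack([normals_c, normals_d])
        region = np.array(["cortical"] * n_cort + ["deep"] * n_deep)
    else:
        positions, normals = pos_c, normals_c
        region = np.array(["cortical"] * n_cort)

    space = SourceSpace(positions, normals, region, "dense", geometry)
    if density == "dense":
        return space
    if density == "sparse":
        return space.subsample(sparse_factor, rng)
    raise ValueError(f"unknown density {density!r}")


def _eeg_potential(sensors_m: np.ndarray, pos_m: np.ndarray,
                   conductor_radius_m: float, conductivity: float) -> np.ndarray:
    """Closed-form surface potential blocks: (m, N, 3) array, V per Am."""
    R = conductor_radius_m
    r_hat = sensors_m / np.linalg.norm(sensors_m, axis=1, keepdims=True)
    r0 = np.linalg.norm(pos_m, axis=1)                      # (N,)
    out = np.empty((len(sensors_m), len(pos_m), 3))

    central = r0 < 1e-9 * R
    if np.any(central):
        # limiting central-dipole potential 3 (q.r_hat) / (4 pi sigma R^2)
        out[:, central, :] = (3.0 / (4.0 * np.pi * conductivity * R**2)
                              ) * r_hat[:, None, :]
    if np.any(~central):
        p = pos_m[~central]
        f = (r0[~central] / R)[None, :]                     # (1, n)
        r0_hat = p / np.linalg.norm(p, axis=1, keepdims=True)
        c = r_hat @ r0_hat.T                                # (m, n)
        g = np.sqrt(np.maximum(1.0 - 2.0 * f * c + f * f, 1e-30))
        coef_a = 2.0 * (c - f) / g**3 + (2.0 * c - f) / (g * (1.0 + g))
        coef_b = 2.0 / g**3 + (1.0 + g) / (g * (1.0 - f * c + g))
        # T = r_hat - c r0_hat, per sensor/source pair
        T = r_hat[:, None, :] - c[:, :, None] * r0_hat[None, :, :]
        block = (coef_a[:, :, None] * r0_hat[None, :, :]
                 + coef_b[:, :, None] * T)
        out[:, ~central, :] = block / (4.0 * np.pi * conductivity * R**2)
    return out


def leadfield_eeg_sphere(sensor_array: SensorArray,
                         source_space: SourceSpace) -> LeadField:
    """Average-referenced EEG lead field for the homogeneous sphere [V/Am]."""
    if sensor_array.modality != "EEG":
        raise ValueError("EEG lead field requires an EEG sensor array")
    geo = source_space.geometry
    radii = np.linalg.norm(source_space.positions, axis=1)
    if np.any(radii >= geo.conductor_radius):
        raise ValueError("source positions must lie inside the conductor")
    blocks = _eeg_potential(sensor_array.positions * _MM,
                            source_space.positions * _MM,
                            geo.conductor_radius * _MM, geo.conductivity)
    matrix = blocks.reshape(sensor_array.count, -1)
    matrix = matrix - matrix.mean(axis=0, keepdims=True)  # average reference
    return LeadField(matrix, source_space, sensor_array)


def _sarvas_field(sensors_m: np.ndarray, pos_m: np.ndarray) -> np.ndarray:
    """Sarvas dipole field blocks: (m, N, 3, 3) array, B_k per unit q_j."""
    m, n = len(sensors_m), len(pos_m)
    r = sensors_m[:, None, :]                      # (m, 1, 3)
    r0 = pos_m[None, :, :]                         # (1, n, 3)
    a_vec = r - r0                                 # (m, n, 3)
    a = np.linalg.norm(a_vec, axis=2)              # (m, n)
    rn = np.linalg.norm(sensors_m, axis=1)[:, None]  # (m, 1)
    ar = np.einsum("mnk,mk->mn", a_vec, sensors_m)   # a . r
    r0r = np.einsum("nk,mk->mn", pos_m, sensors_m)   # r0 . r
    F = a * (rn * a + rn**2 - r0r)                   # (m, n)
    gF = ((a**2 / rn + ar / a + 2.0 * a + 2.0 * rn)[:, :, None] * r
          - (a + 2.0 * rn + ar / a)[:, :, None] * r0)  # (m, n, 3)
    # q x r0 for unit q along axis j: cross(e_j, r0) -> (n, 3, 3)
    eye = np.eye(3)
    qxr0 = np.cross(eye[None, :, :], pos_m[:, None, :])  # (n, 3, 3)
    term1 = F[:, :, None, None] * qxr0[None, :, :, :]
    qxr0_dot_r = np.einsum("njk,mk->mnj", qxr0, sensors_m)  # (m, n, 3)
    term2 = qxr0_dot_r[:, :, :, None] * gF[:, :, None, :]
    return MU0 / (4.0 * np.pi * F[:, :, None, None]**2) * (term1 - term2)


def leadfield_meg_sphere(sensor_array: SensorArray,
                         source_space: SourceSpace) -> LeadField:
    """MEG magnetometer lead field (Sarvas) for a spherical conductor [T/Am].

    Radial dipoles are exactly silent (spherical symmetry), so this forward
    model is only sensitive to tangential moment components.
    """
    if sensor_array.modality != "MEG":
        raise ValueError("MEG lead field requires an MEG sensor array")
    geo = source_space.geometry
    if np.any(np.linalg.norm(sensor_array.positions, axis=1)
              <= geo.conductor_radius):
        raise ValueError("MEG sensors must lie outside the conductor")
    blocks = _sarvas_field(sensor_array.positions * _MM,
                           source_space.positions * _MM)  # (m, N, 3q, 3B)
    projected = np.einsum("mnjk,mk->mnj", blocks, sensor_array.orientations)
    matrix = projected.reshape(sensor_array.count, -1)
    return LeadField(matrix, source_space, sensor_array)


@dataclass(frozen=True)
class TruthSource:
    """A ground-truth dipole (position mm, unit orientation, moment Am)."""

    position: np.ndarray
    orientation: np.ndarray
    moment: float = 1.0e-8  # typical 10 nAm cortical dipole

    def __post_init__(self):
        ori = np.asarray(self.orientation, dtype=float)
        n = np.linalg.norm(ori)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("orientation must be a unit vector")


@dataclass(frozen=True)
class SimulatedDataset:
    """One amplitude-normalized time slice of simulated evoked data.

    ``sigma`` is the per-channel noise std actually applied on the normalized
    data; ``amplitude`` is the l2-norm A [V or T] the clean signal was
    divided by; ``truth`` holds the snapped ground-truth dipoles and
    ``truth_offsets_mm`` the snapping distances.
    """

    y_clean: np.ndarray
    y_noisy: np.ndarray
    sigma: float
    epochs: int
    amplitude: float
    truth: tuple[TruthSource, ...]
    truth_indices: tuple[int, ...]
    truth_offsets_mm: tuple[float, ...]
    x_truth: np.ndarray
    noise_convention: str
    seed: int | None = None

    @property
    def metadata(self) -> dict:
        return {
            "sigma": self.sigma, "epochs": self.epochs,
            "amplitude": self.amplitude,
            "noise_convention": self.noise_convention,
            "data_snr_db": float(10.0 * np.log10(
                1.0 / (len(self.y_clean) * self.sigma**2))),
            "seed": self.seed,
        }


def simulate_measurement(leadfield: LeadField,
                         truth: Sequence[TruthSource],
                         noise: NoiseModel = NoiseModel(),
                         rng: int | np.random.Generator = 0,
                         noise_convention: str = "l2") -> SimulatedDataset:
    """Simulate y = L x + n for ground-truth dipoles, amplitude-normalized.

    Truth positions are snapped to the nearest source-space position (the
    offset is recorded).  The clean signal is divided by its l2-norm A; noise
    is i.i.d. zero-mean Gaussian with per-channel std equal to the effective
    relative noise level of ``noise`` — relative to the l2-normalized data by
    default (``noise_convention="l2"``) or to the maximal normalized signal
    amplitude (``"max"``).
    """
    if not truth:
        raise ValueError("truth must contain at least one source")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = (rng if isinstance(rng, np.random.Generator)
           else np.random.default_rng(rng))
    space = leadfield.source_space
    x = np.zeros(3 * space.n_positions)
    snapped, indices, offsets = [], [], []
    for src in truth:
        d = np.linalg.norm(space.positions - np.asarray(src.position), axis=1)
        i = int(np.argmin(d))
        indices.append(i)
        offsets.append(float(d[i]))
        snapped.append(TruthSource(space.positions[i].copy(),
                                   np.asarray(src.orientation, float),
                                   src.moment))
        x[3 * i:3 * i + 3] += src.moment * np.asarray(src.orientation, float)

    y_raw = leadfield.matrix @ x
    amplitude = float(np.linalg.norm(y_raw)) * leadfield.amplitude_norm
    if amplitude == 0.0:
        raise ValueError("truth sources produce zero signal (silent sources?)")
    y_clean = y_raw / np.linalg.norm(y_raw)
    sigma_rel = noise.sigma_effective
    if noise_convention == "l2":
        sigma = sigma_rel
    elif noise_convention == "max":
        sigma = sigma_rel * float(np.max(np.abs(y_clean)))
    else:
        raise ValueError(f"unknown noise convention {noise_convention!r}")
    y_noisy = y_clean + rng.normal(0.0, sigma, size=y_clean.shape)
    return SimulatedDataset(y_clean, y_noisy, float(sigma), noise.epochs,
                            amplitude, tuple(snapped), tuple(indices),
                            tuple(offsets), x, noise_convention, seed)


@dataclass(frozen=True)
class Scenario:
    """Canonical synthetic fixture: lead field, dataset and ROI descriptors."""

    geometry: GeometryConfig
    sensor_array: SensorArray
    source_space: SourceSpace
    leadfield: LeadField
    dataset: SimulatedDataset
    roi_center_mm: np.ndarray
    roi_diameter_mm: float
    truth: tuple[TruthSource, ...]

    def normalized_leadfield(self) -> LeadField:
        """Lead field consistent with the amplitude-normalized data."""
        return self.leadfield.normalized(self.dataset.amplitude)


def scenario_p20n20_like(modality: str = "EEG", density: str = "dense",
                         n_dense: int = 4000, n_sensors: int = 128,
                         include_deep: bool = False,
                         noise: NoiseModel = NoiseModel(),
                         geometry: GeometryConfig = GeometryConfig(),
                         seed: int = 0,
                         superficial_moment: float = 1.0e-8,
                         deep_moment: float = 1.0e-8) -> Scenario:
    """Evoked-response-like scenario: one superficial cortical dipole.

    Emulates the canonical median-nerve P20/N20 setting: a single
    normally-oriented (radial, for the spherical cortex stand-in) superficial
    dipole of 10 nAm, 3% relative Gaussian noise, and a 24 mm-diameter
    spherical ROI centered near the truth.  ``include_deep`` adds a second,
    thalamus-like central source.  For MEG the superficial source is oriented
    tangentially instead, since radial sources are silent in a spherical
    conductor (a sulcal-wall source is tangential to the head surface).
    """
    modality = modality.upper()
    space = build_source_space(geometry, density, n_dense, seed=seed)
    sensors = make_sensor_array(modality, n_sensors, geometry=geometry)
    if modality == "EEG":
        lf = leadfield_eeg_sphere(sensors, space)
    else:
        lf = leadfield_meg_sphere(sensors, space)

    # superficial target: cortical position nearest a fixed off-axis direction
    target_dir = np.array([-0.45, -0.33, 0.83])
    target_dir /= np.linalg.norm(target_dir)
    target = target_dir * 0.5 * (geometry.cortical_inner
                                 + geometry.cortical_outer)
    cort_idx = np.flatnonzero(space.cortical_mask)
    i = cort_idx[np.argmin(np.linalg.norm(
        space.positions[cort_idx] - target, axis=1))]
    pos = space.positions[i]
    radial = pos / np.linalg.norm(pos)
    if modality == "EEG":
        orientation = radial  # normal-constrained (radial) source
    else:
        t = np.cross(radial, [0.0, 0.0, 1.0])
        orientation = t / np.linalg.norm(t)  # tangential, MEG-visible
    truth = [TruthSource(pos.copy(), orientation, superficial_moment)]

    if include_deep:
        deep_target = np.array([-8.0, -12.0, 4.0])
        d = np.linalg.norm(space.positions - deep_target, axis=1)
        d[space.cortical_mask] = np.inf
        j = int(np.argmin(d))
        deep_ori = np.array([0.0, 1.0, 0.0])
        truth.append(TruthSource(space.positions[j].copy(), deep_ori,
                                 deep_moment))

    dataset = simulate_measurement(lf, truth, noise, rng=seed)
    return Scenario(geometry, sensors, space, lf, dataset,
                    roi_center_mm=dataset.truth[0].position.copy(),
                    roi_diameter_mm=24.0, truth=dataset.truth)
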