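"""Synthetic EEG source-coherence scenes with known ground truth.

Generates every input the analysis pipeline needs — a sphere-like
cortical mesh, an analytic homogeneous-medium lead field, patch source
time series with 1/f background noise, a planted band-coupled source
pair, and interictal-spike transients at known times — so the full
pipeline can be exercised and validated without clinical data.

The forward model is the infinite-homogeneous-medium dipole potential

    V(r) = (1 / 4 pi sigma) * p . (r - r0) / |r - r0|^3,

a deliberate simplification of realistic head conduction: it exercises
the inverse and coherence mathematics but carries no skull/scalp
physics. Coupling strength c for a planted pair is defined as the
asymptotic in-band coherence of the two patch waveforms (before
background noise): each focus receives sqrt(c) of a shared band-limited
component plus sqrt(1-c) of an independent one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .events import SensorRecording
from .geometry import (CorticalMesh, LaplacianOperator, PatchTessellation,
                       build_laplacian, tessellate_patches)
from .inverse import LeadField, forward_project
from .spectral import BANDS, ParcelMap

logger = logging.getLogger("corticoh.synthdata")

__all__ = [
    "SimulationConfig",
    "SimulationBundle",
    "make_sphere_mesh",
    "make_gyrified_mesh",
    "fibonacci_sensors",
    "make_leadfield",
    "simulate_sources",
    "simulate_recording",
    "parcels_from_tessellation",
]


@dataclass
class SimulationConfig:
    """Parameters of a synthetic spike-coherence scene.

    Defaults describe the reference desk-scale scene: 64 sensors, ~200
    cortical patches on a sphere of human-head cortical radius, 20 spikes,
    and one pair of antipodal sources coupled at 0.9 in the alpha band.
    The surface is a "gyrified" sphere: an icosphere with radial bumps
    that diversify patch dipole orientations the way cortical folding
    does. A perfectly smooth sphere with purely radial dipoles is a
    degenerate geometry — its lead-field columns are maximally
    correlated — and makes the inverse problem look artificially bad.
    Parcels group ~10 patches each (the clinical analysis groups ~30
    patches per Brodmann area; the ratio here is scaled to the smaller
    patch count), which roughly matches the spatial extent of the
    inverse operator's point spread.

    Background activity is 1/f Gaussian noise of unit amplitude per
    patch. The planted rhythm (amplitude 2.0) carries 4x the background's
    total power, concentrated in its band — a strong spike-locked
    oscillation. Spikes are 8x background (interictal spikes dominate
    the trace).
    """

    n_sensors: int = 64
    subdivisions: int = 3          # icosphere level: 20 * 4^s triangles
    radius_cm: float = 8.0
    n_bumps: int = 24              # gyrification-like bumps; 0 = smooth sphere
    bump_amplitude: float = 0.12   # radial displacement, fraction of radius
    bump_width_rad: float = 0.35   # angular bump width (radians)
    n_patches: int = 200
    n_parcels: int = 20
    fs: float = 250.0
    n_spikes: int = 20
    spike_amplitude: float = 8.0   # dipole-moment units, >> background
    spike_width_ms: float = 70.0   # typical interictal spike duration
    noise_exponent: float = 1.0    # background power ~ 1/f^exponent
    background_sd: float = 1.0
    planted_amplitude: float = 2.0
    planted_pairs: list[tuple] = field(default_factory=lambda: [
        (None, None, "alpha", 0.9),
    ])
    spike_spacing_s: float = 3.2   # >= 3 s so spike windows never overlap
    noise_sd: float = 0.5          # sensor noise, microvolts
    sigma_s_per_m: float = 0.33    # medium conductivity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 2 * 70:
            raise ValueError("fs must be at least 140 Hz to resolve 70 Hz")
        for pair in self.planted_pairs:
            if not 0.0 <= pair[3] <= 1.0:
                raise ValueError("coupling strength must lie in [0, 1]")
            if pair[2] not in BANDS:
                raise ValueError(f"unknown band {pair[2]!r}")


@dataclass
class SimulationBundle:
    """Everything a simulation produced, plus its ground truth."""

    config: SimulationConfig
    mesh: CorticalMesh
    tessellation: PatchTessellation
    laplacian: LaplacianOperator
    leadfield: LeadField
    parcel_map: ParcelMap
    recording: SensorRecording
    J_true: np.ndarray
    truth: dict


def make_sphere_mesh(subdivisions: int, radius_cm: float = 8.0) -> CorticalMesh:
    """Icosphere stand-in for a cortical surface (20 * 4^s triangles).

    Winding is outward-consistent; hemisphere labels split the sphere at
    the x = 0 plane (x < 0 is "left").
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions,
                                     radius=radius_cm * 10.0)  # mm
    hemi = np.where(ico.vertices[:, 0] < 0, "left", "right")
    return CorticalMesh(vertices=np.asarray(ico.vertices),
                        triangles=np.asarray(ico.faces),
                        hemisphere=hemi)


def make_gyrified_mesh(subdivisions: int, radius_cm: float = 8.0,
                       n_bumps: int = 24, amplitude: float = 0.12,
                       width_rad: float = 0.35, seed: int = 0) -> CorticalMesh:
    """Sphere-like mesh with gyrification-style radial bumps.

    Randomly placed Gaussian bumps (fixed by ``seed``) displace each
    vertex radially by up to ~``amplitude`` of the radius, which spreads
    the patch dipole orientations away from the purely radial degenerate
    case and decorrelates the lead-field columns, as cortical folding
    does in real anatomy. Topology and triangle counts match the plain
    icosphere; ``n_bumps=0`` reduces to it exactly.
    """
    mesh = make_sphere_mesh(subdivisions, radius_cm)
    if n_bumps == 0:
        return mesh
    v = mesh.vertices / (radius_cm * 10.0)      # unit directions
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_bumps, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    signs = rng.choice([-1.0, 1.0], n_bumps)
    ang = np.arccos(np.clip(v @ dirs.T, -1.0, 1.0))
    disp = (signs * np.exp(-((ang / width_rad) ** 2))).sum(axis=1)
    r = 1.0 + amplitude * disp
    verts = v * r[:, None] * radius_cm * 10.0
    hemi = np.where(verts[:, 0] < 0, "left", "right")
    return CorticalMesh(vertices=verts, triangles=mesh.triangles,
                        hemisphere=hemi)


def fibonacci_sensors(n_sensors: int, radius_mm: float) -> np.ndarray:
    """Quasi-uniform sensor positions on a sphere (Fibonacci lattice)."""
    i = np.arange(n_sensors, dtype=float)
    golden = (1 + 5 ** 0.5) / 2
    z = 1 - (2 * i + 1) / n_sensors
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pts * radius_mm


def make_leadfield(tess: PatchTessellation, sensor_pos_mm: np.ndarray,
                   sigma_s_per_m: float = 0.33) -> LeadField:
    """Analytic lead field: homogeneous-medium dipole potentials.

    Each patch contributes one column: the potential of a unit dipole at
    the patch centroid with the patch orientation, evaluated at every
    sensor, then average-referenced per column. Sensors must lie strictly
    outside the source positions.
    """
    pos = np.asarray(sensor_pos_mm, dtype=float)
    r0 = tess.centroid                                     # (p, 3)
    p = tess.orientation                                   # (p, 3)
    d = pos[:, None, :] - r0[None, :, :]                   # (s, p, 3)
    dist = np.linalg.norm(d, axis=-1)
    if np.any(dist < 1e-6):
        raise ValueError("a sensor coincides with a source position")
    K = np.einsum("spk,pk->sp", d, p) / dist ** 3
    K = K / (4 * np.pi * sigma_s_per_m)
    K = K - K.mean(axis=0, keepdims=True)                  # average reference
    names = [f"E{i + 1}" for i in range(len(pos))]
    return LeadField(K=K, sensor_names=names,
                     patch_ids=np.arange(tess.n_patches))


def _one_over_f_noise(rng: np.random.Generator, n_series: int, n_samples: int,
                      fs: float, exponent: float, sd: float) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^exponent, unit-free sd."""
    white = rng.standard_normal((n_series, n_samples))
    F = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, d=1 / fs)
    shape = np.ones_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    shape[0] = 0.0                                         # no DC drift
    x = np.fft.irfft(F * shape, n=n_samples, axis=-1)
    s = x.std(axis=-1, keepdims=True)
    s[s == 0] = 1.0
    return x / s * sd


def _band_limited(rng: np.random.Generator, n_samples: int, fs: float,
                  band: tuple[float, float], n_series: int = 1) -> np.ndarray:
    """Unit-variance Gaussian signals confined to a frequency band."""
    f = np.fft.rfftfreq(n_samples, d=1 / fs)
    sel = (f >= band[0]) & (f <= band[1])
    if not np.any(sel):
        raise ValueError(f"band {band} has no frequency support at this length")
    F = np.zeros((n_series, f.size), dtype=complex)
    F[:, sel] = rng.standard_normal((n_series, sel.sum())) \
        + 1j * rng.standard_normal((n_series, sel.sum()))
    x = np.fft.irfft(F, n=n_samples, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _spike_kernel(fs: float, width_ms: float, amplitude: float) -> np.ndarray:
    """Biphasic (derivative-of-Gaussian) transient, peak = ``amplitude``.

    ``width_ms`` is the approximate total duration (+-3 sigma of the
    underlying Gaussian).
    """
    sigma = width_ms / 1000.0 / 6.0
    t = np.arange(-3 * sigma, 3 * sigma + 1 / fs, 1 / fs)
    k = -t * np.exp(-t ** 2 / (2 * sigma ** 2))
    return k / np.abs(k).max() * amplitude


def _respace_spike_times(times: np.ndarray, min_gap: float = 3.0) -> np.ndarray:
    out = np.array(times, dtype=float)
    changed = False
    for i in range(1, len(out)):
        if out[i] - out[i - 1] < min_gap:
            out[i] = out[i - 1] + min_gap
            changed = True
    if changed:
        logger.warning("spike times closer than %.1f s were re-spaced", min_gap)
    return out


def simulate_sources(config: SimulationConfig, tess: PatchTessellation,
                     rng: np.random.Generator | None = None
                     ) -> tuple[np.ndarray, dict]:
    """Patch source waveforms with background, planted pairs, and spikes.

    Returns ``(J, truth)``: J is (n_patches, n_samples); truth records
    spike times (s), the spike focus patch, and every planted pair with
    its band and coupling.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_p = tess.n_patches
    margin = config.spike_spacing_s / 2.0
    times = margin + config.spike_spacing_s * np.arange(config.n_spikes)
    times = _respace_spike_times(times)
    duration = times[-1] + margin + 1.6 if len(times) else 10.0
    n_samples = int(round(duration * config.fs))

    J = _one_over_f_noise(rng, n_p, n_samples, config.fs,
                          config.noise_exponent, config.background_sd)

    # planted coherent pairs: sqrt(c) shared + sqrt(1-c) independent,
    # both band-limited, scaled by planted_amplitude
    pairs_truth = []
    x_axis = tess.centroid[:, 0]
    for (a, b, band_name, c) in config.planted_pairs:
        if a is None or b is None:
            right = np.flatnonzero(tess.hemisphere == "right")
            left = np.flatnonzero(tess.hemisphere == "left")
            a = int(right[np.argmax(x_axis[right])]) if a is None else int(a)
            b = int(left[np.argmin(x_axis[left])]) if b is None else int(b)
        band = BANDS[band_name]
        shared = _band_limited(rng, n_samples, config.fs, band)[0]
        indep = _band_limited(rng, n_samples, config.fs, band, 2)
        amp = config.planted_amplitude
        J[a] += amp * (np.sqrt(c) * shared + np.sqrt(1 - c) * indep[0])
        J[b] += amp * (np.sqrt(c) * shared + np.sqrt(1 - c) * indep[1])
        pairs_truth.append({"patch_a": int(a), "patch_b": int(b),
                            "band": band_name, "coupling": float(c),
                            "amplitude": float(amp)})

    # spike transients on the patch nearest the +z pole (away from the
    # default planted pair at the +-x poles)
    focus = int(np.argmax(tess.centroid[:, 2]))
    kernel = _spike_kernel(config.fs, config.spike_width_ms,
                           config.spike_amplitude)
    peak_off = int(np.argmax(np.abs(kernel)))
    for t in times:
        start = int(round(t * config.fs)) - peak_off
        stop = start + len(kernel)
        if start < 0 or stop > n_samples:
            continue
        J[focus, start:stop] += kernel

    truth = {
        "spike_times_s": [float(t) for t in times],
        "spike_focus_patch": focus,
        "spike_amplitude": float(config.spike_amplitude),
        "spike_width_ms": float(config.spike_width_ms),
        "planted_pairs": pairs_truth,
        "background_sd": float(config.background_sd),
        "noise_exponent": float(config.noise_exponent),
        "fs": float(config.fs),
        "n_patches": int(n_p),
        "seed": int(config.seed),
    }
    return J, truth


def parcels_from_tessellation(tess: PatchTessellation, mesh: CorticalMesh,
                              n_parcels: int, seed: int = 0) -> ParcelMap:
    """Group fine patches into parcels via a coarse tessellation.

    Emulates grouping dipole patches by anatomical region: a second,
    coarser tessellation of the same mesh defines the parcels, and each
    fine patch joins the coarse patch owning the plurality of its area.
    Labels look like ``P07_R``.
    """
    total = mesh.total_area_cm2()
    coarse = tessellate_patches(mesh, total / n_parcels, seed=seed + 1)
    areas = mesh.triangle_areas_cm2()
    assign = np.empty(tess.n_patches, dtype=object)
    labels = {
        p: f"P{p:02d}_{'R' if coarse.hemisphere[p] == 'right' else 'L'}"
        for p in range(coarse.n_patches)
    }
    for p in range(tess.n_patches):
        tris = tess.triangles_of(p)
        owners = coarse.patch_of_triangle[tris]
        best = max(set(owners), key=lambda o: areas[tris[owners == o]].sum())
        assign[p] = labels[int(best)]
    hemi = {labels[p]: str(coarse.hemisphere[p])
            for p in range(coarse.n_patches)}
    used = set(assign.astype(str))
    hemi = {k: v for k, v in hemi.items() if k in used}
    return ParcelMap(parcel_of_patch=assign, hemisphere_of_parcel=hemi)


def simulate_recording(config: SimulationConfig) -> SimulationBundle:
    """Compose mesh -> tessellation -> lead field -> sources -> sensors.

    The lead field is rescaled so its median column norm is 1, which
    fixes the amplitude units: one dipole-moment unit produces on the
    order of 1 microvolt at the sensors. Identical configs (including the
    seed) produce identical bundles.
    """
    rng = np.random.default_rng(config.seed)
    mesh = make_gyrified_mesh(config.subdivisions, config.radius_cm,
                              config.n_bumps, config.bump_amplitude,
                              config.bump_width_rad, seed=config.seed)
    total = mesh.total_area_cm2()
    tess = tessellate_patches(mesh, total / config.n_patches, seed=config.seed)
    lap = build_laplacian(tess.neighbors)
    r_max = np.linalg.norm(mesh.vertices, axis=1).max()
    sensors = fibonacci_sensors(config.n_sensors, 1.15 * r_max)
    lf = make_leadfield(tess, sensors, config.sigma_s_per_m)
    scale = np.median(np.linalg.norm(lf.K, axis=0))
    lf = LeadField(K=lf.K / scale, sensor_names=lf.sensor_names,
                   patch_ids=lf.patch_ids)
    parcel_map = parcels_from_tessellation(tess, mesh, config.n_parcels,
                                           seed=config.seed)
    J, truth = simulate_sources(config, tess, rng)
    Phi = forward_project(lf, J, noise_sd=config.noise_sd, rng=rng)
    rec = SensorRecording(data=Phi, fs=config.fs,
                          spike_times=np.asarray(truth["spike_times_s"]),
                          channel_names=lf.sensor_names)
    truth["leadfield_scale"] = float(scale)
    truth["parcel_of_patch"] = [str(x) for x in parcel_map.parcel_of_patch]
    pairs = truth["planted_pairs"]
    for pr in pairs:
        pr["parcel_a"] = str(parcel_map.parcel_of_patch[pr["patch_a"]])
        pr["parcel_b"] = str(parcel_map.parcel_of_patch[pr["patch_b"]])
    truth["spike_focus_parcel"] = str(
        parcel_map.parcel_of_patch[truth["spike_focus_patch"]])
    return SimulationBundle(config=config, mesh=mesh, tessellation=tess,
                            laplacian=lap, leadfield=lf,
                            parcel_map=parcel_map, recording=rec,
                            J_true=J, truth=truth)
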