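"""File formats: EDF recordings, meshes, lead fields, tables, results.

TSV is used wherever a human might read the file; HDF5 for dense
tensors. EDF is written by a compact built-in writer (16-bit, 1-s data
records) and read back through MNE; round-trip error is bounded by one
quantization step of the 16-bit encoding.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import trimesh

from .events import SensorRecording
from .geometry import CorticalMesh, LaplacianOperator, PatchTessellation
from .inverse import LeadField
from .spectral import CoherenceResult, ParcelMap

logger = logging.getLogger("corticoh.io")

__all__ = [
    "write_edf", "read_edf",
    "write_mesh", "read_mesh",
    "write_leadfield", "read_leadfield",
    "write_events", "read_events",
    "write_parcels", "read_parcels",
    "write_tessellation", "write_laplacian", "read_laplacian",
    "write_coherence", "write_edges",
]


# ---------------------------------------------------------------- EDF

def _fix(s, n: int) -> bytes:
    b = str(s).encode("ascii")[:n]
    return b + b" " * (n - len(b))


def write_edf(path, rec: SensorRecording) -> None:
    """Write a recording as EDF (16-bit, 1-s records, microvolt units)."""
    data, fs = rec.data, rec.fs
    n_ch, n_samp = data.shape
    spr = int(round(fs))
    n_rec = int(np.ceil(n_samp / spr))
    pad = n_rec * spr - n_samp
    d = np.pad(data, ((0, 0), (0, pad)), mode="edge") if pad else data
    pmin = d.min(axis=1)
    pmax = d.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax[flat] = pmin[flat] + 1.0
    # physical min/max are stored as 8-char ASCII; quantize against the
    # stored (rounded) values so the scale used for encoding matches them
    pmin_s = [f"{v:.6g}"[:8] for v in pmin]
    pmax_s = [f"{v:.6g}"[:8] for v in pmax]
    pmin = np.array([float(s) for s in pmin_s])
    pmax = np.array([float(s) for s in pmax_s])
    pmin = np.minimum(pmin, d.min(axis=1))
    pmax = np.maximum(pmax, d.max(axis=1))
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    dig = np.round((d - pmin[:, None]) * scale[:, None] + dmin)
    dig = np.clip(dig, dmin, dmax).astype("<i2")
    with open(path, "wb") as f:
        f.write(_fix("0", 8))
        f.write(_fix("X X X X", 80))
        f.write(_fix("Startdate 01-JAN-2000 X X X", 80))
        f.write(_fix("01.01.00", 8))
        f.write(_fix("00.00.00", 8))
        f.write(_fix(256 * (1 + n_ch), 8))
        f.write(_fix("", 44))
        f.write(_fix(n_rec, 8))
        f.write(_fix(1, 8))
        f.write(_fix(n_ch, 4))
        for nm in rec.channel_names:
            f.write(_fix(nm, 16))
        for _ in range(n_ch):
            f.write(_fix("", 80))
        for _ in range(n_ch):
            f.write(_fix("uV", 8))
        for s in [f"{v:.6g}"[:8] for v in pmin]:
            f.write(_fix(s, 8))
        for s in [f"{v:.6g}"[:8] for v in pmax]:
            f.write(_fix(s, 8))
        for _ in range(n_ch):
            f.write(_fix(dmin, 8))
        for _ in range(n_ch):
            f.write(_fix(dmax, 8))
        for _ in range(n_ch):
            f.write(_fix("", 80))
        for _ in range(n_ch):
            f.write(_fix(spr, 8))
        for _ in range(n_ch):
            f.write(_fix("", 32))
        for r in range(n_rec):
            f.write(dig[:, r * spr:(r + 1) * spr].tobytes())


def read_edf(path, spike_times=None) -> SensorRecording:
    """Read an EDF recording (via MNE); values returned in microvolts."""
    import mne
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE works in volts internally
    return SensorRecording(
        data=data, fs=float(raw.info["sfreq"]),
        spike_times=np.asarray(spike_times if spike_times is not None else []),
        channel_names=list(raw.ch_names))


# ---------------------------------------------------------------- mesh

def write_mesh(path, mesh: CorticalMesh) -> None:
    """Write an ASCII PLY/OFF mesh plus a hemisphere-label sidecar."""
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles,
                         process=False)
    kind = path.suffix.lstrip(".").lower() or "ply"
    data = tm.export(file_type=kind, encoding="ascii") \
        if kind == "ply" else tm.export(file_type=kind)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as f:
        f.write(data)
    side = path.with_suffix(path.suffix + ".hemi")
    side.write_text("\n".join(mesh.hemisphere) + "\n")


def read_mesh(path, hemisphere_path=None) -> CorticalMesh:
    """Read a PLY/OFF mesh; hemisphere labels come from a sidecar file
    (one 'left'/'right' per vertex) or default to the sign of x."""
    path = Path(path)
    tm = trimesh.load_mesh(str(path), process=False)
    v = np.asarray(tm.vertices, dtype=float)
    f = np.asarray(tm.faces, dtype=np.int64)
    side = Path(hemisphere_path) if hemisphere_path else \
        path.with_suffix(path.suffix + ".hemi")
    if side.exists():
        hemi = np.array(side.read_text().split())
        if len(hemi) != len(v):
            raise ValueError(
                f"{side}: {len(hemi)} hemisphere labels for {len(v)} vertices")
    else:
        logger.warning("no hemisphere sidecar found; labelling by sign of x")
        hemi = np.where(v[:, 0] < 0, "left", "right")
    return CorticalMesh(vertices=v, triangles=f, hemisphere=hemi)


# ---------------------------------------------------------------- lead field

def write_leadfield(path, lf: LeadField) -> None:
    """TSV (sensors x patches, sensor names as index) or HDF5 by suffix."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("K", data=lf.K)
            f.create_dataset("sensor_names",
                             data=np.array(lf.sensor_names, dtype="S"))
    else:
        df = pd.DataFrame(lf.K, index=lf.sensor_names)
        df.to_csv(path, sep="\t", header=[f"patch{j}" for j in
                                          range(lf.n_patches)])


def read_leadfield(path) -> LeadField:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            K = f["K"][()]
            names = [s.decode() for s in f["sensor_names"][()]]
        return LeadField(K=K, sensor_names=names)
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LeadField(K=df.to_numpy(dtype=float),
                     sensor_names=[str(i) for i in df.index])


# ---------------------------------------------------------------- events

def write_events(path, spike_times, label: str = "spike") -> None:
    pd.DataFrame({"onset_s": np.asarray(spike_times, dtype=float),
                  "label": label}).to_csv(path, sep="\t", index=False)


def read_events(path) -> np.ndarray:
    """Read spike onset times from a TSV with columns onset_s, label."""
    df = pd.read_csv(path, sep="\t")
    if "onset_s" not in df.columns:
        raise ValueError(f"{path}: missing required column 'onset_s'")
    onsets = pd.to_numeric(df["onset_s"], errors="coerce")
    bad = np.flatnonzero(onsets.isna().to_numpy())
    if bad.size:
        raise ValueError(
            f"{path}: non-numeric onset_s at row {bad[0] + 2} "
            f"(value {df['onset_s'].iloc[bad[0]]!r})")
    return onsets.to_numpy(dtype=float)


# ---------------------------------------------------------------- parcels

def write_parcels(path, parcel_map: ParcelMap) -> None:
    labels = parcel_map.parcel_of_patch.astype(str)
    pd.DataFrame({
        "patch_id": np.arange(len(labels)),
        "parcel": labels,
        "hemisphere": [parcel_map.hemisphere_of_parcel[l] for l in labels],
    }).to_csv(path, sep="\t", index=False)


def read_parcels(path) -> ParcelMap:
    df = pd.read_csv(path, sep="\t")
    for col in ("patch_id", "parcel", "hemisphere"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    df = df.sort_values("patch_id")
    if not np.array_equal(df["patch_id"].to_numpy(), np.arange(len(df))):
        raise ValueError(f"{path}: patch_id must enumerate 0..n-1")
    hemi = {}
    for lab, h in zip(df["parcel"], df["hemisphere"]):
        if lab in hemi and hemi[lab] != h:
            raise ValueError(f"{path}: parcel {lab!r} has conflicting "
                             "hemisphere labels")
        hemi[str(lab)] = str(h)
    return ParcelMap(parcel_of_patch=df["parcel"].to_numpy(dtype=object),
                     hemisphere_of_parcel=hemi)


# ---------------------------------------------------------------- geometry

def write_tessellation(prefix, tess: PatchTessellation) -> None:
    """Write triangle->patch and per-patch summary TSVs."""
    prefix = Path(prefix)
    pd.DataFrame({
        "triangle_id": np.arange(len(tess.patch_of_triangle)),
        "patch_id": tess.patch_of_triangle,
    }).to_csv(prefix.with_suffix(".triangles.tsv"), sep="\t", index=False)
    pd.DataFrame({
        "patch_id": np.arange(tess.n_patches),
        "x": tess.centroid[:, 0], "y": tess.centroid[:, 1],
        "z": tess.centroid[:, 2],
        "nx": tess.orientation[:, 0], "ny": tess.orientation[:, 1],
        "nz": tess.orientation[:, 2],
        "hemisphere": tess.hemisphere,
        "area_cm2": tess.patch_area,
    }).to_csv(prefix.with_suffix(".patches.tsv"), sep="\t", index=False)


def write_laplacian(path, lap: LaplacianOperator) -> None:
    """Sparse triples (i, j, value) TSV."""
    coo = lap.W.tocoo()
    pd.DataFrame({"i": coo.row, "j": coo.col, "value": coo.data}).to_csv(
        path, sep="\t", index=False)


def read_laplacian(path) -> LaplacianOperator:
    import scipy.sparse as sp
    df = pd.read_csv(path, sep="\t")
    n = int(max(df["i"].max(), df["j"].max())) + 1
    W = sp.csr_matrix((df["value"], (df["i"], df["j"])), shape=(n, n))
    return LaplacianOperator(W=W)


# ---------------------------------------------------------------- results

def write_coherence(outdir, interval: str, result: CoherenceResult) -> None:
    """Per-band TSV matrices plus the per-frequency tensor as HDF5."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for b, band in enumerate(result.band_names):
        pd.DataFrame(result.per_band[:, :, b], index=result.parcels,
                     columns=result.parcels).to_csv(
            outdir / f"coherence_{interval}_{band}.tsv", sep="\t")
    with h5py.File(outdir / f"coherence_{interval}.h5", "w") as f:
        f.create_dataset("per_freq", data=result.per_freq)
        f.create_dataset("per_band", data=result.per_band)
        f.create_dataset("freqs", data=result.freqs)
        f.create_dataset("parcels", data=np.array(result.parcels, dtype="S"))
        f.attrs["n_epochs"] = result.n_epochs


def write_edges(path, edges_by_interval: dict) -> None:
    """Edge lists: TSV (interval, band, parcel_a, parcel_b, coherence)."""
    rows = []
    for interval, edges in edges_by_interval.items():
        for band, a, b, v in edges:
            rows.append((interval, band, a, b, v))
    pd.DataFrame(rows, columns=["interval", "band", "parcel_a", "parcel_b",
                                "coherence"]).to_csv(path, sep="\t",
                                                     index=False)


def write_json(path, obj) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=1, sort_keys=True)
        f.write("\n")
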