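"""Parcel aggregation and spike-locked spectral coherence.

Source waveforms are averaged within named parcels (Brodmann-area-like
regions), then coherence is estimated between every parcel pair on
integer-Hz bins from 1 to 70 Hz:

    Coh(f) = |mean_epochs X(f) conj(Y(f))| / sqrt(S_XX(f) S_YY(f))

where X, Y are the FFTs of the demeaned 1-s epochs and S_XX, S_YY the
epoch-averaged autospectra. The magnitude of the complex mean
cross-spectrum is taken so the value is real and bounded in [0, 1]; with
a single epoch the estimate degenerates to 1 everywhere and a warning is
logged. Per-frequency coherences are summarized into the five classical
EEG bands and the strongest K parcel pairs per band form the coherence
network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("corticoh.spectral")

__all__ = [
    "ParcelMap",
    "CoherenceResult",
    "BANDS",
    "average_by_parcel",
    "cross_spectra",
    "coherence",
    "band_average",
    "pair_count",
    "coherence_matrix",
    "top_k_edges",
]

#: analysis frequency range (integer-Hz bins, inclusive)
FMIN, FMAX = 1, 70

#: band -> integer bins included (half-open bands; boundary bin goes to the
#: upper band; delta starts at 1 Hz because analysis covers 1-70 Hz; gamma
#: keeps its printed closed top at 70 Hz)
BANDS: dict[str, tuple[int, int]] = {
    "delta": (1, 3),
    "theta": (4, 7),
    "alpha": (8, 12),
    "beta": (13, 29),
    "gamma": (30, 70),
}
BAND_ORDER = tuple(BANDS)

#: power product below this is treated as an undefined coherence bin
POWER_TOL = 1e-300


@dataclass
class ParcelMap:
    """Assignment of patches to named parcels with hemisphere labels."""

    parcel_of_patch: np.ndarray        # (n_patches,) parcel label strings
    hemisphere_of_parcel: dict[str, str]

    def __post_init__(self) -> None:
        self.parcel_of_patch = np.asarray(self.parcel_of_patch, dtype=object)
        labels = set(np.unique(self.parcel_of_patch.astype(str)))
        missing = labels - set(self.hemisphere_of_parcel)
        if missing:
            raise ValueError(f"parcels without hemisphere label: {sorted(missing)}")

    @property
    def labels(self) -> list[str]:
        """All declared parcels (a declared parcel may have no patches)."""
        return sorted(self.hemisphere_of_parcel)

    def ordered_labels(self) -> list[str]:
        """Right-hemisphere parcels first, then left, each sorted by label.

        This puts right-intra pairs in the upper-left quadrant of the
        coherence matrix and left-intra in the lower-right.
        """
        right = sorted(l for l in self.labels
                       if self.hemisphere_of_parcel[l] == "right")
        left = sorted(l for l in self.labels
                      if self.hemisphere_of_parcel[l] == "left")
        return right + left


@dataclass
class CoherenceResult:
    """Coherence matrices for one analysis interval.

    ``per_freq`` is (n_parcels, n_parcels, n_freqs) over ``freqs`` (Hz);
    ``per_band`` is (n_parcels, n_parcels, 5) over ``BAND_ORDER``. Parcels
    are ordered right hemisphere first (see ParcelMap.ordered_labels).
    Undefined bins (vanishing power) hold NaN.
    """

    parcels: list[str]
    freqs: np.ndarray
    per_freq: np.ndarray
    per_band: np.ndarray
    n_epochs: int
    band_names: tuple[str, ...] = BAND_ORDER
    meta: dict = field(default_factory=dict)


def pair_count(n_signals: int) -> int:
    """Number of unordered signal pairs, (N^2 - N) / 2."""
    if n_signals < 1:
        raise ValueError("need at least one signal")
    return (n_signals * n_signals - n_signals) // 2


def average_by_parcel(J_epochs: np.ndarray, parcel_map: ParcelMap
                      ) -> tuple[np.ndarray, list[str]]:
    """Average signed patch waveforms within each parcel.

    Parameters
    ----------
    J_epochs : (..., n_patches, n_samples) array
        Patch waveforms; any leading epoch axes are preserved.
    parcel_map : ParcelMap

    Returns
    -------
    parcel_epochs : (..., n_parcels, n_samples) array, parcels in
        ``ordered_labels()`` order.
    labels : the parcel labels in matrix order.

    Notes
    -----
    The mean is taken over *signed* waveforms, so patches with opposing
    dipole orientations within one parcel can cancel. This mirrors the
    plain averaging used when grouping dipoles by anatomical region and is
    a known hazard of the approach.
    """
    J_epochs = np.asarray(J_epochs, dtype=float)
    assign = parcel_map.parcel_of_patch.astype(str)
    if J_epochs.shape[-2] != len(assign):
        raise ValueError(
            f"parcel map covers {len(assign)} patches but waveforms have "
            f"{J_epochs.shape[-2]}")
    labels = parcel_map.ordered_labels()
    out = []
    kept = []
    for lab in labels:
        idx = np.flatnonzero(assign == lab)
        if idx.size == 0:
            logger.warning("parcel %s has no member patches; excluded", lab)
            continue
        out.append(J_epochs[..., idx, :].mean(axis=-2))
        kept.append(lab)
    return np.stack(out, axis=-2), kept


def _freq_bins(n_samples: int, fs: float, fmin: int = FMIN, fmax: int = FMAX
               ) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the rfft bins nearest each integer frequency.

    For 1-s epochs the bin spacing is exactly 1 Hz and the mapping is
    exact; otherwise the nearest bin is used (a warning is issued at
    epoching time).
    """
    if n_samples < 2:
        raise ValueError("epochs must contain at least 2 samples")
    if fmax > fs / 2:
        raise ValueError(
            f"requested bins up to {fmax} Hz exceed the Nyquist frequency "
            f"{fs / 2:g} Hz")
    df = fs / n_samples
    freqs = np.arange(fmin, fmax + 1, dtype=float)
    idx = np.round(freqs / df).astype(int)
    return freqs, idx


def _epoch_fft(epochs: np.ndarray) -> np.ndarray:
    """Demean each epoch along time and take the real FFT."""
    epochs = np.asarray(epochs, dtype=float)
    epochs = epochs - epochs.mean(axis=-1, keepdims=True)
    return np.fft.rfft(epochs, axis=-1)


def cross_spectra(x_epochs: np.ndarray, y_epochs: np.ndarray, fs: float
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Epoch-averaged auto- and cross-spectra on integer-Hz bins 1-70.

    Parameters
    ----------
    x_epochs, y_epochs : (n_epochs, n_samples) arrays
    fs : sampling rate (Hz)

    Returns
    -------
    freqs, S_xx, S_yy, S_xy — S_xy is complex (the epoch mean of
    X(f) conj(Y(f))); S_xx and S_yy are real and non-negative.
    """
    x_epochs = np.atleast_2d(np.asarray(x_epochs, dtype=float))
    y_epochs = np.atleast_2d(np.asarray(y_epochs, dtype=float))
    if x_epochs.shape != y_epochs.shape:
        raise ValueError("x and y epochs must have identical shape")
    freqs, idx = _freq_bins(x_epochs.shape[-1], fs)
    X = _epoch_fft(x_epochs)[:, idx]
    Y = _epoch_fft(y_epochs)[:, idx]
    S_xx = np.mean(np.abs(X) ** 2, axis=0)
    S_yy = np.mean(np.abs(Y) ** 2, axis=0)
    S_xy = np.mean(X * np.conj(Y), axis=0)
    return freqs, S_xx, S_yy, S_xy


def coherence(S_xx: np.ndarray, S_yy: np.ndarray, S_xy: np.ndarray,
              n_epochs: int | None = None) -> np.ndarray:
    """Magnitude coherence |S_xy| / sqrt(S_xx S_yy), clipped to [0, 1].

    Bins where the power product vanishes are returned as NaN (undefined)
    and excluded downstream. With a single epoch the estimate is
    identically 1 and carries no information; a warning is logged.
    """
    S_xx = np.asarray(S_xx, dtype=float)
    S_yy = np.asarray(S_yy, dtype=float)
    if np.any(S_xx < 0) or np.any(S_yy < 0):
        raise ValueError("autospectra must be non-negative")
    if n_epochs == 1:
        logger.warning("coherence from a single epoch is identically 1; "
                       "at least 2 epochs are needed for a meaningful estimate")
    denom = S_xx * S_yy
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.abs(S_xy) / np.sqrt(denom)
    c = np.where(denom > POWER_TOL, c, np.nan)
    if np.any(c > 1 + 1e-12):
        raise FloatingPointError("coherence exceeded 1 beyond round-off")
    return np.clip(c, 0.0, 1.0)


def band_average(coh: np.ndarray, freqs: np.ndarray | None = None
                 ) -> np.ndarray:
    """Unweighted mean coherence per band over the last axis.

    ``coh`` holds values on integer-Hz bins (1..70 by default along the
    last axis). NaN bins are excluded; a band with no defined bins yields
    NaN.
    """
    coh = np.asarray(coh, dtype=float)
    if freqs is None:
        freqs = np.arange(FMIN, FMAX + 1, dtype=float)
    freqs = np.asarray(freqs)
    if coh.shape[-1] != freqs.size:
        raise ValueError("frequency axis length mismatch")
    out = np.empty(coh.shape[:-1] + (len(BAND_ORDER),))
    for b, name in enumerate(BAND_ORDER):
        lo, hi = BANDS[name]
        sel = (freqs >= lo) & (freqs <= hi)
        with np.errstate(invalid="ignore"):
            vals = coh[..., sel]
            good = np.isfinite(vals)
            cnt = good.sum(axis=-1)
            s = np.where(good, vals, 0.0).sum(axis=-1)
            out[..., b] = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
    return out


def coherence_matrix(parcel_epochs: np.ndarray, labels: list[str], fs: float
                     ) -> CoherenceResult:
    """Full symmetric parcel x parcel coherence for one interval.

    Parameters
    ----------
    parcel_epochs : (n_epochs, n_parcels, n_samples) array
        Parcel-averaged source waveforms, parcels already in matrix order
        (right hemisphere first; see ParcelMap.ordered_labels).
    labels : parcel labels matching axis 1.
    fs : sampling rate (Hz).
    """
    parcel_epochs = np.asarray(parcel_epochs, dtype=float)
    if parcel_epochs.ndim != 3:
        raise ValueError("parcel_epochs must be (n_epochs, n_parcels, n_samples)")
    n_ep, n_par, n_samp = parcel_epochs.shape
    if n_par != len(labels):
        raise ValueError("label count does not match parcel axis")
    if n_par < 2:
        raise ValueError("need at least 2 parcels")
    if n_ep == 1:
        logger.warning("coherence from a single epoch is identically 1; "
                       "at least 2 epochs are needed for a meaningful estimate")
    freqs, idx = _freq_bins(n_samp, fs)
    X = _epoch_fft(parcel_epochs)[..., idx]        # (ep, par, f)
    S = np.einsum("epf,eqf->pqf", X, np.conj(X)) / n_ep
    auto = np.real(np.einsum("ppf->pf", S))
    denom = auto[:, None, :] * auto[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.abs(S) / np.sqrt(denom)
    C = np.where(denom > POWER_TOL, C, np.nan)
    C = np.clip(C, 0.0, 1.0)
    # enforce exact symmetry and unit diagonal against round-off
    C = 0.5 * (C + np.swapaxes(C, 0, 1))
    ii = np.arange(n_par)
    C[ii, ii, :] = np.where(np.isfinite(C[ii, ii, :]), 1.0, np.nan)
    per_band = band_average(C, freqs)
    return CoherenceResult(parcels=list(labels), freqs=freqs, per_freq=C,
                           per_band=per_band, n_epochs=n_ep)


def top_k_edges(result: CoherenceResult, k: int = 100,
                pooled: bool = False) -> list[tuple]:
    """The k strongest off-diagonal parcel pairs per band (or pooled).

    Returns tuples ``(band, parcel_a, parcel_b, value)`` sorted by value
    descending; ties break deterministically by band order then parcel
    indices. With ``pooled=True`` a single list over all bands is
    returned instead of k per band. NaN (undefined) entries never rank.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(result.parcels)
    iu, ju = np.triu_indices(n, k=1)
    all_edges: list[tuple] = []
    for b, band in enumerate(result.band_names):
        vals = result.per_band[iu, ju, b]
        edges = [
            (float(v), b, int(i), int(j))
            for v, i, j in zip(vals, iu, ju)
            if np.isfinite(v)
        ]
        edges.sort(key=lambda e: (-e[0], e[1], e[2], e[3]))
        if not pooled:
            edges = edges[:k]
        all_edges.extend(edges)
    if pooled:
        all_edges.sort(key=lambda e: (-e[0], e[1], e[2], e[3]))
        all_edges = all_edges[:k]
    return [
        (result.band_names[b], result.parcels[i], result.parcels[j], v)
        for v, b, i, j in all_edges
    ]
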