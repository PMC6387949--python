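"""Directed EEG connectivity via the direct Directed Transfer Function (dDTF).

The estimation chain is: ridge-fit VAR model -> spectral transfer matrix
H(f) = (I - sum_k A_k e^{-i 2 pi f k / fs})^{-1} -> directed measures.

Measures (all on the squared convention, entry (i, j) = influence of
source j on sink i):

* DTF:      gamma2_ij(f) = |H_ij(f)|^2 / sum_k |H_ik(f)|^2
* ffDTF:    eta2_ij(f)   = |H_ij(f)|^2 / sum_{f'} sum_k |H_ik(f')|^2
* partial coherence: chi2_ij(f) = |P_ij(f)|^2 / (P_ii(f) P_jj(f)),
  P(f) = S(f)^{-1}, S(f) = H(f) Sigma H(f)*
* dDTF:     delta_ij(f)  = eta2_ij(f) * chi2_ij(f)

dDTF suppresses indirect (cascade) influences that inflate the plain DTF,
because partial coherence conditions each pair on all other channels.

The default montage is the 12-channel frontoparietal/centroparietal set
CP3, CPz, CP4, P3, Pz, P4, FC5, F7, F3, FC4, F8, F4, yielding 132 ordered
channel pairs (12 x 11, diagonal excluded, sink-major enumeration).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .var import VarModel, fit_var_ridge

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CHANNELS",
    "DEFAULT_BANDS",
    "DEFAULT_FREQS",
    "BandScheme",
    "SpectralSet",
    "ConnectivityTensor",
    "connection_pairs",
    "transfer_function",
    "dtf",
    "ffdtf",
    "partial_coherence",
    "ddtf",
    "ddtf_from_epochs",
    "sliding_ddtf",
    "band_average",
    "baseline_correct",
    "zscore_standardize",
    "outflow",
    "top_fraction_edges",
    "build_feature_matrix",
    "FeatureMatrix",
]

DEFAULT_CHANNELS: tuple[str, ...] = (
    "CP3", "CPz", "CP4", "P3", "Pz", "P4",
    "FC5", "F7", "F3", "FC4", "F8", "F4",
)

#: Canonical EEG band intervals in Hz (closed on both ends). The 3-4 Hz gap
#: between delta and theta is intentional.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 25.0),
}

#: Default analysis grid: 1-25 Hz at 0.5 Hz resolution (covers all bands).
DEFAULT_FREQS: np.ndarray = np.arange(1.0, 25.0 + 0.25, 0.5)


@dataclass(frozen=True)
class BandScheme:
    """Named, non-overlapping, ascending frequency intervals (Hz)."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        prev_hi = -np.inf
        for name, (lo, hi) in self.bands.items():
            if lo > hi:
                raise ValueError(f"band {name!r} has lo > hi")
            if lo <= prev_hi:
                raise ValueError("bands must be non-overlapping and ascending")
            prev_hi = hi

    @property
    def names(self) -> list[str]:
        return list(self.bands)


@dataclass
class SpectralSet:
    """Transfer and spectral matrices of a VAR model on a frequency grid."""

    freqs: np.ndarray           # (n_freq,)
    H: np.ndarray               # (n_freq, n, n) complex transfer matrix
    S: np.ndarray               # (n_freq, n, n) spectral density H Sigma H*
    fs: float

    @property
    def n_channels(self) -> int:
        return self.H.shape[1]

    def inverse_spectrum(self, jitter_rel: float = 1e-10) -> np.ndarray:
        """P(f) = S(f)^{-1}; near-singular S gets a documented relative
        diagonal jitter of ``jitter_rel * trace(S)/n`` with a logged warning."""
        n = self.n_channels
        P = np.empty_like(self.S)
        for k, Sf in enumerate(self.S):
            try:
                P[k] = np.linalg.inv(Sf)
            except np.linalg.LinAlgError:
                jit = jitter_rel * np.trace(Sf).real / n
                logger.warning(
                    "singular spectral matrix at f=%.3f Hz; adding jitter %.3e",
                    self.freqs[k], jit,
                )
                P[k] = np.linalg.inv(Sf + jit * np.eye(n))
        return P


@dataclass
class ConnectivityTensor:
    """Directed connectivity values, sink x source x frequency (or band).

    ``values[i, j]`` is the influence of source channel j on sink channel i.
    A leading time axis is present for sliding-window estimates. The last
    axis is labelled either by the frequency grid (``freqs``) or by band
    names (``bands``).
    """

    values: np.ndarray
    channels: tuple[str, ...]
    measure: str
    freqs: np.ndarray | None = None
    bands: tuple[str, ...] | None = None
    times: np.ndarray | None = None   # window-center times (s) when sliding

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def is_time_resolved(self) -> bool:
        return self.times is not None


def connection_pairs(channels: tuple[str, ...] | list[str]) -> list[tuple[int, int]]:
    """Sink-major enumeration of all ordered (sink, source) index pairs,
    diagonal excluded. For 12 channels this yields the 132 directed pairs."""
    n = len(channels)
    return [(i, j) for i in range(n) for j in range(n) if j != i]


def transfer_function(model: VarModel, freqs: np.ndarray) -> SpectralSet:
    """Compute H(f), S(f) on a frequency grid (must lie below fs/2)."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= model.fs / 2):
        raise ValueError("all frequencies must be below the Nyquist rate fs/2")
    p, n = model.order, model.n_channels
    lags = np.arange(1, p + 1)
    # Abar(f) = I - sum_k A_k exp(-i 2 pi f k / fs)
    phase = np.exp(-2j * np.pi * np.outer(freqs, lags) / model.fs)  # (nf, p)
    Abar = np.eye(n)[None, :, :] - np.einsum("fk,kij->fij", phase, model.coeffs)
    H = np.empty_like(Abar)
    for k in range(len(freqs)):
        try:
            H[k] = np.linalg.inv(Abar[k])
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"singular spectral factor at f={freqs[k]:.3f} Hz"
            ) from exc
    S = H @ model.sigma @ np.conj(np.swapaxes(H, 1, 2))
    return SpectralSet(freqs=freqs, H=H, S=S, fs=model.fs)


def dtf(spec: SpectralSet) -> ConnectivityTensor:
    """DTF: per sink i and frequency, |H_ij|^2 normalized over sources."""
    mag2 = np.abs(spec.H) ** 2                       # (nf, sink, source)
    denom = mag2.sum(axis=2, keepdims=True)
    vals = np.moveaxis(mag2 / denom, 0, -1)          # (sink, source, nf)
    return ConnectivityTensor(vals, _chan(spec), "DTF", freqs=spec.freqs)


def ffdtf(spec: SpectralSet) -> ConnectivityTensor:
    """Full-frequency DTF: normalization sums over the whole grid."""
    mag2 = np.abs(spec.H) ** 2
    denom = mag2.sum(axis=(0, 2))[None, :, None]     # per sink, all f & sources
    vals = np.moveaxis(mag2 / denom, 0, -1)
    return ConnectivityTensor(vals, _chan(spec), "ffDTF", freqs=spec.freqs)


def partial_coherence(spec: SpectralSet) -> ConnectivityTensor:
    """Squared partial coherence from the inverse spectral matrix."""
    P = spec.inverse_spectrum()
    diag = np.real(np.einsum("fii->fi", P))
    denom = diag[:, :, None] * diag[:, None, :]
    vals = np.abs(P) ** 2 / denom
    vals = np.clip(np.moveaxis(vals, 0, -1), 0.0, 1.0)
    return ConnectivityTensor(vals, _chan(spec), "partial coherence", freqs=spec.freqs)


def ddtf(spec: SpectralSet) -> ConnectivityTensor:
    """dDTF = ffDTF * squared partial coherence (squared convention)."""
    eta2 = ffdtf(spec).values
    chi2 = partial_coherence(spec).values
    return ConnectivityTensor(eta2 * chi2, _chan(spec), "dDTF", freqs=spec.freqs)


def _chan(spec: SpectralSet) -> tuple[str, ...]:
    n = spec.n_channels
    return tuple(f"ch{i}" for i in range(n))


def ddtf_from_epochs(
    epochs: np.ndarray,
    fs: float,
    order: int = 15,
    ridge: float = 1e-3,
    freqs: np.ndarray | None = None,
    channels: tuple[str, ...] | None = None,
) -> ConnectivityTensor:
    """Static dDTF from one pooled ridge-VAR fit over all samples/trials."""
    if freqs is None:
        freqs = DEFAULT_FREQS
    model = fit_var_ridge(epochs, order=order, ridge=ridge, fs=fs)
    tensor = ddtf(transfer_function(model, freqs))
    if channels is not None:
        tensor.channels = tuple(channels)
    return tensor


def sliding_ddtf(
    epochs: np.ndarray,
    fs: float,
    times: np.ndarray,
    window_ms: float = 500.0,
    step_ms: float = 50.0,
    order: int = 15,
    ridge: float = 1e-3,
    freqs: np.ndarray | None = None,
    channels: tuple[str, ...] | None = None,
) -> ConnectivityTensor:
    """Time-resolved dDTF: per window position, fit one VAR pooled across
    trials and compute dDTF; emits window-center timestamps.

    Parameters
    ----------
    epochs : ndarray (n_channels, n_samples, n_trials)
    times : ndarray (n_samples,)
        Sample times in seconds relative to the event (may be negative).
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim == 2:
        epochs = epochs[:, :, None]
    n_ch, n_samp, n_trials = epochs.shape
    if freqs is None:
        freqs = DEFAULT_FREQS
    w = int(round(window_ms / 1000.0 * fs))
    step = max(1, int(round(step_ms / 1000.0 * fs)))
    min_rows = n_ch * order
    if (w - order) * n_trials <= min_rows:
        raise ValueError(
            "window too short: need (window_samples - order) * n_trials > "
            f"n_channels * order = {min_rows}; got window_samples={w}, "
            f"n_trials={n_trials}"
        )
    if w > n_samp:
        raise ValueError("window longer than epoch")
    starts = list(range(0, n_samp - w + 1, step))
    vals = []
    centers = []
    for s0 in starts:
        seg = epochs[:, s0 : s0 + w, :]
        model = fit_var_ridge(seg, order=order, ridge=ridge, fs=fs)
        vals.append(ddtf(transfer_function(model, freqs)).values)
        centers.append(0.5 * (times[s0] + times[s0 + w - 1]))
    tensor = ConnectivityTensor(
        np.stack(vals),   # (n_windows, sink, source, n_freq)
        tuple(channels) if channels is not None else tuple(f"ch{i}" for i in range(n_ch)),
        "dDTF",
        freqs=np.asarray(freqs, dtype=float),
        times=np.asarray(centers),
    )
    return tensor


def band_average(tensor: ConnectivityTensor, scheme: BandScheme | None = None) -> ConnectivityTensor:
    """Arithmetic mean over grid frequencies within each closed band interval."""
    if scheme is None:
        scheme = BandScheme()
    if tensor.freqs is None:
        raise ValueError("tensor is already band-averaged")
    out = []
    for name, (lo, hi) in scheme.bands.items():
        mask = (tensor.freqs >= lo) & (tensor.freqs <= hi)
        if not mask.any():
            raise ValueError(f"band {name!r} contains no grid frequencies")
        out.append(tensor.values[..., mask].mean(axis=-1))
    return ConnectivityTensor(
        np.stack(out, axis=-1),
        tensor.channels,
        tensor.measure,
        bands=tuple(scheme.names),
        times=tensor.times,
    )


def baseline_correct(
    tensor: ConnectivityTensor,
    baseline: tuple[float, float] = (-0.250, 0.0),
) -> ConnectivityTensor:
    """Subtract, per connection/band, the mean over window centers falling
    in the closed baseline interval (seconds relative to event onset)."""
    if tensor.times is None:
        raise ValueError("baseline correction needs a time-resolved tensor")
    lo, hi = baseline
    mask = (tensor.times >= lo) & (tensor.times <= hi)
    if not mask.any():
        raise ValueError(
            f"no window centers inside baseline interval [{lo}, {hi}] s"
        )
    base = tensor.values[mask].mean(axis=0, keepdims=True)
    return ConnectivityTensor(
        tensor.values - base,
        tensor.channels,
        tensor.measure + " (baseline-corrected)",
        freqs=tensor.freqs,
        bands=tensor.bands,
        times=tensor.times,
    )


def zscore_standardize(tensor: ConnectivityTensor, axis: int = 0) -> ConnectivityTensor:
    """Z-score per connection/band over the given axis (default: time).

    Zero-SD slices map to zero with a logged warning.
    """
    mean = tensor.values.mean(axis=axis, keepdims=True)
    sd = tensor.values.std(axis=axis, keepdims=True)
    zero = sd == 0
    if zero.any():
        logger.warning(
            "zscore_standardize: %d constant slices mapped to 0", int(zero.sum())
        )
    sd = np.where(zero, 1.0, sd)
    z = (tensor.values - mean) / sd
    z = np.where(np.broadcast_to(zero, z.shape), 0.0, z)
    return ConnectivityTensor(
        z, tensor.channels, tensor.measure + " (z)",
        freqs=tensor.freqs, bands=tensor.bands, times=tensor.times,
    )


def outflow(conn: np.ndarray) -> np.ndarray:
    """Summed connectivity emanating from each source electrode.

    ``conn`` is a sink x source matrix; outflow(j) = sum_{i != j} conn[i, j].
    """
    conn = np.asarray(conn, dtype=float)
    return conn.sum(axis=0) - np.diag(conn)


def top_fraction_edges(
    conn: np.ndarray,
    channels: tuple[str, ...] | list[str],
    fraction: float = 0.10,
) -> list[tuple[str, str, float, int]]:
    """Top ``ceil(fraction * n_pairs)`` directed edges ranked by |value|.

    Returns (sink, source, value, sign) tuples; sign is +1/-1/0 (increase /
    decrease / exactly zero vs baseline). Ties in |value| are broken by the
    fixed sink-major lexicographic pair order, so the output is deterministic.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    pairs = connection_pairs(channels)
    n_top = math.ceil(fraction * len(pairs))
    ranked = sorted(
        range(len(pairs)),
        key=lambda k: (-abs(conn[pairs[k][0], pairs[k][1]]), k),
    )[:n_top]
    out = []
    for k in ranked:
        i, j = pairs[k]
        v = float(conn[i, j])
        out.append((channels[i], channels[j], v, int(np.sign(v))))
    return out


@dataclass
class FeatureMatrix:
    """Per-participant connectivity feature object: 132 pairs x bands x conditions."""

    values: np.ndarray                 # (n_pairs, n_bands, n_conditions)
    channels: tuple[str, ...]
    pairs: list[tuple[int, int]]       # sink-major (sink, source) index pairs
    bands: tuple[str, ...]
    conditions: tuple[str, ...]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    def vector(self, band: str, condition: str) -> np.ndarray:
        """Length-n_pairs feature vector for one band x condition cell."""
        return self.values[:, self.bands.index(band), self.conditions.index(condition)]

    def feature_names(self) -> list[str]:
        return [
            f"{self.channels[i]}_{self.channels[j]}" for i, j in self.pairs
        ]


def build_feature_matrix(
    trial_tensors: list[np.ndarray],
    trial_conditions: list[str],
    channels: tuple[str, ...],
    bands: tuple[str, ...],
    conditions: tuple[str, ...] = ("attend", "reinterpret"),
) -> FeatureMatrix:
    """Assemble the per-participant feature object from per-trial band dDTF.

    Each entry of ``trial_tensors`` is a (n_ch, n_ch, n_bands) array of band
    dDTF averaged over the 2-s presentation window for one trial. Features
    are the trial means per condition; connection ordering is sink-major
    over the channel list (diagonal excluded).
    """
    if len(trial_tensors) != len(trial_conditions):
        raise ValueError("one condition label per trial tensor required")
    pairs = connection_pairs(channels)
    n_bands = len(bands)
    vals = np.full((len(pairs), n_bands, len(conditions)), np.nan)
    for c, cond in enumerate(conditions):
        sel = [t for t, lab in zip(trial_tensors, trial_conditions) if lab == cond]
        if not sel:
            raise ValueError(f"no trials for condition {cond!r}")
        mean = np.mean(np.stack(sel), axis=0)   # (n_ch, n_ch, n_bands)
        for k, (i, j) in enumerate(pairs):
            vals[k, :, c] = mean[i, j, :]
    return FeatureMatrix(
        values=vals,
        channels=tuple(channels),
        pairs=pairs,
        bands=tuple(bands),
        conditions=tuple(conditions),
    )
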