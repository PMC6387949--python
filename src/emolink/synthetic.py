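"""Synthetic multi-participant cohort with planted, recoverable structure.

The generator emulates the two-session study design: a laboratory
emotion-regulation task (12-channel VAR-generated EEG epochs with planted
band-limited directed couplings, per-trial 1-9 intensity ratings) and an
immersive simulation task (RR-interval series with LF/HF oscillatory
modulation, shoot/don't-shoot trial outcomes, adjective-checklist anxiety
scores). A standard-normal participant-level latent trait links all
modalities linearly, so the cross-modal analysis has a known planted
signal and every downstream estimator can be scored against ground truth.

Planted directed couplings are realized by giving the source channel a
damped-oscillator (AR(2)) diagonal term with pole radius 0.99 at the
band's center frequency — a narrowband rhythm — and a one-lag cross
coefficient into the sink. The spectral transfer from source to sink is
then sharply concentrated at the oscillator frequency, which is what the
band-averaged dDTF feature path must recover. Each participant gets an
individual peak frequency (uniform jitter around the band center), the
well-known individual variability of EEG rhythms; this also decorrelates
out-of-band leakage of the resonance from the latent trait.

The latent trait enters on the power scale: squared edge strength and LF
modulation power are both linear in the trait, so the planted brain ->
HRV relationship is itself linear.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .connectivity import DEFAULT_BANDS, DEFAULT_CHANNELS
from .var import VarModel, simulate_var, spectral_radius

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedEdge",
    "GroundTruthSpec",
    "ParticipantData",
    "CohortBundle",
    "make_band_coupled_var",
    "simulate_var_eeg",
    "simulate_rr",
    "simulate_cohort",
]

LAB_CONDITIONS = ("attend", "reinterpret")
SIM_CONDITIONS = ("low", "high")


@dataclass(frozen=True)
class PlantedEdge:
    """Directed coupling source -> sink concentrated in one band.

    ``strength`` is the lag-1 cross-regression coefficient from the
    source's narrowband rhythm into the sink channel.
    """

    source: str
    sink: str
    band: str
    strength: float

    def __post_init__(self) -> None:
        if self.source == self.sink:
            raise ValueError("planted edge must connect two distinct channels")
        if self.band not in DEFAULT_BANDS:
            raise ValueError(f"unknown band {self.band!r}")

    @property
    def key(self) -> str:
        return f"{self.sink}_{self.source}_{self.band}"


def _default_edges() -> list[PlantedEdge]:
    return [
        PlantedEdge("F4", "Pz", "theta", 0.006),
        PlantedEdge("F3", "P3", "theta", 0.006),
        PlantedEdge("FC4", "CP4", "theta", 0.006),
    ]


@dataclass
class GroundTruthSpec:
    """Full parameterization of the synthetic cohort.

    The seed fully determines every output. Loadings are linear
    coefficients of the standard-normal participant trait z on the
    respective (power) scale: squared edge strength and LF band power are
    proportional to ``max(1 + loading * z, latent_floor)``. Simulation
    effect sizes have no published values; the defaults here are the
    package's own choices, anchored to the observable condition means
    where those are known (intensity 3.65/2.85, accuracy 0.87/0.84).
    """

    n_participants: int = 25
    n_channels: int = 12
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    fs: float = 250.0
    var_order: int = 2                      # order of the generated models
    planted_edges: list[PlantedEdge] = field(default_factory=_default_edges)
    latent_loadings: dict[str, float] = field(default_factory=dict)
    default_edge_loading: float = 0.5       # relative edge-power change per SD of z
    hrv_loading: float = 0.5                # relative LF-power change per SD of z
    latent_floor: float = 0.05              # lower clip of the power factor
    behavior_loadings: dict[str, float] = field(
        default_factory=lambda: {"intensity": 0.6, "error_rate": 0.02, "anxiety": 1.2}
    )
    noise_sds: dict[str, float] = field(
        default_factory=lambda: {
            "eeg": 1.0, "rating": 1.5, "rr_jitter_ms": 20.0, "anxiety": 1.0,
        }
    )
    seed: int = 0
    # study design sizes
    n_lab_trials: int = 60                  # per lab condition
    n_sim_trials: int = 128                 # per simulation condition
    epoch_window_s: tuple[float, float] = (-0.75, 2.25)
    # oscillator construction
    pole_radius: float = 0.99
    diag_ar: float = 0.5
    peak_freq_jitter_hz: float = 0.5        # individual peak-frequency spread
    # condition effects (shifts on the power scale / rating scale)
    reinterpret_power_shift: float = -0.3
    intensity_base: dict[str, float] = field(
        default_factory=lambda: {"attend": 3.65, "reinterpret": 2.85}
    )
    error_rate_base: dict[str, float] = field(
        default_factory=lambda: {"low": 0.13, "high": 0.16}
    )
    anxiety_base: dict[str, float] = field(
        default_factory=lambda: {"lab": 2.0, "sim_low": 4.0, "sim_high": 5.0}
    )
    # RR generation
    rr_duration_s: float = 600.0            # per simulation condition
    mean_ibi_ms: float = 800.0
    lf_freq: float = 0.10
    hf_freq: float = 0.25
    base_lf_amp_ms: float = 50.0
    base_hf_amp_ms: float = 30.0
    high_stress_lf_shift_ms: float = 10.0
    rr_artifact_rate: float = 0.02

    def __post_init__(self) -> None:
        if min(self.n_participants, self.n_channels, self.var_order,
               self.n_lab_trials, self.n_sim_trials) < 1:
            raise ValueError("all counts must be positive")
        if len(self.channels) != self.n_channels:
            raise ValueError("channel list length must equal n_channels")

    def edge_loading(self, edge: PlantedEdge) -> float:
        return self.latent_loadings.get(edge.key, self.default_edge_loading)


@dataclass
class ParticipantData:
    """All per-participant signals plus the realized ground-truth values."""

    participant: int
    epochs: np.ndarray                 # (n_ch, n_samples, n_trials), both conditions
    epoch_conditions: list[str]        # attend / reinterpret per trial
    epoch_times: np.ndarray            # sample times (s) relative to onset
    rr_raw: dict[str, np.ndarray]      # condition -> raw RR intervals (ms)
    ratings: pd.DataFrame              # trial, condition, rating
    outcomes: pd.DataFrame             # trial, condition, category
    anxiety: dict[str, int]            # lab / sim_low / sim_high raw counts
    truth: dict                        # z, per-condition edge strengths, lf amps, ...


@dataclass
class CohortBundle:
    """The full synthetic dataset plus the spec that generated it."""

    spec: GroundTruthSpec
    participants: list[ParticipantData]

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def channels(self) -> tuple[str, ...]:
        return self.spec.channels

    def truth_frame(self) -> pd.DataFrame:
        """Per-participant realized ground-truth values as a table."""
        rows = []
        for p in self.participants:
            row = {"participant": p.participant}
            row.update(p.truth)
            rows.append(row)
        return pd.DataFrame(rows).set_index("participant")


def _band_center(band: str) -> float:
    lo, hi = DEFAULT_BANDS[band]
    return 0.5 * (lo + hi)


def make_band_coupled_var(
    n_channels: int,
    planted_edges: list[PlantedEdge],
    fs: float,
    channels: tuple[str, ...] | None = None,
    diag_ar: float = 0.5,
    pole_radius: float = 0.99,
    center_freqs: dict[str, float] | None = None,
    noise_sd: float = 1.0,
) -> VarModel:
    """Construct a stable VAR with band-limited planted directed couplings.

    Channels carry an AR(1) diagonal (coefficient ``diag_ar``). For each
    planted edge, the source channel's diagonal becomes a damped
    oscillator with poles at ``pole_radius * exp(+-i 2 pi f_c / fs)``
    (f_c from ``center_freqs`` or the band center), and the sink receives
    a one-lag cross coefficient equal to the edge strength. A source with
    edges in several bands gets the product of the oscillator
    polynomials. Non-planted cross-terms are exactly zero. Raises if the
    companion spectral radius reaches 1, naming the offending edge.
    """
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(n_channels))
    if len(channels) != n_channels:
        raise ValueError("channel list length must equal n_channels")
    freqs = dict(center_freqs or {})
    for e in planted_edges:
        fc = freqs.get(e.band, _band_center(e.band))
        if fc >= fs / 2:
            raise ValueError(f"band center of {e.band!r} is above Nyquist")
    idx = {c: i for i, c in enumerate(channels)}
    # diagonal polynomial per channel: AR(1) by default, oscillator
    # product for planted sources
    source_bands: dict[int, list[str]] = {}
    for e in planted_edges:
        bands = source_bands.setdefault(idx[e.source], [])
        if e.band not in bands:
            bands.append(e.band)
    diag_polys: dict[int, np.ndarray] = {}
    for i in range(n_channels):
        if i in source_bands:
            poly = np.array([1.0])
            for band in source_bands[i]:
                fc = freqs.get(band, _band_center(band))
                theta = 2.0 * np.pi * fc / fs
                r = pole_radius
                poly = np.polymul(poly, [1.0, -2.0 * r * np.cos(theta), r * r])
            diag_polys[i] = poly
        else:
            diag_polys[i] = np.array([1.0, -diag_ar])
    order = max(2, max(len(p) - 1 for p in diag_polys.values()))
    coeffs = np.zeros((order, n_channels, n_channels))
    for i, poly in diag_polys.items():
        for k, c in enumerate(poly[1:], start=1):
            coeffs[k - 1, i, i] = -c
    for e in planted_edges:
        coeffs[0, idx[e.sink], idx[e.source]] += e.strength
    rad = spectral_radius(coeffs)
    if rad >= 1.0:
        worst = max(planted_edges, key=lambda e: abs(e.strength), default=None)
        raise ValueError(
            f"constructed VAR is unstable (spectral radius {rad:.4f}); "
            f"largest edge strength {worst.strength if worst else 'n/a'} "
            f"on {worst.key if worst else 'n/a'}"
        )
    sigma = (noise_sd ** 2) * np.eye(n_channels)
    return VarModel(coeffs=coeffs, sigma=sigma, fs=fs)


def simulate_var_eeg(
    model: VarModel,
    n_samples: int,
    seed: int | np.random.SeedSequence,
    n_trials: int = 1,
) -> np.ndarray:
    """Simulate EEG-like epochs from a stable VAR model (burn-in discarded)."""
    return simulate_var(model, n_samples, seed, n_trials=n_trials)


def simulate_rr(
    duration_s: float,
    mean_ibi_ms: float = 800.0,
    lf_amp_ms: float = 50.0,
    hf_amp_ms: float = 30.0,
    lf_freq: float = 0.10,
    hf_freq: float = 0.25,
    jitter_sd_ms: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    artifact_rate: float = 0.0,
) -> np.ndarray:
    """RR intervals whose instantaneous IBI is sinusoidally modulated.

    IBI(t) = mean + lf_amp sin(2 pi lf_freq t) + hf_amp sin(2 pi hf_freq t)
    + Gaussian jitter; beats accumulate until ``duration_s``. Direct IBI
    modulation (not integral-pulse-frequency modulation) keeps the
    expected spectrum in closed form. With ``artifact_rate > 0`` a
    matching fraction of intervals is halved to mimic ectopic beats (to
    be removed by the cleaning rules downstream).
    """
    if mean_ibi_ms <= lf_amp_ms + hf_amp_ms:
        raise ValueError("mean_ibi must exceed lf_amp + hf_amp (non-positive IBI)")
    if not (0.04 <= lf_freq <= 0.15):
        raise ValueError("lf_freq must lie in [0.04, 0.15] Hz")
    if not (0.15 <= hf_freq <= 0.40):
        raise ValueError("hf_freq must lie in [0.15, 0.40] Hz")
    rng = np.random.default_rng(seed)
    intervals = []
    t = 0.0
    while True:
        ibi = (
            mean_ibi_ms
            + lf_amp_ms * np.sin(2 * np.pi * lf_freq * t)
            + hf_amp_ms * np.sin(2 * np.pi * hf_freq * t)
        )
        if jitter_sd_ms > 0:
            ibi += jitter_sd_ms * rng.standard_normal()
        ibi = max(ibi, 1.0)
        t_next = t + ibi / 1000.0
        if t_next > duration_s:
            break
        intervals.append(ibi)
        t = t_next
    out = np.asarray(intervals)
    if artifact_rate > 0 and out.size:
        flip = rng.random(out.size) < artifact_rate
        out = np.where(flip, out * 0.5, out)
    return out


def _power_factor(z: float, loading: float, floor: float, shift: float = 0.0) -> float:
    return float(max(1.0 + loading * z + shift, floor))


def _edge_strengths(spec: GroundTruthSpec, z: float, condition: str) -> list[PlantedEdge]:
    shift = spec.reinterpret_power_shift if condition == "reinterpret" else 0.0
    edges = []
    for e in spec.planted_edges:
        factor = _power_factor(z, spec.edge_loading(e), spec.latent_floor, shift)
        edges.append(replace(e, strength=float(e.strength * np.sqrt(factor))))
    return edges


def simulate_cohort(spec: GroundTruthSpec) -> CohortBundle:
    """Draw the full cohort: one latent trait per participant scales the
    planted edge powers, LF modulation power, ratings, error rates, and
    anxiety; all per-participant signals are then simulated."""
    root = np.random.SeedSequence(spec.seed)
    ss_z, ss_freq, ss_participants = root.spawn(3)
    z_all = np.random.default_rng(ss_z).standard_normal(spec.n_participants)
    freq_rng = np.random.default_rng(ss_freq)
    bands_used = sorted({e.band for e in spec.planted_edges})
    peak_freqs = {
        band: _band_center(band) + freq_rng.uniform(
            -spec.peak_freq_jitter_hz, spec.peak_freq_jitter_hz,
            spec.n_participants,
        )
        for band in bands_used
    }
    fs = spec.fs
    t0, t1 = spec.epoch_window_s
    n_samp = int(round((t1 - t0) * fs))
    times = t0 + np.arange(n_samp) / fs
    bl = spec.behavior_loadings
    participants = []
    for p, (z, ss_p) in enumerate(zip(z_all, ss_participants.spawn(spec.n_participants))):
        (ss_eeg_a, ss_eeg_r, ss_order, ss_rr_lo, ss_rr_hi,
         ss_rate, ss_out, ss_anx) = ss_p.spawn(8)
        center_freqs = {band: float(peak_freqs[band][p]) for band in bands_used}
        # --- EEG epochs per condition
        cond_epochs = {}
        strengths = {}
        for cond, ss_e in zip(LAB_CONDITIONS, (ss_eeg_a, ss_eeg_r)):
            edges = _edge_strengths(spec, z, cond)
            strengths[cond] = {e.key: e.strength for e in edges}
            model = make_band_coupled_var(
                spec.n_channels, edges, fs, channels=spec.channels,
                diag_ar=spec.diag_ar, pole_radius=spec.pole_radius,
                center_freqs=center_freqs, noise_sd=spec.noise_sds["eeg"],
            )
            sim = simulate_var_eeg(model, n_samp, ss_e,
                                   n_trials=spec.n_lab_trials)
            cond_epochs[cond] = sim if sim.ndim == 3 else sim[:, :, None]
        order_rng = np.random.default_rng(ss_order)
        labels = [c for c in LAB_CONDITIONS for _ in range(spec.n_lab_trials)]
        perm = order_rng.permutation(len(labels))
        epoch_conditions = [labels[k] for k in perm]
        all_epochs = np.concatenate(
            [cond_epochs[c] for c in LAB_CONDITIONS], axis=2
        )[:, :, perm]
        # --- RR per simulation condition (LF power linear in z)
        hrv_factor = _power_factor(z, spec.hrv_loading, spec.latent_floor)
        lf_amp = {
            "low": spec.base_lf_amp_ms * np.sqrt(hrv_factor),
            "high": (spec.base_lf_amp_ms + spec.high_stress_lf_shift_ms)
            * np.sqrt(hrv_factor),
        }
        rr_raw = {}
        for cond, ss_r in zip(SIM_CONDITIONS, (ss_rr_lo, ss_rr_hi)):
            rr_raw[cond] = simulate_rr(
                spec.rr_duration_s,
                mean_ibi_ms=spec.mean_ibi_ms,
                lf_amp_ms=float(lf_amp[cond]),
                hf_amp_ms=spec.base_hf_amp_ms,
                lf_freq=spec.lf_freq,
                hf_freq=spec.hf_freq,
                jitter_sd_ms=spec.noise_sds["rr_jitter_ms"],
                seed=ss_r,
                artifact_rate=spec.rr_artifact_rate,
            )
        # --- ratings
        rate_rng = np.random.default_rng(ss_rate)
        rating_rows = []
        intensity_mean = {}
        for cond in LAB_CONDITIONS:
            mu = spec.intensity_base[cond] + bl["intensity"] * z
            intensity_mean[cond] = mu
            vals = np.clip(
                np.rint(mu + spec.noise_sds["rating"]
                        * rate_rng.standard_normal(spec.n_lab_trials)),
                1, 9,
            ).astype(int)
            rating_rows += [
                {"trial": t, "condition": cond, "rating": int(v)}
                for t, v in enumerate(vals)
            ]
        ratings = pd.DataFrame(rating_rows)
        # --- simulation outcomes
        out_rng = np.random.default_rng(ss_out)
        outcome_rows = []
        err_rate = {}
        for cond in SIM_CONDITIONS:
            pe = float(np.clip(
                spec.error_rate_base[cond] + bl["error_rate"] * z, 0.01, 0.6
            ))
            err_rate[cond] = pe
            n = spec.n_sim_trials
            n_foe = n // 2
            for t in range(n):
                foe = t < n_foe
                err = out_rng.random() < pe
                if foe:
                    cat = "M" if err else "H"
                else:
                    cat = "FA" if err else "CR"
                outcome_rows.append({"trial": t, "condition": cond, "category": cat})
        outcomes = pd.DataFrame(outcome_rows)
        # --- anxiety raw counts
        anx_rng = np.random.default_rng(ss_anx)
        anxiety = {}
        for key, base in spec.anxiety_base.items():
            val = base + bl["anxiety"] * z + spec.noise_sds["anxiety"] \
                * anx_rng.standard_normal()
            anxiety[key] = int(np.clip(np.rint(val), 0, 10))
        truth = {"z": float(z)}
        for band in bands_used:
            truth[f"peak_freq_{band}"] = center_freqs[band]
        for cond in LAB_CONDITIONS:
            for key, s in strengths[cond].items():
                truth[f"strength_{cond}_{key}"] = s
        for cond in SIM_CONDITIONS:
            truth[f"lf_amp_{cond}"] = float(lf_amp[cond])
            truth[f"error_rate_{cond}"] = err_rate[cond]
        for cond in LAB_CONDITIONS:
            truth[f"intensity_mean_{cond}"] = intensity_mean[cond]
        participants.append(ParticipantData(
            participant=p,
            epochs=all_epochs,
            epoch_conditions=epoch_conditions,
            epoch_times=times,
            rr_raw=rr_raw,
            ratings=ratings,
            outcomes=outcomes,
            anxiety=anxiety,
            truth=truth,
        ))
    return CohortBundle(spec=spec, participants=participants)
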