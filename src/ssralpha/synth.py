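"""Synthetic generator for rhythmically driven, attention-modulated EEG.

Each simulated 3-s epoch is the sum of three components:

* **intrinsic alpha** (8-13 Hz): band-pass filtered Gaussian noise, so its
  phase is random from trial to trial (non-phase-locked by construction).
  Two hemispheric sources with smooth lateralized scalp profiles; the
  source contralateral to the attended hemifield is amplitude-suppressed,
  the ipsilateral one enhanced — the classic retinotopic alpha
  lateralization.
* **steady-state responses (SSRs)**: sinusoids at the two stimulation
  frequencies (10 Hz for the left-hemifield stimulus, projected to a
  right-hemisphere topography; 12 Hz for the right-hemifield stimulus,
  left-hemisphere topography).  SSR phase is fixed across trials up to
  Gaussian jitter, so the component is phase-locked.  Attending the
  driving stimulus's location multiplies the SSR amplitude by
  ``1 + ssr_attended_gain`` and can optionally shrink the phase jitter.
* **1/f^beta background noise**, independent across channels and trials.

The evoked (phase-locked) SSR power sits well below ongoing alpha power
(>= 10 dB with the defaults), which is what makes the ongoing/evoked
decomposition contrast interesting: trial averaging cancels the
random-phase alpha but preserves the weak SSR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.spatial import Delaunay

from .data import ATTEND_LEFT, ATTEND_RIGHT, Epochs, Montage

__all__ = [
    "SimParams",
    "GroundTruth",
    "generate_montage",
    "generate_epochs",
    "simulate_cohort",
    "spatial_profile",
]

#: default analysis frequency resolution (Hz); SSR frequencies must sit on it
DEFAULT_DF = 0.25

# seed directions for the lateralized scalp profiles (parieto-occipital for
# alpha, occipital for the SSRs), normalized in _unit()
_ALPHA_SEED_LEFT = (-0.55, -0.35, 0.76)
_ALPHA_SEED_RIGHT = (0.55, -0.35, 0.76)
_SSR_SEED_LEFT = (-0.30, -0.87, 0.39)
_SSR_SEED_RIGHT = (0.30, -0.87, 0.39)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass
class SimParams:
    """Generator settings.

    Amplitudes are in arbitrary signal units ("microvolt-equivalent"); the
    alpha amplitude is the standard deviation of the band-passed waveform
    at a profile peak, the SSR amplitude is the sinusoid's amplitude, and
    the noise amplitude is the broadband standard deviation per channel.
    Fractions (suppression / enhancement / gain) are relative amplitude
    changes.  Defaults reproduce the qualitative regime of interest:
    lateralized alpha modulation of a few dB and an evoked SSR roughly
    12 dB below ongoing alpha power.
    """

    n_trials_per_condition: int = 34
    n_channels: int = 32
    srate: float = 256.0
    epoch_len: float = 3.0
    alpha_band: tuple[float, float] = (8.0, 13.0)
    alpha_amp_base: float = 1.0
    alpha_suppression: float = 0.20
    alpha_enhancement: float = 0.10
    ssr_freqs: dict = field(default_factory=lambda: {"left_stim": 10.0, "right_stim": 12.0})
    ssr_amp_base: float = 0.09
    ssr_attended_gain: float = 0.30
    ssr_phase_jitter_sd: float = 0.4
    ssr_attended_jitter_factor: float = 0.45
    noise_exponent: float = 1.0
    noise_amp: float = 0.25
    trial_amp_sd: float = 0.2
    trial_coupling: float = 0.0
    profile_width: float = 0.35
    ssr_profile_width: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_condition < 1:
            raise ValueError("need at least one trial per condition")
        for name in ("alpha_amp_base", "ssr_amp_base", "noise_amp",
                     "alpha_suppression", "alpha_enhancement",
                     "ssr_attended_gain", "ssr_phase_jitter_sd",
                     "trial_amp_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        n_samp = self.epoch_len * self.srate
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("epoch_len * srate must be an integer")
        lo, hi = self.alpha_band
        if not (0 < lo < hi < self.srate / 2):
            raise ValueError("alpha_band must be within (0, Nyquist)")
        for f in self.ssr_freqs.values():
            if abs(f / DEFAULT_DF - round(f / DEFAULT_DF)) > 1e-9:
                raise ValueError(
                    f"SSR frequency {f} Hz is off the {DEFAULT_DF} Hz analysis grid")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_len * self.srate))


@dataclass
class GroundTruth:
    """Expected signs of the attended-vs-ignored contrasts injected by the
    generator: alpha band power drops contralateral to attention (-1),
    while evoked SSR power and phase coherence rise when the driving
    stimulus is attended (+1)."""

    expected_sign_onpow_alpha: int = -1
    expected_sign_evopow_ssr: int = +1
    expected_sign_itcz_ssr: int = +1

    def __post_init__(self) -> None:
        for s in (self.expected_sign_onpow_alpha,
                  self.expected_sign_evopow_ssr,
                  self.expected_sign_itcz_ssr):
            if s not in (-1, 0, 1):
                raise ValueError("signs must be in {-1, 0, +1}")


def generate_montage(n_channels: int, seed: int = 0) -> Montage:
    """Quasi-uniform upper-hemisphere montage with Delaunay adjacency.

    Channels are laid out on a Fibonacci spiral over the upper hemisphere
    (with a small seeded jitter) and neighbourhoods derive from the
    Delaunay triangulation of the (x, y) projection — the standard
    triangulated-proximity definition of sensor neighbours.
    """
    if n_channels < 8:
        raise ValueError("cluster-based statistics need at least 8 channels")
    rng = np.random.default_rng(seed)
    i = np.arange(n_channels)
    # z spans the upper hemisphere but avoids the rim and the pole
    z = 0.10 + 0.85 * (i + 0.5) / n_channels
    golden = np.pi * (3.0 - np.sqrt(5.0))
    az = golden * i
    r = np.sqrt(1.0 - z**2)
    pos = np.column_stack([r * np.cos(az), r * np.sin(az), z])
    pos += 0.01 * rng.standard_normal(pos.shape)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    tri = Delaunay(pos[:, :2])
    adj = np.zeros((n_channels, n_channels), dtype=bool)
    for simplex in tri.simplices:
        for a in simplex:
            for b in simplex:
                if a != b:
                    adj[a, b] = True
    names = [f"ch{i:02d}" for i in range(n_channels)]
    return Montage(positions=pos, adjacency=adj, names=names)


def spatial_profile(positions: np.ndarray, center, width: float) -> np.ndarray:
    """Gaussian-on-the-sphere scalp profile, 1 at ``center``.

    ``width`` is the angular standard deviation in radians; the default
    keeps the left/right profiles' overlap across the midline below 20 %.
    """
    c = _unit(center)
    ang = np.arccos(np.clip(positions @ c, -1.0, 1.0))
    return np.exp(-0.5 * (ang / width) ** 2)


def _alpha_source(rng: np.random.Generator, n_trials: int, n_samples: int,
                  band: tuple[float, float], srate: float) -> np.ndarray:
    """Band-passed Gaussian noise, unit standard deviation per trial."""
    sos = signal.butter(4, band, btype="bandpass", fs=srate, output="sos")
    x = rng.standard_normal((n_trials, n_samples))
    y = signal.sosfiltfilt(sos, x, axis=-1)
    sd = y.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def _pink_noise(rng: np.random.Generator, shape: tuple, n_samples: int,
                beta: float, srate: float) -> np.ndarray:
    """1/f^beta noise, unit standard deviation, shape + (n_samples,)."""
    n_freq = n_samples // 2 + 1
    f = np.fft.rfftfreq(n_samples, d=1.0 / srate)
    scale = np.zeros(n_freq)
    scale[1:] = f[1:] ** (-beta / 2.0)
    spec = (rng.standard_normal(shape + (n_freq,))
            + 1j * rng.standard_normal(shape + (n_freq,))) * scale
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_epochs(params: SimParams, montage: Montage,
                    rng: np.random.Generator | None = None
                    ) -> tuple[Epochs, GroundTruth]:
    """Simulate one subject's epoched EEG under the two attention cues.

    Returns the epochs (first all attend-left trials, then attend-right)
    and the ground-truth effect signs the analysis should recover.
    """
    if montage.n_channels != params.n_channels:
        raise ValueError("montage size does not match params.n_channels")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_trials_per_condition
    n_trials = 2 * n
    ns = params.n_samples
    t = np.arange(ns) / params.srate

    prof_alpha_l = spatial_profile(montage.positions, _ALPHA_SEED_LEFT, params.profile_width)
    prof_alpha_r = spatial_profile(montage.positions, _ALPHA_SEED_RIGHT, params.profile_width)
    prof_ssr_l = spatial_profile(montage.positions, _SSR_SEED_LEFT, params.ssr_profile_width)
    prof_ssr_r = spatial_profile(montage.positions, _SSR_SEED_RIGHT, params.ssr_profile_width)

    condition = np.array([ATTEND_LEFT] * n + [ATTEND_RIGHT] * n)
    attends_left = condition == ATTEND_LEFT

    # per-trial lognormal-free amplitude fluctuations (clipped linear)
    z_left = rng.standard_normal(n_trials)
    z_right = rng.standard_normal(n_trials)
    e_left = np.clip(1.0 + params.trial_amp_sd * z_left, 0.1, None)
    e_right = np.clip(1.0 + params.trial_amp_sd * z_right, 0.1, None)

    # SSR per-trial amplitude factors, optionally coupled to the alpha
    # left-right asymmetry (for coupling-recovery experiments)
    rho = params.trial_coupling
    lat = (z_left - z_right) / np.sqrt(2.0)
    w10 = rng.standard_normal(n_trials)
    w12 = rng.standard_normal(n_trials)
    u10 = rho * lat + np.sqrt(max(0.0, 1.0 - rho**2)) * w10
    u12 = rho * lat + np.sqrt(max(0.0, 1.0 - rho**2)) * w12
    g10 = np.clip(1.0 + params.trial_amp_sd * u10, 0.1, None)
    g12 = np.clip(1.0 + params.trial_amp_sd * u12, 0.1, None)

    # alpha: amplitude per (trial, hemisphere-source)
    supp, enh = params.alpha_suppression, params.alpha_enhancement
    # attend-left -> right source contralateral (suppressed), left ipsilateral
    amp_left_src = np.where(attends_left, 1.0 + enh, 1.0 - supp)
    amp_right_src = np.where(attends_left, 1.0 - supp, 1.0 + enh)
    alpha_l = _alpha_source(rng, n_trials, ns, params.alpha_band, params.srate)
    alpha_r = _alpha_source(rng, n_trials, ns, params.alpha_band, params.srate)
    alpha_l *= (params.alpha_amp_base * amp_left_src * e_left)[:, None]
    alpha_r *= (params.alpha_amp_base * amp_right_src * e_right)[:, None]

    # SSRs: fixed phase per frequency plus per-trial jitter
    f10 = params.ssr_freqs["left_stim"]
    f12 = params.ssr_freqs["right_stim"]
    phi10, phi12 = rng.uniform(0, 2 * np.pi, size=2)
    gain = params.ssr_attended_gain
    jf = params.ssr_attended_jitter_factor
    # 10 Hz driven by the left stimulus -> attended in attend-left trials
    att10 = attends_left
    att12 = ~attends_left
    jit10 = rng.standard_normal(n_trials) * params.ssr_phase_jitter_sd * np.where(att10, jf, 1.0)
    jit12 = rng.standard_normal(n_trials) * params.ssr_phase_jitter_sd * np.where(att12, jf, 1.0)
    amp10 = params.ssr_amp_base * np.where(att10, 1.0 + gain, 1.0) * g10
    amp12 = params.ssr_amp_base * np.where(att12, 1.0 + gain, 1.0) * g12
    ssr10 = amp10[:, None] * np.cos(2 * np.pi * f10 * t[None, :] + phi10 + jit10[:, None])
    ssr12 = amp12[:, None] * np.cos(2 * np.pi * f12 * t[None, :] + phi12 + jit12[:, None])

    data = (alpha_l[:, None, :] * prof_alpha_l[None, :, None]
            + alpha_r[:, None, :] * prof_alpha_r[None, :, None]
            # contralateral SSR projections: left stimulus -> right hemisphere
            + ssr10[:, None, :] * prof_ssr_r[None, :, None]
            + ssr12[:, None, :] * prof_ssr_l[None, :, None])
    if params.noise_amp > 0:
        data += params.noise_amp * _pink_noise(
            rng, (n_trials, montage.n_channels), ns,
            params.noise_exponent, params.srate)

    epochs = Epochs(data=data, srate=params.srate, condition=condition,
                    channel_names=list(montage.names), units="uV")
    return epochs, GroundTruth()


def simulate_cohort(n_subjects: int, params: SimParams, master_seed: int,
                    subject_amp_jitter: float = 0.2,
                    subject_effect_jitter: float = 0.3,
                    effect_coupling: float = 0.0,
                    montage: Montage | None = None
                    ) -> tuple[list[Epochs], Montage, GroundTruth]:
    """Simulate a cohort sharing one montage, one subject per child seed.

    Between-subject heterogeneity is injected as multiplicative jitter on
    the amplitude parameters (+-``subject_amp_jitter``) and on the effect
    fractions (+-``subject_effect_jitter``).  ``effect_coupling`` sets the
    correlation between a subject's alpha-suppression strength and SSR
    gain, enabling coupled-effect recovery experiments (default: the two
    effects are independent across subjects).
    """
    if montage is None:
        # the montage is the recording cap, common to all cohorts; only the
        # subjects vary with the master seed
        montage = generate_montage(params.n_channels, seed=0)
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(n_subjects + 1)
    meta_rng = np.random.default_rng(children[0])
    subjects = []
    for k in range(n_subjects):
        a = meta_rng.standard_normal()
        b_ = meta_rng.standard_normal()
        b = effect_coupling * a + np.sqrt(max(0.0, 1.0 - effect_coupling**2)) * b_
        amp_f = np.clip(1.0 + subject_amp_jitter * meta_rng.standard_normal(3), 0.2, None)
        supp = params.alpha_suppression * np.clip(1.0 + subject_effect_jitter * a, 0.05, None)
        gain = params.ssr_attended_gain * np.clip(1.0 + subject_effect_jitter * b, 0.05, None)
        p_k = replace(
            params,
            alpha_amp_base=params.alpha_amp_base * amp_f[0],
            ssr_amp_base=params.ssr_amp_base * amp_f[1],
            noise_amp=params.noise_amp * amp_f[2],
            alpha_suppression=min(supp, 0.95),
            ssr_attended_gain=gain,
        )
        rng = np.random.default_rng(children[k + 1])
        epochs, _ = generate_epochs(p_k, montage, rng=rng)
        subjects.append(epochs)
    return subjects, montage, GroundTruth()
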