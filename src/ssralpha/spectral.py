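"""Trial-wise Fourier decomposition and the three aggregate measures.

Given per-trial complex Fourier coefficients Z(trial, channel, f), three
aggregates summarize rhythmic activity across the n trials of a
condition:

* ``onPOW(f)  = (1/n) sum_i |Z_i(f)|^2``   — ongoing (classical) power:
  averaging powers keeps activity regardless of its phase across trials;
* ``evoPOW(f) = |(1/n) sum_i Z_i(f)|^2``  — evoked power: averaging the
  complex spectra first cancels non-phase-locked activity, identical to
  the power spectrum of the time-domain trial average;
* ``ITC(f)   = |(1/n) sum_i Z_i(f)/|Z_i(f)||`` — intertrial phase
  coherence: the resultant length of the per-trial unit phase vectors,
  i.e. pure phase locking with all amplitude information removed.

By Cauchy-Schwarz (and Jensen), ``evoPOW <= onPOW`` everywhere, and
``ITC`` lies in [0, 1].  ITC is mapped to the Rayleigh-z style
``ITCz = n * ITC^2`` to reduce the trial-count bias when comparing
conditions with different n (under uniform random phases E[ITCz] ~= 1
for any n).

Power maps are compared on the decibel scale, ``dB = 10 log10(power)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .data import Epochs

__all__ = [
    "SpectralSet", "MeasureMap", "detrend_taper", "fft_complex",
    "onpow", "evopow", "itc", "itcz", "to_db", "band_mean",
    "jackknife_single_trial",
]


@dataclass
class SpectralSet:
    """Per-trial one-sided complex spectra on a uniform frequency grid."""

    Z: np.ndarray                       # (trials, channels, freqs) complex
    freqs: np.ndarray                   # Hz, starting at 0
    condition: np.ndarray               # label per trial
    channel_names: list[str]
    n_samples_orig: int                 # pre-padding trial length

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.condition = np.asarray(self.condition)
        if self.Z.ndim != 3:
            raise ValueError("Z must be (trials, channels, freqs)")
        if self.Z.shape[0] < 1:
            raise ValueError("need at least one trial")
        steps = np.diff(self.freqs)
        if steps.size and not np.allclose(steps, steps[0]):
            raise ValueError("frequency grid must be uniform")

    @property
    def n_trials(self) -> int:
        return self.Z.shape[0]

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def select(self, condition: str) -> "SpectralSet":
        mask = self.condition == condition
        if not mask.any():
            raise ValueError(f"no trials with condition {condition!r}")
        return replace(self, Z=self.Z[mask], condition=self.condition[mask])

    def freq_index(self, f: float) -> int:
        i = int(round((f - self.freqs[0]) / self.df))
        if not (0 <= i < len(self.freqs)) or abs(self.freqs[i] - f) > 1e-6:
            raise ValueError(f"{f} Hz is not on the frequency grid")
        return i


@dataclass
class MeasureMap:
    """Per-(channel, frequency) scalar map of one aggregate measure."""

    values: np.ndarray
    measure: str                        # onPOW | evoPOW | ITC | ITCz
    scale: str                          # linear | dB | a.u.
    freqs: np.ndarray | None = None
    channel_names: list[str] = field(default_factory=list)
    n_trials: int | None = None
    n_excluded: int = 0                 # zero-amplitude trials dropped (ITC)


def detrend_taper(epochs: Epochs, taper_ratio: float = 0.1) -> Epochs:
    """Remove mean and linear trend per trial/channel, then apply a Tukey
    (tapered-cosine) window; ``taper_ratio=0`` degenerates to a
    rectangular window."""
    if not (0.0 <= taper_ratio <= 1.0):
        raise ValueError("taper_ratio must be in [0, 1]")
    if epochs.n_samples < 2:
        raise ValueError("trials must have at least 2 samples")
    x = signal.detrend(epochs.data, axis=-1, type="linear")
    win = signal.windows.tukey(epochs.n_samples, alpha=taper_ratio, sym=True)
    return epochs.copy_with(data=x * win)


def fft_complex(epochs: Epochs, df: float = 0.25) -> SpectralSet:
    """Zero-padded one-sided FFT of every trial at resolution ``df``.

    Trials are zero-padded to ``srate/df`` samples.  Coefficients are
    scaled to sinusoid amplitude (an on-grid unit-amplitude cosine
    spanning the un-padded trial gives |Z| = 1 at its frequency), which
    keeps power maps comparable across epoch lengths.
    """
    if epochs.n_trials == 0:
        raise ValueError("empty epochs")
    nfft_f = epochs.srate / df
    nfft = int(round(nfft_f))
    if abs(nfft_f - nfft) > 1e-9:
        raise ValueError("srate/df must be an integer number of samples")
    if nfft < epochs.n_samples:
        raise ValueError("df too coarse: padding target shorter than trial")
    Z = np.fft.rfft(epochs.data, n=nfft, axis=-1) * (2.0 / epochs.n_samples)
    Z[..., 0] *= 0.5  # DC carries no conjugate-symmetric twin
    freqs = np.fft.rfftfreq(nfft, d=1.0 / epochs.srate)
    return SpectralSet(Z=Z, freqs=freqs, condition=epochs.condition.copy(),
                       channel_names=list(epochs.channel_names),
                       n_samples_orig=epochs.n_samples)


def _common_meta(S: SpectralSet) -> dict:
    return dict(freqs=S.freqs.copy(), channel_names=list(S.channel_names),
                n_trials=S.n_trials)


def onpow(S: SpectralSet) -> MeasureMap:
    """Ongoing power: mean over trials of squared coefficient magnitudes."""
    vals = np.mean(np.abs(S.Z) ** 2, axis=0)
    return MeasureMap(values=vals, measure="onPOW", scale="linear", **_common_meta(S))


def evopow(S: SpectralSet) -> MeasureMap:
    """Evoked power: squared magnitude of the trial-averaged spectrum."""
    vals = np.abs(np.mean(S.Z, axis=0)) ** 2
    return MeasureMap(values=vals, measure="evoPOW", scale="linear", **_common_meta(S))


def itc(S: SpectralSet) -> MeasureMap:
    """Intertrial phase coherence, excluding zero-amplitude coefficients.

    A coefficient with |Z| = 0 has no defined phase; such trials are
    excluded at the affected (channel, frequency) cells and the total
    number of exclusions is recorded on the returned map.
    """
    mag = np.abs(S.Z)
    ok = mag > 0
    u = np.zeros_like(S.Z)
    np.divide(S.Z, mag, out=u, where=ok)
    counts = ok.sum(axis=0)
    resultant = np.abs(u.sum(axis=0))
    vals = np.zeros(resultant.shape)
    np.divide(resultant, counts, out=vals, where=counts > 0)
    n_excluded = int(S.n_trials * counts.size - counts.sum())
    m = MeasureMap(values=vals, measure="ITC", scale="a.u.", **_common_meta(S))
    m.n_excluded = n_excluded
    return m


def itcz(itc_map: MeasureMap, n: int, variant: str = "rayleigh") -> MeasureMap:
    """Trial-count bias correction of ITC.

    ``rayleigh`` (default): ITCz = n * ITC^2, the Rayleigh z statistic —
    its expectation under uniform random phases is ~1 for any n.
    ``unbiased``: (n - 1) * ITC^2 - 1, an alternative de-biasing
    convention exposed for comparison.
    """
    if itc_map.measure != "ITC":
        raise ValueError("itcz expects an ITC map")
    if n < 1:
        raise ValueError("n must be >= 1")
    if variant == "rayleigh":
        vals = n * itc_map.values**2
    elif variant == "unbiased":
        vals = (n - 1) * itc_map.values**2 - 1.0
    else:
        raise ValueError(f"unknown ITCz variant {variant!r}")
    return MeasureMap(values=vals, measure="ITCz", scale="a.u.",
                      freqs=None if itc_map.freqs is None else itc_map.freqs.copy(),
                      channel_names=list(itc_map.channel_names), n_trials=n,
                      n_excluded=itc_map.n_excluded)


def to_db(m: MeasureMap) -> MeasureMap:
    """Decibel scale: 10 * log10(value); strictly positive input required."""
    if m.scale == "dB":
        raise ValueError("map is already in dB")
    if np.any(m.values <= 0):
        raise ValueError("nonpositive values cannot be converted to dB")
    return replace(m, values=10.0 * np.log10(m.values), scale="dB")


def band_mean(m: MeasureMap, band: tuple[float, float]) -> np.ndarray:
    """Per-channel mean over grid frequencies in [band_lo, band_hi]
    (inclusive endpoints).  Applied to dB maps for the alpha statistics."""
    if m.freqs is None:
        raise ValueError("map has no frequency axis")
    lo, hi = band
    sel = (m.freqs >= lo - 1e-9) & (m.freqs <= hi + 1e-9)
    if not sel.any():
        raise ValueError("band contains no grid frequencies")
    return m.values[..., sel].mean(axis=-1)


def jackknife_single_trial(S: SpectralSet, measure: str, *,
                           band: tuple[float, float] | None = None,
                           freq: float | None = None,
                           itcz_variant: str = "rayleigh") -> np.ndarray:
    """Leave-one-out single-trial estimates of a trial-aggregate measure.

    ``measure`` is one of:

    * ``"onpow_band"`` — band mean of dB ongoing power (needs ``band``);
    * ``"evopow"``     — dB evoked power at ``freq``;
    * ``"itcz"``       — ITCz at ``freq``.

    Estimate i is the measure recomputed on all trials except trial i;
    the result is a ``(n_trials, n_channels)`` array.  ITC (and hence
    ITCz) has no single-trial definition, which is what motivates the
    jackknife; power measures get the same treatment for comparability.
    """
    n = S.n_trials
    if n < 3:
        raise ValueError("jackknife needs at least 3 trials")
    if measure == "onpow_band":
        if band is None:
            raise ValueError("onpow_band requires band=(lo, hi)")
        sel = (S.freqs >= band[0] - 1e-9) & (S.freqs <= band[1] + 1e-9)
        if not sel.any():
            raise ValueError("band contains no grid frequencies")
        P = np.abs(S.Z[..., sel]) ** 2            # (trials, ch, bins)
        loo = (P.sum(axis=0)[None] - P) / (n - 1)
        return 10.0 * np.log10(loo).mean(axis=-1)
    if measure == "evopow":
        if freq is None:
            raise ValueError("evopow requires freq=")
        k = S.freq_index(freq)
        Zf = S.Z[:, :, k]
        loo = np.abs(Zf.sum(axis=0)[None] - Zf) ** 2 / (n - 1) ** 2
        return 10.0 * np.log10(loo)
    if measure == "itcz":
        if freq is None:
            raise ValueError("itcz requires freq=")
        k = S.freq_index(freq)
        Zf = S.Z[:, :, k]
        mag = np.abs(Zf)
        if np.any(mag == 0):
            raise ValueError("zero-amplitude coefficient: ITC jackknife undefined")
        u = Zf / mag
        r_loo = np.abs(u.sum(axis=0)[None] - u) / (n - 1)
        if itcz_variant == "rayleigh":
            return (n - 1) * r_loo**2
        if itcz_variant == "unbiased":
            return (n - 2) * r_loo**2 - 1.0
        raise ValueError(f"unknown ITCz variant {itcz_variant!r}")
    raise ValueError(f"unknown measure {measure!r}")
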