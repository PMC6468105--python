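"""Subject-level single-trial covariation of alpha lateralization and SSR
attentional modulation.

Within each subject, leave-one-out (jackknife) single-trial estimates of
(i) the hemispheric alpha-band power lateralization and (ii) an SSR
measure (evoked power or ITCz at one driving frequency) are formed, the
attention effect is expressed as all pairwise differences between trials
of the two cue conditions (identical trial pairs for both measures), the
two z-scored difference distributions are related by a per-sensor robust
linear regression, and the per-subject slopes are tested against zero at
the group level (cluster permutation across sensors plus per-sensor JZS
Bayes factors).

Note on jackknife sign conventions: a leave-one-out estimate varies
inversely with the left-out trial's contribution, so a statistic that
correlates a jackknifed variable with a raw single-trial variable must
be sign-inverted.  Here *both* variables are jackknifed, the two
inversions cancel, and slopes keep their natural sign (exposed as
``jackknife_sign_invert`` for the mixed case).

The pairwise-difference pools are massively dependent (n_a * n_b pairs
from n_a + n_b trials), so no inference is ever drawn on the pools
themselves — only on the per-subject slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import logging

import numpy as np

from .bayes import BayesResult, jzs_ttest_bf
from .cluster import ClusterResult, cluster_permutation_test
from .data import ATTEND_LEFT, ATTEND_RIGHT, Montage
from .spectral import SpectralSet, jackknife_single_trial

__all__ = ["RegressionResult", "pairwise_condition_differences", "zscore",
           "robust_fit", "subject_level_regression"]

logger = logging.getLogger(__name__)

BISQUARE_C = 4.685
MAD_NORM = 0.6745


@dataclass
class RegressionResult:
    """Per-subject, per-channel robust slopes plus group-level tests."""

    beta: np.ndarray                    # (subjects, channels)
    intercept: np.ndarray
    weights_converged: np.ndarray       # bool (subjects, channels)
    group_clusters: ClusterResult | None = None
    bf_map: list[BayesResult] = field(default_factory=list)
    channel_names: list[str] = field(default_factory=list)
    measure: str = ""
    freq: float | None = None

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "freq": self.freq,
            "channel_names": self.channel_names,
            "beta": self.beta.tolist(),
            "intercept": self.intercept.tolist(),
            "weights_converged": self.weights_converged.tolist(),
            "group_clusters": (None if self.group_clusters is None
                               else self.group_clusters.to_dict(self.channel_names)),
            "bf_map": [b.to_dict() for b in self.bf_map],
        }


def pairwise_condition_differences(est_a: np.ndarray, est_b: np.ndarray) -> np.ndarray:
    """All ordered differences ``a_i - b_j``.

    1-D inputs give an ``(n_a * n_b,)`` vector; 2-D ``(trials, channels)``
    inputs give ``(n_a * n_b, channels)``.  The pair ordering (index of a
    major, index of b minor) is fixed, so difference vectors computed for
    different measures from the same trials stay aligned pair-for-pair.
    """
    a = np.asarray(est_a, dtype=float)
    b = np.asarray(est_b, dtype=float)
    if a.ndim != b.ndim or a.ndim not in (1, 2):
        raise ValueError("inputs must both be 1-D or both 2-D")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 trials per condition")
    if a.ndim == 1:
        return (a[:, None] - b[None, :]).reshape(-1)
    if a.shape[1] != b.shape[1]:
        raise ValueError("channel dimensions differ")
    d = a[:, None, :] - b[None, :, :]
    return d.reshape(-1, a.shape[1])


def zscore(v: np.ndarray, axis: int = 0) -> np.ndarray:
    """Standardize to mean 0, SD 1 (ddof=1); errors on zero variance."""
    v = np.asarray(v, dtype=float)
    sd = v.std(axis=axis, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance input cannot be z-scored")
    return (v - v.mean(axis=axis, keepdims=True)) / sd


def robust_fit(x: np.ndarray, y: np.ndarray, tol: float = 1e-8,
               max_iter: int = 50) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Robust line fit by IRLS with the Tukey bisquare weight function.

    Mirrors the common robust-regression default: tuning constant 4.685,
    scale = median absolute residual / 0.6745, intercept included,
    iterated until the relative coefficient change drops below ``tol``
    (or ``max_iter``; non-convergence returns the last iterate with a
    cleared flag).  ``y`` may be ``(n,)`` or ``(n, k)`` for k response
    columns sharing the same ``x`` — all columns are fit at once.

    Returns ``(slope, intercept, converged)`` with shapes ``(k,)`` (or
    scalars for 1-D ``y``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scalar_out = y.ndim == 1
    Y = y[:, None] if scalar_out else y
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    if Y.shape[0] != n:
        raise ValueError("x and y lengths differ")

    def wls(w):
        # closed-form weighted LS for [intercept, slope], per column
        sw = w.sum(axis=0)
        swx = (w * x[:, None]).sum(axis=0)
        swxx = (w * x[:, None] ** 2).sum(axis=0)
        swy = (w * Y).sum(axis=0)
        swxy = (w * x[:, None] * Y).sum(axis=0)
        det = sw * swxx - swx**2
        det = np.where(det == 0, np.nan, det)
        slope = (sw * swxy - swx * swy) / det
        inter = (swxx * swy - swx * swxy) / det
        return slope, inter

    w = np.ones_like(Y)
    slope, inter = wls(w)
    converged = np.zeros(Y.shape[1], dtype=bool)
    for _ in range(max_iter):
        resid = Y - inter[None, :] - slope[None, :] * x[:, None]
        scale = np.median(np.abs(resid), axis=0) / MAD_NORM
        exact = scale <= np.finfo(float).eps * np.abs(Y).max(initial=1.0)
        scale = np.where(exact, 1.0, scale)
        u = resid / (BISQUARE_C * scale[None, :])
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        w[:, exact] = 1.0
        new_slope, new_inter = wls(w)
        denom = np.maximum(np.abs(slope), np.abs(inter)) + 1e-300
        change = np.maximum(np.abs(new_slope - slope), np.abs(new_inter - inter)) / denom
        slope, inter = new_slope, new_inter
        converged |= (change < tol) | exact
        if converged.all():
            break
    if not converged.all():
        logger.warning("robust_fit: %d column(s) did not converge in %d iterations",
                       int((~converged).sum()), max_iter)
    slope = np.nan_to_num(slope)
    inter = np.nan_to_num(inter)
    if scalar_out:
        return float(slope[0]), float(inter[0]), bool(converged[0])
    return slope, inter, converged


def subject_level_regression(
    spectra: list[SpectralSet],
    montage: Montage,
    measure: str,
    freq: float,
    alpha_band: tuple[float, float] = (8.0, 13.0),
    left_cluster: np.ndarray | None = None,
    right_cluster: np.ndarray | None = None,
    n_perm: int = 5000,
    cluster_alpha: float = 0.05,
    cauchy_scale: float = 0.5,
    itcz_variant: str = "rayleigh",
    jackknife_sign_invert: bool = False,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    compute_bf: bool = True,
) -> RegressionResult:
    """Run the full subject-level covariation analysis for one SSR measure
    (``"evopow"`` or ``"itcz"``) at one driving frequency.

    ``left_cluster`` / ``right_cluster`` are channel-index sets defining
    the hemispheric alpha aggregates (typically the clusters from the
    group alpha analysis); they default to all posterior left/right
    channels when not given.
    """
    if len(spectra) < 3:
        raise ValueError("need at least 3 subjects")
    if measure not in ("evopow", "itcz"):
        raise ValueError("measure must be 'evopow' or 'itcz'")
    if left_cluster is None or len(left_cluster) == 0:
        left_cluster = montage.left_channels
        logger.info("no left alpha cluster supplied; using all left-hemisphere channels")
    if right_cluster is None or len(right_cluster) == 0:
        right_cluster = montage.right_channels
        logger.info("no right alpha cluster supplied; using all right-hemisphere channels")
    left_cluster = np.asarray(left_cluster, dtype=int)
    right_cluster = np.asarray(right_cluster, dtype=int)
    n_ch = montage.n_channels
    n_subj = len(spectra)
    if rng is None:
        rng = np.random.default_rng(seed)

    beta = np.zeros((n_subj, n_ch))
    inter = np.zeros((n_subj, n_ch))
    conv = np.zeros((n_subj, n_ch), dtype=bool)
    for s, S in enumerate(spectra):
        Sa, Sb = S.select(ATTEND_LEFT), S.select(ATTEND_RIGHT)
        # x: jackknife alpha lateralization (left minus right cluster mean)
        lat = []
        for Sc in (Sa, Sb):
            jk = jackknife_single_trial(Sc, "onpow_band", band=alpha_band)
            lat.append(jk[:, left_cluster].mean(axis=1)
                       - jk[:, right_cluster].mean(axis=1))
        x = zscore(pairwise_condition_differences(lat[0], lat[1]))
        # y: jackknife SSR measure per channel, aligned pairs
        kw = dict(freq=freq) if measure == "evopow" else dict(freq=freq, itcz_variant=itcz_variant)
        ya = jackknife_single_trial(Sa, measure, **kw)
        yb = jackknife_single_trial(Sb, measure, **kw)
        y = zscore(pairwise_condition_differences(ya, yb), axis=0)
        beta[s], inter[s], conv[s] = robust_fit(x, y)
    if jackknife_sign_invert:
        beta = -beta

    zeros = np.zeros_like(beta)
    clusters = cluster_permutation_test(beta, zeros, montage, n_perm=n_perm,
                                        cluster_alpha=cluster_alpha, rng=rng)
    bf_map = []
    if compute_bf:
        for c in range(n_ch):
            bf_map.append(jzs_ttest_bf(beta[:, c], cauchy_scale=cauchy_scale))
    return RegressionResult(beta=beta, intercept=inter, weights_converged=conv,
                            group_clusters=clusters, bf_map=bf_map,
                            channel_names=list(montage.names),
                            measure=measure, freq=freq)
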