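"""Sensor-space cluster-based permutation tests for paired contrasts.

Family-wise error over channels is controlled by the standard
cluster-mass permutation scheme for paired designs: per-channel paired t
values are thresholded at the two-tailed critical value, suprathreshold
channels of equal sign are grouped into connected components of the
montage adjacency, and each cluster's summed t (``t_sum``) is compared
against the permutation distribution of the most extreme cluster mass
obtained under random within-subject condition swaps (sign flips of the
per-subject difference maps).  Positive clusters are referred to the
distribution of the per-permutation maximum positive cluster mass and
negative clusters to the minimum; the resulting one-tailed Monte-Carlo p
values are doubled (capped at 1) to correct for two-sided testing.  The
observed labeling is always included in the null, so p >= 1/(n_perm+1).

Cluster membership is a deterministic function of the data; only the p
values are Monte-Carlo (and reproducible through ``seed``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import Montage

__all__ = ["Cluster", "ClusterResult", "paired_t_map", "cluster_permutation_test"]

logger = logging.getLogger(__name__)

#: stand-in for an infinite t at a zero-variance channel
LARGE_T = 1e6


@dataclass
class Cluster:
    channels: np.ndarray          # member channel indices
    t_sum: float
    p: float
    sign: int

    def to_dict(self, names: list[str] | None = None) -> dict:
        ch = [names[i] for i in self.channels] if names else self.channels.tolist()
        return {"channels": ch, "t_sum": float(self.t_sum),
                "p": float(self.p), "sign": int(self.sign)}


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_permutations: int
    cluster_alpha: float
    t_map: np.ndarray = field(default=None)
    threshold: float = float("nan")

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]

    def to_dict(self, names: list[str] | None = None) -> dict:
        return {"n_permutations": self.n_permutations,
                "cluster_alpha": self.cluster_alpha,
                "threshold": float(self.threshold),
                "clusters": [c.to_dict(names) for c in self.clusters]}


def paired_t_map(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-channel paired t of ``a - b`` against zero, df = n_subjects - 1.

    Zero-variance channels yield t = sign * LARGE_T (or 0 when the
    difference itself is zero) instead of +-inf, and are logged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("a and b must have the same shape")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    return _t_from_diffs(a - b)


def _t_from_diffs(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    t = np.zeros_like(m)
    ok = sd > 0
    t[ok] = m[ok] * np.sqrt(n) / sd[ok]
    bad = ~ok & (m != 0)
    if bad.any():
        logger.warning("zero-variance difference at %d channel(s); using +-%g",
                       int(bad.sum()), LARGE_T)
        t[bad] = np.sign(m[bad]) * LARGE_T
    return t


def _components(mask: np.ndarray, neighbors: list[np.ndarray]) -> list[np.ndarray]:
    """Connected components of the suprathreshold channel set."""
    comps = []
    seen = np.zeros(mask.shape[0], dtype=bool)
    for start in np.flatnonzero(mask):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in neighbors[u]:
                if mask[v] and not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(np.array(sorted(comp)))
    return comps


def _cluster_masses(t: np.ndarray, thr: float, neighbors: list[np.ndarray]
                    ) -> tuple[list[np.ndarray], list[float]]:
    """Clusters of equal-sign suprathreshold channels and their t sums."""
    chans, sums = [], []
    for sign in (1, -1):
        mask = t > thr if sign == 1 else t < -thr
        if not mask.any():
            continue
        for comp in _components(mask, neighbors):
            chans.append(comp)
            sums.append(float(t[comp].sum()))
    return chans, sums


def _max_masses(t: np.ndarray, thr: float, neighbors: list[np.ndarray]
                ) -> tuple[float, float]:
    """(max positive, min negative) cluster mass of one permuted t map."""
    _, sums = _cluster_masses(t, thr, neighbors)
    pos = max((s for s in sums if s > 0), default=0.0)
    neg = min((s for s in sums if s < 0), default=0.0)
    return pos, neg


def cluster_permutation_test(a: np.ndarray, b: np.ndarray, montage: Montage,
                             n_perm: int = 5000, cluster_alpha: float = 0.05,
                             two_sided: bool = True,
                             seed: int | None = None,
                             rng: np.random.Generator | None = None
                             ) -> ClusterResult:
    """Cluster-mass permutation test of paired maps ``a`` vs ``b``.

    ``a`` and ``b`` are (subjects, channels) arrays of the same
    within-subject measure under the two conditions; ``cluster_alpha`` is
    the two-tailed per-channel threshold used to form clusters.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("a and b must have the same shape")
    n_subj, n_ch = a.shape
    if n_ch != montage.n_channels:
        raise ValueError("maps do not match the montage channel count")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if rng is None:
        rng = np.random.default_rng(seed)

    diffs = a - b
    df = n_subj - 1
    thr = stats.t.ppf(1.0 - cluster_alpha / 2.0, df)
    neighbors = montage.neighbor_lists()

    t_obs = _t_from_diffs(diffs)
    chans, sums = _cluster_masses(t_obs, thr, neighbors)

    # vectorized permutation t maps: the flipped per-channel second moment
    # is unchanged, so only the flipped mean must be recomputed
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    ssq = np.sum(diffs**2, axis=0)                       # (ch,)
    M = signs @ diffs / n_subj                           # (perm, ch)
    var = (ssq[None, :] - n_subj * M**2) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        T = M * np.sqrt(n_subj) / np.sqrt(var / 1.0)
    T = np.where(np.isfinite(T), T, np.sign(M) * LARGE_T)

    null_pos = np.empty(n_perm + 1)
    null_neg = np.empty(n_perm + 1)
    null_pos[0], null_neg[0] = _max_masses(t_obs, thr, neighbors)
    any_supra = np.any(np.abs(T) > thr, axis=1)
    for i in range(n_perm):
        if any_supra[i]:
            null_pos[i + 1], null_neg[i + 1] = _max_masses(T[i], thr, neighbors)
        else:
            null_pos[i + 1] = null_neg[i + 1] = 0.0

    clusters = []
    for comp, s in zip(chans, sums):
        if s > 0:
            p1 = np.mean(null_pos >= s)
        else:
            p1 = np.mean(null_neg <= s)
        p = min(1.0, 2.0 * p1) if two_sided else p1
        clusters.append(Cluster(channels=comp, t_sum=s, p=float(p),
                                sign=1 if s > 0 else -1))
    clusters.sort(key=lambda c: abs(c.t_sum), reverse=True)
    return ClusterResult(clusters=clusters, n_permutations=n_perm,
                         cluster_alpha=cluster_alpha, t_map=t_obs, threshold=thr)
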