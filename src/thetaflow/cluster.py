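"""Paired cluster-based permutation testing on time-frequency maps.

Family-wise control over a 2-D time-frequency grid via the size of
contiguous suprathreshold clusters: a paired t-statistic is computed per
voxel across observations (channels, or trials in individual-subject
mode); the observed t-map is ranked against a permutation null built by
flipping each observation's condition labels independently with
probability 1/2; voxels with two-sided rank p below the cluster-forming
threshold are grouped into connected components separately for positive
and negative t, and each observed cluster's size is compared with the
null distribution of per-permutation maximum cluster sizes of the same
sign (significant above the 95th percentile).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


@dataclass
class Cluster:
    """One suprathreshold connected component."""

    mask: np.ndarray       # (n_freqs, n_times) bool
    size: int
    sign: int              # +1 or -1
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


@dataclass
class ClusterSet:
    """All clusters plus the voxel-level p-map and the null summaries."""

    clusters: list
    p_map: np.ndarray
    t_map: np.ndarray
    null_max_pos: np.ndarray
    null_max_neg: np.ndarray
    forming_p: float
    connectivity: int
    n_perm: int

    @property
    def significant(self) -> list:
        return [c for c in self.clusters if c.significant]

    def to_frame(self, freqs=None, times=None):
        """Tab-separated-ready voxel list (freq, time, cluster id, p)."""
        import pandas as pd
        rows = []
        for cid, cl in enumerate(self.clusters):
            fi, ti = np.nonzero(cl.mask)
            for f, t in zip(fi, ti):
                rows.append({
                    "freq_Hz": freqs[f] if freqs is not None else f,
                    "time_s": times[t] if times is not None else t,
                    "cluster_id": cid,
                    "sign": cl.sign,
                    "cluster_p": cl.p_value,
                })
        return pd.DataFrame(rows)


def paired_tmap(zmaps_a: np.ndarray, zmaps_b: np.ndarray) -> np.ndarray:
    """Per-voxel paired t across observations.

    Inputs have shape (n_obs, n_freqs, n_times), paired per observation.
    Voxels where any observation is non-finite come out NaN.
    """
    a = np.asarray(zmaps_a, dtype=float)
    b = np.asarray(zmaps_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have identical shape")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return t


def permutation_null(zmaps_a: np.ndarray, zmaps_b: np.ndarray,
                     n_perm: int = 1000, seed: int = 0) -> np.ndarray:
    """Null t-map stack from random per-observation condition flips.

    Each permutation independently swaps each observation's A/B labels
    with probability 1/2 (sign flip of the paired difference), the
    standard paired exchange.  Returns (n_perm, n_freqs, n_times).
    """
    a = np.asarray(zmaps_a, dtype=float)
    b = np.asarray(zmaps_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have identical shape")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d = (a - b).reshape(n, -1)
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    mean = signs @ d / n
    msq = (d * d).mean(axis=0)                    # sign-invariant
    var = (msq[None, :] - mean ** 2) * n / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    return t.reshape((n_perm,) + zmaps_a.shape[1:])


def _max_cluster_size(supra: np.ndarray, structure) -> int:
    if not supra.any():
        return 0
    labels, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def cluster_correct(t_map: np.ndarray, null_t: np.ndarray,
                    forming_p: float = 0.05,
                    connectivity: int = 8) -> ClusterSet:
    """Form suprathreshold clusters and assign permutation p-values.

    Voxel p-values are two-sided ranks of |t| within the null |t| at the
    same voxel.  Suprathreshold voxels (p < ``forming_p``) are grouped
    into connected components (8-neighborhood default) separately for
    positive and negative t; each observed cluster's size is compared to
    the null distribution of per-permutation maximum cluster sizes of the
    matching sign (cluster p = fraction of null maxima >= observed size).
    An empty ClusterSet (no suprathreshold voxels) is a valid outcome.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    from scipy.stats import rankdata

    structure = _STRUCTURES[connectivity]
    n_perm = null_t.shape[0]
    abs_null = np.abs(null_t)
    # observed voxel p: fraction of null |t| >= |t_obs|; the tolerance
    # counts float-level ties (e.g. the observed sign pattern recurring
    # among permutations, computed along a different arithmetic path)
    abs_obs = np.abs(t_map)[None]
    tol = 1e-9 * abs_obs + 1e-12
    p_map = (abs_null >= abs_obs - tol).mean(axis=0)
    # per-permutation voxel p: count of null values >= own value
    # (ties included via min-rank; p in [1/n_perm, 1])
    min_rank = rankdata(abs_null, method="min", axis=0)
    p_null = (n_perm - min_rank + 1) / n_perm

    null_max_pos = np.empty(n_perm, dtype=int)
    null_max_neg = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        supra = p_null[i] < forming_p
        null_max_pos[i] = _max_cluster_size(supra & (null_t[i] > 0),
                                            structure)
        null_max_neg[i] = _max_cluster_size(supra & (null_t[i] < 0),
                                            structure)

    clusters: list[Cluster] = []
    supra_obs = (p_map < forming_p) & np.isfinite(t_map)
    for sign, null_max in ((1, null_max_pos), (-1, null_max_neg)):
        part = supra_obs & (np.sign(t_map) == sign)
        labels, n_cl = ndimage.label(part, structure=structure)
        for cid in range(1, n_cl + 1):
            mask = labels == cid
            size = int(mask.sum())
            p_val = float((null_max >= size).mean())
            clusters.append(Cluster(mask=mask, size=size, sign=sign,
                                    p_value=p_val))
    clusters.sort(key=lambda c: c.p_value)
    return ClusterSet(clusters=clusters, p_map=p_map, t_map=t_map,
                      null_max_pos=null_max_pos, null_max_neg=null_max_neg,
                      forming_p=forming_p, connectivity=connectivity,
                      n_perm=n_perm)
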