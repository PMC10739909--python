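"""Condition-contrast statistics: permutation tests, FDR, RM-ANOVA.

Paired non-parametric permutation testing (observations are channels,
channel pairs, or trials), Benjamini-Hochberg false-discovery-rate
correction at q = 0.05, effect reporting as the difference of group
means, and a two-way repeated-measures ANOVA (time, time x condition)
with the most conservative lower-bound sphericity adjustment
(epsilon = 1/(k-1)) for the time-resolved PTE analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats


@dataclass
class PermTestResult:
    """Outcome of one paired permutation test."""

    observed: float            # mean(A) - mean(B), the reported "effect"
    p_value: float
    n_perm: int
    sided: str
    n_obs: int
    unit: str = "observations"


def paired_permutation_test(values_a, values_b, n_perm: int = 1000,
                            sided: str = "two", seed: int = 0,
                            add_one: bool = False,
                            unit: str = "observations") -> PermTestResult:
    """Paired permutation test by random sign flips of pair differences.

    Each permutation independently flips each pair's condition labels
    with probability 1/2.  Two-sided: ``p = #(|null| >= |observed|) /
    n_perm`` (the plain count ratio; ``add_one`` switches to the
    (b+1)/(m+1) convention that cannot return 0).  One-sided
    (``sided="greater"``) counts ``null >= observed``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired inputs must be equal-length 1-D vectors")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if sided not in ("two", "greater", "less"):
        raise ValueError(f"unknown sidedness {sided!r}")
    d = a - b
    observed = float(d.mean())
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_perm, n)) * 2 - 1
    null = (signs * d[None, :]).mean(axis=1)
    if sided == "two":
        count = int((np.abs(null) >= abs(observed)).sum())
    elif sided == "greater":
        count = int((null >= observed).sum())
    else:
        count = int((null <= observed).sum())
    p = (count + 1) / (n_perm + 1) if add_one else count / n_perm
    return PermTestResult(observed=observed, p_value=float(p),
                          n_perm=n_perm, sided=sided, n_obs=n, unit=unit)


def fdr_correct(pvalues, q: float = 0.05):
    """Benjamini-Hochberg step-up correction.

    Returns ``(flags, threshold)``: per-test significance flags and the
    largest raw p-value passing the step-up rule (NaN when none pass) --
    the "p_FDR threshold" reporting style.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    flags = multipletests(p, alpha=q, method="fdr_bh")[0]
    threshold = float(p[flags].max()) if flags.any() else float("nan")
    return flags, threshold


@dataclass
class AnovaResult:
    """Two-way repeated-measures ANOVA with lower-bound df adjustment."""

    f_time: float
    f_interaction: float
    df_time: tuple[int, int]          # unadjusted (k-1, (n-1)(k-1))
    df_interaction: tuple[int, int]
    df_time_lb: tuple[float, float]   # lower-bound epsilon = 1/(k-1)
    df_interaction_lb: tuple[float, float]
    p_time_lb: float
    p_interaction_lb: float
    eta2_time: float                  # SS_effect / SS_total
    eta2_interaction: float


def rm_anova_lowerbound(data: np.ndarray) -> AnovaResult:
    """Repeated-measures ANOVA on a units x time x condition array.

    Both factors are within-unit; exactly 2 conditions and k time bins.
    F(time) uses the units x time interaction as its error term and
    F(time x condition) the units x time x condition residual.  The
    lower-bound sphericity correction multiplies both df of each effect
    by epsilon = 1/(k-1) before the p-value; eta^2 is SS_effect /
    SS_total.  Missing cells are not imputed.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 3:
        raise ValueError("data must be units x time x condition")
    if not np.isfinite(x).all():
        raise ValueError("missing cells are not supported")
    n, k, c = x.shape
    if c != 2:
        raise ValueError("exactly 2 conditions are required")
    if n < 2 or k < 2:
        raise ValueError("need >= 2 units and >= 2 time bins")

    grand = x.mean()
    m_unit = x.mean(axis=(1, 2))
    m_time = x.mean(axis=(0, 2))
    m_cond = x.mean(axis=(0, 1))
    m_ut = x.mean(axis=2)            # units x time
    m_uc = x.mean(axis=1)            # units x cond
    m_tc = x.mean(axis=0)            # time x cond

    ss_time = n * c * ((m_time - grand) ** 2).sum()
    ss_cond = n * k * ((m_cond - grand) ** 2).sum()
    ss_unit = k * c * ((m_unit - grand) ** 2).sum()
    ss_ut = c * ((m_ut - m_unit[:, None] - m_time[None, :] + grand) ** 2
                 ).sum()
    ss_uc = k * ((m_uc - m_unit[:, None] - m_cond[None, :] + grand) ** 2
                 ).sum()
    ss_tc = n * ((m_tc - m_time[:, None] - m_cond[None, :] + grand) ** 2
                 ).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_resid = (ss_total - ss_time - ss_cond - ss_unit - ss_ut - ss_uc
                - ss_tc)

    df_time = (k - 1, (n - 1) * (k - 1))
    df_tc = (k - 1, (n - 1) * (k - 1))
    ms_time = ss_time / df_time[0]
    ms_ut = ss_ut / df_time[1]
    ms_tc = ss_tc / df_tc[0]
    ms_resid = ss_resid / ((n - 1) * (k - 1) * (c - 1))

    f_time = float(ms_time / ms_ut) if ms_ut > 0 else 0.0
    f_tc = float(ms_tc / ms_resid) if ms_resid > 0 else 0.0
    if ss_time == 0:
        f_time = 0.0

    eps = 1.0 / (k - 1)
    df_time_lb = (df_time[0] * eps, df_time[1] * eps)
    df_tc_lb = (df_tc[0] * eps, df_tc[1] * eps)
    p_time_lb = float(sstats.f.sf(f_time, *df_time_lb)) if f_time > 0 else 1.0
    p_tc_lb = float(sstats.f.sf(f_tc, *df_tc_lb)) if f_tc > 0 else 1.0
    return AnovaResult(
        f_time=f_time, f_interaction=f_tc,
        df_time=df_time, df_interaction=df_tc,
        df_time_lb=df_time_lb, df_interaction_lb=df_tc_lb,
        p_time_lb=p_time_lb, p_interaction_lb=p_tc_lb,
        eta2_time=float(ss_time / ss_total) if ss_total > 0 else 0.0,
        eta2_interaction=float(ss_tc / ss_total) if ss_total > 0 else 0.0,
    )


def epochwise_contrast(fot_a: np.ndarray, fot_b: np.ndarray,
                       window_starts=None, n_perm: int = 1000,
                       q: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Per-window paired permutation tests with FDR across windows.

    ``fot_a``/``fot_b`` are (n_pairs, n_windows) time-resolved PTE values
    under two conditions, aligned window-for-window.  Each window gets a
    two-sided paired permutation test across pairs; Benjamini-Hochberg
    correction runs across windows.  Significant windows carry the
    direction of the observed difference (positive = larger NC->HC bias
    in A).
    """
    a = np.asarray(fot_a, dtype=float)
    b = np.asarray(fot_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("condition arrays must share (n_pairs, n_windows)")
    n_win = a.shape[1]
    if window_starts is None:
        window_starts = np.arange(n_win, dtype=float)
    if len(window_starts) != n_win:
        raise ValueError("window_starts length mismatch")
    results = [paired_permutation_test(a[:, w], b[:, w], n_perm=n_perm,
                                       seed=seed + w, unit="channel pairs")
               for w in range(n_win)]
    pvals = np.array([r.p_value for r in results])
    flags, threshold = fdr_correct(pvals, q=q)
    return pd.DataFrame({
        "window_start_s": np.asarray(window_starts, dtype=float),
        "effect": [r.observed for r in results],
        "p": pvals,
        "p_fdr_pass": flags,
        "direction": np.where(
            [r.observed > 0 for r in results], "nc->hc", "hc->nc"),
        "p_fdr_threshold": threshold,
    })
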