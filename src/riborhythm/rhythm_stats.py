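"""Rhythm detection in circadian time courses.

The primary test is a JTK_CYCLE-style nonparametric scan: the observed
series is compared against cosine reference templates over a grid of
periods and phases using Kendall's tau-b, with an exact null
distribution of the Kendall S statistic computed for the template's tie
pattern.  The reported p-value is the minimum over templates with a
Bonferroni correction for the number of sign-distinct templates (a
template and its anti-phase mirror are the same two-sided test), the
within-series correction JTK_CYCLE itself applies and the reason its
p-values run slightly conservative; family-wise control across features
is by Benjamini-Hochberg.

Amplitude and mesor of a winning rhythm are taken from a cosinor fit
(least squares of a single cosine at the winning period); a classical
Lomb-Scargle periodogram is provided for long, irregularly sampled
series such as activity traces.

Null-distribution note: the exact null assumes the data ranks are
distinct (ties occur only in the template).  This is the assumption of
the original JTK null; with heavily tied count data the p-values are
approximate.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

MAX_EXACT_N = 25
_TEMPLATE_DECIMALS = 9  # rounding used to group tied template values


@dataclass
class TimeCourse:
    """An ordered (time, value) series for one feature.

    Times are in hours and non-decreasing; replicate measurements share a
    time value.  At least 4 points are required for any rhythm test.
    """

    feature_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.values, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        order = np.argsort(t, kind="stable")
        self.times = t[order]
        self.values = y[order]

    @property
    def n(self) -> int:
        return len(self.times)


@dataclass
class RhythmResult:
    feature_id: str
    period: float
    phase: float
    tau: float
    amplitude: float
    mesor: float
    p: float
    p_adj: float = float("nan")
    exact_null: bool = True


# ---------------------------------------------------------------------------
# Kendall machinery


def kendall_tau_b(x, y) -> tuple[float, float]:
    """Kendall's tau-b and the raw S statistic.

    S = sum over pairs i<j of sign(x_j-x_i)*sign(y_j-y_i); tau-b divides
    by the tie-corrected pair count.  With all-tied x or y, tau is NaN
    and S is 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D with n >= 2")
    ii, jj = np.triu_indices(len(x), k=1)
    sx = np.sign(x[jj] - x[ii])
    sy = np.sign(y[jj] - y[ii])
    S = float(np.sum(sx * sy))
    n0 = len(ii)
    n1 = n0 - int(np.sum(sx != 0))  # tied x pairs
    n2 = n0 - int(np.sum(sy != 0))
    denom = np.sqrt(float(n0 - n1) * float(n0 - n2))
    tau = S / denom if denom > 0 else float("nan")
    return tau, S


def _q_binomial(n: int, k: int) -> np.ndarray:
    """Coefficients of the Gaussian binomial [n choose k]_q."""
    # Pascal-style recurrence [n;k] = [n-1;k-1] + q^k [n-1;k]
    prev = {0: np.ones(1)}
    for m in range(1, n + 1):
        cur: dict[int, np.ndarray] = {0: np.ones(1)}
        top = min(m, k)
        for j in range(1, top + 1):
            a = prev.get(j - 1)
            b = prev.get(j)
            deg = j * (m - j)
            out = np.zeros(deg + 1)
            if a is not None:
                out[: len(a)] += a
            if b is not None:
                out[j : j + len(b)] += b
            cur[j] = out
        prev = cur
    return prev[min(n, k)] if k <= n else np.zeros(1)


@functools.lru_cache(maxsize=512)
def _null_distribution(groups: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Exact null of Kendall S against a fixed tie pattern.

    ``groups`` are the template's tie-group sizes.  Under a uniformly
    random permutation of distinct data values, the number of concordant
    cross-group pairs J follows the Gaussian-multinomial distribution
    prod_i [n_i choose g_i]_q; S = 2J - N with N the number of
    template-untied pairs.  Returns (support of S, probability masses).
    """
    poly = np.ones(1)
    n_sofar = 0
    for g in groups:
        n_sofar += g
        poly = np.convolve(poly, _q_binomial(n_sofar, g))
    pmf = poly / poly.sum()
    n_comparable = len(pmf) - 1
    support = 2 * np.arange(len(pmf)) - n_comparable
    return support.astype(float), pmf


def exact_kendall_null(n: int, tie_pattern=None) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of Kendall S for n points vs a tied template.

    ``tie_pattern`` gives the template's tie-group sizes (default: no
    ties, n groups of 1).  Only feasible for n <= 25; larger n should use
    the normal approximation inside the scan.
    """
    if tie_pattern is None:
        tie_pattern = (1,) * n
    tie_pattern = tuple(int(g) for g in tie_pattern)
    if sum(tie_pattern) != n:
        raise ValueError("tie_pattern must sum to n")
    if n > MAX_EXACT_N:
        raise ValueError(f"exact null infeasible for n={n} (max {MAX_EXACT_N})")
    return _null_distribution(tie_pattern)


def _p_two_sided_exact(s_obs: float, groups: tuple[int, ...]) -> float:
    support, pmf = _null_distribution(groups)
    s = abs(s_obs)
    p_one = float(pmf[support >= s - 1e-9].sum())
    return min(1.0, 2.0 * p_one)


def _p_two_sided_normal(s_obs: float, n: int, groups: tuple[int, ...]) -> float:
    v0 = n * (n - 1) * (2 * n + 5)
    vu = sum(u * (u - 1) * (2 * u + 5) for u in groups)
    var = (v0 - vu) / 18.0
    if var <= 0:
        return 1.0
    z = (abs(s_obs) - 1.0) / np.sqrt(var)  # continuity correction
    return float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))


# ---------------------------------------------------------------------------
# the JTK scan


def _template_library(times, periods, phase_step):
    """Cosine templates on the sample grid, ordered for tie-breaking.

    Tie-break among equally minimal p is smallest phase, then smallest
    period, so templates are enumerated in (phase, period) order.
    """
    templates = []
    for tau in periods:
        for phi in np.arange(0.0, tau, phase_step):
            vals = np.round(np.cos(2 * np.pi * (times - phi) / tau), _TEMPLATE_DECIMALS)
            templates.append((float(tau), float(phi), vals))
    templates.sort(key=lambda t: (t[1], t[0]))
    return templates


def jtk_scan(
    values: np.ndarray,
    times: np.ndarray,
    feature_ids=None,
    periods=(24.0,),
    phase_step: float = 4.0,
) -> pd.DataFrame:
    """Vectorized JTK-style rhythm test over many features.

    ``values`` is (n_features, n_samples); ``times`` the shared sample
    times in hours (replicates appear as repeated times and are matched
    against the same template value).  Returns one row per feature with
    the winning period, phase, tau-b, and the two-sided template p.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    times = np.asarray(times, dtype=float)
    n = len(times)
    if values.shape[1] != n:
        raise ValueError("values and times disagree on sample count")
    if n < 4:
        raise ValueError("rhythm tests require at least 4 samples")
    if feature_ids is None:
        feature_ids = [f"feature_{i}" for i in range(values.shape[0])]

    ii, jj = np.triu_indices(n, k=1)
    D = np.sign(values[:, jj] - values[:, ii])  # (F, n_pairs)
    n0 = len(ii)
    n1 = n0 - (D != 0).sum(axis=1)  # tied data pairs per feature

    exact = n <= MAX_EXACT_N
    templates = _template_library(times, periods, phase_step)
    # Bonferroni family: templates identical up to sign are one two-sided test
    keys = set()
    for _, _, tpl in templates:
        lead = tpl[np.nonzero(tpl)[0][0]] if np.any(tpl) else 1.0
        keys.add(tuple(tpl if lead > 0 else -tpl))
    n_eff = max(1, len(keys))

    n_feat, n_tpl = values.shape[0], len(templates)
    P = np.empty((n_tpl, n_feat))
    TAU = np.empty((n_tpl, n_feat))
    PHASE = np.empty((n_tpl, n_feat))
    PERIOD = np.empty(n_tpl)
    for k, (tau_period, phi, tpl) in enumerate(templates):
        tsign = np.sign(tpl[jj] - tpl[ii])
        n2 = n0 - int((tsign != 0).sum())
        S = D @ tsign
        denom = np.sqrt((n0 - n1).astype(float) * float(n0 - n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            tau_b = np.where(denom > 0, S / denom, np.nan)
        _, counts = np.unique(tpl, return_counts=True)
        groups = tuple(sorted(int(c) for c in counts))
        if exact:
            support, pmf = _null_distribution(groups)
            tail = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])
            idx = np.searchsorted(support, np.abs(S) - 1e-9, side="left")
            p = np.minimum(1.0, 2.0 * tail[idx])
        else:
            p = np.array([_p_two_sided_normal(s, n, groups) for s in S])
        # anti-correlated match: the rhythm peaks half a period away
        mirrored = S < 0
        P[k] = p
        TAU[k] = np.where(mirrored, -tau_b, tau_b)
        PHASE[k] = np.where(mirrored, (phi + tau_period / 2) % tau_period, phi)
        PERIOD[k] = tau_period

    # winner: smallest p, then smallest (peak) phase, then smallest period
    cand = P == P.min(axis=0)
    ph = np.where(cand, PHASE, np.inf)
    cand &= ph == ph.min(axis=0)
    per = np.where(cand, PERIOD[:, None], np.inf)
    cand &= per == per.min(axis=0)
    win = cand.argmax(axis=0)
    cols = np.arange(n_feat)
    return pd.DataFrame(
        {
            "feature_id": feature_ids,
            "period": PERIOD[win],
            "phase": PHASE[win, cols],
            "tau": TAU[win, cols],
            "p": np.minimum(1.0, n_eff * P[win, cols]),
            "exact_null": exact,
        }
    )


def jtk_test(
    tc: TimeCourse,
    periods=(24.0,),
    phase_step: float = 4.0,
) -> RhythmResult:
    """JTK-style rhythm test for one time course.

    The winning template's phase is the estimated peak time (modulo the
    period); amplitude and mesor come from a cosinor fit at the winning
    period.  A constant series returns p = 1 with undefined tau.
    """
    if tc.n < 4:
        return RhythmResult(tc.feature_id, *([float("nan")] * 4), float("nan"), 1.0)
    row = jtk_scan(
        tc.values[None, :], tc.times, [tc.feature_id], periods, phase_step
    ).iloc[0]
    if np.ptp(tc.values) == 0:
        return RhythmResult(
            tc.feature_id,
            float(row["period"]),
            float(row["phase"]),
            float("nan"),
            0.0,
            float(tc.values[0]),
            1.0,
            exact_null=bool(row["exact_null"]),
        )
    mesor, amplitude, _, _ = cosinor_fit(tc, float(row["period"]))
    return RhythmResult(
        feature_id=tc.feature_id,
        period=float(row["period"]),
        phase=float(row["phase"]),
        tau=float(row["tau"]),
        amplitude=amplitude,
        mesor=mesor,
        p=float(row["p"]),
        exact_null=bool(row["exact_null"]),
    )


# ---------------------------------------------------------------------------
# cosinor / periodogram / FDR


def cosinor_fit(tc, period: float):
    """Single-component cosinor: y = M + A cos(2 pi (t - phi) / period).

    Returns (mesor, amplitude, acrophase, p) where acrophase is the peak
    time in [0, period) and p is the F-test of the cosine terms jointly
    zero.  Raises on a singular design (all times equal modulo period).
    """
    if isinstance(tc, TimeCourse):
        t, y = tc.times, tc.values
    else:
        t, y = (np.asarray(v, dtype=float) for v in tc)
    n = len(t)
    if n < 4:
        raise ValueError("cosinor requires n >= 4")
    if period <= 0:
        raise ValueError("period must be positive")
    w = 2 * np.pi * t / period
    X = np.column_stack([np.ones(n), np.cos(w), np.sin(w)])
    if np.linalg.matrix_rank(X) < 3:
        raise np.linalg.LinAlgError(
            "singular cosinor design (times equal modulo period)"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    mesor, b1, b2 = beta
    amplitude = float(np.hypot(b1, b2))
    acrophase = float((np.arctan2(b2, b1) * period / (2 * np.pi)) % period)
    resid = y - X @ beta
    rss1 = float(resid @ resid)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    scale = max(rss0, 1.0)
    if n > 3 and rss1 > scale * 1e-12:
        F = ((rss0 - rss1) / 2.0) / (rss1 / (n - 3))
        p = float(stats.f.sf(F, 2, n - 3))
    elif rss0 <= scale * 1e-12:
        p = 1.0  # constant series: nothing to explain
    else:
        p = 0.0  # perfect fit
    return float(mesor), amplitude, acrophase, p


def lomb_scargle(tc, periods: np.ndarray | None = None) -> pd.DataFrame:
    """Classical normalized Lomb-Scargle periodogram.

    ``periods`` is the grid of trial periods in hours (default 16-32 h in
    0.1-h steps).  Returns a DataFrame (period_hours, power) with the
    peak row flagged; a constant series has zero power everywhere.
    """
    if isinstance(tc, TimeCourse):
        t, y = tc.times, tc.values
    else:
        t, y = (np.asarray(v, dtype=float) for v in tc)
    if len(t) < 4:
        raise ValueError("periodogram requires n >= 4")
    if periods is None:
        periods = np.arange(16.0, 32.0 + 1e-9, 0.1)
    periods = np.asarray(periods, dtype=float)
    omega = 2 * np.pi / periods
    if np.ptp(y) == 0:
        power = np.zeros_like(periods)
    else:
        power = signal.lombscargle(t, y - y.mean(), omega, normalize=True)
    out = pd.DataFrame({"period_hours": periods, "power": power})
    out["is_peak"] = False
    out.loc[out["power"].idxmax(), "is_peak"] = True
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving).

    NaN entries propagate and are excluded from the tested family.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def rhythm_table(
    series: pd.DataFrame,
    times: np.ndarray,
    periods=(24.0,),
    phase_step: float = 4.0,
    adjust: bool = True,
) -> pd.DataFrame:
    """Run the JTK scan plus cosinor over a feature-by-sample matrix.

    ``series`` is indexed by feature id with one column per sample, in
    the order of ``times``.  Output columns: feature_id, period, phase,
    tau, amplitude, mesor, p, p_adj.
    """
    values = series.to_numpy(dtype=float)
    res = jtk_scan(values, times, list(series.index), periods, phase_step)
    amps = np.full(len(res), np.nan)
    mesors = np.full(len(res), np.nan)
    for k, period in enumerate(res["period"].to_numpy()):
        mesors[k], amps[k], _, _ = cosinor_fit((times, values[k]), float(period))
    res["amplitude"] = amps
    res["mesor"] = mesors
    res["p_adj"] = bh_adjust(res["p"].to_numpy()) if adjust else np.nan
    return res[
        ["feature_id", "period", "phase", "tau", "amplitude", "mesor", "p", "p_adj"]
    ]
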