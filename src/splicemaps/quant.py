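"""PSI quantitation and differential-splicing testing from junction counts.

PSI uses junction counts only, normalized by effective form lengths:
PSI = (ijc/lI) / (ijc/lI + sjc/lS). A skipped exon contributes two
inclusion junctions but one skipping junction, so lI=2, lS=1 by default.

Differential splicing between two replicated conditions is tested with a
beta-binomial likelihood-ratio test on the inclusion-read probability:
under H0 both conditions share one probability, under H1 each condition has
its own, with a dispersion parameter shared throughout; the statistic is
referred to chi-square(1). The test degenerates to a binomial LRT as the
fitted dispersion goes to zero.

Events are then filtered on total junction counts, BH-adjusted FDR and
|ΔPSI|, with three threshold profiles: the main significance profile
(JC ≥ 50, FDR < 0.05, |ΔPSI| ≥ 0.10), the relaxed map test-set profile
(|ΔPSI| ≥ 0.05) and the map background profile (FDR > 0.1, |ΔPSI| < 0.05).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import EventTableRow


@dataclasses.dataclass
class PsiEstimate:
    replicate_psi: np.ndarray  # NaN where ijc+sjc == 0
    mean_psi: float  # mean over informative replicates; NaN if none
    total_jc: int  # sum of ijc+sjc over replicates


@dataclasses.dataclass
class ContrastResult:
    event_id: str
    psi_1: float
    psi_2: float
    delta_psi: float  # psi_1 - psi_2; sample1 is the reference (D control)
    p_value: float
    fdr: float
    jc_1: int
    jc_2: int
    passes_jc: bool = False
    passes_fdr: bool = False
    passes_dpsi: bool = False
    significant: bool = False
    map_test: bool = False
    map_background: bool = False


@dataclasses.dataclass(frozen=True)
class FilterProfile:
    """Closed/open threshold semantics exactly as printed."""

    jc_min: int = 50  # total JC >= jc_min in both conditions
    fdr_max: float = 0.05  # fdr < fdr_max
    dpsi_min: float = 0.10  # |dpsi| >= dpsi_min


MAIN_PROFILE = FilterProfile()
MAP_TEST_PROFILE = FilterProfile(jc_min=50, fdr_max=0.05, dpsi_min=0.05)
#: background: FDR > 0.1 and |ΔPSI| < 0.05, JC filter still applies
MAP_BACKGROUND_FDR_MIN = 0.1
MAP_BACKGROUND_DPSI_MAX = 0.05


def psi_from_counts(
    ijc: np.ndarray | Sequence[int] | int,
    sjc: np.ndarray | Sequence[int] | int,
    inc_form_len: int = 2,
    skip_form_len: int = 1,
) -> np.ndarray | float:
    """Length-normalized PSI; NaN where ijc = sjc = 0."""
    ijc = np.asarray(ijc, dtype=float)
    sjc = np.asarray(sjc, dtype=float)
    if np.any(ijc < 0) or np.any(sjc < 0):
        raise ValueError("negative junction counts")
    if inc_form_len < 1 or skip_form_len < 1:
        raise ValueError("form lengths must be >= 1")
    inc = ijc / inc_form_len
    skip = sjc / skip_form_len
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(inc + skip > 0, inc / (inc + skip), np.nan)
    return float(psi) if psi.ndim == 0 else psi


def estimate_psi(ijc, sjc, inc_form_len: int = 2, skip_form_len: int = 1) -> PsiEstimate:
    ijc = np.asarray(ijc, dtype=np.int64)
    sjc = np.asarray(sjc, dtype=np.int64)
    rep = psi_from_counts(ijc, sjc, inc_form_len, skip_form_len)
    rep = np.atleast_1d(rep)
    mean = float(np.nanmean(rep)) if np.any(np.isfinite(rep)) else float("nan")
    return PsiEstimate(replicate_psi=rep, mean_psi=mean, total_jc=int((ijc + sjc).sum()))


# --- beta-binomial likelihood-ratio test -----------------------------------

_PHI_FLOOR = 1e-9


def _bb_nll(k: np.ndarray, n: np.ndarray, theta: float, phi: float) -> float:
    """Negative log-likelihood of beta-binomial counts (binomial as phi->0)."""
    if not (0.0 < theta < 1.0) or not (0.0 <= phi < 1.0):
        return np.inf
    if phi < _PHI_FLOOR:
        return float(-np.sum(k * np.log(theta) + (n - k) * np.log1p(-theta)))
    a = theta * (1.0 - phi) / phi
    b = (1.0 - theta) * (1.0 - phi) / phi
    ll = special.betaln(k + a, n - k + b) - special.betaln(a, b)
    return float(-np.sum(ll))


def _bb_nll_grad(k, n, theta: float, phi: float) -> tuple[float, float, float]:
    """NLL and its partials w.r.t. theta and phi for one condition."""
    nu = (1.0 - phi) / phi
    a = theta * nu
    b = (1.0 - theta) * nu
    m = k.size
    f = -float(np.sum(special.betaln(k + a, n - k + b) - special.betaln(a, b)))
    dig_ab = special.digamma(a + b)
    df_da = -(
        float(np.sum(special.digamma(k + a) - special.digamma(n + a + b)))
        - m * (special.digamma(a) - dig_ab)
    )
    df_db = -(
        float(np.sum(special.digamma(n - k + b) - special.digamma(n + a + b)))
        - m * (special.digamma(b) - dig_ab)
    )
    df_dtheta = (df_da - df_db) * nu
    df_dphi = -(df_da * theta + df_db * (1.0 - theta)) / (phi * phi)
    return f, df_dtheta, df_dphi


# dispersion bounded away from {0, 1} on the logit scale; at the lower
# bound the beta-binomial is numerically binomial
_X_PHI_BOUNDS = (-16.0, 8.0)
_X_THETA_BOUNDS = (-16.0, 16.0)


def _fit_h0(k: np.ndarray, n: np.ndarray, phi: float) -> float:
    """NLL of a single shared inclusion probability at fixed dispersion."""

    def fun(x):
        theta = special.expit(x[0])
        f, dt, _ = _bb_nll_grad(k, n, theta, phi)
        return f, np.array([dt * theta * (1 - theta)])

    theta0 = float(np.clip(k.sum() / max(n.sum(), 1), 1e-6, 1 - 1e-6))
    res = optimize.minimize(
        fun,
        x0=[special.logit(theta0)],
        jac=True,
        method="L-BFGS-B",
        bounds=[_X_THETA_BOUNDS],
    )
    return float(res.fun)


def _fit_h1(kA, nA, kB, nB) -> tuple[float, float]:
    """NLL and dispersion MLE with per-condition probabilities.

    The dispersion is estimated once, under the richer model, and reused by
    the null fit; letting the null re-estimate it would absorb the very
    condition difference being tested.
    """

    def fun(x):
        tA = special.expit(x[0])
        tB = special.expit(x[1])
        phi = special.expit(x[2])
        fA, dtA, dpA = _bb_nll_grad(kA, nA, tA, phi)
        fB, dtB, dpB = _bb_nll_grad(kB, nB, tB, phi)
        return fA + fB, np.array(
            [
                dtA * tA * (1 - tA),
                dtB * tB * (1 - tB),
                (dpA + dpB) * phi * (1 - phi),
            ]
        )

    tA0 = float(np.clip(kA.sum() / max(nA.sum(), 1), 1e-6, 1 - 1e-6))
    tB0 = float(np.clip(kB.sum() / max(nB.sum(), 1), 1e-6, 1 - 1e-6))
    res = optimize.minimize(
        fun,
        x0=[special.logit(tA0), special.logit(tB0), -6.0],
        jac=True,
        method="L-BFGS-B",
        bounds=[_X_THETA_BOUNDS, _X_THETA_BOUNDS, _X_PHI_BOUNDS],
    )
    return float(res.fun), float(special.expit(res.x[2]))


def test_event(
    counts_a: Sequence[tuple[int, int]],
    counts_b: Sequence[tuple[int, int]],
    inc_form_len: int = 2,
    skip_form_len: int = 1,
) -> float:
    """Two-sided p-value for a PSI difference between conditions.

    ``counts_a``/``counts_b``: per-replicate (ijc, sjc). The likelihood is
    on the inclusion-read probability, a monotone transform of PSI, so the
    test is invariant to the form lengths. Returns NaN when a condition has
    no informative replicate.
    """
    kA = np.array([c[0] for c in counts_a], dtype=np.int64)
    nA = kA + np.array([c[1] for c in counts_a], dtype=np.int64)
    kB = np.array([c[0] for c in counts_b], dtype=np.int64)
    nB = kB + np.array([c[1] for c in counts_b], dtype=np.int64)
    if np.any(kA < 0) or np.any(kB < 0) or np.any(nA < kA) or np.any(nB < kB):
        raise ValueError("invalid junction counts")
    kA, nA = kA[nA > 0], nA[nA > 0]
    kB, nB = kB[nB > 0], nB[nB > 0]
    if kA.size == 0 or kB.size == 0:
        return float("nan")
    nll1, phi_hat = _fit_h1(kA, nA, kB, nB)
    nll0 = _fit_h0(np.concatenate([kA, kB]), np.concatenate([nA, nB]), phi_hat)
    lr = max(0.0, 2.0 * (nll0 - nll1))
    return float(stats.chi2.sf(lr, df=1))


def adjust_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg over non-missing entries; NaN propagates."""
    p = np.asarray(p_values, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def apply_filters(
    results: Sequence[ContrastResult],
    profile: FilterProfile = MAIN_PROFILE,
) -> list[ContrastResult]:
    """Set the per-event filter flags; boundaries closed exactly as printed.

    ``significant`` requires all three main-profile conditions. ``map_test``
    uses the relaxed |ΔPSI| >= 0.05 profile and ``map_background`` requires
    FDR > 0.1 and |ΔPSI| < 0.05 (both still need the JC filter).
    """
    for r in results:
        r.passes_jc = r.jc_1 >= profile.jc_min and r.jc_2 >= profile.jc_min
        r.passes_fdr = bool(np.isfinite(r.fdr) and r.fdr < profile.fdr_max)
        r.passes_dpsi = bool(
            np.isfinite(r.delta_psi) and abs(r.delta_psi) >= profile.dpsi_min
        )
        r.significant = r.passes_jc and r.passes_fdr and r.passes_dpsi
        r.map_test = (
            r.passes_jc
            and r.passes_fdr
            and np.isfinite(r.delta_psi)
            and abs(r.delta_psi) >= MAP_TEST_PROFILE.dpsi_min
        )
        r.map_background = (
            r.passes_jc
            and np.isfinite(r.fdr)
            and r.fdr > MAP_BACKGROUND_FDR_MIN
            and np.isfinite(r.delta_psi)
            and abs(r.delta_psi) < MAP_BACKGROUND_DPSI_MAX
        )
    return list(results)


def run_contrast(
    rows: Sequence[EventTableRow],
    profile: FilterProfile = MAIN_PROFILE,
) -> list[ContrastResult]:
    """Quantify, test and filter every event of one contrast table."""
    results = []
    for row in rows:
        est1 = estimate_psi(row.ijc_sample1, row.sjc_sample1, row.inc_form_len, row.skip_form_len)
        est2 = estimate_psi(row.ijc_sample2, row.sjc_sample2, row.inc_form_len, row.skip_form_len)
        if est1.total_jc == 0 or est2.total_jc == 0:
            p = float("nan")
        else:
            p = test_event(
                list(zip(row.ijc_sample1, row.sjc_sample1)),
                list(zip(row.ijc_sample2, row.sjc_sample2)),
                row.inc_form_len,
                row.skip_form_len,
            )
        results.append(
            ContrastResult(
                event_id=row.event_id,
                psi_1=est1.mean_psi,
                psi_2=est2.mean_psi,
                delta_psi=est1.mean_psi - est2.mean_psi,
                p_value=p,
                fdr=float("nan"),
                jc_1=est1.total_jc,
                jc_2=est2.total_jc,
            )
        )
    q = adjust_fdr([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.fdr = float(qv)
    return apply_filters(results, profile)


def results_frame(results: Sequence[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])
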