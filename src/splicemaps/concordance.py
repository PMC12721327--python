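"""Integration of knockdown contrasts against the differentiation program.

Covers the quadrant concordance analysis (knockdown ΔPSI vs program ΔPSI,
with r² and OLS slope over the congruently regulated upper-right/lower-left
quadrants), hypergeometric overlap of significant event sets, per-RBP
regulation calls with program-normalized ΔPSI, the coregulation heatmap
matrix, and row-Z hierarchical clustering of condition-mean PSIs.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .quant import ContrastResult, FilterProfile, MAIN_PROFILE

LABELS = ("activated", "repressed", "unregulated")


@dataclasses.dataclass
class QuadrantSummary:
    """Quadrant counts by sign of (x=program ΔPSI, y=knockdown ΔPSI).

    Events with a zero coordinate have no quadrant and are excluded.
    r² (Pearson) and the OLS slope (y on x, intercept fitted) are computed
    on the congruent subset (upper-right ∪ lower-left) only.
    """

    ur: int
    ll: int
    ul: int
    lr: int
    n_total: int
    congruent_count: int
    congruent_fraction: float
    r_squared: float
    slope: float


def quadrant_summary(x: Sequence[float], y: Sequence[float]) -> QuadrantSummary:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    nz = (x != 0) & (y != 0)
    xs, ys = x[nz], y[nz]
    ur = int(np.sum((xs > 0) & (ys > 0)))
    ll = int(np.sum((xs < 0) & (ys < 0)))
    ul = int(np.sum((xs < 0) & (ys > 0)))
    lr = int(np.sum((xs > 0) & (ys < 0)))
    n_quadrant = ur + ll + ul + lr
    congruent = ur + ll
    frac = congruent / n_quadrant if n_quadrant else float("nan")
    mask = ((xs > 0) & (ys > 0)) | ((xs < 0) & (ys < 0))
    if mask.sum() >= 3:
        fit = stats.linregress(xs[mask], ys[mask])
        slope = float(fit.slope)
        r2 = float(fit.rvalue**2)
    else:
        slope = float("nan")
        r2 = float("nan")
    return QuadrantSummary(
        ur=ur, ll=ll, ul=ul, lr=lr,
        n_total=int(x.size),
        congruent_count=congruent,
        congruent_fraction=frac,
        r_squared=r2,
        slope=slope,
    )


def overlap_hypergeometric(n_a: int, n_b: int, n_overlap: int, n_universe: int) -> float:
    """Upper-tail P(X >= n_overlap) for the overlap of two event sets."""
    if not (0 <= n_overlap <= min(n_a, n_b) <= max(n_a, n_b) <= n_universe):
        raise ValueError(
            f"inconsistent counts: A={n_a} B={n_b} overlap={n_overlap} universe={n_universe}"
        )
    if n_overlap == 0:
        return 1.0  # P(X >= 0); sf(-1) is degenerate for empty sets
    return float(stats.hypergeom.sf(n_overlap - 1, n_universe, n_a, n_b))


@dataclasses.dataclass
class RegulationCall:
    """Per-event, per-RBP activity call from the knockdown contrast.

    A positive knockdown ΔPSI (= PSI_D − PSI_KD) means depletion lowered
    inclusion, i.e. the RBP activates the exon. ``normalized_dpsi`` is the
    knockdown ΔPSI divided by the program (D vs P) ΔPSI, clipped, so the
    sign encodes concordance with the differentiation program.
    """

    event_id: str
    rbp: str
    label: str
    normalized_dpsi: float


def call_regulation(
    kd_result: ContrastResult,
    program_result: ContrastResult,
    rbp: str,
    profile: FilterProfile = MAIN_PROFILE,
    clip: float = 1.5,
) -> RegulationCall:
    kd_dpsi = kd_result.delta_psi
    significant = (
        np.isfinite(kd_result.fdr)
        and kd_result.fdr < profile.fdr_max
        and np.isfinite(kd_dpsi)
        and abs(kd_dpsi) >= profile.dpsi_min
    )
    if significant and kd_dpsi > 0:
        label = "activated"
    elif significant and kd_dpsi < 0:
        label = "repressed"
    else:
        label = "unregulated"
    prog = program_result.delta_psi
    if not np.isfinite(prog) or prog == 0 or not np.isfinite(kd_dpsi):
        norm = float("nan")
    else:
        norm = float(np.clip(kd_dpsi / prog, -clip, clip))
    return RegulationCall(
        event_id=kd_result.event_id, rbp=rbp, label=label, normalized_dpsi=norm
    )


_LABEL_ORDER = {"activated": 0, "repressed": 1, "unregulated": 2}


def coregulation_matrix(
    calls: Mapping[str, Sequence[RegulationCall]],
    program_results: Sequence[ContrastResult],
    rbp_order: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Program-normalized ΔPSI heatmap matrices, one per program direction.

    Rows are program-significant events split into D-included (program
    ΔPSI > 0) and D-skipped (< 0); columns are RBPs. Rows are ordered by the
    label vector (lexicographic, activated < repressed < unregulated) then
    by |program ΔPSI| descending; ties keep event order. The returned
    frames carry ``label_<rbp>`` columns and a ``cluster_size`` column with
    the per-label-vector row counts.
    """
    rbps = list(rbp_order) if rbp_order is not None else sorted(calls)
    call_index = {
        rbp: {c.event_id: c for c in calls[rbp]} for rbp in rbps
    }
    prog_index = {r.event_id: r for r in program_results if r.significant}
    out = {}
    for direction, keep in (
        ("D_included", lambda d: d > 0),
        ("D_skipped", lambda d: d < 0),
    ):
        rows = []
        for eid, prog in prog_index.items():
            if not keep(prog.delta_psi):
                continue
            rec: dict = {"event_id": eid, "program_dpsi": prog.delta_psi}
            for rbp in rbps:
                call = call_index[rbp].get(eid)
                if call is None:
                    raise KeyError(f"no {rbp} call for program event {eid}")
                rec[rbp] = call.normalized_dpsi
                rec[f"label_{rbp}"] = call.label
            rows.append(rec)
        df = pd.DataFrame(rows)
        if not df.empty:
            key = df[[f"label_{r}" for r in rbps]].apply(
                lambda col: col.map(_LABEL_ORDER)
            )
            df["_vec"] = list(map(tuple, key.to_numpy()))
            df = df.sort_values(
                by=["_vec", "program_dpsi"],
                key=lambda s: s.abs() if s.name == "program_dpsi" else s,
                ascending=[True, False],
                kind="stable",
            )
            df["cluster_size"] = df.groupby("_vec")["event_id"].transform("size")
            df = df.drop(columns="_vec").reset_index(drop=True)
        out[direction] = df
    return out


def zscore_rows(matrix: np.ndarray) -> np.ndarray:
    """Row z-scores (mean 0, sd 1); constant rows map to all zeros."""
    m = np.asarray(matrix, dtype=float)
    mean = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, keepdims=True, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (m - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return z


def cluster_rows(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
    """Hierarchical clustering of row-Z-scored condition-mean PSIs.

    Agglomerative, Euclidean distance, average linkage; the leaf order is
    SciPy's deterministic order (ties broken by original row index).
    Returns (leaf order, linkage matrix); fewer than two rows yield the
    identity order and no linkage.
    """
    m = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix must have no missing values")
    if m.shape[0] < 2:
        return np.arange(m.shape[0]), None
    z = zscore_rows(m)
    link = hierarchy.linkage(pdist(z, metric="euclidean"), method="average")
    order = hierarchy.leaves_list(link)
    return order, link


def overlap_table(
    sets: Mapping[str, set[str]], n_universe: int
) -> pd.DataFrame:
    """Pairwise overlap counts with hypergeometric p-values."""
    names = list(sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            k = len(sets[a] & sets[b])
            rows.append(
                {
                    "set_a": a,
                    "set_b": b,
                    "n_a": len(sets[a]),
                    "n_b": len(sets[b]),
                    "n_overlap": k,
                    "n_universe": n_universe,
                    "p_value": overlap_hypergeometric(
                        len(sets[a]), len(sets[b]), k, n_universe
                    ),
                }
            )
    return pd.DataFrame(rows)
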