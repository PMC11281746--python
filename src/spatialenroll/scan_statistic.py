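"""Kulldorff's purely spatial Poisson scan statistic.

Circular windows are grown around every area centroid up to a maximum radius
(30 km by default, the setting appropriate for sparsely populated regions
where the usual 50%-of-population cap yields impractically large clusters).
For each window the Poisson log likelihood ratio

    LLR = O_in log(O_in/E_in) + (O_tot-O_in) log((O_tot-O_in)/(E_tot-E_in))

is computed when the inside rate exceeds the outside rate (0 otherwise), and
significance of the maximum is assessed by conditional Monte-Carlo: the
observed total is redistributed multinomially proportional to the expected
counts (9,999 replications by default).  Secondary clusters are reported in
LLR order subject to sharing no member area with a better-ranked cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class ScanWindow:
    """One circular scan window: a center area plus all areas whose centroid
    lies within ``radius_km`` of the center centroid, ordered by distance."""

    center_area_id: str
    radius_km: float
    member_area_ids: list[str]
    member_index: np.ndarray  # positions into the area order


@dataclass
class Cluster:
    """A detected cluster with its Monte-Carlo p-value."""

    window: ScanWindow
    observed: float
    expected: float
    llr: float
    relative_risk_inside: float
    p_value: float
    rank: int


def enumerate_windows(
    distances: np.ndarray,
    max_radius_km: float,
    area_ids: list[str] | None = None,
) -> list[ScanWindow]:
    """All distinct circular windows: for each center, the window grows by
    adding the next-nearest centroid while its distance stays within the
    radius cap.  Distance ties are broken by area order; enumeration order is
    (center index, then radius).
    """
    if max_radius_km < 0:
        raise ValueError("max_radius_km must be >= 0")
    distances = np.asarray(distances, dtype=float)
    n = distances.shape[0]
    if area_ids is None:
        area_ids = [str(i) for i in range(n)]
    windows: list[ScanWindow] = []
    order_idx = np.arange(n)
    for c in range(n):
        d = distances[c]
        order = np.lexsort((order_idx, d))  # by distance, ties by area order
        within = order[d[order] <= max_radius_km]
        for k in range(len(within)):
            members = within[: k + 1]
            windows.append(
                ScanWindow(
                    center_area_id=area_ids[c],
                    radius_km=float(d[within[k]]),
                    member_area_ids=[area_ids[i] for i in members],
                    member_index=members.copy(),
                )
            )
    return windows


def membership_matrix(windows: list[ScanWindow], n_areas: int) -> sp.csr_matrix:
    """Sparse (n_windows x n_areas) 0/1 window-membership indicator."""
    rows = np.concatenate(
        [np.full(len(w.member_index), i) for i, w in enumerate(windows)]
    )
    cols = np.concatenate([w.member_index for w in windows])
    return sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(windows), n_areas)
    )


def poisson_llr(O_in, E_in, O_tot, E_tot):
    """Kulldorff Poisson log likelihood ratio; 0 unless the window rate
    exceeds the outside rate.  Vectorised over ``O_in``/``E_in``; expects
    E scaled so that E_tot = O_tot.  0*log(0/x) is taken as 0."""
    O_in = np.asarray(O_in, dtype=float)
    E_in = np.asarray(E_in, dtype=float)
    if np.any(E_in <= 0):
        raise ValueError("E_in must be > 0")
    O_out = O_tot - O_in
    E_out = E_tot - E_in
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(O_in > 0, O_in * np.log(O_in / E_in), 0.0)
        t2 = np.where(O_out > 0, O_out * np.log(O_out / E_out), 0.0)
    high = O_in * E_out > O_out * E_in  # inside rate strictly above outside
    out = np.where(high, t1 + t2, 0.0)
    return out if out.ndim else float(out)


def monte_carlo_null(
    O_tot: float,
    E: np.ndarray,
    windows: list[ScanWindow],
    n_sim: int = 9999,
    seed: int = 0,
    chunk: int = 250,
) -> np.ndarray:
    """Max-LLR null distribution: each replication redistributes the observed
    total multinomially over areas with probabilities E_i / sum(E)."""
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    E = np.asarray(E, dtype=float)
    E_tot = E.sum()
    E_scaled = E * (O_tot / E_tot)
    p = E / E_tot
    M = membership_matrix(windows, len(E))
    if M.shape[0] * M.shape[1] <= 8_000_000:
        M = M.toarray()  # dense BLAS beats sparse at these sizes
    E_in = np.asarray(M @ E_scaled).ravel()
    rng = np.random.default_rng(seed)
    out = np.empty(n_sim)
    done = 0
    while done < n_sim:
        b = min(chunk, n_sim - done)
        counts = rng.multinomial(int(round(O_tot)), p, size=b).astype(float)
        O_in = (M @ counts.T).T
        llr = poisson_llr(O_in, E_in[None, :], O_tot, O_tot)
        out[done : done + b] = llr.max(axis=1)
        done += b
    return out


def detect_clusters(
    O: np.ndarray,
    E: np.ndarray,
    distances: np.ndarray,
    area_ids: list[str] | None = None,
    max_radius_km: float = 30.0,
    n_sim: int = 9999,
    seed: int = 0,
) -> list[Cluster]:
    """Detect high-rate clusters of unenrolled diabetics.

    Returns the primary cluster (maximal LLR; ties broken toward fewer
    members, then the lower center index) followed by secondary clusters in
    LLR order, each sharing no member area with a better-ranked cluster.
    Every p-value is (1 + #{null max-LLR >= cluster LLR}) / (1 + n_sim),
    against the same null max-LLR distribution.
    """
    O = np.asarray(O, dtype=float)
    E = np.asarray(E, dtype=float)
    distances = np.asarray(distances, dtype=float)
    n = len(O)
    if area_ids is None:
        area_ids = [str(i) for i in range(n)]
    O_tot = O.sum()
    if O_tot == 0:
        warnings.warn("no observed cases; nothing to scan", UserWarning, stacklevel=2)
        return []
    E_scaled = E * (O_tot / E.sum())

    windows = enumerate_windows(distances, max_radius_km, area_ids)
    M = membership_matrix(windows, n)
    O_in = np.asarray(M @ O).ravel()
    E_in = np.asarray(M @ E_scaled).ravel()
    llr = np.asarray(poisson_llr(O_in, E_in, O_tot, O_tot))

    center_pos = {a: i for i, a in enumerate(area_ids)}
    order = sorted(
        range(len(windows)),
        key=lambda i: (
            -llr[i],
            len(windows[i].member_index),
            center_pos[windows[i].center_area_id],
        ),
    )

    null = monte_carlo_null(O_tot, E, windows, n_sim=n_sim, seed=seed)

    clusters: list[Cluster] = []
    used = np.zeros(n, dtype=bool)
    for i in order:
        if llr[i] <= 0:
            break
        w = windows[i]
        if used[w.member_index].any():
            continue
        p = (1 + int((null >= llr[i]).sum())) / (1 + n_sim)
        clusters.append(
            Cluster(
                window=w,
                observed=float(O_in[i]),
                expected=float(E_in[i]),
                llr=float(llr[i]),
                relative_risk_inside=float(O_in[i] / E_in[i]),
                p_value=p,
                rank=len(clusters) + 1,
            )
        )
        used[w.member_index] = True
    return clusters


def clusters_to_frame(clusters: list[Cluster]) -> pd.DataFrame:
    """Cluster report table (rank, center, radius, n_areas, counts, RR, LLR, p)."""
    return pd.DataFrame(
        [
            {
                "rank": c.rank,
                "center_area_id": c.window.center_area_id,
                "radius_km": c.window.radius_km,
                "n_areas": len(c.window.member_area_ids),
                "observed": c.observed,
                "expected": c.expected,
                "relative_risk": c.relative_risk_inside,
                "llr": c.llr,
                "p_value": c.p_value,
            }
            for c in clusters
        ]
    )
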