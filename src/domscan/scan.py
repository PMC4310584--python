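"""Genome-scan layer: outlier calls and kernel-smoothed permutation scans.

Per-locus statistics (per-locus Weir-Cockerham theta, or standardized LnRH)
are smoothed along each linkage group with a local-linear Gaussian-kernel
regression evaluated on a 401-point grid. The null distribution at each grid
point comes from permuting the per-locus values across ALL mapped positions
genome-wide (the scan asks where a locus deviates from the genome-wide
average, so the exchangeable unit is the value, not the position) and
re-smoothing with the observed bandwidth. FST scans are upper-tailed; LnRH
scans two-tailed. Regions are maximal runs of grid points below the region
alpha.

The bandwidth per linkage group comes from a direct plug-in rule for
local-linear regression (global quartic pilot fit for the curvature
functional, residual variance from the same fit); when the rule degenerates
(too few loci, pathological spacing) it falls back to twice the median
intermarker distance. Linkage groups with fewer than five usable loci are
skipped with a warning rather than crashing, which generalizes the usual
manual removal of isolated markers at sparse chromosome ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import LinkageMap

GRID_POINTS = 401
MIN_LOCI = 5

_GAUSS_NORM = 1.0 / np.sqrt(2.0 * np.pi)


def plugin_bandwidth(positions: np.ndarray, values: np.ndarray) -> float | None:
    """Direct plug-in bandwidth for local-linear Gaussian-kernel regression.

    Uses a global quartic pilot fit to estimate the curvature functional
    theta_22 = mean(m''(x)^2) and the residual variance, then
    ``h = [ R(K) sigma^2 (b - a) / (n mu2(K)^2 theta_22) ]^(1/5)`` with
    R(K) = 1/(2 sqrt(pi)) and mu2(K) = 1 for the Gaussian kernel. Returns
    None when the rule degenerates.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(values, dtype=float)
    n = len(x)
    span = np.ptp(x)
    if n < 7 or span <= 0:
        return None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", np.exceptions.RankWarning)
            coef = np.polyfit(x, y, 4)
    except np.linalg.LinAlgError:
        return None
    fitted = np.polyval(coef, x)
    dof = n - 5
    sigma2 = float(np.sum((y - fitted) ** 2) / dof)
    dd = np.polyder(np.poly1d(coef), 2)
    theta22 = float(np.mean(dd(x) ** 2))
    if not np.isfinite(sigma2) or not np.isfinite(theta22) or theta22 <= 1e-300:
        return None
    rk = 0.5 / np.sqrt(np.pi)
    h = (rk * sigma2 * span / (n * theta22)) ** 0.2
    if not np.isfinite(h) or h <= 0:
        return None
    return float(min(h, span))


def fallback_bandwidth(positions: np.ndarray) -> float:
    """Twice the median intermarker distance (degenerate-spacing fallback)."""
    x = np.sort(np.asarray(positions, dtype=float))
    gaps = np.diff(x)
    gaps = gaps[gaps > 0]
    if len(gaps) == 0:
        raise ValueError("all positions identical: no usable bandwidth")
    return float(2.0 * np.median(gaps))


def local_linear_matrix(
    positions: np.ndarray, grid: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Linear-smoother matrix S with smoothed = S @ values.

    Row i holds the local-linear weights at grid point i; where the local
    design is singular (no spread of positions inside the kernel window) the
    row degrades to Nadaraya-Watson weights.
    """
    x = np.asarray(positions, dtype=float)
    g = np.asarray(grid, dtype=float)
    d = x[None, :] - g[:, None]  # (grid, loci)
    k = _GAUSS_NORM * np.exp(-0.5 * (d / bandwidth) ** 2)
    s0 = k.sum(axis=1, keepdims=True)
    s1 = (k * d).sum(axis=1, keepdims=True)
    s2 = (k * d * d).sum(axis=1, keepdims=True)
    w = k * (s2 - d * s1)
    denom = w.sum(axis=1, keepdims=True)
    scale = np.abs(s0 * s2 - s1 * s1)
    singular = (scale.ravel() <= 1e-12 * np.maximum(s0, 1e-300).ravel() ** 2) | (
        np.abs(denom.ravel()) <= 1e-300
    )
    S = np.where(denom != 0, w / np.where(denom == 0, 1.0, denom), 0.0)
    if singular.any():
        nw = k / np.maximum(s0, 1e-300)
        S[singular] = nw[singular]
    return S


@dataclass
class SmoothedTrack:
    grid: np.ndarray
    smoothed: np.ndarray
    bandwidth: float


def smooth_track(
    values: np.ndarray,
    positions: np.ndarray,
    bandwidth: float | None = None,
    grid_points: int = GRID_POINTS,
) -> SmoothedTrack | None:
    """Smooth one linkage group's per-locus statistic onto an even grid.

    Returns None (with a warning) when fewer than five loci carry defined
    values, mirroring the removal of sparse chromosome regions instead of
    crashing the scan.
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=float)
    ok = np.isfinite(values) & np.isfinite(positions)
    values, positions = values[ok], positions[ok]
    if len(values) < MIN_LOCI:
        warnings.warn(
            f"skipping group with {len(values)} usable loci (< {MIN_LOCI})",
            stacklevel=2,
        )
        return None
    if bandwidth is None:
        bandwidth = plugin_bandwidth(positions, values)
        if bandwidth is None:
            bandwidth = fallback_bandwidth(positions)
    grid = np.linspace(positions.min(), positions.max(), grid_points)
    S = local_linear_matrix(positions, grid, bandwidth)
    return SmoothedTrack(grid=grid, smoothed=S @ values, bandwidth=bandwidth)


@dataclass
class GroupTrack:
    linkage_group: str
    grid: np.ndarray
    smoothed: np.ndarray
    bandwidth: float
    pvalues: np.ndarray | None = None
    tail: np.ndarray | None = None  # 'high'/'low' per grid point (two-tailed)


@dataclass
class ScanTrack:
    groups: dict[str, GroupTrack]
    regions: pd.DataFrame
    skipped: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lg, tr in self.groups.items():
            rows.append(
                pd.DataFrame(
                    {
                        "linkage_group": lg,
                        "position_cm": tr.grid,
                        "smoothed": tr.smoothed,
                        "p_value": tr.pvalues,
                        "bandwidth": tr.bandwidth,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def permutation_pvalues(
    values: np.ndarray,
    positions: np.ndarray,
    nperm: int,
    tails: str = "upper",
    seed: int | None = 0,
    bandwidth: float | None = None,
    grid_points: int = GRID_POINTS,
) -> tuple[SmoothedTrack, np.ndarray]:
    """Single-group permutation scan (the genome-wide version for one group).

    p(grid point) = (1 + #{permuted smoothed >= observed}) / (1 + nperm) for
    the upper tail; the two-tailed p doubles the smaller tail and caps at 1.
    The add-one rule keeps p strictly positive.
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    track = smooth_track(values, positions, bandwidth=bandwidth, grid_points=grid_points)
    if track is None:
        raise ValueError("too few usable loci for a permutation scan")
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=float)
    ok = np.isfinite(values) & np.isfinite(positions)
    values, positions = values[ok], positions[ok]
    S = local_linear_matrix(positions, track.grid, track.bandwidth)
    rng = np.random.default_rng(seed)
    perm = np.empty((nperm, len(values)))
    for i in range(nperm):
        perm[i] = rng.permutation(values)
    sm = S @ perm.T  # (grid, nperm)
    p = _tail_pvalues(sm, track.smoothed, tails)[0]
    return track, p


def _tail_pvalues(
    perm_smoothed: np.ndarray, observed: np.ndarray, tails: str
) -> tuple[np.ndarray, np.ndarray]:
    nperm = perm_smoothed.shape[1]
    # numerical ties (e.g. constant tracks) must count as exceedances, so the
    # comparison carries a small tolerance; this only ever increases p
    tol = 1e-9 * (1.0 + np.abs(observed))
    ge = (perm_smoothed >= (observed - tol)[:, None]).sum(axis=1)
    p_hi = (1.0 + ge) / (1.0 + nperm)
    if tails == "upper":
        return p_hi, np.full(len(observed), "high", dtype=object)
    if tails != "two":
        raise ValueError("tails must be 'upper' or 'two'")
    le = (perm_smoothed <= (observed + tol)[:, None]).sum(axis=1)
    p_lo = (1.0 + le) / (1.0 + nperm)
    p = np.minimum(1.0, 2.0 * np.minimum(p_lo, p_hi))
    tail = np.where(p_hi <= p_lo, "high", "low").astype(object)
    return p, tail


def scan_genome(
    values: pd.Series,
    lmap: LinkageMap,
    nperm: int = 10_000,
    tails: str = "upper",
    region_alpha: float = 0.001,
    seed: int | None = 0,
    grid_points: int = GRID_POINTS,
) -> ScanTrack:
    """Full genome scan: smooth, permute genome-wide, call regions.

    ``values`` is indexed by locus id; only mapped loci with defined values
    enter. The bandwidth of each linkage group is estimated once from the
    observed data and held fixed across permutations.
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    frame = lmap.frame.join(values.rename("value"), how="inner")
    frame = frame[np.isfinite(frame["value"])]
    groups: dict[str, GroupTrack] = {}
    skipped: list[str] = []
    smoothers: dict[str, np.ndarray] = {}
    slices: dict[str, np.ndarray] = {}

    kept_idx: list[np.ndarray] = []
    lg_order = []
    offset_index = np.arange(len(frame))
    for lg in lmap.linkage_groups():
        sel = offset_index[(frame["linkage_group"] == lg).to_numpy()]
        if len(sel) < MIN_LOCI:
            if len(sel):
                warnings.warn(
                    f"skipping {lg}: {len(sel)} usable loci (< {MIN_LOCI})",
                    stacklevel=2,
                )
                skipped.append(lg)
            continue
        lg_order.append(lg)
        kept_idx.append(sel)

    all_values = frame["value"].to_numpy()
    pooled_idx = np.concatenate(kept_idx) if kept_idx else np.array([], dtype=int)
    pooled_values = all_values[pooled_idx]
    pos_in_pool = {}
    start = 0
    for lg, sel in zip(lg_order, kept_idx):
        pos_in_pool[lg] = np.arange(start, start + len(sel))
        start += len(sel)

    for lg, sel in zip(lg_order, kept_idx):
        pos = frame["position_cm"].to_numpy()[sel]
        vals = all_values[sel]
        track = smooth_track(vals, pos, grid_points=grid_points)
        assert track is not None
        groups[lg] = GroupTrack(
            linkage_group=lg,
            grid=track.grid,
            smoothed=track.smoothed,
            bandwidth=track.bandwidth,
        )
        smoothers[lg] = local_linear_matrix(pos, track.grid, track.bandwidth)
        slices[lg] = pos_in_pool[lg]

    if groups:
        rng = np.random.default_rng(seed)
        n_pool = len(pooled_values)
        perm = np.empty((nperm, n_pool))
        for i in range(nperm):
            perm[i] = pooled_values[rng.permutation(n_pool)]
        for lg, tr in groups.items():
            sm = smoothers[lg] @ perm[:, slices[lg]].T  # (grid, nperm)
            tr.pvalues, tr.tail = _tail_pvalues(sm, tr.smoothed, tails)

    regions = call_regions_from_groups(groups, frame, region_alpha)
    return ScanTrack(groups=groups, regions=regions, skipped=skipped)


def call_regions_from_groups(
    groups: dict[str, GroupTrack],
    mapped_frame: pd.DataFrame | None,
    alpha: float,
) -> pd.DataFrame:
    """Maximal runs of consecutive grid points with p < alpha, annotated."""
    rows = []
    for lg, tr in groups.items():
        if tr.pvalues is None:
            continue
        sig = tr.pvalues < alpha
        if not sig.any():
            continue
        step = tr.grid[1] - tr.grid[0] if len(tr.grid) > 1 else 0.0
        edges = np.flatnonzero(np.diff(np.concatenate([[0], sig.view(np.int8), [0]])))
        for lo, hi in zip(edges[::2], edges[1::2]):
            run = slice(lo, hi)
            sm = tr.smoothed[run]
            if tr.tail is not None:
                # direction at the most significant point of the run
                best = lo + int(np.argmin(tr.pvalues[run]))
                direction = tr.tail[best]
            else:
                direction = "high"
            if direction == "high":
                extremal = float(sm.max())
                peak = tr.grid[lo + int(np.argmax(sm))]
            else:
                extremal = float(sm.min())
                peak = tr.grid[lo + int(np.argmin(sm))]
            nearest = ""
            if mapped_frame is not None:
                in_lg = mapped_frame[mapped_frame["linkage_group"] == lg]
                if len(in_lg):
                    dist = (in_lg["position_cm"] - peak).abs()
                    nearest = str(dist.idxmin())
            rows.append(
                {
                    "linkage_group": lg,
                    "start_cm": float(tr.grid[lo]),
                    "end_cm": float(tr.grid[hi - 1] + step),
                    "direction": direction,
                    "min_p": float(tr.pvalues[run].min()),
                    "extremal_value": extremal,
                    "nearest_marker": nearest,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "linkage_group",
            "start_cm",
            "end_cm",
            "direction",
            "min_p",
            "extremal_value",
            "nearest_marker",
        ],
    )


def call_regions(track: ScanTrack, alpha: float) -> pd.DataFrame:
    """Re-call regions on an already-scanned track at a different alpha."""
    return call_regions_from_groups(track.groups, None, alpha)


def lnrh_outliers(lnrh_z: pd.Series, z_threshold: float) -> pd.DataFrame:
    """Loci beyond +/- z_threshold, tagged by which tail they fall in.

    ``high`` means the wild population carries the higher variability
    estimate (diversity reduced in the domesticated strain), ``low`` the
    reverse.
    """
    z = lnrh_z.dropna()
    out = z[(z > z_threshold) | (z < -z_threshold)]
    return pd.DataFrame(
        {
            "lnrh_z": out,
            "direction": np.where(out > 0, "high", "low"),
        }
    )
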