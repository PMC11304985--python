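"""Mass-univariate sensor statistics with Monte-Carlo cluster correction.

The pipeline: average correct trials per condition, combine planar
gradiometer pairs by root-sum-square, run a paired t-test per channel and
timepoint across participants, binarize the p-map at a threshold split by
t-sign, arrange the binary values on the flattened 2D sensor layout to get a
(rows x cols x time) matrix M, find connected clusters of 1s, and assess
cluster sizes against a null built by randomly permuting the occupied cells
of M (1,000 permutations, maximum cluster size per permutation, 99.9th
percentile criterion).  Magnetometers, whose field sign flips across the
helmet, are re-tested only inside the time window the gradiometer clusters
establish.  A 1D variant of the same Monte-Carlo scheme corrects
per-timepoint behavior-neural correlation/ANOVA scans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .layout import GRID_COLS, GRID_ROWS, site_grid
from .synth import EpochSet

# ---------------------------------------------------------------------------
# per-participant condition averages and planar combination
# ---------------------------------------------------------------------------


def average_trials(epochs: EpochSet,
                   correct_only: bool = True) -> dict[str, np.ndarray]:
    """Mean trial (channels x time) per condition, correct trials only by
    default.  Raises if a condition has no usable trials."""
    trials = epochs.trials
    keep = trials["correct"].to_numpy() if correct_only else np.ones(
        len(trials), dtype=bool)
    out: dict[str, np.ndarray] = {}
    for cond in sorted(trials["condition"].unique()):
        m = keep & (trials["condition"] == cond).to_numpy()
        if m.sum() == 0:
            raise ValueError(f"condition {cond!r} has no correct trials")
        out[cond] = epochs.data[m].mean(axis=0)
    return out


def combine_planar_pair(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Root-sum-square of a planar gradiometer pair: sqrt(g1^2 + g2^2)."""
    return np.sqrt(np.asarray(g1) ** 2 + np.asarray(g2) ** 2)


def combine_planar(data: np.ndarray, channels) -> np.ndarray:
    """Combine every planar-gradiometer pair of a (channels x time) array
    into one non-negative (sites x time) array, sites in layout order."""
    by_site: dict[int, list[int]] = {}
    for i, ch in enumerate(channels):
        if ch.kind != "planar_grad":
            continue
        if ch.pair_index is None:
            raise ValueError(f"gradiometer {ch.name} has no planar partner")
        by_site.setdefault(ch.site, []).append(i)
    sites = sorted(by_site)
    out = np.empty((len(sites), data.shape[-1]))
    for k, site in enumerate(sites):
        pair = by_site[site]
        if len(pair) != 2:
            raise ValueError(f"site {site} has {len(pair)} gradiometers")
        out[k] = combine_planar_pair(data[pair[0]], data[pair[1]])
    return out


# ---------------------------------------------------------------------------
# mass t-tests and binarization onto the 2D layout
# ---------------------------------------------------------------------------


def mass_ttests(mean_a: np.ndarray,
                mean_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Paired two-sided t-test per channel/timepoint across participants.

    Inputs are (participants x channels x time) stacks of condition means.
    Cells with zero difference variance get t = 0, p = 1.
    """
    mean_a = np.asarray(mean_a, float)
    mean_b = np.asarray(mean_b, float)
    if mean_a.shape != mean_b.shape or mean_a.ndim != 3:
        raise ValueError("need matching (participants, channels, time) stacks")
    if mean_a.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_rel(mean_a, mean_b, axis=0)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        warnings.warn(
            f"{degenerate.sum()} zero-variance cells set to t=0, p=1"
        )
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    return t, p


@dataclass
class BinaryStatMatrix:
    """Binary (rows x cols x time) matrix on the flattened sensor layout.

    ``values[r, c, t] = 1`` iff the channel at layout cell (r, c) has
    p < threshold at timepoint t AND its t-value matches ``sign``.  Cells
    without a sensor are structurally empty (``occupied`` False) and are
    excluded from clustering and permutation.
    """

    values: np.ndarray           # bool (rows, cols, T)
    occupied: np.ndarray         # bool (rows, cols)
    sign: str                    # "positive" | "negative"
    threshold: float
    times: np.ndarray
    stat: np.ndarray | None = field(default=None, repr=False)
    pval: np.ndarray | None = field(default=None, repr=False)
    grid: np.ndarray | None = field(default=None, repr=False)  # cell -> site


def binarize(
    t_map: np.ndarray,
    p_map: np.ndarray,
    times: np.ndarray,
    p_threshold: float = 0.01,
    sign: str = "positive",
    grid: np.ndarray | None = None,
) -> BinaryStatMatrix:
    """Threshold a (sites x time) stat map and arrange it on the 2D layout.

    ``grid`` maps layout cells to row indices of ``t_map`` (-1 = empty cell);
    defaults to the package's 102-site layout.
    """
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    if grid is None:
        grid = site_grid()
    t_map = np.asarray(t_map)
    p_map = np.asarray(p_map)
    n_time = t_map.shape[-1]
    rows, cols = grid.shape
    occupied = grid >= 0
    values = np.zeros((rows, cols, n_time), dtype=bool)
    sig = (p_map < p_threshold) & (
        t_map > 0 if sign == "positive" else t_map < 0
    )
    values[occupied, :] = sig[grid[occupied], :]
    return BinaryStatMatrix(values, occupied, sign, p_threshold,
                            np.asarray(times), t_map, p_map, grid)


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------


@dataclass
class ClusterRecord:
    cells: list[tuple[int, int, int]]  # (row, col, time-bin)
    size: int
    time_window: tuple[float, float]   # seconds
    sign: str
    mcs_p: float | None = None
    significant: bool | None = None


def _structure(neighborhood: str) -> np.ndarray:
    if neighborhood == "face":
        return ndimage.generate_binary_structure(3, 1)
    if neighborhood == "edge8":
        s = np.zeros((3, 3, 3), dtype=bool)
        s[:, :, 1] = True          # 8-connected in the spatial plane
        s[1, 1, :] = True          # +/-1 in time, same cell
        return s
    raise ValueError("neighborhood must be 'face' or 'edge8'")


def find_clusters(matrix: BinaryStatMatrix | np.ndarray,
                  neighborhood: str = "face",
                  times: np.ndarray | None = None,
                  sign: str = "positive") -> list[ClusterRecord]:
    """Connected components of 1-cells, largest first.

    Face adjacency (4-neighbour in the layout plane, +/-1 in time) by
    default; ``edge8`` allows diagonal spatial neighbours.
    """
    if isinstance(matrix, BinaryStatMatrix):
        values = matrix.values
        times = matrix.times
        sign = matrix.sign
    else:
        values = np.asarray(matrix, dtype=bool)
        if times is None:
            times = np.arange(values.shape[-1], dtype=float)
    labels, n = ndimage.label(values, structure=_structure(neighborhood))
    clusters: list[ClusterRecord] = []
    for lab in range(1, n + 1):
        where = np.argwhere(labels == lab)
        tbins = where[:, 2]
        clusters.append(ClusterRecord(
            [tuple(c) for c in where],
            where.shape[0],
            (float(times[tbins.min()]), float(times[tbins.max()])),
            sign,
        ))
    clusters.sort(key=lambda c: c.size, reverse=True)
    return clusters


@dataclass
class ClusterMCSResult:
    clusters: list[ClusterRecord]
    null_max_sizes: np.ndarray
    size_threshold: float
    percentile: float
    n_perms: int

    @property
    def significant(self) -> list[ClusterRecord]:
        return [c for c in self.clusters if c.significant]


def mcs_cluster_test(
    matrix: BinaryStatMatrix,
    n_perms: int = 1000,
    percentile: float = 99.9,
    seed: int = 0,
    neighborhood: str = "face",
    scope: str = "global",
) -> ClusterMCSResult:
    """Monte-Carlo cluster-size test by element permutation.

    Each permutation shuffles the values of the occupied cells of M uniformly
    (``scope='global'``: across space and time jointly, the literal reading;
    ``scope='per_timeslice'``: within each time slice), preserving the total
    count of 1s.  The maximum cluster size per permutation forms the null;
    original clusters larger than its ``percentile`` quantile are flagged
    significant, and each cluster also gets the empirical
    p = (1 + #{null >= size}) / (1 + n_perms).
    """
    if n_perms < 100:
        warnings.warn(f"n_perms={n_perms} is low for a cluster-size null")
    clusters = find_clusters(matrix, neighborhood)
    occ = matrix.occupied
    vals = matrix.values[occ, :]  # (n_sites, T)
    rng = np.random.default_rng(seed)
    structure = _structure(neighborhood)
    null_max = np.zeros(n_perms, dtype=int)
    perm_matrix = np.zeros_like(matrix.values)
    flat = vals.ravel()
    for i in range(n_perms):
        if scope == "global":
            shuffled = rng.permutation(flat).reshape(vals.shape)
        elif scope == "per_timeslice":
            shuffled = np.column_stack(
                [rng.permutation(vals[:, t]) for t in range(vals.shape[1])]
            )
        else:
            raise ValueError("scope must be 'global' or 'per_timeslice'")
        perm_matrix[occ, :] = shuffled
        labels, n = ndimage.label(perm_matrix, structure=structure)
        if n:
            null_max[i] = np.bincount(labels.ravel())[1:].max()
    size_threshold = float(np.percentile(null_max, percentile))
    for c in clusters:
        c.mcs_p = float(
            (1 + (null_max >= c.size).sum()) / (1 + n_perms)
        )
        c.significant = c.size > size_threshold
    return ClusterMCSResult(clusters, null_max, size_threshold,
                            percentile, n_perms)


def cluster_table(result: ClusterMCSResult,
                  grid: np.ndarray | None = None) -> pd.DataFrame:
    """Flat summary table of a cluster MCS (one row per cluster)."""
    rows = []
    for i, c in enumerate(result.clusters):
        sites: list[int] = []
        if grid is not None:
            sites = sorted({int(grid[r, co]) for r, co, _ in c.cells})
        rows.append({
            "cluster": i, "sign": c.sign, "size": c.size,
            "t_start_s": c.time_window[0], "t_end_s": c.time_window[1],
            "mcs_p": c.mcs_p, "significant": c.significant,
            "sites": ";".join(map(str, sites)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group-level sensor pipeline and magnetometer follow-up
# ---------------------------------------------------------------------------


@dataclass
class SensorMCSOutcome:
    ran: bool
    positive: ClusterMCSResult | None = None
    negative: ClusterMCSResult | None = None

    def significant_window(self) -> tuple[float, float] | None:
        """Union time window of all significant clusters, or None."""
        wins = [
            c.time_window
            for res in (self.positive, self.negative) if res
            for c in res.significant
        ]
        if not wins:
            return None
        return (min(w[0] for w in wins), max(w[1] for w in wins))


def sensor_mcs(
    mean_a: np.ndarray,
    mean_b: np.ndarray,
    times: np.ndarray,
    p_threshold: float = 0.01,
    n_perms: int = 1000,
    percentile: float = 99.9,
    seed: int = 0,
    neighborhood: str = "face",
    grid: np.ndarray | None = None,
    tmin: float = 0.0,
    tmax: float = 2.5,
) -> SensorMCSOutcome:
    """t-maps -> binarize (both signs) -> cluster MCS, on (participants x
    sites x time) condition-mean stacks restricted to [tmin, tmax]."""
    times = np.asarray(times)
    win = (times >= tmin) & (times <= tmax)
    if not win.any():
        return SensorMCSOutcome(ran=False)
    t, p = mass_ttests(mean_a[:, :, win], mean_b[:, :, win])
    out = {}
    for k, sign in enumerate(("positive", "negative")):
        m = binarize(t, p, times[win], p_threshold, sign, grid)
        out[sign] = mcs_cluster_test(
            m, n_perms=n_perms, percentile=percentile, seed=seed + k,
            neighborhood=neighborhood,
        )
    return SensorMCSOutcome(True, out["positive"], out["negative"])


def magnetometer_followup(
    mag_mean_a: np.ndarray,
    mag_mean_b: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float] | None,
    **kwargs,
) -> SensorMCSOutcome:
    """Re-run the full MCS on magnetometers inside the significant
    gradiometer window; the two-step design sidesteps magnetometer sign
    ambiguity.  An empty window yields a no-follow-up outcome."""
    if window is None or window[1] <= window[0]:
        return SensorMCSOutcome(ran=False)
    return sensor_mcs(mag_mean_a, mag_mean_b, times,
                      tmin=window[0], tmax=window[1], **kwargs)


# ---------------------------------------------------------------------------
# tone windows
# ---------------------------------------------------------------------------


def tone_window_average(
    stat_map: np.ndarray,
    times: np.ndarray,
    tone_ms: float = 250.0,
    n_tones: int = 5,
) -> np.ndarray:
    """Average a (... x time) map over the per-tone windows [0, 250), [250,
    500), ... ms (half-open bins).  Requires coverage of the full excerpt."""
    times = np.asarray(times)
    total = n_tones * tone_ms / 1000.0
    if times.max() < total - 1e-9:
        raise ValueError("map does not cover the full excerpt duration")
    out = []
    for k in range(n_tones):
        lo, hi = k * tone_ms / 1000.0, (k + 1) * tone_ms / 1000.0
        m = (times >= lo) & (times < hi)
        out.append(np.asarray(stat_map)[..., m].mean(axis=-1))
    return np.stack(out, axis=-1)


# ---------------------------------------------------------------------------
# behavior scans with 1D MCS
# ---------------------------------------------------------------------------


def max_run_length(binary: np.ndarray) -> int:
    """Length of the longest run of 1s in a 1D binary array."""
    best = cur = 0
    for v in binary:
        cur = cur + 1 if v else 0
        best = max(best, cur)
    return best


def _max_run_rows(rows: np.ndarray) -> np.ndarray:
    """Maximum run of 1s per row of a binary matrix (vectorized: a window of
    length m is all ones iff m-1 successive ANDs of shifted copies survive)."""
    r = rows.astype(bool)
    out = np.zeros(r.shape[0], dtype=int)
    length = 0
    while r.size and r.any():
        length += 1
        out[r.any(axis=1)] = length
        r = r[:, 1:] & r[:, :-1]
    return out


def runs_of_ones(binary: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs (half-open) of each run of 1s."""
    b = np.asarray(binary, dtype=int)
    edges = np.diff(np.concatenate([[0], b, [0]]))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return list(zip(starts.tolist(), stops.tolist()))


@dataclass
class BehaviorScanResult:
    stat: np.ndarray            # per-timepoint r or F
    pval: np.ndarray
    binary: np.ndarray
    clusters: pd.DataFrame      # start/stop bins, length, mcs_p, significant
    null_max_runs: np.ndarray
    measure: str


def behavior_scan(
    diff_series: np.ndarray,
    behavior: np.ndarray | pd.Series,
    groups: np.ndarray | None = None,
    alpha_point: float = 0.05,
    n_perms: int = 1000,
    percentile: float = 99.9,
    seed: int = 0,
    measure: str = "",
) -> BehaviorScanResult:
    """Per-timepoint behavior-neural scan corrected by a 1D cluster MCS.

    ``diff_series`` is (participants x time) — e.g. the memorized-novel
    difference averaged over a significant cluster's channels.  With
    ``groups`` given, a one-way ANOVA across the (3) expertise groups replaces
    the Pearson correlation.  Significant points (p < alpha_point) are
    binarized; runs of 1s are compared with the maximum run length under
    1,000 random reorderings of the binarized series.
    """
    d = np.asarray(diff_series, float)
    if d.ndim != 2 or d.shape[0] < 3:
        raise ValueError("need (participants >= 3, time) neural series")
    n_time = d.shape[1]
    if groups is not None:
        groups = np.asarray(groups)
        stat = np.empty(n_time)
        pv = np.empty(n_time)
        level_masks = [groups == g for g in np.unique(groups)]
        for t in range(n_time):
            samples = [d[m, t] for m in level_masks]
            f, p = stats.f_oneway(*samples)
            stat[t], pv[t] = f, p
    else:
        b = np.asarray(behavior, float)
        if b.shape[0] != d.shape[0]:
            raise ValueError("behavior length must match participants")
        if np.std(b) == 0:
            warnings.warn(
                "constant behavioral vector: correlation undefined, "
                "reported as non-significant"
            )
            stat = np.zeros(n_time)
            pv = np.ones(n_time)
        else:
            bz = (b - b.mean()) / b.std()
            dz = d - d.mean(axis=0)
            sd = d.std(axis=0)
            sd[sd == 0] = np.inf
            r = (bz @ dz) / (d.shape[0] * sd)
            r = np.clip(r, -1.0, 1.0)
            df = d.shape[0] - 2
            with np.errstate(divide="ignore"):
                tstat = r * np.sqrt(df / np.maximum(1e-300, 1 - r**2))
            pv = 2 * stats.t.sf(np.abs(tstat), df)
            stat = r
    binary = (pv < alpha_point).astype(int)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(
        np.broadcast_to(binary, (n_perms, binary.size)), axis=1
    )
    null_max = _max_run_rows(perms)
    thr = float(np.percentile(null_max, percentile))
    rows = []
    for start, stop in runs_of_ones(binary):
        length = stop - start
        rows.append({
            "start_bin": start, "stop_bin": stop, "length": length,
            "mcs_p": float((1 + (null_max >= length).sum()) / (1 + n_perms)),
            "significant": length > thr,
        })
    clusters = pd.DataFrame(
        rows, columns=["start_bin", "stop_bin", "length", "mcs_p",
                       "significant"],
    )
    return BehaviorScanResult(stat, pv, binary, clusters, null_max, measure)


__all__ = [
    "average_trials", "combine_planar_pair", "combine_planar", "mass_ttests",
    "BinaryStatMatrix", "binarize", "ClusterRecord", "find_clusters",
    "ClusterMCSResult", "mcs_cluster_test", "cluster_table", "sensor_mcs",
    "SensorMCSOutcome", "magnetometer_followup", "tone_window_average",
    "behavior_scan", "BehaviorScanResult", "max_run_length", "runs_of_ones",
    "GRID_ROWS", "GRID_COLS",
]
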