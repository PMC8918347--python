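"""Shoal cohesion and polarization metrics.

Cohesion is summarized per focal fish and frame by the Euclidean distances
to all other shoal members: the nearest-neighbor distance (NND, minimum),
inter-individual distance (IID, mean) and farthest-neighbor distance (FND,
maximum), each averaged over frames per fish and then over fish for the
shoal-level value. Swim activity is the cumulative shoal distance (summed
per-fish path lengths).

Polarization is quantified by a PCA of the trajectory matrix: the x- and
y-components of all N trajectories are stacked into a 2N x T matrix (for a
20-fish, 30 min, 30 fps recording: 40 x 54,000), its 2N x 2N covariance
across time is eigendecomposed, and the fraction of total variance carried
by the first two principal components — which correspond to the x and y
motion of the shoal centroid — measures how strongly individual movement
follows the shoal's collective movement. The statistic is bounded below by
1/N (uncoordinated fish) and equals 1 for perfectly coherent motion.

The mixed-movie control composes pseudo-shoals from fish recorded in
different sessions (which cannot be coordinated): variance explained is
then minimal and rises continuously with the number of fish drawn from the
same recording.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedStatisticError
from .trajectory import TrajectorySet, step_lengths


@dataclass
class TrajectoryMatrix:
    """2N x T matrix of stacked trajectory components, fish-major
    (fish1_x, fish1_y, fish2_x, ...). Frames with any missing sample are
    dropped; ``frames_retained`` masks the original frames kept."""

    data: np.ndarray
    row_labels: list[str]
    frames_retained: np.ndarray  # boolean over original frames

    @property
    def n_fish(self) -> int:
        return self.data.shape[0] // 2

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


@dataclass
class PCAResult:
    """Eigendecomposition of the trajectory-matrix row covariance."""

    eigenvalues: np.ndarray  # descending, length 2N
    variance_explained: float  # fraction carried by the top-k eigenvalues
    k: int
    components: np.ndarray | None = None  # top-k eigenvectors as rows


@dataclass
class NeighborDistances:
    """Per-fish and shoal-level neighbor-distance summaries (mm)."""

    per_fish_nnd: np.ndarray
    per_fish_iid: np.ndarray
    per_fish_fnd: np.ndarray
    shoal_nnd: float
    shoal_iid: float
    shoal_fnd: float
    pairwise_iid: float  # mean over unordered pairs (equal to shoal_iid when gap-free)


@dataclass
class ShoalMetrics:
    """One record per shoal."""

    nnd_mm: float
    iid_mm: float
    fnd_mm: float
    cumulative_distance_mm: float
    variance_explained_2: float
    n_fish: int
    frames_used: int


def neighbor_distances(ts: TrajectorySet, block: int = 2000) -> NeighborDistances:
    """Time-averaged nearest/inter-individual/farthest neighbor distances.

    Per frame and focal fish, distances to all other fish with a present
    sample are taken; pairs where either sample is missing are dropped
    pairwise. Per-fish values are means over frames, shoal-level values the
    mean over fish. Frames are processed in blocks to bound memory.
    """
    n, t = ts.n_fish, ts.n_frames
    if n < 2:
        raise ConfigurationError("neighbor distances need at least 2 fish")
    sum_nnd = np.zeros(n)
    sum_iid = np.zeros(n)
    sum_fnd = np.zeros(n)
    cnt = np.zeros(n, dtype=int)
    sum_pair = 0.0
    cnt_pair = 0
    pos = ts.positions  # (N, T, 2)
    for s in range(0, t, block):
        e = min(s + block, t)
        p = pos[:, s:e]  # (N, B, 2)
        diff = p[:, None, :, :] - p[None, :, :, :]  # (N, N, B, 2)
        dist = np.hypot(diff[..., 0], diff[..., 1])  # NaN where either missing
        idx = np.arange(n)
        dist[idx, idx] = np.nan
        with warnings.catch_warnings():
            # focal fish with no co-tracked neighbor in a frame -> NaN, checked below
            warnings.simplefilter("ignore", RuntimeWarning)
            nnd = np.nanmin(dist, axis=1)  # (N, B)
            fnd = np.nanmax(dist, axis=1)
            iid = np.nanmean(dist, axis=1)
        ok = ~np.isnan(nnd)
        sum_nnd += np.where(ok, nnd, 0.0).sum(axis=1)
        sum_iid += np.where(ok, iid, 0.0).sum(axis=1)
        sum_fnd += np.where(ok, fnd, 0.0).sum(axis=1)
        cnt += ok.sum(axis=1)
        iu = np.triu_indices(n, k=1)
        pair_d = dist[iu]  # (n_pairs, B)
        pair_ok = ~np.isnan(pair_d)
        sum_pair += np.where(pair_ok, pair_d, 0.0).sum()
        cnt_pair += int(pair_ok.sum())
    if np.any(cnt == 0):
        lonely = [ts.fish_ids[i] for i in np.flatnonzero(cnt == 0)]
        raise UndefinedStatisticError(
            f"fish never co-tracked with any neighbor: {lonely}"
        )
    per_nnd = sum_nnd / cnt
    per_iid = sum_iid / cnt
    per_fnd = sum_fnd / cnt
    return NeighborDistances(
        per_fish_nnd=per_nnd,
        per_fish_iid=per_iid,
        per_fish_fnd=per_fnd,
        shoal_nnd=float(per_nnd.mean()),
        shoal_iid=float(per_iid.mean()),
        shoal_fnd=float(per_fnd.mean()),
        pairwise_iid=float(sum_pair / cnt_pair) if cnt_pair else float("nan"),
    )


def cumulative_shoal_distance(ts: TrajectorySet, mode: str = "per_fish") -> float:
    """Total swim activity of the shoal (mm).

    ``mode="per_fish"`` (default): sum over fish of per-fish path lengths,
    each the sum of consecutive non-missing step lengths. ``mode="centroid"``:
    path length of the frame-wise shoal centroid (complete frames only).
    """
    if mode == "per_fish":
        return float(sum(step_lengths(ts, fid).sum() for fid in ts.fish_ids))
    if mode == "centroid":
        complete = ~ts.missing.any(axis=0)
        c = ts.positions[:, complete].mean(axis=0)
        if c.shape[0] < 2:
            return 0.0
        d = np.diff(c, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())
    raise ConfigurationError(f"unknown mode {mode!r}")


def assemble_trajectory_matrix(ts: TrajectorySet) -> TrajectoryMatrix:
    """Stack all trajectories into the 2N x T matrix used for the PCA.

    Rows are ordered fish1_x, fish1_y, fish2_x, ...; frames containing any
    missing sample are dropped (listwise) and recorded in the mask.
    """
    retained = ~ts.missing.any(axis=0)
    if not retained.any():
        raise ConfigurationError("no complete frames to assemble")
    kept = ts.positions[:, retained]  # (N, T', 2)
    data = kept.transpose(0, 2, 1).reshape(2 * ts.n_fish, -1)
    labels = [f"{fid}_{ax}" for fid in ts.fish_ids for ax in ("x", "y")]
    return TrajectoryMatrix(data=data, row_labels=labels, frames_retained=retained)


def variance_explained(m: TrajectoryMatrix, k: int = 2,
                       return_components: bool = False) -> PCAResult:
    """Fraction of total variance captured by the top-k principal
    components of the trajectory matrix.

    Rows are centered by their time means and the 2N x 2N sample covariance
    across time (unbiased, T-1 denominator) is eigendecomposed. No variance
    scaling is applied (covariance PCA, not correlation PCA). For
    coordinated shoals the top two components track the x/y centroid
    motion.
    """
    p, t = m.data.shape
    if t < 2:
        raise ConfigurationError("need at least 2 frames for a covariance")
    if not 1 <= k <= p:
        raise ConfigurationError(f"k={k} out of range for {p} rows")
    x = m.data - m.data.mean(axis=1, keepdims=True)
    cov = (x @ x.T) / (t - 1)
    total = float(np.trace(cov))
    if total <= 0 or not np.isfinite(total):
        raise UndefinedStatisticError("zero total variance: all fish stationary")
    if return_components:
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = evals[order]
        comps = evecs[:, order[:k]].T
    else:
        evals = np.linalg.eigvalsh(cov)[::-1]
        comps = None
    evals = np.clip(evals, 0.0, None)
    ve = float(evals[:k].sum() / evals.sum())
    return PCAResult(eigenvalues=evals, variance_explained=ve, k=k, components=comps)


def mixed_shoal_control(recordings: Sequence[TrajectorySet],
                        k_same_values: Sequence[int] | None = None,
                        n_total: int = 20,
                        replicates: int = 10,
                        seed: int = 0) -> pd.DataFrame:
    """Variance explained of pseudo-shoals mixing fish across recordings.

    For each ``k_same``, every replicate draws ``k_same`` fish from one
    focal recording and the remaining ``n_total - k_same`` fish from
    *distinct* other recordings (one fish each), truncates all trajectories
    to the shortest recording, and computes the two-component variance
    explained. Fish from different recordings cannot be coordinated, so
    the mean curve rises from about 1/N at ``k_same = 0`` toward the true
    shoal value at ``k_same = n_total``.

    Returns a DataFrame with columns ``k_same, mean_ve, sd_ve, replicates``.
    """
    if len(recordings) < 2:
        raise ConfigurationError("mixed control needs at least 2 recordings")
    if k_same_values is None:
        k_same_values = list(range(n_total + 1))
    t_min = min(r.n_frames for r in recordings)
    frame_rate = recordings[0].frame_rate_hz
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for k_same in k_same_values:
        if not 0 <= k_same <= n_total:
            raise ConfigurationError(f"k_same={k_same} outside [0, {n_total}]")
        need_others = n_total - k_same
        if need_others + 1 > len(recordings) and need_others > 0:
            raise ConfigurationError(
                f"k_same={k_same} needs {need_others + 1} recordings, have {len(recordings)}"
            )
        if k_same > min(r.n_fish for r in recordings):
            raise ConfigurationError("k_same exceeds the smallest recording's shoal size")
        ves = []
        for _ in range(replicates):
            focal = int(rng.integers(len(recordings)))
            tracks = []
            if k_same > 0:
                fish = rng.choice(recordings[focal].n_fish, size=k_same, replace=False)
                tracks.append(recordings[focal].positions[fish, :t_min])
            if need_others > 0:
                pool = [j for j in range(len(recordings)) if j != focal]
                others = rng.choice(len(pool), size=need_others, replace=False)
                for j in others:
                    r = recordings[pool[j]]
                    f = int(rng.integers(r.n_fish))
                    tracks.append(r.positions[f:f + 1, :t_min])
            pos = np.concatenate(tracks, axis=0)
            pseudo = TrajectorySet(
                fish_ids=[f"p{i:02d}" for i in range(n_total)],
                positions=pos,
                frame_rate_hz=frame_rate,
                arena=recordings[focal].arena,
                source_id="mixed-control",
            )
            ves.append(variance_explained(assemble_trajectory_matrix(pseudo)).variance_explained)
        rows.append({"k_same": int(k_same), "mean_ve": float(np.mean(ves)),
                     "sd_ve": float(np.std(ves, ddof=1)) if len(ves) > 1 else 0.0,
                     "replicates": len(ves)})
    return pd.DataFrame(rows)


def shoal_metrics(ts: TrajectorySet) -> ShoalMetrics:
    """All shoal summaries for one recording (one record per shoal)."""
    nd = neighbor_distances(ts)
    matrix = assemble_trajectory_matrix(ts)
    pca = variance_explained(matrix, k=2)
    return ShoalMetrics(
        nnd_mm=nd.shoal_nnd,
        iid_mm=nd.shoal_iid,
        fnd_mm=nd.shoal_fnd,
        cumulative_distance_mm=cumulative_shoal_distance(ts),
        variance_explained_2=pca.variance_explained,
        n_fish=ts.n_fish,
        frames_used=matrix.n_frames,
    )
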