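"""Cross-batch common-peak matching and fingerprint similarity scoring.

A peak that appears with good resolution in every batch is a
"characteristic" (common) peak; the set of common peaks, their matched
retention times and areas form the fingerprint table.  Batch similarity is
the congruence (cosine) coefficient between a batch trace and the mean
reference chromatogram over the analysis window, after an optional rigid
retention shift that removes the shared per-batch drift (no time warping).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .peaks import DEFAULT_WINDOW, Peak
from .simulate import Chromatogram

__all__ = [
    "FingerprintError",
    "FingerprintTable",
    "SimilarityResult",
    "match_common_peaks",
    "build_reference",
    "similarity",
    "FingerprintModel",
]


class FingerprintError(ValueError):
    pass


@dataclass(frozen=True)
class SimilarityResult:
    batch_id: str
    score: float
    window: tuple[float, float]


@dataclass(frozen=True)
class FingerprintTable:
    """Common peaks x batches matrix of matched retention times and areas."""

    batches: tuple[str, ...]
    rt: pd.DataFrame      # rows: common peak number, columns: batch ids
    area: pd.DataFrame    # same shape
    rt_tolerance: float

    @property
    def n_common(self) -> int:
        return len(self.rt)

    @property
    def median_rt(self) -> pd.Series:
        return self.rt.median(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rt = self.rt.add_prefix("rt_")
        area = self.area.add_prefix("area_")
        out = pd.concat([rt, area], axis=1)
        out.index.name = "common_peak"
        return out


def _as_batch_dict(
    peak_lists: Union[Mapping[str, Sequence[Peak]], Sequence[Sequence[Peak]]],
) -> dict[str, Sequence[Peak]]:
    if isinstance(peak_lists, Mapping):
        return {str(k): v for k, v in peak_lists.items()}
    return {f"batch{i:02d}": v for i, v in enumerate(peak_lists)}


def match_common_peaks(
    peak_lists: Union[Mapping[str, Sequence[Peak]], Sequence[Sequence[Peak]]],
    rt_tolerance: float = 0.3,
) -> FingerprintTable:
    """Chain peaks across batches into clusters by apex retention time.

    Batches are processed in sorted batch-id order (so the result does not
    depend on input order).  Each new batch is first anchored by removing
    the median retention offset of its peaks against the current cluster
    centers, then greedily matched nearest-first within ``rt_tolerance``,
    one peak per batch per cluster.  A cluster is a common peak iff it
    received exactly one peak from every batch; common peaks are numbered
    by ascending median retention time.
    """
    if rt_tolerance <= 0:
        raise FingerprintError("rt_tolerance must be > 0")
    batches = _as_batch_dict(peak_lists)
    if len(batches) < 2:
        raise FingerprintError("need at least two batches")
    order = sorted(batches)

    # clusters: list of dicts batch_id -> Peak; centers in the anchor frame
    clusters: list[dict[str, Peak]] = []
    centers: list[float] = []

    for bi, batch_id in enumerate(order):
        pks = sorted(batches[batch_id], key=lambda p: p.apex_rt)
        if bi == 0:
            for p in pks:
                clusters.append({batch_id: p})
                centers.append(p.apex_rt)
            continue
        offset = 0.0
        if centers and pks:
            diffs = []
            carr = np.asarray(centers)
            for p in pks:
                d = p.apex_rt - carr[np.argmin(np.abs(carr - p.apex_rt))]
                if abs(d) <= 3.0 * rt_tolerance:
                    diffs.append(d)
            if diffs:
                offset = float(np.median(diffs))
        # nearest-first greedy assignment
        cand = []
        for pi, p in enumerate(pks):
            for ci, c in enumerate(centers):
                d = abs((p.apex_rt - offset) - c)
                if d <= rt_tolerance:
                    cand.append((d, pi, ci))
        cand.sort()
        used_p: set[int] = set()
        used_c: set[int] = set()
        for d, pi, ci in cand:
            if pi in used_p or ci in used_c:
                continue
            clusters[ci][batch_id] = pks[pi]
            used_p.add(pi)
            used_c.add(ci)
        for pi, p in enumerate(pks):
            if pi not in used_p:
                clusters.append({batch_id: p})
                centers.append(p.apex_rt - offset)
        # refresh centers as the running mean of member apexes (anchor frame
        # approximation: member rts are close enough at this tolerance)
        for ci, cl in enumerate(clusters):
            centers[ci] = float(np.mean([q.apex_rt for q in cl.values()]))

    n_batches = len(order)
    common = [cl for cl in clusters if len(cl) == n_batches]
    common.sort(key=lambda cl: float(np.median([p.apex_rt for p in cl.values()])))
    idx = pd.RangeIndex(1, len(common) + 1, name="common_peak")
    rt = pd.DataFrame(
        {b: [cl[b].apex_rt for cl in common] for b in order}, index=idx
    )
    area = pd.DataFrame(
        {b: [cl[b].area for cl in common] for b in order}, index=idx
    )
    return FingerprintTable(tuple(order), rt, area, rt_tolerance)


def _resample(
    chrom: Chromatogram, grid: np.ndarray
) -> np.ndarray:
    t, y = chrom.time, chrom.intensity
    if t[0] > grid[0] + 1e-9 or t[-1] < grid[-1] - 1e-9:
        raise FingerprintError("chromatogram does not cover the window")
    return np.interp(grid, t, y)


def _window_grid(
    chroms: Sequence[Chromatogram], window: tuple[float, float]
) -> np.ndarray:
    lo, hi = window
    if not lo < hi:
        raise FingerprintError("empty window")
    dt = min(c.sampling_interval for c in chroms)
    return np.arange(lo, hi + 0.5 * dt, dt)


def _best_shift(y: np.ndarray, ref: np.ndarray, max_lag: int) -> int:
    """Integer-sample rigid shift of ``y`` maximizing correlation with ``ref``."""
    best, best_lag = -np.inf, 0
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = y[lag:], ref[: ref.size - lag]
        else:
            a, b = y[:lag], ref[-lag:]
        s = float(np.dot(a, b))
        if s > best:
            best, best_lag = s, lag
    return best_lag


def build_reference(
    chroms: Sequence[Chromatogram],
    window: tuple[float, float] = DEFAULT_WINDOW,
    align: bool = True,
    max_shift: float = 0.3,
    method: str = "mean",
) -> Chromatogram:
    """Reference fingerprint: pointwise mean of the resampled batch traces.

    With ``align=True`` every trace is first rigidly shifted (cross-
    correlation, at most ``max_shift`` minutes) onto the first trace so the
    mean is not smeared by shared per-batch retention drift.  ``method``
    may be ``"median"`` for a median reference.
    """
    if len(chroms) < 2:
        raise FingerprintError("need at least two chromatograms")
    grid = _window_grid(chroms, window)
    mat = np.vstack([_resample(c, grid) for c in chroms])
    if align:
        dt = float(grid[1] - grid[0])
        max_lag = max(1, int(round(max_shift / dt)))
        for i in range(1, mat.shape[0]):
            lag = _best_shift(mat[i], mat[0], max_lag)
            if lag:
                mat[i] = np.interp(grid, grid - lag * dt, mat[i])
    agg = np.median(mat, axis=0) if method == "median" else mat.mean(axis=0)
    return Chromatogram(grid, agg, {"batch_id": "reference", "n": len(chroms)})


def similarity(
    chrom: Chromatogram,
    reference: Chromatogram,
    window: tuple[float, float] = DEFAULT_WINDOW,
    align: bool = True,
    max_shift: float = 0.3,
    metric: str = "cosine",
) -> SimilarityResult:
    """Congruence of a batch trace with the reference over the window.

    ``metric="cosine"`` is the congruence coefficient on the raw resampled
    vectors (scale invariant); ``metric="pearson"`` centers the vectors
    first.  Scores are clipped to [0, 1].
    """
    grid = _window_grid([chrom, reference], window)
    y = _resample(chrom, grid)
    r = _resample(reference, grid)
    if align:
        dt = float(grid[1] - grid[0])
        lag = _best_shift(y, r, max(1, int(round(max_shift / dt))))
        if lag:
            y = np.interp(grid, grid - lag * dt, y)
    if metric == "pearson":
        y = y - y.mean()
        r = r - r.mean()
    ny, nr = np.linalg.norm(y), np.linalg.norm(r)
    if ny == 0 or nr == 0:
        raise FingerprintError("similarity undefined for a zero-norm trace")
    score = float(np.clip(np.dot(y, r) / (ny * nr), 0.0, 1.0))
    return SimilarityResult(str(chrom.meta.get("batch_id", "")), score, tuple(window))


class FingerprintModel(BaseEstimator):
    """Estimator facade: fit a reference fingerprint, score batches.

    ``fit`` consumes per-batch chromatograms (and optionally peak lists)
    and stores the mean reference trace and the common-peak table;
    ``score_batches`` returns per-batch similarity results.
    """

    def __init__(
        self,
        window: tuple[float, float] = DEFAULT_WINDOW,
        rt_tolerance: float = 0.3,
        align: bool = True,
        metric: str = "cosine",
        reference_method: str = "mean",
    ):
        self.window = window
        self.rt_tolerance = rt_tolerance
        self.align = align
        self.metric = metric
        self.reference_method = reference_method

    def fit(
        self,
        chroms: Sequence[Chromatogram],
        peak_lists: Optional[
            Union[Mapping[str, Sequence[Peak]], Sequence[Sequence[Peak]]]
        ] = None,
    ) -> "FingerprintModel":
        self.reference_ = build_reference(
            chroms, self.window, align=self.align, method=self.reference_method
        )
        if peak_lists is not None:
            self.fingerprint_table_ = match_common_peaks(peak_lists, self.rt_tolerance)
        return self

    def score_batches(self, chroms: Sequence[Chromatogram]) -> list[SimilarityResult]:
        if not hasattr(self, "reference_"):
            raise FingerprintError("model is not fitted")
        return [
            similarity(c, self.reference_, self.window, self.align, metric=self.metric)
            for c in chroms
        ]
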