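"""Chromatographic feature extraction: raw runs -> aligned feature table.

Detection operates on per-integer-m/z extracted ion chromatograms (EICs) —
appropriate for unit-mass quadrupole GC-MS, where the usual high-resolution
region-of-interest machinery collapses to one slice per nominal mass. Apexes
are located on a Gaussian-smoothed EIC, while the half-height width filter is
applied to the *deconvolved* width (observed width minus smoothing kernel, in
quadrature) so the stated 5–20 s peak-width window refers to the underlying
peak, not the smoothed one.

Cross-sample retention alignment uses peak-group anchors (well-behaved peaks
present in nearly all samples) and a local-regression warp, a documented
stand-in for raw-profile dynamic warping with the same purpose: remove
inter-run drift before grouping. Grouping follows the kernel-density approach
of XCMS with the stated defaults (mzwid 0.015, bw 5 s, minfrac 0.5).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .synthio import Run, SampleMeta

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionParams",
    "GroupingParams",
    "Peak",
    "Feature",
    "Warp",
    "extract_eics",
    "detect_peaks",
    "correct_rt",
    "group_peaks",
    "fill_missing",
    "average_technical_replicates",
    "features_to_dataframe",
    "peaks_to_dataframe",
]


@dataclass(frozen=True)
class DetectionParams:
    """Peak-detection parameters (defaults follow the untargeted workflow:
    peak width 5–20 s, S/N 6, mzdiff 0.01, prefilter 3 scans ≥ 100 counts,
    absolute noise filter 0)."""

    peakwidth_min: float = 5.0   # seconds
    peakwidth_max: float = 20.0  # seconds
    sn_threshold: float = 6.0
    mzdiff: float = 0.01
    prefilter_k: int = 3
    prefilter_I: float = 100.0
    noise: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.peakwidth_min < self.peakwidth_max):
            raise ValueError("require 0 < peakwidth_min < peakwidth_max")
        if self.sn_threshold < 0:
            raise ValueError("sn_threshold must be >= 0")
        if self.prefilter_k < 1:
            raise ValueError("prefilter_k must be >= 1")


@dataclass(frozen=True)
class GroupingParams:
    """Cross-sample grouping parameters (mzwid 0.015 m/z, bw 5 s,
    minfrac 0.5, max 100 groups per slice, minsamp 1)."""

    mzwid: float = 0.015
    bw: float = 5.0  # seconds
    minfrac: float = 0.5
    max_per_slice: int = 100
    minsamp: int = 1

    def __post_init__(self) -> None:
        if min(self.mzwid, self.bw) <= 0 or self.max_per_slice <= 0 or self.minsamp <= 0:
            raise ValueError("grouping parameters must be positive")
        if not (0 < self.minfrac <= 1):
            raise ValueError("minfrac must lie in (0, 1]")


@dataclass
class Peak:
    """A detected chromatographic peak in one run (rt fields in minutes,
    area in counts·s — the 'into' of XCMS — height in counts)."""

    run_id: str
    mz: int
    rt: float
    rt_lo: float
    rt_hi: float
    area: float
    height: float
    sn: float


@dataclass
class Feature:
    """A cross-sample aligned feature ``M{mz}T{rt}`` with one intensity per
    column (run before replicate averaging, biological sample after)."""

    feature_id: str
    mzmed: int
    rtmed: float
    rt_lo: float
    rt_hi: float
    intensity: dict[str, float]
    detected: set[str] = field(default_factory=set)
    class_fraction: dict[str, float] = field(default_factory=dict)


class Warp:
    """Monotone retention-time correction for one run.

    Stored as a strictly increasing piecewise-linear map evaluated by
    interpolation; guaranteed never to reorder scans.
    """

    def __init__(self, grid: np.ndarray, corrected: np.ndarray):
        corrected = np.asarray(corrected, dtype=float).copy()
        # clamp to strict monotonicity
        eps = 1e-9
        np.maximum.accumulate(corrected, out=corrected)
        corrected += eps * np.arange(corrected.size)
        self.grid = np.asarray(grid, dtype=float)
        self.corrected = corrected

    @classmethod
    def identity(cls) -> "Warp":
        return cls(np.array([0.0, 1.0]), np.array([0.0, 1.0]))

    def __call__(self, rt: float | np.ndarray) -> np.ndarray | float:
        out = np.interp(rt, self.grid, self.corrected)
        # linear extrapolation with edge slope ~1 outside the grid
        lo, hi = self.grid[0], self.grid[-1]
        rt_arr = np.asarray(rt, dtype=float)
        below = rt_arr < lo
        above = rt_arr > hi
        if np.any(below) or np.any(above):
            out = np.where(below, self.corrected[0] + (rt_arr - lo), out)
            out = np.where(above, self.corrected[-1] + (rt_arr - hi), out)
        return float(out) if np.isscalar(rt) else out


# ---------------------------------------------------------------------------
# EIC extraction
# ---------------------------------------------------------------------------


def extract_eics(run: Run) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Bin a run's centroid scans onto nominal-mass channels.

    Returns ``(times, {mz: intensity array})``; every channel covers all scan
    times, absent m/z values are zero, and the per-scan sum over channels
    equals the scan's total ion current.
    """
    if not run.scans:
        raise ValueError("run has no scans")
    times = run.times
    n = times.size
    channels: dict[int, np.ndarray] = {}
    # fast path: identical m/z axis on every scan (the simulator's layout)
    first_mz = run.scans[0][1]
    uniform = all(len(mz) == len(first_mz) and np.array_equal(mz, first_mz) for _, mz, _ in run.scans)
    if uniform and len(first_mz) and np.all(np.asarray(first_mz) == np.round(first_mz)):
        mat = np.stack([inten for _, _, inten in run.scans])
        for j, mz in enumerate(np.asarray(first_mz, dtype=int)):
            if mz in channels:
                channels[mz] = channels[mz] + mat[:, j]
            else:
                channels[mz] = mat[:, j].copy()
        return times, channels
    for i, (_, mz, inten) in enumerate(run.scans):
        for m, v in zip(np.rint(np.asarray(mz)).astype(int), np.asarray(inten, dtype=float)):
            ch = channels.get(m)
            if ch is None:
                ch = channels[m] = np.zeros(n)
            ch[i] += v
    return times, channels


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------


def _runs_of_at_least(mask: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of positions belonging to a run of >= k consecutive True."""
    if k <= 1:
        return mask.copy()
    conv = np.convolve(mask.astype(int), np.ones(k, dtype=int), mode="valid")
    hit = conv == k
    out = np.zeros(mask.size, dtype=bool)
    for off in range(k):
        out[off : off + hit.size] |= hit
    return out


def _half_height_width(x: np.ndarray, apex: int, lo: int, hi: int, base: float, dt_s: float) -> float:
    """Width at half height (seconds) of x[lo:hi+1] around apex, by linear
    interpolation of the half-level crossings."""
    h = x[apex] - base
    if h <= 0:
        return 0.0
    half = base + h / 2.0
    left = float(apex)
    i = apex
    while i > lo and x[i] > half:
        i -= 1
    if x[i] <= half and x[i + 1] != x[i]:
        left = i + (half - x[i]) / (x[i + 1] - x[i])
    elif i == lo:
        left = float(lo)
    right = float(apex)
    i = apex
    while i < hi and x[i] > half:
        i += 1
    if x[i] <= half and x[i - 1] != x[i]:
        right = i - (half - x[i]) / (x[i - 1] - x[i])
    elif i == hi:
        right = float(hi)
    return (right - left) * dt_s


def detect_peaks(run: Run, params: DetectionParams | None = None) -> list[Peak]:
    """Detect chromatographic peaks on every nominal-mass EIC of a run.

    A candidate apex (local maximum of the Gaussian-smoothed EIC) is retained
    iff (i) its window contains a run of ``prefilter_k`` consecutive raw scans
    at or above ``prefilter_I``; (ii) its deconvolved half-height width falls
    within ``[peakwidth_min, peakwidth_max]`` seconds; and (iii) its
    signal-to-noise, (raw height − local baseline) / noise estimate, reaches
    ``sn_threshold``, with the noise estimated as 1.4826 × MAD of the channel
    outside candidate windows (floor 1). The area is the trapezoid above a
    straight baseline drawn between the window endpoints.

    A run shorter than one minimum peak width yields an empty list.
    """
    params = params or DetectionParams()
    times, channels = extract_eics(run)
    if times.size < 3:
        return []
    dt_min = float(np.median(np.diff(times)))
    dt_s = dt_min * 60.0
    min_scans = params.peakwidth_min / dt_s
    if times.size * dt_s < params.peakwidth_min:
        return []
    sigma_smooth_s = params.peakwidth_min / 2.355
    sigma_scans = max(sigma_smooth_s / dt_s, 0.5)
    kernel_fwhm_s = 2.355 * sigma_smooth_s
    dilate = max(int(round(params.peakwidth_max / dt_s)), 2)

    peaks: list[Peak] = []
    for mz in sorted(channels):
        x = channels[mz]
        pre = _runs_of_at_least(x >= params.prefilter_I, params.prefilter_k)
        if not pre.any():
            continue
        # candidate region: prefilter runs dilated by one max peak width
        idx = np.flatnonzero(pre)
        region = np.zeros_like(pre)
        for i in idx:
            region[max(0, i - dilate) : i + dilate + 1] = True
        outside = x[~region]
        if outside.size >= 10:
            baseline = float(np.median(outside))
            mad = float(np.median(np.abs(outside - baseline)))
            noise_est = max(1.4826 * mad, 1.0)
        else:
            baseline = float(np.median(x))
            noise_est = max(1.4826 * float(np.median(np.abs(x - baseline))), 1.0)

        smooth = gaussian_filter1d(x, sigma_scans)
        # permissive height gate; the definitive S/N test is on the raw height
        gate = baseline + 0.5 * params.sn_threshold * noise_est
        apexes, _ = find_peaks(smooth, height=gate)
        apexes = apexes[region[apexes]]
        for apex in apexes:
            # walk down the smoothed EIC to the enclosing valleys
            lo = apex
            while lo > 0 and smooth[lo - 1] < smooth[lo]:
                lo -= 1
            hi = apex
            while hi < smooth.size - 1 and smooth[hi + 1] < smooth[hi]:
                hi += 1
            if hi - lo + 1 < max(3, int(min_scans * 0.5)):
                continue
            if not pre[lo : hi + 1].any():
                continue
            w_obs = _half_height_width(smooth, apex, lo, hi, baseline, dt_s)
            w_raw = float(np.sqrt(max(w_obs**2 - kernel_fwhm_s**2, 0.0)))
            if not (params.peakwidth_min <= w_raw <= params.peakwidth_max):
                continue
            height = float(np.max(x[lo : hi + 1]))
            sn = (height - baseline) / noise_est
            if sn < params.sn_threshold or height <= params.noise:
                continue
            seg = x[lo : hi + 1].astype(float)
            base_line = np.linspace(x[lo], x[hi], seg.size)
            above = np.clip(seg - base_line, 0.0, None)
            area = float(np.trapezoid(above, times[lo : hi + 1] * 60.0))
            if area <= 0:
                continue
            peaks.append(
                Peak(
                    run_id=run.meta.run_id,
                    mz=int(mz),
                    rt=float(times[apex]),
                    rt_lo=float(times[lo]),
                    rt_hi=float(times[hi]),
                    area=area,
                    height=height,
                    sn=float(sn),
                )
            )
    peaks.sort(key=lambda p: (p.mz, p.rt))
    return peaks


# ---------------------------------------------------------------------------
# retention-time correction
# ---------------------------------------------------------------------------


def _density_segments(rts: np.ndarray, bw_min: float) -> list[np.ndarray]:
    """Partition peak rts (one m/z slice) into groups under the maxima of a
    Gaussian kernel density with bandwidth ``bw_min`` (minutes). Returns a
    list of index arrays into ``rts``."""
    if rts.size == 1:
        return [np.array([0])]
    lo, hi = rts.min() - 3 * bw_min, rts.max() + 3 * bw_min
    step = bw_min / 4.0
    grid = np.arange(lo, hi + step, step)
    dens = np.exp(-0.5 * ((grid[:, None] - rts[None, :]) / bw_min) ** 2).sum(axis=1)
    maxima, _ = find_peaks(dens)
    if maxima.size == 0:
        return [np.arange(rts.size)]
    # boundaries at density minima between adjacent maxima
    bounds = []
    for a, b in zip(maxima[:-1], maxima[1:]):
        bounds.append(grid[a + int(np.argmin(dens[a : b + 1]))])
    which = np.searchsorted(np.asarray(bounds), rts)
    return [np.flatnonzero(which == g) for g in range(maxima.size) if np.any(which == g)]


def correct_rt(
    peaks: Sequence[Peak],
    n_runs: int | None = None,
    min_anchor_fraction: float = 0.9,
    ladder_rts: Mapping[str, Sequence[float]] | None = None,
    lowess_frac: float = 0.6,
) -> tuple[dict[str, Warp], list[Peak], pd.DataFrame]:
    """Estimate a monotone retention-time warp per run from anchor peak
    groups and return (warps, corrected peaks, diagnostics).

    Anchors are peak groups detected in at least ``min_anchor_fraction`` of
    the runs with exactly one peak per run. Each run's deviations from the
    anchor median rt are smoothed by local regression (lowess) and subtracted;
    the result is clamped to strict monotonicity. With fewer than five anchors
    the alkane ladder (if per-run ladder rts are supplied) provides fallback
    anchors; with none at all, warps are identity and a warning is issued.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    run_ids = sorted({p.run_id for p in peaks})
    if n_runs is None:
        n_runs = len(run_ids)
    if n_runs < 2:
        warnings.warn("retention correction needs >= 2 runs; returning identity warps")
        return {r: Warp.identity() for r in run_ids}, list(peaks), pd.DataFrame()

    # candidate anchor groups per m/z channel
    by_mz: dict[int, list[Peak]] = {}
    for p in peaks:
        by_mz.setdefault(p.mz, []).append(p)
    anchors: list[dict[str, float]] = []  # run_id -> rt for each anchor group
    for mz, plist in by_mz.items():
        rts = np.array([p.rt for p in plist])
        for seg in _density_segments(rts, 5.0 / 60.0):
            grp = [plist[i] for i in seg]
            ids = [p.run_id for p in grp]
            if len(set(ids)) == len(ids) and len(ids) >= min_anchor_fraction * n_runs:
                anchors.append({p.run_id: p.rt for p in grp})
    if len(anchors) < 5 and ladder_rts is not None:
        for i in range(min(len(v) for v in ladder_rts.values())):
            anchors.append({r: float(ladder_rts[r][i]) for r in ladder_rts})
    if not anchors:
        warnings.warn("no anchor groups found; retention times left uncorrected")
        warps = {r: Warp.identity() for r in run_ids}
        return warps, list(peaks), pd.DataFrame()

    med = np.array([float(np.median(list(a.values()))) for a in anchors])
    warps: dict[str, Warp] = {}
    diag_rows = []
    grid = np.linspace(min(p.rt_lo for p in peaks) - 1.0, max(p.rt_hi for p in peaks) + 1.0, 400)
    for rid in run_ids:
        xs, dev = [], []
        for a, m in zip(anchors, med):
            if rid in a:
                xs.append(a[rid])
                dev.append(a[rid] - m)
        xs = np.array(xs)
        dev = np.array(dev)
        if xs.size == 0:
            warps[rid] = Warp.identity()
            continue
        if xs.size < 3:
            shift = float(np.median(dev))
            corrected = grid - shift
        else:
            frac = min(1.0, max(lowess_frac, 5.0 / xs.size))
            fit = lowess(dev, xs, frac=frac, it=1, return_sorted=True)
            dev_on_grid = np.interp(grid, fit[:, 0], fit[:, 1])
            corrected = grid - dev_on_grid
        warps[rid] = Warp(grid, corrected)
        after = np.array([warps[rid](x) for x in xs]) - med[[i for i, a in enumerate(anchors) if rid in a]]
        diag_rows.append(
            {
                "run_id": rid,
                "n_anchors": xs.size,
                "mad_before_s": float(np.median(np.abs(dev))) * 60.0,
                "mad_after_s": float(np.median(np.abs(after))) * 60.0,
            }
        )
    corrected_peaks = [
        Peak(
            run_id=p.run_id,
            mz=p.mz,
            rt=float(warps.get(p.run_id, Warp.identity())(p.rt)),
            rt_lo=float(warps.get(p.run_id, Warp.identity())(p.rt_lo)),
            rt_hi=float(warps.get(p.run_id, Warp.identity())(p.rt_hi)),
            area=p.area,
            height=p.height,
            sn=p.sn,
        )
        for p in peaks
    ]
    return warps, corrected_peaks, pd.DataFrame(diag_rows)


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------


def _class_of(meta: SampleMeta) -> str:
    return f"{meta.rootstock}/{meta.irrigation}"


def group_peaks(
    peaks: Sequence[Peak],
    metadata: Sequence[SampleMeta],
    params: GroupingParams | None = None,
) -> list[Feature]:
    """Group rt-corrected peaks across runs into features.

    On nominal-mass data every integer m/z is its own slice (mzwid 0.015 is
    far below unit spacing). Within a slice, groups form under maxima of a
    Gaussian kernel density over rt (bandwidth ``bw`` seconds), at most
    ``max_per_slice`` per slice. A group is kept iff some metadata class
    (rootstock × irrigation cell) contains it in at least
    ``max(minsamp, minfrac × class size)`` of its runs — the minfrac boundary
    is inclusive. One peak per run per feature; the larger area wins.
    """
    params = params or GroupingParams()
    meta_by_run = {m.run_id: m for m in metadata}
    class_sizes: dict[str, int] = {}
    level_sizes: dict[str, int] = {}
    for m in metadata:
        class_sizes[_class_of(m)] = class_sizes.get(_class_of(m), 0) + 1
        for lv in (m.rootstock, m.irrigation):
            level_sizes[lv] = level_sizes.get(lv, 0) + 1

    by_mz: dict[int, list[Peak]] = {}
    for p in peaks:
        by_mz.setdefault(p.mz, []).append(p)

    features: list[Feature] = []
    seen_ids: dict[str, int] = {}
    bw_min = params.bw / 60.0
    for mz in sorted(by_mz):
        plist = by_mz[mz]
        rts = np.array([p.rt for p in plist])
        segs = _density_segments(rts, bw_min)
        if len(segs) > params.max_per_slice:
            segs = sorted(segs, key=len, reverse=True)[: params.max_per_slice]
        for seg in segs:
            grp = [plist[i] for i in seg]
            best: dict[str, Peak] = {}
            for p in grp:
                cur = best.get(p.run_id)
                if cur is None or p.area > cur.area:
                    best[p.run_id] = p
            counts: dict[str, int] = {}
            for rid in best:
                cls = _class_of(meta_by_run[rid]) if rid in meta_by_run else "?"
                counts[cls] = counts.get(cls, 0) + 1
            keep = any(
                counts.get(cls, 0) >= max(params.minsamp, params.minfrac * size)
                for cls, size in class_sizes.items()
            )
            if not keep:
                continue
            rtmed = float(np.median([p.rt for p in best.values()]))
            fid = f"M{mz}T{rtmed:.2f}"
            if fid in seen_ids:
                seen_ids[fid] += 1
                fid = f"{fid}_{seen_ids[fid]}"
            else:
                seen_ids[fid] = 1
            level_counts: dict[str, int] = {}
            for rid in best:
                m = meta_by_run.get(rid)
                if m is None:
                    continue
                for lv in (m.rootstock, m.irrigation):
                    level_counts[lv] = level_counts.get(lv, 0) + 1
            features.append(
                Feature(
                    feature_id=fid,
                    mzmed=int(mz),
                    rtmed=rtmed,
                    rt_lo=float(np.median([p.rt_lo for p in best.values()])),
                    rt_hi=float(np.median([p.rt_hi for p in best.values()])),
                    intensity={rid: p.area for rid, p in best.items()},
                    detected=set(best),
                    class_fraction={
                        lv: level_counts.get(lv, 0) / size for lv, size in level_sizes.items()
                    },
                )
            )
    features.sort(key=lambda f: (f.rtmed, f.mzmed))
    return features


# ---------------------------------------------------------------------------
# fill-in and replicate averaging
# ---------------------------------------------------------------------------


def fill_missing(
    features: Sequence[Feature],
    runs: Sequence[Run],
    warps: Mapping[str, Warp] | None = None,
    noise_floor: float = 1.0,
) -> list[Feature]:
    """Complete every feature's intensity map by integrating the raw (warped)
    EIC over the group's median rt window for runs without a detected peak.
    A zero integral falls back to a noise-floor area; detected intensities
    are never modified."""
    eics: dict[str, tuple[np.ndarray, dict[int, np.ndarray]]] = {}
    for run in runs:
        times, channels = extract_eics(run)
        w = warps.get(run.meta.run_id) if warps else None
        tw = w(times) if w is not None else times
        eics[run.meta.run_id] = (np.asarray(tw, dtype=float), channels)

    out: list[Feature] = []
    for f in features:
        intensity = dict(f.intensity)
        for rid, (tw, channels) in eics.items():
            if rid in intensity:
                continue
            ch = channels.get(f.mzmed)
            filled = 0.0
            if ch is not None:
                mask = (tw >= f.rt_lo) & (tw <= f.rt_hi)
                if mask.sum() >= 2:
                    filled = float(np.trapezoid(ch[mask], tw[mask] * 60.0))
            if filled <= 0:
                filled = max(noise_floor * (f.rt_hi - f.rt_lo) * 60.0, 1.0)
            intensity[rid] = filled
        out.append(
            Feature(
                feature_id=f.feature_id,
                mzmed=f.mzmed,
                rtmed=f.rtmed,
                rt_lo=f.rt_lo,
                rt_hi=f.rt_hi,
                intensity=intensity,
                detected=set(f.detected),
                class_fraction=dict(f.class_fraction),
            )
        )
    return out


def average_technical_replicates(
    features: Sequence[Feature], metadata: Sequence[SampleMeta]
) -> list[Feature]:
    """Average duplicate injections: feature intensities become the arithmetic
    mean over a sample's injections, keyed by biological ``sample_id``.
    Class fractions are recomputed on biological samples (a sample counts as
    detected if any of its injections was)."""
    run_to_bio = {m.run_id: m.sample_id for m in metadata}
    bio_meta: dict[str, SampleMeta] = {}
    for m in metadata:
        bio_meta.setdefault(m.sample_id, m)
    n_inj: dict[str, int] = {}
    for m in metadata:
        n_inj[m.sample_id] = n_inj.get(m.sample_id, 0) + 1
    if len(set(n_inj.values())) > 1:
        logger.warning("unbalanced replicate counts: %s", sorted(set(n_inj.values())))

    level_sizes: dict[str, int] = {}
    for m in bio_meta.values():
        for lv in (m.rootstock, m.irrigation):
            level_sizes[lv] = level_sizes.get(lv, 0) + 1

    out: list[Feature] = []
    for f in features:
        sums: dict[str, float] = {}
        counts: dict[str, int] = {}
        det_bio: set[str] = set()
        for rid, v in f.intensity.items():
            sid = run_to_bio.get(rid, rid)
            sums[sid] = sums.get(sid, 0.0) + v
            counts[sid] = counts.get(sid, 0) + 1
        for rid in f.detected:
            det_bio.add(run_to_bio.get(rid, rid))
        intensity = {sid: sums[sid] / counts[sid] for sid in sums}
        level_counts: dict[str, int] = {}
        for sid in det_bio:
            m = bio_meta.get(sid)
            if m is None:
                continue
            for lv in (m.rootstock, m.irrigation):
                level_counts[lv] = level_counts.get(lv, 0) + 1
        out.append(
            Feature(
                feature_id=f.feature_id,
                mzmed=f.mzmed,
                rtmed=f.rtmed,
                rt_lo=f.rt_lo,
                rt_hi=f.rt_hi,
                intensity=intensity,
                detected=det_bio,
                class_fraction={lv: level_counts.get(lv, 0) / sz for lv, sz in level_sizes.items()},
            )
        )
    return out


# ---------------------------------------------------------------------------
# tabular views
# ---------------------------------------------------------------------------


def features_to_dataframe(features: Sequence[Feature], columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Feature table: rows = feature ids, columns = samples (or runs)."""
    if columns is None:
        cols: list[str] = []
        for f in features:
            for c in f.intensity:
                if c not in cols:
                    cols.append(c)
        columns = sorted(cols)
    df = pd.DataFrame(
        [[f.intensity.get(c, np.nan) for c in columns] for f in features],
        index=[f.feature_id for f in features],
        columns=list(columns),
    )
    df.index.name = "feature_id"
    return df


def peaks_to_dataframe(peaks: Sequence[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "run_id": p.run_id,
                "mz": p.mz,
                "rt": p.rt,
                "rt_lo": p.rt_lo,
                "rt_hi": p.rt_hi,
                "area": p.area,
                "height": p.height,
                "sn": p.sn,
            }
            for p in peaks
        ]
    )
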