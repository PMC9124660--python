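"""Drift evaluation for sequential mosaicking.

Ground-truth camera motion is unavailable for in vivo footage, so
registration quality is quantified by structural similarity: warp frame
``i+t`` into frame ``i``'s coordinates through the composition of the
``t`` intervening pairwise transforms and compute SSIM over the valid
overlap, for ``t = 1..N`` (default N=5).  Because the warp is built
incrementally, drift accumulates with ``t``; the per-``t`` SSIM
distributions are summarized as standard boxplots (median, Q1, Q3,
whiskers at 1.5*IQR, outliers) and the ``t=1`` slice doubles as the
consecutive-registration time plot.  Low-side outliers flag registration
failures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.metrics import structural_similarity

from .correspondence import CircularMask
from .flow import to_gray
from .mosaic import CanvasBounds, warp_frame
from .registration import PairwiseRegistration

__all__ = ["SsimConfig", "BoxplotStats", "DriftReport", "ssim", "drift_metric", "boxplot_stats", "ssim_timeplot"]


@dataclass(frozen=True)
class SsimConfig:
    """SSIM parameterization (the standard one: 11x11 Gaussian window,
    sigma 1.5, K1=0.01, K2=0.03, dynamic range 1.0, grayscale)."""

    window: int = 11
    k1: float = 0.01
    k2: float = 0.03
    gaussian_sigma: float = 1.5
    data_range: float = 1.0
    use_overlap_mask: bool = True

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")


def ssim(a, b, valid: np.ndarray | None = None, cfg: SsimConfig | None = None) -> float:
    """Mean SSIM between two frames over windows fully inside ``valid``.

    Gaussian-weighted local statistics; color input is converted to
    grayscale first.  Raises on an empty valid region.
    """
    cfg = cfg or SsimConfig()
    ga = to_gray(getattr(a, "pixels", a))
    gb = to_gray(getattr(b, "pixels", b))
    if ga.shape != gb.shape:
        raise ValueError(f"frame size mismatch: {ga.shape} vs {gb.shape}")
    _, smap = structural_similarity(
        ga,
        gb,
        win_size=cfg.window,
        gaussian_weights=True,
        sigma=cfg.gaussian_sigma,
        use_sample_covariance=False,
        K1=cfg.k1,
        K2=cfg.k2,
        data_range=cfg.data_range,
        full=True,
    )
    pad = cfg.window // 2
    if valid is None:
        keep = np.zeros(ga.shape, dtype=bool)
        keep[pad:-pad, pad:-pad] = True
    else:
        valid = np.asarray(valid, dtype=bool)
        keep = ndimage.binary_erosion(valid, structure=np.ones((cfg.window, cfg.window)))
        keep[:pad, :] = keep[-pad:, :] = keep[:, :pad] = keep[:, -pad:] = False
    if not keep.any():
        raise ValueError("valid region does not cover a single SSIM window")
    return float(smap[keep].mean())


@dataclass
class BoxplotStats:
    """Five-number boxplot summary with 1.5*IQR whiskers clipped to data."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]
    n: int

    def as_dict(self) -> dict:
        return {
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "whisker_low": self.whisker_low,
            "whisker_high": self.whisker_high,
            "outliers": list(self.outliers),
            "n": self.n,
        }


def boxplot_stats(values) -> BoxplotStats:
    """Median/Q1/Q3 (linear-interpolation quantiles), whiskers at the most
    extreme data inside [Q1 - 1.5 IQR, Q3 + 1.5 IQR], the rest outliers."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("boxplot_stats requires at least one value")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return BoxplotStats(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=[float(x) for x in np.sort(outliers)],
        n=int(v.size),
    )


@dataclass
class DriftReport:
    """SSIM drift records plus per-offset boxplot summaries."""

    records: pd.DataFrame  # columns: i, t, ssim
    summaries: dict[int, BoxplotStats] = field(default_factory=dict)
    N: int = 5

    def summary_json(self) -> dict:
        return {str(t): s.as_dict() for t, s in self.summaries.items()}

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def _as_transform(p):
    return p.transform if isinstance(p, PairwiseRegistration) else p


def drift_metric(
    frames,
    pairwise,
    mask: CircularMask | None = None,
    N: int = 5,
    cfg: SsimConfig | None = None,
) -> DriftReport:
    """SSIM between frame ``i`` and warped frame ``i+t`` for ``t <= N``.

    ``pairwise[k]`` maps frame k+1 into frame k; composing transforms
    ``A_i .. A_{i+t-1}`` maps frame i+t into frame i.  SSIM is restricted
    to the warped overlap of the circular field-of-view masks when
    ``cfg.use_overlap_mask`` (default).
    """
    cfg = cfg or SsimConfig()
    arrays = [np.asarray(getattr(f, "pixels", f), dtype=float) for f in frames]
    n = len(arrays)
    if len(pairwise) != n - 1:
        raise ValueError(f"expected {n - 1} pairwise transforms, got {len(pairwise)}")
    if n < 2:
        raise ValueError("need at least two frames for drift evaluation")
    transforms = [_as_transform(p) for p in pairwise]
    h, w = arrays[0].shape[:2]
    bounds = CanvasBounds(x_min=0.0, y_min=0.0, width=w, height=h)
    mask_raster = mask.raster((h, w)) if (mask is not None and cfg.use_overlap_mask) else None

    rows = []
    for i in range(n - 1):
        A = None
        for t in range(1, N + 1):
            j = i + t
            if j > n - 1:
                break
            A = transforms[j - 1] if A is None else A @ transforms[j - 1]
            warped, validity = warp_frame(arrays[j], A, mask if cfg.use_overlap_mask else None, bounds)
            overlap = validity if mask_raster is None else (validity & mask_raster)
            try:
                value = ssim(arrays[i], warped, valid=overlap, cfg=cfg)
            except ValueError:
                continue  # overlap too small for one window
            rows.append((i, t, value))
    if not rows:
        raise ValueError("sequence span too short for any (i, t) evaluation")
    records = pd.DataFrame(rows, columns=["i", "t", "ssim"])
    summaries = {
        int(t): boxplot_stats(grp["ssim"].to_numpy()) for t, grp in records.groupby("t")
    }
    return DriftReport(records=records, summaries=summaries, N=N)


def ssim_timeplot(frames, pairwise, mask=None, cfg=None, path=None):
    """Consecutive-frame SSIM series (the t=1 drift slice) + optional plot.

    Returns the series as a DataFrame indexed by pair; a sharp minimum
    marks a broken registration.
    """
    report = drift_metric(frames, pairwise, mask=mask, N=1, cfg=cfg)
    series = report.records[report.records["t"] == 1][["i", "ssim"]].reset_index(drop=True)
    if path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 3))
        ax.plot(series["i"], series["ssim"], lw=1.2)
        ax.set_xlabel("frame pair index")
        ax.set_ylabel("SSIM (t=1)")
        ax.set_ylim(min(0.0, float(series["ssim"].min())), 1.02)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return series


def drift_boxplot(report: DriftReport, path) -> None:
    """Render per-offset SSIM boxplots (median, quartiles, 1.5 IQR whiskers)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = [report.records.loc[report.records["t"] == t, "ssim"] for t in sorted(report.summaries)]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(data, tick_labels=[str(t) for t in sorted(report.summaries)], whis=1.5)
    ax.set_xlabel("frame offset t")
    ax.set_ylabel("SSIM")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
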