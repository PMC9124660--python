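"""Robust pairwise affine estimation from point correspondences.

The estimation pipeline follows the multiple-view-geometry "gold
standard": a 3-point minimal least-squares solver generates candidate
models inside RANSAC (inlier test ``||dst - A.src||_2 <= threshold``,
threshold 6 px by default), and the winning model is refined on its
inliers with Levenberg-Marquardt on the squared re-projection error

    E = sum_i (x_i - a11 x'_i - a12 y'_i - b1)^2
             + (y_i - a21 x'_i - a22 y'_i - b2)^2 .

Because the affine model is linear in its six parameters, E is quadratic
and LM converges to the closed-form least-squares minimizer; the damped
iteration is retained for fidelity to the pipeline and for its
monotone accepted-step property.  An alternative single-stage robust
regression (soft-L1 loss, no RANSAC) is provided for comparison.

All solvers here fit the transform ``A`` with ``A . src ~ dst``.  The
frame-level orchestration (:func:`register_pair`) swaps correspondence
roles so the stored transform maps frame ``i+1`` coordinates into frame
``i``, which makes chaining toward an earlier reference frame a plain
left multiplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .correspondence import CircularMask, CorrespondenceSet, estimate_mask, flow_to_correspondences
from .flow import FlowField, lk_pyramidal
from .geometry import AffineTransform

__all__ = [
    "RansacConfig",
    "PairwiseRegistration",
    "DegenerateSampleError",
    "RegistrationFailureError",
    "solve_affine_minimal",
    "solve_affine_lsq",
    "ransac_affine",
    "refine_lm",
    "robust_regression_affine",
    "register_pair",
    "reprojection_residuals",
]

_MIN_TRIANGLE_AREA = 1e-8  # px^2; degenerate minimal-sample rejection


class DegenerateSampleError(ValueError):
    """Source points are (near-)collinear or the design is rank deficient."""


class RegistrationFailureError(RuntimeError):
    """No affine model with at least 3 inliers could be found."""


@dataclass(frozen=True)
class RansacConfig:
    """RANSAC parameters.

    ``threshold`` is the inlier re-projection bound in pixels (points at
    exactly the threshold count as inliers).  The iteration count adapts
    to the running inlier ratio under ``confidence`` and is capped at
    ``max_iterations``.  ``seed`` makes a run deterministic.
    """

    threshold: float = 6.0
    max_iterations: int = 2000
    confidence: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must lie in (0, 1)")


@dataclass
class PairwiseRegistration:
    """Estimated transform + inlier labelling for one frame pair.

    ``transform`` maps frame ``i+1`` coordinates into frame ``i`` when
    produced by :func:`register_pair`; solver-level helpers label it in
    the fitting direction they were given.
    """

    transform: AffineTransform
    inlier_mask: np.ndarray
    rmse: float
    outlier_points: np.ndarray | None = None
    pair_index: int = field(default=-1)

    @property
    def n_inliers(self) -> int:
        return int(np.count_nonzero(self.inlier_mask))

    @property
    def n(self) -> int:
        return int(len(self.inlier_mask))


def reprojection_residuals(A: AffineTransform, c: CorrespondenceSet) -> np.ndarray:
    """Per-pair Euclidean re-projection error ``||dst - A.src||_2``."""
    return np.linalg.norm(c.dst - A.apply(c.src), axis=1)


def _energy(A: AffineTransform, c: CorrespondenceSet) -> float:
    return float(np.sum((c.dst - A.apply(c.src)) ** 2))


def solve_affine_minimal(c: CorrespondenceSet) -> AffineTransform:
    """Exact interpolating affine from exactly 3 correspondences."""
    if len(c) != 3:
        raise ValueError(f"minimal solver needs exactly 3 pairs, got {len(c)}")
    s = c.src
    area = 0.5 * abs(
        (s[1, 0] - s[0, 0]) * (s[2, 1] - s[0, 1]) - (s[2, 0] - s[0, 0]) * (s[1, 1] - s[0, 1])
    )
    if area < _MIN_TRIANGLE_AREA:
        raise DegenerateSampleError(f"collinear source points (triangle area {area:.3e} px^2)")
    design = np.column_stack([s, np.ones(3)])
    sol = np.linalg.solve(design, c.dst)  # columns: x-row params, y-row params
    return AffineTransform(sol.T)


def solve_affine_lsq(c: CorrespondenceSet) -> AffineTransform:
    """Linear least-squares affine over n >= 3 correspondences.

    The x and y coordinate equations decouple into two independent
    3-parameter problems sharing one design matrix.
    """
    if len(c) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(c)}")
    design = np.column_stack([c.src, np.ones(len(c))])
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateSampleError("rank-deficient design (collinear source points)")
    sol, *_ = np.linalg.lstsq(design, c.dst, rcond=None)
    return AffineTransform(sol.T)


def ransac_affine(
    c: CorrespondenceSet, cfg: RansacConfig | None = None, rng: np.random.Generator | None = None
) -> PairwiseRegistration:
    """3-point RANSAC for an affine model with adaptive termination.

    The candidate with the most inliers wins; it is then refit by least
    squares on its consensus set and the inlier mask re-derived from the
    refit model.  Deterministic given ``cfg.seed`` (or an explicit
    ``rng``, which takes precedence).
    """
    cfg = cfg or RansacConfig()
    if len(c) < 3:
        raise RegistrationFailureError(f"need at least 3 correspondences, got {len(c)}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    n = len(c)
    best_mask = None
    best_count = 0
    needed = cfg.max_iterations
    it = 0
    while it < min(needed, cfg.max_iterations):
        it += 1
        idx = rng.choice(n, size=3, replace=False)
        try:
            cand = solve_affine_minimal(c.subset(idx))
        except DegenerateSampleError:
            continue
        mask = reprojection_residuals(cand, c) <= cfg.threshold
        count = int(np.count_nonzero(mask))
        if count > best_count:
            best_count, best_mask = count, mask
            w = count / n
            if w >= 1.0 - 1e-12:
                break
            denom = np.log1p(-(w**3))
            needed = int(np.ceil(np.log(1.0 - cfg.confidence) / denom)) if denom < 0 else 1

    if best_mask is None or best_count < 3:
        raise RegistrationFailureError(
            f"no affine model with >= 3 inliers in {it} iterations (n={n})"
        )

    model = solve_affine_lsq(c.subset(best_mask))
    res = reprojection_residuals(model, c)
    mask = res <= cfg.threshold
    if np.count_nonzero(mask) < 3:  # refit degraded the consensus: keep the raw vote
        mask = best_mask
        model = solve_affine_lsq(c.subset(best_mask))
        res = reprojection_residuals(model, c)
    rmse = float(np.sqrt(np.mean(res[mask] ** 2)))
    return PairwiseRegistration(transform=model, inlier_mask=mask, rmse=rmse)


def refine_lm(
    A0: AffineTransform,
    inliers: CorrespondenceSet,
    tol: float = 1e-10,
    max_steps: int = 100,
    full_output: bool = False,
):
    """Levenberg-Marquardt refinement of the squared re-projection error.

    Damped normal equations with multiplicative lambda adaptation; a step
    is accepted only if it decreases E, so the accepted-step cost sequence
    is non-increasing.  Terminates when the accepted step norm falls below
    ``tol`` or after ``max_steps``.  With ``full_output`` the accepted-step
    cost history is returned alongside the transform.
    """
    if len(inliers) < 3:
        raise ValueError("need at least 3 inlier pairs")
    s = inliers.src
    design = np.column_stack([s, np.ones(len(s))])  # shared by both residual blocks

    p = np.asarray(A0.to_list(), dtype=float)  # [a11, a12, b1, a21, a22, b2]

    def residuals(params):
        rx = inliers.dst[:, 0] - design @ params[:3]
        ry = inliers.dst[:, 1] - design @ params[3:]
        return np.concatenate([rx, ry])

    # Jacobian is constant for this linear-in-parameters model
    J = np.zeros((2 * len(s), 6))
    J[: len(s), :3] = -design
    J[len(s) :, 3:] = -design
    JtJ = J.T @ J
    diag = np.diag(np.diag(JtJ))

    r = residuals(p)
    cost = float(r @ r)
    history = [cost]
    lam = 1e-3
    for _ in range(max_steps):
        g = J.T @ r
        try:
            step = np.linalg.solve(JtJ + lam * diag, -g)
        except np.linalg.LinAlgError:
            lam *= 10.0
            continue
        trial = p + step
        r_trial = residuals(trial)
        cost_trial = float(r_trial @ r_trial)
        if cost_trial <= cost:
            p, r, cost = trial, r_trial, cost_trial
            history.append(cost)
            lam = max(lam / 10.0, 1e-12)
            if np.linalg.norm(step) < tol:
                break
        else:
            lam *= 10.0
            if lam > 1e12:
                break
    A = AffineTransform.from_list(p)
    return (A, history) if full_output else A


def robust_regression_affine(
    c: CorrespondenceSet, f_scale: float = 6.0, threshold: float = 6.0
) -> PairwiseRegistration:
    """Single-stage robust fit with the soft-L1 loss (no RANSAC).

    Minimizes ``sum rho(r^2 / f_scale^2)`` with ``rho(z) = 2(sqrt(1+z)-1)``
    over the per-coordinate residuals, initialized from the plain
    least-squares solution.  The inlier mask is re-derived post hoc with
    the usual re-projection threshold, for reporting only.
    """
    A0 = solve_affine_lsq(c)
    design = np.column_stack([c.src, np.ones(len(c))])

    def residuals(params):
        rx = c.dst[:, 0] - design @ params[:3]
        ry = c.dst[:, 1] - design @ params[3:]
        return np.concatenate([rx, ry])

    sol = least_squares(
        residuals, np.asarray(A0.to_list()), loss="soft_l1", f_scale=f_scale, method="trf"
    )
    A = AffineTransform.from_list(sol.x)
    res = reprojection_residuals(A, c)
    mask = res <= threshold
    rmse = float(np.sqrt(np.mean(res[mask] ** 2))) if mask.any() else float("nan")
    return PairwiseRegistration(transform=A, inlier_mask=mask, rmse=rmse)


def register_pair(
    src_frame,
    tgt_frame,
    flow: FlowField | None = None,
    mask: CircularMask | None = None,
    stride: int = 2,
    cfg: RansacConfig | None = None,
    method: str = "ransac_lm",
    lk_kwargs: dict | None = None,
    edge_margin: float | None = None,
    pair_index: int = 0,
) -> PairwiseRegistration:
    """Full per-pair registration: flow -> correspondences -> robust fit.

    Parameters
    ----------
    src_frame, tgt_frame
        Consecutive frames i and i+1 (arrays or :class:`~.flow.Frame`).
    flow
        Precomputed flow field from src to tgt; when omitted, the built-in
        pyramidal Lucas-Kanade backend is used.
    mask
        Circular field-of-view mask; estimated from ``src_frame`` when
        omitted.
    method
        ``"ransac_lm"`` (RANSAC + LM refinement, default) or ``"rr"``
        (single-stage soft-L1 robust regression).

    Returns
    -------
    PairwiseRegistration
        With ``transform`` mapping frame i+1 coordinates into frame i and
        ``outlier_points`` the frame-i coordinates rejected as outliers.
    """
    cfg = cfg or RansacConfig()
    builtin = flow is None
    if builtin:
        flow = lk_pyramidal(src_frame, tgt_frame, **(lk_kwargs or {}))
    if mask is None:
        mask = estimate_mask(src_frame)
    if edge_margin is None:
        # LK windows that overlap the static field-of-view rim are biased
        # toward zero motion with residuals below the RANSAC threshold, so
        # exclude the rim annulus (full pyramid spatial support) outright.
        kw = lk_kwargs or {}
        window, levels = kw.get("window", 21), kw.get("levels", 3)
        edge_margin = (window // 2) * 2 ** (levels - 1) if builtin else 0.0
    if edge_margin > 0 and isinstance(mask, CircularMask):
        sample_mask = CircularMask(mask.cx, mask.cy, max(mask.radius - edge_margin, 3.0))
    else:
        sample_mask = mask
    corr = flow_to_correspondences(flow, sample_mask, stride=stride)
    if len(corr) < 3:
        raise RegistrationFailureError(f"pair {pair_index}: only {len(corr)} correspondences")
    fit = corr.swapped()  # fit A with A.(frame i+1 point) ~ (frame i point)

    if method == "rr":
        reg = robust_regression_affine(fit, f_scale=cfg.threshold, threshold=cfg.threshold)
    elif method == "ransac_lm":
        rng = np.random.default_rng([cfg.seed, pair_index])
        reg = ransac_affine(fit, cfg, rng=rng)
        refined = refine_lm(reg.transform, fit.subset(reg.inlier_mask))
        res = reprojection_residuals(refined, fit)
        mask_new = res <= cfg.threshold
        if np.count_nonzero(mask_new) >= 3:
            reg = PairwiseRegistration(
                transform=refined,
                inlier_mask=mask_new,
                rmse=float(np.sqrt(np.mean(res[mask_new] ** 2))),
            )
    else:
        raise ValueError(f"unknown registration method {method!r}")

    reg.outlier_points = corr.src[~reg.inlier_mask]
    reg.pair_index = pair_index
    return reg
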