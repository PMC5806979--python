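"""Motion-mode decomposition and group statistics.

The grid trajectory of one recording is flattened into a T x 108 observation
matrix (36 nodes x 3 coordinates, node-major, rest frame subtracted), and
principal component analysis decomposes it into orthonormal motion modes.
The first and second principal component scores (PCS1/PCS2) summarize each
frame; mode shapes are reconstructed as mean + score * loading.  Group-level
questions (do maximum CoG shifts differ between males and females? can the
sexes be discriminated from (PCS1, PCS2)?) use a two-sided Mann-Whitney U
test and a two-class linear discriminant.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .grid import GridTrajectory, cog_trajectory

__all__ = [
    "MotionMatrix",
    "PCAModel",
    "GroupTestResult",
    "DiscriminantResult",
    "build_motion_matrix",
    "fit_pca",
    "reconstruct_mode_shape",
    "mann_whitney",
    "discriminant_classify",
    "subject_scores",
]

log = logging.getLogger(__name__)

#: Sample-size bound below which the exact Mann-Whitney null is enumerated.
_EXACT_LIMIT = 25


@dataclass
class MotionMatrix:
    """T x (3*N) observation matrix of rest-relative node coordinates.

    Column order is node-major: (node0.x, node0.y, node0.z, node1.x, ...).
    """

    data: np.ndarray
    timestamps: np.ndarray
    node_index: np.ndarray  # original node ids of retained nodes
    rest_frame: int = 0
    subject: str | None = None
    group: str | None = None

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1] // 3


@dataclass
class PCAModel:
    mean: np.ndarray  # (P,)
    loadings: np.ndarray  # (k, P), orthonormal rows
    eigenvalues: np.ndarray  # (k,), descending
    scores: np.ndarray  # (T, k)
    total_variance: float
    rest_config: np.ndarray | None = None  # (N, 3) rest-frame node positions

    @property
    def k(self) -> int:
        return len(self.eigenvalues)

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.total_variance


@dataclass
class GroupTestResult:
    U: float
    p_value: float
    n1: int
    n2: int
    method: str
    values1: np.ndarray
    values2: np.ndarray


@dataclass
class DiscriminantResult:
    weights: np.ndarray
    intercept: float
    predicted: np.ndarray
    accuracy_pct: float
    loso_accuracy_pct: float | None = None
    classes: tuple = ()


def build_motion_matrix(
    traj: GridTrajectory,
    rest_frame: int = 0,
    subtract_rest: bool = True,
    subject: str | None = None,
    group: str | None = None,
) -> MotionMatrix:
    """Flatten a grid trajectory into the T x 3N observation matrix.

    Nodes that are invalid in any frame (after temporal filling) are dropped
    from every frame so the matrix stays rectangular; coordinates are
    expressed relative to the rest-frame configuration.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    keep = traj.valid.all(axis=0)
    if not keep.any():
        raise ValueError("non-rectangular trajectory: no node valid in all frames")
    if not keep.all():
        log.warning("dropping %d never-rectangular nodes", int((~keep).sum()))
    pts = traj.points[:, keep, :]  # (T, N', 3)
    if subtract_rest:
        pts = pts - pts[rest_frame]
    T = pts.shape[0]
    return MotionMatrix(
        data=pts.reshape(T, -1),
        timestamps=traj.timestamps,
        node_index=np.flatnonzero(keep),
        rest_frame=rest_frame,
        subject=subject,
        group=group,
    )


def unflatten(row: np.ndarray) -> np.ndarray:
    """Reshape one 3N observation row back to (N, 3) node coordinates."""
    return np.asarray(row).reshape(-1, 3)


def fit_pca(matrix: MotionMatrix, k: int = 12) -> PCAModel:
    """PCA of the column-centered observation matrix via SVD.

    Eigenvalues are the variances of the scores (divisor T-1), sorted
    descending; loadings are orthonormal.  Sign convention: each loading is
    oriented so the score of the frame with the largest rest-relative
    displacement is non-negative, which removes the eigenvector sign
    ambiguity that otherwise breaks cross-subject pooling.

    If ``k`` exceeds the achievable rank, the model is truncated with a
    warning ("rank deficiency").
    """
    X = matrix.data
    T, P = X.shape
    if T < 2:
        raise ValueError("need at least 2 frames")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (T - 1)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    max_k = min(T - 1, P, max(rank, 1))
    if k > max_k:
        warnings.warn(f"rank deficiency: requested k={k}, achievable k={max_k}")
        k = max_k
    loadings = Vt[:k]
    scores = Xc @ loadings.T
    # sign alignment on the frame of maximum displacement magnitude
    ref = int(np.argmax(np.linalg.norm(X, axis=1)))
    flip = np.where(scores[ref] < 0, -1.0, 1.0)
    loadings = loadings * flip[:, None]
    scores = scores * flip
    rest = None
    return PCAModel(
        mean=mean,
        loadings=loadings,
        eigenvalues=eig[:k],
        scores=scores,
        total_variance=float(Xc.var(axis=0, ddof=1).sum()) if T > 1 else 0.0,
        rest_config=rest,
    )


def reconstruct_mode_shape(
    pca: PCAModel,
    component: int,
    score: float,
    rest_config: np.ndarray | None = None,
) -> np.ndarray:
    """Node configuration for a single mode at a given score.

    ``mean + score * loading`` reshaped to (N, 3); when the rest-frame
    configuration is supplied (matrix rows being rest-relative) it is added
    back so the result is an absolute soft-palate shape, as used to render
    mode figures at e.g. +/- 2 SD.
    """
    if not 1 <= component <= pca.k:
        raise ValueError(f"component must be in [1, {pca.k}]")
    row = pca.mean + score * pca.loadings[component - 1]
    shape = unflatten(row)
    rc = rest_config if rest_config is not None else pca.rest_config
    if rc is not None:
        shape = shape + np.asarray(rc).reshape(-1, 3)
    return shape


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def mann_whitney(group_a, group_b) -> GroupTestResult:
    """Two-sided Mann-Whitney U test on two independent samples.

    The exact null distribution is used when there are no ties and
    ``n1 + n2 <= 25``; otherwise the normal approximation with tie and
    continuity corrections.  If every value is identical across both groups
    the test is uninformative and ``p = 1`` is returned with a warning.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; p = 1")
        return GroupTestResult(U=a.size * b.size / 2.0, p_value=1.0,
                               n1=a.size, n2=b.size, method="degenerate",
                               values1=a, values2=b)
    ties = np.unique(pooled).size < pooled.size
    if not ties and a.size + b.size <= _EXACT_LIMIT:
        method = "exact"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
    return GroupTestResult(U=float(res.statistic), p_value=float(res.pvalue),
                           n1=a.size, n2=b.size, method=method,
                           values1=a, values2=b)


def discriminant_classify(
    scores: np.ndarray,
    labels,
    subject_ids=None,
) -> DiscriminantResult:
    """Two-class linear discriminant (pooled covariance) on (PCS1, PCS2).

    Reports resubstitution accuracy (%) and, when per-observation subject ids
    are given, leave-one-subject-out accuracy as the honest alternative to
    the optimistic frame-level resubstitution figure.
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    w, b0 = _lda_boundary(X, y, classes)
    pred = np.where(X @ w + b0 > 0, classes[1], classes[0])
    acc = 100.0 * float(np.mean(pred == y))
    loso = None
    if subject_ids is not None:
        sid = np.asarray(subject_ids)
        hits = 0
        for s in np.unique(sid):
            hold = sid == s
            if np.unique(y[~hold]).size < 2:
                continue
            ww, bb = _lda_boundary(X[~hold], y[~hold], classes)
            ph = np.where(X[hold] @ ww + bb > 0, classes[1], classes[0])
            hits += int(np.sum(ph == y[hold]))
        loso = 100.0 * hits / len(y)
    return DiscriminantResult(
        weights=w,
        intercept=b0,
        predicted=pred,
        accuracy_pct=acc,
        loso_accuracy_pct=loso,
        classes=tuple(classes.tolist()),
    )


def _lda_boundary(X, y, classes) -> tuple[np.ndarray, float]:
    """Two-class pooled-covariance discriminant, equal priors.

    A near-singular pooled covariance is regularized by adding
    ``1e-8 * trace / p`` to the diagonal (logged).
    """
    Xa, Xb = X[y == classes[0]], X[y == classes[1]]
    ma, mb = Xa.mean(axis=0), Xb.mean(axis=0)
    Sa = np.atleast_2d(np.cov(Xa, rowvar=False)) * (len(Xa) - 1)
    Sb = np.atleast_2d(np.cov(Xb, rowvar=False)) * (len(Xb) - 1)
    S = (Sa + Sb) / max(len(X) - 2, 1)
    p = X.shape[1]
    if np.linalg.cond(S) > 1e12 or not np.isfinite(np.linalg.cond(S)):
        log.warning("singular pooled covariance; regularizing diagonal")
        S = S + np.eye(p) * max(1e-8 * np.trace(S) / p, 1e-12)
    w = np.linalg.solve(S, mb - ma)
    b0 = -float(w @ (ma + mb) / 2.0)
    return w, b0


def subject_scores(
    trajectories: dict[str, tuple[GridTrajectory, str]],
    k: int = 12,
    rest_frame: int = 0,
) -> pd.DataFrame:
    """Per-subject PCA, pooled frame-level (PCS1, PCS2) table.

    Each subject's trajectory gets its own PCA fit (the per-subject reading
    of the analysis); the loading sign convention in :func:`fit_pca` aligns
    score signs across subjects.  Returns a tidy frame with columns
    subject, group, frame, pcs1, pcs2, max_cog_shift_mm.
    """
    rows = []
    for subject, (traj, group) in trajectories.items():
        mm = build_motion_matrix(traj, rest_frame=rest_frame, subject=subject,
                                 group=group)
        pca = fit_pca(mm, k=k)
        shift = float(cog_trajectory(traj, rest_frame=rest_frame).shifts.max())
        for t in range(mm.n_frames):
            rows.append(
                {
                    "subject": subject,
                    "group": group,
                    "frame": t,
                    "pcs1": pca.scores[t, 0],
                    "pcs2": pca.scores[t, 1] if pca.k > 1 else 0.0,
                    "max_cog_shift_mm": shift,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_pca(pca: PCAModel, outdir: str | Path, prefix: str = "pca") -> None:
    """Export JSON (mean, eigenvalues) plus CSV loadings and scores."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "mean": pca.mean.tolist(),
        "eigenvalues": pca.eigenvalues.tolist(),
        "total_variance": pca.total_variance,
        "k": pca.k,
    }
    (outdir / f"{prefix}.json").write_text(json.dumps(meta, indent=2))
    pd.DataFrame(pca.loadings).to_csv(outdir / f"{prefix}_loadings.csv", index=False)
    pd.DataFrame(
        pca.scores, columns=[f"pcs{i+1}" for i in range(pca.k)]
    ).to_csv(outdir / f"{prefix}_scores.csv", index=False)


def export_mode_shapes(
    pca: PCAModel,
    outdir: str | Path,
    components: tuple[int, ...] = (1, 2),
    rest_config: np.ndarray | None = None,
) -> None:
    """Per-mode CSV point sets at scores {-2 SD, 0, +2 SD} for visualization."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for c in components:
        sd = float(np.sqrt(pca.eigenvalues[c - 1]))
        for label, s in (("m2sd", -2 * sd), ("mean", 0.0), ("p2sd", 2 * sd)):
            shape = reconstruct_mode_shape(pca, c, s, rest_config=rest_config)
            pd.DataFrame(shape, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
                outdir / f"mode{c}_{label}.csv", index=False
            )
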