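"""Landmark-based geometric morphometrics and tactical-dimorphism statistics.

Implements the standard shape-analysis chain: generalized Procrustes
superimposition (center, scale to unit centroid size, least-squares rotation
with reflections disallowed), semilandmark sliding along chord directions
under the Procrustes-distance criterion, orthogonal projection into the
tangent space at the consensus (Kendall tangent coordinates), and principal
components of the tangent-coordinate covariance matrix with a >= 10%
variance retention rule.  Missing landmarks are filled in by a thin-plate
spline from a reference configuration.

Dimorphism statistics: Welch two-sample t test, Yates-corrected chi-square
for 2x2 tables, sword index, and 95% confidence ellipses of group centroids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatypes import LandmarkSet

__all__ = [
    "centroid_size",
    "AlignedShapes",
    "gpa",
    "slide_semilandmarks",
    "procrustes_distance",
    "tangent_project",
    "ShapePCA",
    "shape_pca",
    "retained_axes",
    "shape_along_axis",
    "tps_warp",
    "estimate_missing",
    "dimorphism_welch",
    "sword_index",
    "yates_chi_square",
    "confidence_ellipse",
]


def centroid_size(config: np.ndarray) -> float:
    """sqrt of summed squared landmark distances to the configuration
    centroid."""
    config = np.asarray(config, dtype=float)
    centered = config - config.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def _center_scale(config: np.ndarray) -> tuple[np.ndarray, float]:
    centered = config - config.mean(axis=0)
    cs = np.sqrt(np.sum(centered**2))
    if cs <= 0:
        raise ValueError("degenerate configuration: all landmarks coincident")
    return centered / cs, float(cs)


def _optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation R (det +1, no reflection) minimizing ||a @ R - b||_F."""
    m = a.T @ b
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations (each centered
    and scaled to unit centroid size, then optimally rotated)."""
    a, _ = _center_scale(np.asarray(a, dtype=float))
    b, _ = _center_scale(np.asarray(b, dtype=float))
    r = _optimal_rotation(a, b)
    return float(np.linalg.norm(a @ r - b))


@dataclass
class AlignedShapes:
    """Superimposed configurations: each centered, unit centroid size,
    rotated to the consensus; the consensus is the (re-normalized) mean."""

    ids: list[str]
    aligned: np.ndarray  # (n, k, 2)
    consensus: np.ndarray  # (k, 2)
    centroid_sizes: np.ndarray  # (n,)
    sliders: tuple[tuple[int, int, int], ...] = ()
    objective_history: list[float] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    @property
    def distances(self) -> np.ndarray:
        """Per-individual Procrustes distance to the consensus."""
        diff = self.aligned - self.consensus
        return np.sqrt(np.sum(diff**2, axis=(1, 2)))


def _gpa_arrays(
    configs: np.ndarray, tol: float, max_iter: int, history: list[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Core iteration on pre-centered unit-CS configs; returns (aligned,
    consensus) and appends the objective after each pass."""
    n = configs.shape[0]
    aligned = configs.copy()
    if n == 1:
        history.append(0.0)
        return aligned, aligned[0].copy()
    # initialize from the first configuration: the raw mean of arbitrarily
    # oriented configurations can be near-degenerate
    consensus = aligned[0].copy()
    for _ in range(max_iter):
        for i in range(n):
            aligned[i] = aligned[i] @ _optimal_rotation(aligned[i], consensus)
        new_consensus, _ = _center_scale(aligned.mean(axis=0))
        history.append(float(np.sum((aligned - new_consensus) ** 2)))
        change = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if change < tol:
            break
    # canonical orientation: principal axes of the consensus, with the
    # pi-rotation ambiguity resolved by a sign rule, so the superimposed
    # coordinates do not depend on the input orientations
    rot = _principal_rotation(consensus)
    consensus = consensus @ rot
    aligned = aligned @ rot
    return aligned, consensus


def _principal_rotation(config: np.ndarray) -> np.ndarray:
    """Rotation (det +1) taking a centered configuration to its principal
    axes, with the dominant coordinate of the first axis made positive."""
    cov = config.T @ config
    eigvals, eigvecs = np.linalg.eigh(cov)
    rot = eigvecs[:, ::-1]  # descending variance
    if np.linalg.det(rot) < 0:
        rot[:, 1] *= -1.0
    proj = config @ rot
    j = np.argmax(np.abs(proj[:, 0]))
    if proj[j, 0] < 0:
        rot = -rot  # rotate by pi, keeps det +1
    return rot


def gpa(
    landmarks: LandmarkSet, tol: float = 1e-8, max_iter: int = 100
) -> AlignedShapes:
    """Generalized Procrustes superimposition.

    Raises if any landmark is missing (run :func:`estimate_missing` first)
    or any configuration is degenerate.
    """
    if landmarks.missing.any():
        raise ValueError("missing landmarks present; run estimate_missing first")
    n = landmarks.n
    scaled = np.empty_like(landmarks.coords)
    sizes = np.empty(n)
    for i in range(n):
        scaled[i], sizes[i] = _center_scale(landmarks.coords[i])
    history: list[float] = []
    aligned, consensus = _gpa_arrays(scaled, tol, max_iter, history)
    return AlignedShapes(
        ids=list(landmarks.ids),
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        sliders=tuple(landmarks.sliders),
        objective_history=history,
    )


def slide_semilandmarks(
    aligned: AlignedShapes, tol: float = 1e-8, max_iter: int = 20
) -> AlignedShapes:
    """Slide each semilandmark along the chord between its neighbors to
    minimize Procrustes distance to the consensus, alternating sliding with
    re-superimposition until the consensus stabilizes.

    With no sliders declared the input is returned unchanged.
    """
    if not aligned.sliders:
        return aligned
    for b, s, a in aligned.sliders:
        if b == a:
            raise ValueError(f"slider {s}: identical neighbors")
    shapes = aligned.aligned.copy()
    consensus = aligned.consensus.copy()
    history = list(aligned.objective_history)
    for _ in range(max_iter):
        for i in range(shapes.shape[0]):
            for b, s, a in aligned.sliders:
                chord = shapes[i, a] - shapes[i, b]
                norm2 = float(chord @ chord)
                if norm2 <= 0:
                    raise ValueError(f"slider {s}: coincident neighbors")
                t = float(chord @ (consensus[s] - shapes[i, s])) / norm2
                shapes[i, s] = shapes[i, s] + t * chord
        # re-superimpose (sliding changes centering/scale slightly)
        rescaled = np.empty_like(shapes)
        for i in range(shapes.shape[0]):
            rescaled[i], _ = _center_scale(shapes[i])
        shapes, new_consensus = _gpa_arrays(rescaled, tol, 100, history)
        change = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if change < tol:
            break
    return AlignedShapes(
        ids=list(aligned.ids),
        aligned=shapes,
        consensus=consensus,
        centroid_sizes=aligned.centroid_sizes.copy(),
        sliders=aligned.sliders,
        objective_history=history,
    )


def tangent_project(aligned: AlignedShapes) -> np.ndarray:
    """Kendall tangent-space coordinates, shape (n, 2k).

    Each aligned configuration (flattened, unit norm) is orthogonally
    projected onto the tangent plane at the consensus; coordinates are
    returned as consensus + tangent deviation, so the consensus projects to
    itself and the map is idempotent.
    """
    c = aligned.consensus.reshape(-1)
    c = c / np.linalg.norm(c)
    x = aligned.aligned.reshape(aligned.n, -1)
    coef = x @ c
    return c + (x - coef[:, None] * c)


@dataclass
class ShapePCA:
    """Covariance-matrix PCA of tangent coordinates."""

    mean: np.ndarray  # (p,)
    eigenvectors: np.ndarray  # (n_axes, p), rows are axes
    eigenvalues: np.ndarray  # (n_axes,)
    proportions: np.ndarray  # (n_axes,)
    scores: np.ndarray  # (n, n_axes)
    retained: np.ndarray  # boolean mask over axes

    def reconstruct(self, scores: np.ndarray | None = None) -> np.ndarray:
        s = self.scores if scores is None else np.asarray(scores)
        return self.mean + s @ self.eigenvectors


def shape_pca(tangent: np.ndarray, retain_threshold: float = 0.10) -> ShapePCA:
    """Eigendecomposition of the (n-1)-denominator covariance of tangent
    coordinates; axes sorted by eigenvalue, retained where the variance
    proportion is >= ``retain_threshold``.

    Sign convention: each axis's largest-magnitude loading is positive.
    """
    x = np.asarray(tangent, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 specimens for a covariance PCA")
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order].T
    # deterministic sign: largest-|loading| component positive
    for row in eigvecs:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1.0
    total = eigvals.sum()
    props = eigvals / total if total > 0 else np.zeros_like(eigvals)
    scores = xc @ eigvecs.T
    return ShapePCA(
        mean=mean,
        eigenvectors=eigvecs,
        eigenvalues=eigvals,
        proportions=props,
        scores=scores,
        retained=retained_axes(props, retain_threshold),
    )


def retained_axes(proportions: np.ndarray, threshold: float = 0.10) -> np.ndarray:
    """Boolean mask of axes whose variance proportion meets the threshold."""
    return np.asarray(proportions, dtype=float) >= threshold


def shape_along_axis(pca: ShapePCA, axis: int, score: float) -> np.ndarray:
    """Configuration (k, 2) at the given score along one PC axis; used for
    deformation-grid exports of extreme shapes."""
    flat = pca.mean + score * pca.eigenvectors[axis]
    return flat.reshape(-1, 2)


# ---------------------------------------------------------------------------
# thin-plate spline missing-landmark estimation


def tps_warp(
    source: np.ndarray, target: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Map ``points`` through the thin-plate spline interpolating
    source -> target (2-D, kernel U(r) = r^2 log r).  Exactly reproduces
    affine maps through its affine part."""
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    m = len(source)
    if m < 3:
        raise ValueError("thin-plate spline needs at least 3 anchor points")

    def kernel(r2: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = 0.5 * r2 * np.log(r2)
        return np.where(r2 > 0, out, 0.0)

    d2 = np.sum((source[:, None, :] - source[None, :, :]) ** 2, axis=2)
    k = kernel(d2)
    p = np.hstack([np.ones((m, 1)), source])
    lhs = np.zeros((m + 3, m + 3))
    lhs[:m, :m] = k
    lhs[:m, m:] = p
    lhs[m:, :m] = p.T
    rhs = np.zeros((m + 3, 2))
    rhs[:m] = target
    sol = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
    w, a = sol[:m], sol[m:]
    d2p = np.sum((points[:, None, :] - source[None, :, :]) ** 2, axis=2)
    return kernel(d2p) @ w + np.hstack([np.ones((len(points), 1)), points]) @ a


def estimate_missing(
    landmarks: LandmarkSet, reference: np.ndarray | None = None
) -> LandmarkSet:
    """Fill missing landmarks via a TPS from a reference configuration.

    The reference defaults to the GPA consensus of the complete specimens.
    For each incomplete specimen a spline is fitted from the reference's
    *present* landmarks to the specimen's present landmarks; the missing
    ones are mapped through it.  Requires >= 3 present landmarks.
    """
    missing = landmarks.missing
    if not missing.any():
        return landmarks
    if reference is None:
        complete = ~missing.any(axis=1)
        if complete.sum() < 1:
            raise ValueError("no complete specimens to build a reference from")
        ref_set = LandmarkSet(
            ids=[landmarks.ids[i] for i in np.nonzero(complete)[0]],
            coords=landmarks.coords[complete],
            sliders=landmarks.sliders,
        )
        reference = gpa(ref_set).consensus
    reference = np.asarray(reference, dtype=float)
    coords = landmarks.coords.copy()
    for i in np.nonzero(missing.any(axis=1))[0]:
        present = ~missing[i]
        if present.sum() < 3:
            raise ValueError(
                f"{landmarks.ids[i]}: fewer than 3 present landmarks"
            )
        coords[i, ~present] = tps_warp(
            reference[present], coords[i, present], reference[~present]
        )
    return LandmarkSet(
        ids=list(landmarks.ids), coords=coords, sliders=landmarks.sliders
    )


# ---------------------------------------------------------------------------
# dimorphism statistics


def dimorphism_welch(values: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """Welch two-sample t test between the two label groups.

    Returns (t, Satterthwaite df, two-sided p).  Degenerate zero-variance
    groups: equal means give (0, nan, 1); unequal means give (+/-inf, nan, 0).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, math.nan, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), math.nan, 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def sword_index(sword_length: float, standard_length: float) -> float:
    """Sword length / standard length (size-corrected sword)."""
    if np.any(np.asarray(standard_length) <= 0):
        raise ValueError("standard length must be positive")
    return sword_length / standard_length


def yates_chi_square(table: np.ndarray) -> tuple[float, float]:
    """Yates continuity-corrected chi-square for a 2x2 table.

    chi2 = sum over cells of max(0, |O - E| - 0.5)^2 / E; p from the 1-df
    chi-square distribution.  Raises on zero marginals (expecteds undefined).
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    rows, cols = obs.sum(axis=1), obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero marginal: expected counts undefined")
    exp = np.outer(rows, cols) / obs.sum()
    stat = float(np.sum(np.maximum(0.0, np.abs(obs - exp) - 0.5) ** 2 / exp))
    return stat, float(stats.chi2.sf(stat, df=1))


def confidence_ellipse(
    scores: np.ndarray, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray, float]:
    """Confidence ellipse of a group's centroid in a 2-D score space.

    Uses the covariance of the mean (sample covariance / n) scaled by the
    2-df chi-square quantile.  Returns (center, semi-axes sorted descending,
    angle of major axis in radians).
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("scores must be (n, 2)")
    if not (0.0 <= level < 1.0):
        raise ValueError("level must be in [0, 1)")
    n = x.shape[0]
    center = x.mean(axis=0)
    cov_mean = np.cov(x, rowvar=False, ddof=1) / n
    eigvals, eigvecs = np.linalg.eigh(cov_mean)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    q = stats.chi2.ppf(level, df=2)
    semi = np.sqrt(np.clip(eigvals, 0.0, None) * q)
    angle = math.atan2(eigvecs[1, 0], eigvecs[0, 0])
    return center, semi, angle
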