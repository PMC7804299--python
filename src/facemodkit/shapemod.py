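"""Global-to-local facial shape phenotyping.

Dense homologous landmark configurations are turned into a hierarchy of
multivariate module phenotypes:

1. generalized Procrustes analysis (GPA) co-aligns all configurations;
2. landmarks are clustered into co-varying groups by spectral bipartition of
   an RV-coefficient similarity matrix, recursively, giving a five-level
   binary hierarchy of 31 overlapping segments (modules);
3. each module's aligned coordinates are summarised by PCA, with the number
   of retained components chosen by parallel analysis;
4. covariate effects (sex, age, height, weight, facial size, ancestry PCs)
   are removed by partial least-squares regression of the module scores on
   the covariates;
5. robust squared Mahalanobis distances flag outlying faces per module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans
from sklearn.covariance import EmpiricalCovariance, MinCovDet

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkSet",
    "Segment",
    "SegmentHierarchy",
    "ModulePhenotype",
    "gpa_align",
    "landmark_similarity",
    "spectral_bipartition",
    "build_hierarchy",
    "module_pca",
    "parallel_analysis",
    "pls_adjust",
    "mahalanobis_outliers",
    "segment_phenotype",
    "phenotype_modules",
    "validate_covariates",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class LandmarkSet:
    """Homologous landmark configurations for a cohort.

    coords has shape (n, L, 3) in mm-scale units; row i of ``ids`` labels
    coords[i]. ``centroid_sizes`` holds the pre-scaling centroid sizes and is
    present iff the set has been Procrustes-aligned.
    """

    ids: np.ndarray
    coords: np.ndarray
    aligned: bool = False
    centroid_sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.ids = np.asarray(self.ids)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n, L, 3)")
        if len(self.ids) != self.coords.shape[0]:
            raise ValueError("ids and coords row counts differ")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    def subset_landmarks(self, indices: np.ndarray) -> "LandmarkSet":
        """New LandmarkSet restricted to the given landmark indices (unaligned)."""
        return LandmarkSet(self.ids, self.coords[:, np.asarray(indices, dtype=int), :])


@dataclass
class Segment:
    segment_id: int
    level: int
    parent_id: int | None
    indices: np.ndarray


@dataclass
class SegmentHierarchy:
    """Binary hierarchy of landmark segments, level-order numbered from 1.

    Segment 1 (level 0) is the full face; the children of segment i are
    2i and 2i + 1. A full d-level hierarchy has 2**d - 1 segments.
    """

    segments: list[Segment]
    n_levels: int
    complete: bool = True

    def __post_init__(self) -> None:
        self._by_id = {s.segment_id: s for s in self.segments}

    def get(self, segment_id: int) -> Segment:
        return self._by_id[segment_id]

    @property
    def segment_ids(self) -> list[int]:
        return [s.segment_id for s in self.segments]

    def leaves(self) -> list[Segment]:
        child_ids = {2 * s.segment_id for s in self.segments}
        child_ids |= {2 * s.segment_id + 1 for s in self.segments}
        have = set(self._by_id)
        return [s for s in self.segments if s.segment_id * 2 not in have]

    def leaf_labels(self, n_landmarks: int) -> np.ndarray:
        """Landmark -> leaf segment id (leaves partition the full face)."""
        labels = np.full(n_landmarks, -1, dtype=int)
        for leaf in self.leaves():
            labels[leaf.indices] = leaf.segment_id
        return labels

    def validate_partition(self) -> None:
        """Check that each non-leaf's children exactly partition its landmarks."""
        for seg in self.segments:
            left, right = self._by_id.get(2 * seg.segment_id), self._by_id.get(
                2 * seg.segment_id + 1
            )
            if left is None and right is None:
                continue
            if left is None or right is None:
                raise ValueError(f"segment {seg.segment_id} has only one child")
            union = np.sort(np.concatenate([left.indices, right.indices]))
            if len(np.intersect1d(left.indices, right.indices)) > 0:
                raise ValueError(f"children of segment {seg.segment_id} overlap")
            if not np.array_equal(union, np.sort(seg.indices)):
                raise ValueError(
                    f"children of segment {seg.segment_id} do not partition it"
                )

    def to_dict(self) -> dict:
        return {
            "n_levels": self.n_levels,
            "complete": self.complete,
            "segments": [
                {
                    "segment_id": s.segment_id,
                    "level": s.level,
                    "parent_id": s.parent_id,
                    "indices": [int(i) for i in s.indices],
                }
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentHierarchy":
        segs = [
            Segment(
                int(s["segment_id"]),
                int(s["level"]),
                None if s["parent_id"] is None else int(s["parent_id"]),
                np.asarray(s["indices"], dtype=int),
            )
            for s in d["segments"]
        ]
        return cls(segs, int(d["n_levels"]), bool(d.get("complete", True)))


@dataclass
class ModulePhenotype:
    """Retained-PC score representation of one facial module."""

    segment_id: int
    ids: np.ndarray
    scores: np.ndarray  # (n, K)
    eigenvalues: np.ndarray  # (K,)
    loadings: np.ndarray  # (3*|segment|, K), column-orthonormal
    mean_shape: np.ndarray  # (|segment|, 3) segment GPA mean
    adjusted: bool = False
    zero_residual: bool = False

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def retain(self, k: int) -> "ModulePhenotype":
        k = max(1, min(k, self.scores.shape[1]))
        return replace(
            self,
            scores=self.scores[:, :k].copy(),
            eigenvalues=self.eigenvalues[:k].copy(),
            loadings=self.loadings[:, :k].copy(),
        )

    def subset_individuals(self, keep: np.ndarray) -> "ModulePhenotype":
        return replace(self, ids=self.ids[keep], scores=self.scores[keep])


# ---------------------------------------------------------------------------
# GPA


def _kabsch(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det = +1) minimising ||x @ R - target||_F."""
    h = x.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def gpa_align(
    landmarks: LandmarkSet,
    scale: bool = True,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> tuple[LandmarkSet, np.ndarray]:
    """Generalized Procrustes analysis.

    Removes translation (centroids to origin) and rotation (orthogonal
    Procrustes fits, reflections forbidden), optionally scales every
    configuration to unit centroid size, and iterates mean re-estimation to
    convergence. Returns the aligned set (with pre-scaling centroid sizes
    recorded) and the consensus mean shape.
    """
    x = landmarks.coords.copy()
    n = x.shape[0]
    if n < 2:
        raise ValueError("GPA requires at least two configurations")
    x -= x.mean(axis=1, keepdims=True)
    sizes = np.sqrt((x**2).sum(axis=(1, 2)))
    if np.any(sizes < 1e-12):
        raise ValueError("degenerate configuration: all landmarks coincident")
    if scale:
        x /= sizes[:, None, None]

    mean = x.mean(axis=0)
    mean_size = np.sqrt((mean**2).sum())
    if mean_size < 1e-12:
        raise ValueError("degenerate mean shape in GPA")
    if scale:
        mean /= mean_size

    for _ in range(max_iter):
        for i in range(n):
            x[i] = x[i] @ _kabsch(x[i], mean)
        new_mean = x.mean(axis=0)
        new_mean -= new_mean.mean(axis=0)
        if scale:
            new_mean /= np.sqrt((new_mean**2).sum())
        change = np.sqrt(((new_mean - mean) ** 2).sum())
        mean = new_mean
        if change < tol:
            break
    else:
        raise RuntimeError(
            f"GPA did not converge in {max_iter} iterations (residual {change:.3e})"
        )

    # canonical orientation: GPA output is defined only up to a global
    # rotation of the consensus, so align the mean shape to its principal
    # axes (deterministic signs, proper rotation). This makes the aligned
    # coordinates themselves invariant under rigid transformation of the
    # input, not merely equivalent up to rotation — downstream permutation
    # benchmarks (parallel analysis) operate on coordinates and would
    # otherwise flip retention decisions at threshold-grazing eigenvalues.
    _, axes = np.linalg.eigh(mean.T @ mean)
    axes = axes[:, ::-1]
    for j in range(3):
        i = np.argmax(np.abs(axes[:, j]))
        if axes[i, j] < 0:
            axes[:, j] = -axes[:, j]
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    x = x @ axes
    mean = mean @ axes

    return (
        LandmarkSet(landmarks.ids, x, aligned=True, centroid_sizes=sizes),
        mean,
    )


# ---------------------------------------------------------------------------
# landmark similarity and spectral segmentation


def landmark_similarity(
    aligned: LandmarkSet, indices: np.ndarray | None = None
) -> np.ndarray:
    """Pairwise RV coefficients between per-landmark displacement blocks.

    For landmarks i and j with centered n-by-3 displacement matrices X_i,
    X_j, RV(i, j) = ||X_i' X_j||_F^2 / (||X_i' X_i||_F ||X_j' X_j||_F),
    which lies in [0, 1], equals 1 on the diagonal, and is invariant to a
    common 3D rotation of both blocks.
    """
    if not aligned.aligned:
        raise ValueError("landmark_similarity requires GPA-aligned landmarks")
    coords = aligned.coords
    if indices is not None:
        coords = coords[:, np.asarray(indices, dtype=int), :]
    n, lp, _ = coords.shape
    disp = coords - coords.mean(axis=0, keepdims=True)
    m = disp.reshape(n, 3 * lp)
    b = (m.T @ m).reshape(lp, 3, lp, 3)
    g = np.einsum("iajb,iajb->ij", b, b)
    d = np.sqrt(np.diag(g))
    zero = d < 1e-12
    if np.any(zero):
        logger.info("landmark_similarity: %d zero-variance landmarks", zero.sum())
        d = np.where(zero, 1.0, d)
    s = g / np.outer(d, d)
    s[zero, :] = 0.0
    s[:, zero] = 0.0
    np.fill_diagonal(s, 1.0)
    return np.clip(s, 0.0, 1.0)


def _components_split(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Group disconnected components into two non-empty balanced parts."""
    n_comp, labels = connected_components((adj > 1e-12).astype(np.int8), directed=False)
    sizes = np.bincount(labels)
    order = np.argsort(-sizes)
    bins: list[list[int]] = [[], []]
    totals = [0, 0]
    for comp in order:
        b = int(totals[1] < totals[0])
        bins[b].append(comp)
        totals[b] += sizes[comp]
    a = np.flatnonzero(np.isin(labels, bins[0]))
    b_ = np.flatnonzero(np.isin(labels, bins[1]))
    return a, b_


def spectral_bipartition(
    similarity: np.ndarray, indices: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split landmarks into two co-varying groups.

    Builds the normalized Laplacian of the similarity graph, embeds landmarks
    in the two lowest eigenvectors, and refines the sign split of the Fiedler
    vector by k-means (k = 2, deterministically seeded from the sign split).
    Disconnected graphs are split along connected components; a structureless
    (all-equal) similarity falls back to a deterministic half split with the
    lowest-index landmark in part A.
    """
    s = np.asarray(similarity, dtype=float)
    p = s.shape[0]
    if indices is None:
        indices = np.arange(p)
    indices = np.asarray(indices)
    if p < 2:
        raise ValueError("cannot bipartition fewer than 2 landmarks")
    if p < 4:
        logger.warning("spectral_bipartition on %d < 4 landmarks", p)

    adj = s.copy()
    np.fill_diagonal(adj, 0.0)

    off = adj[~np.eye(p, dtype=bool)]
    if np.ptp(off) < 1e-12:
        logger.info("spectral_bipartition: degenerate similarity, half split")
        half = (p + 1) // 2
        return indices[:half], indices[half:]

    n_comp, _ = connected_components((adj > 1e-12).astype(np.int8), directed=False)
    if n_comp > 1:
        logger.info("spectral_bipartition: %d connected components", n_comp)
        a, b = _components_split(adj)
        if indices[a.min() if len(a) else 0] > indices[b.min()]:
            a, b = b, a
        return indices[a], indices[b]

    deg = adj.sum(axis=1)
    d_isqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    lap = np.eye(p) - d_isqrt[:, None] * adj * d_isqrt[None, :]
    lap = (lap + lap.T) / 2.0
    eigval, eigvec = np.linalg.eigh(lap)
    embed = eigvec[:, :2]
    fiedler = eigvec[:, 1]
    # orient the Fiedler vector deterministically
    j = np.argmax(np.abs(fiedler))
    if fiedler[j] < 0:
        fiedler = -fiedler
        embed = embed * np.array([1.0, -1.0])

    pos = fiedler >= 0
    if pos.all() or (~pos).all():
        pos = fiedler >= np.median(fiedler)
    if pos.all() or (~pos).all():
        half = (p + 1) // 2
        return indices[:half], indices[half:]

    centers = np.vstack([embed[pos].mean(axis=0), embed[~pos].mean(axis=0)])
    km = KMeans(n_clusters=2, init=centers, n_init=1, max_iter=100, random_state=0)
    labels = km.fit_predict(embed)
    if (labels == 0).all() or (labels == 1).all():
        labels = (~pos).astype(int)

    a = np.flatnonzero(labels == labels[np.argmin(indices)])
    b = np.flatnonzero(labels != labels[np.argmin(indices)])
    return indices[a], indices[b]


def build_hierarchy(
    landmarks: LandmarkSet, n_levels: int = 5, min_split: int = 8
) -> SegmentHierarchy:
    """Recursive GPA -> similarity -> bipartition segmentation.

    Level 0 is the full face; each node is re-aligned on its own landmarks,
    its RV similarity recomputed, and split in two, down to ``n_levels``
    levels (2**n_levels - 1 segments for a full hierarchy). Branches smaller
    than ``min_split`` landmarks stop splitting and the hierarchy is reported
    incomplete.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    all_idx = np.arange(landmarks.n_landmarks)
    segments = [Segment(1, 0, None, all_idx)]
    complete = True
    queue = [segments[0]]
    while queue:
        seg = queue.pop(0)
        if seg.level >= n_levels - 1:
            continue
        if len(seg.indices) < min_split:
            logger.warning(
                "segment %d has %d < %d landmarks; branch not split",
                seg.segment_id,
                len(seg.indices),
                min_split,
            )
            complete = False
            continue
        sub, _ = gpa_align(landmarks.subset_landmarks(seg.indices))
        sim = landmark_similarity(sub)
        a, b = spectral_bipartition(sim, seg.indices)
        if a.min() > b.min():
            a, b = b, a
        left = Segment(2 * seg.segment_id, seg.level + 1, seg.segment_id, np.sort(a))
        right = Segment(
            2 * seg.segment_id + 1, seg.level + 1, seg.segment_id, np.sort(b)
        )
        segments.extend([left, right])
        queue.extend([left, right])
    segments.sort(key=lambda s: s.segment_id)
    return SegmentHierarchy(segments, n_levels, complete)


# ---------------------------------------------------------------------------
# per-module PCA, retention, adjustment, QC


def module_pca(aligned: LandmarkSet, segment_id: int = 1) -> ModulePhenotype:
    """PCA of a segment's aligned coordinates (all non-null components).

    Input must already be GPA-aligned on exactly the segment's landmarks.
    Scores are uncorrelated, loadings column-orthonormal, eigenvalues
    descending. Column signs follow a deterministic convention: the
    largest-magnitude entry of each score column is positive (this keeps
    scores invariant under rigid transformation of the raw input).
    """
    if not aligned.aligned:
        raise ValueError("module_pca requires GPA-aligned landmarks")
    n, lp, _ = aligned.coords.shape
    x = aligned.coords.reshape(n, 3 * lp)
    mean = x.mean(axis=0)
    xc = x - mean
    u, sv, vt = np.linalg.svd(xc, full_matrices=False)
    keep = sv > max(1e-12, 1e-10 * sv[0])
    if not keep.any():  # constant segment: keep one (zero-variance) component
        keep = np.zeros_like(keep)
        keep[0] = True
    if keep.sum() < xc.shape[1] and keep.sum() < n - 1:
        logger.info(
            "module_pca segment %d: rank deficiency, %d/%d components",
            segment_id,
            int(keep.sum()),
            min(n - 1, xc.shape[1]),
        )
    u, sv, vt = u[:, keep], sv[keep], vt[keep]
    scores = u * sv
    loadings = vt.T
    # deterministic sign convention
    for j in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
            loadings[:, j] = -loadings[:, j]
    eigenvalues = sv**2 / (n - 1)
    return ModulePhenotype(
        segment_id=segment_id,
        ids=aligned.ids,
        scores=scores,
        eigenvalues=eigenvalues,
        loadings=loadings,
        mean_shape=mean.reshape(lp, 3),
    )


def parallel_analysis(
    data: np.ndarray,
    n_perm: int = 100,
    percentile: float = 95.0,
    rng: np.random.Generator | int | None = None,
) -> int:
    """Number of principal components to retain by parallel analysis.

    Observed covariance eigenvalues are compared position-wise against the
    ``percentile`` of eigenvalues from column-permuted copies of the data;
    retention stops at the first observed eigenvalue not exceeding its noise
    benchmark. At least one component is always retained.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    x = np.asarray(data, dtype=float)
    xc = x - x.mean(axis=0)
    n = x.shape[0]
    r = min(n - 1, x.shape[1])
    obs = (np.linalg.svd(xc, compute_uv=False) ** 2)[:r] / (n - 1)
    null = np.empty((n_perm, r))
    for b in range(n_perm):
        perm = rng.permuted(xc, axis=0)
        null[b] = (np.linalg.svd(perm, compute_uv=False) ** 2)[:r] / (n - 1)
    thresh = np.percentile(null, percentile, axis=0)
    exceeds = obs > thresh
    k = 0
    for flag in exceeds:
        if not flag:
            break
        k += 1
    return max(k, 1)


def validate_covariates(table: pd.DataFrame, ids: np.ndarray) -> pd.DataFrame:
    """Align a covariate table to the given individual ids; no missing values."""
    if "id" not in table.columns:
        raise ValueError("covariate table needs an 'id' column")
    t = table.set_index(table["id"].astype(str)).drop(columns=["id"])
    missing = [i for i in np.asarray(ids).astype(str) if i not in t.index]
    if missing:
        raise ValueError(f"covariate table missing ids: {missing[:5]}...")
    t = t.loc[np.asarray(ids).astype(str)]
    if t.isna().any().any():
        raise ValueError("covariate table contains missing values")
    return t


def pls_adjust(
    phenotype: ModulePhenotype,
    covariates: pd.DataFrame,
    columns: list[str] | None = None,
) -> ModulePhenotype:
    """Remove covariate effects from module scores by PLS regression.

    The number of PLS components equals the rank of the covariate matrix, at
    which point the PLS2 fit coincides with the least-squares projection onto
    the covariate column space; the residualisation is therefore computed in
    that closed form, leaving residual scores exactly (to machine precision)
    orthogonal to every covariate.
    """
    t = validate_covariates(covariates, phenotype.ids)
    if columns is not None:
        t = t[columns]
    xcols = []
    for c in t.columns:
        col = np.asarray(t[c], dtype=float)
        if np.std(col) < 1e-12:
            warnings.warn(f"constant covariate column '{c}' dropped")
            continue
        xcols.append((col - col.mean()) / col.std())
    x = np.column_stack([np.ones(phenotype.n)] + xcols)
    beta, *_ = np.linalg.lstsq(x, phenotype.scores, rcond=None)
    resid = phenotype.scores - x @ beta
    zero = bool(resid.size == 0 or np.max(np.abs(resid)) < 1e-10)
    if zero:
        warnings.warn("phenotype fully explained by covariates; residuals are zero")
    return replace(phenotype, scores=resid, adjusted=True, zero_residual=zero)


def mahalanobis_outliers(
    phenotype: ModulePhenotype, alpha: float = 0.05, random_state: int = 0
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Robust squared Mahalanobis distances and outlier flags for a module.

    Center/covariance come from the minimum covariance determinant estimator
    (classical estimate as fallback if the robust covariance is singular).
    Flags use a Bonferroni-style chi-squared cutoff at 1 - alpha/n with K
    degrees of freedom. Q-Q data (chi-squared quantiles vs ordered distances)
    are returned for visual review.
    """
    scores = phenotype.scores
    n, k = scores.shape
    if n <= 5 * k:
        warnings.warn(f"n = {n} <= 5K = {5 * k}: robust distances may be unstable")
    try:
        est = MinCovDet(random_state=random_state).fit(scores)
        if np.linalg.cond(est.covariance_) > 1e12:
            raise np.linalg.LinAlgError("singular robust covariance")
        d2 = est.mahalanobis(scores)
    except (np.linalg.LinAlgError, ValueError):
        logger.warning("MCD failed or singular; classical covariance fallback")
        est = EmpiricalCovariance().fit(scores)
        d2 = est.mahalanobis(scores)
    cutoff = stats.chi2.ppf(1.0 - alpha / n, df=k)
    flags = d2 > cutoff
    order = np.argsort(d2)
    qq = pd.DataFrame(
        {
            "id": np.asarray(phenotype.ids)[order],
            "chi2_quantile": stats.chi2.ppf((np.arange(1, n + 1) - 0.5) / n, df=k),
            "distance": d2[order],
        }
    )
    return d2, flags, qq


# ---------------------------------------------------------------------------
# pipeline


def segment_phenotype(
    landmarks: LandmarkSet,
    indices: np.ndarray,
    segment_id: int = 1,
    n_perm: int = 100,
    percentile: float = 95.0,
    rng: np.random.Generator | int | None = None,
    covariates: pd.DataFrame | None = None,
) -> ModulePhenotype:
    """Segment GPA -> PCA -> parallel-analysis retention -> PLS adjustment."""
    sub, _ = gpa_align(landmarks.subset_landmarks(indices))
    phen = module_pca(sub, segment_id)
    x = sub.coords.reshape(sub.n, -1)
    k = parallel_analysis(x, n_perm=n_perm, percentile=percentile, rng=rng)
    phen = phen.retain(k)
    if covariates is not None:
        phen = pls_adjust(phen, covariates)
    return phen


def phenotype_modules(
    landmarks: LandmarkSet,
    covariates: pd.DataFrame | None = None,
    n_levels: int = 5,
    n_perm: int = 100,
    percentile: float = 95.0,
    seed: int = 0,
    hierarchy: SegmentHierarchy | None = None,
    qc_alpha: float | None = 0.05,
) -> tuple[SegmentHierarchy, list[ModulePhenotype], dict]:
    """Full phenotyping stage: hierarchy plus one adjusted phenotype per module.

    The full-face GPA centroid sizes are inserted into the covariate table as
    the facial-size covariate (column ``centroid_size``) before adjustment.
    A ``hierarchy`` computed on another dataset may be supplied to freeze
    segment boundaries. Returns (hierarchy, phenotypes, qc) where qc maps
    segment_id -> dict with robust distances, flags and Q-Q data.
    """
    aligned, _ = gpa_align(landmarks)
    if hierarchy is None:
        hierarchy = build_hierarchy(aligned, n_levels=n_levels)
    cov = None
    if covariates is not None:
        cov = covariates.copy()
        sizes = pd.Series(
            aligned.centroid_sizes, index=np.asarray(aligned.ids).astype(str)
        )
        cov["centroid_size"] = sizes.reindex(cov["id"].astype(str)).to_numpy()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(hierarchy.segments))
    phens: list[ModulePhenotype] = []
    qc: dict[int, dict] = {}
    for seg, child in zip(hierarchy.segments, children):
        phen = segment_phenotype(
            aligned,
            seg.indices,
            segment_id=seg.segment_id,
            n_perm=n_perm,
            percentile=percentile,
            rng=np.random.default_rng(child),
            covariates=cov,
        )
        if qc_alpha is not None:
            d2, flags, qq = mahalanobis_outliers(phen, alpha=qc_alpha)
            qc[seg.segment_id] = {"distances": d2, "flags": flags, "qq": qq}
        phens.append(phen)
        logger.info(
            "module %d: %d landmarks, %d PCs retained",
            seg.segment_id,
            len(seg.indices),
            phen.k,
        )
    return hierarchy, phens, qc
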