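"""Multiplicity correction, significance calling, effect sizes, morph export.

The scan produces one omnibus p-value per (gene, module) pair. Because the
31 modules overlap along the hierarchy, their tests are correlated; the
effective number of independent modules M_eff is computed from the
eigenvalues of the inter-module RV-correlation matrix (Li-Ji procedure), and
the Bonferroni threshold is alpha / (n_genes * M_eff). Effect sizes are
Euclidean distances between carrier and non-carrier centroids in a module's
PC space; morphs export the carrier-minus-non-carrier mean shape
displacement (exaggerated for visibility) with a signed surface-normal
component for depression/protrusion colouring.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .shapemod import ModulePhenotype, SegmentHierarchy, LandmarkSet

logger = logging.getLogger(__name__)

__all__ = [
    "MultiplicityPlan",
    "EffectSize",
    "module_correlation",
    "effective_tests_li_ji",
    "significance_threshold",
    "make_plan",
    "effect_size_centroid",
    "morph_export",
    "assemble_report",
]


@dataclass
class MultiplicityPlan:
    n_genes: int
    correlation: np.ndarray
    eigenvalues: np.ndarray
    m_eff_raw: float
    m_eff: int
    alpha: float
    threshold: float


@dataclass
class EffectSize:
    target_id: str
    module_id: int
    carrier_count: int
    noncarrier_count: int
    distance: float


def _rv(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    num = np.linalg.norm(xc.T @ yc) ** 2
    den = np.linalg.norm(xc.T @ xc) * np.linalg.norm(yc.T @ yc)
    return float(num / den) if den > 0 else 0.0


def module_correlation(modules: list[ModulePhenotype]) -> np.ndarray:
    """Inter-module RV coefficients between PC score blocks.

    Symmetric with unit diagonal; projected to PSD (eigenvalue floor at 0,
    with a warning) if numerics put a small negative eigenvalue in.
    """
    ids0 = np.asarray(modules[0].ids)
    for m in modules[1:]:
        if not np.array_equal(np.asarray(m.ids), ids0):
            raise ValueError("modules must share a common set of individuals")
    k = len(modules)
    c = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            c[i, j] = c[j, i] = _rv(modules[i].scores, modules[j].scores)
    w = np.linalg.eigvalsh(c)
    if w.min() < -1e-10:
        warnings.warn(f"module correlation not PSD (min eig {w.min():.2e}); floored")
        w_, v = np.linalg.eigh(c)
        c = v @ np.diag(np.clip(w_, 0.0, None)) @ v.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
    return c


def effective_tests_li_ji(corr: np.ndarray) -> tuple[float, int]:
    """Li-Ji effective number of independent tests.

    M_eff = sum_i [ 1(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ] over
    the eigenvalues of the correlation matrix. Returns (raw, rounded)
    with round-half-up integer reporting.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    lam = np.clip(np.linalg.eigvalsh(corr), 0.0, None)
    # guard the floor against eigenvalues like 2.9999999999996
    lam = np.round(lam, 10)
    m_eff = float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))
    return m_eff, int(np.floor(m_eff + 0.5))


def significance_threshold(n_genes: int, m_eff: int, alpha: float = 0.05) -> float:
    """Bonferroni threshold alpha / (n_genes * M_eff)."""
    if n_genes <= 0 or m_eff <= 0 or alpha <= 0:
        raise ValueError("n_genes, m_eff and alpha must be positive")
    return alpha / (n_genes * m_eff)


def format_threshold(threshold: float, sig_figs: int = 2) -> str:
    """Threshold at 2 significant figures, as printed in reports."""
    return f"{threshold:.{sig_figs - 1}e}"


def make_plan(
    modules: list[ModulePhenotype], n_genes: int, alpha: float = 0.05
) -> MultiplicityPlan:
    corr = module_correlation(modules)
    lam = np.clip(np.linalg.eigvalsh(corr), 0.0, None)
    m_raw, m_int = effective_tests_li_ji(corr)
    return MultiplicityPlan(
        n_genes=n_genes,
        correlation=corr,
        eigenvalues=lam,
        m_eff_raw=m_raw,
        m_eff=m_int,
        alpha=alpha,
        threshold=significance_threshold(n_genes, m_int, alpha),
    )


def effect_size_centroid(
    phenotype: ModulePhenotype, carrier_flags: np.ndarray, target_id: str = ""
) -> EffectSize:
    """Euclidean distance between carrier and non-carrier PC-space centroids."""
    flags = np.asarray(carrier_flags, dtype=bool)
    if flags.sum() == 0:
        raise ValueError("no carriers: effect size undefined")
    if (~flags).sum() == 0:
        raise ValueError("no non-carriers: effect size undefined")
    mu_c = phenotype.scores[flags].mean(axis=0)
    mu_n = phenotype.scores[~flags].mean(axis=0)
    return EffectSize(
        target_id=target_id,
        module_id=phenotype.segment_id,
        carrier_count=int(flags.sum()),
        noncarrier_count=int((~flags).sum()),
        distance=float(np.linalg.norm(mu_c - mu_n)),
    )


def _local_normals(points: np.ndarray, k_neighbors: int = 8) -> np.ndarray:
    """Per-point unit normals from local plane fits (PCA of k nearest points)."""
    from scipy.spatial import cKDTree

    tree = cKDTree(points)
    k = min(k_neighbors + 1, len(points))
    _, idx = tree.query(points, k=k)
    normals = np.empty_like(points)
    for i in range(len(points)):
        nb = points[idx[i]]
        nb = nb - nb.mean(axis=0)
        _, _, vt = np.linalg.svd(nb, full_matrices=False)
        nrm = vt[-1]
        if nrm[2] < 0:  # orient toward +z (the patch opens upward)
            nrm = -nrm
        normals[i] = nrm
    return normals


def morph_export(
    aligned: LandmarkSet,
    hierarchy: SegmentHierarchy,
    segment_id: int,
    carrier_flags: np.ndarray,
    exaggeration: float = 7.0,
    out_prefix: str | None = None,
) -> dict:
    """Carrier-vs-non-carrier morph for one segment.

    Returns the non-carrier mean shape, the carrier-minus-non-carrier
    displacement per landmark multiplied by ``exaggeration``, and a signed
    normal-component scalar (negative = depression, positive = protrusion).
    With ``out_prefix``, writes an ASCII PLY point cloud (with a
    signed_displacement vertex property) and a TSV.
    """
    if segment_id not in hierarchy._by_id:
        raise ValueError(f"unknown segment {segment_id}")
    flags = np.asarray(carrier_flags, dtype=bool)
    seg = hierarchy.get(segment_id)
    coords = aligned.coords[:, seg.indices, :]
    mean_non = coords[~flags].mean(axis=0)
    mean_car = coords[flags].mean(axis=0) if flags.any() else mean_non.copy()
    disp = exaggeration * (mean_car - mean_non)
    normals = _local_normals(mean_non)
    signed = (disp * normals).sum(axis=1)
    result = {
        "segment_id": segment_id,
        "landmark_indices": seg.indices,
        "noncarrier_mean": mean_non,
        "displacement": disp,
        "signed_displacement": signed,
    }
    if out_prefix is not None:
        _write_ply(f"{out_prefix}.ply", mean_non, signed)
        pd.DataFrame(
            {
                "landmark": seg.indices,
                "x": mean_non[:, 0],
                "y": mean_non[:, 1],
                "z": mean_non[:, 2],
                "dx": disp[:, 0],
                "dy": disp[:, 1],
                "dz": disp[:, 2],
                "signed_displacement": signed,
            }
        ).to_csv(f"{out_prefix}.tsv", sep="\t", index=False)
    return result


def _write_ply(path: str, points: np.ndarray, scalar: np.ndarray) -> None:
    """Minimal ASCII PLY point cloud with a per-vertex scalar channel."""
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(points)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property float signed_displacement\nend_header\n")
        for p, s in zip(points, scalar):
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {s:.6f}\n")


def assemble_report(
    scan_results: pd.DataFrame,
    plan: MultiplicityPlan,
    effects: list[EffectSize] | None = None,
    out_dir: str | None = None,
    seed: int | None = None,
) -> dict:
    """Bundle the scan into reporting tables.

    * significant: gene, modules passing the threshold, best p-value;
    * manhattan: one row per gene per module (p-value export for plotting);
    * qq: expected-vs-observed -log10 p of all omnibus p-values;
    * manifest: n_genes, M_eff, threshold, seed.
    """
    sig_mask = scan_results["p_omnibus"] < plan.threshold
    sig = (
        scan_results.loc[sig_mask]
        .groupby("gene")
        .agg(
            modules=("module", lambda m: ",".join(str(v) for v in sorted(m))),
            best_p=("p_omnibus", "min"),
        )
        .reset_index()
        .sort_values("best_p", ignore_index=True)
        if sig_mask.any()
        else pd.DataFrame(columns=["gene", "modules", "best_p"])
    )
    manhattan = scan_results[["gene", "module", "p_omnibus"]].copy()
    pvals = np.sort(scan_results["p_omnibus"].to_numpy())
    n = len(pvals)
    qq = pd.DataFrame(
        {
            "expected": -np.log10((np.arange(1, n + 1) - 0.5) / n),
            "observed": -np.log10(np.clip(pvals, 1e-300, 1.0)),
        }
    )
    manifest = {
        "n_genes": plan.n_genes,
        "n_modules": plan.correlation.shape[0],
        "m_eff_raw": plan.m_eff_raw,
        "m_eff": plan.m_eff,
        "alpha": plan.alpha,
        "threshold": plan.threshold,
        "threshold_printed": format_threshold(plan.threshold),
        "n_significant_genes": int(len(sig)),
        "seed": seed,
    }
    bundle = {"significant": sig, "manhattan": manhattan, "qq": qq, "manifest": manifest}
    if effects:
        bundle["effects"] = pd.DataFrame(
            [
                {
                    "target_id": e.target_id,
                    "module": e.module_id,
                    "carriers": e.carrier_count,
                    "noncarriers": e.noncarrier_count,
                    "centroid_distance": e.distance,
                }
                for e in effects
            ]
        )
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        sig.to_csv(os.path.join(out_dir, "significant_genes.tsv"), sep="\t", index=False)
        manhattan.to_csv(os.path.join(out_dir, "manhattan.tsv"), sep="\t", index=False)
        qq.to_csv(os.path.join(out_dir, "qq.tsv"), sep="\t", index=False)
        if effects:
            bundle["effects"].to_csv(
                os.path.join(out_dir, "effect_sizes.tsv"), sep="\t", index=False
            )
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
    return bundle
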