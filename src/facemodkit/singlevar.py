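"""Single-variant multivariate follow-up tests.

Reverse ordinal regression: for one variant, the genotype category (0/1/2
copies of the minor allele) is regressed on all K PCs of a facial module
jointly, and a likelihood-ratio test with K degrees of freedom asks whether
any linear combination of the PCs predicts carrier status. With only two
observed genotype classes this reduces to binary logistic regression; a
Firth-type penalized fit takes over when the likelihood is separated, which
low-frequency heterozygote-only variants are prone to.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .shapemod import ModulePhenotype
from .genoprep import GeneVariantSet

logger = logging.getLogger(__name__)

__all__ = ["VariantTestResult", "multiphen_test", "followup_scan", "best_only"]


@dataclass
class VariantTestResult:
    variant_id: str
    module_id: int
    p_value: float
    df: int
    model: str  # 'ordinal' | 'binary-logistic' | 'penalized'
    carrier_count: int


def _null_loglik(counts: np.ndarray) -> float:
    """Intercept-only log-likelihood of an ordered categorical response."""
    n = counts.sum()
    nz = counts[counts > 0]
    return float((nz * np.log(nz / n)).sum())


def _firth_logit(x: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-10):
    """Jeffreys-penalized logistic regression (Firth). Returns (beta, penalized ll)."""
    beta = np.zeros(x.shape[1])
    ll_pen = -np.inf
    for _ in range(max_iter):
        eta = x @ beta
        p = expit(eta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        xtwx = (x * w[:, None]).T @ x
        try:
            inv = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError:
            inv = np.linalg.pinv(xtwx)
        h = np.einsum("ij,jk,ik->i", x, inv, x) * w
        u = x.T @ (y - p + h * (0.5 - p))
        step = inv @ u
        # damped update for stability
        nrm = np.linalg.norm(step)
        if nrm > 5.0:
            step *= 5.0 / nrm
        beta = beta + step
        eta = x @ beta
        p = expit(eta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        sign, logdet = np.linalg.slogdet((x * w[:, None]).T @ x)
        ll = float(
            np.sum(y * np.log(np.clip(p, 1e-300, 1)) + (1 - y) * np.log(np.clip(1 - p, 1e-300, 1)))
        )
        new_ll_pen = ll + 0.5 * logdet
        if abs(new_ll_pen - ll_pen) < tol:
            ll_pen = new_ll_pen
            break
        ll_pen = new_ll_pen
    return beta, ll_pen


def _is_separated(x: np.ndarray, y: np.ndarray, fitted) -> bool:
    p = np.asarray(fitted)
    return bool(np.all((p > 0.5) == (y > 0.5)) and (np.min(np.abs(p - 0.5)) > 0.499))


def multiphen_test(dosage: np.ndarray, phenotype: ModulePhenotype) -> VariantTestResult:
    """Joint reverse-regression test of one variant against a module.

    Likelihood-ratio test (df = K) of proportional-odds ordinal regression of
    the genotype category on all module PCs, against the intercept-only
    model. Dosages are rounded to the nearest integer category. Binary
    logistic with two observed classes; Firth-penalized on separation.
    """
    d = np.rint(np.asarray(dosage, dtype=float)).astype(int)
    classes, counts = np.unique(d, return_counts=True)
    if len(classes) < 2:
        raise ValueError("constant dosage: variant cannot be tested")
    scores = phenotype.scores
    n, k = scores.shape
    if len(d) != n:
        raise ValueError("dosage length does not match phenotype")
    z = (scores - scores.mean(axis=0)) / np.where(
        scores.std(axis=0) > 1e-12, scores.std(axis=0), 1.0
    )
    ll0 = _null_loglik(counts)
    carrier_count = int((d > 0).sum())

    if len(classes) == 2:
        y = (d == classes.max()).astype(float)
        import statsmodels.api as sm

        xm = sm.add_constant(z)
        model = "binary-logistic"
        llf = None
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, xm).fit(disp=0, maxiter=200)
            if (
                not np.all(np.isfinite(fit.params))
                or np.max(np.abs(fit.params)) > 50
                or _is_separated(xm, y, fit.predict())
            ):
                raise np.linalg.LinAlgError("separation suspected")
            llf = fit.llf
        except Exception:
            model = "penalized"
            _, ll_full = _firth_logit(xm, y)
            _, ll_null = _firth_logit(np.ones((n, 1)), y)
            lrt = 2.0 * (ll_full - ll_null)
            p = float(stats.chi2.sf(max(lrt, 0.0), df=k))
            return VariantTestResult(
                "", phenotype.segment_id, max(p, 1e-300), k, model, carrier_count
            )
        lrt = 2.0 * (llf - ll0)
    else:
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = OrderedModel(d, z, distr="logit").fit(
                method="bfgs", disp=0, maxiter=500
            )
        model = "ordinal"
        lrt = 2.0 * (fit.llf - ll0)
    p = float(stats.chi2.sf(max(lrt, 0.0), df=k))
    return VariantTestResult(
        "", phenotype.segment_id, max(p, 1e-300), k, model, carrier_count
    )


def followup_scan(
    scan_results: pd.DataFrame,
    threshold: float,
    genes: list[GeneVariantSet],
    modules: dict[int, ModulePhenotype],
) -> pd.DataFrame:
    """Single-variant tests for variants in genes with gene-level significance.

    Every variant of a significant gene is tested against every module in
    which its gene passed the threshold; the table is sorted by p-value.
    Returns an empty (but well-formed) table when nothing is significant.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    sig = scan_results.loc[scan_results["p_omnibus"] < threshold]
    rows = []
    for _, hit in sig.iterrows():
        gene = gene_by_id.get(hit["gene"])
        if gene is None:
            logger.warning("significant gene %s missing from gene sets", hit["gene"])
            continue
        phen = modules[int(hit["module"])]
        for j, vid in enumerate(gene.variant_ids):
            dosage = gene.dosages[:, j]
            if np.rint(dosage).std() == 0:
                continue
            res = multiphen_test(dosage, phen)
            rows.append(
                {
                    "variant_id": vid,
                    "gene": gene.gene_id,
                    "module": int(hit["module"]),
                    "maf": gene.mafs[j],
                    "p_value": res.p_value,
                    "df": res.df,
                    "model": res.model,
                    "carrier_count": res.carrier_count,
                }
            )
    cols = ["variant_id", "gene", "module", "maf", "p_value", "df", "model", "carrier_count"]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values("p_value", ignore_index=True) if len(out) else out


def best_only(followup: pd.DataFrame) -> pd.DataFrame:
    """Per variant, keep only the module with the smallest p-value."""
    if len(followup) == 0:
        return followup
    return (
        followup.sort_values("p_value")
        .groupby("variant_id", as_index=False)
        .first()
        .sort_values("p_value", ignore_index=True)
    )
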