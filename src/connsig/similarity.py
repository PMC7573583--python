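"""FC-signature similarity framework.

A group-level FC-signature (the vector of CWAS betas) is correlated with
individual connectomes from another cohort; cases and controls of that
cohort are then compared on their similarity scores with a Mann-Whitney U
test, summarized by the rank-biserial correlation 2U/(n1 n2) - 1. The scan
runs whole-brain (one 2080-value profile per subject) or regionally (the 64
values attached to one seed region), and per-subject similarity scores can
be correlated with symptom-severity measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cwas import CohortDataset, SignatureMap, design_matrix
from .connectome import matrixize
from .exceptions import (
    DegenerateDataError,
    LeakageError,
    SampleSizeError,
)


@dataclass
class SimilarityResult:
    """Mann-Whitney comparison of case vs control similarity scores."""

    target_signature: str
    cohort: str
    scope: str                      # "whole_brain" or "region_<k>"
    region_id: int | None
    case_scores: np.ndarray
    control_scores: np.ndarray
    U: float
    p: float
    rank_biserial: float
    q: float = np.nan

    @property
    def n_cases(self) -> int:
        return self.case_scores.size

    @property
    def n_controls(self) -> int:
        return self.control_scores.size


def results_to_frame(results: list[SimilarityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "signature": [r.target_signature for r in results],
            "cohort": [r.cohort for r in results],
            "scope": [r.scope for r in results],
            "region_id": [r.region_id for r in results],
            "n_cases": [r.n_cases for r in results],
            "n_controls": [r.n_controls for r in results],
            "U": [r.U for r in results],
            "rank_biserial": [r.rank_biserial for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
        }
    )


def adjust_connectomes(
    dataset: CohortDataset,
    covariates: tuple[str, ...] | list[str] = ("sex", "site", "age", "mean_fd"),
    include_mean_fc: bool = True,
) -> CohortDataset:
    """Residualize each connection on nuisance covariates.

    Cases and controls of the cohort are pooled in one OLS fit per
    connection (intercept + covariates + optionally the subject's mean
    connectivity over all L connections), and the connectome is replaced by
    the residuals, orthogonal to every covariate column.
    """
    X, _ = design_matrix(dataset.phenotypes, covariates, include_status=False)
    if include_mean_fc:
        X = np.column_stack([X, dataset.connectomes.mean(axis=1)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        from .exceptions import DesignMatrixError

        raise DesignMatrixError("rank-deficient adjustment design")
    coefs, *_ = np.linalg.lstsq(X, dataset.connectomes, rcond=None)
    resid = dataset.connectomes - X @ coefs
    from dataclasses import replace

    return replace(dataset, connectomes=resid)


def similarity_scores(signature: np.ndarray, connectomes: np.ndarray) -> np.ndarray:
    """Pearson correlation of each subject's profile with the signature."""
    signature = np.asarray(signature, dtype=float)
    connectomes = np.atleast_2d(np.asarray(connectomes, dtype=float))
    if connectomes.shape[1] != signature.size:
        raise ValueError("signature and connectome lengths differ")
    sig_c = signature - signature.mean()
    sig_norm = np.linalg.norm(sig_c)
    if sig_norm == 0:
        raise DegenerateDataError("zero-variance signature")
    conn_c = connectomes - connectomes.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(conn_c, axis=1)
    if np.any(norms == 0):
        raise DegenerateDataError("zero-variance connectome profile")
    return (conn_c @ sig_c) / (norms * sig_norm)


def similarity_test(
    signature: np.ndarray,
    case_connectomes: np.ndarray,
    control_connectomes: np.ndarray,
    target_signature: str = "signature",
    cohort: str = "cohort",
    scope: str = "whole_brain",
    region_id: int | None = None,
) -> SimilarityResult:
    """Mann-Whitney U comparison of case vs control similarity scores.

    Exact enumeration for n1 + n2 <= 12 without ties, otherwise the normal
    approximation with midranks and tie-corrected variance. The effect size
    is the rank-biserial correlation 2U/(n1 n2) - 1 in [-1, 1].
    """
    case_scores = similarity_scores(signature, case_connectomes)
    control_scores = similarity_scores(signature, control_connectomes)
    return similarity_test_on_scores(
        case_scores, control_scores, target_signature, cohort, scope, region_id
    )


def similarity_test_on_scores(
    case_scores: np.ndarray,
    control_scores: np.ndarray,
    target_signature: str = "signature",
    cohort: str = "cohort",
    scope: str = "whole_brain",
    region_id: int | None = None,
) -> SimilarityResult:
    case_scores = np.asarray(case_scores, dtype=float)
    control_scores = np.asarray(control_scores, dtype=float)
    n1, n2 = case_scores.size, control_scores.size
    if n1 < 2 or n2 < 2:
        raise SampleSizeError("need >= 2 scores in each group")
    small = (n1 + n2) <= 12
    ties = np.unique(np.concatenate([case_scores, control_scores])).size < n1 + n2
    method = "exact" if (small and not ties) else "asymptotic"
    res = stats.mannwhitneyu(
        case_scores, control_scores, alternative="two-sided", method=method
    )
    u = float(res.statistic)
    rank_biserial = 2.0 * u / (n1 * n2) - 1.0
    return SimilarityResult(
        target_signature=target_signature,
        cohort=cohort,
        scope=scope,
        region_id=region_id,
        case_scores=case_scores,
        control_scores=control_scores,
        U=u,
        p=float(res.pvalue),
        rank_biserial=rank_biserial,
    )


def _apply_fdr(results: list[SimilarityResult], q_threshold: float) -> None:
    pvals = np.array([r.p for r in results])
    _, q, _, _ = multipletests(pvals, alpha=q_threshold, method="fdr_bh")
    for r, qi in zip(results, q):
        r.q = float(qi)


def whole_brain_similarity_scan(
    signatures: dict[str, SignatureMap | np.ndarray],
    cohorts: dict[str, CohortDataset],
    q_threshold: float = 0.05,
) -> list[SimilarityResult]:
    """All directed (signature source, target cohort) whole-brain tests.

    For every ordered pair with source != target, the source group's beta
    map is correlated with each individual connectome of the target cohort
    and cases vs controls are compared; FDR is taken over the tests actually
    run (42 for 7 groups). Subject overlap between a signature's source
    cohort and its target cohort raises a leakage error.
    """
    results: list[SimilarityResult] = []
    for sig_name, sig in signatures.items():
        beta = sig.beta if isinstance(sig, SignatureMap) else np.asarray(sig)
        for coh_name, cohort in cohorts.items():
            if coh_name == sig_name:
                continue
            source = cohorts.get(sig_name)
            if source is not None:
                overlap = source.subject_ids & cohort.subject_ids
                if overlap:
                    raise LeakageError(
                        f"subjects shared between {sig_name} and {coh_name}: "
                        f"{sorted(overlap)[:5]}"
                    )
            is_case = cohort.is_case.astype(bool)
            results.append(
                similarity_test(
                    beta,
                    cohort.connectomes[is_case],
                    cohort.connectomes[~is_case],
                    target_signature=sig_name,
                    cohort=coh_name,
                )
            )
    if results:
        _apply_fdr(results, q_threshold)
    return results


def regional_signatures(
    signature: SignatureMap | np.ndarray, include_diagonal: bool = True
) -> np.ndarray:
    """Break a signature into R region-level profiles (rows of the matrix).

    Region k's profile is row k of the symmetric beta matrix: the R values
    linking region k to every region, including its within-region entry by
    default (set ``include_diagonal=False`` to mask it with NaN).
    """
    beta = signature.beta if isinstance(signature, SignatureMap) else np.asarray(signature)
    mat = matrixize(beta)
    if not include_diagonal:
        mat = mat.copy()
        np.fill_diagonal(mat, np.nan)
    return mat


def regional_similarity_scan(
    signature: SignatureMap | np.ndarray,
    case_connectomes: np.ndarray,
    control_connectomes: np.ndarray,
    q_threshold: float = 0.05,
    target_signature: str = "signature",
    cohort: str = "cohort",
    include_diagonal: bool = True,
) -> list[SimilarityResult]:
    """One similarity test per seed region, FDR over the R regions.

    Connectomes should already be adjusted (see :func:`adjust_connectomes`).
    Region k's similarity correlates the signature's regional profile with
    the matching R values of each subject's connectome.
    """
    sig_rows = regional_signatures(signature, include_diagonal=True)
    r = sig_rows.shape[0]
    case_mats = np.stack([matrixize(c) for c in np.atleast_2d(case_connectomes)])
    ctrl_mats = np.stack([matrixize(c) for c in np.atleast_2d(control_connectomes)])
    results = []
    for k in range(r):
        cols = np.fromiter(
            (i for i in range(r) if include_diagonal or i != k), dtype=int
        )
        results.append(
            similarity_test(
                sig_rows[k, cols],
                case_mats[:, k, cols],
                ctrl_mats[:, k, cols],
                target_signature=target_signature,
                cohort=cohort,
                scope=f"region_{k}",
                region_id=k,
            )
        )
    _apply_fdr(results, q_threshold)
    return results


def behavior_correlation(
    similarity_by_region: pd.DataFrame,
    scores: pd.DataFrame,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of regional similarity scores with behavior.

    ``similarity_by_region``: subjects x regions frame of similarity scores;
    ``scores``: subjects x score-name frame (NaN = missing). Each (region,
    score) pair with >= 3 non-missing subjects contributes one correlation;
    BH-FDR is taken across all pairs tested. All-missing scores are skipped
    with a warning.
    """
    rows = []
    for score_name in scores.columns:
        s = scores[score_name].to_numpy(dtype=float)
        ok = np.isfinite(s)
        if ok.sum() == 0:
            warnings.warn(f"score '{score_name}' entirely missing; skipped", stacklevel=2)
            continue
        if ok.sum() < 3:
            raise SampleSizeError(
                f"score '{score_name}' has {int(ok.sum())} subjects; >= 3 required"
            )
        for region in similarity_by_region.columns:
            sim = similarity_by_region[region].to_numpy(dtype=float)[ok]
            r, p = stats.pearsonr(sim, s[ok])
            rows.append(
                {"region_id": region, "score_name": score_name, "r": float(r), "p": float(p)}
            )
    out = pd.DataFrame(rows)
    if len(out):
        _, q, _, _ = multipletests(out["p"].to_numpy(), alpha=q_threshold, method="fdr_bh")
        out["q"] = q
    return out
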