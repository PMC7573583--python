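"""Connectome-wide association studies (CWAS).

A CWAS contrasts cases against controls one connection at a time: connectomes
are first standardized against the control group's mean and variance, then
each of the L connectivity values is regressed on clinical status plus
nuisance covariates (sex, site, age, head motion by default). The status
coefficient beta, its two-tailed t-test, Benjamini-Hochberg FDR over the L
tests, and a per-connection Cohen's d make up the FC-signature of the
contrast. The mean beta over all connections ("global shift") is tested with
a label-permutation null, and the same label shuffling generates null
FC-signatures reused by the similarity and transcriptomics stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import RegionAtlas
from .connectome import index_to_pair, n_pairs
from .exceptions import (
    ConfigurationError,
    DegenerateDataError,
    DesignMatrixError,
    SampleSizeError,
)

DEFAULT_COVARIATES = ("sex", "site", "age", "mean_fd")

PHENOTYPE_COLUMNS = ["subject_id", "group", "role", "sex", "site", "age", "mean_fd"]


@dataclass
class CohortDataset:
    """Case/control subjects with covariates and connectomes for one contrast.

    ``phenotypes`` has one row per subject (columns ``subject_id``, ``group``,
    ``role`` in {case, control}, ``sex``, ``site``, ``age``, ``mean_fd`` and
    optional behavior-score columns); ``connectomes`` is the aligned n x L
    matrix of canonical connectivity vectors.
    """

    phenotypes: pd.DataFrame
    connectomes: np.ndarray
    contrast_name: str = "contrast"
    zscored: bool = False

    def __post_init__(self) -> None:
        self.connectomes = np.asarray(self.connectomes, dtype=float)
        if len(self.phenotypes) != self.connectomes.shape[0]:
            raise ConfigurationError("phenotype rows and connectome rows differ")
        roles = self.phenotypes["role"].to_numpy()
        if (roles == "case").sum() < 2 or (roles == "control").sum() < 2:
            raise SampleSizeError("need >= 2 cases and >= 2 controls")
        if "site" in self.phenotypes.columns:
            counts = self.phenotypes["site"].value_counts()
            if (counts < 2).any():
                small = counts[counts < 2].index.tolist()
                raise SampleSizeError(f"sites with < 2 subjects: {small}")

    @property
    def n_subjects(self) -> int:
        return len(self.phenotypes)

    @property
    def n_connections(self) -> int:
        return self.connectomes.shape[1]

    @property
    def is_case(self) -> np.ndarray:
        return (self.phenotypes["role"].to_numpy() == "case").astype(float)

    @property
    def subject_ids(self) -> set:
        return set(self.phenotypes["subject_id"])


@dataclass
class SignatureMap:
    """Per-connection estimates from one CWAS (the FC-signature)."""

    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    sig_mask: np.ndarray
    cohens_d: np.ndarray
    global_shift: float
    q_threshold: float = 0.05
    global_shift_p: float | None = None
    n_perm: int = 0
    seed: int | None = None
    contrast_name: str = "contrast"

    @property
    def n_connections(self) -> int:
        return self.beta.size

    @property
    def n_regions(self) -> int:
        r = int((np.sqrt(8 * self.beta.size + 1) - 1) // 2)
        if n_pairs(r) != self.beta.size:
            raise ValueError("signature length is not triangular")
        return r

    def to_frame(self) -> pd.DataFrame:
        r = self.n_regions
        pairs = [index_to_pair(k, r) for k in range(self.n_connections)]
        return pd.DataFrame(
            {
                "connection_id": np.arange(self.n_connections),
                "region_i": [p[0] for p in pairs],
                "region_j": [p[1] for p in pairs],
                "beta": self.beta,
                "t": self.t,
                "p": self.p,
                "q": self.q,
                "sig": self.sig_mask.astype(int),
                "cohens_d": self.cohens_d,
            }
        )


def zscore_to_controls(dataset: CohortDataset) -> CohortDataset:
    """Standardize every connection against the cohort's own controls.

    Each value becomes ``(x - control_mean) / control_SD`` (sample SD,
    ddof=1), so betas downstream are in control-SD units and the global
    shift reads as a displacement of cases relative to controls.
    """
    ctrl = dataset.connectomes[dataset.phenotypes["role"].to_numpy() == "control"]
    mu = ctrl.mean(axis=0)
    sd = ctrl.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateDataError(
            f"zero control variance at connection(s) {bad[:5].tolist()}"
        )
    z = (dataset.connectomes - mu) / sd
    return replace(dataset, connectomes=z, zscored=True)


def design_matrix(
    phenotypes: pd.DataFrame,
    covariates: tuple[str, ...] | list[str] = DEFAULT_COVARIATES,
    include_status: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Build the regression design: intercept, status, then covariates.

    ``sex`` is coded 0/1 (sorted levels), ``site`` one-hot with the first
    level dropped, numeric covariates enter linearly. Raises on rank
    deficiency, naming the collinear columns.
    """
    n = len(phenotypes)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    if include_status:
        cols.append((phenotypes["role"].to_numpy() == "case").astype(float))
        names.append("status")
    for cov in covariates:
        if cov not in phenotypes.columns:
            raise DesignMatrixError(f"covariate '{cov}' missing from phenotypes")
        series = phenotypes[cov]
        if cov == "sex":
            levels = sorted(series.unique())
            if len(levels) > 2:
                raise DesignMatrixError("sex must be binary")
            cols.append((series == levels[-1]).to_numpy(dtype=float))
            names.append("sex")
        elif cov == "site":
            levels = sorted(series.unique())
            for level in levels[1:]:
                cols.append((series == level).to_numpy(dtype=float))
                names.append(f"site[{level}]")
        else:
            values = series.to_numpy(dtype=float)
            if np.any(~np.isfinite(values)):
                raise DesignMatrixError(f"covariate '{cov}' has missing values")
            cols.append(values)
            names.append(cov)
    X = np.column_stack(cols)
    if X.shape[0] <= X.shape[1]:
        raise SampleSizeError(
            f"n={X.shape[0]} subjects <= p={X.shape[1]} design columns"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = [
            names[k]
            for k in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, k, axis=1)) == rank
        ]
        raise DesignMatrixError(f"rank-deficient design; collinear columns: {collinear}")
    return X, names


def _ols_status(X: np.ndarray, Y: np.ndarray, status_col: int):
    """Vectorized OLS of every column of Y on X.

    Returns (beta_status, t, p, residuals, coefs) with a two-tailed t-test
    on the status coefficient; df = n - p.
    """
    n, p = X.shape
    if n <= p:
        raise SampleSizeError(f"n={n} subjects <= p={p} design columns")
    xtx_inv = np.linalg.inv(X.T @ X)
    coefs = xtx_inv @ (X.T @ Y)
    resid = Y - X @ coefs
    df = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(xtx_inv[status_col, status_col] * sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coefs[status_col] / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return coefs[status_col], t, pvals, resid, coefs


def run_cwas(
    dataset: CohortDataset,
    covariates: tuple[str, ...] | list[str] = DEFAULT_COVARIATES,
    q_threshold: float = 0.05,
) -> SignatureMap:
    """Mass-univariate case/control contrast over all connections.

    Per connection: OLS of the (z-scored) connectivity value on clinical
    status + covariates; two-tailed t-test on the status beta;
    Benjamini-Hochberg FDR over exactly L tests; Cohen's d from the
    covariate-adjusted values (residuals + status effect, pooled SD).
    """
    X, names = design_matrix(dataset.phenotypes, covariates)
    status_col = names.index("status")
    beta, t, p, resid, _ = _ols_status(X, dataset.connectomes, status_col)

    _, q, _, _ = multipletests(p, alpha=q_threshold, method="fdr_bh")
    sig_mask = q < q_threshold

    # Cohen's d on adjusted values: residuals plus the group effect, so the
    # mean difference is exactly beta, scaled by the pooled residual SD.
    is_case = dataset.is_case.astype(bool)
    adjusted = resid + np.outer(X[:, status_col], beta)
    case_vals, ctrl_vals = adjusted[is_case], adjusted[~is_case]
    n1, n2 = case_vals.shape[0], ctrl_vals.shape[0]
    pooled = np.sqrt(
        ((n1 - 1) * case_vals.var(axis=0, ddof=1) + (n2 - 1) * ctrl_vals.var(axis=0, ddof=1))
        / (n1 + n2 - 2)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(pooled > 0, (case_vals.mean(axis=0) - ctrl_vals.mean(axis=0)) / pooled, 0.0)

    return SignatureMap(
        beta=beta,
        t=t,
        p=p,
        q=q,
        sig_mask=sig_mask,
        cohens_d=d,
        global_shift=float(beta.mean()),
        q_threshold=q_threshold,
        contrast_name=dataset.contrast_name,
    )


def permutation_pvalue(null: np.ndarray, observed: float, alternative: str = "two-sided",
                       plain_frequency: bool = False) -> float:
    """(1 + #extreme) / (1 + n) permutation p, or the plain frequency.

    ``alternative='greater'`` counts null values >= observed; the default
    two-sided variant compares absolute values.
    """
    null = np.asarray(null, dtype=float)
    if alternative == "greater":
        k = int((null >= observed).sum())
    elif alternative == "two-sided":
        k = int((np.abs(null) >= abs(observed)).sum())
    else:
        raise ConfigurationError(f"unknown alternative '{alternative}'")
    if plain_frequency:
        return k / null.size
    return (1 + k) / (1 + null.size)


def _permuted_betas(
    dataset: CohortDataset,
    covariates,
    n_perm: int,
    seed: int,
) -> np.ndarray:
    """Beta maps from ``n_perm`` case/control label shuffles (n_perm x L)."""
    X, names = design_matrix(dataset.phenotypes, covariates)
    status_col = names.index("status")
    status = X[:, status_col].copy()
    rng = np.random.default_rng(seed)
    Y = dataset.connectomes
    out = np.empty((n_perm, Y.shape[1]))
    Xp = X.copy()
    for k in range(n_perm):
        Xp[:, status_col] = rng.permutation(status)
        xtx_inv = np.linalg.inv(Xp.T @ Xp)
        out[k] = (xtx_inv[status_col] @ (Xp.T @ Y))
    return out


def global_shift_test(
    dataset: CohortDataset,
    covariates: tuple[str, ...] | list[str] = DEFAULT_COVARIATES,
    n_perm: int = 5000,
    seed: int = 0,
    alternative: str = "two-sided",
    plain_frequency: bool = False,
) -> tuple[float, float]:
    """Permutation test of the global FC shift (mean beta over connections).

    The null is built from ``n_perm`` random CWAS obtained by shuffling the
    case/control labels; reproducible from ``seed``.
    """
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100")
    observed = float(run_cwas(dataset, covariates).beta.mean())
    null_shifts = _permuted_betas(dataset, covariates, n_perm, seed).mean(axis=1)
    p = permutation_pvalue(null_shifts, observed, alternative, plain_frequency)
    return observed, p


def generate_null_signatures(
    dataset: CohortDataset,
    covariates: tuple[str, ...] | list[str] = DEFAULT_COVARIATES,
    n: int = 5000,
    seed: int = 0,
) -> np.ndarray:
    """Null FC-signatures: beta maps under case/control label shuffling.

    Returns an ``n x L`` array, reproducible from ``seed``. These nulls feed
    the mirror test, PLSR permutation p-values and per-gene empirical tests.
    """
    if n == 0:
        warnings.warn("generate_null_signatures called with n=0", stacklevel=2)
        return np.empty((0, dataset.n_connections))
    return _permuted_betas(dataset, covariates, n, seed)


def connection_network_groups(atlas: RegionAtlas) -> pd.Series:
    """Grouping label of every connection: the network pair of its regions.

    Connections whose two regions share a network get that network's name;
    cross-network connections get ``"<netA>|<netB>"`` (sorted ids).
    """
    nets = atlas.network_ids
    r = atlas.n_regions
    names = {k: atlas.network_name(k) for k in np.unique(nets)}
    labels = []
    for j in range(r):
        for i in range(j + 1):
            a, b = sorted((int(nets[i]), int(nets[j])))
            labels.append(names[a] if a == b else f"{names[a]}|{names[b]}")
    return pd.Series(labels, name="network_group")


def network_mirror_test(
    beta_del: np.ndarray,
    beta_dup: np.ndarray,
    atlas: RegionAtlas,
    null_del: np.ndarray | None = None,
    null_dup: np.ndarray | None = None,
) -> pd.DataFrame:
    """Gene-dosage mirror statistic per network grouping.

    For every connection the product ``beta_del * beta_dup`` is formed;
    negative products indicate opposite-direction (mirror) effects of
    deletion and duplication. Products are averaged within each network
    grouping. When paired null signatures are supplied, a two-sided
    empirical p-value is computed from the same statistic on the nulls.
    """
    beta_del = np.asarray(beta_del, dtype=float)
    beta_dup = np.asarray(beta_dup, dtype=float)
    if beta_del.shape != beta_dup.shape:
        raise ValueError("beta vectors must have equal length")
    if beta_del.size != n_pairs(atlas.n_regions):
        raise ValueError("beta length does not match atlas")
    groups = connection_network_groups(atlas)
    prod = beta_del * beta_dup
    rows = []
    have_null = null_del is not None and null_dup is not None
    if have_null:
        null_del = np.asarray(null_del, dtype=float)
        null_dup = np.asarray(null_dup, dtype=float)
        if null_del.shape != null_dup.shape:
            raise ValueError("null signature lists must be paired (same shape)")
        null_prod = null_del * null_dup
    for label in groups.unique():
        members = np.flatnonzero(groups.to_numpy() == label)
        stat = float(prod[members].mean())
        row = {
            "network_group": label,
            "within_network": "|" not in label,
            "n_connections": members.size,
            "statistic": stat,
        }
        if have_null:
            null_stats = null_prod[:, members].mean(axis=1)
            row["p"] = permutation_pvalue(null_stats, stat, "two-sided")
        rows.append(row)
    return pd.DataFrame(rows)
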