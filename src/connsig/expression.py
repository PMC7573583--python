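"""Imaging transcriptomics: donor expression aligned to the parcellation,
PLSR of gene-set expression against FC-signatures, genome-wide spatial
correlations, and gene-set specificity tests.

Donor microarray samples (gene-level values, one brain region per sample)
are normalized with a scaled robust sigmoid — first within each sample
across genes, then per donor for each gene across samples — averaged within
region per donor and then across donors, giving one expression value per
gene and region. A deletion's regional FC alteration (mean beta per region)
is then regressed on the expression of the genes in the deleted locus by
partial least squares, with significance from label-shuffled null
FC-signatures, and per-gene spatial correlations are ranked genome-wide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests

from .atlas import RegionAtlas
from .connectome import matrixize
from .cwas import SignatureMap
from .exceptions import (
    ConfigurationError,
    DegenerateDataError,
    IntegrityError,
    SampleSizeError,
    SchemaError,
)

SAMPLE_META_COLUMNS = ["donor_id", "sample_id", "region_id"]


@dataclass
class ExpressionPanel:
    """Region x gene matrix of normalized expression in [0, 1].

    Rows follow atlas region ids; regions without any donor sample carry
    NaN and are excluded from ``regions_covered``.
    """

    X: np.ndarray
    genes: list[str]
    regions_covered: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        covered = [r for r in range(self.X.shape[0]) if np.all(np.isfinite(self.X[r]))]
        if not self.regions_covered:
            self.regions_covered = set(covered)

    @property
    def n_regions(self) -> int:
        return self.X.shape[0]

    def subset(self, gene_set: list[str]) -> "ExpressionPanel":
        missing = [g for g in gene_set if g not in self.genes]
        if missing:
            raise ConfigurationError(f"genes not in panel: {missing[:5]}")
        idx = [self.genes.index(g) for g in gene_set]
        return ExpressionPanel(
            X=self.X[:, idx], genes=list(gene_set), regions_covered=set(self.regions_covered)
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.genes)
        df.insert(0, "region_id", np.arange(self.n_regions))
        return df


@dataclass
class PLSRResult:
    n_components: int
    r2_response: float
    p_perm: float
    component_gene_weights: np.ndarray


@dataclass
class GeneCorrelation:
    gene: str
    r: float
    p_emp: float
    q_genomewide: float
    percentile: float


def scaled_robust_sigmoid(x: np.ndarray, name: str = "vector") -> np.ndarray:
    """Scaled robust sigmoid normalization of one vector.

    ``s(x) = 1 / (1 + exp(-(x - median(x)) / (IQR(x)/1.35)))`` followed by a
    min-max rescale to [0, 1]. The 1.35 constant converts the interquartile
    range to a normal-equivalent SD. Location/scale changes of the input
    leave the output unchanged.
    """
    x = np.asarray(x, dtype=float)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        raise DegenerateDataError(f"zero IQR in {name}; cannot normalize")
    s = 1.0 / (1.0 + np.exp(-(x - np.median(x)) / (iqr / 1.35)))
    lo, hi = s.min(), s.max()
    return (s - lo) / (hi - lo)


def _validate_samples(samples: pd.DataFrame, atlas: RegionAtlas) -> list[str]:
    missing = [c for c in SAMPLE_META_COLUMNS if c not in samples.columns]
    if missing:
        raise SchemaError(f"sample table missing columns: {missing}")
    if samples["sample_id"].duplicated().any():
        raise IntegrityError("duplicate sample_id in expression samples")
    bad = set(samples["region_id"]) - set(range(atlas.n_regions))
    if bad:
        raise SchemaError(f"unknown region_id values: {sorted(bad)[:5]}")
    return [c for c in samples.columns if c not in SAMPLE_META_COLUMNS]


def normalize_expression(samples: pd.DataFrame, atlas: RegionAtlas) -> ExpressionPanel:
    """Align donor expression samples to the parcellation.

    Four stages: (1) scaled-robust-sigmoid normalize each sample's gene
    vector across genes; (2) per donor, normalize each gene across that
    donor's samples; (3) mean over samples within each region per donor;
    (4) mean across donors. Regions with no sample in any donor are NaN.

    ``samples``: one row per sample with columns donor_id, sample_id,
    region_id and one column per gene (raw expression, arbitrary units).
    """
    genes = _validate_samples(samples, atlas)
    r = atlas.n_regions
    donor_panels = []
    for donor, block in samples.groupby("donor_id", sort=True):
        expr = block[genes].to_numpy(dtype=float)
        # stage 1: within each sample, across genes
        stage1 = np.stack(
            [
                scaled_robust_sigmoid(row, name=f"sample {sid}")
                for row, sid in zip(expr, block["sample_id"])
            ]
        )
        # stage 2: per gene, across this donor's samples
        stage2 = np.empty_like(stage1)
        for g, gene in enumerate(genes):
            stage2[:, g] = scaled_robust_sigmoid(
                stage1[:, g], name=f"gene {gene} (donor {donor})"
            )
        # stage 3: mean within region
        panel = np.full((r, len(genes)), np.nan)
        regions = block["region_id"].to_numpy(dtype=int)
        for region in np.unique(regions):
            panel[region] = stage2[regions == region].mean(axis=0)
        donor_panels.append(panel)
    # stage 4: mean across donors (ignoring donors lacking the region)
    stacked = np.stack(donor_panels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        X = np.nanmean(stacked, axis=0)
    return ExpressionPanel(X=X, genes=genes)


def _leading_axis(X: np.ndarray) -> np.ndarray:
    """First principal axis (gene loadings) of a region x gene matrix."""
    Xc = X - X.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    return vt[0]


def loo_consistency(samples: pd.DataFrame, atlas: RegionAtlas) -> float:
    """Leave-one-donor-out sensitivity of the expression panel.

    Rebuilds the panel once per left-out donor, extracts each panel's first
    principal axis over genes, sign-aligns them, and returns the mean
    pairwise Pearson correlation — near 1 when donors share their spatial
    structure.
    """
    donors = sorted(samples["donor_id"].unique())
    if len(donors) < 3:
        raise SampleSizeError("leave-one-donor-out requires >= 3 donors")
    axes = []
    for donor in donors:
        panel = normalize_expression(samples[samples["donor_id"] != donor], atlas)
        covered = sorted(panel.regions_covered)
        axes.append(_leading_axis(panel.X[covered]))
    ref = axes[0]
    axes = [a if np.dot(a, ref) >= 0 else -a for a in axes]
    cors = []
    for a in range(len(axes)):
        for b in range(a + 1, len(axes)):
            cors.append(stats.pearsonr(axes[a], axes[b])[0])
    return float(np.mean(cors))


def regional_response(signature: SignatureMap | np.ndarray) -> np.ndarray:
    """Mean beta of each region over its R connections (global connectivity).

    Row means of the symmetric beta matrix, including the within-region
    diagonal entry.
    """
    beta = signature.beta if isinstance(signature, SignatureMap) else np.asarray(signature)
    return matrixize(beta).mean(axis=1)


def _restrict(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop regions with missing expression or response (pairwise deletion)."""
    ok = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
    return X[ok], y[ok]


def _plsr_r2(X: np.ndarray, y: np.ndarray, k: int) -> tuple[float, np.ndarray]:
    model = PLSRegression(n_components=k, scale=True, tol=1e-6, max_iter=1000)
    with warnings.catch_warnings():
        # an exact fit deflates the response to zero before the last
        # component; sklearn warns about the constant residual
        warnings.filterwarnings("ignore", message=".*residual is constant.*")
        model.fit(X, y)
    pred = model.predict(X).ravel()
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return min(max(r2, 0.0), 1.0), model.x_weights_


def plsr_association(
    panel: ExpressionPanel,
    y: np.ndarray,
    k: int,
    null_y: np.ndarray,
    gene_set: list[str] | None = None,
) -> PLSRResult:
    """PLSR of a regional FC response on gene-set expression.

    Components are latent combinations of (standardized) gene expression
    maximally covarying with the (centered) response. ``r2_response`` is the
    response variance explained by ``k`` components on the fitted regions;
    ``p_perm = (1 + #{null r2 >= observed}) / (1 + n_null)`` where each null
    response derives from a label-shuffled FC-signature.
    """
    sub = panel.subset(gene_set) if gene_set is not None else panel
    X, yv = _restrict(sub.X, np.asarray(y, dtype=float))
    if k > min(X.shape[0] - 1, X.shape[1]):
        raise ValueError(
            f"k={k} exceeds min(regions-1, genes) = {min(X.shape[0] - 1, X.shape[1])}"
        )
    null_y = np.atleast_2d(np.asarray(null_y, dtype=float))
    if null_y.shape[0] < 3:
        raise ConfigurationError("need >= 3 null responses for the permutation test")
    r2, weights = _plsr_r2(X, yv, k)
    null_r2 = np.empty(null_y.shape[0])
    for i, yn in enumerate(null_y):
        Xn, ynv = _restrict(sub.X, yn)
        null_r2[i], _ = _plsr_r2(Xn, ynv, k)
    p_perm = (1 + int((null_r2 >= r2).sum())) / (1 + null_y.shape[0])
    return PLSRResult(
        n_components=k, r2_response=r2, p_perm=p_perm, component_gene_weights=weights
    )


def plsr_per_region(
    panel: ExpressionPanel,
    signature: SignatureMap | np.ndarray,
    k: int,
    null_signatures: np.ndarray,
    gene_set: list[str] | None = None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """One PLSR per region: the region's R-value FC profile as response.

    BH-FDR is applied across the R regional tests.
    """
    beta = signature.beta if isinstance(signature, SignatureMap) else np.asarray(signature)
    mat = matrixize(beta)
    r = mat.shape[0]
    null_mats = np.stack([matrixize(b) for b in np.atleast_2d(null_signatures)])
    rows = []
    for region in range(r):
        res = plsr_association(
            panel, mat[region], k, null_mats[:, region, :], gene_set=gene_set
        )
        rows.append(
            {"region_id": region, "r2_response": res.r2_response, "p_perm": res.p_perm}
        )
    out = pd.DataFrame(rows)
    _, q, _, _ = multipletests(out["p_perm"].to_numpy(), alpha=q_threshold, method="fdr_bh")
    out["q"] = q
    return out


def _pearson_to_y(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of every column of X with y (columns may be many)."""
    Xc = X - X.mean(axis=0, keepdims=True)
    yc = y - y.mean()
    xn = np.linalg.norm(Xc, axis=0)
    yn = np.linalg.norm(yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (Xc.T @ yc) / (xn * yn)


def genome_wide_correlation(
    panel: ExpressionPanel,
    y: np.ndarray,
    null_y: np.ndarray,
    q_threshold: float = 0.05,
) -> list[GeneCorrelation]:
    """Spatial Pearson correlation of every gene with the FC response.

    Per gene: r against the observed response; an empirical two-sided p
    against the label-shuffled null responses; BH-FDR across all genes; and
    the percentile rank of r within the genome-wide r distribution.
    Zero-variance genes are skipped with a warning.
    """
    y = np.asarray(y, dtype=float)
    ok_regions = np.all(np.isfinite(panel.X), axis=1) & np.isfinite(y)
    if ok_regions.sum() < 3:
        raise SampleSizeError("need >= 3 covered regions")
    X = panel.X[ok_regions]
    yv = y[ok_regions]
    variances = X.std(axis=0)
    keep = variances > 0
    skipped = [g for g, k in zip(panel.genes, keep) if not k]
    if skipped:
        warnings.warn(f"zero-variance genes skipped: {skipped[:5]}", stacklevel=2)
    X = X[:, keep]
    genes = [g for g, k in zip(panel.genes, keep) if k]

    r = _pearson_to_y(X, yv)
    null_y = np.atleast_2d(np.asarray(null_y, dtype=float))[:, ok_regions]
    # G x n_null matrix of null correlations, one column per null response
    null_r = np.stack([_pearson_to_y(X, yn) for yn in null_y], axis=1)
    p_emp = (1 + (np.abs(null_r) >= np.abs(r)[:, None]).sum(axis=1)) / (1 + null_y.shape[0])
    _, q, _, _ = multipletests(p_emp, alpha=q_threshold, method="fdr_bh")
    pct = 100.0 * (stats.rankdata(r) - 1) / (len(r) - 1)
    return [
        GeneCorrelation(gene=g, r=float(ri), p_emp=float(pi), q_genomewide=float(qi),
                        percentile=float(ci))
        for g, ri, pi, qi, ci in zip(genes, r, p_emp, q, pct)
    ]


def gene_set_tests(
    gene_set: list[str],
    all_correlations: list[GeneCorrelation],
    n_random: int = 10000,
    seed: int = 0,
    percentile_cut: float = 98.0,
) -> tuple[float, float]:
    """Specificity of a gene set's spatial correlations vs random sets.

    ``p_median``: fraction of random same-size gene sets whose median r is
    at least the observed median (+1 smoothing). ``p_top_percentile``: the
    same for the count of set genes whose r exceeds the genome-wide
    ``percentile_cut`` percentile (over-representation of top-ranking
    genes).
    """
    if n_random < 100:
        raise ConfigurationError("n_random must be >= 100")
    gene_to_r = {c.gene: c.r for c in all_correlations}
    missing = [g for g in gene_set if g not in gene_to_r]
    if missing:
        raise ConfigurationError(f"gene set members without correlations: {missing[:5]}")
    all_r = np.array([c.r for c in all_correlations])
    if len(gene_set) > all_r.size:
        raise ConfigurationError("gene set larger than the gene panel")
    set_r = np.array([gene_to_r[g] for g in gene_set])
    obs_median = float(np.median(set_r))
    threshold = float(np.percentile(all_r, percentile_cut))
    obs_count = int((set_r > threshold).sum())

    rng = np.random.default_rng(seed)
    size = len(gene_set)
    medians = np.empty(n_random)
    counts = np.empty(n_random, dtype=int)
    for i in range(n_random):
        draw = all_r[rng.choice(all_r.size, size=size, replace=False)]
        medians[i] = np.median(draw)
        counts[i] = (draw > threshold).sum()
    p_median = (1 + int((medians >= obs_median).sum())) / (1 + n_random)
    p_top = (1 + int((counts >= obs_count).sum())) / (1 + n_random)
    return p_median, p_top
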