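"""Expression preprocessing: normalization, ComBat batch correction,
ordination, clustering homogeneity, and differential expression.

The container is :class:`ExpressionMatrix`: a log2 gene x sample matrix with
per-sample batch and condition ('naive' / 'primed') metadata.

Batch correction is the parametric empirical-Bayes location/scale model of
Johnson, Li & Rabinovic (2007): per-gene standardization against a design
that includes the biological condition (so condition effects are protected),
method-of-moments hyperpriors for per-batch location (normal) and scale
(inverse gamma), iterative refinement of the posterior adjustments to a fixed
tolerance, and back-transformation.

Differential expression is a two-group moderated-free test: per-gene
logFC = mean(naive) - mean(primed) with a Welch two-sample t-test and
Benjamini-Hochberg adjustment; significance tiers for the marker panel
follow the *, **, *** convention at adjusted p < 1e-2, 1e-4, 1e-6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, silhouette_score
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "ConfoundedBatchError",
    "normalize",
    "combat_correct",
    "pca",
    "kmeans_heterogeneity",
    "differential_expression",
    "marker_panel",
]

CONDITIONS = ("naive", "primed")


class ConfoundedBatchError(ValueError):
    """Batch effect not estimable: batch collinear with condition."""


@dataclass
class ExpressionMatrix:
    """Log2 gene x sample values plus per-sample batch/condition metadata."""

    values: pd.DataFrame                 # genes x samples
    metadata: pd.DataFrame               # samples x {batch, condition}

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if not self.values.index.is_unique:
            raise ValueError("gene ids are not unique")
        if list(self.metadata.index) != list(self.values.columns):
            raise ValueError("metadata index must equal the sample columns")
        for col in ("batch", "condition"):
            if col not in self.metadata.columns:
                raise ValueError(f"metadata lacks the {col!r} column")
            if self.metadata[col].isna().any():
                raise ValueError(f"metadata column {col!r} has missing entries")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def batch(self) -> pd.Series:
        return self.metadata["batch"]

    @property
    def condition(self) -> pd.Series:
        return self.metadata["condition"]

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """Same metadata, new values (order must be preserved)."""
        return ExpressionMatrix(values=values, metadata=self.metadata.copy())

    def subset_samples(self, samples) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(values=self.values[samples],
                                metadata=self.metadata.loc[samples])

    # -- TSV I/O -----------------------------------------------------------
    def to_tsv(self, matrix_path, metadata_path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="gene")
        self.metadata.to_csv(metadata_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, matrix_path, metadata_path) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
        return cls(values=values, metadata=meta)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Median-center each sample onto the global median of sample medians.

    A rank-preserving per-sample shift; all-zero samples are left unshifted
    with a warning.  Idempotent.
    """
    medians = x.values.median(axis=0)
    target = float(np.median(medians.to_numpy()))
    shifted = x.values.copy()
    for s in x.samples:
        if (x.values[s] == 0).all():
            warnings.warn(f"sample {s!r} is constant zero; left unshifted")
            continue
        shifted[s] = x.values[s] + (target - medians[s])
    return x.with_values(shifted)


# ---------------------------------------------------------------------------
# ComBat (parametric empirical Bayes)
# ---------------------------------------------------------------------------

def _design_matrices(x: ExpressionMatrix):
    batches = pd.Categorical(x.batch)
    batch_design = pd.get_dummies(pd.Series(batches, index=x.samples)).to_numpy(float)
    cond = pd.Categorical(x.condition)
    # condition dummies, first level dropped (intercept absorbed by batches)
    cond_design = pd.get_dummies(pd.Series(cond, index=x.samples),
                                 drop_first=True).to_numpy(float)
    return batches, batch_design, cond_design


def _check_confounding(x: ExpressionMatrix, batch_design, cond_design) -> None:
    design = np.hstack([batch_design, cond_design])
    expected_rank = batch_design.shape[1] + cond_design.shape[1]
    if np.linalg.matrix_rank(design) < expected_rank:
        single = sorted(
            b for b, sub in x.metadata.groupby("batch", observed=True)
            if sub["condition"].nunique() == 1
        )
        raise ConfoundedBatchError(
            "condition is confounded with batch; single-condition batches: "
            f"{single}")


def _postmean(gamma_hat, gamma_bar, n, delta_star, tau2):
    return (n * tau2 * gamma_hat + delta_star * gamma_bar) / (n * tau2 + delta_star)


def _it_sol(Z_b, gamma_hat, delta_hat, gamma_bar, tau2, lam, theta, tol=1e-4):
    """Iterate the EB posterior equations for one batch until convergence."""
    n = Z_b.shape[1]
    gamma_old = gamma_hat.copy()
    delta_old = delta_hat.copy()
    change = 1.0
    while change > tol:
        gamma_new = _postmean(gamma_hat, gamma_bar, n, delta_old, tau2)
        ssq = ((Z_b - gamma_new[:, None]) ** 2).sum(axis=1)
        delta_new = (theta + 0.5 * ssq) / (n / 2.0 + lam - 1.0)
        change = max(
            np.abs(gamma_new - gamma_old).max() / max(np.abs(gamma_old).max(), 1e-12),
            np.abs(delta_new - delta_old).max() / max(np.abs(delta_old).max(), 1e-12),
        )
        gamma_old, delta_old = gamma_new, delta_new
    return gamma_old, delta_old


def combat_correct(x: ExpressionMatrix, tol: float = 1e-4) -> ExpressionMatrix:
    """Parametric empirical-Bayes batch adjustment with condition protected.

    Requires >= 2 batches and >= 2 samples per batch.  The biological
    condition enters the standardization design, so condition effects are
    estimated and added back untouched; only per-batch location/scale
    deviations are shrunk (EB, method-of-moments priors) and removed.
    Gene/sample ordering and metadata are preserved.
    """
    batches, batch_design, cond_design = _design_matrices(x)
    levels = list(batches.categories)
    if len(levels) < 2:
        raise ValueError("combat_correct needs at least 2 batches")
    counts = x.metadata["batch"].value_counts()
    small = sorted(counts[counts < 2].index)
    if small:
        raise ValueError(f"batches with fewer than 2 samples: {small}")
    _check_confounding(x, batch_design, cond_design)

    Y = x.values.to_numpy(float)           # G x N
    G, N = Y.shape
    X = np.hstack([batch_design, cond_design])
    # gene-wise OLS over the full design
    B_hat = np.linalg.solve(X.T @ X, X.T @ Y.T)            # p x G
    n_batch = batch_design.sum(axis=0)                      # samples per batch
    grand_mean = (n_batch / N) @ B_hat[:len(levels), :]     # alpha_g
    resid = Y.T - X @ B_hat
    var_pooled = (resid ** 2).mean(axis=0)                  # sigma_g^2 (1/N)
    var_pooled = np.maximum(var_pooled, 1e-16)

    # standardized data: remove grand mean + condition effects, scale by sigma
    stand_mean = grand_mean[None, :] + cond_design @ B_hat[len(levels):, :]
    Z = (Y.T - stand_mean) / np.sqrt(var_pooled)[None, :]   # N x G
    Z = Z.T                                                 # G x N

    bayes = Z.copy()
    for j, level in enumerate(levels):
        idx = np.flatnonzero(batch_design[:, j] == 1)
        Z_b = Z[:, idx]
        n_b = len(idx)
        gamma_hat = Z_b.mean(axis=1)
        delta_hat = Z_b.var(axis=1, ddof=1)
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1) if G > 1 else 0.0
        V = delta_hat.mean()
        S2 = delta_hat.var(ddof=1) if G > 1 else 0.0
        if S2 > 1e-12 and tau2 > 1e-12:
            lam = (V ** 2 + 2 * S2) / S2
            theta = (V ** 3 + V * S2) / S2
            gamma_star, delta_star = _it_sol(
                Z_b, gamma_hat, delta_hat, gamma_bar, tau2, lam, theta, tol=tol)
        else:
            # degenerate priors (few genes / no scale spread): no shrinkage
            gamma_star, delta_star = gamma_hat, delta_hat
        delta_star = np.maximum(delta_star, 1e-16)
        bayes[:, idx] = (Z_b - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    adjusted = bayes * np.sqrt(var_pooled)[:, None] + stand_mean.T
    out = pd.DataFrame(adjusted, index=x.genes, columns=x.samples)
    return x.with_values(out)


# ---------------------------------------------------------------------------
# ordination and clustering
# ---------------------------------------------------------------------------

def pca(x: ExpressionMatrix, n_components: int = 2):
    """PCA of samples over gene-centered values.

    Returns ``(scores, explained)``: a samples x components DataFrame of
    projections onto the top right-singular directions, and the
    explained-variance fractions (non-increasing, summing to <= 1).
    """
    if n_components <= 0:
        raise ValueError("n_components must be positive")
    n_components = int(n_components)
    if n_components > min(len(x.genes), len(x.samples)):
        raise ValueError("n_components exceeds min(genes, samples)")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x.values.to_numpy(float).T)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (pd.DataFrame(scores, index=x.samples, columns=cols),
            model.explained_variance_ratio_.copy())


def kmeans_heterogeneity(scores: pd.DataFrame, k: int, labels, seed: int = 0,
                         n_restarts: int = 50):
    """Seeded k-means on ordination scores plus homogeneity diagnostics.

    Returns ``(assignment, mean_silhouette, ari)`` where ``ari`` is the
    adjusted Rand index between the clusters and the supplied protocol
    labels.  A mean silhouette below ~0.25 is read as "no major
    heterogeneity" among the samples.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(scores):
        raise ValueError("k exceeds the number of samples")
    X = np.asarray(scores, float)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    assignment = km.fit_predict(X)
    if len(np.unique(assignment)) > 1:
        sil = float(silhouette_score(X, assignment))
    else:
        sil = 0.0
    ari = float(adjusted_rand_score(np.asarray(list(labels)), assignment))
    return pd.Series(assignment, index=scores.index, name="cluster"), sil, ari


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


def differential_expression(x: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene naive-vs-primed test.

    logFC = mean(naive) - mean(primed) (log2); Welch two-sample t-test;
    BH adjustment across all genes.  Genes with zero variance in both groups
    get p = 1 by convention and are flagged in the ``degenerate`` column.
    """
    cond = x.condition
    naive_cols = x.samples[(cond == "naive").to_numpy()]
    primed_cols = x.samples[(cond == "primed").to_numpy()]
    if len(naive_cols) < 2 or len(primed_cols) < 2:
        raise ValueError("need >= 2 samples per condition")
    A = x.values[naive_cols].to_numpy(float)
    B = x.values[primed_cols].to_numpy(float)
    logfc = A.mean(axis=1) - B.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(A, B, axis=1, equal_var=False)
    pvals = np.asarray(res.pvalue, float)
    degenerate = (A.var(axis=1, ddof=1) == 0) & (B.var(axis=1, ddof=1) == 0)
    pvals[degenerate] = 1.0
    pvals = np.nan_to_num(pvals, nan=1.0)
    adj = benjamini_hochberg(pvals)
    return pd.DataFrame(
        {"logFC": logfc, "p_value": pvals, "adj_p": adj, "degenerate": degenerate},
        index=x.genes,
    )


_TIER_CUTS = ((1e-6, "***"), (1e-4, "**"), (1e-2, "*"))


def marker_panel(de: pd.DataFrame, markers: dict[str, str]):
    """Score known naive/primed marker genes against the DE table.

    ``markers`` maps gene id -> expected direction ('naive' = expected up in
    naive, i.e. positive logFC).  Returns ``(table, missing)``: a per-marker
    DataFrame with logFC, adj_p, significance tier ('' / '*' / '**' / '***')
    and a direction-consistency flag, plus the list of markers absent from
    the DE universe.
    """
    rows, missing = [], []
    for gene, direction in markers.items():
        if direction not in CONDITIONS:
            raise ValueError(f"expected direction for {gene!r} must be naive/primed")
        if gene not in de.index:
            missing.append(gene)
            continue
        logfc = float(de.loc[gene, "logFC"])
        adj = float(de.loc[gene, "adj_p"])
        tier = ""
        for cut, label in _TIER_CUTS:
            if adj < cut:
                tier = label
                break
        expected_sign = 1.0 if direction == "naive" else -1.0
        rows.append({
            "gene": gene,
            "expected_direction": direction,
            "logFC": logfc,
            "adj_p": adj,
            "tier": tier,
            "direction_consistent": bool(np.sign(logfc) == expected_sign),
        })
    table = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["expected_direction", "logFC", "adj_p", "tier",
                 "direction_consistent"])
    return table, missing
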