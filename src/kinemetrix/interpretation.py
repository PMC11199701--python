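"""Stability of LASSO selections, group statistics, closed-form linear SHAP,
and classical MDS with a separability score."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import silhouette_score

from .features import feature_columns

__all__ = [
    "StabilityConfig",
    "stability_from_counts",
    "group_difference_stats",
    "linear_shap",
    "shap_report",
    "classical_mds",
    "separability_score",
    "compare_continuous",
    "compare_categorical",
]


@dataclass
class StabilityConfig:
    threshold: float = 0.5  # inclusive selection-frequency fraction

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")


def stability_from_counts(
    counts: dict[str, int], total: int, cfg: StabilityConfig | None = None
) -> tuple[list[str], dict[str, float]]:
    """Stable features: selected in at least ``threshold`` of all CV
    iterations (inclusive). Returns (stable names, frequency map)."""
    cfg = cfg or StabilityConfig()
    if total <= 0:
        raise ValueError("total iterations must be > 0")
    bad = {f: c for f, c in counts.items() if c > total}
    if bad:
        raise ValueError(f"selection counts exceed total iterations: {bad}")
    freqs = {f: c / total for f, c in counts.items()}
    stable = sorted(f for f, q in freqs.items() if q >= cfg.threshold)
    return stable, freqs


def group_difference_stats(table: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    """Per-feature low-vs-high comparison on z-scored columns.

    Welch two-sample t-test plus Cohen's d (pooled SD); group means reported
    in z units.
    """
    labels = table["label"]
    if set(labels) != {"low", "high"}:
        raise ValueError("both labels must be present")
    rows = []
    for f in features:
        x = table[f].to_numpy(dtype=float)
        z = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
        lo = z[labels.to_numpy() == "low"]
        hi = z[labels.to_numpy() == "high"]
        t, p = stats.ttest_ind(lo, hi, equal_var=False)
        n1, n2 = len(lo), len(hi)
        pooled = np.sqrt(
            ((n1 - 1) * lo.std(ddof=1) ** 2 + (n2 - 1) * hi.std(ddof=1) ** 2) / (n1 + n2 - 2)
        )
        d = (hi.mean() - lo.mean()) / pooled if pooled > 0 else 0.0
        rows.append({
            "feature": f,
            "mean_low": float(lo.mean()),
            "mean_high": float(hi.mean()),
            "t_stat": float(t),
            "p_value": float(p),
            "cohens_d": float(d),
        })
    return pd.DataFrame(rows)


def linear_shap(
    weights: np.ndarray, intercept: float, X: np.ndarray, background_mean: np.ndarray
) -> np.ndarray:
    """Exact SHAP values for a linear model with an independence baseline:
    ``phi[i, j] = w[j] * (X[i, j] - mu[j])``, so rows sum to f(x) - f(mu) on
    the margin scale."""
    weights = np.asarray(weights, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    mu = np.asarray(background_mean, dtype=float).ravel()
    if X.shape[1] != len(weights) or len(mu) != len(weights):
        raise ValueError("dimension mismatch between weights, X, and background mean")
    return weights[None, :] * (X - mu[None, :])


def shap_report(table: pd.DataFrame, stable_features: list[str], seed: int = 0) -> pd.DataFrame:
    """Fit a reporting LR on the stable features of the full (standardized)
    table and return per-feature mean |phi| with the coefficient sign.

    This is a reporting model over the final feature set, not an evaluation
    model.
    """
    X = table[stable_features].to_numpy(dtype=float)
    mean, std = X.mean(axis=0), X.std(axis=0)
    std[std == 0] = 1.0
    Xz = (X - mean) / std
    y = (table["label"] == "high").to_numpy(dtype=int)
    model = LogisticRegression(max_iter=2000, random_state=seed)
    model.fit(Xz, y)
    phi = linear_shap(model.coef_, float(model.intercept_[0]), Xz, Xz.mean(axis=0))
    return pd.DataFrame({
        "feature": stable_features,
        "mean_abs_shap": np.abs(phi).mean(axis=0),
        "coef": model.coef_.ravel(),
    }).sort_values("mean_abs_shap", ascending=False, ignore_index=True)


def classical_mds(X: np.ndarray, n_dims: int = 2) -> np.ndarray:
    """Torgerson classical scaling of the rows of ``X``.

    Double-centers the squared Euclidean distance matrix and projects onto
    the top ``n_dims`` eigenpairs. Negative eigenvalues (impossible for
    Euclidean input) are clipped to zero; axes are deterministic up to sign.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n <= n_dims:
        raise ValueError(f"need more than {n_dims} rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    sq = (X**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
    np.fill_diagonal(d2, 0.0)
    d2 = np.maximum(d2, 0.0)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:n_dims]
    lam = np.clip(eigval[order], 0.0, None)
    emb = eigvec[:, order] * np.sqrt(lam)[None, :]
    # fix sign convention: largest-magnitude coordinate positive per axis
    for j in range(emb.shape[1]):
        k = np.argmax(np.abs(emb[:, j]))
        if emb[k, j] < 0:
            emb[:, j] = -emb[:, j]
    return emb


def separability_score(embedding: np.ndarray, labels: np.ndarray) -> float:
    """Silhouette coefficient of the 2-class partition; degenerate inputs
    (identical points) score 0 by convention."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) != 2:
        raise ValueError("exactly two labels required")
    embedding = np.asarray(embedding, dtype=float)
    if np.allclose(embedding, embedding[0]):
        return 0.0
    return float(silhouette_score(embedding, labels))


def compare_continuous(a: np.ndarray, b: np.ndarray, method: str = "t") -> tuple[float, float]:
    """Demographic-table comparison of a continuous variable.

    ``method='t'``: Welch t-test; ``'mwu'``: Mann-Whitney U.
    """
    if method == "t":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif method == "mwu":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def compare_categorical(
    contingency: np.ndarray, seed: int = 0, n_mc: int = 20000
) -> float:
    """Fisher's exact test p-value; exact for 2x2, Monte-Carlo (fixed seed)
    for larger tables."""
    table = np.asarray(contingency, dtype=int)
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table)[1])
    rng = np.random.default_rng(seed)
    row_tot = table.sum(axis=1)
    col_tot = table.sum(axis=0)

    def log_prob(t: np.ndarray) -> float:
        from scipy.special import gammaln
        return float(
            gammaln(row_tot + 1).sum() + gammaln(col_tot + 1).sum()
            - gammaln(table.sum() + 1) - gammaln(t + 1).sum()
        )

    obs = log_prob(table)
    # sample tables with fixed margins via random permutation pairing
    rows = np.repeat(np.arange(len(row_tot)), row_tot)
    cols = np.repeat(np.arange(len(col_tot)), col_tot)
    hits = 0
    for _ in range(n_mc):
        perm_cols = rng.permutation(cols)
        t = np.zeros_like(table)
        np.add.at(t, (rows, perm_cols), 1)
        if log_prob(t) <= obs + 1e-12:
            hits += 1
    return (hits + 1) / (n_mc + 1)
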