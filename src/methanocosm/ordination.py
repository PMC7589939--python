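"""PCA of core-taxon relative abundances and a permutation separation test.

The core community of a methane-fed microcosm — Methylococcaceae,
Methylophilaceae, Burkholderiales, Bacteroidetes — is renormalized to
per-sample relative abundances, mean-centered (no unit-variance scaling:
the columns already share a scale) and eigendecomposed.  Separation
between the low- and high-oxygen regimes is tested by a label-permutation
test on the distance between group centroids in the first two components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_CORE_TAXA = (
    "Methylococcaceae",
    "Methylophilaceae",
    "Burkholderiales",
    "Bacteroidetes",
)


class OrdinationError(ValueError):
    pass


@dataclass
class OrdinationResult:
    scores: pd.DataFrame  # sample x component
    loadings: pd.DataFrame  # taxon x component
    variance_explained: np.ndarray  # fraction per component, non-increasing


def core_matrix(
    abundance_table: pd.DataFrame, core_taxa: Sequence[str] = DEFAULT_CORE_TAXA
) -> pd.DataFrame:
    """Relative abundances over the core taxa, rows renormalized to sum 1.

    A requested taxon missing from the table becomes a zero column (with a
    warning); a sample with no core signal at all is a hard error.
    """
    cols = {}
    for t in core_taxa:
        if t in abundance_table.columns:
            cols[t] = abundance_table[t].astype(float)
        else:
            warnings.warn(f"core taxon {t!r} absent from table; using zeros")
            cols[t] = pd.Series(0.0, index=abundance_table.index)
    mat = pd.DataFrame(cols)
    totals = mat.sum(axis=1)
    dead = totals[totals <= 0]
    if len(dead):
        raise OrdinationError(
            f"samples with zero core-taxon signal: {list(dead.index)}"
        )
    return mat.div(totals, axis=0)


def pca(matrix: pd.DataFrame, n_components: int | None = None) -> OrdinationResult:
    """Column-mean-centered PCA via SVD with a deterministic sign convention.

    Each loading vector is flipped so its largest-magnitude entry is
    positive; scores are flipped accordingly.  A constant (zero-variance)
    matrix is a hard error.
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise OrdinationError("need at least 2 samples")
    max_rank = min(n - 1, p)
    k = max_rank if n_components is None else n_components
    if not 1 <= k <= min(n, p):
        raise OrdinationError(f"n_components must be in [1, {min(n, p)}]")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if not np.any(s > 1e-12):
        raise OrdinationError("constant matrix: all components degenerate")
    total_var = float((s**2).sum())
    k = min(k, s.size)
    # sign convention: largest-|entry| of each loading vector is positive
    for i in range(k):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = U[:, :k] * s[:k]
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(Vt[:k].T, index=matrix.columns, columns=comp_names),
        variance_explained=(s[:k] ** 2) / total_var,
    )


def group_separation(
    scores: pd.DataFrame,
    labels: Mapping[str, str] | pd.Series,
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test for LO-vs-HO separation in the first two components.

    The statistic is the Euclidean distance between the two group centroids
    in (PC1, PC2); the p-value is ``(1 + #{permuted >= observed}) /
    (1 + n_perm)`` under random label permutation.
    """
    lab = pd.Series(labels).reindex(scores.index)
    if lab.isna().any():
        raise OrdinationError(f"missing labels for samples: {list(lab[lab.isna()].index)}")
    groups = sorted(lab.unique())
    if len(groups) != 2:
        raise OrdinationError(f"exactly two groups required, got {groups}")
    X = scores.iloc[:, : min(2, scores.shape[1])].to_numpy(dtype=float)
    mask = (lab == groups[0]).to_numpy()
    n1 = int(mask.sum())
    if n1 == 0 or n1 == len(mask):
        raise OrdinationError("one group is empty")

    def centroid_distance(m: np.ndarray) -> float:
        return float(np.linalg.norm(X[m].mean(axis=0) - X[~m].mean(axis=0)))

    observed = centroid_distance(mask)
    rng = np.random.default_rng(seed)
    count = 0
    idx = np.arange(len(mask))
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        pm = np.zeros(len(mask), dtype=bool)
        pm[perm[:n1]] = True
        if centroid_distance(pm) >= observed:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return observed, p


def plot_scores(result: OrdinationResult, labels, path) -> None:
    """Basic PC1/PC2 scatter colored by condition label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lab = pd.Series(labels).reindex(result.scores.index)
    fig, ax = plt.subplots(figsize=(5, 4))
    for g, color in zip(sorted(lab.unique()), ("tab:blue", "tab:red", "tab:green")):
        sel = lab == g
        ax.scatter(
            result.scores.loc[sel, "PC1"],
            result.scores.loc[sel, "PC2"],
            s=14,
            label=str(g),
            color=color,
        )
    ve = result.variance_explained
    ax.set_xlabel(f"PC1 ({100 * ve[0]:.1f}%)")
    if len(ve) > 1:
        ax.set_ylabel(f"PC2 ({100 * ve[1]:.1f}%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
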