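"""Canonical variates analysis of paired longitudinal feature tables.

CVA finds linear combinations of the (mean-centred) feature intensities
whose between-design-cell variance is maximal relative to the residual
within-cell variance -- the generalised eigenproblem ``B a = lambda W a``
with B the between-cells and W the within-cells scatter of the data
projected onto a rank-reduced PCA basis.  The design cells are the
condition x time-fraction combinations of the paired burn/control time
course; the eigenvectors, back-projected through the PCA loadings, give
each feature a *canonical weight* measuring its contribution to a
canonical contrast (the burn-control profile across fractions expressed by
a component).  Ranking features by |canonical weight| and keeping a top
fraction yields the discriminant shortlist.

PCA reduction to at most (samples - design cells) dimensions is applied
before solving the eigenproblem, the standard remedy for a singular within
scatter in the p >> n regime.  Centring is column mean-centring only, so
weights retain intensity-scale meaning; unit-variance scaling is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .tables import FeatureTable

__all__ = ["Design", "CVAResult", "design_from_samples", "fit_cva",
           "rank_features", "select_top_fraction"]

_EIG_TOL = 1e-10


@dataclass
class Design:
    """Cell-means coding of condition x fraction.

    ``matrix`` is a samples x cells indicator matrix; ``cells`` the
    corresponding (condition, fraction) labels.
    """

    matrix: np.ndarray
    cells: list[tuple[str, int]]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        G = np.asarray(self.matrix, dtype=float)
        if G.shape[1] != len(self.cells):
            raise ValueError("cell labels do not match design columns")
        if np.linalg.matrix_rank(G) < G.shape[1]:
            raise ValueError("rank-deficient design (empty or duplicated cells)")
        self.matrix = G


def design_from_samples(samples: pd.DataFrame) -> Design:
    """Build the condition x fraction cell-means design from sample metadata."""
    bio = samples.loc[~samples["is_qc"].astype(bool)]
    cells = sorted(
        {(str(c), int(f)) for c, f in zip(bio["condition"], bio["fraction"])},
        key=lambda cf: (cf[1], cf[0]),
    )
    index = {cf: j for j, cf in enumerate(cells)}
    G = np.zeros((len(bio), len(cells)))
    for i, (c, f) in enumerate(zip(bio["condition"], bio["fraction"])):
        G[i, index[(str(c), int(f))]] = 1.0
    return Design(matrix=G, cells=cells, sample_ids=list(bio.index))


@dataclass
class CVAResult:
    """Canonical vectors, variates, contrasts and eigenvalues."""

    canonical_vectors: pd.DataFrame    # features x k, canonical weights
    canonical_variates: pd.DataFrame   # samples x k
    canonical_contrasts: pd.DataFrame  # design cells x k
    eigenvalues: np.ndarray            # descending, > 0
    n_components_retained: int
    pca_rank: int


def fit_cva(table: FeatureTable, design: Design | None = None,
            pca_rank: int | None = None, scale: bool = False) -> CVAResult:
    """Fit CVA to the non-QC samples of ``table``.

    Parameters
    ----------
    design : Design, optional
        Defaults to the condition x fraction cell-means design derived from
        the sample metadata.
    pca_rank : int, optional
        Dimensions retained before the eigenproblem; defaults to
        ``n_samples - n_cells`` (capped at the data rank).  Must not exceed
        ``n_samples - n_cells`` or the within scatter becomes singular.
    scale : bool
        Additionally scale columns to unit variance before PCA (off by
        default so canonical weights keep intensity-scale meaning).
    """
    bio = table.biological()
    if design is None:
        design = design_from_samples(bio.samples)
    if list(bio.intensities.index) != design.sample_ids:
        raise ValueError("design rows do not align with table samples")
    G = design.matrix
    n, g = G.shape
    if n < g + 2:
        raise ValueError("need at least design cells + 2 samples")

    X = bio.intensities.to_numpy(dtype=float)
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd

    max_rank = n - g
    if pca_rank is None:
        pca_rank = max_rank
    if pca_rank > n - 1:
        raise ValueError("pca_rank exceeds samples - 1 (over-parameterised)")
    if pca_rank > max_rank:
        raise ValueError(
            f"pca_rank {pca_rank} leaves no residual degrees of freedom "
            f"(max {max_rank} for {g} design cells)"
        )

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    r = min(pca_rank, int((s > s[0] * 1e-12).sum()) if s.size else 0)
    if r == 0:
        raise ValueError("data matrix has rank 0")
    T = U[:, :r] * s[:r]          # PCA scores
    V = Vt[:r].T                  # loadings, features x r

    # cell-means fit in score space
    GtG_inv = np.linalg.inv(G.T @ G)
    M = GtG_inv @ (G.T @ T)       # cell means, g x r
    F = G @ M                     # fitted values
    R = T - F
    B = F.T @ F
    W = R.T @ R

    try:
        evals, evecs = linalg.eigh(B, W)    # ascending; vectors W-orthonormal
    except np.linalg.LinAlgError:
        # near-singular within scatter (e.g. a perfectly discriminating
        # direction leaves ~zero residual variance): add a small ridge
        ridge = 1e-10 * np.trace(W) / r
        evals, evecs = linalg.eigh(B, W + ridge * np.eye(r))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > _EIG_TOL
    k = int(min(keep.sum(), g - 1, r))
    evals, A = evals[:k], evecs[:, :k]

    variates = T @ A
    contrasts = M @ A
    vectors = V @ A

    # sign convention: burn - control contrast at the final fraction >= 0
    cells = design.cells
    fractions = sorted({f for _, f in cells})
    last = fractions[-1]
    try:
        ib = cells.index(("burn", last))
        ic = cells.index(("control", last))
        flip = np.sign(contrasts[ib] - contrasts[ic])
        flip[flip == 0] = 1.0
    except ValueError:
        flip = np.ones(k)
    variates, contrasts, vectors = variates * flip, contrasts * flip, vectors * flip

    comp_ix = [f"CV{c + 1}" for c in range(k)]
    return CVAResult(
        canonical_vectors=pd.DataFrame(vectors, index=bio.intensities.columns, columns=comp_ix),
        canonical_variates=pd.DataFrame(variates, index=bio.intensities.index, columns=comp_ix),
        canonical_contrasts=pd.DataFrame(
            contrasts, index=pd.MultiIndex.from_tuples(cells, names=["condition", "fraction"]),
            columns=comp_ix,
        ),
        eigenvalues=np.asarray(evals),
        n_components_retained=k,
        pca_rank=r,
    )


def rank_features(result: CVAResult, component: int = 0) -> pd.DataFrame:
    """Features ordered by |canonical weight| on one component.

    Descending by absolute weight; exact ties broken by feature id
    (ascending), so the order is deterministic.
    """
    if not 0 <= component < result.n_components_retained:
        raise IndexError(f"component {component} out of range")
    col = result.canonical_vectors.columns[component]
    df = pd.DataFrame(
        {
            "feature_id": result.canonical_vectors.index,
            "weight": result.canonical_vectors[col].to_numpy(),
        }
    )
    df["abs_weight"] = df["weight"].abs()
    df = df.sort_values(["abs_weight", "feature_id"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def select_top_fraction(ranking: pd.DataFrame, fraction: float) -> list[str]:
    """The first ceil(fraction * n) feature ids of a ranking."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(ranking) == 0:
        raise ValueError("empty ranking")
    n = int(np.ceil(fraction * len(ranking)))
    return ranking["feature_id"].head(n).tolist()
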