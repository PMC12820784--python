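"""Multicellular niche discovery from spatial neighborhoods.

For every cell, the cell-type composition of its <= r µm neighborhood
(default 30 µm, focal cell included) is counted within its own sample. The
resulting cells x cell-types frequency matrix is clustered with k-means over
a range of k; the k maximizing the silhouette score is selected. Per-niche
cell-type enrichment is then tested with a chi-squared test of independence
whose per-cell p-values come from standardized residuals, Bonferroni
corrected over all (niche, type) cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import chi2, norm
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import DegenerateInputError, IntegrityError
from .io import CellTable

DEFAULT_RADIUS_UM = 30.0
DEFAULT_K_RANGE = range(5, 36)
SILHOUETTE_SUBSAMPLE_CAP = 10_000


@dataclass
class CompositionMatrix:
    """Cells x cell-types neighbor-count matrix with its generating radius."""

    counts: pd.DataFrame  # rows aligned to the CellTable, columns = types
    r_um: float
    include_self: bool = True

    @property
    def cell_types(self) -> list[str]:
        return list(self.counts.columns)

    def values(self, proportions: bool = False) -> np.ndarray:
        x = self.counts.to_numpy(float)
        if proportions:
            rs = x.sum(axis=1, keepdims=True)
            rs[rs == 0] = 1.0
            x = x / rs
        return x


def neighborhood_composition(
    cells: CellTable, r_um: float = DEFAULT_RADIUS_UM, include_self: bool = True
) -> CompositionMatrix:
    """Count, per cell, the neighbors of each type within ``r_um`` (closed).

    Distances are 2-D Euclidean and strictly within-sample; with
    ``include_self`` (the default) every row sums to at least 1.
    """
    if r_um <= 0:
        raise IntegrityError("radius must be > 0")
    df = cells.df
    types = cells.cell_types
    type_codes = pd.Categorical(df["cell_type"], categories=types).codes
    out = np.zeros((len(df), len(types)), dtype=np.int64)
    for _, idx in df.groupby("sample_id", sort=False).indices.items():
        xy = df.iloc[idx][["x_um", "y_um"]].to_numpy(float)
        codes = type_codes[idx]
        tree = cKDTree(xy)
        neighbors = tree.query_ball_point(xy, r=r_um)
        for local_i, nb in enumerate(neighbors):
            nb_codes = codes[nb]
            if not include_self:
                # query_ball_point returns the point itself; drop one copy
                self_code = codes[local_i]
                counts = np.bincount(nb_codes, minlength=len(types))
                counts[self_code] -= 1
                out[idx[local_i]] = counts
                continue
            out[idx[local_i]] = np.bincount(nb_codes, minlength=len(types))
    counts = pd.DataFrame(out, index=df.index, columns=types)
    return CompositionMatrix(counts, r_um=r_um, include_self=include_self)


@dataclass
class NicheModel:
    k_selected: int
    centroids: np.ndarray  # k x C
    labels: np.ndarray  # per-cell niche id in 0..k-1
    silhouette_by_k: dict[int, float]
    k_range: list[int]
    seed: int
    cell_types: list[str] = field(default_factory=list)


def fit_niches(
    comp: CompositionMatrix,
    k_range: range | list[int] | None = None,
    seed: int = 0,
    proportions: bool = False,
    n_restarts: int = 10,
    silhouette_cap: int = SILHOUETTE_SUBSAMPLE_CAP,
) -> NicheModel:
    """K-means over ``k_range`` (default 5..35); select argmax silhouette.

    Composition rows are clustered as raw counts by default (set
    ``proportions`` for row-normalized mode). The silhouette is computed on a
    seeded uniform subsample when the matrix exceeds ``silhouette_cap`` rows.
    Ties in the silhouette go to the smallest k. Deterministic given seed.
    """
    ks = list(k_range if k_range is not None else DEFAULT_K_RANGE)
    x = comp.values(proportions=proportions)
    n = x.shape[0]
    if np.all(x == x[0]):
        raise DegenerateInputError("all composition rows are identical")
    ks = [k for k in ks if 2 <= k <= n - 1]
    if not ks:
        raise DegenerateInputError("no feasible k in range for this matrix")

    rng = np.random.default_rng(seed)
    if n > silhouette_cap:
        sil_idx = rng.choice(n, size=silhouette_cap, replace=False)
    else:
        sil_idx = np.arange(n)

    fits: dict[int, KMeans] = {}
    scores: dict[int, float] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(x)
        sub_labels = labels[sil_idx]
        if len(np.unique(sub_labels)) < 2:
            scores[k] = -1.0
        else:
            scores[k] = float(silhouette_score(x[sil_idx], sub_labels))
        fits[k] = km
    best_k = max(sorted(scores), key=lambda k: scores[k])  # ties -> smallest k
    km = fits[best_k]
    return NicheModel(
        k_selected=best_k,
        centroids=km.cluster_centers_,
        labels=km.labels_,
        silhouette_by_k=scores,
        k_range=ks,
        seed=seed,
        cell_types=comp.cell_types,
    )


@dataclass
class EnrichmentTable:
    """Per-(niche, type) enrichment from standardized residuals."""

    table: pd.DataFrame  # niche, cell_type, observed, expected, std_residual,
    #                      p_raw, p_bonferroni, enriched_flag
    chi2_total: float
    dof: int
    p_global: float

    def enriched_pairs(self) -> set[tuple[str, str]]:
        sub = self.table[self.table["enriched_flag"]]
        return set(zip(sub["niche"], sub["cell_type"]))

    def niches_for_type(self, cell_type: str) -> set[str]:
        sub = self.table[
            (self.table["cell_type"] == cell_type) & self.table["enriched_flag"]
        ]
        return set(sub["niche"])


def niche_enrichment(
    labels, types, alpha: float = 0.05
) -> EnrichmentTable:
    """Chi-squared independence test of cell types across niches.

    The contingency table is niches x types. Standardized (adjusted)
    residuals ``(obs-exp)/sqrt(exp*(1-row/n)*(1-col/n))`` give per-cell
    two-sided normal p-values, Bonferroni corrected over all N*C cells; a
    cell is flagged enriched when the corrected p is below ``alpha`` and the
    residual is positive. ``dof = (N-1)*(C-1)``. Niches or types with zero
    total are dropped with a warning.
    """
    ct = pd.crosstab(
        pd.Series(labels, name="niche"),
        pd.Series(types, name="cell_type"),
        dropna=False,
    )
    zero_rows = ct.index[ct.sum(axis=1) == 0]
    zero_cols = ct.columns[ct.sum(axis=0) == 0]
    if len(zero_rows) or len(zero_cols):
        warnings.warn(
            f"dropping {len(zero_rows)} empty niche(s) and "
            f"{len(zero_cols)} empty type(s) from the contingency table",
            stacklevel=2,
        )
        ct = ct.drop(index=zero_rows, columns=zero_cols)
    if ct.shape[0] < 2 or ct.shape[1] < 2:
        raise DegenerateInputError("need >=2 niches and >=2 types with counts")

    obs = ct.to_numpy(float)
    n = obs.sum()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / n
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = np.sqrt(exp * (1 - row / n) * (1 - col / n))
        resid = np.where(denom > 0, (obs - exp) / denom, 0.0)
    chi2_total = float(((obs - exp) ** 2 / exp).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p_global = float(chi2.sf(chi2_total, dof))

    p_raw = 2 * norm.sf(np.abs(resid))
    m = obs.size
    p_bonf = np.minimum(1.0, p_raw * m)
    flags = (p_bonf < alpha) & (resid > 0)

    niches_col, types_col = np.meshgrid(ct.index, ct.columns, indexing="ij")
    table = pd.DataFrame(
        {
            "niche": niches_col.ravel(),
            "cell_type": types_col.ravel(),
            "observed": obs.ravel(),
            "expected": exp.ravel(),
            "std_residual": resid.ravel(),
            "p_raw": p_raw.ravel(),
            "p_bonferroni": p_bonf.ravel(),
            "enriched_flag": flags.ravel(),
        }
    )
    return EnrichmentTable(table, chi2_total=chi2_total, dof=dof, p_global=p_global)
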