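"""Niche-constrained ligand-receptor communication networks.

Marker detection (one-vs-rest rank-sum), interaction scoring with an
expression-fraction relevance threshold, a spatial co-enrichment constraint
(sender and receiver must be enriched in at least one common niche), weighted
directed network assembly, and distance-binned proximity-expression profiles.

The interaction score is the product of the two partners' mean expression
summaries, each min-max scaled within gene across cell types, so scores are
bounded in [0, 1] and monotone in both partners. Mean expression is computed
on library-size-normalized log1p values (logTP10K).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, IntegrityError
from .io import CellTable, DETable, ExpressionMatrix, LRDatabase
from .niches import EnrichmentTable

DEFAULT_TAU_EXPR = 0.05
DEFAULT_PROXIMITY_BINS = (0.0, 30.0, 60.0, 100.0, 200.0, np.inf)


@dataclass
class MarkerConfig:
    """Marker specificity and relevance thresholds.

    The specificity defaults reproduce a stringent cell-state marker filter
    (p < 0.05, log fold change > 3, expressed in > 25% of the foreground and
    < 10% of the background); ``tau_expr`` is the fraction of expressing
    cells a gene needs to count as relevant for interaction scoring.
    """

    p_max: float = 0.05
    min_lfc: float = 3.0
    min_frac_fg: float = 0.25
    max_frac_bg: float = 0.10
    tau_expr: float = DEFAULT_TAU_EXPR


def detect_markers(
    expr: ExpressionMatrix, labels: pd.Series | np.ndarray
) -> DETable:
    """One-vs-rest Wilcoxon rank-sum marker test for every (gene, type).

    Log fold changes are log2 of (mean+1) ratios on normalized values; BH
    adjustment is within each cell type. All rows are retained; filtering is
    the caller's job (see :func:`apply_specificity_filter`).
    """
    labels = np.asarray(labels)
    types = sorted(pd.unique(labels))
    if len(types) < 2:
        raise DegenerateInputError("marker detection needs >=2 cell types")
    norm = expr.lognorm()
    x = np.asarray(norm.counts.todense())  # genes x cells
    raw = np.asarray(expr.counts.todense())
    rows = []
    for t in types:
        fg = labels == t
        bg = ~fg
        if fg.sum() < 2 or bg.sum() < 2:
            raise DegenerateInputError(f"group {t!r} needs >=2 cells on each side")
        with np.errstate(all="ignore"):
            stat, p = mannwhitneyu(
                x[:, fg], x[:, bg], axis=1, alternative="two-sided"
            )
        p = np.nan_to_num(p, nan=1.0)
        mean_fg = x[:, fg].mean(axis=1)
        mean_bg = x[:, bg].mean(axis=1)
        lfc = np.log2((mean_fg + 1.0) / (mean_bg + 1.0))
        frac_fg = (raw[:, fg] > 0).mean(axis=1)
        frac_bg = (raw[:, bg] > 0).mean(axis=1)
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        for gi, gene in enumerate(expr.genes):
            rows.append((gene, t, lfc[gi], p[gi], adj[gi], frac_fg[gi], frac_bg[gi]))
    df = pd.DataFrame(
        rows,
        columns=[
            "gene", "group", "log_fold_change", "p_value", "adjusted_p",
            "frac_fg", "frac_bg",
        ],
    )
    return DETable(df)


def apply_specificity_filter(de: DETable, cfg: MarkerConfig) -> DETable:
    """Keep rows passing p < p_max, lfc > min_lfc, frac_fg > min_frac_fg and
    frac_bg < max_frac_bg."""
    d = de.df
    keep = (
        (d["p_value"] < cfg.p_max)
        & (d["log_fold_change"] > cfg.min_lfc)
        & (d["frac_fg"] > cfg.min_frac_fg)
        & (d["frac_bg"] < cfg.max_frac_bg)
    )
    return DETable(d[keep].reset_index(drop=True))


@dataclass
class InteractionScore:
    sender_type: str
    ligand: str
    receiver_type: str
    receptor: str
    score: float
    relevant: bool
    significant: bool


def _type_summaries(expr: ExpressionMatrix, labels: np.ndarray, genes: list[str]):
    """Per-gene per-type mean normalized expression, min-max scaled within
    gene across types, plus raw expressing fractions."""
    types = sorted(pd.unique(labels))
    norm = expr.lognorm()
    means = pd.DataFrame(index=genes, columns=types, dtype=float)
    fracs = pd.DataFrame(index=genes, columns=types, dtype=float)
    for g in genes:
        gv_norm = norm.row(g)
        gv_raw = expr.row(g)
        for t in types:
            m = labels == t
            means.loc[g, t] = gv_norm[m].mean()
            fracs.loc[g, t] = (gv_raw[m] > 0).mean()
    lo = means.min(axis=1)
    hi = means.max(axis=1)
    span = (hi - lo).replace(0, 1.0)
    scaled = means.sub(lo, axis=0).div(span, axis=0)
    return types, scaled, fracs


def score_interactions(
    expr: ExpressionMatrix,
    labels: pd.Series | np.ndarray,
    de: DETable,
    lrdb: LRDatabase,
    tau_expr: float = DEFAULT_TAU_EXPR,
) -> list[InteractionScore]:
    """Score every (sender, ligand, receiver, receptor) combination.

    relevant  <=> both partners expressed in > tau_expr of their cells;
    significant <=> relevant and the ligand is DE-up in the sender or the
    receptor is DE-up in the receiver; score = product of the two min-max
    scaled mean expressions. LR genes absent from the matrix skip their pairs
    with a warning.
    """
    labels = np.asarray(labels)
    known = set(expr.genes)
    pairs = []
    for _, r in lrdb.pairs.iterrows():
        if r["ligand"] not in known or r["receptor"] not in known:
            warnings.warn(
                f"skipping pair ({r['ligand']}, {r['receptor']}): gene absent "
                "from expression matrix",
                stacklevel=2,
            )
            continue
        pairs.append((r["ligand"], r["receptor"]))
    genes = sorted({g for p in pairs for g in p})
    types, scaled, fracs = _type_summaries(expr, labels, genes)
    up = {t: de.upregulated(t) for t in types}

    out: list[InteractionScore] = []
    for lig, rec in pairs:
        for s in types:
            for r in types:
                relevant = bool(
                    fracs.loc[lig, s] > tau_expr and fracs.loc[rec, r] > tau_expr
                )
                if not relevant:
                    continue
                significant = lig in up[s] or rec in up[r]
                score = float(scaled.loc[lig, s] * scaled.loc[rec, r])
                out.append(
                    InteractionScore(s, lig, r, rec, score, relevant, significant)
                )
    return out


def constrain_by_niche(
    scores: list[InteractionScore], enr: EnrichmentTable
) -> list[InteractionScore]:
    """Keep interactions whose sender and receiver are co-enriched in at
    least one common niche; types absent from the table are retained in no
    edge (warned)."""
    known_types = set(enr.table["cell_type"])
    seen = {s.sender_type for s in scores} | {s.receiver_type for s in scores}
    missing = sorted(seen - known_types)
    if missing:
        warnings.warn(
            f"type(s) absent from enrichment table treated as enriched "
            f"nowhere: {', '.join(missing)}",
            stacklevel=2,
        )
    niches_of = {t: enr.niches_for_type(t) for t in known_types}
    kept = []
    for s in scores:
        sn = niches_of.get(s.sender_type, set())
        rn = niches_of.get(s.receiver_type, set())
        if sn & rn:
            kept.append(s)
    return kept


@dataclass
class InteractionNetwork:
    """Directed weighted graph over cell types.

    Edge weight = sum of significant interaction scores; edges exist iff at
    least one significant interaction contributes.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def weight(self, sender: str, receiver: str) -> float:
        if self.graph.has_edge(sender, receiver):
            return self.graph[sender][receiver]["weight"]
        return 0.0

    def edges(self) -> list[tuple[str, str, float, int]]:
        return sorted(
            (u, v, d["weight"], d["n_interactions"])
            for u, v, d in self.graph.edges(data=True)
        )

    def top_incoming(self, receiver: str) -> str | None:
        """Sender with the maximum-weight edge into ``receiver``."""
        inc = [
            (d["weight"], u) for u, v, d in self.graph.in_edges(receiver, data=True)
        ]
        if not inc:
            return None
        return max(inc)[1]


def build_network(scores: list[InteractionScore]) -> InteractionNetwork:
    """Sum significant interaction scores into sender->receiver edge weights."""
    g = nx.DiGraph()
    for s in scores:
        if not s.significant:
            continue
        if g.has_edge(s.sender_type, s.receiver_type):
            g[s.sender_type][s.receiver_type]["weight"] += s.score
            g[s.sender_type][s.receiver_type]["n_interactions"] += 1
        else:
            g.add_edge(
                s.sender_type, s.receiver_type, weight=s.score, n_interactions=1
            )
    return InteractionNetwork(graph=g)


@dataclass
class ProximityProfile:
    """Distance-binned expression of a gene in target cells relative to the
    nearest source cell."""

    bin_edges: np.ndarray  # left-closed partition of [0, inf)
    n: np.ndarray
    mean_expression: np.ndarray
    fraction_expressing: np.ndarray
    distances: np.ndarray  # per target cell
    expression: np.ndarray  # per target cell (normalized)

    def as_frame(self) -> pd.DataFrame:
        lefts = self.bin_edges[:-1]
        rights = self.bin_edges[1:]
        return pd.DataFrame(
            {
                "bin_left_um": lefts,
                "bin_right_um": rights,
                "n": self.n,
                "mean_expression": self.mean_expression,
                "fraction_expressing": self.fraction_expressing,
            }
        )


def proximity_profile(
    cells: CellTable,
    expr: ExpressionMatrix,
    source_type: str,
    target_type: str,
    gene: str,
    bin_edges=DEFAULT_PROXIMITY_BINS,
) -> ProximityProfile:
    """Profile a gene's expression in target cells by distance to the nearest
    same-sample source cell (bins left-closed)."""
    edges = np.asarray(bin_edges, float)
    if edges[0] != 0 or not np.all(np.diff(edges) > 0):
        raise IntegrityError("bin edges must start at 0 and be increasing")
    df = cells.df
    norm = expr.lognorm()
    gv = norm.row(gene)
    raw = expr.row(gene)

    dists, exprs, raws = [], [], []
    any_source = False
    for _, idx in df.groupby("sample_id", sort=False).indices.items():
        sub = df.iloc[idx]
        src = sub["cell_type"] == source_type
        tgt = sub["cell_type"] == target_type
        if not tgt.any():
            continue
        if not src.any():
            continue
        any_source = True
        tree = cKDTree(sub.loc[src, ["x_um", "y_um"]].to_numpy(float))
        d, _ = tree.query(sub.loc[tgt, ["x_um", "y_um"]].to_numpy(float))
        gidx = idx[tgt.to_numpy()]
        dists.append(d)
        exprs.append(gv[gidx])
        raws.append(raw[gidx])
    if not any_source:
        raise IntegrityError(f"no {source_type!r} source cells in any sample")
    d = np.concatenate(dists)
    e = np.concatenate(exprs)
    r = np.concatenate(raws)

    which = np.digitize(d, edges[1:-1], right=False)  # left-closed bins
    nb = len(edges) - 1
    n = np.zeros(nb, dtype=int)
    mean_e = np.full(nb, np.nan)
    frac = np.full(nb, np.nan)
    for b in range(nb):
        m = which == b
        n[b] = m.sum()
        if n[b]:
            mean_e[b] = e[m].mean()
            frac[b] = (r[m] > 0).mean()
    return ProximityProfile(edges, n, mean_e, frac, d, e)
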