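"""Driver-ligand prioritization: the TF-to-ligand funnel.

Active transcription factors are selected along two routes — by marker
expression in the target population and by activity difference against the
background — then each selected TF votes for its top-n ligands in a
regulatory-potential matrix. Ligands appearing in at least ``min_votes``
top-n lists survive, and are finally restricted to those with a cognate
receptor expressed in more than a threshold fraction of target cells.
Defaults follow the published funnel: activity difference > 0.75 at
p < 0.01, top 10 ligands per TF, >= 5 votes, receptor expressed in > 5% of
target cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import ConfigError
from .io import DETable, ExpressionMatrix, LRDatabase

DEFAULT_TOP_N = 10
DEFAULT_MIN_VOTES = 5
DEFAULT_RECEPTOR_TAU = 0.05


@dataclass
class TFSelectionConfig:
    activity_min_diff: float = 0.75
    activity_p_max: float = 0.01
    expression_p_max: float = 0.05


@dataclass
class TFSelection:
    expression_route: set[str]
    activity_route: set[str]

    @property
    def union(self) -> set[str]:
        return self.expression_route | self.activity_route


def select_tfs(
    markers: DETable | None,
    activity: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    target_type: str,
    tf_universe: list[str],
    cfg: TFSelectionConfig | None = None,
) -> TFSelection:
    """Select active TFs by marker expression and by activity difference.

    Expression route: target-type marker genes (rank-sum p below
    ``expression_p_max``) intersected with the TF universe; pass
    ``markers=None`` to skip it. Activity route: TFs whose mean activity in
    the target type exceeds the background by more than ``activity_min_diff``
    with a rank-sum p below ``activity_p_max``.
    """
    if not tf_universe:
        raise ConfigError("TF universe is empty")
    cfg = cfg or TFSelectionConfig()
    universe = set(tf_universe)

    expression_route: set[str] = set()
    if markers is not None:
        d = markers.df
        hits = d[
            (d["group"] == target_type)
            & (d["p_value"] < cfg.expression_p_max)
            & (d["log_fold_change"] > 0)
        ]
        expression_route = set(hits["gene"]) & universe

    labels = np.asarray(labels)
    fg = labels == target_type
    bg = ~fg
    activity_route: set[str] = set()
    for tf in activity.columns:
        if tf not in universe:
            continue
        a_fg = activity.loc[fg, tf].to_numpy(float)
        a_bg = activity.loc[bg, tf].to_numpy(float)
        diff = a_fg.mean() - a_bg.mean()
        if diff <= cfg.activity_min_diff:
            continue
        _, p = mannwhitneyu(a_fg, a_bg, alternative="two-sided")
        if p < cfg.activity_p_max:
            activity_route.add(tf)
    return TFSelection(expression_route, activity_route)


def vote_ligands(
    tfs: TFSelection | set[str],
    rp: pd.DataFrame,
    top_n: int = DEFAULT_TOP_N,
    min_votes: int = DEFAULT_MIN_VOTES,
) -> pd.DataFrame:
    """Vote ligands via each selected TF's top-``top_n`` regulatory scores.

    Within a TF column, ties are broken by ligand label (lexicographic) so
    vote counts are reproducible. Returns ligands with votes >= min_votes,
    sorted by votes descending then label ascending, as columns
    (ligand, votes).
    """
    if len(rp.index) < top_n:
        raise ConfigError(
            f"regulatory-potential matrix has {len(rp.index)} ligands, "
            f"fewer than top_n={top_n}"
        )
    selected = tfs.union if isinstance(tfs, TFSelection) else set(tfs)
    missing = sorted(selected - set(rp.columns))
    if missing:
        warnings.warn(
            f"TF(s) absent from regulatory-potential matrix dropped: "
            f"{', '.join(missing)}",
            stacklevel=2,
        )
    used = sorted(selected & set(rp.columns))

    votes: dict[str, int] = {}
    for tf in used:
        col = rp[tf].sort_index()  # lexicographic tie-break under stable sort
        top = col.sort_values(ascending=False, kind="stable").head(top_n)
        for lig in top.index:
            votes[lig] = votes.get(lig, 0) + 1
    rows = [(l, v) for l, v in votes.items() if v >= min_votes]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["ligand", "votes"])


@dataclass
class LigandShortlist:
    table: pd.DataFrame  # ligand, votes, receptors_expressed
    top_n: int = DEFAULT_TOP_N
    min_votes: int = DEFAULT_MIN_VOTES
    receptor_tau: float = DEFAULT_RECEPTOR_TAU

    @property
    def ligands(self) -> list[str]:
        return list(self.table["ligand"])

    def __len__(self) -> int:
        return len(self.table)


def filter_by_receptor(
    voted: pd.DataFrame,
    lrdb: LRDatabase,
    expr: ExpressionMatrix,
    labels: pd.Series | np.ndarray,
    target_type: str,
    tau: float = DEFAULT_RECEPTOR_TAU,
    top_n: int = DEFAULT_TOP_N,
    min_votes: int = DEFAULT_MIN_VOTES,
) -> LigandShortlist:
    """Keep voted ligands with >=1 cognate receptor expressed in more than
    ``tau`` of target-type cells; ligands with no receptor in the database
    are dropped with a warning."""
    labels = np.asarray(labels)
    tgt = labels == target_type
    if not tgt.any():
        raise ConfigError(f"target type {target_type!r} absent from labels")
    known = set(expr.genes)

    rows = []
    for _, r in voted.iterrows():
        lig, v = r["ligand"], int(r["votes"])
        receptors = lrdb.receptors_for(lig)
        if not receptors:
            warnings.warn(
                f"ligand {lig!r} has no receptor in the database; dropped",
                stacklevel=2,
            )
            continue
        expressed = []
        for rec in receptors:
            if rec not in known:
                continue
            frac = (expr.row(rec)[tgt] > 0).mean()
            if frac > tau:
                expressed.append(rec)
        if expressed:
            rows.append((lig, v, ";".join(expressed)))
    table = pd.DataFrame(rows, columns=["ligand", "votes", "receptors_expressed"])
    return LigandShortlist(table, top_n=top_n, min_votes=min_votes, receptor_tau=tau)
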