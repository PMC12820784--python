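"""Synthetic multi-sample tissues and cohorts with planted ground truth.

The generators emulate the structure of a multi-sample spatial atlas:
rectangular niche regions with distinct cell-type compositions, a planted
sender -> receiver signalling circuit whose target gene decays with distance
to the nearest sender cell, condition-dependent abundance shifts, a
ligand/TF regulatory-potential resource with planted support, and a bulk
cohort whose ordinal severity is driven by a planted gene signature.

All generators are pure functions of (config, seed). A single integer seed
drives an explicit hierarchical ``SeedSequence`` tree (per sample, per
stage), so adding samples never perturbs earlier samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree
from scipy.stats import norm

from .errors import ConfigError
from .io import CellTable, ExpressionMatrix, LRDatabase


# ---------------------------------------------------------------------------
# Tissue generation
# ---------------------------------------------------------------------------

@dataclass
class NicheSpec:
    """A planted niche: an axis-aligned rectangle with a fixed composition."""

    name: str
    rect: tuple[float, float, float, float]  # x0, y0, x1, y1 in µm
    composition: dict[str, float]  # cell type -> mixing proportion

    @property
    def area(self) -> float:
        x0, y0, x1, y1 = self.rect
        return (x1 - x0) * (y1 - y0)


@dataclass
class CircuitSpec:
    """Planted sender -> receiver circuit with distance-decaying induction.

    In receiver cells the target gene's mean is scaled by
    ``1 + (max_induction - 1) * exp(-d / decay_length)`` where ``d`` is the
    distance (µm) to the nearest sender cell in the same sample.
    """

    sender_type: str = "macrophage_act"
    receiver_type: str = "fibroblast_inflam"
    ligand: str = "LIG1"
    receptor: str = "REC1"
    target_gene: str = "TGT1"
    decay_length_um: float = 30.0
    max_induction: float = 5.0

    def __post_init__(self) -> None:
        if self.decay_length_um <= 0:
            raise ConfigError("decay_length_um must be > 0")


@dataclass
class TissueConfig:
    """Configuration for the synthetic spatial tissue generator.

    ``density`` is cells per 10^4 µm^2; the default of 50 puts ~14 cells in a
    30-µm neighborhood, a realistic packing for intestinal mucosa. Counts are
    negative-binomial with shared ``dispersion`` (size parameter) to mimic the
    overdispersion of UMI data.
    """

    niches: list[NicheSpec]
    n_samples: dict[str, int] = field(
        default_factory=lambda: {"control": 2, "disease": 2}
    )
    density: float = 50.0  # cells per 1e4 µm²
    abundance_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    circuit: CircuitSpec | None = field(default_factory=CircuitSpec)
    dispersion: float = 10.0
    marker_genes_per_type: int = 3
    marker_mean: float = 5.0
    background_mean: float = 0.05
    target_base_mean: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ConfigError("density must be > 0")
        if not self.niches:
            raise ConfigError("at least one niche region is required")
        for n in self.niches:
            if n.area <= 0:
                raise ConfigError(f"niche {n.name!r} has an empty region")
            tot = sum(n.composition.values())
            if abs(tot - 1.0) > 1e-8:
                raise ConfigError(
                    f"niche {n.name!r} composition sums to {tot}, expected 1"
                )
        for a, b in zip(self.niches, self.niches[1:]):
            pass
        rects = [n.rect for n in self.niches]
        for i in range(len(rects)):
            for j in range(i + 1, len(rects)):
                if _rects_overlap(rects[i], rects[j]):
                    raise ConfigError(
                        f"niche regions {self.niches[i].name!r} and "
                        f"{self.niches[j].name!r} overlap"
                    )

    @property
    def cell_types(self) -> list[str]:
        types: list[str] = []
        for n in self.niches:
            for t in n.composition:
                if t not in types:
                    types.append(t)
        return types


def _rects_overlap(a, b) -> bool:
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    return ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1


@dataclass
class TissueTruth:
    """Planted ground truth aligned 1:1 with the generated cells."""

    niche_id: pd.Series  # per cell, indexed like the CellTable rows
    type_condition_lfc: dict[str, float]
    circuit: CircuitSpec | None
    sender_distance: pd.Series  # per cell, NaN for non-receivers


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, size_param: float):
    """Negative binomial via gamma-Poisson mixture; var = m + m^2/size."""
    lam = rng.gamma(shape=size_param, scale=np.maximum(mean, 1e-12) / size_param)
    return rng.poisson(lam)


def _gene_panel(config: TissueConfig) -> tuple[list[str], dict[str, np.ndarray]]:
    """Build the gene list and per-type mean-expression programs."""
    types = config.cell_types
    genes: list[str] = []
    for t in types:
        genes += [f"{t}_mk{i+1}" for i in range(config.marker_genes_per_type)]
    if config.circuit is not None:
        for g in (config.circuit.ligand, config.circuit.receptor,
                  config.circuit.target_gene):
            if g not in genes:
                genes.append(g)
    programs = {}
    for t in types:
        mu = np.full(len(genes), config.background_mean)
        for i in range(config.marker_genes_per_type):
            mu[genes.index(f"{t}_mk{i+1}")] = config.marker_mean
        if config.circuit is not None:
            c = config.circuit
            if t == c.sender_type:
                mu[genes.index(c.ligand)] = config.marker_mean
            if t == c.receiver_type:
                mu[genes.index(c.receptor)] = config.marker_mean
                mu[genes.index(c.target_gene)] = config.target_base_mean
        programs[t] = mu
    return genes, programs


def generate_tissue(
    config: TissueConfig,
) -> tuple[CellTable, ExpressionMatrix, TissueTruth]:
    """Generate a multi-sample tissue with planted niches and circuit.

    Cells are placed by a homogeneous spatial Poisson process within each
    niche rectangle; the type is drawn from the niche's composition (reweighted
    by condition abundance effects); counts are negative-binomial from
    type-specific programs; the circuit target gene in receiver cells is
    scaled by ``1 + (max_induction-1)*exp(-d/decay_length)`` with ``d`` the
    distance to the nearest sender cell in the same sample.
    """
    root = np.random.SeedSequence(config.seed)
    genes, programs = _gene_panel(config)
    types = config.cell_types

    sample_names = []
    for cond, n in config.n_samples.items():
        sample_names += [(f"{cond}_s{i+1}", cond) for i in range(n)]
    sample_seeds = root.spawn(len(sample_names))

    rows = []
    niche_ids = []
    type_arrays = []
    count_blocks = []
    sender_dists = []
    for (sname, cond), sseed in zip(sample_names, sample_seeds):
        place_rng, type_rng, expr_rng = (
            np.random.default_rng(s) for s in sseed.spawn(3)
        )
        xs, ys, nids, tlabels = [], [], [], []
        for niche in config.niches:
            x0, y0, x1, y1 = niche.rect
            lam = config.density * niche.area / 1e4
            n_cells = place_rng.poisson(lam)
            xs.append(place_rng.uniform(x0, x1, n_cells))
            ys.append(place_rng.uniform(y0, y1, n_cells))
            nids += [niche.name] * n_cells
            comp_types = list(niche.composition)
            weights = np.array([niche.composition[t] for t in comp_types])
            eff = config.abundance_effects.get(cond, {})
            weights = weights * np.array([eff.get(t, 1.0) for t in comp_types])
            weights = weights / weights.sum()
            tlabels.append(
                type_rng.choice(comp_types, size=n_cells, p=weights)
            )
        x = np.concatenate(xs) if xs else np.empty(0)
        y = np.concatenate(ys) if ys else np.empty(0)
        tl = np.concatenate(tlabels) if tlabels else np.empty(0, dtype=object)
        nid = np.array(nids, dtype=object)

        mu = np.stack([programs[t] for t in tl], axis=1)  # genes x cells
        sdist = np.full(len(tl), np.nan)
        if config.circuit is not None:
            c = config.circuit
            senders = tl == c.sender_type
            receivers = tl == c.receiver_type
            if senders.any() and receivers.any():
                tree = cKDTree(np.column_stack([x[senders], y[senders]]))
                d, _ = tree.query(np.column_stack([x[receivers], y[receivers]]))
                sdist[receivers] = d
                scale = 1.0 + (c.max_induction - 1.0) * np.exp(
                    -d / c.decay_length_um
                )
                gi = genes.index(c.target_gene)
                mu[gi, receivers] = mu[gi, receivers] * scale
        counts = _nb_sample(expr_rng, mu, config.dispersion)

        for i in range(len(tl)):
            rows.append((f"{sname}_c{i}", x[i], y[i], tl[i], sname, cond))
        niche_ids += list(nid)
        type_arrays.append(tl)
        count_blocks.append(sp.csr_matrix(counts))
        sender_dists += list(sdist)

    df = pd.DataFrame(
        rows, columns=["cell_id", "x_um", "y_um", "cell_type", "sample_id", "condition"]
    )
    cells = CellTable(df)
    counts_all = sp.hstack(count_blocks, format="csr")
    expr = ExpressionMatrix(genes, list(df["cell_id"]), counts_all)

    lfc = {}
    for t in types:
        effs = [
            np.log2(config.abundance_effects.get(cond, {}).get(t, 1.0))
            for cond in config.n_samples
            if cond != next(iter(config.n_samples))
        ]
        lfc[t] = float(effs[0]) if effs else 0.0
    truth = TissueTruth(
        niche_id=pd.Series(niche_ids, index=df.index, name="niche_id"),
        type_condition_lfc=lfc,
        circuit=config.circuit,
        sender_distance=pd.Series(sender_dists, index=df.index, name="d_um"),
    )
    return cells, expr, truth


# ---------------------------------------------------------------------------
# Ligand / TF resources for the prioritization funnel
# ---------------------------------------------------------------------------

@dataclass
class LRResourceConfig:
    """Planted resources for the TF-to-ligand prioritization funnel.

    ``support`` maps each planted ligand to the TFs for which it must rank
    inside the top ``top_n`` of the regulatory-potential column; all other
    (ligand, TF) scores are exchangeable uniforms. Ligands named in
    ``receptor_expressed`` get their cognate receptor expressed in
    ``receptor_frac`` of target cells; all other receptors stay silent.
    """

    ligands: list[str]
    tfs: list[str]
    support: dict[str, list[str]] = field(default_factory=dict)
    receptors: dict[str, str] | None = None
    receptor_expressed: set[str] | None = None
    receptor_frac: float = 0.5
    active_tfs: list[str] | None = None
    activity_diff: float = 1.0
    n_target_cells: int = 200
    n_background_cells: int = 600
    target_type: str = "fibroblast_inflam"
    top_n: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.ligands) < self.top_n:
            raise ConfigError(
                f"need at least top_n={self.top_n} ligands, got {len(self.ligands)}"
            )
        unknown = set(self.support) - set(self.ligands)
        if unknown:
            raise ConfigError(f"support names unknown ligand(s): {unknown}")
        if self.receptors is None:
            self.receptors = {l: f"{l}_R" for l in self.ligands}
        if self.receptor_expressed is None:
            self.receptor_expressed = set(self.support)
        if self.active_tfs is None:
            active = sorted({tf for tfs in self.support.values() for tf in tfs})
            self.active_tfs = active if active else list(self.tfs)


@dataclass
class LRResources:
    lrdb: LRDatabase
    reg_potential: pd.DataFrame  # ligands x TFs
    tf_activity: pd.DataFrame  # cells x TFs
    cell_labels: pd.Series  # per activity row: cell type
    receptor_expr: ExpressionMatrix
    planted_ligands: list[str]


def generate_lr_resources(config: LRResourceConfig) -> LRResources:
    """Generate the LR database, regulatory-potential and TF-activity inputs.

    Planted ligands are forced above every decoy in their supported TF
    columns and below every decoy elsewhere, so their top-``top_n`` ranks are
    exact by construction; decoy scores are i.i.d. uniform (exchangeable).
    """
    root = np.random.SeedSequence(config.seed)
    rp_rng, act_rng, rec_rng = (np.random.default_rng(s) for s in root.spawn(3))

    planted = sorted(config.support)
    rp = pd.DataFrame(
        rp_rng.uniform(0, 1, size=(len(config.ligands), len(config.tfs))),
        index=list(config.ligands),
        columns=list(config.tfs),
    )
    for lig in planted:
        supported = set(config.support[lig])
        for tf in config.tfs:
            if tf in supported:
                rp.loc[lig, tf] = 1.0 + rp_rng.uniform(0, 1)
            else:
                rp.loc[lig, tf] = -1.0 - rp_rng.uniform(0, 1)

    n = config.n_target_cells + config.n_background_cells
    labels = pd.Series(
        [config.target_type] * config.n_target_cells + ["background"]
        * config.n_background_cells,
        index=[f"cell{i}" for i in range(n)],
        name="cell_type",
    )
    act = pd.DataFrame(
        act_rng.normal(0, 1, size=(n, len(config.tfs))),
        index=labels.index,
        columns=list(config.tfs),
    )
    for tf in config.active_tfs:
        act.loc[labels == config.target_type, tf] += config.activity_diff

    pairs = pd.DataFrame(
        {"ligand": list(config.ligands),
         "receptor": [config.receptors[l] for l in config.ligands]}
    )
    lrdb = LRDatabase(pairs)

    rec_genes = [config.receptors[l] for l in config.ligands]
    counts = np.zeros((len(rec_genes), n), dtype=np.int64)
    tgt = (labels == config.target_type).to_numpy()
    for gi, lig in enumerate(config.ligands):
        if lig in config.receptor_expressed:
            counts[gi, tgt] = rec_rng.binomial(1, config.receptor_frac, tgt.sum())
    receptor_expr = ExpressionMatrix(
        rec_genes, list(labels.index), sp.csr_matrix(counts)
    )
    return LRResources(lrdb, rp, act, labels, receptor_expr, planted)


# ---------------------------------------------------------------------------
# Abundance count cohorts
# ---------------------------------------------------------------------------

def generate_composition_counts(
    base_proportions: dict[str, float],
    fold_changes: dict[str, float],
    n_per_group: int = 20,
    cells_per_sample: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial per-sample cell counts with planted relative shifts.

    ``fold_changes`` multiplies the disease-group proportions before
    renormalization. Returns a samples x categories frame with a
    ``condition`` column (control/disease).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cats = list(base_proportions)
    p0 = np.array([base_proportions[c] for c in cats], float)
    p0 = p0 / p0.sum()
    p1 = p0 * np.array([fold_changes.get(c, 1.0) for c in cats])
    p1 = p1 / p1.sum()
    rows, conds = [], []
    for cond, p in (("control", p0), ("disease", p1)):
        for _ in range(n_per_group):
            rows.append(rng.multinomial(cells_per_sample, p))
            conds.append(cond)
    df = pd.DataFrame(rows, columns=cats)
    df["condition"] = conds
    return df


# ---------------------------------------------------------------------------
# Bulk cohort with ordinal severity
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Bulk-like cohort whose ordinal severity tracks a planted signature.

    Each subject gets a latent signature level ``s ~ N(0,1)``; signature-gene
    expression is shifted by ``s``; severity is the ordinal bin of
    ``u = beta_true*s + N(0,1)`` by fixed thresholds (quantiles of the
    theoretical marginal of ``u``, so categories are balanced in expectation).
    """

    n_subjects: int = 200
    n_genes: int = 400
    n_signature: int = 50
    beta_true: float = 2.0
    n_categories: int = 4
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ConfigError("need at least 2 ordinal categories")
        if self.n_signature >= self.n_genes:
            raise ConfigError("signature must be a proper subset of the genes")


@dataclass
class CohortTruth:
    signature_genes: list[str]
    s: np.ndarray
    u: np.ndarray
    beta_true: float
    thresholds: np.ndarray


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.Series, CohortTruth]:
    """Generate (profiles genes x subjects, ordinal severity, ground truth)."""
    root = np.random.SeedSequence(config.seed)
    s_rng, e_rng, u_rng = (np.random.default_rng(x) for x in root.spawn(3))

    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    sig = genes[: config.n_signature]
    subjects = [f"subj{i:03d}" for i in range(config.n_subjects)]

    s = s_rng.normal(0, 1, config.n_subjects)
    expr = e_rng.normal(0, config.noise_sd, (config.n_genes, config.n_subjects))
    expr[: config.n_signature, :] += s[None, :]

    u = config.beta_true * s + u_rng.normal(0, 1, config.n_subjects)
    sd_u = np.sqrt(config.beta_true**2 + 1.0)
    qs = np.linspace(0, 1, config.n_categories + 1)[1:-1]
    thresholds = norm.ppf(qs, scale=sd_u)
    severity = pd.Series(
        np.digitize(u, thresholds), index=subjects, name="severity"
    )
    profiles = pd.DataFrame(expr, index=genes, columns=subjects)
    truth = CohortTruth(sig, s, u, config.beta_true, thresholds)
    return profiles, severity, truth
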