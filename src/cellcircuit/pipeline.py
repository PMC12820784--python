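"""End-to-end orchestration: simulate -> niches -> enrichment -> abundance ->
communication -> prioritization -> scoring, driven by one JSON config.

Stages exchange plain files so each is independently testable and resumable;
all randomness flows from the config seed through an explicit seed tree. The
run manifest records parameters, seeds and SHA-256 digests of every output,
so identical config + inputs give identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abundance import CountTable, test_abundance
from .communication import (
    build_network,
    constrain_by_niche,
    detect_markers,
    proximity_profile,
    score_interactions,
)
from .errors import ConfigError
from .io import (
    CellTable,
    LRDatabase,
    read_cell_table,
    read_expression,
    write_cell_table,
    write_expression,
    write_network,
)
from .ligands import filter_by_receptor, select_tfs, vote_ligands
from .niches import fit_niches, neighborhood_composition, niche_enrichment
from .scoring import ordered_probit, score_cohort
from .synthetic import (
    CircuitSpec,
    CohortConfig,
    LRResourceConfig,
    NicheSpec,
    TissueConfig,
    generate_cohort,
    generate_lr_resources,
    generate_tissue,
)

logger = logging.getLogger(__name__)

STAGE_ORDER = (
    "niches",
    "enrichment",
    "abundance",
    "communication",
    "prioritization",
    "scoring",
)


def default_tissue_config(
    seed: int, n_samples_per_condition: int = 2, size_um: float = 1000.0
) -> TissueConfig:
    """Four quadrant niches with distinct compositions over a size_um x
    size_um section; ~5,000 cells per sample at the default density and
    size."""
    h = size_um / 2
    niches = [
        NicheSpec(
            "epithelial_zone",
            (0, 0, h, h),
            {"epithelial": 0.7, "t_cell": 0.2, "fibroblast": 0.1},
        ),
        NicheSpec(
            "inflamed_zone",
            (h, 0, size_um, h),
            {"fibroblast_inflam": 0.4, "macrophage_act": 0.4, "t_cell": 0.2},
        ),
        NicheSpec(
            "stromal_zone",
            (0, h, h, size_um),
            {"fibroblast": 0.6, "smc": 0.3, "endothelial": 0.1},
        ),
        NicheSpec(
            "muscularis_zone",
            (h, h, size_um, size_um),
            {"smc": 0.8, "endothelial": 0.1, "fibroblast": 0.1},
        ),
    ]
    return TissueConfig(
        niches=niches,
        n_samples={"control": n_samples_per_condition,
                   "disease": n_samples_per_condition},
        abundance_effects={"disease": {"fibroblast_inflam": 3.0,
                                       "macrophage_act": 2.0}},
        circuit=CircuitSpec(),
        seed=seed,
    )


def gradient_tissue_config(
    seed: int, max_induction: float = 6.0, decay_length_um: float = 60.0
) -> TissueConfig:
    """Sender-gradient tissue for proximity profiling: senders confined to a
    200-µm strip, receivers spanning the full 800-µm width, so target cells
    populate every distance bin."""
    niches = [
        NicheSpec(
            "sender_zone",
            (0, 0, 200, 1200),
            {"macrophage_act": 0.5, "fibroblast_inflam": 0.5},
        ),
        NicheSpec(
            "distal_zone",
            (200, 0, 800, 1200),
            {"fibroblast_inflam": 0.3, "fibroblast": 0.7},
        ),
    ]
    return TissueConfig(
        niches=niches,
        n_samples={"control": 1},
        circuit=CircuitSpec(
            decay_length_um=decay_length_um, max_induction=max_induction
        ),
        seed=seed,
    )


def tissue_lr_database(config: TissueConfig) -> LRDatabase:
    """Circuit pair plus decoy pairs drawn from the marker panel."""
    pairs = []
    if config.circuit is not None:
        pairs.append((config.circuit.ligand, config.circuit.receptor))
    types = config.cell_types
    for i, ta in enumerate(types):
        tb = types[(i + 1) % len(types)]
        pairs.append((f"{ta}_mk1", f"{tb}_mk2"))
    df = pd.DataFrame(pairs, columns=["ligand", "receptor"]).drop_duplicates()
    return LRDatabase(df.reset_index(drop=True))


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "out"
    simulate: bool = True
    n_samples_per_condition: int = 2
    size_um: float = 1000.0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGE_ORDER}
    )
    inputs: dict[str, str] = field(default_factory=dict)
    r_um: float = 30.0
    k_min: int = 2
    k_max: int = 8
    tau_expr: float = 0.05
    top_n: int = 10
    min_votes: int = 5
    fdr: float = 0.20
    reference_category: str = "smc"
    target_type: str = "fibroblast_inflam"
    sender_type: str = "macrophage_act"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cfg = cls(**raw)
        for s in cfg.stages:
            if s not in STAGE_ORDER:
                raise ConfigError(f"unknown stage {s!r}")
        return cfg

    def to_json(self, path: str | Path) -> None:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _validate_dependencies(cfg: RunConfig) -> None:
    """Dry-run check: every enabled stage's inputs must be resolvable."""
    on = {s for s in STAGE_ORDER if cfg.stages.get(s, False)}
    if cfg.simulate:
        return
    need = {"cells", "mtx", "genes", "cell_ids"}
    if "prioritization" in on:
        need |= {"activity", "activity_labels", "rp", "lr"}
    if "communication" in on:
        need |= {"lr"}
    if "enrichment" in on and "niches" not in on:
        need |= {"niche_labels"}
    missing = sorted(need - set(cfg.inputs))
    if missing:
        raise ConfigError(
            f"enabled stages need input path(s) not in config: {', '.join(missing)}"
        )
    for k in need:
        if not Path(cfg.inputs[k]).exists():
            raise ConfigError(f"input {k!r} -> {cfg.inputs[k]} does not exist")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    _validate_dependencies(cfg)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}
    root = np.random.SeedSequence(cfg.seed)
    sim_seed, niche_seed, resource_seed, cohort_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(4)
    )

    def _emit(name: str, path: Path) -> None:
        outputs[name] = str(path.relative_to(out))

    # ---- inputs / simulation ------------------------------------------------
    t0 = time.time()
    truth = None
    tissue_cfg = None
    if cfg.simulate:
        tissue_cfg = default_tissue_config(
            sim_seed, cfg.n_samples_per_condition, cfg.size_um
        )
        cells, expr, truth = generate_tissue(tissue_cfg)
        write_cell_table(cells, out / "cells.tsv")
        write_expression(
            expr, out / "expr.mtx", out / "expr_genes.tsv", out / "expr_cells.tsv"
        )
        lrdb = tissue_lr_database(tissue_cfg)
        for name in ("cells.tsv", "expr.mtx", "expr_genes.tsv", "expr_cells.tsv"):
            _emit(name.split(".")[0] if name == "cells.tsv" else name, out / name)
    else:
        cells = read_cell_table(cfg.inputs["cells"])
        expr = read_expression(
            cfg.inputs["mtx"], cfg.inputs["genes"], cfg.inputs["cell_ids"]
        )
        lrdb = (
            LRDatabase(pd.read_csv(cfg.inputs["lr"], sep="\t", comment="#"))
            if "lr" in cfg.inputs
            else None
        )
    timings["inputs"] = time.time() - t0

    labels_types = cells.df["cell_type"].to_numpy()
    niche_labels = None
    enr = None

    # ---- niches -------------------------------------------------------------
    if cfg.stages.get("niches", False):
        t0 = time.time()
        comp = neighborhood_composition(cells, r_um=cfg.r_um)
        model = fit_niches(
            comp, range(cfg.k_min, cfg.k_max + 1), seed=niche_seed
        )
        niche_labels = model.labels
        lab = cells.df[["cell_id", "sample_id"]].copy()
        lab["niche"] = niche_labels
        lab.to_csv(out / "niche_labels.tsv", sep="\t", index=False)
        sil = pd.DataFrame(
            sorted(model.silhouette_by_k.items()), columns=["k", "silhouette"]
        )
        sil.to_csv(out / "silhouette.tsv", sep="\t", index=False)
        _emit("niche_labels", out / "niche_labels.tsv")
        _emit("silhouette", out / "silhouette.tsv")
        timings["niches"] = time.time() - t0
    elif "niche_labels" in cfg.inputs:
        niche_labels = pd.read_csv(cfg.inputs["niche_labels"], sep="\t")[
            "niche"
        ].to_numpy()

    # ---- enrichment ---------------------------------------------------------
    if cfg.stages.get("enrichment", False):
        t0 = time.time()
        enr = niche_enrichment(niche_labels, labels_types)
        enr.table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        _emit("enrichment", out / "enrichment.tsv")
        timings["enrichment"] = time.time() - t0

    # ---- abundance ----------------------------------------------------------
    if cfg.stages.get("abundance", False):
        t0 = time.time()
        counts = pd.crosstab(cells.df["sample_id"], cells.df["cell_type"])
        cond = cells.df.groupby("sample_id")["condition"].first().loc[counts.index]
        ref = (
            cfg.reference_category
            if cfg.reference_category in counts.columns
            else counts.columns[0]
        )
        res = test_abundance(
            CountTable(counts, cond, reference=ref), fdr=cfg.fdr
        )
        res.table.to_csv(out / "abundance.tsv", sep="\t", index=False)
        _emit("abundance", out / "abundance.tsv")
        timings["abundance"] = time.time() - t0

    # ---- communication ------------------------------------------------------
    if cfg.stages.get("communication", False):
        t0 = time.time()
        if lrdb is None:
            raise ConfigError("communication stage needs an LR database")
        de = detect_markers(expr, labels_types)
        de.df.to_csv(out / "markers.tsv", sep="\t", index=False)
        scores = score_interactions(expr, labels_types, de, lrdb, cfg.tau_expr)
        if enr is not None:
            scores = constrain_by_niche(scores, enr)
        net = build_network(scores)
        write_network(net, out / "network.tsv")
        _emit("markers", out / "markers.tsv")
        _emit("network", out / "network.tsv")
        if tissue_cfg is not None and tissue_cfg.circuit is not None:
            c = tissue_cfg.circuit
            prof = proximity_profile(
                cells, expr, c.sender_type, c.receiver_type, c.target_gene
            )
            prof.as_frame().to_csv(out / "proximity.tsv", sep="\t", index=False)
            _emit("proximity", out / "proximity.tsv")
        timings["communication"] = time.time() - t0

    # ---- prioritization -----------------------------------------------------
    if cfg.stages.get("prioritization", False):
        t0 = time.time()
        if cfg.simulate:
            rc = LRResourceConfig(
                ligands=[f"L{i:02d}" for i in range(20)],
                tfs=[f"TF{i}" for i in range(8)],
                support={
                    "L00": [f"TF{i}" for i in range(8)],
                    "L01": [f"TF{i}" for i in range(6)],
                },
                seed=resource_seed,
            )
            res = generate_lr_resources(rc)
            activity, act_labels = res.tf_activity, res.cell_labels
            rp, funnel_lrdb, rec_expr = res.reg_potential, res.lrdb, res.receptor_expr
        else:
            activity = pd.read_csv(cfg.inputs["activity"], sep="\t", index_col=0)
            act_labels = pd.read_csv(
                cfg.inputs["activity_labels"], sep="\t", index_col=0
            ).iloc[:, 0]
            rp = pd.read_csv(cfg.inputs["rp"], sep="\t", index_col=0)
            funnel_lrdb = LRDatabase(pd.read_csv(cfg.inputs["lr"], sep="\t"))
            rec_expr = expr
        sel = select_tfs(
            None, activity, act_labels, cfg.target_type, list(activity.columns)
        )
        voted = vote_ligands(sel, rp, top_n=cfg.top_n, min_votes=cfg.min_votes)
        shortlist = filter_by_receptor(
            voted, funnel_lrdb, rec_expr, np.asarray(act_labels),
            cfg.target_type, top_n=cfg.top_n, min_votes=cfg.min_votes,
        )
        shortlist.table.to_csv(out / "shortlist.tsv", sep="\t", index=False)
        _emit("shortlist", out / "shortlist.tsv")
        timings["prioritization"] = time.time() - t0

    # ---- scoring ------------------------------------------------------------
    if cfg.stages.get("scoring", False):
        t0 = time.time()
        cc = CohortConfig(seed=cohort_seed)
        profiles, severity, ctruth = generate_cohort(cc)
        sc = score_cohort(profiles, ctruth.signature_genes)
        fit = ordered_probit(sc, severity)
        frame = pd.DataFrame(
            {"subject": sc.index, "ssgsea": sc.values,
             "severity": severity.loc[sc.index].values}
        )
        frame.to_csv(out / "severity_scores.tsv", sep="\t", index=False)
        (out / "probit.json").write_text(
            json.dumps(
                {
                    "beta": fit.beta,
                    "se_beta": fit.se_beta,
                    "p_one_sided": fit.p_one_sided,
                    "cutpoints": list(fit.cutpoints),
                    "n": fit.n,
                    "J": fit.J,
                },
                indent=2,
            )
        )
        _emit("severity_scores", out / "severity_scores.tsv")
        _emit("probit", out / "probit.json")
        timings["scoring"] = time.time() - t0

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": {
            "simulate": sim_seed,
            "niches": niche_seed,
            "resources": resource_seed,
            "cohort": cohort_seed,
        },
        "stages_run": [s for s in STAGE_ORDER if cfg.stages.get(s, False)],
        "outputs": {
            name: {"path": rel, "sha256": _sha256(out / rel)}
            for name, rel in sorted(outputs.items())
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log_lines = [f"cellcircuit {__version__} run, seed={cfg.seed}"]
    log_lines += [f"{k}: {v:.2f}s" for k, v in timings.items()]
    log_lines.append(f"total: {time.time() - t_start:.2f}s")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return manifest
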