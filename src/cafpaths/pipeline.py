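"""End-to-end orchestration: simulate/ingest -> prep -> cluster -> classify
-> origin -> trajectory, with a machine-readable run report.

A single top-level seed fans out to per-stage seeds by fixed offsets, so a
config plus seed regenerates every number in the report byte-for-byte.
Stage failures abort with the stage name and cause.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cluster_mod
from . import io_prep, origin, signatures, syndata, trajectory
from .panels import GeneSetPanel, default_panel
from .signatures import BM_MSC_LIKE, ICAF, MYCAF, PACAF, TR_MSCF

logger = logging.getLogger(__name__)

STAGES = ("simulate", "prep", "cluster", "classify", "origin", "trajectory")

#: per-stage seed offsets from the top-level seed
SEED_OFFSETS = {"simulate": 0, "prep": 1, "cluster": 2, "classify": 3,
                "trajectory": 4}


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def default_config(seed: int = 1) -> dict:
    """The default simulation-driven pipeline configuration."""
    sim = syndata.SimConfig().to_dict()
    sim.pop("seed")  # inherits the top-level seed unless set explicitly
    return {
        "seed": seed,
        "simulate": sim,
        "prep": {
            "min_genes_per_cell": 200, "min_cells_per_gene": 3,
            "coarse_k": 10, "step1_margin": 1.0, "step2_max_norm_expr": 0.25,
            "n_hvg": 2000, "n_pc": 20,
        },
        "cluster": {
            "k_min": 1, "k_max": 10, "drop_threshold": 0.10,
            "n_hvg": 2000, "n_pc": 20, "n_init": 10,
        },
        "classify": {
            "high_margin_sd": 0.5, "low_ceiling": 0.1, "alpha": 0.05,
            "resubcluster": True,
        },
        "origin": {"n_hvg": 2000, "delta": 0.05},
        "trajectory": {
            "root_population": TR_MSCF, "smooth_span": 0.3,
            "max_iter": 50, "tol": 1e-6,
        },
        "panel": None,
    }


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    config = default_config(seed=user.get("seed", 1))
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


@dataclass
class RunReport:
    """Headline quantities of one pipeline run."""

    fibroblast_fraction: float
    chosen_k: dict
    pacaf_fraction_of_cafs: float
    taxonomy: list = field(default_factory=list)
    origin_calls: list = field(default_factory=list)
    ordering_tests: list = field(default_factory=list)
    truth_metrics: dict = field(default_factory=dict)
    n_cells: int = 0
    n_fibroblasts: int = 0
    n_tumour_fibroblasts: int = 0
    config: dict = field(default_factory=dict)
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "fibroblast_fraction": self.fibroblast_fraction,
            "chosen_k": self.chosen_k,
            "paCAF_fraction_of_CAFs": self.pacaf_fraction_of_cafs,
            "taxonomy": self.taxonomy,
            "origin_calls": self.origin_calls,
            "ordering_tests": self.ordering_tests,
            "truth_metrics": self.truth_metrics,
            "n_cells": self.n_cells,
            "n_fibroblasts": self.n_fibroblasts,
            "n_tumour_fibroblasts": self.n_tumour_fibroblasts,
            "config": self.config,
            "seed": self.seed,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True,
                          default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def summarize_pacaf_fraction(taxonomy: pd.DataFrame,
                             cluster_ids: pd.Series) -> float:
    """Fraction of tumour fibroblast cells sitting in paCAF-labelled clusters."""
    tumour_clusters = taxonomy.index[taxonomy["tissue"] == "tumour"]
    if len(tumour_clusters) == 0:
        raise ValueError("no tumour fibroblast clusters")
    in_tumour = cluster_ids.isin(tumour_clusters)
    n_tumour = int(in_tumour.sum())
    if n_tumour == 0:
        raise ValueError("no tumour fibroblast cells")
    pacaf_clusters = taxonomy.index[(taxonomy["tissue"] == "tumour")
                                    & taxonomy["pacaf"]]
    n_pacaf = int(cluster_ids.isin(pacaf_clusters).sum())
    return n_pacaf / n_tumour


def _classify_stage(norm_fib, clustering, panel, params, seed):
    """Score sets and apply the full cluster taxonomy; returns the taxonomy
    table, the (possibly resubclustered) per-cell cluster ids and scores."""
    cluster_ids = clustering.assignments["cluster_id"]
    tissue_per_cell = norm_fib.obs["tissue"]
    cluster_tissue = tissue_per_cell.groupby(cluster_ids, observed=True).agg(
        lambda s: s.mode().iloc[0])
    scores = signatures.score_sets(norm_fib, cluster_ids, panel)

    tumour_clusters = [c for c in cluster_tissue.index if cluster_tissue[c] == "tumour"]
    normal_clusters = [c for c in cluster_tissue.index if cluster_tissue[c] == "normal"]
    bm_clusters = [c for c in cluster_tissue.index if cluster_tissue[c] == "bm"]
    if not normal_clusters:
        raise ValueError("no normal-tissue fibroblast clusters; the taxonomy "
                         "needs matched normal fibroblasts")
    if not tumour_clusters:
        raise ValueError("no tumour fibroblast clusters")

    pacaf_tab = signatures.call_pacaf(scores, tumour_clusters,
                                      high_margin_sd=params["high_margin_sd"])
    normal_tab = signatures.call_normal_taxonomy(
        scores, normal_clusters, high_margin_sd=params["high_margin_sd"],
        low_ceiling=params["low_ceiling"])

    # myCAF/iCAF subtyping runs per tumour sample (clusters are sample-scoped)
    sample_of_cluster = pd.Series(
        {c: c.split("|")[0] for c in cluster_tissue.index})
    final_ids = cluster_ids.copy()
    subtype_rows = []
    for sample in sorted({sample_of_cluster[c] for c in tumour_clusters}):
        pacaf_here = [c for c in tumour_clusters
                      if sample_of_cluster[c] == sample
                      and pacaf_tab.loc[c, "label"] == PACAF]
        if not pacaf_here:
            continue
        sub = signatures.subtype_pacaf(
            scores, final_ids, pacaf_here, alpha=params["alpha"],
            resubcluster=params.get("resubcluster", True),
            embedding=clustering.embedding, norm=norm_fib, seed=seed,
        )
        final_ids = sub.cluster_ids
        subtype_rows.append(sub.table)
    subtype_tab = (pd.concat(subtype_rows) if subtype_rows
                   else pd.DataFrame(columns=["mycaf_score", "icaf_score",
                                              "statistic", "p_value", "label"]))

    # assemble one taxonomy table over the final cluster ids
    final_tissue = tissue_per_cell.groupby(final_ids, observed=True).agg(
        lambda s: s.mode().iloc[0])
    rows = []
    for cid in final_tissue.index:
        tissue = final_tissue[cid]
        parent = cid.split("#")[0]
        if tissue == "bm":
            label, pacaf = BM_MSC_LIKE, False
        elif tissue == "normal":
            label, pacaf = normal_tab.loc[parent, "label"], False
        else:
            if parent in pacaf_tab.index and pacaf_tab.loc[parent, "label"] == PACAF:
                pacaf = True
                label = (subtype_tab.loc[cid, "label"]
                         if cid in subtype_tab.index else PACAF)
            else:
                pacaf = False
                label = signatures.NON_PACAF
        n_cells = int((final_ids == cid).sum())
        row = {"cluster_id": cid, "tissue": tissue, "label": label,
               "pacaf": pacaf, "n_cells": n_cells}
        for tab in (pacaf_tab, normal_tab):
            if parent in tab.index:
                row.update({k: float(v) for k, v in tab.loc[parent].items()
                            if k != "label"})
        if cid in subtype_tab.index:
            for k in ("mycaf_score", "icaf_score", "statistic", "p_value"):
                v = subtype_tab.loc[cid, k]
                row[k] = float(v) if pd.notna(v) else None
        rows.append(row)
    taxonomy = pd.DataFrame(rows).set_index("cluster_id")
    return taxonomy, final_ids, scores


def run_all(config: dict | None = None, out_dir=None, seed: int | None = None,
            truth: pd.DataFrame | None = None,
            counts=None) -> RunReport:
    """Run the full pipeline from a config.

    ``counts`` (an AnnData) may be passed directly; otherwise the config's
    ``simulate`` block generates the dataset (or ``input.dir`` is read as a
    Matrix Market triplet). With ``out_dir`` set, every stage's tables and
    the report are written there.
    """
    config = config or default_config()
    if seed is not None:
        config = {**config, "seed": seed}
    top_seed = int(config.get("seed", 1))
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def _write(df: pd.DataFrame, name: str, **kw):
        if out is not None:
            df.to_csv(out / name, sep="\t", **kw)

    panel = (GeneSetPanel.from_yaml(config["panel"]) if config.get("panel")
             else default_panel())

    stage = "simulate"
    try:
        if counts is not None:
            adata = counts
        elif "input" in config and config["input"]:
            adata = io_prep.read_mtx_triplet(config["input"]["dir"])
        else:
            sim_cfg = syndata.SimConfig.from_dict(
                {**config["simulate"],
                 "seed": config["simulate"].get("seed", top_seed)})
            adata, truth = syndata.simulate_dataset(sim_cfg)
            if out is not None:
                io_prep.write_mtx_triplet(adata, out / "sim")
                syndata.write_truth(truth, out / "sim" / "truth.tsv")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "prep"
    try:
        p = config["prep"]
        adata = io_prep.qc_filter(adata, p["min_genes_per_cell"],
                                  p["min_cells_per_gene"])
        norm = io_prep.normalize(adata)
        calls = io_prep.identify_fibroblasts(
            norm, panel=panel, coarse_k=p["coarse_k"],
            step1_margin=p["step1_margin"],
            step2_max_norm_expr=p["step2_max_norm_expr"],
            n_hvg=p["n_hvg"], n_pc=p["n_pc"],
            random_state=top_seed + SEED_OFFSETS["prep"],
        )
        fib_mask = calls.fibroblast_mask
        n_cells = norm.n_obs
        n_fib = int(fib_mask.sum())
        fibroblast_fraction = n_fib / n_cells
        if n_fib == 0:
            raise ValueError("no cells called fibroblast")
        norm_fib = norm[fib_mask.to_numpy()].copy()
        _write(calls.to_frame(), "fibroblast_calls.tsv", index_label="cell_id")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "cluster"
    try:
        c = config["cluster"]
        clustering = cluster_mod.cluster_fibroblasts(
            norm_fib, k_min=c["k_min"], k_max=c["k_max"],
            drop_threshold=c["drop_threshold"], n_hvg=c["n_hvg"],
            n_pc=c["n_pc"], n_init=c["n_init"],
            seed=top_seed + SEED_OFFSETS["cluster"],
        )
        _write(clustering.assignments, "clusters.tsv", index_label="cell_id")
        sse_rows = [(s, k, v) for s, curve in clustering.sse_curves.items()
                    for k, v in sorted(curve.items())]
        _write(pd.DataFrame(sse_rows, columns=["sample_id", "k", "sse"]),
               "sse_curves.tsv", index=False)
        _write(clustering.embedding, "embedding.tsv", index_label="cell_id")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "classify"
    try:
        taxonomy, final_ids, scores = _classify_stage(
            norm_fib, clustering, panel, config["classify"],
            seed=top_seed + SEED_OFFSETS["classify"],
        )
        pacaf_fraction = summarize_pacaf_fraction(taxonomy, final_ids)
        n_tumour_fib = int(final_ids.isin(
            taxonomy.index[taxonomy["tissue"] == "tumour"]).sum())
        _write(taxonomy, "taxonomy.tsv")
        _write(scores.per_cluster, "signature_scores.tsv")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "origin"
    try:
        o = config["origin"]
        cluster_tissue = taxonomy["tissue"]
        origin_map = origin.trace_origins(
            norm_fib, final_ids, cluster_tissue,
            n_hvg=o["n_hvg"], delta=o["delta"],
        )
        _write(origin_map.rho, "origin_map.tsv", index_label="tumour_cluster")
        _write(origin_map.calls, "origin_calls.tsv")
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "trajectory"
    try:
        t = config["trajectory"]
        label_of_cluster = taxonomy["label"]
        cell_labels = final_ids.map(label_of_cluster)
        wanted = [TR_MSCF, ICAF, MYCAF, BM_MSC_LIKE]
        traj_mask = cell_labels.isin(wanted)
        traj_cells = cell_labels.index[traj_mask]
        emb = clustering.embedding.loc[traj_cells]
        if (cell_labels == BM_MSC_LIKE).any():
            background = norm_fib.var_names[
                ~norm_fib.var_names.isin(
                    [g for s in panel.sets.values() for g in s])]
            aligned = trajectory.align_background_shift(
                norm_fib[traj_mask.to_numpy()].copy(),
                norm_fib.obs["tissue"][traj_mask.to_numpy()],
                background, reference_batch="normal")
            emb_pca = cluster_mod.embed_pca(
                aligned, n_hvg=config["cluster"]["n_hvg"],
                n_pc=config["cluster"]["n_pc"],
                random_state=top_seed + SEED_OFFSETS["trajectory"])
            emb = pd.DataFrame(emb_pca.coords, index=traj_cells)
        curve = trajectory.PrincipalCurve(
            smooth_span=t["smooth_span"], max_iter=t["max_iter"], tol=t["tol"],
            random_state=top_seed + SEED_OFFSETS["trajectory"],
        ).fit(emb.to_numpy())
        result = trajectory.assign_pseudotime(
            curve, emb, cell_labels.loc[traj_cells], t["root_population"])
        pairs = [(MYCAF, ICAF), (ICAF, TR_MSCF)]
        if (result.labels == BM_MSC_LIKE).any():
            pairs.append((TR_MSCF, BM_MSC_LIKE))
        counts_by_label = result.labels.value_counts()
        for a, b in pairs:
            if counts_by_label.get(a, 0) >= 3 and counts_by_label.get(b, 0) >= 3:
                trajectory.test_ordering(result, a, b)
        pt = pd.DataFrame({"pseudotime": result.pseudotime,
                           "label": result.labels})
        _write(pt, "pseudotime.tsv", index_label="cell_id")
        _write(pd.DataFrame(result.curve_points), "curve.tsv", index=False)
        _write(result.ordering_tests, "ordering_tests.tsv", index=False)
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, e) from e

    truth_metrics = {}
    if truth is not None:
        truth = truth.reindex(norm.obs_names)
        true_fib = (truth["major_type"] == "fibroblast") | (
            truth["major_type"] == "bm_msc")
        called = fib_mask.to_numpy()
        tp = int((called & true_fib.to_numpy()).sum())
        truth_metrics["fibroblast_recall"] = tp / max(int(true_fib.sum()), 1)
        truth_metrics["fibroblast_precision"] = tp / max(int(called.sum()), 1)
        from sklearn.metrics import adjusted_rand_score
        common = final_ids.index.intersection(
            truth.index[true_fib & truth.index.isin(final_ids.index)])
        if len(common):
            truth_metrics["cluster_ari"] = float(adjusted_rand_score(
                truth.loc[common, "fib_subtype"], final_ids.loc[common]))
        t_true = truth["latent_pseudotime"].reindex(result.pseudotime.index)
        on_cont = t_true.notna().to_numpy()
        if on_cont.sum() >= 3:
            from .stats import spearman_rho
            truth_metrics["pseudotime_spearman"] = spearman_rho(
                result.pseudotime.to_numpy()[on_cont],
                t_true.to_numpy()[on_cont])

    report = RunReport(
        fibroblast_fraction=float(fibroblast_fraction),
        chosen_k={str(k): int(v) for k, v in clustering.chosen_k.items()},
        pacaf_fraction_of_cafs=float(pacaf_fraction),
        taxonomy=json.loads(taxonomy.reset_index().to_json(orient="records")),
        origin_calls=json.loads(
            origin_map.calls.reset_index().to_json(orient="records")),
        ordering_tests=json.loads(
            result.ordering_tests.to_json(orient="records")),
        truth_metrics=truth_metrics,
        n_cells=int(n_cells),
        n_fibroblasts=int(n_fib),
        n_tumour_fibroblasts=int(n_tumour_fib),
        config=config,
        seed=top_seed,
    )
    if out is not None:
        (out / "report.json").write_text(report.to_json())
        flat = {
            "fibroblast_fraction": report.fibroblast_fraction,
            "paCAF_fraction_of_CAFs": report.pacaf_fraction_of_cafs,
            "n_cells": report.n_cells,
            "n_fibroblasts": report.n_fibroblasts,
            **{f"chosen_k[{k}]": v for k, v in report.chosen_k.items()},
        }
        pd.Series(flat, name="value").to_csv(out / "report.tsv", sep="\t",
                                             index_label="quantity")
    return report
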