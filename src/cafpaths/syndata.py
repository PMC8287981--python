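"""Synthetic mixed-tissue scRNA-seq generator with planted fibroblast structure.

The generator emulates the kind of dataset the downstream pipeline assumes:
a tumour/normal pair of tissues in which fibroblasts are a small minority
among epithelial, immune and endothelial cells, the tumour fibroblasts
split into non-paCAF, iCAF and myCAF subtypes, the normal fibroblasts into
tr-RF and tr-MSCF, and the tr-MSCF -> iCAF -> myCAF cells lie on a latent
differentiation continuum. Optionally a bone-marrow MSC population sits at
the root of that continuum.

Counts are negative binomial with a per-gene mean that is a baseline for
background genes, a near-zero off-state for marker genes of inactive
programs, and baseline x fold-change^w for active programs, where the
activity w of the continuum programs (BM-MSC, iCAF, myCAF) is a logistic
function of the cell's latent pseudotime:

* iCAF program: decreasing logistic (high at the root),
* myCAF program: increasing logistic (high at the terminus),
* BM-MSC program: highest near pseudotime 0, floored at half activity in
  paCAFs (CAFs retain elevated MSC-marker expression relative to resting
  fibroblasts).

All randomness flows from a single ``numpy`` Generator seeded once per
call; draws are consumed in a fixed, documented order (cell types, sample
assignment, pseudotimes, continuum noise, library factors, counts), so
identical configs and seeds yield byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml
from anndata import AnnData

from .panels import CANONICAL_MARKERS

logger = logging.getLogger(__name__)

#: split of non-fibroblast cells across the majority lineages
MAJOR_SPLIT = {"epithelial": 0.5, "immune": 0.3, "endothelial": 0.2}

#: latent pseudotime window sampled uniformly per subtype
PSEUDOTIME_WINDOWS = {
    "tr_MSCF": (0.02, 0.30),
    "iCAF": (0.38, 0.62),
    "myCAF": (0.70, 0.98),
    "bm_msc": (0.00, 0.12),
}

#: programs whose activity varies along the continuum, with logistic centres
CONTINUUM_CENTRES = {"bm_msc": 0.34, "icaf": 0.66, "mycaf": 0.66}

#: program name -> (canonical seed symbols, padding prefix)
PROGRAM_SEEDS = {
    "fibroblast": (CANONICAL_MARKERS["fibroblast_markers"], "FIB"),
    "epithelial": (CANONICAL_MARKERS["epithelial_markers"], "EPI"),
    "immune": (CANONICAL_MARKERS["immune_markers"], "IMM"),
    "endothelial": (CANONICAL_MARKERS["endothelial_markers"], "END"),
    "caf_related": (CANONICAL_MARKERS["caf_related"], "CAFR"),
    "bm_msc": (CANONICAL_MARKERS["bm_msc_markers"], "MSC"),
    "mycaf": (CANONICAL_MARKERS["mycaf_signature"], "MYC"),
    "icaf": (CANONICAL_MARKERS["icaf_signature"], "ICF"),
}

FIB_SUBTYPES = ("tr_RF", "tr_MSCF", "non_paCAF", "iCAF", "myCAF")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class SimConfig:
    """Study conditions for one simulated tumour/normal dataset.

    Defaults place the dataset inside the regimes the analysis expects:
    ~5,000 cells, fibroblasts just under 10% of cells, paCAFs (iCAF+myCAF)
    65% of CAFs, two samples per tissue.
    """

    n_cells_tumour: int = 2500
    n_cells_normal: int = 2500
    fibroblast_fraction: float = 0.08
    caf_composition: dict = field(
        default_factory=lambda: {"non_paCAF": 0.35, "iCAF": 0.35, "myCAF": 0.30}
    )
    nf_composition: dict = field(
        default_factory=lambda: {"tr_RF": 0.60, "tr_MSCF": 0.40}
    )
    include_bm_msc: bool = False
    n_bm_msc: int = 300
    n_samples_per_tissue: int = 1
    n_genes: int = 2000
    n_marker_genes_per_program: int = 25
    baseline_mean: float = 0.3
    #: mean of a marker gene in cells whose program is off (lineage leakage)
    offstate_mean: float = 0.001
    marker_fold_change: float = 8.0
    nb_dispersion: float = 0.4
    library_size_lognormal_sigma: float = 0.2
    continuum_noise_sd: float = 0.2
    logistic_steepness: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.fibroblast_fraction < 1.0:
            raise ValueError("fibroblast_fraction must be in (0, 1)")
        for name, comp, keys in (
            ("caf_composition", self.caf_composition, {"non_paCAF", "iCAF", "myCAF"}),
            ("nf_composition", self.nf_composition, {"tr_RF", "tr_MSCF"}),
        ):
            if set(comp) != keys:
                raise ValueError(f"{name} must have keys {sorted(keys)}")
            if any(not 0.0 < p < 1.0 for p in comp.values()):
                raise ValueError(f"{name} proportions must be in (0, 1)")
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {sum(comp.values())})")
        if self.marker_fold_change < 1.0:
            raise ValueError("marker_fold_change must be >= 1")
        if self.baseline_mean <= 0 or self.offstate_mean <= 0:
            raise ValueError("baseline_mean and offstate_mean must be positive")
        if self.nb_dispersion < 0 or self.library_size_lognormal_sigma < 0:
            raise ValueError("dispersion and library sigma must be non-negative")
        if self.continuum_noise_sd < 0:
            raise ValueError("continuum_noise_sd must be non-negative")
        catalog = build_gene_catalog(self.n_marker_genes_per_program)
        n_markers = sum(len(v) for v in catalog.values())
        if self.n_genes < n_markers:
            raise ValueError(
                f"n_genes={self.n_genes} smaller than total marker genes ({n_markers})"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "SimConfig":
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def build_gene_catalog(n_per_program: int) -> dict[str, list[str]]:
    """Disjoint marker-program gene lists (canonical seeds plus padding).

    The ``activation`` program is the single gene *PRRX1* and ``hsc`` is
    {PTPRC, CD34} regardless of ``n_per_program``; the remaining programs
    are padded to ``n_per_program`` symbols.
    """
    catalog: dict[str, list[str]] = {}
    for prog, (seeds, prefix) in PROGRAM_SEEDS.items():
        genes = list(seeds[:n_per_program])
        i = 1
        while len(genes) < n_per_program:
            genes.append(f"{prefix}{i:03d}")
            i += 1
        catalog[prog] = genes
    catalog["activation"] = list(CANONICAL_MARKERS["activation"])
    catalog["hsc"] = list(CANONICAL_MARKERS["hsc_markers"])
    seen: set[str] = set()
    for prog, genes in catalog.items():
        dup = seen & set(genes)
        if dup:
            raise ValueError(f"marker programs must be disjoint; {prog} repeats {dup}")
        seen |= set(genes)
    return catalog


def _gene_table(config: SimConfig) -> tuple[pd.Index, dict[str, np.ndarray], pd.Series]:
    """Gene index, program -> column positions, and per-gene program label."""
    catalog = build_gene_catalog(config.n_marker_genes_per_program)
    symbols: list[str] = []
    programs: list[str] = []
    for prog, genes in catalog.items():
        symbols.extend(genes)
        programs.extend([prog] * len(genes))
    n_bg = config.n_genes - len(symbols)
    symbols.extend(f"GENE{i:04d}" for i in range(1, n_bg + 1))
    programs.extend(["background"] * n_bg)
    genes = pd.Index(symbols, name="gene")
    prog_series = pd.Series(programs, index=genes, name="program")
    cols = {p: np.flatnonzero(prog_series.to_numpy() == p) for p in catalog}
    return genes, cols, prog_series


def _draw_cells(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-cell tissue, major type, fibroblast subtype and sample.

    Types are multinomial draws (so the realized fibroblast fraction is a
    binomial realization of the configured one), samples are assigned
    uniformly within tissue.
    """
    rows = []
    for tissue, n in (("tumour", config.n_cells_tumour), ("normal", config.n_cells_normal)):
        majors = list(MAJOR_SPLIT) + ["fibroblast"]
        probs = [p * (1 - config.fibroblast_fraction) for p in MAJOR_SPLIT.values()]
        probs.append(config.fibroblast_fraction)
        major = rng.choice(majors, size=n, p=probs)
        comp = config.caf_composition if tissue == "tumour" else config.nf_composition
        subtype = np.full(n, "none", dtype=object)
        fib = major == "fibroblast"
        subtype[fib] = rng.choice(list(comp), size=int(fib.sum()), p=list(comp.values()))
        sample = rng.integers(0, config.n_samples_per_tissue, size=n)
        prefix = "T" if tissue == "tumour" else "N"
        rows.append(pd.DataFrame({
            "tissue": tissue,
            "major_type": major,
            "fib_subtype": subtype,
            "sample_id": [f"{prefix}{s + 1}" for s in sample],
        }))
    if config.include_bm_msc:
        rows.append(pd.DataFrame({
            "tissue": "bm",
            "major_type": "bm_msc",
            "fib_subtype": "none",
            "sample_id": "BM1",
        }, index=range(config.n_bm_msc)))
    cells = pd.concat(rows, ignore_index=True)
    cells.index = pd.Index([f"c{i:05d}" for i in range(len(cells))], name="cell_id")
    return cells


def _draw_pseudotime(cells: pd.DataFrame, rng: np.random.Generator) -> pd.Series:
    t = pd.Series(np.nan, index=cells.index, name="latent_pseudotime")
    for subtype, (lo, hi) in PSEUDOTIME_WINDOWS.items():
        mask = (cells["fib_subtype"] == subtype) | (
            subtype == "bm_msc") & (cells["major_type"] == "bm_msc")
        mask = mask.to_numpy()
        t.iloc[np.flatnonzero(mask)] = rng.uniform(lo, hi, size=int(mask.sum()))
    return t


def _program_activity(config: SimConfig, truth: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-cell activity weight w in [0, 1] for every marker program."""
    n = len(truth)
    major = truth["major_type"].to_numpy()
    subtype = truth["fib_subtype"].to_numpy()
    t = truth["latent_pseudotime"].to_numpy(dtype=float)
    on_continuum = ~np.isnan(t)
    s = config.logistic_steepness

    w = {p: np.zeros(n) for p in build_gene_catalog(1)}
    for lineage in ("epithelial", "immune", "endothelial"):
        w[lineage][major == lineage] = 1.0
    w["hsc"][major == "immune"] = 1.0
    w["fibroblast"][(major == "fibroblast") | (major == "bm_msc")] = 1.0
    pacaf = np.isin(subtype, ("iCAF", "myCAF"))
    w["activation"][pacaf] = 1.0
    w["caf_related"][pacaf] = 1.0
    tc = t[on_continuum]
    w["bm_msc"][on_continuum] = 0.5 + 0.5 * _sigmoid(s * (CONTINUUM_CENTRES["bm_msc"] - tc))
    w["icaf"][on_continuum] = _sigmoid(s * (CONTINUUM_CENTRES["icaf"] - tc))
    w["mycaf"][on_continuum] = _sigmoid(s * (tc - CONTINUUM_CENTRES["mycaf"]))
    return w


def expected_log_means(config: SimConfig, truth: pd.DataFrame) -> tuple[np.ndarray, pd.Index]:
    """Deterministic per-cell x gene log mean expression (no noise terms).

    This is the model's backbone: the expected log NB mean with the
    continuum noise, library-size factor and count sampling all switched
    off. Used to study the noiseless limit of downstream inference.
    """
    genes, cols, _ = _gene_table(config)
    log_mu = _log_mean_matrix(config, truth, cols, len(genes), rng=None)
    return log_mu, genes


def _log_mean_matrix(config, truth, cols, n_genes, rng) -> np.ndarray:
    """log NB mean per cell x gene, before the library-size factor.

    When ``rng`` is given, adds N(0, continuum_noise_sd) noise to the
    marker-program log-mean of continuum cells (one draw per cell and
    continuum program, consumed in fixed program order).
    """
    n = len(truth)
    log_mu = np.full((n, n_genes), np.log(config.baseline_mean))
    marker_cols = np.concatenate([c for c in cols.values()])
    log_mu[:, marker_cols] = np.log(config.offstate_mean)
    log_fc = np.log(config.marker_fold_change)
    log_base = np.log(config.baseline_mean)
    on_continuum = ~np.isnan(truth["latent_pseudotime"].to_numpy(dtype=float))
    activity = _program_activity(config, truth)
    for prog in sorted(activity):
        w = activity[prog]
        active = w > 1e-12
        if not active.any():
            continue
        vals = log_base + w[active, None] * log_fc
        if rng is not None and prog in CONTINUUM_CENTRES and config.continuum_noise_sd > 0:
            noise = np.zeros(n)
            noise[on_continuum] = rng.normal(0.0, config.continuum_noise_sd,
                                             size=int(on_continuum.sum()))
            vals = vals + noise[active, None]
        log_mu[np.ix_(active, cols[prog])] = vals
    return log_mu


def simulate_dataset(config: SimConfig | None = None) -> tuple[AnnData, pd.DataFrame]:
    """Simulate counts and ground truth for one tumour/normal dataset.

    Returns
    -------
    adata
        ``AnnData`` with sparse integer counts (cells x genes), per-cell
        ``sample_id`` and ``tissue`` in ``.obs`` and the planted program of
        each gene in ``.var["program"]``.
    truth
        Per-cell table with ``tissue``, ``major_type``, ``fib_subtype``,
        ``latent_pseudotime`` (NaN off the continuum) and ``sample_id``.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, cols, prog_series = _gene_table(config)

    cells = _draw_cells(config, rng)                      # draw 1-2
    cells["latent_pseudotime"] = _draw_pseudotime(cells, rng)  # draw 3
    log_mu = _log_mean_matrix(config, cells, cols, len(genes), rng)  # draw 4
    lib = np.exp(rng.normal(0.0, config.library_size_lognormal_sigma,
                            size=len(cells)))            # draw 5
    mu = np.exp(log_mu) * lib[:, None]
    phi = config.nb_dispersion
    if phi > 1e-12:  # gamma-Poisson mixture: var = mu + phi * mu^2
        lam = rng.gamma(1.0 / phi, mu * phi)             # draw 6a
    else:
        lam = mu
    counts = rng.poisson(lam)                            # draw 6b

    adata = AnnData(
        X=sp.csr_matrix(counts.astype(np.int64)),
        obs=cells[["sample_id", "tissue"]].copy(),
        var=pd.DataFrame({"program": prog_series.to_numpy()}, index=genes),
    )
    adata.uns["sim_config"] = config.to_dict()
    truth = cells[["tissue", "major_type", "fib_subtype", "latent_pseudotime",
                   "sample_id"]].copy()
    return adata, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write the ground-truth table as TSV (lossless round-trip)."""
    truth.to_csv(path, sep="\t", index=True, index_label="cell_id")


def read_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", index_col="cell_id")
    if len(truth) and "latent_pseudotime" in truth:
        truth["latent_pseudotime"] = truth["latent_pseudotime"].astype(float)
    return truth
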