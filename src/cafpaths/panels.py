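"""Marker gene-set panels.

A :class:`GeneSetPanel` bundles the named marker sets the classification
stages consume: a pan-fibroblast set and three lineage exclusion sets
(epithelial / immune / endothelial) for the two-step fibroblast screen,
the PRRX1 activation marker and CAF-related genes for the paCAF call,
BM-MSC and hematopoietic (HSC) sets for the tr-MSCF / tr-RF split, and
the myofibroblastic (ACTA2/TAGLN) vs inflammatory (PDGFRA/CFD/CXCL12)
CAF signatures.

Gene identity is matched by exact symbol, optionally routed through a
synonym map; panel genes absent from a matrix are logged and ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

REQUIRED_SETS = (
    "fibroblast_markers",
    "epithelial_markers",
    "immune_markers",
    "endothelial_markers",
    "activation",
    "caf_related",
    "bm_msc_markers",
    "hsc_markers",
    "mycaf_signature",
    "icaf_signature",
)

#: Exclusion sets used by step 2 of the fibroblast screen.
EXCLUSION_SETS = ("epithelial_markers", "immune_markers", "endothelial_markers")

#: Canonical seed symbols per set.  These are real, widely used markers;
#: the synthetic generator plants the same symbols so that default panels
#: and default simulations agree without any file plumbing.
CANONICAL_MARKERS: dict[str, list[str]] = {
    "fibroblast_markers": ["COL1A1", "COL1A2", "COL3A1", "DCN", "LUM"],
    "epithelial_markers": ["EPCAM", "KRT8", "KRT18", "KRT19", "CDH1"],
    "immune_markers": ["CD3D", "CD3E", "CD2", "LYZ", "CD79A"],
    "endothelial_markers": ["PECAM1", "VWF", "CDH5", "CLDN5", "FLT1"],
    "activation": ["PRRX1"],
    "caf_related": ["FAP", "PDPN", "POSTN", "TNC", "COL11A1"],
    "bm_msc_markers": ["ENG", "NT5E", "THY1", "PDGFRB", "CD44"],
    "hsc_markers": ["PTPRC", "CD34"],
    "mycaf_signature": ["ACTA2", "TAGLN", "MYH11", "MYL9", "TPM2"],
    "icaf_signature": ["PDGFRA", "CFD", "CXCL12", "IL6", "CXCL14"],
}


@dataclass
class GeneSetPanel:
    """Named marker gene sets plus the thresholds the taxonomy rules use.

    Parameters
    ----------
    sets
        Mapping of set name to gene-symbol list. Must contain every name in
        :data:`REQUIRED_SETS`, each non-empty; the myCAF and iCAF signatures
        must be disjoint.
    high_margin_sd
        How many across-cluster standard deviations above the mean a cluster
        score must lie to count as "high" (paCAF and tr-MSCF calls).
    low_ceiling
        Maximum HSC-marker score compatible with a tr-MSCF call.
    synonyms
        Optional symbol -> canonical-symbol map applied before matching.
    """

    sets: dict[str, list[str]]
    high_margin_sd: float = 0.5
    low_ceiling: float = 0.1
    synonyms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [s for s in REQUIRED_SETS if s not in self.sets]
        if missing:
            raise ValueError(f"panel is missing required sets: {missing}")
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"panel set {name!r} is empty")
        overlap = set(self.sets["mycaf_signature"]) & set(self.sets["icaf_signature"])
        if overlap:
            raise ValueError(
                f"myCAF and iCAF signatures must be disjoint; shared: {sorted(overlap)}"
            )

    def match(self, genes: pd.Index | list[str]) -> dict[str, np.ndarray]:
        """Map each set to integer positions of its genes in ``genes``.

        Unmatched symbols are logged and dropped; a set that matches nothing
        maps to an empty array (callers flag the score as undefined).
        """
        index = pd.Index(genes)
        out: dict[str, np.ndarray] = {}
        for name, symbols in self.sets.items():
            resolved = [self.synonyms.get(g, g) for g in symbols]
            pos = index.get_indexer(resolved)
            unmatched = [g for g, p in zip(resolved, pos) if p < 0]
            if unmatched:
                logger.warning(
                    "panel set %r: %d/%d genes not in matrix (%s)",
                    name, len(unmatched), len(symbols), ", ".join(unmatched[:5]),
                )
            out[name] = pos[pos >= 0].astype(int)
        return out

    def to_yaml(self, path) -> None:
        payload = {
            "sets": {k: list(v) for k, v in self.sets.items()},
            "high_margin_sd": float(self.high_margin_sd),
            "low_ceiling": float(self.low_ceiling),
        }
        if self.synonyms:
            payload["synonyms"] = dict(self.synonyms)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneSetPanel":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            sets={k: list(v) for k, v in payload["sets"].items()},
            high_margin_sd=float(payload.get("high_margin_sd", 0.5)),
            low_ceiling=float(payload.get("low_ceiling", 0.1)),
            synonyms=dict(payload.get("synonyms", {})),
        )


def default_panel() -> GeneSetPanel:
    """Panel of canonical marker symbols matching the synthetic generator."""
    return GeneSetPanel(sets={k: list(v) for k, v in CANONICAL_MARKERS.items()})
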