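"""Data model, file I/O and configuration.

Input formats are two documented TSV dialects: a genotype table
(``snp_id  chrom  pos  marker_type`` followed by one integer column per
individual, missing cells blank or ``NA``) and a long-format phenotype
table (``individual_id  trait  time  value``).  Networks are written both
as an edge-list TSV and as a JSON document; either round-trips exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("idopnet")

MISSING = -9  # sentinel for a missing genotype code

__all__ = [
    "MISSING",
    "SnpRecord",
    "GenotypeMatrix",
    "PhenotypePanel",
    "AnalysisConfig",
    "NetworkNode",
    "NetworkEdge",
    "IdopNetwork",
    "read_genotypes",
    "read_phenotypes",
    "write_network",
    "read_network",
    "write_curve_table",
    "load_config",
]


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class SnpRecord:
    snp_id: str
    chromosome: str
    position: int
    marker_type: str  # "testcross" (codes 0/1) or "intercross" (codes 0/1/2)
    allele_labels: Optional[str] = None


@dataclass
class GenotypeMatrix:
    """SNP-by-individual integer genotype codes for a mapping population."""

    snps: List[SnpRecord]
    individuals: List[str]
    codes: np.ndarray  # int matrix, MISSING for absent calls

    @property
    def snp_ids(self) -> List[str]:
        return [s.snp_id for s in self.snps]

    def n_classes(self, i: int) -> int:
        return 2 if self.snps[i].marker_type == "testcross" else 3

    def row(self, snp_id: str) -> np.ndarray:
        return self.codes[self.snp_ids.index(snp_id)]


def read_genotypes(path) -> GenotypeMatrix:
    """Load and validate a genotype TSV.

    Monomorphic SNPs (fewer than two distinct observed codes) are dropped
    with a warning.  A code of 2 on a testcross SNP, a duplicate snp_id, or
    a code outside the marker type's range is a load error naming the cell.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta_cols = ["snp_id", "chrom", "pos", "marker_type"]
    for c in meta_cols:
        if c not in df.columns:
            raise ValueError(f"genotype file missing required column '{c}'")
    individuals = [c for c in df.columns if c not in meta_cols]
    if df["snp_id"].duplicated().any():
        dups = df.loc[df["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValueError(f"duplicate snp_id(s): {dups}")

    snps: List[SnpRecord] = []
    rows: List[np.ndarray] = []
    for _, rec in df.iterrows():
        mtype = rec["marker_type"]
        if mtype not in ("testcross", "intercross"):
            raise ValueError(f"{rec['snp_id']}: unknown marker_type '{mtype}'")
        codes = np.full(len(individuals), MISSING, dtype=int)
        valid = {0, 1} if mtype == "testcross" else {0, 1, 2}
        for j, ind in enumerate(individuals):
            cell = rec[ind]
            if pd.isna(cell) or cell in ("", "NA", "."):
                continue
            code = int(cell)
            if code not in valid:
                raise ValueError(
                    f"invalid code {code} for {mtype} SNP {rec['snp_id']} "
                    f"at individual {ind}"
                )
            codes[j] = code
        observed = np.unique(codes[codes != MISSING])
        if observed.size < 2:
            logger.warning("dropping monomorphic SNP %s", rec["snp_id"])
            continue
        snps.append(
            SnpRecord(
                snp_id=rec["snp_id"],
                chromosome=rec["chrom"],
                position=int(rec["pos"]),
                marker_type=mtype,
            )
        )
        rows.append(codes)
    codes_mat = np.vstack(rows) if rows else np.empty((0, len(individuals)), dtype=int)
    return GenotypeMatrix(snps=snps, individuals=individuals, codes=codes_mat)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypePanel:
    """Longitudinal phenotypes on a common per-trait measurement grid.

    ``values[trait]`` is an (n_individuals, T_trait) matrix aligned with
    ``individuals`` and ``times[trait]``; missing observations are NaN.
    """

    individuals: List[str]
    times: Dict[str, np.ndarray]
    values: Dict[str, np.ndarray]

    @property
    def traits(self) -> List[str]:
        return list(self.values)


def read_phenotypes(path) -> PhenotypePanel:
    """Load a long-format phenotype TSV and pivot onto per-trait grids."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str, "trait": str})
    for c in ("individual_id", "trait", "time", "value"):
        if c not in df.columns:
            raise ValueError(f"phenotype file missing required column '{c}'")
    if (df["value"].dropna() < 0).any():
        bad = df.loc[df["value"] < 0].iloc[0]
        raise ValueError(
            f"negative phenotype value for ({bad['individual_id']}, "
            f"{bad['trait']}, t={bad['time']})"
        )
    dup = df.duplicated(subset=["individual_id", "trait", "time"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise ValueError(
            f"duplicate record ({bad['individual_id']}, {bad['trait']}, "
            f"t={bad['time']})"
        )
    for (ind, trait), grp in df.groupby(["individual_id", "trait"], sort=False):
        t = grp["time"].to_numpy()
        if not np.all(np.diff(t) > 0):
            raise ValueError(
                f"times are not strictly increasing for series ({ind}, {trait})"
            )
    individuals = list(dict.fromkeys(df["individual_id"]))
    times: Dict[str, np.ndarray] = {}
    values: Dict[str, np.ndarray] = {}
    for trait, grp in df.groupby("trait", sort=False):
        grid = np.array(sorted(grp["time"].unique()), dtype=float)
        if grid.size < 3:
            raise ValueError(f"trait {trait}: need >= 3 time points, got {grid.size}")
        mat = np.full((len(individuals), grid.size), np.nan)
        pos = {t: j for j, t in enumerate(grid)}
        idx = {i: k for k, i in enumerate(individuals)}
        for _, rec in grp.iterrows():
            mat[idx[rec["individual_id"]], pos[rec["time"]]] = rec["value"]
        times[trait] = grid
        values[trait] = mat
    return PhenotypePanel(individuals=individuals, times=times, values=values)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Tunable parameters shared across the pipeline.

    ``lambda_grid`` holds multiplicative fractions of the data-dependent
    lambda_max (the smallest penalty zeroing every regulator group), sorted
    ascending, so one grid is reusable across response scales.
    """

    lop_order_independent: int = 2
    lop_order_dependent: int = 0
    independent_form: str = "logistic"  # or "lop"
    rss_floor_rel: float = 1e-5
    noise_floor_mult: float = 3.5
    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(1e-2, 1.0, 10)
    )
    k_range: Sequence[int] = (1, 2, 3, 4)
    em_tol: float = 1e-5
    em_max_iter: int = 100
    n_permutations: int = 100
    alpha: float = 0.05
    unit_size: int = 20
    seed: int = 0
    criterion: str = "BIC"

    def __post_init__(self) -> None:
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        if np.any(self.lambda_grid <= 0):
            raise ValueError("lambda_grid entries must be positive")
        if np.any(np.diff(self.lambda_grid) < 0):
            raise ValueError("lambda_grid must be sorted ascending")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("em_tol", "em_max_iter", "n_permutations", "unit_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lop_order_independent < 1:
            raise ValueError("lop_order_independent must be >= 1")
        if self.lop_order_dependent < 0:
            raise ValueError("lop_order_dependent must be >= 0")
        if self.criterion not in ("AIC", "BIC"):
            raise ValueError("criterion must be 'AIC' or 'BIC'")
        if self.independent_form not in ("logistic", "lop"):
            raise ValueError("independent_form must be 'logistic' or 'lop'")


def load_config(path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return AnalysisConfig(**raw)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkNode:
    id: str
    layer: str  # trait layer
    module: str = ""


@dataclass(frozen=True)
class NetworkEdge:
    source: str
    target: str
    layer_source: str
    layer_target: str
    edge_type: str  # "epistatic" or "pleiotropic"
    sign: int
    weight: float


@dataclass
class IdopNetwork:
    """Signed, weighted, directed epistatic-pleiotropic network."""

    nodes: List[NetworkNode] = field(default_factory=list)
    edges: List[NetworkEdge] = field(default_factory=list)

    def validate(self) -> None:
        ids = {(n.id, n.layer) for n in self.nodes}
        seen = set()
        for e in self.edges:
            if e.weight < 0:
                raise ValueError(f"negative edge weight on {e.source}->{e.target}")
            if e.edge_type == "epistatic" and e.source == e.target:
                raise ValueError(f"epistatic self-loop on {e.source}")
            if e.edge_type == "pleiotropic":
                if e.layer_source == e.layer_target or e.source != e.target:
                    raise ValueError(
                        "pleiotropic edges must connect the same SNP across "
                        f"distinct layers: {e}"
                    )
            key = (e.source, e.target, e.layer_source, e.layer_target, e.edge_type)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)
            if (e.source, e.layer_source) not in ids or (e.target, e.layer_target) not in ids:
                raise ValueError(f"edge {e} references unknown node")

    def edge_set(self):
        """Hashable summary {(source, layer_s, target, layer_t, type)}."""
        return {
            (e.source, e.layer_source, e.target, e.layer_target, e.edge_type)
            for e in self.edges
        }

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiDiGraph()
        for n in self.nodes:
            g.add_node((n.id, n.layer), module=n.module)
        for e in self.edges:
            g.add_edge(
                (e.source, e.layer_source),
                (e.target, e.layer_target),
                edge_type=e.edge_type,
                sign=e.sign,
                weight=e.weight,
            )
        return g


def write_network(net: IdopNetwork, path_prefix) -> None:
    """Write a network as edge-list TSV and JSON; both round-trip exactly."""
    net.validate()
    prefix = Path(path_prefix)
    rows = [
        {
            "source": e.source,
            "target": e.target,
            "layer_source": e.layer_source,
            "layer_target": e.layer_target,
            "edge_type": e.edge_type,
            "sign": e.sign,
            "weight": e.weight,
        }
        for e in net.edges
    ]
    cols = ["source", "target", "layer_source", "layer_target",
            "edge_type", "sign", "weight"]
    pd.DataFrame(rows, columns=cols).to_csv(
        prefix.with_suffix(".edges.tsv"), sep="\t", index=False
    )
    doc = {
        "nodes": [
            {"id": n.id, "layer": n.layer, "module": n.module} for n in net.nodes
        ],
        "edges": rows,
    }
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(doc, fh, indent=1)


def read_network(path_prefix) -> IdopNetwork:
    """Read back a network written by :func:`write_network` (from the JSON)."""
    prefix = Path(path_prefix)
    with open(prefix.with_suffix(".json")) as fh:
        doc = json.load(fh)
    nodes = [NetworkNode(**n) for n in doc["nodes"]]
    edges = [NetworkEdge(**e) for e in doc["edges"]]
    return IdopNetwork(nodes=nodes, edges=edges)


def write_curve_table(curves, path) -> None:
    """Write genotypic-value / component curves to a long-format TSV.

    ``curves`` is an iterable of dicts with keys snp_id, genotype, trait,
    individual, component, regulator plus parallel ``times``/``values``.
    """
    records = []
    for c in curves:
        for t, v in zip(c["times"], c["values"]):
            rec = {k: c.get(k, "") for k in
                   ("snp_id", "genotype", "individual", "trait",
                    "component", "regulator")}
            rec["time"] = t
            rec["value"] = v
            records.append(rec)
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)
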