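"""Readers/writers for the external text formats and the run configuration.

Formats
-------
* expression TSV: columns ``gene_id, ref, test[, flag]``; ``#`` comments
* interaction edge list TSV: ``gene_a, gene_b[, interaction]``
* GMT gene sets: ``name <TAB> description <TAB> member...``
* YAML run configuration mirroring :class:`RunConfig`
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

logger = logging.getLogger("evoccur.io")

__all__ = [
    "IntensityPair",
    "RunConfig",
    "FormatError",
    "read_intensity_table",
    "write_intensity_table",
    "read_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "load_config",
    "save_config",
    "write_json",
]

DEFAULT_SEED = 20101020

_INTERACTIONS = {"direct", "indirect"}


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass(frozen=True)
class IntensityPair:
    """One probe's background-subtracted paired intensities."""

    gene_id: str
    donor_id: str
    intensity_ref: float
    intensity_test: float
    flagged: bool = False

    def __post_init__(self):
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        for v in (self.intensity_ref, self.intensity_test):
            if not (isinstance(v, (int, float)) and v == v and abs(v) != float("inf")):
                raise ValueError(f"non-finite intensity for gene {self.gene_id}")


@dataclass
class RunConfig:
    """Pipeline parameters (YAML-serializable)."""

    p_threshold: float = 0.1
    ev_threshold: float | None = None  # derived from p_threshold when None
    occurrence_levels: list[int] = field(default_factory=list)  # empty -> n..3
    network_max_size: int = 35
    major_network_min_focus: int = 15
    overlap_metric: str = "mean"
    background_size: int | None = None
    technical_variability_pct: float = 20.0
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError(f"p_threshold must be in (0,1), got {self.p_threshold}")
        if self.network_max_size < 2:
            raise ValueError("network_max_size must be >= 2")
        if self.overlap_metric not in {"mean", "min", "jaccard"}:
            raise ValueError(f"unknown overlap metric {self.overlap_metric!r}")
        for k in self.occurrence_levels:
            if k < 1:
                raise ValueError(f"occurrence level must be >= 1, got {k}")

    def resolved_ev_threshold(self) -> float:
        if self.ev_threshold is not None:
            return float(self.ev_threshold)
        from .ev_core import p_to_ev

        return p_to_ev(self.p_threshold)

    def levels_for(self, n_donors: int) -> list[int]:
        levels = self.occurrence_levels or list(range(n_donors, 2, -1))
        for k in levels:
            if k > n_donors:
                raise ValueError(f"occurrence level {k} exceeds n_donors={n_donors}")
        return sorted(set(levels), reverse=True)


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def read_intensity_table(path: str | Path, donor_id: str) -> list[IntensityPair]:
    """Read one donor's paired-intensity TSV.

    Header must contain ``gene_id``, ``ref`` and ``test``; a 0/1 ``flag``
    column is optional (default unflagged).  Duplicate gene_ids are retained
    as replicate probes.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse TSV: {exc}") from exc
    required = {"gene_id", "ref", "test"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    has_flag = "flag" in df.columns

    pairs: list[IntensityPair] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        gene = str(row.gene_id).strip()
        if not gene or gene.lower() == "nan":
            raise FormatError(f"{path}: line {i}: empty gene_id")
        try:
            ref = float(row.ref)
            test = float(row.test)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: line {i}: non-numeric intensity") from exc
        flagged = False
        if has_flag:
            raw = str(row.flag).strip()
            if raw not in {"0", "1", "", "nan"}:
                raise FormatError(f"{path}: line {i}: flag must be 0 or 1, got {raw!r}")
            flagged = raw == "1"
        pairs.append(IntensityPair(gene, donor_id, ref, test, flagged))
    logger.info("read_intensity_table %s donor=%s rows=%d", path.name, donor_id, len(pairs))
    return pairs


def write_intensity_table(pairs: Sequence[IntensityPair], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [p.gene_id for p in pairs],
            "ref": [repr(p.intensity_ref) for p in pairs],
            "test": [repr(p.intensity_test) for p in pairs],
            "flag": [int(p.flagged) for p in pairs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# interaction graph
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, background_size: int | None = None):
    """Read an undirected gene-interaction edge list into a KnowledgeGraph.

    Self-loops are dropped with a warning; duplicate edges collapse; the
    interaction tag defaults to ``direct``.
    """
    from .netstruct import KnowledgeGraph

    path = Path(path)
    g = nx.Graph()
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None and parts[0] == "gene_a":
                header = parts
                continue
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno}: expected >= 2 columns")
            a, b = parts[0].strip(), parts[1].strip()
            tag = parts[2].strip() if len(parts) > 2 and parts[2].strip() else "direct"
            if tag not in _INTERACTIONS:
                raise FormatError(
                    f"{path}: line {lineno}: unknown interaction label {tag!r}"
                )
            if a == b:
                logger.warning("%s: line %d: self-loop (%s) dropped", path.name, lineno, a)
                continue
            g.add_edge(a, b, interaction=tag)
            n_rows += 1
    if n_rows == 0:
        raise FormatError(f"{path}: no edges found")
    logger.info("read_edge_list %s nodes=%d edges=%d", path.name, g.number_of_nodes(), g.number_of_edges())
    return KnowledgeGraph(g, background_size=background_size)


def write_edge_list(graph, path: str | Path) -> None:
    g = graph.graph if hasattr(graph, "graph") else graph
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tinteraction\n")
        for a, b, data in sorted(g.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('interaction', 'direct')}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a GMT file into ``{set name: frozenset of members}``."""
    path = Path(path)
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: GMT line needs >= 3 fields")
            name = parts[0]
            members = frozenset(m for m in parts[2:] if m)
            if not members:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} is empty")
            sets[name] = members
    logger.info("read_gmt %s sets=%d", path.name, len(sets))
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(set(sets[name])))
            fh.write(f"{name}\tna\t{members}\n")


# ---------------------------------------------------------------------------
# configuration / reports
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)


def write_json(obj, path: str | Path) -> None:
    def default(o):
        import numpy as np

        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")
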