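"""Stringency-grid evaluation and occurrence-threshold recommendation.

Runs gene selection, network construction and structuring metrics at every
occurrence level (strictest first), then applies two decision rules:

* Rule A (structuring peak): pick the level maximizing the percentage of
  network-eligible genes common to at least two networks.
* Rule B (best-score continuity): walk from the strictest level; while the
  top network's focus genes land their plurality share in the next level's
  top network, keep relaxing; the first time the plurality falls outside
  the top network, the preceding (stricter) level is chosen.

Rule B, the stated stopping criterion, takes precedence when defined;
otherwise Rule A decides.  Disagreement between the rules is logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ev_core import EVTable
from .io_formats import RunConfig
from .netstruct import (
    KnowledgeGraph,
    SharingMatrix,
    StringencyMetrics,
    build_networks,
    compute_metrics,
    cross_level_sharing,
    rank_networks,
    score_genesets,
)
from .occurrence import GeneSelection, count_occurrence, select_by_occurrence

logger = logging.getLogger("evoccur.optimizer")

__all__ = ["GridLevel", "GridResult", "Recommendation", "run_grid", "choose_threshold"]


@dataclass
class GridLevel:
    k: int
    selection: GeneSelection
    networks: list
    metrics: StringencyMetrics | None
    sharing_to_next: SharingMatrix | None = None
    geneset_scores: list[dict] | None = None

    @property
    def label(self) -> str:
        return self.selection.level


@dataclass
class GridResult:
    levels: list[GridLevel]  # strictly decreasing k

    def level(self, k: int) -> GridLevel:
        for lv in self.levels:
            if lv.k == k:
                return lv
        raise KeyError(k)


@dataclass
class Recommendation:
    chosen_k: int
    chosen_level: str
    rule_a_k: int
    rule_b_k: int | None
    rationale: str


def run_grid(
    ev_table: EVTable,
    graph: KnowledgeGraph,
    genesets: Mapping[str, frozenset[str]] | None,
    config: RunConfig,
) -> GridResult:
    """Evaluate every occurrence level from strictest to loosest."""
    ev_thr = config.resolved_ev_threshold()
    records = count_occurrence(ev_table, ev_thr, config.p_threshold)
    levels: list[GridLevel] = []
    for k in config.levels_for(ev_table.n_donors):
        try:
            selection = select_by_occurrence(records, k, ev_threshold=ev_thr)
            focus = {g for g in selection.gene_ids if g in graph}
            if focus:
                nets = build_networks(focus, graph, config.network_max_size)
                nets = rank_networks(nets, graph, n_focus_total=len(focus))
                metrics = compute_metrics(nets, len(selection), level=selection.level)
            else:
                nets, metrics = [], None
            gs = (
                score_genesets(selection, genesets, graph.background_size)
                if genesets and selection.gene_ids
                else None
            )
            levels.append(GridLevel(k=k, selection=selection, networks=nets,
                                    metrics=metrics, geneset_scores=gs))
        except Exception as exc:
            raise RuntimeError(f"grid evaluation failed at level k={k}: {exc}") from exc
    for strict, loose in zip(levels, levels[1:]):
        if strict.networks and loose.networks:
            strict.sharing_to_next = cross_level_sharing(
                strict.networks, loose.networks, top_k=5
            )
    logger.info("run_grid levels=%s", [lv.label for lv in levels])
    return GridResult(levels=levels)


def _rule_a(grid: GridResult) -> int:
    """Level with maximal common-gene percentage (tie -> strictest)."""
    best_k, best_pct = None, -1.0
    for lv in grid.levels:
        if lv.metrics is None:
            continue
        if lv.metrics.common_pct > best_pct:
            best_k, best_pct = lv.k, lv.metrics.common_pct
    if best_k is None:
        raise ValueError("no level has metrics; cannot apply Rule A")
    return best_k


def _rule_b(grid: GridResult, min_informative_focus: int = 15) -> int | None:
    """Best-score continuity walk; None when the chain never breaks.

    Transitions whose strict-level top network is below major-network size
    (focus genes < ``min_informative_focus``) carry no signal about score
    continuity and are skipped rather than treated as breaks.
    """
    for strict, loose in zip(grid.levels, grid.levels[1:]):
        sm = strict.sharing_to_next
        if sm is None or not loose.networks:
            continue
        if len(strict.networks[0].focus) < min_informative_focus:
            continue
        row = sm.row(0)
        if row.max() <= 0:
            # top network's focus genes vanish entirely -> chain broken
            return strict.k
        plurality_col = int(np.argmax(row))  # ties -> lower-ranked network
        # networks tied for the loose level's best score are interchangeable
        # "N deg 1" networks: landing in any of them keeps the best score shared
        best_score = loose.networks[0].score
        tied_top = {n.network_id for n in loose.networks if n.score == best_score}
        if sm.col_ids[plurality_col] in tied_top:
            continue
        # a break is the stark signature of restructuring: the plurality
        # network clearly dominates the top network's share, not a one-gene
        # photo finish
        top_share = max(
            (row[j] for j, cid in enumerate(sm.col_ids) if cid in tied_top),
            default=0.0,
        )
        if row[plurality_col] >= 2.0 * top_share:
            return strict.k
    return None


def choose_threshold(grid: GridResult, min_informative_focus: int = 15) -> Recommendation:
    """Recommend the occurrence level using Rules A and B."""
    if len(grid.levels) < 2:
        raise ValueError("need at least 2 grid levels to choose a threshold")
    a = _rule_a(grid)
    b = _rule_b(grid, min_informative_focus)
    if b is not None:
        chosen = b
        rationale = f"Rule B (best-score continuity) selects k={b}"
        if a != b:
            rationale += f"; NOTE Rule A (structuring peak) disagrees with k={a}"
            logger.warning("decision rules disagree: rule_a=%d rule_b=%d", a, b)
    else:
        chosen = a
        rationale = (
            f"Rule B undefined (plurality stayed in the top network); "
            f"Rule A (structuring peak) selects k={a}"
        )
    lv = grid.level(chosen)
    logger.info("choose_threshold chosen=%s rule_a=%s rule_b=%s", chosen, a, b)
    return Recommendation(
        chosen_k=chosen,
        chosen_level=lv.label,
        rule_a_k=a,
        rule_b_k=b,
        rationale=rationale,
    )
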