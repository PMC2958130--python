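"""Occurrence counting and gene selection across donors.

A gene "occurs" in a donor when its EV exceeds the stringency threshold in
a given regulation direction; the occurrence count of a gene is the number
of donors in which it varies in the *same* direction (both directions are
evaluated and the larger count is kept).  Per-donor significance combines
multiplicatively (upper bound ``p_threshold**k``) or via the binomial tail
``P(X >= k)``, ``X ~ Binomial(n, p_threshold)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ev_core import EVTable, p_to_ev

logger = logging.getLogger("evoccur.occurrence")

__all__ = [
    "OccurrenceRecord",
    "GeneSelection",
    "count_occurrence",
    "combined_p",
    "select_by_occurrence",
    "select_by_mean",
]


@dataclass(frozen=True)
class OccurrenceRecord:
    gene_id: str
    n_up: int
    n_down: int
    occurrence: int
    consensus_direction: int
    summary_ev: float          # median EV across consensus donors (NaN if none)
    median_signed_ev: float    # median signed EV across all donors
    combined_p_product: float
    combined_p_binomial: float
    n_donors: int


@dataclass(frozen=True)
class GeneSelection:
    """Genes surviving (EV threshold, occurrence >= k_min)."""

    level: str
    k_min: int
    n_donors: int
    ev_threshold: float
    gene_ids: frozenset[str]
    summary_ev: dict[str, float]  # per-gene median signed EV over all donors

    def __len__(self) -> int:
        return len(self.gene_ids)


def combined_p(k: int, n: int, p_threshold: float) -> tuple[float, float]:
    """(product bound, binomial tail) for k exceedances out of n donors."""
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k} n={n}")
    if not (0.0 < p_threshold < 1.0):
        raise ValueError(f"p_threshold must be in (0,1), got {p_threshold}")
    product = p_threshold ** k
    binom_tail = float(stats.binom.sf(k - 1, n, p_threshold))
    return product, binom_tail


def count_occurrence(
    ev_table: EVTable, ev_threshold: float, p_threshold: float = 0.1
) -> list[OccurrenceRecord]:
    """Per-gene occurrence records at the given EV stringency threshold."""
    if ev_threshold <= 0:
        raise ValueError(f"ev_threshold must be > 0, got {ev_threshold}")
    if not ev_table.genes:
        raise ValueError("empty EV table")
    n = ev_table.n_donors
    out: list[OccurrenceRecord] = []
    for gene in ev_table.genes:
        recs = ev_table.gene_records(gene)
        up = [r.ev for r in recs if r.ev >= ev_threshold and r.direction > 0]
        down = [r.ev for r in recs if r.ev >= ev_threshold and r.direction < 0]
        n_up, n_down = len(up), len(down)
        if n_up > n_down:
            consensus, consensus_evs = 1, up
        elif n_down > n_up:
            consensus, consensus_evs = -1, down
        else:
            # tie: direction with larger total EV, then +1
            consensus = -1 if sum(down) > sum(up) else 1
            consensus_evs = down if consensus < 0 else up
        occ = max(n_up, n_down)
        prod, binom_tail = combined_p(occ, n, p_threshold)
        signed = [r.direction * r.ev for r in recs]
        out.append(
            OccurrenceRecord(
                gene_id=gene,
                n_up=n_up,
                n_down=n_down,
                occurrence=occ,
                consensus_direction=consensus,
                summary_ev=float(np.median(consensus_evs)) if consensus_evs else math.nan,
                median_signed_ev=float(np.median(signed)),
                combined_p_product=prod,
                combined_p_binomial=binom_tail,
                n_donors=n,
            )
        )
    logger.info(
        "count_occurrence genes=%d threshold=%.4f nonzero=%d",
        len(out), ev_threshold, sum(1 for r in out if r.occurrence > 0),
    )
    return out


def select_by_occurrence(
    records: list[OccurrenceRecord], k_min: int, ev_threshold: float | None = None
) -> GeneSelection:
    """Genes with occurrence >= ``k_min`` (direction-consistent)."""
    if not records:
        raise ValueError("no occurrence records")
    n = records[0].n_donors
    if not (1 <= k_min <= n):
        raise ValueError(f"k_min must be in [1, {n}], got {k_min}")
    chosen = [r for r in records if r.occurrence >= k_min]
    label = f"{k_min}/{n}" if k_min == n else f">={k_min}/{n}"
    sel = GeneSelection(
        level=label,
        k_min=k_min,
        n_donors=n,
        ev_threshold=float(ev_threshold) if ev_threshold is not None else math.nan,
        gene_ids=frozenset(r.gene_id for r in chosen),
        summary_ev={r.gene_id: r.median_signed_ev for r in chosen},
    )
    logger.info("select_by_occurrence level=%s genes=%d", label, len(sel))
    return sel


def select_by_mean(ev_table: EVTable, p_cut: float, stat: str = "mean") -> GeneSelection:
    """Baseline selection on the cohort-averaged signed EV.

    A gene is selected when |mean (or median) signed EV across donors|
    meets the EV value equivalent to ``p_cut``.
    """
    if not (0.0 < p_cut < 1.0):
        raise ValueError(f"p_cut must be in (0,1), got {p_cut}")
    if stat not in {"mean", "median"}:
        raise ValueError(f"stat must be 'mean' or 'median', got {stat!r}")
    cut = p_to_ev(min(p_cut, 0.5))
    mat = ev_table.signed_ev_matrix()
    avg = mat.mean(axis=1) if stat == "mean" else np.median(mat, axis=1)
    genes = [g for g, v in zip(ev_table.genes, avg) if abs(v) >= cut]
    summary = {g: float(v) for g, v in zip(ev_table.genes, avg) if abs(v) >= cut}
    label = f"{stat}-p<={p_cut:g}"
    logger.info("select_by_mean stat=%s cut=%.4f genes=%d", stat, cut, len(genes))
    return GeneSelection(
        level=label,
        k_min=0,
        n_donors=ev_table.n_donors,
        ev_threshold=cut,
        gene_ids=frozenset(genes),
        summary_ev=summary,
    )
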