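"""Inter-donor variability: pairwise selection overlap, decomposition into
technical and biological components, and projected gene counts across
occurrence levels under geometric attrition."""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("evoccur.variability")

__all__ = [
    "VariabilityReport",
    "pairwise_overlap",
    "overlap_pct",
    "decompose",
    "project_counts",
    "build_report",
]


def overlap_pct(a: set[str], b: set[str], metric: str = "mean") -> float:
    """Percent overlap of two gene sets.

    ``mean``: 100*|A&B| / ((|A|+|B|)/2); ``min``: 100*|A&B| / min(|A|,|B|);
    ``jaccard``: 100*|A&B| / |A|B union|.  NaN when a set is empty.
    """
    if not a or not b:
        return math.nan
    inter = len(a & b)
    if metric == "mean":
        return 100.0 * inter / ((len(a) + len(b)) / 2.0)
    if metric == "min":
        return 100.0 * inter / min(len(a), len(b))
    if metric == "jaccard":
        return 100.0 * inter / len(a | b)
    raise ValueError(f"unknown overlap metric {metric!r}")


def pairwise_overlap(
    selections: list[set[str]], metric: str = "mean"
) -> tuple[np.ndarray, float]:
    """Overlap matrix over donor pairs and its average.

    Donors with empty selections yield NaN entries which are excluded from
    the average (with a warning).
    """
    n = len(selections)
    if n < 2:
        raise ValueError("need at least 2 donors")
    empties = [i for i, s in enumerate(selections) if not s]
    if empties:
        logger.warning("donors with empty selections excluded from average: %s", empties)
    mat = np.full((n, n), math.nan)
    np.fill_diagonal(mat, 100.0)
    vals = []
    for i, j in itertools.combinations(range(n), 2):
        v = overlap_pct(set(selections[i]), set(selections[j]), metric)
        mat[i, j] = mat[j, i] = v
        if not math.isnan(v):
            vals.append(v)
    avg = float(np.mean(vals)) if vals else math.nan
    return mat, avg


def decompose(avg_overlap: float, technical: float) -> tuple[float, float]:
    """(total variability, biological variability), in percent.

    total = 100 - average overlap; biological = max(0, total - technical).
    """
    for name, v in (("avg_overlap", avg_overlap), ("technical", technical)):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"{name} must be in [0, 100], got {v}")
    total = 100.0 - avg_overlap
    biological = max(0.0, total - technical)
    return total, biological


def project_counts(n_observed: int, total_variability: float, delta_k: int) -> int:
    """Expected gene count after ``delta_k`` occurrence steps.

    Geometric attrition: ``round(n * (1 - v)**delta_k)``, half away from
    zero.  ``total_variability`` is a fraction in [0, 1).
    """
    if not (0.0 <= total_variability < 1.0):
        raise ValueError(f"total_variability must be in [0,1), got {total_variability}")
    if delta_k < 0:
        raise ValueError("delta_k must be >= 0")
    if n_observed < 0:
        raise ValueError("n_observed must be >= 0")
    x = n_observed * (1.0 - total_variability) ** delta_k
    return int(math.floor(x + 0.5))


@dataclass
class VariabilityReport:
    overlap_matrix: np.ndarray
    donor_ids: list[str]
    metric: str
    avg_overlap: float
    total_variability: float
    technical: float
    biological: float
    projections: dict[int, int]  # delta_k -> expected count

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "donor_ids": self.donor_ids,
            "overlap_matrix": self.overlap_matrix.tolist(),
            "avg_overlap_pct": self.avg_overlap,
            "total_variability_pct": self.total_variability,
            "technical_pct": self.technical,
            "biological_pct": self.biological,
            "projections": {str(k): v for k, v in self.projections.items()},
        }


def build_report(
    per_donor_selections: dict[str, set[str]],
    n_observed: int,
    technical_pct: float = 20.0,
    metric: str = "mean",
    max_delta_k: int = 2,
) -> VariabilityReport:
    """Overlap matrix, variability decomposition and count projections."""
    donors = sorted(per_donor_selections)
    mat, avg = pairwise_overlap([per_donor_selections[d] for d in donors], metric)
    total, biological = decompose(avg, technical_pct)
    proj = {
        dk: project_counts(n_observed, total / 100.0, dk)
        for dk in range(max_delta_k + 1)
    }
    logger.info(
        "variability avg_overlap=%.1f%% total=%.1f%% biological=%.1f%%",
        avg, total, biological,
    )
    return VariabilityReport(
        overlap_matrix=mat,
        donor_ids=donors,
        metric=metric,
        avg_overlap=avg,
        total_variability=total,
        technical=technical_pct,
        biological=biological,
        projections=proj,
    )
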