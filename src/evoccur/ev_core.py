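"""Per-donor expression-variation (EV) scoring.

The EV of a gene is the standardized distance of its paired expression
difference from an intensity-dependent confidence band.  Both channels are
first variance-stabilized with a one-parameter Box-Cox transform; on that
scale the data are decomposed into mean intensity ``A = (y_test + y_ref)/2``
and difference ``M = y_test - y_ref``.  A smoothing spline through windowed
robust location/scale estimates of ``M`` as a function of ``A`` defines the
dispersion band; ``ev = |M - center(A)| / spread(A)`` and the associated
one-sided p-value is the standard-normal upper tail of ``ev``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.interpolate import make_smoothing_spline

from .io_formats import IntensityPair

logger = logging.getLogger("evoccur.ev_core")

__all__ = [
    "DispersionModel",
    "EVRecord",
    "EVTable",
    "HomogeneitySummary",
    "DonorAnalysis",
    "fit_boxcox",
    "boxcox_transform",
    "fit_dispersion",
    "compute_ev",
    "aggregate_replicates",
    "ev_to_p",
    "p_to_ev",
    "display_ev",
    "analyze_donor",
    "analyze_cohort",
]

# absolute lower bound for the spread floor; keeps EV finite on degenerate
# (noise-free) inputs without influencing any realistic fit
_SPREAD_EPS = 1e-9


# ---------------------------------------------------------------------------
# EV <-> p mapping
# ---------------------------------------------------------------------------

def ev_to_p(ev: float) -> float:
    """One-sided upper-tail p-value for a standardized deviation ``ev >= 0``."""
    ev = float(ev)
    if not math.isfinite(ev) or ev < 0:
        raise ValueError(f"ev must be finite and >= 0, got {ev!r}")
    return float(stats.norm.sf(ev))


def p_to_ev(p: float) -> float:
    """Inverse of :func:`ev_to_p`; requires ``0 < p <= 0.5``."""
    p = float(p)
    if not (0.0 < p <= 0.5):
        raise ValueError(f"p must be in (0, 0.5], got {p!r}")
    return float(stats.norm.isf(p))


def display_ev(ev: float) -> float:
    """Two-decimal display value of an EV threshold (truncated toward zero)."""
    return math.trunc(float(ev) * 100.0) / 100.0


# ---------------------------------------------------------------------------
# Box-Cox fit
# ---------------------------------------------------------------------------

def boxcox_transform(values: np.ndarray, lmbda: float) -> np.ndarray:
    """One-parameter Box-Cox transform ``(v**l - 1)/l`` (``ln v`` at l=0)."""
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("Box-Cox transform requires strictly positive values")
    if lmbda == 0.0:
        return np.log(values)
    return (np.power(values, lmbda) - 1.0) / lmbda


def fit_boxcox(values: Sequence[float], bounds: tuple[float, float] = (-5.0, 5.0)) -> float:
    """Maximum-likelihood Box-Cox power parameter for positive intensities.

    Maximizes the profile log-likelihood of the one-parameter Box-Cox
    family.  Fails on fewer than 10 values (unstable) and on constant input
    (zero variance at every lambda).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        values = values.ravel()
    if values.size < 10:
        raise ValueError(f"need at least 10 values to fit Box-Cox, got {values.size}")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in Box-Cox input")
    if np.any(values <= 0):
        raise ValueError("Box-Cox fit requires strictly positive values (apply shift first)")
    if np.ptp(values) == 0:
        raise ValueError("constant input: zero variance, Box-Cox fit undefined")

    def neg_llf(lam: float) -> float:
        return -float(stats.boxcox_llf(lam, values))

    res = optimize.minimize_scalar(
        neg_llf, bounds=bounds, method="bounded", options={"xatol": 1e-8}
    )
    return float(res.x)


def resolve_shift(values: np.ndarray) -> float:
    """Shift making intensities strictly positive: +1 when zeros are present."""
    values = np.asarray(values, dtype=float)
    mn = float(np.min(values))
    if mn > 0:
        return 0.0
    if mn == 0.0:
        return 1.0
    raise ValueError("negative intensities cannot be shifted by the +1 rule")


# ---------------------------------------------------------------------------
# Dispersion model
# ---------------------------------------------------------------------------

@dataclass
class DispersionModel:
    """Intensity-dependent dispersion band on the Box-Cox scale.

    ``center_curve`` and ``spread_curve`` are smooth functions of the mean
    Box-Cox intensity; queries outside ``fit_domain`` are clamped to the
    nearest boundary.  ``spread_floor`` bounds the spread away from zero.
    """

    boxcox_lambda: float
    shift: float
    center_curve: Callable[[np.ndarray], np.ndarray]
    spread_curve: Callable[[np.ndarray], np.ndarray]
    fit_domain: tuple[float, float]
    spread_floor: float
    donor_id: str | None = None
    window_mids: np.ndarray | None = None

    def _clamp(self, a: np.ndarray) -> np.ndarray:
        lo, hi = self.fit_domain
        return np.clip(np.asarray(a, dtype=float), lo, hi)

    def center(self, a: np.ndarray) -> np.ndarray:
        return np.asarray(self.center_curve(self._clamp(a)), dtype=float)

    def spread(self, a: np.ndarray) -> np.ndarray:
        s = np.asarray(self.spread_curve(self._clamp(a)), dtype=float)
        s = np.maximum(s, self.spread_floor)
        if np.any(s <= 0):
            raise RuntimeError("spread curve non-positive after clamping (internal error)")
        return s


def _windows(n: int) -> int:
    return max(20, n // 500)


def _scale_free_spline(x: np.ndarray, y: np.ndarray):
    """GCV smoothing spline fitted in standardized coordinates.

    Fitting in standardized units makes the result equivariant under affine
    changes of the x axis and linear rescaling of y (the Box-Cox scale
    shifts with the data), up to floating-point noise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x0, xs = float(x.mean()), float(x.std()) or 1.0
    ys = float(np.abs(y).max()) or 1.0
    spline = make_smoothing_spline((x - x0) / xs, y / ys)
    return lambda a: ys * spline((np.asarray(a, dtype=float) - x0) / xs)


def fit_dispersion(
    pairs: Sequence[IntensityPair],
    lmbda: float,
    shift: float = 0.0,
    donor_id: str | None = None,
) -> DispersionModel:
    """Fit the dispersion band for one donor.

    Bins mean intensity ``A`` into ``max(20, n/500)`` equal-count windows and
    smooths the windowed median of ``M`` (center) and the windowed robust SD
    ``1.4826 * MAD`` of ``M`` (spread) with GCV-tuned cubic smoothing
    splines.  The spread curve is clamped below at 10% of the median
    windowed spread.
    """
    kept = [p for p in pairs if not p.flagged]
    n = len(kept)
    if n < 200:
        raise ValueError(f"need >= 200 unflagged pairs to fit dispersion, got {n}")

    ref = np.array([p.intensity_ref for p in kept], dtype=float) + shift
    test = np.array([p.intensity_test for p in kept], dtype=float) + shift
    y_ref = boxcox_transform(ref, lmbda)
    y_test = boxcox_transform(test, lmbda)
    a = (y_test + y_ref) / 2.0
    m = y_test - y_ref

    n_win = _windows(n)
    order = np.argsort(a, kind="stable")
    chunks = np.array_split(order, n_win)
    mids, centers, spreads = [], [], []
    for idx in chunks:
        if idx.size == 0:
            continue
        aw, mw = a[idx], m[idx]
        med = float(np.median(mw))
        mids.append(float(np.median(aw)))
        centers.append(med)
        spreads.append(1.4826 * float(np.median(np.abs(mw - med))))
    mids = np.asarray(mids)
    centers = np.asarray(centers)
    spreads = np.asarray(spreads)

    # splines need strictly increasing knots; merge windows with tied midpoints
    uniq, inv = np.unique(mids, return_inverse=True)
    if uniq.size < len(mids):
        centers = np.array([centers[inv == i].mean() for i in range(uniq.size)])
        spreads = np.array([spreads[inv == i].mean() for i in range(uniq.size)])
        mids = uniq
    if mids.size < 20:
        raise ValueError(f"fewer than 20 distinct windows feasible ({mids.size})")

    center_spline = _scale_free_spline(mids, centers)
    spread_spline = _scale_free_spline(mids, spreads)
    floor = max(0.1 * float(np.median(spreads)), _SPREAD_EPS)

    model = DispersionModel(
        boxcox_lambda=float(lmbda),
        shift=float(shift),
        center_curve=center_spline,
        spread_curve=spread_spline,
        fit_domain=(float(mids[0]), float(mids[-1])),
        spread_floor=floor,
        donor_id=donor_id,
        window_mids=mids,
    )
    logger.info(
        "fit_dispersion donor=%s n=%d windows=%d lambda=%.4f floor=%.3g",
        donor_id, n, mids.size, lmbda, floor,
    )
    return model


# ---------------------------------------------------------------------------
# EV records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EVRecord:
    gene_id: str
    donor_id: str
    ev: float
    p: float
    direction: int  # +1 up-regulated, -1 down-regulated


def compute_ev(pairs: Sequence[IntensityPair], model: DispersionModel) -> list[EVRecord]:
    """Probe-level EV records for one donor under a fitted dispersion model.

    Genes whose probes are all flagged are omitted (logged).  Direction ties
    at exactly the band center break to +1.
    """
    flagged_genes = {p.gene_id for p in pairs if p.flagged}
    kept = [p for p in pairs if not p.flagged]
    kept_genes = {p.gene_id for p in kept}
    for g in sorted(flagged_genes - kept_genes):
        logger.warning("gene %s has flagged-only probes; omitted", g)
    if not kept:
        return []

    ref = np.array([p.intensity_ref for p in kept], dtype=float) + model.shift
    test = np.array([p.intensity_test for p in kept], dtype=float) + model.shift
    y_ref = boxcox_transform(ref, model.boxcox_lambda)
    y_test = boxcox_transform(test, model.boxcox_lambda)
    a = (y_test + y_ref) / 2.0
    m = y_test - y_ref
    resid = m - model.center(a)
    ev = np.abs(resid) / model.spread(a)
    direction = np.where(resid < 0, -1, 1)  # tie (resid == 0) -> +1
    pvals = stats.norm.sf(ev)
    return [
        EVRecord(p.gene_id, p.donor_id, float(e), float(pv), int(d))
        for p, e, pv, d in zip(kept, ev, pvals, direction)
    ]


@dataclass(frozen=True)
class HomogeneitySummary:
    """Replicate-probe agreement: relative spread (%) statistics across genes.

    For genes with >= 2 replicate probes the relative spread is
    ``100 * mean(|EV_i - median EV|) / median EV``.  This is a stated
    stand-in definition; there is no canonical formula for it.
    """

    n_genes_with_replicates: int
    mean_pct: float
    median_pct: float
    sd_pct: float


def aggregate_replicates(
    records: Sequence[EVRecord],
) -> tuple[list[EVRecord], HomogeneitySummary]:
    """Collapse replicate probes to one EV record per gene.

    Gene-level EV is the median of replicate EVs; direction is the majority
    sign (tie -> sign of the summed signed EV, then +1); p is re-derived
    from the aggregated EV.
    """
    by_gene: dict[str, list[EVRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, []).append(r)

    out: list[EVRecord] = []
    spreads: list[float] = []
    for gene in sorted(by_gene):
        reps = by_gene[gene]
        evs = np.array([r.ev for r in reps], dtype=float)
        med = float(np.median(evs))
        n_up = sum(1 for r in reps if r.direction > 0)
        n_down = len(reps) - n_up
        if n_up > n_down:
            direction = 1
        elif n_down > n_up:
            direction = -1
        else:
            signed_sum = sum(r.direction * r.ev for r in reps)
            direction = -1 if signed_sum < 0 else 1
        out.append(EVRecord(gene, reps[0].donor_id, med, ev_to_p(med), direction))
        if len(reps) >= 2 and med > 0:
            spreads.append(100.0 * float(np.mean(np.abs(evs - med))) / med)

    if spreads:
        arr = np.asarray(spreads)
        summary = HomogeneitySummary(
            n_genes_with_replicates=len(spreads),
            mean_pct=float(arr.mean()),
            median_pct=float(np.median(arr)),
            sd_pct=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        )
    else:
        summary = HomogeneitySummary(0, math.nan, math.nan, math.nan)
    return out, summary


# ---------------------------------------------------------------------------
# EV table (cohort view)
# ---------------------------------------------------------------------------

class EVTable:
    """Gene x donor collection of aggregated EV records.

    Every donor covers the same gene universe (the intersection across
    donors after replicate aggregation); exactly one record per
    (gene, donor).
    """

    def __init__(self, records: Mapping[str, Sequence[EVRecord]]):
        if not records:
            raise ValueError("empty EV table")
        universes = {d: {r.gene_id for r in recs} for d, recs in records.items()}
        common = set.intersection(*universes.values())
        if not common:
            raise ValueError("no genes shared by all donors")
        dropped = {d: len(u - common) for d, u in universes.items() if u - common}
        if dropped:
            logger.warning("EVTable: dropping donor-specific genes %s", dropped)
        self.donors: list[str] = sorted(records)
        self.genes: list[str] = sorted(common)
        self._ev: dict[tuple[str, str], EVRecord] = {}
        for d, recs in records.items():
            seen: set[str] = set()
            for r in recs:
                if r.gene_id not in common:
                    continue
                if r.gene_id in seen:
                    raise ValueError(f"duplicate record for gene {r.gene_id} donor {d}")
                seen.add(r.gene_id)
                self._ev[(r.gene_id, d)] = r

    @property
    def n_donors(self) -> int:
        return len(self.donors)

    def record(self, gene: str, donor: str) -> EVRecord:
        return self._ev[(gene, donor)]

    def gene_records(self, gene: str) -> list[EVRecord]:
        return [self._ev[(gene, d)] for d in self.donors]

    def signed_ev_matrix(self) -> np.ndarray:
        """Genes x donors matrix of ``direction * ev``."""
        mat = np.empty((len(self.genes), len(self.donors)))
        for i, g in enumerate(self.genes):
            for j, d in enumerate(self.donors):
                r = self._ev[(g, d)]
                mat[i, j] = r.direction * r.ev
        return mat

    def to_frame(self):
        import pandas as pd

        rows = [
            (r.gene_id, r.donor_id, r.ev, r.p, r.direction)
            for r in self._ev.values()
        ]
        df = pd.DataFrame(rows, columns=["gene_id", "donor_id", "ev", "p", "direction"])
        return df.sort_values(["donor_id", "gene_id"], ignore_index=True)

    @classmethod
    def from_frame(cls, df) -> "EVTable":
        records: dict[str, list[EVRecord]] = {}
        for row in df.itertuples(index=False):
            records.setdefault(str(row.donor_id), []).append(
                EVRecord(str(row.gene_id), str(row.donor_id), float(row.ev),
                         float(row.p), int(row.direction))
            )
        return cls(records)


# ---------------------------------------------------------------------------
# Donor / cohort pipelines
# ---------------------------------------------------------------------------

@dataclass
class DonorAnalysis:
    donor_id: str
    model: DispersionModel
    probe_records: list[EVRecord]
    gene_records: list[EVRecord]
    homogeneity: HomogeneitySummary


def analyze_donor(pairs: Sequence[IntensityPair], donor_id: str) -> DonorAnalysis:
    """Full per-donor EV pipeline: shift, Box-Cox fit, band fit, EV scores."""
    kept = [p for p in pairs if not p.flagged]
    pooled = np.array(
        [p.intensity_ref for p in kept] + [p.intensity_test for p in kept], dtype=float
    )
    shift = resolve_shift(pooled)
    lam = fit_boxcox(pooled + shift)
    model = fit_dispersion(pairs, lam, shift=shift, donor_id=donor_id)
    probe_records = compute_ev(pairs, model)
    gene_records, homogeneity = aggregate_replicates(probe_records)
    logger.info(
        "analyze_donor donor=%s probes_in=%d genes_out=%d",
        donor_id, len(pairs), len(gene_records),
    )
    return DonorAnalysis(donor_id, model, probe_records, gene_records, homogeneity)


@dataclass
class CohortAnalysis:
    table: EVTable
    donors: dict[str, DonorAnalysis]


def analyze_cohort(donor_pairs: Mapping[str, Sequence[IntensityPair]]) -> CohortAnalysis:
    """Run :func:`analyze_donor` for every donor and assemble the EV table."""
    analyses = {d: analyze_donor(pairs, d) for d, pairs in donor_pairs.items()}
    table = EVTable({d: a.gene_records for d, a in analyses.items()})
    return CohortAnalysis(table=table, donors=analyses)
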