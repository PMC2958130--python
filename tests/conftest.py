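import numpy as np
import pytest

from evoccur.ev_core import DispersionModel
from evoccur.io_formats import IntensityPair


def make_flat_model(center: float = 0.0, spread: float = 1.0) -> DispersionModel:
    """Dispersion model with constant curves, for unit tests."""
    return DispersionModel(
        boxcox_lambda=1.0,
        shift=0.0,
        center_curve=lambda a: np.full_like(np.asarray(a, dtype=float), center),
        spread_curve=lambda a: np.full_like(np.asarray(a, dtype=float), spread),
        fit_domain=(-1e9, 1e9),
        spread_floor=1e-12,
        donor_id="test",
    )


def null_pairs(n: int, seed: int, donor: str = "d1") -> list[IntensityPair]:
    """Paired lognormal intensities with no true expression changes."""
    rng = np.random.default_rng(seed)
    b = rng.normal(7.0, 1.0, n)
    sig = 0.15 + 0.6 * np.exp(-(b - 5.0) / 1.5)
    ref = np.exp(b + rng.normal(0.0, sig))
    test = np.exp(b + rng.normal(0.0, sig))
    return [
        IntensityPair(f"G{i:05d}", donor, float(r), float(t))
        for i, (r, t) in enumerate(zip(ref, test))
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic 6-donor cohort with strong responders."""
    from evoccur.synthdata import CohortSpec, generate_cohort

    spec = CohortSpec(
        n_genes=800, n_donors=6, frac_de=0.1, response_prob=1.0,
        effect_size=4.0, seed=11,
    )
    tables, truth = generate_cohort(spec)
    return spec, tables, truth


@pytest.fixture(scope="session")
def small_ev_table(small_cohort):
    from evoccur.ev_core import analyze_cohort

    _, tables, _ = small_cohort
    return analyze_cohort(tables).table
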