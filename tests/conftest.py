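"""Shared fixtures.

The ten-seed construct-validation battery (generation, full inversion,
Bayesian model reduction and clamped refit for both members of each
isotropic/anisotropic pair) is expensive, so it is computed once per
session and shared by the recovery, model-selection and reduction tests.
"""

from dataclasses import dataclass

import numpy as np
import pytest

from anisofield.inversion import PriorSpec, invert
from anisofield.reduction import compare_models, reduce_model, refit_reduced
from anisofield.synthetic_data import make_paper_replica, perturb

BATTERY_SEEDS = list(range(10))


@dataclass
class FitRecord:
    """Everything computed for one dataset of a replica pair."""

    truth: float
    full: object
    f_delta: float
    bmr_winner: str
    refit: object
    refit_winner: str


def fit_pair(pair, priors=None, refit=True):
    priors = priors or PriorSpec()
    reduced_prior = priors.with_reduced_beta(0.0)
    out = {}
    for label, ds, truth in (
        ("isotropic", pair.isotropic, pair.isotropic.config.beta),
        ("anisotropic", pair.anisotropic, pair.anisotropic.config.beta),
    ):
        full = invert(ds.observed, ds.config, priors=priors)
        f_delta, _ = reduce_model(priors, full, reduced_prior)
        bmr = compare_models(full.free_energy, full.free_energy + f_delta)
        if refit:
            refit_rep = refit_reduced(ds.observed, ds.config, reduced_prior)
            refit_winner = compare_models(
                full.free_energy, refit_rep.free_energy
            ).winner
        else:
            refit_rep, refit_winner = None, None
        out[label] = FitRecord(
            truth=truth,
            full=full,
            f_delta=f_delta,
            bmr_winner=bmr.winner,
            refit=refit_rep,
            refit_winner=refit_winner,
        )
    return out


@pytest.fixture(scope="session")
def replica_battery():
    """Full fits of the construct-validation pair across ten seeds."""
    return {seed: fit_pair(make_paper_replica(seed)) for seed in BATTERY_SEEDS}


@pytest.fixture(scope="session")
def jittered_battery():
    """Ten +/-10% jitters of one base pair, fitted like the main battery."""
    base = make_paper_replica(100)
    out = {}
    for k in range(10):
        pair = type(base)(
            isotropic=perturb(base.isotropic, fraction=0.10, seed=200 + k),
            anisotropic=perturb(base.anisotropic, fraction=0.10, seed=200 + k),
            seed=base.seed,
        )
        out[k] = fit_pair(pair, refit=False)
    return out
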