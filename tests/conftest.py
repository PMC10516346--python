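import numpy as np
import pytest

from fungalcomp import SimConfig, simulate_experiment
from fungalcomp.growth import fit_plates, select_svs_plug
from fungalcomp.metrics import compute_eoc

THREE_SPECIES = ("Amanita_muscaria", "Laccaria_bicolor", "Paxillus_involutus")
FOUR_SPECIES = THREE_SPECIES + ("Hebeloma_cylindrosporum",)


def make_config(n_species=3, **overrides):
    """Small-but-real simulation config for fast tests."""
    base = SimConfig()
    names = THREE_SPECIES[:n_species] if n_species <= 3 else FOUR_SPECIES[:n_species]
    rates = {(s, p): base.intrinsic_rates[(s, p)] for s in names for p in (5.6, 7.0)}
    kwargs = dict(
        species_names=names,
        intrinsic_rates=rates,
        n_replicates=3,
        dropout_prob=0.0,
        tree_seed=42,
        noise_seed=1,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def noiseless_config(**overrides):
    """All randomness off: EoC is exactly the fixed-effect linear predictor."""
    kwargs = dict(
        sigma_species=0.0,
        sigma_plate=0.0,
        sigma_resid=0.0,
        sigma_obs=0.0,
        dropout_prob=0.0,
    )
    kwargs.update(overrides)
    return make_config(**kwargs)


def run_to_eoc(config, svs_seed=0, response="growth_rate"):
    """simulate -> fit -> plug-select -> EoC, returning all intermediates."""
    records, truth = simulate_experiment(config)
    fits = fit_plates(records)
    svs = select_svs_plug(fits, svs_seed)
    comp = fits[fits["treatment"] == "competition"]
    eoc = compute_eoc(comp, svs, response=response)
    return records, truth, fits, svs, eoc


@pytest.fixture(scope="session")
def default_run():
    """One full-size (5 species, 2 pH, 10 reps) simulated experiment."""
    config = SimConfig(noise_seed=11)
    records, truth = simulate_experiment(config)
    fits = fit_plates(records)
    svs = select_svs_plug(fits, 5)
    comp = fits[fits["treatment"] == "competition"]
    eoc = compute_eoc(comp, svs)
    return {
        "config": config,
        "records": records,
        "truth": truth,
        "fits": fits,
        "svs": svs,
        "eoc": eoc,
    }


@pytest.fixture(scope="session")
def noiseless_run():
    config = noiseless_config()
    records, truth, fits, svs, eoc = run_to_eoc(config)
    return {
        "config": config,
        "records": records,
        "truth": truth,
        "fits": fits,
        "svs": svs,
        "eoc": eoc,
    }
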