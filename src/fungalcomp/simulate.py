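"""Synthetic replica of a pairwise fungal-competition plate experiment.

The generator mirrors a factorial in-vitro design: each of five
ectomycorrhizal species is grown alone (``single``), against itself
(``SvS``, self-versus-self), and against every other species
(``competition``) on media at two pH levels, with ten replicate plates per
treatment — 400 plates in all at the defaults.

Colony area follows exponential growth ``A(t) = a0 * exp(r * t)`` with
multiplicative lognormal measurement noise.  On competition plates the
focal colony's realised rate is its intrinsic rate ``mu[species, pH]``
scaled by an effect-of-competition (EoC) factor drawn from a log-linear
model::

    log EoC = beta0 + beta_dist * d(i, j) + beta_ph * 1[pH = high]
              + u_species + w_plate + eps_plug

with ``d`` the patristic distance between the two competitors, a random
intercept ``u`` per focal species, a random intercept ``w`` shared by the
two plugs of a plate, and an independent residual per plug.  Because the
ground truth (tree, intrinsic rates, per-plug EoC) is recorded, every
downstream estimator can be validated by parameter recovery.

Tree and noise use independent seed streams so the phylogeny can be held
fixed while replicating noise draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .phylo import DistanceMatrix, patristic_distances, read_newick

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ConfigError",
    "DEFAULT_SPECIES",
    "simulate_tree",
    "simulate_experiment",
    "plates_to_frame",
    "write_outputs",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


DEFAULT_SPECIES = (
    "Amanita_muscaria",
    "Cenococcum_geophilum",
    "Hebeloma_cylindrosporum",
    "Laccaria_bicolor",
    "Paxillus_involutus",
)

# Intrinsic exponential-phase area growth rates (day^-1) by (species, pH).
# Chosen as plausible plate-culture rates: slower growth on acidic medium
# for most species, a strongly pH-sensitive Hebeloma, and a pH-insensitive
# Paxillus.
_DEFAULT_RATES = {
    ("Amanita_muscaria", 5.6): 0.22,
    ("Amanita_muscaria", 7.0): 0.30,
    ("Cenococcum_geophilum", 5.6): 0.12,
    ("Cenococcum_geophilum", 7.0): 0.18,
    ("Hebeloma_cylindrosporum", 5.6): 0.16,
    ("Hebeloma_cylindrosporum", 7.0): 0.36,
    ("Laccaria_bicolor", 5.6): 0.33,
    ("Laccaria_bicolor", 7.0): 0.35,
    ("Paxillus_involutus", 5.6): 0.40,
    ("Paxillus_involutus", 7.0): 0.40,
}

_EXCLUSION_REASONS = ("contamination", "dislodged plug", "dormancy")


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    ``sigma_species``, ``sigma_plate`` and ``sigma_resid`` are the SDs of
    the species random intercept, the plate random intercept, and the
    per-plug residual of the log-EoC model; ``sigma_obs`` is the SD of the
    lognormal area-measurement noise.  ``a0`` is the initial plug area in
    mm² (a 5.6 mm diameter plug ≈ 24.6 mm²).
    """

    species_names: tuple[str, ...] = DEFAULT_SPECIES
    tree_seed: int = 42
    noise_seed: int = 1
    n_replicates: int = 10
    ph_levels: tuple[float, ...] = (5.6, 7.0)
    intrinsic_rates: dict = field(default_factory=lambda: dict(_DEFAULT_RATES))
    beta0: float = -0.02
    beta_dist: float = -0.05
    beta_ph: float = -0.10
    sigma_species: float = 0.10
    sigma_plate: float = 0.05
    sigma_resid: float = 0.10
    sigma_obs: float = 0.05
    a0: float = 24.6
    days: tuple[float, ...] = tuple(float(d) for d in range(11))
    dropout_prob: float = 0.08
    saturation_day: float | None = None

    def __post_init__(self) -> None:
        if len(self.species_names) < 2:
            raise ConfigError("need at least 2 species")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        if not (0 <= self.dropout_prob < 1):
            raise ConfigError("dropout_prob must lie in [0, 1)")
        for name in ("sigma_species", "sigma_plate", "sigma_resid", "sigma_obs"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        days = tuple(float(d) for d in self.days)
        if len(days) < 3 or any(b <= a for a, b in zip(days, days[1:])):
            raise ConfigError("days must be strictly increasing with >= 3 points")
        self.days = days
        self.species_names = tuple(self.species_names)
        self.ph_levels = tuple(float(p) for p in self.ph_levels)
        missing = [
            (s, p)
            for s in self.species_names
            for p in self.ph_levels
            if (s, p) not in self.intrinsic_rates
        ]
        if missing:
            raise ConfigError(f"intrinsic_rates missing entries for {missing}")


@dataclass
class GroundTruth:
    """True parameters behind one simulated experiment."""

    tree: str                      # newick
    patristic: DistanceMatrix
    rate_table: dict               # (species, ph) -> intrinsic rate
    eoc_table: pd.DataFrame        # per competition plug: realised true EoC
    species_effects: dict          # species -> random intercept u
    config: SimConfig


def simulate_tree(
    species_names: tuple[str, ...] | list[str], tree_seed: int
) -> tuple[str, DistanceMatrix]:
    """Simulate a rooted Yule (pure-birth) tree over the given tips.

    Returns the newick string and its patristic distance matrix.  The same
    seed always yields the same tree.
    """
    if len(species_names) < 2:
        raise ConfigError("need at least 2 species for a tree")
    rng = np.random.default_rng(tree_seed)
    # Pure-birth construction: start from a cherry, repeatedly pick a random
    # extant lineage to split; waiting times are exponential in the number
    # of extant lineages (birth rate 1).
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.edge.length = 0.0
    left = tree.seed_node.new_child(edge_length=0.0)
    right = tree.seed_node.new_child(edge_length=0.0)
    extant = [left, right]
    while len(extant) < len(species_names):
        wait = rng.exponential(1.0 / len(extant))
        for node in extant:
            node.edge.length += wait
        k = rng.integers(len(extant))
        parent = extant.pop(k)
        extant.append(parent.new_child(edge_length=0.0))
        extant.append(parent.new_child(edge_length=0.0))
    wait = rng.exponential(1.0 / len(extant))
    for node in extant:
        node.edge.length += wait
    order = rng.permutation(len(species_names))
    names = list(species_names)
    for node, k in zip(extant, order):
        node.taxon = taxa.require_taxon(label=names[k])
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    matrix = patristic_distances(read_newick(newick), tuple(species_names))
    return newick, matrix


def _plate_layout(config: SimConfig):
    """Yield (treatment, focal, opponent, ph, replicate) for every plate."""
    species = config.species_names
    pairs = [
        (species[i], species[j])
        for i in range(len(species))
        for j in range(i + 1, len(species))
    ]
    for ph in config.ph_levels:
        for rep in range(1, config.n_replicates + 1):
            for s in species:
                yield ("single", s, None, ph, rep)
                yield ("SvS", s, s, ph, rep)
            for a, b in pairs:
                yield ("competition", a, b, ph, rep)


def _area_series(config: SimConfig, rate: float, rng: np.random.Generator) -> np.ndarray:
    days = np.asarray(config.days)
    if config.saturation_day is not None:
        eff = np.minimum(days, config.saturation_day)
    else:
        eff = days
    log_area = np.log(config.a0) + rate * eff
    if config.sigma_obs > 0:
        log_area = log_area + rng.normal(0.0, config.sigma_obs, size=days.shape)
    return np.exp(log_area)


def simulate_experiment(config: SimConfig):
    """Simulate the full plate experiment.

    Returns ``(records, truth)`` where ``records`` is a list of plug-level
    :class:`~fungalcomp.growth.PlateRecord` (one per plug: single plates
    contribute one, SvS and competition plates two) and ``truth`` a
    :class:`GroundTruth`.  Excluded plates are flagged, never deleted.
    """
    from .growth import PlateRecord  # deferred to avoid a cycle

    newick, patristic = simulate_tree(config.species_names, config.tree_seed)
    rng = np.random.default_rng(config.noise_seed)

    high_ph = max(config.ph_levels)
    u = {s: rng.normal(0.0, config.sigma_species) for s in config.species_names}

    records: list[PlateRecord] = []
    truth_rows = []
    plate_counter = 0
    for treatment, focal, opponent, ph, rep in _plate_layout(config):
        plate_counter += 1
        plate_id = f"plate{plate_counter:04d}"
        excluded = bool(rng.random() < config.dropout_prob)
        reason = str(rng.choice(_EXCLUSION_REASONS)) if excluded else ""
        w_plate = rng.normal(0.0, config.sigma_plate) if treatment == "competition" else 0.0
        if treatment == "single":
            plugs = [(1, focal, None)]
        elif treatment == "SvS":
            plugs = [(1, focal, focal), (2, focal, focal)]
        else:
            plugs = [(1, focal, opponent), (2, opponent, focal)]
        for plug_index, plug_focal, plug_opponent in plugs:
            mu = config.intrinsic_rates[(plug_focal, ph)]
            if treatment == "competition":
                d = patristic[plug_focal, plug_opponent]
                log_eoc = (
                    config.beta0
                    + config.beta_dist * d
                    + config.beta_ph * (1.0 if ph == high_ph else 0.0)
                    + u[plug_focal]
                    + w_plate
                    + rng.normal(0.0, config.sigma_resid)
                )
                eoc = float(np.exp(log_eoc))
                rate = mu * eoc
                truth_rows.append(
                    {
                        "plate_id": plate_id,
                        "plug": plug_index,
                        "focal": plug_focal,
                        "opponent": plug_opponent,
                        "ph": ph,
                        "true_eoc": eoc,
                        "true_rate": rate,
                        "excluded": excluded,
                    }
                )
            else:
                rate = mu
            areas = _area_series(config, rate, rng)
            records.append(
                PlateRecord(
                    plate_id=plate_id,
                    treatment=treatment,
                    focal=plug_focal,
                    opponent=plug_opponent,
                    ph=ph,
                    replicate=rep,
                    plug_index=plug_index,
                    days=np.asarray(config.days),
                    areas=areas,
                    excluded=excluded,
                    exclusion_reason=reason,
                )
            )
    truth = GroundTruth(
        tree=newick,
        patristic=patristic,
        rate_table=dict(config.intrinsic_rates),
        eoc_table=pd.DataFrame(truth_rows),
        species_effects=u,
        config=config,
    )
    return records, truth


def plates_to_frame(records) -> pd.DataFrame:
    """Long-format plate table, one row per (plug, day) measurement."""
    rows = []
    for rec in records:
        for day, area in zip(rec.days, rec.areas):
            rows.append(
                {
                    "plate_id": rec.plate_id,
                    "treatment": rec.treatment,
                    "focal": rec.focal,
                    "opponent": "" if rec.opponent is None else rec.opponent,
                    "ph": rec.ph,
                    "replicate": rec.replicate,
                    "plug": rec.plug_index,
                    "day": day,
                    "area_mm2": area,
                    "excluded": rec.excluded,
                    "exclusion_reason": rec.exclusion_reason,
                }
            )
    return pd.DataFrame(rows)


def write_outputs(records, truth: GroundTruth, outdir) -> dict:
    """Write plates CSV, newick tree and ground-truth JSON into ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    plates_path = out / "plates.csv"
    plates_to_frame(records).to_csv(plates_path, index=False, float_format="%.10g")
    tree_path = out / "tree.nwk"
    tree_path.write_text(truth.tree + "\n")
    truth_path = out / "ground_truth.json"
    cfg = asdict(truth.config)
    cfg["intrinsic_rates"] = {f"{s}|{p}": v for (s, p), v in cfg["intrinsic_rates"].items()}
    payload = {
        "config": cfg,
        "rate_table": {f"{s}|{p}": v for (s, p), v in truth.rate_table.items()},
        "species_effects": truth.species_effects,
        "eoc_table": truth.eoc_table.to_dict(orient="records"),
        "patristic": {
            "labels": list(truth.patristic.labels),
            "values": truth.patristic.values.tolist(),
        },
    }
    truth_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return {"plates": plates_path, "tree": tree_path, "ground_truth": truth_path}
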