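"""End-to-end pipeline: simulate (or load) → growth fits → EoC/distances →
mixed models → networks, with a reproducibility manifest.

Every stage writes a plain CSV/JSON/newick intermediate so the pipeline
composes with external tools, and the manifest records seeds, the config
hash and per-stage record counts so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .simulate import SimConfig, simulate_experiment, write_outputs
from .growth import DEFAULT_WINDOW, read_plates, fit_plates, select_svs_plug, write_fits
from .phylo import DistanceMatrix, read_newick, patristic_distances
from .metrics import compute_eoc, growth_distance
from .inference import (
    LMMSpec,
    fit_lmm,
    fit_interaction_lm,
    compare_models,
    distance_correlation_check,
)
from .network import build_control_network, build_eoc_network, export_network

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("fungalcomp")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source: either ``plates_csv`` + ``tree_file`` or a
    ``simulate`` block (a :class:`~fungalcomp.simulate.SimConfig`).
    """

    outdir: str = "fungalcomp_run"
    plates_csv: str | None = None
    tree_file: str | None = None
    simulate: SimConfig | None = None
    window: tuple[float, float] = DEFAULT_WINDOW
    svs_seed: int = 0
    response: str = "growth_rate"
    estimation: str = "REML"
    drop_species: tuple[str, ...] = ()
    pooled_eoc_wins: bool = False

    def __post_init__(self) -> None:
        has_files = self.plates_csv is not None and self.tree_file is not None
        has_sim = self.simulate is not None
        if has_files == has_sim:
            raise ValueError("provide exactly one of (plates_csv + tree_file) or a simulate block")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulate" in d and d["simulate"] is not None and not isinstance(d["simulate"], SimConfig):
            sim = dict(d["simulate"])
            if "intrinsic_rates" in sim and isinstance(sim["intrinsic_rates"], dict):
                sim["intrinsic_rates"] = {
                    (k.split("|")[0], float(k.split("|")[1])) if isinstance(k, str) else k: v
                    for k, v in sim["intrinsic_rates"].items()
                }
            d["simulate"] = SimConfig(**sim)
        if "window" in d:
            d["window"] = tuple(d["window"])
        if "drop_species" in d:
            d["drop_species"] = tuple(d["drop_species"])
        return cls(**d)

    def digest(self) -> str:
        payload = asdict(self)
        if payload.get("simulate") and isinstance(payload["simulate"].get("intrinsic_rates"), dict):
            payload["simulate"]["intrinsic_rates"] = {
                f"{s}|{p}": v for (s, p), v in payload["simulate"]["intrinsic_rates"].items()
            }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.digest(),
        "svs_seed": config.svs_seed,
        "response": config.response,
        "stages": {},
    }

    # --- stage: inputs -----------------------------------------------------
    if config.simulate is not None:
        records, truth = simulate_experiment(config.simulate)
        write_outputs(records, truth, out)
        tree = read_newick(truth.tree)
        species = list(config.simulate.species_names)
        manifest["seeds"] = {
            "tree": config.simulate.tree_seed,
            "noise": config.simulate.noise_seed,
        }
    else:
        records = read_plates(config.plates_csv)
        tree = read_newick(config.tree_file)
        species = sorted({r.focal for r in records})
    if config.drop_species:
        species = [s for s in species if s not in config.drop_species]
        records = [
            r
            for r in records
            if r.focal in species and (r.opponent is None or r.opponent in species)
        ]
    n_excluded = len({r.plate_id for r in records if r.excluded})
    manifest["stages"]["input"] = {
        "plug_records": len(records),
        "plates": len({r.plate_id for r in records}),
        "excluded_plates": n_excluded,
        "species": species,
    }
    log.info("input: %d plug records, %d excluded plates", len(records), n_excluded)

    # --- stage: growth fits ------------------------------------------------
    fits = fit_plates(records, config.window)
    write_fits(fits, out / "growth_fits.csv")
    svs = select_svs_plug(fits, config.svs_seed)
    manifest["stages"]["growth"] = {"fits": len(fits), "svs_selected": len(svs)}

    # --- stage: metrics ----------------------------------------------------
    comp_fits = fits[fits["treatment"] == "competition"]
    eoc = compute_eoc(comp_fits, svs, response=config.response)
    eoc.to_csv(out / "eoc.csv", index=False, float_format="%.10g")
    ph_levels = sorted(eoc["ph"].unique())
    growth_dists = [growth_distance(svs, ph, response=config.response) for ph in ph_levels]
    for m in growth_dists:
        m.to_csv(out / f"growth_distance_ph{m.ph}.csv")
    patristic = patristic_distances(tree, tuple(species))
    patristic.to_csv(out / "patristic.csv")
    manifest["stages"]["metrics"] = {"eoc_records": len(eoc), "ph_levels": ph_levels}

    # --- stage: models -----------------------------------------------------
    growth_kind = "growth_rate" if config.response == "growth_rate" else "colony_size"
    spec_g = LMMSpec(distance_kind=growth_kind, estimation=config.estimation)
    spec_p = LMMSpec(distance_kind="patristic", estimation=config.estimation)
    lmm_g = fit_lmm(eoc, growth_dists, spec_g)
    lmm_p = fit_lmm(eoc, patristic, spec_p)
    comparison = compare_models(lmm_g, lmm_p)
    interaction = fit_interaction_lm(eoc, response_col="eoc")
    indep = distance_correlation_check(growth_dists, patristic)
    (out / "lmm_growth.json").write_text(json.dumps(lmm_g.to_dict(), indent=1))
    (out / "lmm_patristic.json").write_text(json.dumps(lmm_p.to_dict(), indent=1))
    (out / "model_comparison.json").write_text(json.dumps(comparison.to_dict(), indent=1))
    (out / "model_table.txt").write_text(format_model_table(lmm_g, lmm_p))
    manifest["stages"]["models"] = {
        "n_obs": lmm_g.n_obs,
        "aic_growth": lmm_g.aic,
        "aic_patristic": lmm_p.aic,
        "preferred_by_aic": comparison.preferred_by_aic,
        "boundary_flags": {"growth": lmm_g.boundary, "patristic": lmm_p.boundary},
        "interaction_lm": {
            "f": interaction.f_stat,
            "df": [interaction.df_num, interaction.df_den],
            "adj_r2": interaction.adj_r_squared,
        },
        "distance_correlation_p": indep.p_value,
    }
    if lmm_g.boundary or lmm_p.boundary:
        log.warning("singular (boundary) variance component in at least one mixed model")

    # --- stage: networks ---------------------------------------------------
    net_dir = out / "networks"
    n_nets = 0
    for ph in ph_levels:
        nets = [
            build_control_network(fits, ph, which="single"),
            build_control_network(svs, ph, which="svs"),
            build_eoc_network(eoc, ph, pooled=config.pooled_eoc_wins),
        ]
        for net in nets:
            export_network(net, net_dir / f"{net.metric}_ph{ph}.json", "json")
            export_network(net, net_dir / f"{net.metric}_ph{ph}.csv", "csv")
            n_nets += 1
    manifest["stages"]["networks"] = {"exported": n_nets}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def format_model_table(lmm_g, lmm_p) -> str:
    """Side-by-side text summary of the two mixed models."""
    terms = list(dict.fromkeys(lmm_g.fixed_names + lmm_p.fixed_names))
    width = max(len(t) for t in terms) + 2
    lines = [
        f"{'':{width}}{'growth-based':>18}{'phylogenetic':>18}",
        "-" * (width + 36),
    ]
    for t in terms:
        cells = []
        for m in (lmm_g, lmm_p):
            if t in m.coefficients:
                c = m.coefficients[t]
                cells.append(f"{c['estimate']:.3f} ({c['se']:.3f})")
            else:
                cells.append("")
        lines.append(f"{t:{width}}{cells[0]:>18}{cells[1]:>18}")
    lines.append("-" * (width + 36))
    for label, attr in [
        ("Marginal pseudo-R2", "r2_marginal"),
        ("Conditional pseudo-R2", "r2_conditional"),
        ("Observations", "n_obs"),
        ("Log likelihood", "log_lik"),
        ("Akaike inf. crit.", "aic"),
        ("Bayesian inf. crit.", "bic"),
    ]:
        a, b = getattr(lmm_g, attr), getattr(lmm_p, attr)
        fmt = (lambda v: f"{v:d}") if attr == "n_obs" else (lambda v: f"{v:.4f}")
        lines.append(f"{label:{width}}{fmt(a):>18}{fmt(b):>18}")
    return "\n".join(lines) + "\n"
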