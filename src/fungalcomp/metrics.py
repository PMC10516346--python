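"""Competition statistics: effect of competition (EoC), growth-based
distances, and index-of-antagonism (IoA) scores.

EoC is the ratio of a strain's growth response on a competition plate to
the mean response on its pH-matched self-versus-self (SvS) control plates —
a value below 1 means the strain performed worse under interspecific
competition than against itself.  The growth-rate distance between two
species at a given pH is the absolute difference of their mean SvS
responses; it is the trait-based competitor of patristic distance in the
downstream models.  IoA assigns Wicklow–Hirschfield-style points to the
physical interaction observed at the contact zone (overgrowth scores high
for the overgrower and low for the overgrown; deadlocks score evenly).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .phylo import DistanceMatrix

__all__ = [
    "BaselineError",
    "ScoringError",
    "DEFAULT_IOA_TABLE",
    "RESPONSE_COLUMNS",
    "compute_eoc",
    "growth_distance",
    "load_scoring_table",
    "score_ioa",
]


class BaselineError(ValueError):
    """A competition observation has no usable SvS baseline."""


class ScoringError(ValueError):
    """Unknown contact-zone category or malformed scoring table."""


RESPONSE_COLUMNS = {"growth_rate": "rate", "colony_size": "max_area"}

# Per-plug points for the contact-zone interaction.  Deadlock at a distance
# (inhibition before contact) scores below deadlock with mycelial contact;
# overgrowth is asymmetric: the overgrowing plug scores high, the overgrown
# one low.  Any published variant can be supplied as a YAML mapping.
DEFAULT_IOA_TABLE = {
    "intermingling": 2,
    "deadlock_distance": 1,
    "deadlock_contact": 2,
    "overgrowth_partial": 4,
    "overgrown_partial": 1,
    "overgrowth_complete": 5,
    "overgrown_complete": 0,
}


def compute_eoc(
    competition_fits: pd.DataFrame,
    svs_fits: pd.DataFrame,
    response: str = "growth_rate",
) -> pd.DataFrame:
    """Per-plug EoC: competition response over the mean same-(species, pH)
    SvS baseline.

    ``competition_fits`` and ``svs_fits`` are fits tables as produced by
    :func:`fungalcomp.growth.fit_plates` (the SvS table after plug
    selection).  Returns one row per competition plug with ``eoc`` and
    ``log_eoc = ln(eoc)`` columns.
    """
    if response not in RESPONSE_COLUMNS:
        raise ValueError(f"response must be one of {sorted(RESPONSE_COLUMNS)}")
    col = RESPONSE_COLUMNS[response]
    comp = competition_fits[competition_fits["treatment"] == "competition"].copy()
    svs = svs_fits[svs_fits["treatment"] == "SvS"]
    baseline = svs.groupby(["focal", "ph"])[col].mean()
    needed = set(zip(comp["focal"], comp["ph"]))
    missing = sorted(p for p in needed if p not in baseline.index)
    if missing:
        raise BaselineError(f"no SvS baseline for (focal, ph) pairs: {missing}")
    nonpos = sorted(baseline.index[baseline <= 0].tolist())
    used_nonpos = [p for p in nonpos if p in needed]
    if used_nonpos:
        raise BaselineError(f"non-positive SvS baseline mean for: {used_nonpos}")
    base = baseline.loc[pd.MultiIndex.from_arrays([comp["focal"], comp["ph"]])]
    comp["response"] = response
    comp["baseline"] = base.to_numpy()
    comp["eoc"] = comp[col] / comp["baseline"]
    if (comp["eoc"] <= 0).any():
        raise BaselineError("non-positive EoC ratio (negative competition response)")
    comp["log_eoc"] = np.log(comp["eoc"])
    cols = [
        "plate_id", "plug", "focal", "opponent", "ph", "replicate",
        "response", "baseline", "eoc", "log_eoc",
    ]
    return comp[cols].reset_index(drop=True)


def growth_distance(
    svs_fits: pd.DataFrame, ph: float, response: str = "growth_rate"
) -> DistanceMatrix:
    """Absolute difference of mean SvS responses between species at ``ph``.

    d(i, j) = |mean_i - mean_j| of the SvS growth rates (or maximum colony
    sizes) at the requested pH; a one-dimensional trait distance, hence
    symmetric with zero diagonal and satisfying the triangle inequality.
    """
    if response not in RESPONSE_COLUMNS:
        raise ValueError(f"response must be one of {sorted(RESPONSE_COLUMNS)}")
    col = RESPONSE_COLUMNS[response]
    svs = svs_fits[(svs_fits["treatment"] == "SvS") & (svs_fits["ph"] == ph)]
    means = svs.groupby("focal")[col].mean().sort_index()
    all_species = sorted(svs_fits.loc[svs_fits["treatment"] == "SvS", "focal"].unique())
    missing = [s for s in all_species if s not in means.index]
    if missing or means.empty:
        raise BaselineError(f"species with no SvS data at pH {ph}: {missing or all_species}")
    vals = np.abs(means.to_numpy()[:, None] - means.to_numpy()[None, :])
    kind = "growth_rate" if response == "growth_rate" else "colony_size"
    return DistanceMatrix(tuple(means.index), vals, kind=kind, ph=ph)


def load_scoring_table(path) -> dict:
    """Load an IoA scoring table (category -> integer points) from YAML."""
    table = yaml.safe_load(Path(path).read_text())
    if not isinstance(table, dict) or not table:
        raise ScoringError(f"scoring table {path} is not a non-empty mapping")
    for cat, pts in table.items():
        if not isinstance(pts, (int, float)):
            raise ScoringError(f"scoring table entry {cat!r} is not numeric")
    return {str(k): v for k, v in table.items()}


def score_ioa(
    observations: pd.DataFrame, scoring_table: dict | None = None
) -> pd.DataFrame:
    """Score contact-zone observations against a scoring table.

    ``observations`` needs columns plate_id, focal, opponent, ph,
    focal_category, opponent_category; categories must come from the
    scoring-table vocabulary.  Returns the table with ``focal_score``,
    ``opponent_score`` and a combined ``category`` label appended.
    """
    table = DEFAULT_IOA_TABLE if scoring_table is None else scoring_table
    required = ["plate_id", "focal", "opponent", "ph", "focal_category", "opponent_category"]
    missing = [c for c in required if c not in observations.columns]
    if missing:
        raise ScoringError(f"observations missing columns: {missing}")
    cats = set(observations["focal_category"]) | set(observations["opponent_category"])
    unknown = sorted(cats - set(table))
    if unknown:
        raise ScoringError(f"unknown contact-zone categories: {unknown}")
    out = observations.copy()
    out["focal_score"] = out["focal_category"].map(table)
    out["opponent_score"] = out["opponent_category"].map(table)
    out["category"] = out["focal_category"] + "|" + out["opponent_category"]
    return out
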