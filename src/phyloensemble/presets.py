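"""Model presets for the comparative analyses, plus table preparation.

Every analysis in the study family is available as a named preset: a
declarative :class:`~phyloensemble.design.ModelSpec` plus a preprocessing
plan (derived columns and row filters) that compiles against the synthetic
observation or lake tables. Presets live in ``data/presets.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .design import ModelSpec, RandomTerm
from .growth import add_growth_columns

__all__ = [
    "PresetCatalog",
    "PreprocessingPlan",
    "PathPreset",
    "build_preset",
    "list_presets",
    "prepare_observation_table",
    "prepare_lake_table",
    "expand_interactions",
    "select_interaction_depth",
]

_RANDOM_SETS = {
    "random_experiment": [
        {"group": "strain", "covariance": "phylo"},
        {"group": "strain"},
        {"group": "lake"},
    ],
    "random_lake": [{"group": "genus", "covariance": "phylo"}],
}


def _load_catalog() -> dict:
    text = resources.files("phyloensemble").joinpath("data/presets.yaml").read_text()
    return yaml.safe_load(text)


class PresetCatalog:
    """Name -> (ModelSpec, preprocessing plan) lookup."""

    def __init__(self):
        self._raw = _load_catalog()

    def names(self) -> list[str]:
        return list(self._raw)

    def raw(self, name: str) -> dict:
        if name not in self._raw:
            raise KeyError(
                f"unknown preset {name!r}; available: {', '.join(self._raw)}"
            )
        return self._raw[name]


@dataclass
class PreprocessingPlan:
    """Derived-variable rules and filters applied before model fitting."""

    dataset: str = "experiment"
    filters: list = field(default_factory=list)

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.dataset in ("experiment", "experiment2"):
            df = prepare_observation_table(table)
        else:
            df = prepare_lake_table(table)
        for rule in self.filters:
            df = _apply_filter(df, rule)
        return df.reset_index(drop=True)


@dataclass
class PathPreset:
    """A path-analysis preset: variable mapping plus the default DAG set."""

    variables: dict[str, str]

    def dags(self):
        from .paths import default_model_set

        return default_model_set(*self.variables.keys())


def _apply_filter(df: pd.DataFrame, rule: dict) -> pd.DataFrame:
    if "drop_strains_all_zero" in rule:
        col = rule["drop_strains_all_zero"]
        totals = df.groupby("strain")[col].transform("sum")
        return df[totals > 0]
    if "keep_where_zero" in rule:
        col = rule["keep_where_zero"]
        return df[df[col] == 0]
    if "drop_zero_trials" in rule:
        a, b = rule["drop_zero_trials"]
        return df[(df[a] + df[b]) > 0]
    if "drop_level" in rule:
        fac = rule["drop_level"]["factor"]
        lev = str(rule["drop_level"]["level"])
        return df[df[fac].astype(str) != lev]
    raise ValueError(f"unknown filter rule: {rule!r}")


def build_preset(name: str, interaction_depth: int = 1):
    """Return the ModelSpec (or PathPreset) and preprocessing plan for a name.

    ``interaction_depth`` > 1 adds all factor interactions up to that order;
    lower-order terms are always retained, so estimates from an
    interaction-bearing model include all terms of the same order and lower.
    """
    catalog = PresetCatalog()
    raw = catalog.raw(name)
    plan = PreprocessingPlan(
        dataset=raw.get("dataset", "experiment"), filters=raw.get("filters", [])
    )
    if raw.get("kind") == "path":
        return PathPreset(variables=dict(raw["variables"])), plan
    fixed = [_normalise_term(t) for t in raw.get("fixed_terms", [])]
    random = [RandomTerm(**t) for t in _RANDOM_SETS[raw["random"]]]
    spec = ModelSpec(
        family=raw["family"],
        response=raw["response"],
        fixed_terms=fixed,
        random_terms=random,
        name=name,
    )
    if interaction_depth > 1:
        spec = expand_interactions(spec, interaction_depth)
    return spec, plan


def _normalise_term(term: dict) -> dict:
    # YAML may parse bare yes/no factor levels as booleans
    term = dict(term)
    if "at" in term:
        at = dict(term["at"])
        if isinstance(at.get("level"), bool):
            at["level"] = "yes" if at["level"] else "no"
        term["at"] = at
    return term


def list_presets() -> list[str]:
    return PresetCatalog().names()


def expand_interactions(spec: ModelSpec, depth: int) -> ModelSpec:
    """Add all interactions among the spec's factor terms up to ``depth``.

    All lower-order terms are kept, so a depth-3 spec contains every main
    effect, every pairwise interaction, and the three-way interaction.
    """
    from itertools import combinations

    factors = [t for t in spec.fixed_terms if "factor" in t]
    extra = []
    for d in range(2, depth + 1):
        for combo in combinations(factors, d):
            extra.append({"interaction": [dict(t) for t in combo]})
    return ModelSpec(
        family=spec.family,
        response=spec.response,
        fixed_terms=list(spec.fixed_terms) + extra,
        random_terms=list(spec.random_terms),
        name=f"{spec.name}@depth{depth}" if spec.name else "",
    )


def select_interaction_depth(
    name: str,
    data: pd.DataFrame,
    covariances: dict | None = None,
    depths=(1, 2, 3),
    by: str = "r2",
    fit_kwargs: dict | None = None,
):
    """Fit a preset at several interaction depths and pick the best model.

    ``by="r2"`` selects the highest squared prediction correlation (ties go
    to the model with fewer parameters); ``by="dic"`` the lowest DIC
    (gaussian presets only). Returns ``(best_depth, {depth: results})``.
    """
    from .model import PhyloMixedModel

    if by not in ("r2", "dic"):
        raise ValueError("by must be 'r2' or 'dic'")
    fit_kwargs = fit_kwargs or {}
    fits = {}
    scores = {}
    for depth in depths:
        spec, plan = build_preset(name, interaction_depth=depth)
        prepared = plan.apply(data)
        model = PhyloMixedModel(prepared, spec, covariances=covariances)
        res = model.fit(**fit_kwargs)
        fits[depth] = res
        if by == "r2":
            scores[depth] = (-res.r2(), len(res.samples.names))
        else:
            scores[depth] = (res.dic(), len(res.samples.names))
    best = min(scores, key=lambda d: scores[d])
    return best, fits


# ---------------------------------------------------------------------------
# table preparation
# ---------------------------------------------------------------------------

def prepare_observation_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add the derived columns the experiment presets reference.

    Counts -> proportions, presence factors (multicellular groups present;
    ECM present, binarised at >10% of inspected cells), logit-scale path
    variables, and growth-rate columns.
    """
    df = table.copy()
    df["n_classified"] = (
        df["n_single"] + df["n_palmelloid_cells"] + df["n_group_cells"]
        + (df["n_other"] if "n_other" in df.columns else 0)
    )
    df["n_nongroup"] = df["n_single"] + df["n_palmelloid_cells"]
    df["prop_group"] = df["n_group_cells"] / df["n_classified"]
    df["prop_palmelloid"] = df["n_palmelloid_cells"] / df["n_classified"]
    df["group_present"] = np.where(df["n_group_cells"] > 0, "yes", "no")
    if "ecm_single" in df.columns:
        n_images = df["n_images_ecm"] if "n_images_ecm" in df.columns else 10
        df["prop_ecm"] = df["ecm_single"] / n_images
        df["n_ecm_no"] = n_images - df["ecm_single"]
        df["ecm_present"] = np.where(df["prop_ecm"] > 0.10, "yes", "no")
        df["ecm01"] = (df["prop_ecm"] > 0.10).astype(float)
    from .design import logit_shrunk

    df["logit_group"] = logit_shrunk(df["prop_group"], df["n_classified"])
    df["logit_palmelloid"] = logit_shrunk(df["prop_palmelloid"], df["n_classified"])
    if "N_t0" in df.columns and "sgr" not in df.columns:
        df = add_growth_columns(df)
    return df


def prepare_lake_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add derived columns for the genus-level lake presets."""
    df = table.copy()
    df["ecm"] = np.where(df["ecm_present"].astype(int) == 1, "yes", "no")
    df["ratio_np"] = df["log_nitratenitrite"] - df["log_total_phosphorus"]
    return df
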