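"""Synthetic data generators with known ground truth.

The generators emulate the statistical structure the comparative analyses
assume: a factorial stress experiment on lake-derived algal strains (particle
classification counts out of 400, ECM inspection of 10 images, paired cell
concentrations) and a genus-level lake survey (binomial species counts with
water-chemistry covariates), both with phylogenetically structured random
variation. All outputs are pure functions of (inputs, seed).

Defaults mirror the study scale: 19 species, 35 strains, 10 lakes, a 2x2x2
factorial (280 strain x treatment rows), 400 classified particles per row,
and logit-scale treatment effects equal to the reported posterior contrasts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
import pandas as pd

from .trees import Phylogeny, TreeEnsemble, parse_newick, phylo_covariance

__all__ = [
    "SimulationParams",
    "FactorialDesign",
    "ExperimentData",
    "LakeData",
    "simulate_yule_tree",
    "jitter_tree_ensemble",
    "simulate_experiment",
    "simulate_lake_data",
    "default_experiment_effects",
    "default_lake_effects",
]


def default_experiment_effects() -> dict[str, dict[str, float]]:
    """True logit/identity-scale fixed effects for the experiment generator.

    Treatment offsets are the reported posterior contrasts between factor
    levels; intercepts set baseline prevalences (rare multicellular groups,
    uncommon palmelloids, roughly half of strains producing ECM). The
    ``ecm`` entry under ``palmelloid`` couples palmelloid formation to ECM
    presence, emulating the retention mechanism.
    """
    return {
        "group": {
            "intercept": -6.0,
            "predation:yes": 2.73,
            "nitrate:high": 6.73,
            "turbulence:turbulent": 3.81,
        },
        "palmelloid": {
            "intercept": -2.0,
            "predation:yes": -0.89,
            "nitrate:high": 0.67,
            "turbulence:turbulent": 0.35,
            "ecm": 0.71,
        },
        "ecm": {
            "intercept": -0.5,
            "nitrate:high": 0.84,
        },
        "sgr": {
            "intercept": 0.35,
            "predation:yes": -0.04,
            "turbulence:turbulent": -0.04,
        },
    }


def default_lake_effects() -> dict[str, dict[str, float]]:
    """True effects for the lake generator (logit scale, z-scored chemistry)."""
    return {
        "ecm": {"intercept": 0.0, "log_ammonium": 1.5, "log_nitratenitrite": 0.0},
        "multicellular": {
            "intercept": -0.5,
            "ecm": 2.0,
            "log_ammonium": 1.5,
            "ecm:log_ammonium": -1.5,
        },
    }


@dataclass
class SimulationParams:
    """Ground-truth parameters for the synthetic generators."""

    n_species: int = 19
    n_strains: int = 35
    n_lakes: int = 10
    fixed_effects: dict = field(default_factory=default_experiment_effects)
    V_phylo: float = 1.0
    V_lake: float = 0.15
    V_strain: float = 0.5
    V_residual: float = 1.0
    # growth-rate scale variances (doublings/day units, not logits)
    sgr_V_phylo: float = 0.005
    sgr_V_lake: float = 0.001
    sgr_V_strain: float = 0.002
    sgr_V_residual: float = 0.0025
    n_particles: int = 400
    n_ecm_images: int = 10
    include_other_class: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "V_phylo", "V_lake", "V_strain", "V_residual",
            "sgr_V_phylo", "sgr_V_lake", "sgr_V_strain", "sgr_V_residual",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")


@dataclass
class FactorialDesign:
    """A fully crossed factorial over named factors.

    The default is the 2x2x2 stress experiment: predation (no/yes), nitrate
    (low/high), turbulence (still/turbulent); the first level of each factor
    is the baseline.
    """

    factors: dict[str, list[str]] = field(
        default_factory=lambda: {
            "predation": ["no", "yes"],
            "nitrate": ["low", "high"],
            "turbulence": ["still", "turbulent"],
        }
    )

    def cells(self) -> list[dict[str, str]]:
        out = [{}]
        for name, levels in self.factors.items():
            out = [{**cell, name: lev} for cell in out for lev in levels]
        return out

    @classmethod
    def predator_density(cls) -> "FactorialDesign":
        """The follow-up design manipulating predator density only."""
        return cls(factors={"predation": ["none", "low", "high"]})


@dataclass
class ExperimentData:
    """A simulated observation table together with its generating truth."""

    table: pd.DataFrame
    truth: dict
    tree: Phylogeny
    design: FactorialDesign
    params: SimulationParams

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def truth_json(self) -> str:
        return json.dumps(_jsonable(self.truth), indent=2)


@dataclass
class LakeData:
    table: pd.DataFrame
    truth: dict
    tree: Phylogeny
    params: SimulationParams

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def truth_json(self) -> str:
        return json.dumps(_jsonable(self.truth), indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------

def simulate_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int | None = None,
    rng: np.random.Generator | None = None, label_prefix: str = "t",
) -> Phylogeny:
    """Simulate an ultrametric pure-birth (Yule) tree.

    The process starts from the root split (two lineages); while k lineages
    are extant the waiting time to the next split is Exp(k * birth_rate), and
    a final Exp(n * birth_rate) stretch follows the last split, so the
    expected root-to-tip depth is sum_{k=2..n} 1/(k * birth_rate).
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    tree = dendropy.Tree()
    ns = tree.taxon_namespace
    # active lineages: (node, birth_time)
    t = 0.0
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = root.new_child()
        active.append((child, 0.0))
    k = 2
    while k < n_tips:
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        node, born = active.pop(i)
        node.edge.length = t - born
        for _ in range(2):
            active.append((node.new_child(), t))
        k += 1
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    # randomize label assignment order deterministically
    order = rng.permutation(len(active))
    for rank, idx in enumerate(order, start=1):
        node, born = active[idx]
        node.edge.length = t - born
        node.taxon = ns.new_taxon(label=f"{label_prefix}{rank}")
    return Phylogeny(tree)


def jitter_tree_ensemble(
    tree: Phylogeny, k: int, noise_sd: float, seed: int | None = None
) -> TreeEnsemble:
    """Perturb branch lengths to emulate a posterior sample of trees.

    Each branch length is multiplied by an independent lognormal(0, noise_sd)
    factor and the tree is re-ultrametrized by adjusting terminal branches to
    the mean tip depth. ``noise_sd=0`` returns k exact copies.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    trees = []
    base_newick = tree.to_newick()
    for _ in range(k):
        t = parse_newick(base_newick)
        if noise_sd > 0:
            for edge in t._tree.preorder_edge_iter():
                if edge.length is not None:
                    edge.length = float(edge.length * rng.lognormal(0.0, noise_sd))
            depths = t.tip_depths()
            # re-ultrametrize by extending terminal branches to the deepest
            # tip, so no adjusted branch can go negative
            target = float(max(depths.values()))
            for leaf in t._tree.leaf_node_iter():
                leaf.edge.length = (leaf.edge.length or 0.0) + (
                    target - depths[leaf.taxon.label]
                )
        trees.append(t)
    return TreeEnsemble(trees, source=f"jitter(sd={noise_sd})")


# ---------------------------------------------------------------------------
# experiment simulation
# ---------------------------------------------------------------------------

def _phylo_effects(
    cov_corr: np.ndarray, variance: float, rng: np.random.Generator
) -> np.ndarray:
    if variance == 0:
        return np.zeros(cov_corr.shape[0])
    L = np.linalg.cholesky(cov_corr + 1e-10 * np.eye(cov_corr.shape[0]))
    return np.sqrt(variance) * (L @ rng.standard_normal(cov_corr.shape[0]))


def _assign_strains(
    species: list[str], n_strains: int, rng: np.random.Generator
) -> dict[str, str]:
    """Map strain id -> species, each species getting at least one strain."""
    if n_strains < len(species):
        raise ValueError("need at least one strain per species")
    owners = list(species) + list(
        rng.choice(species, size=n_strains - len(species), replace=True)
    )
    rng.shuffle(owners)
    return {f"s{i + 1:02d}": owners[i] for i in range(n_strains)}


def _eta(effects: dict[str, float], cell: dict[str, str]) -> float:
    """Fixed-effect linear predictor for one treatment cell."""
    eta = effects.get("intercept", 0.0)
    for factor, level in cell.items():
        eta += effects.get(f"{factor}:{level}", 0.0)
    return eta


def simulate_experiment(
    tree: Phylogeny,
    design: FactorialDesign | None = None,
    params: SimulationParams | None = None,
    seed: int | None = None,
) -> ExperimentData:
    """Simulate a strain x treatment observation table on a species tree.

    For every strain x treatment cell, logit-linear predictors for the
    probability that a classified cell sits in a multicellular group, in a
    palmelloid, and that a single cell carries ECM are formed from treatment
    effects plus phylogenetic (MVN over species), lake, strain, and residual
    Gaussian effects; counts are one multinomial of ``n_particles`` per row
    and ECM is a binomial over ``n_ecm_images`` inspected images. Specific
    growth rate is Gaussian on the doublings/day scale with its own (smaller)
    variance components; concentrations are back-derived from it.
    """
    design = design or FactorialDesign()
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)

    species = tree.tip_labels
    if params.n_species and params.n_species != len(species):
        # tree defines the species set; n_species follows the tree
        params = _replace(params, n_species=len(species))
    C = phylo_covariance(tree, as_correlation=True)
    strain_species = _assign_strains(species, params.n_strains, rng)
    strains = sorted(strain_species)
    lakes = [f"L{i + 1:02d}" for i in range(params.n_lakes)]
    strain_lake = {s: lakes[int(rng.integers(params.n_lakes))] for s in strains}

    responses = ["group", "palmelloid", "ecm"]
    sp_index = {sp: i for i, sp in enumerate(species)}
    effs = {}
    for resp in responses:
        effs[resp] = {
            "phylo": _phylo_effects(C.matrix, params.V_phylo, rng),
            "lake": rng.normal(0, np.sqrt(params.V_lake), params.n_lakes),
            "strain": rng.normal(0, np.sqrt(params.V_strain), params.n_strains),
        }
    effs["sgr"] = {
        "phylo": _phylo_effects(C.matrix, params.sgr_V_phylo, rng),
        "lake": rng.normal(0, np.sqrt(params.sgr_V_lake), params.n_lakes),
        "strain": rng.normal(0, np.sqrt(params.sgr_V_strain), params.n_strains),
    }
    lake_index = {lk: i for i, lk in enumerate(lakes)}
    strain_index = {s: i for i, s in enumerate(strains)}
    fx = params.fixed_effects

    def random_part(resp: str, strain: str) -> float:
        e = effs[resp]
        return (
            e["phylo"][sp_index[strain_species[strain]]]
            + e["lake"][lake_index[strain_lake[strain]]]
            + e["strain"][strain_index[strain]]
        )

    rows = []
    cells = design.cells()
    factor_names = list(design.factors)
    # strain-level baseline palmelloid share at t0 (pre-treatment)
    p_palm_t0 = {
        s: _logistic(fx["palmelloid"].get("intercept", 0.0) + random_part("palmelloid", s))
        for s in strains
    }
    for strain in strains:
        for cell in cells:
            eta_ecm = (
                _eta(fx.get("ecm", {}), cell)
                + random_part("ecm", strain)
                + rng.normal(0, np.sqrt(params.V_residual))
            )
            p_ecm = _logistic(eta_ecm)
            ecm_single = int(rng.binomial(params.n_ecm_images, p_ecm))

            eta_palm = (
                _eta(fx.get("palmelloid", {}), cell)
                + fx.get("palmelloid", {}).get("ecm", 0.0) * p_ecm
                + random_part("palmelloid", strain)
                + rng.normal(0, np.sqrt(params.V_residual))
            )
            eta_grp = (
                _eta(fx.get("group", {}), cell)
                + fx.get("group", {}).get("palmelloid", 0.0) * eta_palm
                + random_part("group", strain)
                + rng.normal(0, np.sqrt(params.V_residual))
            )
            p_grp = _logistic(eta_grp)
            p_palm = (1.0 - p_grp) * _logistic(eta_palm)
            if params.include_other_class:
                p_other = 0.02 * (1.0 - p_grp - p_palm)
            else:
                p_other = 0.0
            p_single = max(1.0 - p_grp - p_palm - p_other, 0.0)
            probs = np.array([p_single, p_palm, p_grp, p_other])
            probs = probs / probs.sum()
            counts = rng.multinomial(params.n_particles, probs)

            sgr = (
                _eta(fx.get("sgr", {}), cell)
                + random_part("sgr", strain)
                + rng.normal(0, np.sqrt(params.sgr_V_residual))
            )
            n_t0 = float(rng.uniform(5000, 10000))
            t0, t1 = 0.0, 14.0
            n_t1 = n_t0 * 2.0 ** (sgr * (t1 - t0))
            row = {
                "observation_id": f"{strain}_{'_'.join(cell[f] for f in factor_names)}",
                "strain": strain,
                "species": strain_species[strain],
                "lake": strain_lake[strain],
                **cell,
                "n_single": int(counts[0]),
                "n_palmelloid_cells": int(counts[1]),
                "n_group_cells": int(counts[2]),
                "ecm_single": ecm_single,
                "prop_palmelloid_t0": p_palm_t0[strain],
                "N_t0": n_t0,
                "N_t1": n_t1,
                "t0": t0,
                "t1": t1,
            }
            if params.include_other_class:
                row["n_other"] = int(counts[3])
            rows.append(row)
    table = pd.DataFrame(rows)
    truth = {
        "fixed_effects": fx,
        "variances": {
            "V_phylo": params.V_phylo,
            "V_lake": params.V_lake,
            "V_strain": params.V_strain,
            "V_residual": params.V_residual,
        },
        "sgr_variances": {
            "V_phylo": params.sgr_V_phylo,
            "V_lake": params.sgr_V_lake,
            "V_strain": params.sgr_V_strain,
            "V_residual": params.sgr_V_residual,
        },
        "random_effects": {r: {k: v for k, v in e.items()} for r, e in effs.items()},
        "strain_species": strain_species,
        "strain_lake": strain_lake,
    }
    return ExperimentData(table=table, truth=truth, tree=tree, design=design, params=params)


def _replace(params: SimulationParams, **kw) -> SimulationParams:
    d = asdict(params)
    d.update(kw)
    return SimulationParams(**d)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# lake survey simulation
# ---------------------------------------------------------------------------

def simulate_lake_data(
    tree: Phylogeny,
    params: SimulationParams | None = None,
    effects: dict | None = None,
    species_mean: float = 2.0,
    seed: int | None = None,
) -> LakeData:
    """Simulate the genus-level lake table on a genus tree.

    Chemistry covariates are lognormal (their logs Gaussian); genus-level ECM
    presence and the number of obligately multicellular species out of the
    genus's species count follow logit-linear models with phylogenetic
    effects. Chemistry slopes apply to z-scored log concentrations.
    """
    params = params or SimulationParams()
    effects = effects or default_lake_effects()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    genera = tree.tip_labels
    n = len(genera)
    C = phylo_covariance(tree, as_correlation=True)

    chem = {
        "log_ammonium": rng.normal(3.0, 1.0, n),
        "log_nitratenitrite": rng.normal(4.0, 1.0, n),
        "log_total_phosphorus": rng.normal(2.5, 0.8, n),
    }
    z_am = (chem["log_ammonium"] - chem["log_ammonium"].mean()) / chem["log_ammonium"].std()
    z_nn = (
        chem["log_nitratenitrite"] - chem["log_nitratenitrite"].mean()
    ) / chem["log_nitratenitrite"].std()

    e_ecm = effects["ecm"]
    phylo_e = _phylo_effects(C.matrix, params.V_phylo, rng)
    eta_ecm = (
        e_ecm.get("intercept", 0.0)
        + e_ecm.get("log_ammonium", 0.0) * z_am
        + e_ecm.get("log_nitratenitrite", 0.0) * z_nn
        + phylo_e
    )
    ecm_flag = rng.random(n) < _logistic(eta_ecm)

    e_mc = effects["multicellular"]
    phylo_m = _phylo_effects(C.matrix, params.V_phylo, rng)
    eta_mc = (
        e_mc.get("intercept", 0.0)
        + e_mc.get("ecm", 0.0) * ecm_flag
        + e_mc.get("log_ammonium", 0.0) * z_am
        + e_mc.get("log_nitratenitrite", 0.0) * z_nn
        + e_mc.get("ecm:log_ammonium", 0.0) * ecm_flag * z_am
        + phylo_m
        + rng.normal(0, np.sqrt(params.V_residual), n)
    )
    n_species = 1 + rng.poisson(species_mean, n)
    n_mc = rng.binomial(n_species, _logistic(eta_mc))
    table = pd.DataFrame(
        {
            "genus": genera,
            "n_species_multicellular": n_mc,
            "n_species_unicellular": n_species - n_mc,
            "ecm_present": ecm_flag.astype(int),
            "n_species_ecm": np.where(ecm_flag, n_species, 0),
            "n_species_no_ecm": np.where(ecm_flag, 0, n_species),
            **chem,
        }
    )
    truth = {
        "effects": effects,
        "V_phylo": params.V_phylo,
        "V_residual": params.V_residual,
        "phylo_ecm": phylo_e,
        "phylo_multicellular": phylo_m,
    }
    return LakeData(table=table, truth=truth, tree=tree, params=params)
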