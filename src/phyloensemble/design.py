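"""Model specification and design-matrix construction.

The fixed-effect coding follows the comparative-analysis convention used
throughout the package: the global intercept is removed so the first factor
contributes one column per level (absolute level estimates), subsequent
factors drop their first (baseline) level, continuous covariates are z-scored
on the analysis data, proportion covariates are logit-transformed after a
shrink that keeps 0 and 1 finite, and conditional ("at level") covariates are
active only within one factor level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ModelSpec", "PriorSpec", "RandomTerm", "build_design", "DesignError"]


class DesignError(ValueError):
    """Raised for invalid model specifications or rank-deficient designs."""


@dataclass(frozen=True)
class RandomTerm:
    """A variance component: a grouping column with a covariance structure.

    ``covariance`` is ``"identity"`` or a key into the covariance mapping
    passed at fit time (e.g. ``"phylo"``).
    """

    group: str
    covariance: str = "identity"
    name: str = ""

    def __post_init__(self):
        if not self.name:
            object.__setattr__(
                self,
                "name",
                self.group if self.covariance == "identity"
                else f"{self.covariance}.{self.group}",
            )


@dataclass
class ModelSpec:
    """Declarative description of a (phylogenetic) mixed model.

    ``response`` is a column name for the gaussian family or a
    ``(successes, failures)`` column pair for binomial-logit. ``fixed_terms``
    is a list of term dicts:

    - ``{"factor": col}``
    - ``{"covariate": col, "transform": "z" | "logit" | "none"}``
    - ``{"covariate": col, "at": {"factor": col2, "level": lev}, ...}``
    - ``{"interaction": [term, term, ...]}``
    """

    family: str
    response: str | tuple[str, str] | list
    fixed_terms: list = field(default_factory=list)
    random_terms: list = field(default_factory=list)
    name: str = ""

    def __post_init__(self):
        if self.family not in ("gaussian", "binomial-logit"):
            raise DesignError(f"unknown family: {self.family!r}")
        if isinstance(self.response, list):
            self.response = tuple(self.response)
        if self.family == "binomial-logit" and not (
            isinstance(self.response, tuple) and len(self.response) == 2
        ):
            raise DesignError(
                "binomial-logit requires a (successes, failures) column pair"
            )
        self.random_terms = [
            t if isinstance(t, RandomTerm) else RandomTerm(**t)
            for t in self.random_terms
        ]

    def response_columns(self) -> list[str]:
        if isinstance(self.response, tuple):
            return list(self.response)
        return [self.response]


@dataclass
class PriorSpec:
    """Default priors: diffuse normal fixed effects, inverse-gamma variances.

    The variance prior is inverse-gamma with shape nu/2 and scale nu*V/2
    (equivalently scaled-inverse-chi-square(nu, V)), applied independently to
    each random term and the residual.
    """

    fixed_mean: float = 0.0
    fixed_variance: float = 1e10
    variance_prior_V: float = 1.0
    variance_prior_nu: float = 0.002

    def __post_init__(self):
        if self.fixed_variance <= 0:
            raise DesignError("fixed_variance must be positive")
        if self.variance_prior_nu <= 0:
            raise DesignError("variance_prior_nu must be positive")


def logit_shrunk(p: np.ndarray, n: int | np.ndarray = 400) -> np.ndarray:
    """Logit of proportions after the (p(n-1)+0.5)/n shrink avoiding +-inf."""
    p = np.asarray(p, dtype=float)
    q = (p * (np.asarray(n) - 1) + 0.5) / np.asarray(n)
    return np.log(q / (1 - q))


def _factor_block(
    data: pd.DataFrame, col: str, drop_first: bool
) -> tuple[np.ndarray, list[str]]:
    if col not in data.columns:
        raise DesignError(f"factor column not in data: {col!r}")
    values = data[col].astype(str)
    levels = sorted(values.unique())
    use = levels[1:] if drop_first else levels
    cols = np.column_stack([(values == lev).to_numpy(float) for lev in use])
    names = [f"{col}[{lev}]" for lev in use]
    return cols, names


def _covariate_block(
    data: pd.DataFrame, term: dict
) -> tuple[np.ndarray, list[str]]:
    col = term["covariate"]
    if col not in data.columns:
        raise DesignError(f"covariate column not in data: {col!r}")
    x = data[col].to_numpy(float)
    transform = term.get("transform", "z")
    if transform == "logit":
        n = term.get("denominator", 400)
        if isinstance(n, str):
            n = data[n].to_numpy(float)
        x = logit_shrunk(x, n)
    elif transform == "z":
        sd = x.std()
        x = (x - x.mean()) / (sd if sd > 0 else 1.0)
    elif transform != "none":
        raise DesignError(f"unknown transform: {transform!r}")
    name = col if transform == "none" else f"{transform}({col})"
    if "at" in term:
        fac, lev = term["at"]["factor"], str(term["at"]["level"])
        if fac not in data.columns:
            raise DesignError(f"conditional factor not in data: {fac!r}")
        values = data[fac].astype(str)
        if lev not in set(values):
            raise DesignError(f"level {lev!r} not found in factor {fac!r}")
        x = x * (values == lev).to_numpy(float)
        name = f"{name}@{fac}[{lev}]"
    return x[:, None], [name]


def _term_block(
    data: pd.DataFrame, term: dict, first_factor_seen: list[bool]
) -> tuple[np.ndarray, list[str]]:
    if "factor" in term:
        drop_first = first_factor_seen[0]
        first_factor_seen[0] = True
        return _factor_block(data, term["factor"], drop_first)
    if "covariate" in term:
        return _covariate_block(data, term)
    if "interaction" in term:
        blocks = [
            _term_block(data, sub, [True])  # interactions always drop-first
            for sub in term["interaction"]
        ]
        X, names = blocks[0]
        for Xb, nb in blocks[1:]:
            X = np.concatenate(
                [X[:, [i]] * Xb for i in range(X.shape[1])], axis=1
            )
            names = [f"{a}:{b}" for a in names for b in nb]
        return X, names
    raise DesignError(f"unrecognised fixed term: {term!r}")


def build_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, list[str]]:
    """Build the intercept-free fixed-effect design matrix.

    Returns ``(X, column_names)``. Raises :class:`DesignError` listing aliased
    columns if the design is rank-deficient.
    """
    for col in spec.response_columns():
        if col not in data.columns:
            raise DesignError(f"response column not in data: {col!r}")
    first_factor_seen = [False]
    blocks, names = [], []
    for term in spec.fixed_terms:
        X, nm = _term_block(data, term, first_factor_seen)
        blocks.append(X)
        names.extend(nm)
    if not blocks:
        # intercept-only model
        return np.ones((len(data), 1)), ["intercept"]
    X = np.concatenate(blocks, axis=1)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = _aliased_columns(X, names)
        raise DesignError(f"rank-deficient design; aliased columns: {aliased}")
    return X, names


def _aliased_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, R, piv = _qr_pivot(X)
    tol = abs(R[0, 0]) * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(np.abs(np.diag(R)) > tol))
    return sorted(names[i] for i in piv[rank:])


def _qr_pivot(X):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv
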