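"""Bayesian phylogenetic mixed models with MCMC estimation.

The model is a Gaussian or binomial-logit mixed regression

    y = X b + sum_k Z_k u_k + e,   u_k ~ N(0, s2_k A_k),   e ~ N(0, s2_e I)

where each ``A_k`` is the identity or a phylogenetic covariance matrix over
group levels. Fixed effects carry diffuse normal priors; every variance has
an inverse-gamma prior with shape nu/2 and scale nu*V/2 (V=1, nu=0.002 by
default). Gaussian responses yield a fully conjugate Gibbs sampler. Binomial
counts are handled through latent logit-scale liabilities updated by
random-walk Metropolis with Robbins-Monro adaptation (target acceptance 0.44,
frozen after burn-in); conditional on the liabilities everything else is
conjugate. The final chain state is returned so ensembles of trees can be
chained, passing the state of tree i as the start of tree i+1.
"""

from __future__ import annotations

import hashlib
import io
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignError, ModelSpec, PriorSpec, RandomTerm, build_design
from .trees import PhyloCovariance

__all__ = [
    "PosteriorSamples",
    "MCMCState",
    "PhyloMixedModel",
    "PMMResults",
    "fit_pmm",
    "gls_oracle",
    "compute_dic",
    "compute_r2",
]


@dataclass
class PosteriorSamples:
    """Pooled MCMC draws for fixed effects and variance components."""

    names: list[str]
    draws: np.ndarray  # (n_draws, n_params)
    meta: pd.DataFrame  # columns: tree_index, iteration
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.draws = np.atleast_2d(np.asarray(self.draws, dtype=float))
        if self.draws.shape[0] < 1:
            raise ValueError("PosteriorSamples requires >= 1 draw")
        if self.draws.shape[1] != len(self.names):
            raise ValueError("draw matrix width does not match parameter names")
        if np.isnan(self.draws).any():
            raise ValueError("NaN in posterior draws")

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.draws[:, self.names.index(name)]

    def variance_columns(self) -> dict[str, np.ndarray]:
        return {
            n[2:-1]: self.column(n) for n in self.names if n.startswith("V[")
        }

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=self.names)
        return pd.concat([self.meta.reset_index(drop=True), df], axis=1)

    def to_csv(self, path) -> None:
        header = {
            "names": self.names,
            "spec_hash": self.extras.get("spec_hash"),
            "seed": self.extras.get("seed"),
        }
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header) + "\n")
            self.to_dataframe().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "PosteriorSamples":
        with open(path) as fh:
            first = fh.readline()
            header = json.loads(first.lstrip("# ")) if first.startswith("#") else {}
            df = pd.read_csv(fh)
        names = header.get("names") or [
            c for c in df.columns if c not in ("tree_index", "iteration")
        ]
        meta = df[[c for c in ("tree_index", "iteration") if c in df.columns]]
        return cls(
            names=list(names),
            draws=df[names].to_numpy(),
            meta=meta,
            extras={k: header.get(k) for k in ("spec_hash", "seed")},
        )

    @classmethod
    def concatenate(cls, parts: list["PosteriorSamples"]) -> "PosteriorSamples":
        names = parts[0].names
        for p in parts[1:]:
            if p.names != names:
                raise ValueError("cannot pool posteriors with different parameters")
        draws = np.vstack([p.draws for p in parts])
        meta = pd.concat([p.meta for p in parts], ignore_index=True)
        extras = dict(parts[0].extras)
        # pool prediction/deviance accumulators weighted by draw counts
        for key in ("mean_eta",):
            if all(key in p.extras for p in parts):
                w = np.array([p.n_draws for p in parts], dtype=float)
                stacked = np.stack([np.asarray(p.extras[key]) for p in parts])
                extras[key] = (stacked * w[:, None]).sum(0) / w.sum()
        for key in ("deviance",):
            if all(key in p.extras for p in parts):
                extras[key] = np.concatenate(
                    [np.asarray(p.extras[key]) for p in parts]
                )
        if all("u_mean" in p.extras for p in parts):
            w = np.array([p.n_draws for p in parts], dtype=float)
            keys = parts[0].extras["u_mean"].keys()
            extras["u_mean"] = {
                k: (
                    np.stack([np.asarray(p.extras["u_mean"][k]) for p in parts])
                    * w[:, None]
                ).sum(0)
                / w.sum()
                for k in keys
            }
        return cls(names=names, draws=draws, meta=meta, extras=extras)


@dataclass
class MCMCState:
    """Chain state handed from one tree's fit to the next."""

    beta: np.ndarray
    u: dict[str, np.ndarray]
    variances: dict[str, float]
    liabilities: np.ndarray | None = None
    step_size: float = 0.5

    def copy(self) -> "MCMCState":
        return MCMCState(
            beta=self.beta.copy(),
            u={k: v.copy() for k, v in self.u.items()},
            variances=dict(self.variances),
            liabilities=None if self.liabilities is None else self.liabilities.copy(),
            step_size=self.step_size,
        )


def gls_oracle(y, X, V):
    """Closed-form generalized least squares: (X'V^-1X)^-1 X'V^-1 y.

    Returns ``(coefficients, coefficient covariance)``. Independent of the
    MCMC path; used as a test oracle for the Gaussian sampler.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    V = np.asarray(V, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix X is rank deficient")
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"covariance V not positive-definite: {exc}")
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    XtX = Xw.T @ Xw
    coef = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ coef
    n, p = X.shape
    s2 = float(resid @ resid) / max(n - p, 1)
    cov = s2 * np.linalg.inv(XtX)
    return coef, cov


def _spec_hash(spec: ModelSpec) -> str:
    blob = json.dumps(
        {
            "family": spec.family,
            "response": spec.response,
            "fixed": spec.fixed_terms,
            "random": [(t.name, t.group, t.covariance) for t in spec.random_terms],
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


class _Sampler:
    """Internal Gibbs/Metropolis machinery shared by single and chained fits."""

    def __init__(self, data, spec, covariances, priors, fix_residual=False):
        self.spec = spec
        self.priors = priors or PriorSpec()
        self.fix_residual = fix_residual
        self.X, self.xnames = build_design(data, spec)
        self.n, self.p = self.X.shape
        self.XtX = self.X.T @ self.X

        if spec.family == "gaussian":
            self.y = data[spec.response].to_numpy(float)
            if np.isnan(self.y).any():
                raise ValueError("NaN in response")
            self.successes = self.trials = None
        else:
            s_col, f_col = spec.response
            succ = data[s_col].to_numpy()
            fail = data[f_col].to_numpy()
            if not (
                np.issubdtype(succ.dtype, np.integer)
                or np.allclose(succ, np.round(succ))
            ) or not (
                np.issubdtype(fail.dtype, np.integer)
                or np.allclose(fail, np.round(fail))
            ):
                raise ValueError("binomial responses must be integer count pairs")
            self.successes = succ.astype(float)
            self.trials = (succ + fail).astype(float)
            if (self.trials < 1).any():
                raise ValueError("binomial rows need at least one trial")
            self.y = None

        covariances = covariances or {}
        self.terms = []
        for term in spec.random_terms:
            groups = data[term.group].astype(str).to_numpy()
            if term.covariance == "identity":
                levels = sorted(set(groups))
                A_inv = np.eye(len(levels))
            else:
                if term.covariance not in covariances:
                    raise DesignError(
                        f"no covariance supplied for random term {term.name!r}"
                    )
                cov = covariances[term.covariance]
                if not isinstance(cov, PhyloCovariance):
                    cov = PhyloCovariance(list(cov.index), np.asarray(cov))
                levels = sorted(set(groups))
                cov = cov.reorder(levels)
                w, _ = np.linalg.eigh(cov.matrix)
                if w.min() <= 0:
                    raise np.linalg.LinAlgError(
                        f"covariance for term {term.name!r} not positive-definite "
                        f"(min eigenvalue {w.min():.3e})"
                    )
                A_inv = np.linalg.inv(cov.matrix)
                A_inv = 0.5 * (A_inv + A_inv.T)
            level_index = {lev: i for i, lev in enumerate(levels)}
            g = np.array([level_index[x] for x in groups])
            counts = np.bincount(g, minlength=len(levels)).astype(float)
            self.terms.append(
                {
                    "name": term.name,
                    "g": g,
                    "q": len(levels),
                    "levels": levels,
                    "A_inv": A_inv,
                    "counts": counts,
                }
            )

        self.param_names = list(self.xnames) + [
            f"V[{t['name']}]" for t in self.terms
        ] + ["V[units]"]

    # -- state -------------------------------------------------------------
    def initial_state(self, rng) -> MCMCState:
        beta = np.zeros(self.p)
        u = {t["name"]: np.zeros(t["q"]) for t in self.terms}
        variances = {t["name"]: 1.0 for t in self.terms}
        variances["units"] = 1.0
        liab = None
        if self.spec.family == "binomial-logit":
            from .design import logit_shrunk

            liab = logit_shrunk(self.successes / self.trials, self.trials)
        return MCMCState(beta=beta, u=u, variances=variances, liabilities=liab)

    def _zu_sum(self, state) -> np.ndarray:
        out = np.zeros(self.n)
        for t in self.terms:
            out += state.u[t["name"]][t["g"]]
        return out

    def run(
        self,
        iterations,
        burn_in,
        thin,
        rng,
        state: MCMCState | None = None,
        tree_index: int = 0,
        adapt: bool = True,
    ):
        if burn_in >= iterations:
            raise ValueError("burn_in must be < iterations")
        pr = self.priors
        nu, V0 = pr.variance_prior_nu, pr.variance_prior_V
        Binv = 1.0 / pr.fixed_variance
        binomial = self.spec.family == "binomial-logit"
        st = state.copy() if state is not None else self.initial_state(rng)
        if binomial and st.liabilities is None:
            st.liabilities = self.initial_state(rng).liabilities

        keep = []
        meta_rows = []
        mean_eta = np.zeros(self.n)
        u_mean = {t["name"]: np.zeros(t["q"]) for t in self.terms}
        deviances = []
        n_keep = 0
        accepts = 0.0
        proposals = 0.0

        for it in range(iterations):
            sig_e = st.variances["units"]
            if binomial:
                mu = self.X @ st.beta + self._zu_sum(st)
                l = st.liabilities
                prop = l + rng.normal(0.0, st.step_size, self.n)
                delta = (
                    self.successes * (prop - l)
                    - self.trials * (np.logaddexp(0, prop) - np.logaddexp(0, l))
                    - ((prop - mu) ** 2 - (l - mu) ** 2) / (2 * sig_e)
                )
                acc = np.log(rng.random(self.n)) < delta
                l = np.where(acc, prop, l)
                st.liabilities = l
                rate = float(acc.mean())
                if it >= burn_in:  # report post-adaptation acceptance
                    accepts += acc.sum()
                    proposals += self.n
                if adapt and it < burn_in:
                    st.step_size *= float(
                        np.exp((rate - 0.44) / np.sqrt(1.0 + it))
                    )
                    st.step_size = min(max(st.step_size, 1e-3), 10.0)
                ywork = l
            else:
                ywork = self.y

            # fixed effects (conjugate)
            resid0 = ywork - self._zu_sum(st)
            P = self.XtX / sig_e + Binv * np.eye(self.p)
            Lp = np.linalg.cholesky(P)
            rhs = self.X.T @ resid0 / sig_e
            mean = np.linalg.solve(Lp.T, np.linalg.solve(Lp, rhs))
            st.beta = mean + np.linalg.solve(Lp.T, rng.standard_normal(self.p))

            # random effects (conjugate per term)
            fitted_fixed = self.X @ st.beta
            for t in self.terms:
                others = np.zeros(self.n)
                for t2 in self.terms:
                    if t2 is not t:
                        others += st.u[t2["name"]][t2["g"]]
                r = ywork - fitted_fixed - others
                b = np.bincount(t["g"], weights=r, minlength=t["q"]) / sig_e
                M = t["A_inv"] / st.variances[t["name"]] + np.diag(
                    t["counts"] / sig_e
                )
                Lm = np.linalg.cholesky(M)
                m = np.linalg.solve(Lm.T, np.linalg.solve(Lm, b))
                st.u[t["name"]] = m + np.linalg.solve(
                    Lm.T, rng.standard_normal(t["q"])
                )
                # variance update: scaled-inverse-chi-square posterior
                uu = st.u[t["name"]] @ t["A_inv"] @ st.u[t["name"]]
                st.variances[t["name"]] = (nu * V0 + uu) / rng.chisquare(
                    nu + t["q"]
                )

            # residual ("units") variance
            e = ywork - fitted_fixed - self._zu_sum(st)
            if not self.fix_residual:
                st.variances["units"] = (nu * V0 + e @ e) / rng.chisquare(
                    nu + self.n
                )

            if it >= burn_in and (it - burn_in) % thin == 0:
                row = np.concatenate(
                    [
                        st.beta,
                        [st.variances[t["name"]] for t in self.terms],
                        [st.variances["units"]],
                    ]
                )
                keep.append(row)
                meta_rows.append((tree_index, it))
                eta = fitted_fixed + self._zu_sum(st)
                mean_eta += eta
                for t in self.terms:
                    u_mean[t["name"]] += st.u[t["name"]]
                if not binomial:
                    sig = st.variances["units"]
                    dev = float(
                        self.n * np.log(2 * np.pi * sig)
                        + ((self.y - eta) ** 2).sum() / sig
                    )
                    deviances.append(dev)
                n_keep += 1

        draws = np.array(keep)
        extras = {
            "mean_eta": mean_eta / n_keep,
            "u_mean": {k: v / n_keep for k, v in u_mean.items()},
            "spec_hash": _spec_hash(self.spec),
            "acceptance": (accepts / proposals) if proposals else None,
        }
        if deviances:
            extras["deviance"] = np.array(deviances)
        samples = PosteriorSamples(
            names=self.param_names,
            draws=draws,
            meta=pd.DataFrame(meta_rows, columns=["tree_index", "iteration"]),
            extras=extras,
        )
        return samples, st


def fit_pmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    covariances: dict | None = None,
    priors: PriorSpec | None = None,
    iterations: int = 13000,
    burn_in: int = 3000,
    thin: int = 10,
    seed: int | None = None,
    initial: MCMCState | None = None,
    rng: np.random.Generator | None = None,
    tree_index: int = 0,
    fix_residual: bool = False,
    adapt: bool = True,
) -> tuple[PosteriorSamples, MCMCState]:
    """Fit a single-tree Bayesian phylogenetic mixed model by MCMC.

    Retains ``(iterations - burn_in) / thin`` draws and returns the final
    chain state so fits can be chained across a tree ensemble.
    """
    sampler = _Sampler(data, spec, covariances, priors, fix_residual=fix_residual)
    if rng is None:
        rng = np.random.default_rng(seed)
    samples, state = sampler.run(
        iterations, burn_in, thin, rng, state=initial, tree_index=tree_index,
        adapt=adapt,
    )
    samples.extras["seed"] = seed
    return samples, state


def compute_dic(samples: PosteriorSamples, data: pd.DataFrame, spec: ModelSpec) -> float:
    """Deviance information criterion for Gaussian models.

    DIC = Dbar + pD with pD = Dbar - D(posterior mean parameters). Only
    defined here for the gaussian family: marginalising random effects
    analytically is problematic for non-Gaussian responses, so no DIC is
    reported for binomial models.
    """
    if spec.family != "gaussian":
        raise ValueError(
            "DIC is only supported for gaussian models; binomial-logit models "
            "have no analytic marginal deviance here"
        )
    if "deviance" not in samples.extras:
        raise ValueError("samples carry no deviance draws (not produced by fit_pmm?)")
    dev = np.asarray(samples.extras["deviance"], dtype=float)
    dbar = float(dev.mean())
    y = data[spec.response].to_numpy(float)
    eta = np.asarray(samples.extras["mean_eta"], dtype=float)
    sig = float(samples.column("V[units]").mean())
    d_at_mean = float(len(y) * np.log(2 * np.pi * sig) + ((y - eta) ** 2).sum() / sig)
    pd_ = dbar - d_at_mean
    return dbar + pd_


def compute_r2(
    samples: PosteriorSamples,
    data: pd.DataFrame,
    spec: ModelSpec,
    include_random: bool = True,
) -> float:
    """Squared correlation between posterior-mean predictions and responses.

    Predictions include fixed and random effect posterior means by default
    (``include_random=False`` restricts to the fixed part); binomial
    predictions are mapped to the proportion scale through the inverse logit
    of the posterior-mean linear predictor and compared with observed
    proportions.
    """
    if include_random:
        eta = np.asarray(samples.extras["mean_eta"], dtype=float)
    else:
        X, names = build_design(data, spec)
        beta = np.array([samples.column(n).mean() for n in names])
        eta = X @ beta
    if spec.family == "gaussian":
        pred = eta
        obs = data[spec.response].to_numpy(float)
    else:
        s_col, f_col = spec.response
        succ = data[s_col].to_numpy(float)
        tot = succ + data[f_col].to_numpy(float)
        pred = 1.0 / (1.0 + np.exp(-eta))
        obs = succ / tot
    if len(obs) < 3:
        raise ValueError("R2 requires at least 3 observations")
    if pred.std() == 0 or obs.std() == 0:
        warnings.warn("zero-variance predictions; returning R2 = 0")
        return 0.0
    return float(np.corrcoef(pred, obs)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# model-object surface
# ---------------------------------------------------------------------------

class PhyloMixedModel:
    """A Bayesian phylogenetic mixed model bound to one dataset.

    ``fit`` runs a single-tree chain; ``fit_ensemble`` (see
    :mod:`phyloensemble.ensemble`) integrates over phylogenetic uncertainty
    by chaining the sampler across a posterior sample of trees.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        spec: ModelSpec,
        covariances: dict | None = None,
        priors: PriorSpec | None = None,
        fix_residual: bool = False,
    ):
        self.data = data
        self.spec = spec
        self.covariances = covariances or {}
        self.priors = priors or PriorSpec()
        self.fix_residual = fix_residual
        # validate the design early so errors surface before sampling; a
        # missing phylo covariance is allowed here because fit_ensemble
        # rebuilds it per tree
        try:
            self._sampler = _Sampler(
                data, spec, self.covariances, self.priors,
                fix_residual=fix_residual,
            )
            self._xnames = list(self._sampler.xnames)
        except DesignError as exc:
            if "no covariance supplied" not in str(exc):
                raise
            self._sampler = None
            _, self._xnames = build_design(data, spec)

    @classmethod
    def from_preset(cls, name: str, data: pd.DataFrame, covariances=None, **kw):
        from .presets import build_preset

        spec, plan = build_preset(name)
        prepared = plan.apply(data)
        return cls(prepared, spec, covariances=covariances, **kw)

    @property
    def exog_names(self) -> list[str]:
        return list(self._xnames)

    def fit(
        self,
        iterations: int = 13000,
        burn_in: int = 3000,
        thin: int = 10,
        seed: int | None = None,
        initial: MCMCState | None = None,
        rng: np.random.Generator | None = None,
    ) -> "PMMResults":
        samples, state = fit_pmm(
            self.data,
            self.spec,
            self.covariances,
            self.priors,
            iterations=iterations,
            burn_in=burn_in,
            thin=thin,
            seed=seed,
            initial=initial,
            rng=rng,
            fix_residual=self.fix_residual,
        )
        return PMMResults(self, samples, state)

    def fit_ensemble(self, ensemble, settings=None, augmentation=None) -> "PMMResults":
        from .ensemble import EnsembleSettings, run_over_trees

        settings = settings or EnsembleSettings.fast()
        samples, state = run_over_trees(
            self.data,
            self.spec,
            ensemble,
            priors=self.priors,
            settings=settings,
            augmentation=augmentation,
            fix_residual=self.fix_residual,
            return_state=True,
        )
        return PMMResults(self, samples, state)


class PMMResults:
    """Posterior summaries and diagnostics for a fitted model."""

    def __init__(self, model: PhyloMixedModel, samples: PosteriorSamples, state: MCMCState):
        self.model = model
        self.samples = samples
        self.final_state = state

    def summary(self) -> pd.DataFrame:
        from .summaries import hpd_interval, pmcmc, posterior_mode

        rows = []
        for name in self.samples.names:
            x = self.samples.column(name)
            lo, hi = hpd_interval(x)
            rows.append(
                {
                    "term": name,
                    "post_mode": posterior_mode(x),
                    "post_mean": float(x.mean()),
                    "hpd_low": lo,
                    "hpd_high": hi,
                    "pMCMC": pmcmc(x) if not name.startswith("V[") else np.nan,
                    "n_draws": len(x),
                }
            )
        return pd.DataFrame(rows)

    def contrast(self, term_a: str, term_b: str):
        from .summaries import level_contrast

        return level_contrast(
            self.samples.column(term_a),
            self.samples.column(term_b),
            label=f"{term_a} - {term_b}",
        )

    def i2(self) -> dict:
        from .summaries import i2_partition

        return i2_partition(self.samples.variance_columns(), self.model.spec.family)

    def dic(self) -> float:
        return compute_dic(self.samples, self.model.data, self.model.spec)

    def r2(self) -> float:
        return compute_r2(self.samples, self.model.data, self.model.spec)

    def plot_trace(self, names=None, path=None):  # pragma: no cover - thin plotting
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        names = names or self.samples.names
        fig, axes = plt.subplots(len(names), 1, figsize=(7, 1.8 * len(names)))
        if len(names) == 1:
            axes = [axes]
        for ax, name in zip(axes, names):
            ax.plot(self.samples.column(name), lw=0.5)
            ax.set_ylabel(name)
        fig.tight_layout()
        if path:
            fig.savefig(path)
            plt.close(fig)
        return fig
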