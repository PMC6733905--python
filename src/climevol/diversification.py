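"""Likelihood-based birth-death diversification models with time- and
paleotemperature-dependent speciation.

The model grid contains 15 specifications: speciation constant, linear or
exponential in time, or linear or exponential in a paleotemperature curve
T(t); extinction zero, constant, or linearly covarying with the same driver
as speciation (with time for constant-speciation models).  Models are fitted
by maximum likelihood on the branching times of an ultrametric tree,
conditioning on survival of both crown lineages, and ranked by AIC.

The log-likelihood uses the standard reconstructed-process survival
integrals for time-varying rates.  With time t measured backwards from the
present, let r(t) = lambda(t) - mu(t), R(t) = ∫_0^t r, and
I(t) = ∫_0^t lambda(s) e^{R(s)} ds.  Then the probability that a lineage
alive at age t has surviving descendants is e^{R(t)} / (1 + I(t)), the
per-lineage reconstructed density factor is g(t) = e^{R(t)} / (1 + I(t))^2,
and the crown-conditioned log-likelihood of branching ages x_1..x_{n-2}
(crown age T) is

    sum_i [log lambda(x_i) + log g(x_i)] + 2 log g(T) - 2 log( e^{R(T)} / (1 + I(T)) ).

For a pure-birth process this reduces to the closed form
lambda^{n-2} exp(-lambda * total branch length).  The integrals are
evaluated by composite Simpson quadrature on a dense age grid augmented with
the exact branching ages (so the likelihood involves no interpolation at the
evaluation points).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.integrate import cumulative_simpson

from .treekit import Tree

logger = logging.getLogger(__name__)

__all__ = [
    "DiversificationModelSpec",
    "MODEL_GRID",
    "make_spec",
    "branching_ages",
    "bd_loglik",
    "BirthDeathModel",
    "ModelFit",
    "fit_model",
    "model_grid_rank",
    "grid_to_frame",
]


@dataclass(frozen=True)
class DiversificationModelSpec:
    """One cell of the model grid: a speciation form and an extinction form.

    Speciation forms: ``const`` lambda0; ``lin_t`` lambda0 + beta*t;
    ``exp_t`` lambda0*exp(beta*t); ``lin_T`` lambda0 + beta*T(t); ``exp_T``
    lambda0*exp(beta*T(t)).  Extinction forms: ``zero``; ``const`` mu0;
    ``lin_t``/``lin_T`` mu0 + gamma*(t or T(t)).  t is age in Ma before the
    present; rates must stay positive (lambda) / non-negative (mu) over the
    tree's span.
    """

    name: str
    lambda_form: str
    mu_form: str

    @property
    def needs_paleo(self) -> bool:
        return self.lambda_form.endswith("_T") or self.mu_form.endswith("_T")

    @property
    def param_names(self) -> list[str]:
        names = ["lambda0"]
        if self.lambda_form != "const":
            names.append("beta")
        if self.mu_form == "const":
            names.append("mu0")
        elif self.mu_form in ("lin_t", "lin_T"):
            names.extend(["mu0", "gamma"])
        return names

    @property
    def k(self) -> int:
        return len(self.param_names)

    def rates(self, params: np.ndarray, paleo=None):
        """Vectorised (lambda(t), mu(t)) callables of age t."""
        p = dict(zip(self.param_names, params))
        lam0 = p["lambda0"]
        beta = p.get("beta", 0.0)
        mu0 = p.get("mu0", 0.0)
        gamma = p.get("gamma", 0.0)

        if self.lambda_form == "const":
            lam = lambda t: np.full_like(np.asarray(t, dtype=float), lam0)
        elif self.lambda_form == "lin_t":
            lam = lambda t: lam0 + beta * np.asarray(t, dtype=float)
        elif self.lambda_form == "exp_t":
            lam = lambda t: lam0 * np.exp(beta * np.asarray(t, dtype=float))
        elif self.lambda_form == "lin_T":
            lam = lambda t: lam0 + beta * paleo(t)
        elif self.lambda_form == "exp_T":
            lam = lambda t: lam0 * np.exp(beta * paleo(t))
        else:
            raise ValueError(f"unknown speciation form {self.lambda_form!r}")

        if self.mu_form == "zero":
            mu = lambda t: np.zeros_like(np.asarray(t, dtype=float))
        elif self.mu_form == "const":
            mu = lambda t: np.full_like(np.asarray(t, dtype=float), mu0)
        elif self.mu_form == "lin_t":
            mu = lambda t: mu0 + gamma * np.asarray(t, dtype=float)
        elif self.mu_form == "lin_T":
            mu = lambda t: mu0 + gamma * paleo(t)
        else:
            raise ValueError(f"unknown extinction form {self.mu_form!r}")
        return lam, mu


def _grid_specs() -> list[DiversificationModelSpec]:
    specs = []
    for lf in ("lin_t", "exp_t"):
        for mf in ("zero", "const", "lin_t"):
            specs.append(DiversificationModelSpec(f"lambda_{lf}__mu_{mf}", lf, mf))
    for lf in ("lin_T", "exp_T"):
        for mf in ("zero", "const", "lin_T"):
            specs.append(DiversificationModelSpec(f"lambda_{lf}__mu_{mf}", lf, mf))
    for mf in ("zero", "const", "lin_t"):
        specs.append(DiversificationModelSpec(f"lambda_const__mu_{mf}", "const", mf))
    return specs


#: The 15-model grid: {linear, exponential}-in-time x 3 extinction forms,
#: {linear, exponential}-in-paleotemperature x 3, constant speciation x 3.
MODEL_GRID: list[DiversificationModelSpec] = _grid_specs()


def make_spec(name: str) -> DiversificationModelSpec:
    for spec in MODEL_GRID:
        if spec.name == name:
            return spec
    raise KeyError(f"unknown model {name!r}; grid has {[s.name for s in MODEL_GRID]}")


def branching_ages(tree: Tree) -> tuple[float, np.ndarray]:
    """Crown age and ages (Ma before present) of the non-root internal nodes."""
    if not tree.is_ultrametric(rtol=1e-4):
        raise ValueError("tree must be ultrametric (dated)")
    depths = tree.depths()
    total = tree.depth
    ages = np.array(
        sorted(total - depths[n] for n in tree.internal_nodes() if n is not tree.root)
    )
    return total, ages


def bd_loglik(
    tree: Tree,
    spec: DiversificationModelSpec,
    params,
    paleo=None,
    conditioning: str = "crown",
    n_grid: int = 512,
) -> float:
    """Log-likelihood of the tree's branching times under the model.

    Returns -inf (with a debug log) if the rate functions leave their bounds
    anywhere on [0, crown age].
    """
    if spec.needs_paleo and paleo is None:
        raise ValueError(f"model {spec.name} requires a paleotemperature curve")
    if conditioning not in ("crown", "none"):
        raise ValueError("conditioning must be 'crown' or 'none'")
    params = np.asarray(params, dtype=float)
    if len(params) != spec.k:
        raise ValueError(f"model {spec.name} expects {spec.param_names}")
    T, ages = branching_ages(tree)
    lam_fn, mu_fn = spec.rates(params, paleo)

    grid = np.union1d(np.linspace(0.0, T, n_grid + 1), np.append(ages, T))
    lam_g = np.asarray(lam_fn(grid), dtype=float)
    mu_g = np.asarray(mu_fn(grid), dtype=float)
    if np.any(lam_g <= 0) or np.any(mu_g < 0) or not np.all(np.isfinite(lam_g + mu_g)):
        logger.debug("rates out of bounds for %s at params %s", spec.name, params)
        return -np.inf

    R = cumulative_simpson(lam_g - mu_g, x=grid, initial=0.0)
    I = cumulative_simpson(lam_g * np.exp(R), x=grid, initial=0.0)

    def at(t):
        idx = np.searchsorted(grid, t)
        return R[idx], I[idx], lam_g[idx]

    R_x, I_x, lam_x = at(ages)
    R_T, I_T, _ = at(np.array([T]))
    log_g = lambda r, i: r - 2.0 * np.log1p(i)
    ll = float(np.sum(np.log(lam_x) + log_g(R_x, I_x)) + 2.0 * log_g(R_T, I_T)[0])
    if conditioning == "crown":
        log_surv = float(R_T[0] - np.log1p(I_T[0]))
        ll -= 2.0 * log_surv
    return ll


@dataclass
class ModelFit:
    """MLE fit of one diversification model."""

    spec: DiversificationModelSpec
    params: dict[str, float]
    logL: float
    aic: float
    converged: bool
    n_tips: int
    delta_aic: float | None = None
    weight: float | None = None
    rank: int | None = None

    def summary(self) -> str:
        pars = ", ".join(f"{k} = {v:.4g}" for k, v in self.params.items())
        head = f"{self.spec.name}: logL = {self.logL:.3f}, AIC = {self.aic:.3f}"
        if self.rank is not None:
            head += f", rank {self.rank}, dAIC = {self.delta_aic:.2f}, w = {self.weight:.3f}"
        return head + f"\n  {pars}"


class BirthDeathModel:
    """A diversification model bound to a tree (and optionally a paleocurve).

    ``fit()`` maximises the crown-conditioned likelihood by multi-start
    bounded optimisation (Nelder-Mead with rate-positivity penalties) and
    returns a :class:`ModelFit`.
    """

    _BOUNDS = {"lambda0": (1e-6, 50.0), "beta": (-10.0, 10.0), "mu0": (0.0, 50.0), "gamma": (-10.0, 10.0)}

    def __init__(self, tree: Tree, spec: DiversificationModelSpec | str, paleo=None):
        self.tree = tree
        self.spec = make_spec(spec) if isinstance(spec, str) else spec
        self.paleo = paleo
        if self.spec.needs_paleo and paleo is None:
            raise ValueError(f"model {self.spec.name} requires a paleotemperature curve")
        self.crown_age, self.ages = branching_ages(tree)
        self.n_tips = len(tree.tip_labels)

    def loglik(self, params) -> float:
        return bd_loglik(self.tree, self.spec, params, self.paleo)

    def _start_points(self, rng: np.random.Generator, n_starts: int) -> list[np.ndarray]:
        n = self.n_tips
        tl = sum(node.length for node in self.tree.preorder() if node.parent is not None)
        lam_yule = max((n - 2) / tl, 1e-3) if tl > 0 else 0.5
        # for temperature-driven models, scale lambda0 to the mean-temperature level
        scale_T = float(np.mean(self.paleo(np.linspace(0, self.crown_age, 64)))) if self.paleo else 0.0
        starts = []
        for s in range(n_starts):
            p = []
            jitter = rng.lognormal(0.0, 0.4) if s else 1.0
            for name in self.spec.param_names:
                if name == "lambda0":
                    p.append(lam_yule * jitter)
                elif name == "beta":
                    if s == 0:
                        p.append(0.0)  # the constant-rate submodel is always feasible
                    elif self.spec.lambda_form in ("lin_T", "exp_T") and scale_T:
                        p.append(rng.normal(0.0, 0.02))
                    else:
                        p.append(rng.normal(0.0, 0.05))
                elif name == "mu0":
                    p.append(lam_yule * (0.1 if s == 0 else rng.uniform(0.01, 0.3)))
                elif name == "gamma":
                    p.append(0.0 if s == 0 else rng.normal(0.0, 0.01))
            starts.append(np.asarray(p))
        return starts

    def fit(self, seed: int = 0, n_starts: int = 5) -> ModelFit:
        rng = np.random.default_rng(seed)
        bounds = [self._BOUNDS[n] for n in self.spec.param_names]

        def objective(p):
            for v, (lo, hi) in zip(p, bounds):
                if not (lo <= v <= hi):
                    return 1e10
            ll = self.loglik(p)
            return 1e10 if not np.isfinite(ll) else -ll

        best, best_val, any_ok = None, np.inf, False
        for start in self._start_points(rng, n_starts):
            # repair infeasible starts by shrinking slope terms toward the
            # always-feasible constant-rate submodel
            for _ in range(30):
                if objective(start) < 1e9:
                    break
                start = start.copy()
                for j, name in enumerate(self.spec.param_names):
                    if name in ("beta", "gamma"):
                        start[j] *= 0.5
                    elif name == "mu0":
                        start[j] *= 0.7
            if objective(start) >= 1e9:
                continue
            res = optimize.minimize(
                objective, start, method="Nelder-Mead",
                options={"maxiter": 2000, "xatol": 1e-7, "fatol": 1e-8},
            )
            if res.fun < best_val:
                best, best_val = res, res.fun
                any_ok = any_ok or res.success
        if best is None or not np.isfinite(best_val) or best_val >= 1e10:
            raise RuntimeError(f"all optimisation starts failed for {self.spec.name}")
        logL = -best_val
        return ModelFit(
            spec=self.spec,
            params=dict(zip(self.spec.param_names, (float(v) for v in best.x))),
            logL=logL,
            aic=2 * self.spec.k - 2 * logL,
            converged=bool(any_ok),
            n_tips=self.n_tips,
        )


def fit_model(tree: Tree, spec, paleo=None, seed: int = 0, n_starts: int = 5) -> ModelFit:
    """Fit one diversification model by multi-start maximum likelihood."""
    return BirthDeathModel(tree, spec, paleo).fit(seed=seed, n_starts=n_starts)


def model_grid_rank(tree: Tree, paleo, seed: int = 0, n_starts: int = 5) -> list[ModelFit]:
    """Fit the full 15-model grid and rank by AIC.

    Individual model failures are logged and skipped; an all-failed grid
    raises.  Returns fits sorted by AIC with dAIC, Akaike weights and ranks
    filled in.
    """
    fits = []
    for i, spec in enumerate(MODEL_GRID):
        try:
            fits.append(fit_model(tree, spec, paleo, seed=seed + i, n_starts=n_starts))
        except Exception as exc:  # keep the grid going
            logger.warning("model %s failed: %s", spec.name, exc)
    if not fits:
        raise RuntimeError("every model in the grid failed to fit")
    fits.sort(key=lambda f: f.aic)
    best = fits[0].aic
    rel = np.array([np.exp(-0.5 * (f.aic - best)) for f in fits])
    weights = rel / rel.sum()
    for r, (f, w) in enumerate(zip(fits, weights), start=1):
        f.delta_aic = f.aic - best
        f.weight = float(w)
        f.rank = r
    return fits


def grid_to_frame(fits: list[ModelFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        row = {
            "model": f.spec.name,
            "k": f.spec.k,
            "logL": f.logL,
            "AIC": f.aic,
            "dAIC": f.delta_aic,
            "weight": f.weight,
            "rank": f.rank,
            "converged": f.converged,
        }
        row.update({f"par_{k}": v for k, v in f.params.items()})
        rows.append(row)
    return pd.DataFrame(rows)
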