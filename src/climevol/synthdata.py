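"""Synthetic inputs with known ground truth for the whole pipeline.

Every generator is a pure function of its seed.  The generators emulate the
statistical structure of the empirical inputs the pipeline was designed for:

* a dated birth-death species tree (extinct lineages pruned, ultrametric);
* per-gene trees whose branch lengths are elapsed time multiplied by an
  environment-coupled substitution rate, ``exp(a + b * env)`` with lognormal
  gene-by-branch noise — the structure behind "species in hotter environments
  accumulate substitutions faster";
* BM/OU-evolved continuous traits;
* gridded hourly microclimate with diurnal and seasonal cycles, one
  representative day per month, plus the implied monthly T_max/T_min
  climatology;
* occurrence points within circular species ranges;
* raw physiology series (hourly body weights; per-minute body temperatures)
  with configurable true preferred temperature and water-loss rate;
* a Cenozoic-like cooling paleotemperature curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .bioclim import MicroclimGrid, OccurrenceSet
from .treekit import Tree, TreeNode

__all__ = [
    "SimConfig",
    "PaleoCurve",
    "sim_bd_tree",
    "sim_trait",
    "sim_gene_trees",
    "sim_microclim_grid",
    "sim_occurrences",
    "sim_physio_raw",
    "sim_paleo_curve",
]


@dataclass
class SimConfig:
    """Ground-truth parameters of a synthetic study.

    Defaults define the standard study conditions: a 40-species clade with a
    35-Ma crown (lambda0 = 0.15/Ma per lineage, mu0 = 0.05), a thermal niche
    evolving by BM (sigma2 chosen so tip spread spans a few hundred hot hours
    on the env scale used for rate coupling), 200 genes with coupling slope
    b = 0.02 per env unit and lognormal noise sd 0.1, and physiology truths
    typical of a mid-sized lacertid (T_pref 33 °C, 0.02 g/h loss, 5 g mass).
    """

    seed: int = 0
    lambda0: float = 0.15
    mu0: float = 0.05
    n_species: int = 40
    trait_model: str = "bm"
    sigma2: float = 1.0
    ou_alpha: float = 0.0
    ou_theta: float = 0.0
    n_genes: int = 200
    rate_intercept: float = -5.0
    rate_slope: float = 0.02
    rate_noise_sd: float = 0.1
    grid_shape: tuple[int, int] = (12, 12)
    annual_mean: float = 18.0
    mean_gradient: float = 16.0
    seasonal_amp: float = 8.0
    diurnal_amp: float = 10.0
    rad_peak: float = 800.0
    climate_noise_sd: float = 0.5
    true_tpref: float = 33.0
    tpref_env_slope: float = 0.8
    true_hourly_loss: float = 0.02
    iwl_env_slope: float = -0.002
    mass_mean: float = 5.0
    mass_sd: float = 1.0
    n_individuals: int = 12
    paleo_span: float = 65.0
    paleo_start: float = 26.0
    paleo_end: float = 14.0
    paleo_wiggle: float = 1.5

    def __post_init__(self):
        if not self.lambda0 > self.mu0 >= 0:
            raise ValueError("need lambda0 > mu0 >= 0")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.ou_alpha < 0:
            raise ValueError("ou alpha must be >= 0")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        if self.rate_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# birth-death species tree
# ---------------------------------------------------------------------------

def sim_bd_tree(lambda0: float, mu0: float, n_tips: int, seed: int, max_tries: int = 10_000) -> Tree:
    """Constant-rate birth-death tree conditioned on ``n_tips`` surviving tips.

    Simulated forward from two crown lineages; runs that go extinct restart.
    The simulation stops the first time the extant count reaches ``n_tips``
    and the present is placed a uniform fraction of the next inter-event
    waiting time later, so even 2-tip trees have positive depth.  Extinct
    lineages are pruned; the returned tree is ultrametric with tips labelled
    sp01, sp02, ...
    """
    if not lambda0 > mu0 >= 0:
        raise ValueError("need lambda0 > mu0 >= 0")
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    rng = np.random.default_rng(seed)

    for _ in range(max_tries):
        root = TreeNode()
        left, right = TreeNode(parent=root), TreeNode(parent=root)
        root.children = [left, right]
        birth = {id(root): 0.0, id(left): 0.0, id(right): 0.0}
        alive = [left, right]
        t = 0.0
        failed = False
        while True:
            total_rate = len(alive) * (lambda0 + mu0)
            wait = rng.exponential(1.0 / total_rate)
            if len(alive) == n_tips:
                t += rng.uniform() * wait
                break
            t += wait
            k = rng.integers(len(alive))
            node = alive[k]
            if rng.uniform() < lambda0 / (lambda0 + mu0):
                c1, c2 = TreeNode(parent=node), TreeNode(parent=node)
                node.children = [c1, c2]
                node.length = t - birth[id(node)]
                birth[id(c1)] = birth[id(c2)] = t
                alive[k] = c1
                alive.append(c2)
            else:
                node.length = t - birth[id(node)]
                node.label = "__extinct__"
                alive.pop(k)
                if not alive:
                    failed = True
                    break
        if failed:
            continue
        present = t if len(alive) == n_tips else None
        if present is None:
            continue
        for i, node in enumerate(alive):
            node.length = present - birth[id(node)]
            node.label = f"sp{i + 1:02d}"
        tree = Tree(root)
        tree = _prune_extinct(tree)
        if len(tree.tip_labels) == n_tips:
            return tree
    raise RuntimeError("birth-death simulation failed to condition on n_tips")


def _prune_extinct(tree: Tree) -> Tree:
    from .treekit import _suppress_unifurcations

    changed = True
    while changed:
        changed = False
        for node in list(tree.preorder()):
            if node.is_leaf and node.label == "__extinct__":
                node.parent.children.remove(node)
                changed = True
        _suppress_unifurcations(tree)
    return tree


# ---------------------------------------------------------------------------
# trait evolution
# ---------------------------------------------------------------------------

def sim_trait(
    tree: Tree,
    model: str = "bm",
    sigma2: float = 1.0,
    alpha: float = 0.0,
    theta: float = 0.0,
    root_state: float | None = None,
    seed: int = 0,
) -> dict:
    """Simulate a continuous trait root-to-tip along the tree.

    BM: increments Normal(0, sigma2 * branch).  OU: exact transition,
    mean = theta + (x - theta) e^{-alpha t}, var = sigma2 (1 - e^{-2 alpha t})
    / (2 alpha).  Returns a dict mapping every node (and, for tips, the tip
    label) to its state.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if model not in ("bm", "ou"):
        raise ValueError("model must be 'bm' or 'ou'")
    rng = np.random.default_rng(seed)
    if root_state is None:
        root_state = theta if model == "ou" else 0.0
    states: dict = {tree.root: float(root_state)}
    for node in tree.preorder():
        if node is tree.root:
            continue
        x0 = states[node.parent]
        t = node.length
        if model == "bm" or alpha == 0.0:
            mean, var = x0, sigma2 * t
        else:
            e = np.exp(-alpha * t)
            mean = theta + (x0 - theta) * e
            var = sigma2 * -np.expm1(-2 * alpha * t) / (2 * alpha)
        states[node] = float(mean + np.sqrt(var) * rng.standard_normal()) if var > 0 else float(mean)
    for tip in tree.tips():
        states[tip.label] = states[tip]
    return states


# ---------------------------------------------------------------------------
# environment-coupled gene trees
# ---------------------------------------------------------------------------

def sim_gene_trees(
    species_tree: Tree,
    env: dict[str, float],
    a: float,
    b: float,
    noise_sd: float,
    n_genes: int,
    seed: int,
) -> dict[str, Tree]:
    """Gene trees with substitution-scaled branch lengths coupled to environment.

    For gene g and branch e: length = time(e) * exp(a + b * env(e) + eps),
    eps ~ Normal(0, noise_sd^2), where env on a branch is the midpoint of the
    BM-interpolated (GLS ancestral) node values of the tip environments.  All
    genes share the species topology.
    """
    missing = [lab for lab in species_tree.tip_labels if lab not in env]
    if missing:
        raise ValueError(f"environment missing for species: {sorted(missing)}")
    from .comparative import anc_states_bm

    states = anc_states_bm(species_tree, {k: env[k] for k in species_tree.tip_labels})
    rng = np.random.default_rng(seed)
    genes: dict[str, Tree] = {}
    order = [n for n in species_tree.preorder() if n.parent is not None]
    branch_env = np.array([0.5 * (states[n.parent] + states[n]) for n in order])
    branch_time = np.array([n.length for n in order])
    for g in range(n_genes):
        eps = rng.normal(0.0, noise_sd, size=len(order)) if noise_sd > 0 else np.zeros(len(order))
        lengths = branch_time * np.exp(a + b * branch_env + eps)
        gtree = species_tree.copy()
        gorder = [n for n in gtree.preorder() if n.parent is not None]
        for node, length in zip(gorder, lengths):
            node.length = float(length)
        genes[f"gene{g + 1:04d}"] = gtree
    return genes


# ---------------------------------------------------------------------------
# microclimate, occurrences
# ---------------------------------------------------------------------------

def sim_microclim_grid(
    shape: tuple[int, int] = (12, 12),
    annual_mean: float = 18.0,
    mean_gradient: float = 16.0,
    seasonal_amp: float = 8.0,
    diurnal_amp: float = 10.0,
    rad_peak: float = 800.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> MicroclimGrid:
    """Hourly microclimate for one representative day per month.

    Cell annual means ramp linearly west-to-east over ``mean_gradient`` °C
    (mimicking a cool-to-hot macrogradient); month means follow a seasonal
    cosine peaking in July; the diurnal cycle adds
    ``diurnal_amp * sin(pi (h - 6)/12)`` during daylight (6h-18h) and zero at
    night, plus Gaussian noise.  Radiation is ``rad_peak`` times the daylight
    sine, zero at night.  The monthly T_max/T_min climatology is the max/min
    of each representative day.
    """
    ny, nx = shape
    if ny <= 0 or nx <= 0:
        raise ValueError("grid dimensions must be positive")
    rng = np.random.default_rng(seed)
    xfrac = np.linspace(-0.5, 0.5, nx) if nx > 1 else np.zeros(1)
    cell_mean = annual_mean + mean_gradient * xfrac[None, :] + np.zeros((ny, 1))
    months = np.arange(12)
    season = seasonal_amp * np.cos(2 * np.pi * (months - 6) / 12.0)
    hours = np.arange(24)
    day_sin = np.sin(np.pi * (hours - 6) / 12.0)
    day_sin = np.where((hours >= 6) & (hours <= 18), np.maximum(day_sin, 0.0), 0.0)

    temps = (
        cell_mean[:, :, None, None]
        + season[None, None, :, None]
        + diurnal_amp * day_sin[None, None, None, :]
    )
    if noise_sd > 0:
        temps = temps + rng.normal(0.0, noise_sd, size=temps.shape)
    rad = np.broadcast_to(rad_peak * day_sin[None, None, None, :], temps.shape).copy()
    return MicroclimGrid(temps=temps, rad=rad, x0=0.0, y0=0.0, cell_size=1.0)


def sim_occurrences(
    grid: MicroclimGrid,
    centers: dict[str, tuple[float, float]],
    radii: dict[str, float],
    counts: dict[str, int],
    seed: int = 0,
) -> OccurrenceSet:
    """Uniform occurrence points within a disc per species, clipped to the grid."""
    ny, nx = grid.shape
    x_hi = grid.x0 + nx * grid.cell_size
    y_hi = grid.y0 + ny * grid.cell_size
    rng = np.random.default_rng(seed)
    rows = []
    for sp in sorted(centers):
        cx, cy = centers[sp]
        if not (grid.x0 <= cx < x_hi and grid.y0 <= cy < y_hi):
            raise ValueError(f"center for {sp} outside grid extent")
        r = radii[sp]
        for _ in range(counts[sp]):
            rho = r * np.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * np.pi)
            x = np.clip(cx + rho * np.cos(ang), grid.x0, np.nextafter(x_hi, -np.inf))
            y = np.clip(cy + rho * np.sin(ang), grid.y0, np.nextafter(y_hi, -np.inf))
            rows.append({"species": sp, "x": float(x), "y": float(y)})
    return OccurrenceSet(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# raw physiology series
# ---------------------------------------------------------------------------

def sim_physio_raw(
    species: dict[str, int],
    true_hourly_loss: float | dict[str, float] = 0.02,
    true_tpref: float | dict[str, float] = 33.0,
    mass_mean: float = 5.0,
    mass_sd: float = 1.0,
    weight_noise_sd: float = 0.0,
    temp_noise_sd: float = 0.0,
    room_temp: float = 22.0,
    n_hours: int = 8,
    n_minutes: int = 120,
    seed: int = 0,
) -> pd.DataFrame:
    """Raw experiment records: hourly weights and per-minute body temperatures.

    ``species`` maps species label -> number of individuals.  Weights start
    at the individual's mass and lose ``true_hourly_loss`` g/h plus noise;
    body temperature ramps linearly from room temperature to ``true_tpref``
    over the first 15 minutes and then fluctuates around it.  The truths may
    be a single value or per-species dicts (species differ in their thermal
    physiology).  With zero noise the trait-estimation pipeline recovers the
    truths exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sp in sorted(species):
        sp_loss = true_hourly_loss[sp] if isinstance(true_hourly_loss, dict) else true_hourly_loss
        sp_tpref = true_tpref[sp] if isinstance(true_tpref, dict) else true_tpref
        for i in range(species[sp]):
            ind = f"{sp}_i{i + 1:02d}"
            mass = max(rng.normal(mass_mean, mass_sd), 0.5)
            for h in range(n_hours + 1):
                w = mass - sp_loss * h
                if weight_noise_sd > 0:
                    w += rng.normal(0, weight_noise_sd)
                rows.append(
                    {"individual": ind, "species": sp, "mass": mass, "stream": "weight", "t": float(h), "value": float(w)}
                )
            for m in range(1, n_minutes + 1):
                if m <= 15:
                    v = room_temp + (sp_tpref - room_temp) * m / 15.0
                else:
                    v = sp_tpref
                if temp_noise_sd > 0:
                    v += rng.normal(0, temp_noise_sd)
                rows.append(
                    {"individual": ind, "species": sp, "mass": mass, "stream": "temp", "t": float(m), "value": float(v)}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# paleotemperature curve
# ---------------------------------------------------------------------------

@dataclass
class PaleoCurve:
    """Temperature vs age (Ma before present); linear interpolation between
    knots, clamped to the endpoint values outside the grid."""

    ages: np.ndarray
    temps: np.ndarray

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.temps = np.asarray(self.temps, dtype=float)
        if len(self.ages) < 2:
            raise ValueError("need at least 2 knots")
        if np.any(self.ages < 0) or np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be non-negative and strictly increasing")

    def __call__(self, age):
        return np.interp(age, self.ages, self.temps)

    @classmethod
    def from_tsv(cls, path) -> "PaleoCurve":
        df = pd.read_csv(path, sep="\t", comment="#")
        df = df.sort_values("age_ma")
        return cls(ages=df["age_ma"].to_numpy(), temps=df["temp_c"].to_numpy())

    def to_tsv(self, path) -> None:
        pd.DataFrame({"age_ma": self.ages, "temp_c": self.temps}).to_csv(path, sep="\t", index=False)


def sim_paleo_curve(
    span: float = 65.0,
    start_temp: float = 26.0,
    end_temp: float = 14.0,
    wiggle: float = 1.5,
    n_knots: int = 131,
    seed: int = 0,
) -> PaleoCurve:
    """Cenozoic-like cooling curve: a linear ramp from ``start_temp`` at age
    ``span`` to ``end_temp`` at the present, plus bounded sinusoidal wiggles
    that vanish at both endpoints (wiggle 0 gives an exact linear ramp)."""
    if span <= 0:
        raise ValueError("span must be positive")
    ages = np.linspace(0.0, span, n_knots)
    temps = end_temp + (start_temp - end_temp) * ages / span
    if wiggle > 0:
        rng = np.random.default_rng(seed)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        amp = wiggle * rng.uniform(0.3, 1.0, size=3) / 3
        for k, (ph, am) in enumerate(zip(phase, amp), start=2):
            temps = temps + am * np.sin(np.pi * k * ages / span + ph) * np.sin(np.pi * ages / span)
    return PaleoCurve(ages=ages, temps=temps)
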