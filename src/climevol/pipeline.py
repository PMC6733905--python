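"""End-to-end orchestration: simulate -> traits -> niche metrics ->
comparative / rate-scan / diversification, with a reproducible manifest.

A single YAML config drives every stage; one global seed fans out to fixed
per-stage seeds so stages can be rerun independently yet reproducibly.  All
tabular outputs are TSV; the manifest records the config snapshot, stage
seeds and a SHA-256 digest of every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bioclim import MicroclimGrid, OccurrenceSet, species_climate_table
from .comparative import (
    blomberg_k,
    contrasts_vs_age,
    dtt_envelope,
    pgls_ou,
    phylo_pca,
    phylosig_test,
    pic,
)
from .diversification import grid_to_frame, model_grid_rank
from .physiology import build_trait_table
from .ratescan import gene_rate_scan
from .synthdata import (
    PaleoCurve,
    SimConfig,
    sim_bd_tree,
    sim_gene_trees,
    sim_microclim_grid,
    sim_occurrences,
    sim_physio_raw,
    sim_paleo_curve,
    sim_trait,
)
from .treekit import Tree, TreeNode, parse_newick, write_newick

logger = logging.getLogger(__name__)

ALL_STAGES = ["simulate", "physio", "bioclim", "comparative", "ratescan", "diversify"]

#: artifacts each stage needs, and which stage produces them
_REQUIRES = {
    "physio": {"physio_raw.tsv": "simulate"},
    "bioclim": {"grid.tsv": "simulate", "occurrences.tsv": "simulate"},
    "comparative": {"tree.nwk": "simulate", "trait_table.tsv": "physio", "species_climate.tsv": "bioclim"},
    "ratescan": {"gene_trees.tsv": "simulate", "env.tsv": "simulate"},
    "diversify": {"tree.nwk": "simulate", "paleo.tsv": "simulate"},
}


@dataclass
class RunManifest:
    config: dict
    seeds: dict[str, int]
    version: str
    outputs: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def _stage_seed(seed: int, stage: str) -> int:
    return (seed * 1009 + ALL_STAGES.index(stage) + 1) % (2**31)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _add_outgroup(tree: Tree, label: str = "Outgroup", stem_factor: float = 1.5) -> Tree:
    """Attach an outgroup tip below a new root so the tree stays ultrametric."""
    tree = tree.copy()
    age = tree.depth * stem_factor
    new_root = TreeNode()
    old = tree.root
    old.length = age - tree.depth
    new_root.add_child(old)
    new_root.add_child(TreeNode(label=label, length=age))
    return Tree(new_root)


def run_pipeline(config, outdir=None) -> RunManifest:
    """Run the configured stages in dependency order.

    ``config`` is a YAML path or a dict with keys ``seed``, ``stages`` (any
    subset of simulate/physio/bioclim/comparative/ratescan/diversify),
    ``outdir`` and an optional ``sim`` block of :class:`SimConfig` fields.
    Failures in one stage stop its dependents but not independent stages.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(outdir or config.get("outdir", "climevol_run"))
    out.mkdir(parents=True, exist_ok=True)

    sim_conf = SimConfig(seed=seed, **config.get("sim", {}))
    n_starts = int(config.get("diversify_n_starts", 5))
    n_dtt_sim = int(config.get("n_dtt_sim", 1000))
    n_perm = int(config.get("n_perm", 1000))

    manifest = RunManifest(
        config={k: v for k, v in config.items()},
        seeds={s: _stage_seed(seed, s) for s in stages},
        version=__version__,
    )
    failed: set[str] = set()

    for stage in [s for s in ALL_STAGES if s in stages]:
        needs = _REQUIRES.get(stage, {})
        missing = {f: producer for f, producer in needs.items() if not (out / f).exists()}
        if missing:
            producers = sorted({p for p in missing.values()})
            msg = f"stage {stage}: missing {sorted(missing)}; run stage(s) {producers} first"
            if any(p in failed for p in producers):
                manifest.warnings.append(msg)
                failed.add(stage)
                continue
            raise FileNotFoundError(msg)
        try:
            _STAGE_FNS[stage](out, sim_conf, manifest, n_starts=n_starts, n_dtt_sim=n_dtt_sim, n_perm=n_perm)
        except Exception as exc:
            logger.error("stage %s failed: %s", stage, exc)
            manifest.warnings.append(f"stage {stage} failed: {exc}")
            failed.add(stage)

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest.outputs[f.name] = _digest(f)
    manifest.to_json(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(out: Path, conf: SimConfig, manifest: RunManifest, **kw) -> None:
    seed = _stage_seed(conf.seed, "simulate")
    tree = sim_bd_tree(conf.lambda0, conf.mu0, conf.n_species, seed)
    (out / "tree.nwk").write_text(write_newick(tree) + "\n")

    grid = sim_microclim_grid(
        conf.grid_shape, conf.annual_mean, conf.mean_gradient, conf.seasonal_amp,
        conf.diurnal_amp, conf.rad_peak, conf.climate_noise_sd, seed=seed + 1,
    )
    grid.to_tsv(out / "grid.tsv")

    # thermal-niche position evolves by BM; ranks map species onto the
    # west-to-east temperature gradient of the grid
    niche = sim_trait(tree, model=conf.trait_model, sigma2=conf.sigma2,
                      alpha=conf.ou_alpha, theta=conf.ou_theta, seed=seed + 2)
    labels = tree.tip_labels
    values = np.array([niche[lab] for lab in labels])
    ranks = values.argsort().argsort()
    ny, nx = grid.shape
    rng = np.random.default_rng(seed + 3)
    centers = {
        lab: (0.5 + (nx - 1.0) * ranks[i] / max(len(labels) - 1, 1), rng.uniform(1.0, ny - 1.0))
        for i, lab in enumerate(labels)
    }
    radii = {lab: 1.5 for lab in labels}
    counts = {lab: 30 for lab in labels}
    occ = sim_occurrences(grid, centers, radii, counts, seed=seed + 4)
    occ.to_tsv(out / "occurrences.tsv")

    # environment covariate for the rate scan: standardized hot-hours medians
    from .bioclim import species_median_extract, yearly_hours_layer

    layer = yearly_hours_layer(grid, 30.0)
    env_raw = species_median_extract(grid, layer, occ)
    vals = np.array([env_raw[lab] for lab in labels])
    sd = vals.std(ddof=0)
    env = {lab: float((env_raw[lab] - vals.mean()) / sd) * 3.0 if sd > 0 else 0.0 for lab in labels}
    pd.DataFrame({"species": labels, "env": [env[lab] for lab in labels]}).to_csv(
        out / "env.tsv", sep="\t", index=False
    )

    full = _add_outgroup(tree)
    env_og = dict(env)
    env_og["Outgroup"] = 0.0
    genes = sim_gene_trees(
        full, env_og, conf.rate_intercept, conf.rate_slope, conf.rate_noise_sd,
        conf.n_genes, seed=seed + 5,
    )
    with open(out / "gene_trees.tsv", "w") as fh:
        for gid in sorted(genes):
            fh.write(f"{gid}\t{write_newick(genes[gid])}\n")

    # species physiology truths covary with the thermal niche: hotter ranges
    # mean higher preferred temperature and lower water loss
    species_counts = {lab: conf.n_individuals for lab in labels}
    tpref_truth = {lab: conf.true_tpref + conf.tpref_env_slope * env[lab] for lab in labels}
    loss_truth = {
        lab: max(conf.true_hourly_loss + conf.iwl_env_slope * env[lab], 1e-4) for lab in labels
    }
    raw = sim_physio_raw(
        species_counts, loss_truth, tpref_truth, conf.mass_mean,
        conf.mass_sd, weight_noise_sd=0.002, temp_noise_sd=0.5, seed=seed + 6,
    )
    raw.to_csv(out / "physio_raw.tsv", sep="\t", index=False)

    paleo = sim_paleo_curve(conf.paleo_span, conf.paleo_start, conf.paleo_end,
                            conf.paleo_wiggle, seed=seed + 7)
    paleo.to_tsv(out / "paleo.tsv")

    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(asdict(conf) if hasattr(conf, "__dataclass_fields__") else vars(conf), fh)


def _stage_physio(out: Path, conf: SimConfig, manifest: RunManifest, **kw) -> None:
    raw = pd.read_csv(out / "physio_raw.tsv", sep="\t")
    table = build_trait_table(raw)
    table.to_csv(out / "trait_table.tsv", sep="\t")


def _stage_bioclim(out: Path, conf: SimConfig, manifest: RunManifest, **kw) -> None:
    grid = MicroclimGrid.from_tsv(out / "grid.tsv")
    occ = OccurrenceSet.from_tsv(out / "occurrences.tsv")
    tpref = None
    if (out / "trait_table.tsv").exists():
        traits = pd.read_csv(out / "trait_table.tsv", sep="\t", index_col="species")
        tpref = traits["tpref"].to_dict()
    table = species_climate_table(grid, occ, tpref=tpref)
    table.to_csv(out / "species_climate.tsv", sep="\t")


def _stage_comparative(out: Path, conf: SimConfig, manifest: RunManifest, n_dtt_sim=1000, n_perm=1000, **kw) -> None:
    tree = parse_newick((out / "tree.nwk").read_text())
    traits = pd.read_csv(out / "trait_table.tsv", sep="\t", index_col="species")
    climate = pd.read_csv(out / "species_climate.tsv", sep="\t", index_col="species")
    data = traits.join(climate, how="inner")
    data["log_hours_activity"] = np.log1p(data["hours_activity"])
    data["log_range_size"] = np.log(data["range_size"])
    seed = _stage_seed(conf.seed, "comparative")

    rows = []
    fit = pgls_ou(tree, data["tpref"], data[["hours_above_30"]])
    for term in fit.params.index:
        rows.append({"response": "tpref", "term": term, "coef": fit.params[term],
                     "se": fit.bse[term], "pvalue": fit.pvalues[term],
                     "alpha": fit.alpha, "aic": fit.aic})
    (out / "pgls_tpref.txt").write_text(fit.summary() + "\n")
    pd.DataFrame(rows).to_csv(out / "pgls_fits.tsv", sep="\t", index=False)

    sig = phylosig_test(tree, data["tpref"].to_dict(), n_perm=n_perm, seed=seed)
    pd.DataFrame([{"trait": "tpref", "K": sig.K, "P": sig.P, "n_perm": sig.n_perm}]).to_csv(
        out / "phylosig.tsv", sep="\t", index=False
    )

    ppca = phylo_pca(tree, data[["hours_above_30", "log_hours_activity", "log_range_size"]])
    ppca.scores.to_csv(out / "ppca_scores.tsv", sep="\t")
    dtt = dtt_envelope(tree, ppca.scores[["PC1", "PC2"]], n_sim=n_dtt_sim, seed=seed + 1)
    dtt.to_frame().to_csv(out / "dtt.tsv", sep="\t", index=False)

    contrasts = pic(tree, data["hours_above_30"].to_dict())
    slope, r, p = contrasts_vs_age(contrasts)
    pd.DataFrame([{"trait": "hours_above_30", "slope": slope, "r": r, "pvalue": p}]).to_csv(
        out / "contrasts_vs_age.tsv", sep="\t", index=False
    )


def _stage_ratescan(out: Path, conf: SimConfig, manifest: RunManifest, **kw) -> None:
    genes = {}
    for line in (out / "gene_trees.tsv").read_text().splitlines():
        gid, nwk = line.split("\t", 1)
        genes[gid] = parse_newick(nwk)
    env = pd.read_csv(out / "env.tsv", sep="\t").set_index("species")["env"].to_dict()
    result = gene_rate_scan(genes, env, outgroup="Outgroup")
    result.per_gene.to_csv(out / "ratescan_genes.tsv", sep="\t", index=False)
    summary = pd.DataFrame(
        [
            {
                "n_genes": result.n_genes,
                "n_positive": result.n_positive,
                "n_positive_significant": result.n_positive_significant,
                "n_negative": result.n_negative,
                "n_negative_significant": result.n_negative_significant,
                "n_zero": result.n_zero,
                "n_skipped": result.n_skipped,
                "alpha": result.alpha,
            }
        ]
    )
    summary.to_csv(out / "ratescan_summary.tsv", sep="\t", index=False)


def _stage_diversify(out: Path, conf: SimConfig, manifest: RunManifest, n_starts=5, **kw) -> None:
    tree = parse_newick((out / "tree.nwk").read_text())
    paleo = PaleoCurve.from_tsv(out / "paleo.tsv")
    seed = _stage_seed(conf.seed, "diversify")
    fits = model_grid_rank(tree, paleo, seed=seed, n_starts=n_starts)
    grid_to_frame(fits).to_csv(out / "diversification_models.tsv", sep="\t", index=False)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "physio": _stage_physio,
    "bioclim": _stage_bioclim,
    "comparative": _stage_comparative,
    "ratescan": _stage_ratescan,
    "diversify": _stage_diversify,
}


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def write_report(run_dir) -> str:
    """Human-readable markdown summary of a completed run (idempotent)."""
    run_dir = Path(run_dir)
    if not run_dir.is_dir() or not any(run_dir.iterdir()):
        raise FileNotFoundError(f"run directory {run_dir} is empty or missing")
    lines = ["# climevol run report", ""]

    f = run_dir / "trait_table.tsv"
    if f.exists():
        traits = pd.read_csv(f, sep="\t", index_col="species")
        lines += [
            "## Physiological traits",
            f"{len(traits)} species; median T_pref = {traits['tpref'].median():.2f} °C, "
            f"median IWL = {traits['iwl'].median():.4f} g/h.",
            "",
        ]

    f = run_dir / "species_climate.tsv"
    if f.exists():
        clim = pd.read_csv(f, sep="\t", index_col="species")
        lines += ["## Niche metrics and thermal safety margins"]
        lines.append(
            f"Median yearly hours >30 °C across species: {clim['hours_above_30'].median():.0f} h."
        )
        if "at_risk" in clim:
            lines.append(
                f"{int(clim['at_risk'].sum())} of {len(clim)} species flagged at risk (TSM < 12 °C)."
            )
        lines.append("")

    f = run_dir / "pgls_fits.tsv"
    if f.exists():
        fits = pd.read_csv(f, sep="\t")
        sl = fits[(fits["response"] == "tpref") & (fits["term"] == "hours_above_30")]
        if len(sl):
            row = sl.iloc[0]
            lines += [
                "## Phylogenetic regression (T_pref ~ yearly hours >30 °C)",
                f"slope = {row['coef']:.4g} (SE {row['se']:.3g}), P = {row['pvalue']:.4g} "
                f"(OU alpha = {row['alpha']:.3g}).",
                "",
            ]

    f = run_dir / "ratescan_summary.tsv"
    if f.exists():
        s = pd.read_csv(f, sep="\t").iloc[0]
        lines += [
            "## Substitution-rate scan",
            f"{int(s['n_positive'])} of {int(s['n_genes'])} genes with positive rate-environment "
            f"slope ({int(s['n_positive_significant'])} significant at P < {s['alpha']:g}); "
            f"{int(s['n_negative'])} negative ({int(s['n_negative_significant'])} significant).",
            "",
        ]

    f = run_dir / "diversification_models.tsv"
    if f.exists():
        models = pd.read_csv(f, sep="\t")
        top = models.sort_values("AIC").iloc[0]
        lines += [
            "## Diversification",
            f"Best model by AIC: {top['model']} (AIC = {top['AIC']:.2f}, weight = {top['weight']:.3f}).",
            "",
        ]

    report = "\n".join(lines)
    (run_dir / "report.md").write_text(report)
    return report
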