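"""One-command orchestration of the full stability analysis.

``run_pipeline`` takes a :class:`RunConfig` (built directly or parsed from a
YAML/JSON file), runs validation -> ANOVA/AMMI -> BLUP/WAASB -> cross-
validation -> GGE -> indices, writes per-module CSV artifacts plus a run log
with every resolved default, and returns one wide per-genotype stability
table.  On any module error the partial outputs written by this run are
removed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .ammi import ammi_biplot_coords, asv, fit_ammi, gollob_test, joint_anova
from .blup_waasb import (
    classify_quadrants,
    cluster_rank_profiles,
    fit_blup,
    waas,
    waasb,
    waasby,
    weight_scenarios,
)
from .cross_validation import rmspd_cv, summarize_cv
from .data_model import MetTrial, cell_means, load_trial, write_cell_means, write_trial
from .gge import discrim_vs_repr, fit_gge, mean_vs_stability, rank_vs_ideal_genotype, which_won_where
from .indices import annicchiarico, environmental_index, hsi_from_trial
from .synthetic_data import SimConfig, merge_regimes, simulate_heat_pairs

logger = logging.getLogger("metstab")

__all__ = ["RunConfig", "run_pipeline", "load_config"]

_MODULES = ("ammi", "waasb", "cv", "gge", "indices")


@dataclass
class RunConfig:
    """Resolved pipeline configuration; exactly one of input/simulate set."""

    input: str | None = None
    meta: str | None = None
    simulate: dict[str, Any] | None = None
    modules: dict[str, bool] = field(default_factory=dict)
    theta_y: float = 65.0
    theta_s: float = 35.0
    n_axes: int | str = "all"
    step: float = 5.0
    svp_www: int = 3
    svp_rank: int = 2
    alpha: float = 0.25
    n_resamples: int = 1000
    n_clusters: int = 4
    seed: int = 0
    out_dir: str = "metstab_results"

    def __post_init__(self) -> None:
        if (self.input is None) == (self.simulate is None):
            raise ValueError("exactly one of 'input' and 'simulate' must be given")
        toggles = dict.fromkeys(_MODULES, True)
        toggles.update(self.modules or {})
        unknown = set(toggles) - set(_MODULES)
        if unknown:
            raise ValueError(f"unknown module toggles: {sorted(unknown)}")
        self.modules = toggles


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML (or JSON; YAML is a superset) config file."""
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict):
        raise ValueError("config file must contain a mapping")
    return RunConfig(**payload)


def _acquire_trial(config: RunConfig) -> MetTrial:
    if config.input is not None:
        return load_trial(config.input, meta_path=config.meta)
    sim = SimConfig(**{**config.simulate, "seed": config.simulate.get("seed", config.seed)})
    normal, late, _ = simulate_heat_pairs(sim)
    return merge_regimes(normal, late)


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run all enabled modules; returns the consolidated per-genotype table."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(frame: pd.DataFrame, name: str, index_label: str | None = "GEN") -> None:
        path = out_dir / name
        frame.to_csv(path, index_label=index_label)
        written.append(path)

    try:
        trial = _acquire_trial(config)
        cm = cell_means(trial)
        g = len(cm.genotypes)
        report = pd.DataFrame(index=pd.Index(cm.genotypes, name="GEN"))
        report["mean_yield"] = cm.genotype_means

        write_trial(trial, out_dir / "trial.csv")
        written.append(out_dir / "trial.csv")
        write_cell_means(cm, out_dir / "cell_means.csv")
        written.append(out_dir / "cell_means.csv")

        waasb_res = None
        if config.modules["ammi"]:
            fit = fit_ammi(trial)
            anova = gollob_test(fit, joint_anova(trial))
            save(anova.table, "anova.csv", index_label="source")
            coords = ammi_biplot_coords(fit, "AMMI2")
            save(coords.genotypes, "scores_genotype.csv")
            save(coords.environments, "scores_environment.csv", index_label="ENV")
            asv_tab = asv(fit)
            save(asv_tab, "asv.csv")
            report["ASV"] = asv_tab["ASV"]
            report["ASV_rank"] = asv_tab["rank"]
            waas_res = waas(fit, config.n_axes)
            report["WAAS"] = waas_res.values

        if config.modules["waasb"]:
            blup = fit_blup(trial)
            save(blup.predict(), "blups.csv")
            vc_frame = pd.DataFrame(
                [asdict(blup.vc) | {"H2_entry_mean": blup.h2}]
            )
            vc_frame.to_csv(out_dir / "varcomp.csv", index=False)
            written.append(out_dir / "varcomp.csv")
            waasb_res = waasb(blup, config.n_axes)
            save(waasb_res.by_axes, "waasb_by_axes.csv")
            wy = waasby(waasb_res.values, cm.genotype_means, config.theta_y, config.theta_s)
            save(wy, "waasby.csv")
            scen = weight_scenarios(waasb_res.values, cm.genotype_means, config.step)
            save(scen, "scenarios.csv")
            quad = classify_quadrants(waasb_res.values, cm.genotype_means)
            save(quad.to_frame(), "quadrants.csv")
            clus = cluster_rank_profiles(scen, config.n_clusters)
            save(clus.to_frame(), "clusters.csv")
            report["WAASB"] = waasb_res.values
            report["WAASB_rank"] = waasb_res.ranks
            report["WAASBY"] = wy["WAASBY"]
            report["WAASBY_rank"] = wy["rank"]
            report["quadrant"] = quad
            report["cluster"] = clus

        if config.modules["cv"]:
            dist = rmspd_cv(trial, n_resamples=config.n_resamples, seed=config.seed)
            dist.rmspd.rename_axis("resample").to_csv(out_dir / "rmspd_long.csv")
            written.append(out_dir / "rmspd_long.csv")
            save(summarize_cv(dist), "rmspd_summary.csv", index_label="model")

        if config.modules["gge"]:
            fit_w = fit_gge(cm, svp=config.svp_www)
            www = which_won_where(fit_w)
            save(www.assignments, "gge_sectors.csv", index_label="ENV")
            fit_r = fit_gge(cm, svp=config.svp_rank)
            ms = mean_vs_stability(fit_r)
            save(ms, "gge_mean_vs_stability.csv")
            rk = rank_vs_ideal_genotype(fit_r)
            save(rk, "gge_genotype_ranking.csv")
            save(discrim_vs_repr(fit_r), "gge_environments.csv", index_label="ENV")
            report["GGE_rank"] = rk["rank"]

        if config.modules["indices"]:
            rec = annicchiarico(cm, config.alpha)
            save(rec, "recommendation.csv")
            save(environmental_index(cm), "env_index.csv", index_label="ENV")
            report["omega"] = rec["omega"]
            has_pairs = (
                trial.env_meta is not None
                and {"normal", "late"} <= set(trial.env_meta["sowing"])
            )
            if has_pairs:
                ht = hsi_from_trial(trial)
                save(ht.values, "hsi.csv")
                ht.pairs.to_csv(out_dir / "hsi_pairs.csv", index=False)
                written.append(out_dir / "hsi_pairs.csv")
                report["HSI_mean"] = ht.mean_hsi
                report["HSI_class"] = ht.mean_class
            else:
                logger.info("no normal/late environment pairs in metadata; HSI skipped")

        save(report, "stability_table.csv")
        log = {
            "version": __version__,
            "seed": config.seed,
            "n_genotypes": g,
            "n_environments": len(cm.environments),
            "rep_count": cm.rep_count,
            "config": {k: v for k, v in asdict(config).items()},
        }
        (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
        return report
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
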