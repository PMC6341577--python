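"""Pipeline orchestration: run the analysis stages in the published order
(volumes -> size classes -> signal/model fit -> ancestral states ->
biogeography -> threshold regressions) and bundle their outputs.

Inputs can come from files (see :mod:`phyloseed.io`) or default to the
built-in approximate fixture; all randomized stages consume one seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd

from . import io as pio
from .ancestral import estimate_ancestral_states, traitgram_coordinates
from .biogeography import DECModel, likelihood_ratio_test
from .fixture import fixture_plukenetiinae
from .morphometrics import (
    cluster_seed_sizes,
    pca_seed_dimensions,
    species_trait_vector,
    summarize_species,
)
from .threshold import ThresholdRegression
from .trait_models import blomberg_k, compare_models, fit_trait_model, pagel_lambda
from .tree import Chronogram

logger = logging.getLogger("phyloseed")

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("volumes", "classify", "signal", "fit_models", "asr", "biogeo", "threshold")

_DEFAULTS: dict[str, dict] = {
    "classify": {"cut_height": 0.35},
    "signal": {"n_perm": 999},
    "biogeo": {"max_range": 2, "n_starts": 3},
    "threshold": {"n_gen": 200_000, "thin": 100, "burnin": 0.20},
}


@dataclass
class PipelineConfig:
    """Paths, stage toggles and per-stage parameter blocks."""

    tree: str | None = None
    measurements: str | None = None
    geography: str | None = None
    multipliers: str | None = None
    binary_traits: str | None = None
    outdir: str = "phyloseed-results"
    seed: int = 0
    stages: tuple[str, ...] = _STAGES
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        unknown = set(self.params) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown parameter sections: {sorted(unknown)}")
        for sec, block in self.params.items():
            bad = set(block) - set(_DEFAULTS.get(sec, {}))
            if bad:
                raise ValueError(f"unknown keys in section {sec!r}: {sorted(bad)}")

    def stage_params(self, stage: str) -> dict:
        out = dict(_DEFAULTS.get(stage, {}))
        out.update(self.params.get(stage, {}))
        return out

    def digest(self) -> str:
        payload = json.dumps(
            {
                "tree": self.tree,
                "measurements": self.measurements,
                "geography": self.geography,
                "multipliers": self.multipliers,
                "binary_traits": self.binary_traits,
                "seed": self.seed,
                "stages": self.stages,
                "params": self.params,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_inputs(config: PipelineConfig):
    fx = None
    if None in (
        config.tree,
        config.measurements,
        config.geography,
        config.binary_traits,
    ):
        fx = fixture_plukenetiinae()
    tree = (
        Chronogram.from_file(config.tree) if config.tree else fx.tree
    )
    if config.measurements:
        records = pio.read_measurements(config.measurements)
    else:
        from .fixture import reconstruct_seed_measurements

        records = reconstruct_seed_measurements()
    if config.geography:
        ranges, areas = pio.read_geography(config.geography)
    else:
        ranges, areas = fx.tip_ranges, ("CAM", "AMZ", "ATF", "AFR", "MAD", "SEA")
    if config.multipliers:
        mult, m_areas = pio.read_multipliers(config.multipliers)
        if m_areas != tuple(areas):
            raise ValueError("multiplier areas do not match geography areas")
    elif fx is not None:
        mult = fx.multipliers
    else:
        mult = None
    binary = (
        pio.read_binary_traits(config.binary_traits)
        if config.binary_traits
        else fx.binary_traits
    )
    return tree, records, ranges, tuple(areas), mult, binary


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; returns the report bundle and writes CSVs.

    Deterministic for a fixed config + seed.  A stage failure aborts with the
    stage name in the exception; completed stage outputs remain on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# phyloseed seed={config.seed} config={config.digest()}\n"
    bundle: dict = {"config_digest": config.digest(), "seed": config.seed}
    if not config.stages:
        return bundle
    tree, records, ranges, areas, mult, binary = _load_inputs(config)
    trait = species_trait_vector(records)
    trait = {sp: v for sp, v in trait.items() if sp in set(tree.tip_labels)}
    trait_tree = tree.prune_to_species({sp: sp for sp in trait})

    def save(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh)

    for stage in config.stages:
        t0 = time.perf_counter()
        p = config.stage_params(stage)
        logger.info("stage %s params=%s", stage, p)
        try:
            if stage == "volumes":
                summary = summarize_species(records)
                bundle["volumes"] = summary
                save(summary, "species_summary.csv")
            elif stage == "classify":
                res = cluster_seed_sizes(records, cut_height=p["cut_height"])
                fractions, _ = pca_seed_dimensions(records)
                df = pd.DataFrame(
                    {
                        "taxon": [r.taxon for r in records],
                        "cluster": res.assignments,
                    }
                )
                bundle["classify"] = {
                    "n_clusters": res.n_clusters,
                    "pc_variance_fractions": fractions,
                    "assignments": df,
                }
                save(df.set_index("taxon"), "seed_clusters.csv")
            elif stage == "signal":
                k = blomberg_k(
                    trait_tree, trait, n_perm=p["n_perm"], seed=config.seed
                )
                lam = pagel_lambda(trait_tree, trait)
                df = pd.DataFrame(
                    [
                        {"statistic": "K", "estimate": k.estimate, "p": k.p_value},
                        {
                            "statistic": "lambda",
                            "estimate": lam.estimate,
                            "p": lam.p_value,
                        },
                    ]
                ).set_index("statistic")
                bundle["signal"] = df
                save(df, "phylogenetic_signal.csv")
            elif stage == "fit_models":
                fits = [
                    fit_trait_model(trait_tree, trait, m) for m in ("BM", "OU", "EB")
                ]
                comp = compare_models(fits)
                df = comp.to_dataframe()
                df["lnL"] = [f.loglik for f in fits]
                bundle["fit_models"] = df
                save(df, "trait_model_comparison.csv")
            elif stage == "asr":
                est = estimate_ancestral_states(trait_tree, trait)
                df = est.to_dataframe(trait_tree)
                bundle["asr"] = df
                save(df, "ancestral_states.csv")
                paths = traitgram_coordinates(trait_tree, trait, est)
                rows = [
                    {"lineage": sp, "age_mya": a, "state": s}
                    for sp, poly in paths.items()
                    for a, s in poly
                ]
                save(pd.DataFrame(rows).set_index("lineage"), "traitgram.csv")
            elif stage == "biogeo":
                geo_tree = tree.prune_to_species({sp: sp for sp in ranges})
                fits = {}
                for model in ("DEC", "DECJ"):
                    fits[model] = DECModel(
                        model=model,
                        areas=areas,
                        max_range=p["max_range"],
                        multipliers=mult,
                        n_starts=p["n_starts"],
                        seed=config.seed,
                    ).fit(geo_tree, ranges)
                lrt = likelihood_ratio_test(
                    fits["DEC"].loglik_, fits["DECJ"].loglik_, df=1
                )
                df = pd.DataFrame(
                    [
                        {
                            "model": m,
                            "d": f.d_,
                            "e": f.e_,
                            "j": f.j_,
                            "lnL": f.loglik_,
                        }
                        for m, f in fits.items()
                    ]
                ).set_index("model")
                df.loc["DECJ", "lrt_stat"] = lrt.statistic
                df.loc["DECJ", "lrt_p"] = lrt.p_value
                bundle["biogeo"] = {"fits": df, "lrt": lrt}
                save(df, "biogeography_fits.csv")
                best = fits["DECJ"] if lrt.p_value < 0.05 else fits["DEC"]
                save(best.node_marginals_, "range_node_marginals.csv")
            elif stage == "threshold":
                rows = []
                for name, column in binary.items():
                    est = ThresholdRegression(
                        n_gen=p["n_gen"],
                        thin=p["thin"],
                        burnin=p["burnin"],
                        seed=config.seed,
                    ).fit(trait_tree, trait, column)
                    post = est.posterior_
                    rows.append(
                        {
                            "trait": name,
                            "mean_r": post.mean,
                            "hpd95_lower": post.hpd_lower,
                            "hpd95_upper": post.hpd_upper,
                            "ess": post.ess,
                            "converged": post.converged,
                        }
                    )
                df = pd.DataFrame(rows).set_index("trait")
                bundle["threshold"] = df
                save(df, "threshold_regressions.csv")
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s done in %.2fs", stage, time.perf_counter() - t0)
    return bundle
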