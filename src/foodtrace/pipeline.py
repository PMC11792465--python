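"""End-to-end workflow orchestration.

Runs the stages in dependency order on a generated or loaded world:
compound tracking -> rarefaction and diversity -> centroid collapsing ->
per-fraction PCoA + Procrustes randomization -> per-compound composition
screen -> diversity screen -> taxon screens (all mice and HU-only) ->
balance search for the compounds most associated with composition. All
intermediate tables are written to the output directory and a single
``summary.json`` collects every stage's headline numbers together with the
seeds used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as ftio
from .balances import select_balance
from .community import (
    collapse_abundances,
    collapse_to_centroids,
    compound_composition_screen,
)
from .diversity import bray_curtis, faith_pd, rarefy, unweighted_unifrac
from .io import treatment_units
from .ordination import pcoa, procrustes_randomization_test
from .regression import diversity_screen, taxon_screen
from .results import screen_table
from .simulate import SimConfig, generate_world
from .tracking import MatchParams, track

logger = logging.getLogger("foodtrace")

__all__ = ["RunConfig", "run_pipeline", "run_simulated_pipeline"]


@dataclass
class RunConfig:
    """Paths and knobs for a pipeline run over on-disk inputs."""

    extract_path: str
    blanks_path: str
    plasma_path: str
    baseline_path: str
    feature_table_path: str
    tree_path: str
    metadata_path: str
    out_dir: str
    match_params: MatchParams = field(default_factory=MatchParams)
    rarefaction_depth: int = 40_625
    n_permutations: int = 10_000
    seed: int = 0
    n_taxa_screen: int = 15
    n_balance_compounds: int = 12
    balance_folds: int = 10

    def validate_paths(self) -> None:
        for name in (
            "extract_path", "blanks_path", "plasma_path", "baseline_path",
            "feature_table_path", "tree_path", "metadata_path",
        ):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such input file {p!r}")


def _screen_tsv(rows, path: Path) -> None:
    screen_table(rows).to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full workflow from on-disk inputs. Aborts on the first stage
    error, naming the stage and the offending input."""
    config.validate_paths()
    world = {
        "tree": ftio.read_tree(config.tree_path),
        "feature_table": ftio.read_feature_table(config.feature_table_path),
        "metadata": ftio.read_metadata(config.metadata_path),
        "lcms": {
            "extract": ftio.read_compound_records(config.extract_path),
            "blanks": ftio.read_compound_records(config.blanks_path),
            "plasma": ftio.read_compound_records(config.plasma_path),
            "baseline": ftio.read_compound_records(config.baseline_path),
        },
    }
    return _run(world, config)


def run_simulated_pipeline(
    sim_config: SimConfig, out_dir: str, **overrides
) -> dict:
    """Generate the synthetic world, write its input files, and run the
    pipeline on them (convenience wrapper used by the analysis drivers)."""
    out = Path(out_dir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    world = generate_world(sim_config)
    inputs = out / "inputs"
    ftio.write_feature_table(world["feature_table"], inputs / "asv_counts.tsv")
    ftio.write_tree(world["tree"], inputs / "tree.nwk")
    ftio.write_metadata(world["metadata"], inputs / "metadata.tsv")
    for name in ("extract", "blanks", "plasma", "baseline"):
        ftio.write_compound_records(world["lcms"][name], inputs / f"{name}.csv")
    with open(inputs / "ground_truth.json", "w") as fh:
        json.dump(world["ground_truth"].to_dict(), fh, indent=1)
    config = RunConfig(
        extract_path=str(inputs / "extract.csv"),
        blanks_path=str(inputs / "blanks.csv"),
        plasma_path=str(inputs / "plasma.csv"),
        baseline_path=str(inputs / "baseline.csv"),
        feature_table_path=str(inputs / "asv_counts.tsv"),
        tree_path=str(inputs / "tree.nwk"),
        metadata_path=str(inputs / "metadata.tsv"),
        out_dir=str(out),
        seed=sim_config.seed,
        **overrides,
    )
    return _run(
        {
            "tree": world["tree"],
            "feature_table": world["feature_table"],
            "metadata": world["metadata"],
            "lcms": world["lcms"],
        },
        config,
    )


def _stage(name: str):
    logger.info("pipeline stage: %s", name)


def _run(world: dict, config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "seed": config.seed,
        "n_permutations": config.n_permutations,
        "rarefaction_depth": config.rarefaction_depth,
    }
    metadata = world["metadata"]
    units = treatment_units(metadata)

    _stage("tracking")
    lcms = world["lcms"]
    report = track(
        list(lcms["extract"].values()),
        list(lcms["blanks"].values()),
        lcms["plasma"],
        lcms["baseline"],
        config.match_params,
    )
    compounds = report.retained
    ftio.write_compound_table(
        compounds, out / "tracked_compounds.tsv", out / "tracked_fractions.tsv"
    )
    summary["tracking"] = report.to_dict()

    _stage("diversity")
    rarefied = rarefy(world["feature_table"], config.rarefaction_depth, config.seed)
    pd_vec = faith_pd(rarefied, world["tree"])
    unifrac = unweighted_unifrac(rarefied, world["tree"])
    ftio.write_distance_matrix(unifrac, out / "unifrac.tsv")
    pd_vec.to_series().to_csv(out / "faith_pd.tsv", sep="\t", header=["faith_pd"])
    summary["diversity"] = {
        "faith_pd_mean_hu": float(
            np.mean([pd_vec[m.sample_id] for m in metadata if m.group == "HU"])
        ),
        "faith_pd_mean_lcm": float(
            np.mean([pd_vec[m.sample_id] for m in metadata if m.group == "LCM"])
        ),
    }

    _stage("centroids")
    # order compounds to the microbiome sample order before collapsing
    compounds = compounds.subset_samples(unifrac.labels)
    unifrac_centroids = collapse_to_centroids(unifrac, units)
    compound_centroids = collapse_abundances(compounds, units)
    ftio.write_distance_matrix(unifrac_centroids, out / "unifrac_centroids.tsv")
    summary["centroids"] = {
        "n_samples": len(unifrac.labels),
        "n_units": len(unifrac_centroids.labels),
    }

    _stage("ordination")
    micro_ord = pcoa(unifrac_centroids)
    rng = np.random.default_rng(config.seed)
    summary["procrustes"] = {}
    for fraction in ("lipid", "aqueous"):
        ids = [
            c
            for c in compound_centroids.compound_ids
            if compound_centroids.fractions[c] == fraction
        ]
        if len(ids) < 2:
            continue
        sub = compound_centroids.subset_compounds(ids)
        bc = bray_curtis(sub).reorder(unifrac_centroids.labels)
        comp_ord = pcoa(bc)
        res = procrustes_randomization_test(
            micro_ord.coordinates,
            comp_ord.coordinates,
            n_perm=config.n_permutations,
            seed=int(rng.integers(0, 2**31 - 1)),
            reference_ids=micro_ord.sample_ids,
            target_ids=comp_ord.sample_ids,
        )
        summary["procrustes"][fraction] = {
            "m2": res.m_squared,
            "p": res.p_value,
            "n_perm": res.n_permutations,
        }

    _stage("composition screen")
    comp_rows = compound_composition_screen(
        unifrac_centroids,
        compound_centroids,
        n_perm=config.n_permutations,
        seed=config.seed,
    )
    _screen_tsv(comp_rows, out / "composition_screen.tsv")
    ok = [r for r in comp_rows if not r.excluded]
    summary["composition_screen"] = {
        "n_tested": len(ok),
        "n_raw_significant": sum(1 for r in ok if r.p_value < 0.05),
        "n_adjusted_significant": sum(1 for r in ok if r.p_adjusted < 0.05),
    }

    _stage("diversity screen")
    div_rows = diversity_screen(compounds, pd_vec, metadata)
    _screen_tsv(div_rows, out / "diversity_screen.tsv")
    ok = [r for r in div_rows if not r.excluded]
    summary["diversity_screen"] = {
        "n_tested": len(ok),
        "n_excluded": len(div_rows) - len(ok),
        "n_adjusted_significant": sum(1 for r in ok if r.p_adjusted < 0.05),
    }

    _stage("taxon screens")
    taxa = world["feature_table"]
    rel = taxa.relative_abundances().to_numpy()
    spread = np.arcsinh(100 * rel).std(axis=0, ddof=1)
    top = np.argsort(-spread)[: config.n_taxa_screen]
    taxa_top = ftio.FeatureTable(
        list(taxa.sample_ids),
        [taxa.feature_ids[i] for i in top],
        taxa.counts[:, top],
    )
    summary["taxon_screen"] = {}
    for label, hu_only in (("all_mice", False), ("hu_only", True)):
        rows = taxon_screen(compounds, taxa_top, metadata, hu_only=hu_only)
        _screen_tsv(rows, out / f"taxon_screen_{label}.tsv")
        ok = [r for r in rows if not r.excluded]
        summary["taxon_screen"][label] = {
            "n_pairs": len(rows),
            "n_tested": len(ok),
            "n_excluded": len(rows) - len(ok),
            "n_adjusted_significant": sum(1 for r in ok if r.p_adjusted < 0.05),
        }

    _stage("balances")
    ranked = sorted(
        (r for r in comp_rows if not r.excluded), key=lambda r: (r.p_value, r.feature_id)
    )
    top_ids = [r.feature_id for r in ranked[: config.n_balance_compounds]]
    taxa_centroid_counts = np.vstack(
        [
            taxa.counts[[taxa.sample_ids.index(s) for s in unifrac.labels], :][
                [i for i, s in enumerate(unifrac.labels) if units[s] == u], :
            ].sum(axis=0)
            for u in unifrac_centroids.labels
        ]
    )
    taxa_centroids = ftio.FeatureTable(
        list(unifrac_centroids.labels), list(taxa.feature_ids), taxa_centroid_counts
    )
    balance_rng = np.random.default_rng(config.seed)
    summary["balances"] = {}
    for cid in top_ids:
        j = compound_centroids.compound_ids.index(cid)
        try:
            bal = select_balance(
                taxa_centroids,
                compound_centroids.areas[:, j],
                n_folds=config.balance_folds,
                seed=int(balance_rng.integers(0, 2**31 - 1)),
            )
            summary["balances"][cid] = {
                "numerator": bal.numerator,
                "denominator": bal.denominator,
                "r_squared": bal.r_squared,
                "cv_r_squared": bal.cv_r_squared,
            }
        except ValueError as exc:
            summary["balances"][cid] = {"error": str(exc)}

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    return summary
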