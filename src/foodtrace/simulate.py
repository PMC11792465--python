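"""Synthetic study generator.

Emulates the study design end-to-end so every pipeline stage can be exercised
without downloads: 10 humanized (HU) donor microbiomes x 2 replicate mice
plus 9 low-complexity-microbiome (LCM) mice across 3 cohorts; a random
phylogeny; an LCM community in which 6 clustered ASVs carry >= 90% of reads;
a plasma compound table containing planted taxon-, diversity- and
balance-linked compounds plus noise compounds; and vendor-style LC-MS feature
lists (extract replicates, blanks, plasma, baseline plasma) in which true
compounds are displaced by <= 5 ppm and <= 0.1 min while decoys are displaced
by > 15 ppm or > 0.5 min. Every planted parameter is recorded in a
machine-readable :class:`GroundTruth` ledger.

All outputs are deterministic functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import skbio

from .diversity import faith_pd
from .io import (
    CompoundRecord,
    CompoundTable,
    FeatureTable,
    SampleMetadata,
    Tree,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_tree",
    "generate_microbiomes",
    "generate_compounds",
    "generate_lcms_features",
    "generate_world",
]


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic world.

    Defaults follow the emulated design: 10 donors x 2 replicate mice + 9 LCM
    mice in 3 cohorts; sequencing depths uniform on [40625, 80000] so the
    40,625-read rarefaction depth never excludes a sample; 6 dominant LCM
    ASVs carrying 93% of the community mass.
    """

    n_donors: int = 10
    replicates_per_donor: int = 2
    n_lcm: int = 9
    n_cohorts: int = 3
    n_asv: int = 120
    n_lcm_dominant: int = 6
    n_lcm_background: int = 10
    lcm_dominant_mass: float = 0.93
    donor_subset_prob: float = 0.4
    donor_alpha: float = 0.6
    depth_min: int = 40_625
    depth_max: int = 80_000
    n_compounds: int = 40
    n_taxon_linked: int = 3
    n_diversity_linked: int = 3
    n_balance_linked: int = 2
    n_baseline: int = 6
    taxon_beta: float = 1.0
    diversity_slope: float = -1.0
    balance_coefficient: float = 1.0
    noise_sd: float = 0.3
    area_base: float = 5.0e5
    area_scale: float = 8.0e4
    n_extract_replicates: int = 4
    n_blanks: int = 2
    n_baseline_samples: int = 6
    n_blank_contaminants: int = 5
    n_decoys: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_donors", "replicates_per_donor", "n_lcm", "n_cohorts", "n_asv",
            "n_compounds", "depth_min", "depth_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimConfig.{name} must be positive")
        planted = self.n_taxon_linked + self.n_diversity_linked + self.n_balance_linked
        if planted + self.n_baseline > self.n_compounds:
            raise ValueError("more planted compounds requested than n_compounds")

    @property
    def n_samples(self) -> int:
        return self.n_donors * self.replicates_per_donor + self.n_lcm


@dataclass
class GroundTruth:
    """Ledger of every planted effect in the generated world."""

    taxon_pairs: list[dict] = field(default_factory=list)
    diversity_compounds: list[dict] = field(default_factory=list)
    balance_compounds: list[dict] = field(default_factory=list)
    baseline_compounds: list[str] = field(default_factory=list)
    decoy_ids: list[str] = field(default_factory=list)
    blank_contaminants: list[str] = field(default_factory=list)
    true_compound_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def validate_against(self, table: CompoundTable) -> None:
        ids = set(table.compound_ids)
        planted = (
            {d["compound"] for d in self.taxon_pairs}
            | {d["compound"] for d in self.diversity_compounds}
            | {d["compound"] for d in self.balance_compounds}
            | set(self.baseline_compounds)
        )
        missing = planted - ids
        if missing:
            raise ValueError(f"planted compounds missing from table: {sorted(missing)}")


def generate_tree(n_tips: int, seed: int) -> Tree:
    """Random rooted bifurcating tree with exponential branch lengths."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    width = len(str(n_tips))
    nodes = [skbio.TreeNode(name=f"ASV{i + 1:0{width}d}") for i in range(n_tips)]
    for node in nodes:
        node.length = float(rng.exponential(0.15)) + 1e-4
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = skbio.TreeNode(children=[nodes[i], nodes[j]])
        parent.length = float(rng.exponential(0.15)) + 1e-4
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = 0.0
    return Tree(root)


def _lcm_clade_tips(tree: Tree, n_needed: int) -> list[str]:
    """Tips of the smallest clade holding >= n_needed tips (keeps the LCM
    community phylogenetically clustered, hence low Faith PD)."""
    best: list[str] | None = None
    for node in tree.root.postorder(include_self=True):
        if node.is_tip():
            continue
        tips = [t.name for t in node.tips()]
        if len(tips) >= n_needed and (best is None or len(tips) < len(best)):
            best = tips
    assert best is not None
    return sorted(best)[:n_needed]


def generate_microbiomes(
    config: SimConfig, tree: Tree
) -> tuple[FeatureTable, list[SampleMetadata]]:
    """Multinomial draws from per-donor Dirichlet base compositions (HU) and
    a 6-ASV-dominated clustered base (LCM)."""
    rng = np.random.default_rng(config.seed + 1)
    asvs = list(tree.tip_names)
    n_asv = len(asvs)
    lcm_tips = _lcm_clade_tips(tree, config.n_lcm_dominant + config.n_lcm_background)
    dominant = lcm_tips[: config.n_lcm_dominant]
    background = lcm_tips[config.n_lcm_dominant :]
    pos = {a: i for i, a in enumerate(asvs)}

    sample_ids: list[str] = []
    metadata: list[SampleMetadata] = []
    counts = []

    for d in range(config.n_donors):
        include = rng.random(n_asv) < config.donor_subset_prob
        if include.sum() < 10:
            include[rng.choice(n_asv, size=10, replace=False)] = True
        base = np.zeros(n_asv)
        base[include] = rng.dirichlet(
            np.full(int(include.sum()), config.donor_alpha)
        )
        cohort = f"c{d % config.n_cohorts + 1}"
        for r in range(config.replicates_per_donor):
            depth = int(rng.integers(config.depth_min, config.depth_max + 1))
            row = rng.multinomial(depth, base)
            sid = f"HU_{d + 1:02d}_r{r + 1}"
            sample_ids.append(sid)
            counts.append(row)
            metadata.append(
                SampleMetadata(sid, "HU", donor_id=f"D{d + 1:02d}", cohort_id=cohort)
            )

    dom_w = rng.dirichlet(np.full(config.n_lcm_dominant, 5.0))
    bg_w = rng.dirichlet(np.full(config.n_lcm_background, 1.0))
    lcm_base = np.zeros(n_asv)
    for a, w in zip(dominant, dom_w):
        lcm_base[pos[a]] = w * config.lcm_dominant_mass
    for a, w in zip(background, bg_w):
        lcm_base[pos[a]] = w * (1.0 - config.lcm_dominant_mass)
    for i in range(config.n_lcm):
        cohort = f"c{i % config.n_cohorts + 1}"
        jitter = rng.lognormal(0.0, 0.15, size=n_asv)
        base = lcm_base * jitter
        base /= base.sum()
        depth = int(rng.integers(config.depth_min, config.depth_max + 1))
        row = rng.multinomial(depth, base)
        sid = f"LCM_{i + 1:02d}"
        sample_ids.append(sid)
        counts.append(row)
        metadata.append(SampleMetadata(sid, "LCM", donor_id=None, cohort_id=cohort))

    table = FeatureTable(sample_ids, asvs, np.vstack(counts))
    return table, metadata


def _standardize(v: np.ndarray) -> np.ndarray:
    s = v.std(ddof=1)
    if s == 0:
        raise ValueError("degenerate predictor while planting effects")
    return (v - v.mean()) / s


def generate_compounds(
    config: SimConfig, table: FeatureTable, tree: Tree
) -> tuple[CompoundTable, GroundTruth]:
    """Plasma compound table with planted effects.

    Effects are injected on a z-score latent scale (matching the screens'
    parameterization) and mapped affinely to positive peak areas, so the
    planted structure survives the z-scoring the screens apply.
    """
    rng = np.random.default_rng(config.seed + 2)
    truth = GroundTruth()
    rel = table.relative_abundances().to_numpy()
    asvs = list(table.feature_ids)
    pd_vec = faith_pd(table, tree).values

    prevalence = (rel > 0).mean(axis=0)
    arc = np.arcsinh(100.0 * rel)
    spread = arc.std(axis=0, ddof=1)
    informative = np.argsort(-((prevalence > 0.3).astype(float) * spread))

    width = len(str(config.n_compounds))
    compound_ids = [f"C{i + 1:0{width}d}" for i in range(config.n_compounds)]
    fractions = {
        cid: ("lipid" if i % 2 == 0 else "aqueous")
        for i, cid in enumerate(compound_ids)
    }
    latent = np.empty((config.n_samples, config.n_compounds))
    k = 0

    for i in range(config.n_taxon_linked):
        taxon = asvs[int(informative[i])]
        x = _standardize(arc[:, int(informative[i])])
        latent[:, k] = config.taxon_beta * x + rng.normal(0, config.noise_sd, config.n_samples)
        truth.taxon_pairs.append(
            {
                "compound": compound_ids[k],
                "taxon": taxon,
                "beta_std": config.taxon_beta,
                "beta_per_arcsinh_unit": config.taxon_beta
                / arc[:, int(informative[i])].std(ddof=1),
            }
        )
        k += 1

    pd_std = _standardize(pd_vec)
    for i in range(config.n_diversity_linked):
        latent[:, k] = config.diversity_slope * pd_std + rng.normal(
            0, config.noise_sd, config.n_samples
        )
        truth.diversity_compounds.append(
            {
                "compound": compound_ids[k],
                "slope_std": config.diversity_slope,
                "slope_per_pd_unit": config.diversity_slope / pd_vec.std(ddof=1),
            }
        )
        k += 1

    for i in range(config.n_balance_linked):
        a, b = int(informative[config.n_taxon_linked + 2 * i]), int(
            informative[config.n_taxon_linked + 2 * i + 1]
        )
        pc = rel[rel > 0].min() / 2.0
        ratio = np.log((rel[:, a] + pc) / (rel[:, b] + pc))
        latent[:, k] = config.balance_coefficient * _standardize(ratio) + rng.normal(
            0, config.noise_sd, config.n_samples
        )
        truth.balance_compounds.append(
            {
                "compound": compound_ids[k],
                "numerator": asvs[a],
                "denominator": asvs[b],
                "coefficient_std": config.balance_coefficient,
            }
        )
        k += 1

    n_noise = config.n_compounds - k
    latent[:, k:] = rng.standard_normal((config.n_samples, n_noise))
    truth.baseline_compounds = compound_ids[k : k + config.n_baseline]

    areas = np.clip(config.area_base + config.area_scale * latent, 0.0, None)
    ctable = CompoundTable(
        sample_ids=list(table.sample_ids),
        compound_ids=compound_ids,
        areas=areas,
        fractions=fractions,
    )
    truth.true_compound_ids = [
        c for c in compound_ids if c not in truth.baseline_compounds
    ]
    truth.validate_against(ctable)
    return ctable, truth


def generate_lcms_features(
    config: SimConfig, compound_table: CompoundTable, truth: GroundTruth
) -> dict[str, dict[str, list[CompoundRecord]]]:
    """Vendor-style feature lists for tracking.

    True plasma features sit within 5 ppm / 0.1 min of the extract consensus;
    decoys sit > 15 ppm or > 0.5 min away; blank contaminants appear in both
    extracts and blanks; baseline-designated compounds also appear in
    baseline plasma.
    """
    rng = np.random.default_rng(config.seed + 3)
    n = len(compound_table.compound_ids)
    masses = rng.uniform(150.0, 900.0, n)
    rts = rng.uniform(0.5, 9.5, n)
    m2_ratio = rng.uniform(0.08, 0.30, n)
    props = {
        cid: (masses[i], rts[i], m2_ratio[i])
        for i, cid in enumerate(compound_table.compound_ids)
    }

    def rec(cid, mass, rt, fraction, area, ratio=None, annotation=None):
        return CompoundRecord(
            compound_id=cid,
            neutral_mass=mass,
            rt=rt,
            fraction=fraction,
            area_m1=area,
            area_m2=None if ratio is None else area * ratio,
            annotation=annotation,
        )

    extract: dict[str, list[CompoundRecord]] = {}
    for e in range(config.n_extract_replicates):
        records = []
        for cid in compound_table.compound_ids:
            mass, rt, ratio = props[cid]
            records.append(
                rec(
                    cid,
                    mass * (1 + rng.uniform(-2e-6, 2e-6)),
                    rt + rng.uniform(-0.02, 0.02),
                    compound_table.fractions[cid],
                    float(rng.uniform(1e5, 1e6)),
                    ratio,
                )
            )
        extract[f"extract_{e + 1}"] = records

    # blank contaminants: in every extract replicate AND in the blanks
    blanks: dict[str, list[CompoundRecord]] = {
        f"blank_{b + 1}": [] for b in range(config.n_blanks)
    }
    for c in range(config.n_blank_contaminants):
        cid = f"BLK{c + 1:03d}"
        mass = float(rng.uniform(150.0, 900.0))
        rt = float(rng.uniform(0.5, 9.5))
        frac = "lipid" if c % 2 == 0 else "aqueous"
        truth.blank_contaminants.append(cid)
        for records in extract.values():
            records.append(
                rec(cid, mass * (1 + rng.uniform(-2e-6, 2e-6)),
                    rt + rng.uniform(-0.02, 0.02), frac, float(rng.uniform(1e5, 1e6)))
            )
        for records in blanks.values():
            records.append(
                rec(cid, mass * (1 + rng.uniform(-2e-6, 2e-6)),
                    rt + rng.uniform(-0.02, 0.02), frac, float(rng.uniform(1e4, 1e5)))
            )

    plasma: dict[str, list[CompoundRecord]] = {}
    for i, sid in enumerate(compound_table.sample_ids):
        records = []
        for j, cid in enumerate(compound_table.compound_ids):
            area = compound_table.areas[i, j]
            if area <= 0:
                continue
            mass, rt, ratio = props[cid]
            records.append(
                rec(
                    f"P{i}_{j}",
                    mass * (1 + rng.uniform(-5e-6, 5e-6)),
                    rt + rng.uniform(-0.1, 0.1),
                    compound_table.fractions[cid],
                    float(area),
                    ratio * (1 + rng.uniform(-0.1, 0.1)),
                )
            )
        plasma[sid] = records

    # decoys: near-misses planted in every plasma sample
    for d in range(config.n_decoys):
        j = int(rng.integers(0, n))
        cid_base = compound_table.compound_ids[j]
        mass, rt, ratio = props[cid_base]
        did = f"DEC{d + 1:03d}"
        truth.decoy_ids.append(did)
        if d % 2 == 0:
            mass = mass * (1 + rng.choice([-1, 1]) * rng.uniform(20e-6, 40e-6))
        else:
            rt = rt + rng.uniform(0.55, 0.9)
        frac = compound_table.fractions[cid_base]
        for i, sid in enumerate(compound_table.sample_ids):
            plasma[sid].append(
                rec(f"{did}_{i}", mass, rt, frac, float(rng.uniform(1e5, 1e6)), ratio)
            )

    baseline: dict[str, list[CompoundRecord]] = {}
    for b in range(config.n_baseline_samples):
        records = []
        for cid in truth.baseline_compounds:
            mass, rt, ratio = props[cid]
            records.append(
                rec(
                    f"B{b}_{cid}",
                    mass * (1 + rng.uniform(-5e-6, 5e-6)),
                    rt + rng.uniform(-0.1, 0.1),
                    compound_table.fractions[cid],
                    float(rng.uniform(5e4, 5e5)),
                    ratio,
                )
            )
        baseline[f"baseline_{b + 1}"] = records

    return {"extract": extract, "blanks": blanks, "plasma": plasma, "baseline": baseline}


def generate_world(config: SimConfig) -> dict:
    """Generate every input the pipeline consumes, plus the ground truth."""
    tree = generate_tree(config.n_asv, config.seed)
    table, metadata = generate_microbiomes(config, tree)
    compounds, truth = generate_compounds(config, table, tree)
    features = generate_lcms_features(config, compounds, truth)
    return {
        "tree": tree,
        "feature_table": table,
        "metadata": metadata,
        "compound_table": compounds,
        "ground_truth": truth,
        "lcms": features,
    }
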