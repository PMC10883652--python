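"""Synthetic two-occupation metagenomic studies.

The generator emulates the statistical structure the downstream analyses
assume: two occupation groups of ~20 samples, hundreds of sparse
compositional features of which a few are group-informative, per-sample
sequencing depths, and binary lifestyle covariates (smoking/drinking).

Counts for each sample are drawn hierarchically:

1. a base community composition from a symmetric Dirichlet with
   concentration ``base_concentration`` (small values give the uneven,
   dominance-heavy profiles typical of real shotgun tables);
2. informative features are multiplied by ``effect_size`` (direction
   "up") or divided by it ("down") in the laborer group, then the
   composition is renormalized;
3. structural zeros: each feature is absent from a given sample with
   probability ``sparsity`` (most taxa are detected in a limited number
   of samples);
4. a sequencing depth from a negative binomial with mean ``depth_mean``
   and dispersion ``depth_dispersion`` (``inf`` gives a fixed depth);
5. counts from a multinomial at that depth, so each sample's column sum
   equals its drawn depth exactly.

All randomness flows from ``SimulationConfig.seed``; identical configs
produce byte-identical tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .tables import RANKS, FeatureTable, TaxonomyTree, validate_metadata

#: smoking / drinking / female rates per occupation group.  Defaults mirror
#: a male student vs. male laborer cohort (smoking 4/20 vs 13/20, drinking
#: 16/20 vs 15/20, no women in either modelling group).
DEFAULT_COVARIATE_RATES: Mapping[str, Mapping[str, float]] = {
    "student": {"smoking": 0.20, "drinking": 0.80, "female": 0.0},
    "laborer": {"smoking": 0.65, "drinking": 0.75, "female": 0.0},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of a synthetic occupation study."""

    n_per_group: int = 20
    n_features: int = 200
    n_informative: int = 5
    effect_size: float = 8.0          # fold-change in the laborer group
    depth_mean: float = 100_000.0     # mean reads per sample
    depth_dispersion: float = 5.0     # NB size parameter; inf = fixed depth
    base_concentration: float = 0.3   # symmetric Dirichlet concentration
    sparsity: float = 0.3             # P(feature structurally absent in a sample)
    covariate_rates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(r) for g, r in DEFAULT_COVARIATE_RATES.items()}
    )
    sample_type: str = "saliva"
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must be in [0, n_features]")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be > 0")
        if self.base_concentration <= 0:
            raise ValueError("base_concentration must be > 0")
        if not 0 <= self.sparsity < 1:
            raise ValueError("sparsity must be in [0, 1)")
        if self.sample_type not in ("saliva", "feces"):
            raise ValueError("sample_type must be 'saliva' or 'feces'")
        for group, rates in self.covariate_rates.items():
            for name, rate in rates.items():
                if not 0 <= rate <= 1:
                    raise ValueError(f"covariate rate {group}/{name} not in [0,1]")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["covariate_rates"] = {g: dict(r) for g, r in self.covariate_rates.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class GroundTruth:
    """Which features are group-informative and their direction in the
    laborer group ('up' or 'down')."""

    directions: Mapping[str, str]

    @property
    def informative_feature_ids(self) -> frozenset[str]:
        return frozenset(self.directions)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dict(self.directions), indent=1))


def recovery_benchmark_config(seed: int) -> SimulationConfig:
    """Study conditions of the planted-feature recovery benchmark:
    20 + 20 samples, 200 features, 5 informative at 8-fold change, fixed
    sequencing depth.

    Depth is fixed (not negative-binomial) because the benchmark isolates
    feature-signal recovery: Bayesian-multiplicative imputation maps count
    zeros to a depth-dependent value, and with variable depths a forest
    can memorize training zeros sample-by-sample, which lets degenerate
    one/two-feature models reach perfect training accuracy.
    """
    return SimulationConfig(
        n_per_group=20,
        n_features=200,
        n_informative=5,
        effect_size=8.0,
        depth_mean=100_000,
        depth_dispersion=math.inf,
        seed=seed,
    )


def simulate_taxonomy(n_species: int, seed: int) -> TaxonomyTree:
    """A random rooted seven-rank taxonomy over ``n_species`` species.

    Group counts shrink geometrically towards the root; assignments are
    nested so each taxon has a unique parent.  Deterministic for a fixed
    seed.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    # number of taxa at each rank above species, species -> genus -> ... -> kingdom
    sizes = []
    size = n_species
    for _ in range(len(RANKS) - 1):
        size = max(1, int(math.ceil(size / 3)))
        sizes.append(size)
    sizes = sizes[::-1]  # kingdom ... genus
    # child -> parent assignment from genus upward
    assign = []
    for upper, lower in zip(sizes[:-1], sizes[1:]):
        a = np.concatenate([np.arange(upper), rng.integers(0, upper, lower - upper)])
        assign.append(np.sort(a))
    species_to_genus = np.concatenate(
        [np.arange(sizes[-1]), rng.integers(0, sizes[-1], n_species - sizes[-1])]
    )
    species_to_genus = np.sort(species_to_genus)

    prefixes = ("k", "p", "c", "o", "f", "g")
    lineages = {}
    for i in range(n_species):
        sp = f"sp{i + 1:04d}"
        idx = int(species_to_genus[i])
        upper_ids = [idx]
        for a in reversed(assign):  # genus->family, ..., phylum->kingdom
            idx = int(a[idx])
            upper_ids.append(idx)
        upper_ids = upper_ids[::-1]  # kingdom ... genus
        lineage = [f"{p}_{j + 1:03d}" for p, j in zip(prefixes, upper_ids)] + [sp]
        lineages[sp] = lineage
    return TaxonomyTree(lineages)


def _sample_ids(config: SimulationConfig, genders: dict[str, np.ndarray]) -> dict[str, list[str]]:
    st = "S" if config.sample_type == "saliva" else "F"
    ids = {}
    for group, code in (("student", "St"), ("laborer", "La")):
        g = genders[group]
        ids[group] = [
            f"{'F' if g[i] else 'M'}{code}{i + 1:02d}{st}" for i in range(config.n_per_group)
        ]
    return ids


def simulate_study(
    config: SimulationConfig,
) -> tuple[FeatureTable, pd.DataFrame, GroundTruth]:
    """Draw one synthetic study: a count table, its sample metadata and
    the ground truth of planted informative features."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_features

    tree = simulate_taxonomy(m, seed=config.seed)
    features = list(tree.species)

    base = rng.dirichlet(np.full(m, config.base_concentration))
    # informative features are planted among the detectable (above-median
    # abundance) half so the signal is recoverable at realistic depths
    candidates = np.flatnonzero(base >= np.median(base))
    chosen = rng.choice(candidates, size=config.n_informative, replace=False)
    # balanced directions: both occupations harbour enriched features
    dirs = [i % 2 == 0 for i in range(config.n_informative)]
    truth = GroundTruth(
        {features[int(i)]: ("up" if up else "down") for i, up in zip(chosen, dirs)}
    )

    laborer = base.copy()
    for i, up in zip(chosen, dirs):
        laborer[int(i)] *= config.effect_size if up else 1.0 / config.effect_size
    laborer /= laborer.sum()
    profiles = {"student": base, "laborer": laborer}

    genders = {
        g: rng.random(config.n_per_group) < config.covariate_rates[g].get("female", 0.0)
        for g in ("student", "laborer")
    }
    ids = _sample_ids(config, genders)

    columns = {}
    meta_rows = []
    for group in ("student", "laborer"):
        rates = config.covariate_rates[group]
        for i, sid in enumerate(ids[group]):
            p = profiles[group].copy()
            if config.sparsity > 0:
                absent = rng.random(m) < config.sparsity
                if absent.all():
                    absent[int(np.argmax(p))] = False
                p[absent] = 0.0
                p /= p.sum()
            if math.isinf(config.depth_dispersion):
                depth = int(round(config.depth_mean))
            else:
                k, mu = config.depth_dispersion, config.depth_mean
                depth = max(1, int(rng.negative_binomial(k, k / (k + mu))))
            columns[sid] = rng.multinomial(depth, p)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "occupation": group,
                    "gender": "F" if genders[group][i] else "M",
                    "sample_type": config.sample_type,
                    "smoking": "yes" if rng.random() < rates.get("smoking", 0.0) else "no",
                    "drinking": "yes" if rng.random() < rates.get("drinking", 0.0) else "no",
                }
            )

    counts = pd.DataFrame(columns, index=pd.Index(features, name="feature_id"))
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    validate_metadata(metadata)
    table = FeatureTable(counts, feature_kind="species", lineage=tree)
    return table, metadata, truth


def ground_truth_recovery_report(
    selected_features: set[str] | frozenset[str] | list[str],
    truth: GroundTruth,
) -> dict[str, float]:
    """Precision/recall of a selected feature set against the planted
    informative features."""
    selected = set(selected_features)
    informative = set(truth.informative_feature_ids)
    tp = len(selected & informative)
    return {
        "n_selected": len(selected),
        "n_informative": len(informative),
        "true_positives": tp,
        "precision": tp / len(selected) if selected else 0.0,
        "recall": tp / len(informative) if informative else 0.0,
    }


def write_study(
    out_dir: str | Path,
    table: FeatureTable,
    metadata: pd.DataFrame,
    truth: GroundTruth | None = None,
    config: SimulationConfig | None = None,
) -> None:
    """Write a study as plain-text artifacts: counts TSV, metadata TSV,
    config YAML and ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_tsv(out / "counts.tsv")
    metadata.to_csv(out / "metadata.tsv", sep="\t")
    if truth is not None:
        truth.to_json(out / "ground_truth.json")
    if config is not None:
        config.to_yaml(out / "config.yaml")
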