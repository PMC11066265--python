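"""Synthetic desk-scale datasets with the structure the pipeline assumes.

The generator stands in for the study's deposited sequence data. It draws a
pure-birth phylogeny, evolves per-taxon niche optima along it by Brownian
motion (so niches carry phylogenetic signal — the ingredient betaNTI needs
to detect selection), assembles communities along a salinity-like gradient
by Gaussian environmental filtering of a lognormal regional pool, samples
reads multinomially at fixed depth, and couples nutrient covariates to a
latent multifunctionality signal that increases monotonically along the
gradient. Strong filtering (small niche breadth) with samples at opposite
gradient ends yields deterministic (selection-dominated) turnover; the
neutral switch removes filtering entirely so turnover is drift-like.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from skbio import TreeNode

from . import io_core
from .io_core import CountTable, ValidationError

PHYLA = ["Proteobacteria", "Bacteroidetes", "Actinobacteria",
         "Cyanobacteria", "Firmicutes", "Planctomycetes"]
PHYLUM_PROBS = [0.60, 0.12, 0.10, 0.08, 0.06, 0.04]
PROTEO_CLASSES = ["Alphaproteobacteria", "Gammaproteobacteria",
                  "Betaproteobacteria"]
SEASONS = ["SP", "SU", "FA", "WI"]


@dataclass
class SimConfig:
    """The stated world of the simulator.

    Defaults mirror the desk-scale regime the pipeline is validated on:
    200 taxa, 20 samples, 5,000 reads per sample on a 0-33 PSU salinity
    gradient split into LS/MS/HS thirds. ``niche_signal`` is the Brownian
    variance per unit branch length of the niche optima (PSU^2);
    ``filtering_strength`` is the Gaussian niche breadth sigma_f in PSU —
    smaller means stronger selection — and ``neutral=True`` removes
    filtering (the sigma_f -> infinity limit). sigma_f = 0 is rejected.
    """

    n_taxa: int = 200
    n_samples: int = 20
    depth: int = 5000
    birth_rate: float = 1.0
    niche_signal: float = 20.0
    filtering_strength: float = 6.0
    neutral: bool = False
    gradient: np.ndarray | None = None
    abundance_lognormal: tuple[float, float] = (0.0, 2.0)
    nutrient_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValidationError("need at least 4 taxa")
        if not self.neutral and self.filtering_strength <= 0:
            raise ValidationError(
                "filtering_strength must be > 0; use neutral=True for the "
                "no-filtering limit"
            )
        if self.gradient is not None:
            self.gradient = np.asarray(self.gradient, dtype=float)
            if self.gradient.shape != (self.n_samples,):
                raise ValidationError("gradient length must equal n_samples")


def neutral_config(**overrides) -> SimConfig:
    """Neutral-assembly preset: lognormal regional pool, no filtering."""
    return SimConfig(neutral=True, **overrides)


def selection_config(**overrides) -> SimConfig:
    """Strong-selection preset: narrow niches (sigma_f = 3 PSU) and samples
    split across the two gradient extremes."""
    n_samples = overrides.pop("n_samples", 20)
    half = n_samples // 2
    gradient = np.concatenate([
        np.linspace(0.0, 3.0, half),
        np.linspace(30.0, 33.0, n_samples - half),
    ])
    return SimConfig(n_samples=n_samples, filtering_strength=3.0,
                     gradient=gradient, **overrides)


@dataclass
class SimBundle:
    table: CountTable
    tree: TreeNode
    frame: pd.DataFrame
    taxonomy: pd.DataFrame
    config: SimConfig = field(repr=False)


def simulate_tree(n_taxa: int, seed: int = 0, birth_rate: float = 1.0) -> TreeNode:
    """Ultrametric pure-birth (Yule) tree with tips ASV0001..ASVnnnn."""
    if n_taxa < 4:
        raise ValidationError("need at least 4 taxa")
    dtree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_taxa,
        rng=random.Random(int(seed)),
    )
    tree = TreeNode.read([dtree.as_string(schema="newick").replace("[&R] ", "")])
    for i, tip in enumerate(tree.tips(), start=1):
        tip.name = f"ASV{i:04d}"
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    return tree


def brownian_niches(tree: TreeNode, variance: float, root_value: float,
                    rng: np.random.Generator) -> pd.Series:
    """Brownian-motion trait values at the tips (variance per unit length)."""
    values: dict[int, float] = {id(tree): root_value}
    for node in tree.preorder(include_self=False):
        step_var = variance * (node.length or 0.0)
        step = rng.normal(0.0, np.sqrt(step_var)) if step_var > 0 else 0.0
        values[id(node)] = values[id(node.parent)] + step
    return pd.Series({t.name: values[id(t)] for t in tree.tips()})


def _taxonomy(taxon_ids: list[str], rng: np.random.Generator) -> pd.DataFrame:
    phyla = rng.choice(PHYLA, size=len(taxon_ids), p=PHYLUM_PROBS)
    classes = []
    for p in phyla:
        if p == "Proteobacteria":
            classes.append(rng.choice(PROTEO_CLASSES, p=[0.45, 0.40, 0.15]))
        else:
            classes.append(f"{p}_classis")
    return pd.DataFrame({"phylum": phyla, "class": classes},
                        index=pd.Index(taxon_ids, name="taxon_id"))


def _metadata(gradient: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Environmental frame: nutrients load on a latent multifunctionality
    signal that increases with the gradient; water properties are loosely
    coupled; labels are cyclic for interface completeness."""
    n = len(gradient)
    latent = gradient / 33.0  # monotone 0..1 along the gradient
    noise = lambda scale: rng.normal(0.0, scale, size=n)
    sd = 1.0  # nutrient noise is relative to a unit-latent swing
    eps = lambda: noise(sd * 0.3)
    frame = pd.DataFrame(index=pd.Index(
        [f"S{i + 1:03d}" for i in range(n)], name="sample_id"
    ))
    frame["salinity"] = gradient
    frame["temperature"] = 24.0 + 4.0 * np.sin(
        2 * np.pi * np.arange(n) / max(n, 1)
    ) + noise(1.0)
    frame["pH"] = 7.8 + 0.4 * latent + noise(0.05)
    frame["Chl-a"] = np.maximum(0.05, 8.0 * (1 - latent) + noise(0.8))
    frame["DO"] = 6.5 + 1.0 * latent + noise(0.3)
    frame["COD"] = np.maximum(0.1, 3.0 - 1.5 * latent + noise(0.3))
    # MNI factors: each is loading * latent + noise, on its own scale
    scales = {"TP": (0.02, 0.08), "DIP": (0.005, 0.04),
              "NO3-N": (0.05, 0.40), "NO2-N": (0.005, 0.05),
              "NH4-N": (0.02, 0.20), "DIN": (0.10, 0.60),
              "TN": (0.20, 1.00), "TOC": (1.00, 3.00)}
    for factor, (base, swing) in scales.items():
        frame[factor] = np.maximum(
            0.0, base + swing * latent + eps() * swing
        )
    frame["season"] = [SEASONS[i % 4] for i in range(n)]
    frame["year"] = [2018 if (i // 4) % 2 == 0 else 2020 for i in range(n)]
    group = np.empty(n, dtype=object)
    group[gradient < 11.0] = "LS"
    group[(gradient >= 11.0) & (gradient < 22.0)] = "MS"
    group[gradient >= 22.0] = "HS"
    frame["salinity_group"] = group
    return frame


def simulate_dataset(config: SimConfig | None = None) -> SimBundle:
    """Generate an aligned (CountTable, Phylogeny, SampleFrame, TaxonomyMap)
    bundle under the configured regime; fully deterministic under the seed."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_taxa, seed=config.seed,
                         birth_rate=config.birth_rate)
    taxon_ids = [t.name for t in tree.tips()]
    niches = brownian_niches(tree, config.niche_signal, root_value=16.5,
                             rng=rng).loc[taxon_ids]
    mu, sigma = config.abundance_lognormal
    regional = rng.lognormal(mu, sigma, size=config.n_taxa)
    gradient = (config.gradient if config.gradient is not None
                else np.linspace(0.0, 33.0, config.n_samples))
    counts = np.empty((config.n_samples, config.n_taxa), dtype=np.int64)
    for s, env in enumerate(gradient):
        if config.neutral:
            w = regional
        else:
            z = (env - niches.to_numpy()) / config.filtering_strength
            w = regional * np.exp(-0.5 * z * z)
        total = w.sum()
        if total <= 0:
            raise ValidationError(
                f"all filtering weights underflowed at gradient {env}"
            )
        counts[s] = rng.multinomial(config.depth, w / total)
    frame = _metadata(gradient, rng)
    table = CountTable(list(frame.index), taxon_ids, counts)
    taxonomy = _taxonomy(taxon_ids, rng)
    return SimBundle(table=table, tree=tree, frame=frame, taxonomy=taxonomy,
                     config=config)


# ---------------------------------------------------------------------------
# Fixture round-trip
# ---------------------------------------------------------------------------

FIXTURE_FILES = ("table.tsv", "tree.nwk", "metadata.tsv", "taxonomy.tsv",
                 "manifest.json")


def write_fixture(bundle: SimBundle, out_dir, force: bool = False) -> Path:
    """Write the bundle as plain-text files plus a manifest recording the
    config (seed included) so the fixture can be regenerated bit-for-bit."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ValidationError(f"output dir {out} is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    io_core.write_count_table(bundle.table, out / "table.tsv")
    io_core.write_tree(bundle.tree, out / "tree.nwk")
    io_core.write_metadata(bundle.frame, out / "metadata.tsv")
    io_core.write_taxonomy(bundle.taxonomy, out / "taxonomy.tsv")
    cfg = dataclasses.asdict(bundle.config)
    if cfg["gradient"] is not None:
        cfg["gradient"] = list(map(float, cfg["gradient"]))
    (out / "manifest.json").write_text(
        json.dumps({"generator": "estasm.synthetic_data", "config": cfg},
                   indent=2) + "\n"
    )
    return out


def read_fixture(fixture_dir) -> SimBundle:
    """Read a written fixture back through the io_core readers."""
    d = Path(fixture_dir)
    table = io_core.read_count_table(d / "table.tsv")
    tree = io_core.read_tree(d / "tree.nwk")
    frame = io_core.read_metadata(d / "metadata.tsv")
    taxonomy = io_core.read_taxonomy(d / "taxonomy.tsv")
    manifest = json.loads((d / "manifest.json").read_text())
    cfg = manifest["config"]
    if cfg.get("gradient") is not None:
        cfg["gradient"] = np.asarray(cfg["gradient"], dtype=float)
    if cfg.get("abundance_lognormal") is not None:
        cfg["abundance_lognormal"] = tuple(cfg["abundance_lognormal"])
    return SimBundle(table=table, tree=tree, frame=frame, taxonomy=taxonomy,
                     config=SimConfig(**cfg))
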