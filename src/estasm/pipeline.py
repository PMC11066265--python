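"""End-to-end orchestration: partition -> diversity -> assembly -> MNI ->
associations -> PLS-PM, with a run manifest capturing every seed and choice.

Each stage writes plain TSV outputs into the run directory; a stage failure
aborts with the stage name while earlier outputs are preserved. Reruns with
the same config and inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import association, assembly, diversity, emf, io_core, partition, plspm
from .io_core import MNI_FACTORS, METADATA_VARIABLES, ValidationError

logger = logging.getLogger("estasm")


@dataclass
class RunConfig:
    """Serializable description of a full analysis run."""

    table: str = "table.tsv"
    tree: str = "tree.nwk"
    metadata: str = "metadata.tsv"
    taxonomy: str | None = "taxonomy.tsv"
    out_dir: str = "estasm_out"
    rarefy: bool = True
    rarefaction_depth: int | str = "min"
    rarefaction_seed: int = 0
    abundant_threshold: float = 0.001
    rare_threshold: float = 0.0001
    partition_basis: str = "dataset_total"
    group_column: str = "salinity_group"
    n_perm: int = 999
    n_null: int = 999
    null_seed: int = 0
    beta_score_method: str = "pcoa"
    mni_factors: list[str] = field(default_factory=lambda: list(MNI_FACTORS))
    mantel_variables: list[str] = field(
        default_factory=lambda: list(METADATA_VARIABLES))
    run_plspm: bool = True
    n_boot: int = 199
    plspm_seed: int = 0
    subcommunities: list[str] = field(
        default_factory=lambda: ["abundant", "rare"])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis and return the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "estasm_version": __version__,
        "config": dataclasses.asdict(config),
        "stages": [],
        "warnings": [],
    }
    stage_t0 = time.monotonic()

    def stage_done(name: str) -> None:
        nonlocal stage_t0
        elapsed = time.monotonic() - stage_t0
        manifest["stages"].append({"stage": name,
                                   "elapsed_s": round(elapsed, 3)})
        logger.info("stage %s done in %.2fs", name, elapsed)
        stage_t0 = time.monotonic()

    current = "load"
    try:
        table = io_core.read_count_table(config.table)
        tree = io_core.read_tree(config.tree)
        frame = io_core.read_metadata(config.metadata)
        taxonomy = (io_core.read_taxonomy(config.taxonomy)
                    if config.taxonomy else None)
        table, frame, tree, report = io_core.align(table, frame, tree)
        manifest["alignment"] = dataclasses.asdict(report)
        stage_done(current)

        current = "rarefy"
        if config.rarefy:
            table = io_core.rarefy(table, depth=config.rarefaction_depth,
                                   seed=config.rarefaction_seed)
            manifest["rarefaction_depth"] = int(table.depth[0])
        stage_done(current)

        current = "partition"
        part = partition.classify_taxa(
            table, abundant_threshold=config.abundant_threshold,
            rare_threshold=config.rare_threshold,
            basis=config.partition_basis)
        summary = partition.partition_summary(part, table)
        _write(summary, out / "partition_summary.tsv")
        _write(pd.DataFrame({"label": part.labels,
                             "rel_abundance": part.rel_abundance}),
               out / "partition_labels.tsv")
        if taxonomy is not None:
            comp = partition.composition_by_group(
                table, taxonomy, frame, rank="phylum",
                groupby=config.group_column)
            _write(comp.set_index("group"), out / "composition_phylum.tsv")
        stage_done(current)

        groups = frame[config.group_column]
        subtables: dict[str, io_core.CountTable] = {}
        for which in config.subcommunities:
            sub = partition.subcommunity_table(table, part, which)
            # samples with zero reads in this class cannot enter the
            # per-subcommunity diversity/assembly statistics
            nz = sub.depth > 0
            if not nz.all():
                dropped = [s for s, k in zip(sub.sample_ids, nz) if not k]
                manifest["warnings"].append(
                    f"{which}: dropped {len(dropped)} zero-read samples "
                    f"({dropped[:5]})"
                )
                sub = sub.select_samples(
                    [s for s, k in zip(sub.sample_ids, nz) if k])
            subtables[which] = sub

        current = "diversity"
        beta_score: dict[str, pd.Series] = {}
        dists = {}
        for which, sub in subtables.items():
            alpha = diversity.alpha_diversity(sub)
            _write(alpha, out / f"alpha_{which}.tsv")
            dist = diversity.bray_curtis(sub)
            dists[which] = dist
            _write(diversity.distance_to_frame(dist),
                   out / f"bray_curtis_{which}.tsv")
            sub_groups = groups.loc[sub.sample_ids]
            perm = diversity.permanova(dist, sub_groups,
                                       n_perm=config.n_perm,
                                       seed=config.null_seed)
            _write(pd.DataFrame([dataclasses.asdict(perm)],
                                index=pd.Index([which], name="subcommunity")),
                   out / f"permanova_{which}.tsv")
            beta_score[which] = diversity.beta_scores(
                dist, method=config.beta_score_method,
                salinity=frame.loc[sub.sample_ids, "salinity"]
                if "salinity" in frame.columns else None,
                groups=sub_groups)
        stage_done(current)

        current = "assembly"
        null_cfg = assembly.NullConfig(n_null=config.n_null,
                                       seed=config.null_seed)
        calls = {}
        bntis = {}
        for which, sub in subtables.items():
            sub_tree = tree.shear(sub.taxon_ids)
            bn = assembly.bnti_matrix(sub, sub_tree, null_cfg)
            rc = assembly.rc_bray_matrix(sub, null_cfg)
            call = assembly.classify_processes(bn.bnti, rc, null_cfg)
            calls[which], bntis[which] = call, bn.bnti
            fr = assembly.process_fractions(
                call, groups=groups.loc[sub.sample_ids], bnti=bn.bnti)
            _write(bn.bnti, out / f"bnti_{which}.tsv")
            _write(rc, out / f"rc_bray_{which}.tsv")
            _write(fr, out / f"process_fractions_{which}.tsv")
            long = _pairs_long(bn.bnti, rc, call)
            _write(long, out / f"assembly_pairs_{which}.tsv")
        stage_done(current)

        current = "mni"
        mni_res = emf.mni(frame, factors=config.mni_factors)
        mni_table = mni_res.std.copy()
        mni_table.insert(0, "MNI", mni_res.mni)
        _write(mni_table, out / "mni.tsv")
        stage_done(current)

        current = "associations"
        rows = []
        for which, sub in subtables.items():
            ids = mni_res.mni.index.intersection(sub.sample_ids)
            alpha = diversity.alpha_diversity(sub).loc[ids]
            y = mni_res.mni.loc[ids]
            for name, x in (("shannon", alpha["shannon"]),
                            ("richness", alpha["richness"]),
                            ("beta_score", beta_score[which].loc[ids])):
                if x.std() == 0:
                    manifest["warnings"].append(
                        f"{which}: predictor {name} is constant; "
                        "regression skipped")
                    continue
                fit = association.linear_fit(x.to_numpy(), y.to_numpy())
                rows.append({"subcommunity": which, "predictor": name,
                             "group": "all", **dataclasses.asdict(fit)})
                for g in pd.unique(groups.loc[ids]):
                    mask = (groups.loc[ids] == g).to_numpy()
                    if mask.sum() >= 3 and x[mask].std() > 0:
                        fit = association.linear_fit(
                            x.to_numpy()[mask], y.to_numpy()[mask])
                        rows.append({"subcommunity": which, "predictor": name,
                                     "group": str(g),
                                     **dataclasses.asdict(fit)})
        _write(pd.DataFrame(rows).set_index("subcommunity"),
               out / "regressions.tsv")

        env_vars = [v for v in config.mantel_variables
                    if v in frame.columns and frame[v].std() > 0]
        mantel_rows = []
        for which, sub in subtables.items():
            env_d = association.env_distance(frame.loc[sub.sample_ids],
                                             env_vars)
            mres = association.mantel(dists[which], env_d,
                                      n_perm=config.n_perm,
                                      seed=config.null_seed)
            mantel_rows.append({"subcommunity": which, "matrix": "bray_curtis",
                                **dataclasses.asdict(mres)})
        _write(pd.DataFrame(mantel_rows).set_index("subcommunity"),
               out / "mantel.tsv")
        stage_done(current)

        if config.run_plspm:
            current = "plspm"
            for which, sub in subtables.items():
                ids = mni_res.mni.index.intersection(sub.sample_ids)
                alpha = diversity.alpha_diversity(sub).loc[ids]
                data = frame.loc[ids].copy()
                data["shannon"] = alpha["shannon"]
                data["richness"] = alpha["richness"].astype(float)
                data["beta_score"] = beta_score[which].loc[ids]
                data["MNI"] = mni_res.mni.loc[ids]
                model = plspm.fig6_path_model()
                fit = plspm.fit_plspm(data, model)
                _write(fit.effects.set_index("source"),
                       out / f"plspm_effects_{which}.tsv")
                paths_long = pd.concat(
                    [s.rename("coefficient").rename_axis("source")
                      .reset_index().assign(target=t)
                     for t, s in fit.paths.items()],
                    ignore_index=True,
                )
                _write(paths_long.set_index("target"),
                       out / f"plspm_paths_{which}.tsv")
                if config.n_boot:
                    boot = plspm.bootstrap_plspm(
                        data, model, n_boot=config.n_boot,
                        seed=config.plspm_seed)
                    _write(boot.paths.set_index("source"),
                           out / f"plspm_bootstrap_{which}.tsv")
                manifest[f"plspm_r2_{which}"] = fit.r2
            stage_done(current)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return manifest


def _pairs_long(bnti: pd.DataFrame, rc: pd.DataFrame,
                calls: pd.DataFrame) -> pd.DataFrame:
    ids = list(bnti.index)
    iu = np.triu_indices(len(ids), 1)
    return pd.DataFrame({
        "sample_i": [ids[i] for i in iu[0]],
        "sample_j": [ids[j] for j in iu[1]],
        "bnti": bnti.to_numpy()[iu],
        "rc_bray": rc.to_numpy()[iu],
        "process": calls.to_numpy()[iu],
    }).set_index("sample_i")
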