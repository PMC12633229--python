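"""End-to-end orchestration: simulate/load -> rollup -> profile -> shift ->
modules/PCA -> enrichment, with a reproducibility manifest.

A single config seed fans out to per-stage seeds by stable hashing of the
stage name, so any stage can be rerun independently yet reproducibly. All
stage outputs are plain TSV/JSON; every numeric threshold in play is echoed
in manifest.json.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import correlation, groupshift, gsea, modules, simulate
from .io import (
    ExpressionMatrix,
    file_sha256,
    read_gmt,
    read_matrix,
    read_metadata,
    rollup_peptides,
    write_gmt,
    write_manifest,
    write_matrix,
    write_metadata,
)

logger = logging.getLogger("anchoromics")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed (< 2^31) from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration; every threshold defaults to its calibrated value."""

    out_dir: str = "anchoromics_run"
    seed: int = 0
    simulate: bool = True
    sim: simulate.SimConfig | None = None
    rna_path: str | None = None
    peptides_path: str | None = None  # TSV with peptide ids "PROTEIN_pepK"
    metadata_path: str | None = None
    sets_path: str | None = None
    anchor_id: str = "NPTX2"
    group_pair: tuple[str, str] = ("Control", "AD")
    top_k_correlates: int = 7
    n_cluster_genes: int = 25
    n_perm: int = 500
    n_random_sets: int = 20
    random_set_size: int = 50
    tier_moderate: float = correlation.TIER_MODERATE
    tier_weak: float = correlation.TIER_WEAK
    strong_threshold: float = correlation.STRONG_PAIR
    decorrelation_band: float = groupshift.DECORRELATION_BAND
    separation_cuts: tuple[float, float] = groupshift.SEPARATION_CUTS
    uniqueness_fold: float = gsea.UNIQUENESS_FOLD
    cut_depth: int = 3
    pca_components: int = 2
    outlier_sd: float = 3.0

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        raw = dict(raw)
        sim_raw = raw.pop("sim", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in {
            f.name for f in dataclasses.fields(cls)}})
        if isinstance(cfg.group_pair, list):
            cfg.group_pair = tuple(cfg.group_pair)
        if isinstance(cfg.separation_cuts, list):
            cfg.separation_cuts = tuple(cfg.separation_cuts)
        if sim_raw:
            mods = [
                simulate.ModuleSpec(**m) if isinstance(m, Mapping) else m
                for m in sim_raw.pop("module_specs", [])
            ]
            cfg.sim = simulate.SimConfig(**sim_raw)
            if mods:
                cfg.sim.module_specs = mods
        return cfg

    def echo(self) -> dict:
        out = dataclasses.asdict(self)
        if self.sim is not None:
            out["sim"] = dataclasses.asdict(self.sim)
        return out


def _load_peptides_tsv(path: str) -> "simulate.PeptidePanel":
    from .io import PeptidePanel

    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    mapping = {pep: pep.rsplit("_pep", 1)[0] for pep in df.index}
    return PeptidePanel(abundance=df.astype(float), peptide_to_protein=mapping)


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage, writing TSV artifacts plus manifest.json to out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}

    # --- stage: inputs -----------------------------------------------------
    if cfg.simulate:
        sim_cfg = cfg.sim if cfg.sim is not None else simulate.SimConfig()
        sim_cfg.seed = stage_seed(cfg.seed, "simulate")
        sim_cfg.anchor_id = cfg.anchor_id
        data = simulate.simulate_dataset(sim_cfg)
        rna, peptides, metadata = data.rna, data.peptides, data.metadata
        sets = simulate.emit_true_gene_sets(
            data.truth,
            n_random_sets=cfg.n_random_sets,
            set_size=cfg.random_set_size,
            seed=stage_seed(cfg.seed, "gene_sets"),
        )
        write_matrix(rna, out / "rna.tsv")
        write_matrix(peptides.abundance, out / "peptides.tsv")
        write_metadata(metadata, out / "metadata.tsv")
        write_gmt(sets, out / "sets.gmt")
    else:
        if not (cfg.rna_path and cfg.metadata_path and cfg.sets_path):
            raise ValueError("non-simulation runs need rna_path, metadata_path, sets_path")
        rna = read_matrix(cfg.rna_path, "rna")
        metadata = read_metadata(cfg.metadata_path)
        sets = read_gmt(cfg.sets_path)
        peptides = _load_peptides_tsv(cfg.peptides_path) if cfg.peptides_path else None
        for p in (cfg.rna_path, cfg.peptides_path, cfg.metadata_path, cfg.sets_path):
            if p:
                checksums[p] = file_sha256(p)
    if cfg.anchor_id not in rna.feature_ids:
        raise ValueError(f"anchor feature {cfg.anchor_id!r} not in RNA matrix")

    # --- stage: rollup -----------------------------------------------------
    protein = rollup_peptides(peptides) if peptides is not None else None
    if protein is not None:
        write_matrix(protein, out / "protein.tsv")

    groups = metadata["group"]
    anchor_rna = rna.feature(cfg.anchor_id)

    # --- stage: group-level abundance tests --------------------------------
    stats_rows = []
    gc = groupshift.compare_groups(
        anchor_rna.to_numpy(), groups.loc[anchor_rna.index].to_numpy(),
        feature_id=f"rna:{cfg.anchor_id}",
    )
    stats_rows.append(gc)
    if protein is not None and cfg.anchor_id in protein.feature_ids:
        ap = protein.feature(cfg.anchor_id)
        gc2 = groupshift.compare_groups(
            ap.to_numpy(), groups.loc[ap.index].to_numpy(),
            feature_id=f"protein:{cfg.anchor_id}",
        )
        stats_rows.append(gc2)
    stats_tbl = pd.concat(
        [g.table.assign(feature=g.feature_id) for g in stats_rows], ignore_index=True
    )
    stats_tbl.to_csv(out / "groupstats.tsv", sep="\t", index=False, na_rep="NA")

    # --- stage: anchor profiles --------------------------------------------
    profile_rna = correlation.anchor_profile(
        rna, anchor_rna, p_method="fisher_z",
        anchor_id=cfg.anchor_id, anchor_modality="rna",
        tier_moderate=cfg.tier_moderate, tier_weak=cfg.tier_weak,
    )
    profile_rna.table.to_csv(out / "profile_rna.tsv", sep="\t", na_rep="NA")
    profile_prot = None
    if protein is not None and cfg.anchor_id in protein.feature_ids:
        profile_prot = correlation.anchor_profile(
            rna, protein.feature(cfg.anchor_id), p_method="fisher_z",
            anchor_id=cfg.anchor_id, anchor_modality="protein",
            tier_moderate=cfg.tier_moderate, tier_weak=cfg.tier_weak,
        )
        profile_prot.table.to_csv(out / "profile_protein.tsv", sep="\t", na_rep="NA")

    # --- stage: group shift on top correlates -------------------------------
    scored = profile_rna.scored().drop(index=cfg.anchor_id, errors="ignore")
    top = scored.reindex(scored["r"].abs().sort_values(ascending=False).index)
    top_genes = list(top.index[: cfg.top_k_correlates])
    shift_rows = []
    for gene in top_genes:
        layers = [("rna_rna", anchor_rna)]
        if protein is not None and cfg.anchor_id in protein.feature_ids:
            layers.append(("rna_protein", protein.feature(cfg.anchor_id)))
        for layer, anchor_vec in layers:
            try:
                res = groupshift.group_shift_analysis(
                    rna.feature(gene), anchor_vec, groups,
                    gene_id=gene, layer=layer, group_pair=cfg.group_pair,
                    stable_band=cfg.decorrelation_band,
                    separation_cuts=cfg.separation_cuts,
                )
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("group shift skipped for %s/%s: %s", gene, layer, exc)
                continue
            ga, gb = cfg.group_pair
            ra, rb = res.r_by_group[ga], res.r_by_group[gb]
            shift_rows.append(
                (gene, layer,
                 ra.r if ra.ok else np.nan, ra.n_complete,
                 rb.r if rb.ok else np.nan, rb.n_complete,
                 res.D, res.decorrelation_class, res.separation_class)
            )
    pd.DataFrame(
        shift_rows,
        columns=["gene", "layer", f"r_{cfg.group_pair[0]}", f"n_{cfg.group_pair[0]}",
                 f"r_{cfg.group_pair[1]}", f"n_{cfg.group_pair[1]}",
                 "D", "decorrelation_class", "separation_class"],
    ).to_csv(out / "shift.tsv", sep="\t", index=False, na_rep="NA")

    # --- stage: PCA phenotypes ----------------------------------------------
    pca = modules.pca_phenotypes(
        rna, n_components=cfg.pca_components, outlier_sd=cfg.outlier_sd
    )
    pca.scores.to_csv(out / "scores.tsv", sep="\t", index_label="sample", na_rep="NA")
    pca.loadings.to_csv(out / "loadings.tsv", sep="\t", index_label="feature", na_rep="NA")

    # --- stage: mixed-variable modules --------------------------------------
    cluster_genes = list(dict.fromkeys([cfg.anchor_id] + list(
        top.index[: cfg.n_cluster_genes])))
    rna_sub = ExpressionMatrix(rna.values.loc[cluster_genes], "rna")
    mats = [rna_sub]
    if protein is not None:
        mats.append(protein)
    pc_scores = ExpressionMatrix(pca.scores.T, "component")
    mats.append(pc_scores)
    variables = correlation.assemble_variables(
        mats, metadata=metadata, metadata_cols=["age", "pmi"]
    )
    dist, _excl = modules.correlation_distance_matrix(variables)
    assignment = modules.average_linkage_cluster(dist, cut_depth=cfg.cut_depth)
    write_matrix(dist, out / "dist.tsv")
    pd.Series(assignment.labels, name="module").rename_axis("variable").to_csv(
        out / "modules.tsv", sep="\t"
    )

    # --- stage: all-pairs table ---------------------------------------------
    pairs = correlation.all_pairs_table(variables, strong_threshold=cfg.strong_threshold)
    pairs.table.to_csv(out / "pairs.tsv", sep="\t", index=False, na_rep="NA")

    # --- stage: enrichment ---------------------------------------------------
    report = gsea.permutation_nes(
        rna, anchor_rna, sets,
        n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, "gsea"),
        anchor_id=cfg.anchor_id,
    )
    report.table.to_csv(out / "enrichment.tsv", sep="\t", na_rep="NA")

    thresholds = {
        "tier_moderate": cfg.tier_moderate,
        "tier_weak": cfg.tier_weak,
        "strong_threshold": cfg.strong_threshold,
        "decorrelation_band": cfg.decorrelation_band,
        "separation_cuts": list(cfg.separation_cuts),
        "uniqueness_fold": cfg.uniqueness_fold,
        "outlier_sd": cfg.outlier_sd,
        "cut_depth": cfg.cut_depth,
        "split_min_height": modules.SPLIT_MIN_HEIGHT,
        "exact_wilcoxon_max_n": groupshift.EXACT_WILCOXON_MAX_N,
        "n_perm": cfg.n_perm,
    }
    write_manifest(
        out / "manifest.json",
        config={**cfg.echo(), "thresholds": thresholds,
                "stage_seeds": {s: stage_seed(cfg.seed, s)
                                for s in ("simulate", "gene_sets", "gsea")}},
        seed=cfg.seed,
        input_checksums=checksums,
    )
    return out
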