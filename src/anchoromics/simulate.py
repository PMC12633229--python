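"""Synthetic coupled RNA / protein / metadata datasets with known truth.

The generator emulates the statistical structure the analysis assumes:

* a latent anchor-activity factor per sample, with a stepwise group decline
  of the anchor (Control > MCI > AD) in log units;
* planted gene modules coupled to the anchor with group-specific Pearson
  correlations (a positively coupled "plasticity" block and a negatively
  coupled "stress/lysosomal" block by default), using the closed-form
  construction gene = sign * rho * Z + sqrt(1 - rho^2) * eps so the
  population within-group correlation is exactly rho;
* a protein layer for a small panel of genes, coupled to the RNA layer at a
  configurable moderate correlation, with an additional group shift of the
  anchor protein (the AD protein downshift that drives centroid separation);
* a peptide layer (several peptides per panel protein, log-normal noise,
  positive raw peak-area scale) for exercising the rollup; and
* plausible sample metadata (age, sex, source, PMI, CERAD, Braak) with an
  optional PMI confounder.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection, PeptidePanel

SOURCES = ("Banner", "Irvine", "JH", "NW")


@dataclasses.dataclass
class ModuleSpec:
    """A planted gene module coupled to the anchor factor.

    ``coupling`` maps group -> target within-group Pearson r with the anchor
    (magnitudes, applied with ``sign``).
    """

    name: str
    size: int
    coupling: dict[str, float]
    sign: int = 1


@dataclasses.dataclass
class SimConfig:
    n_per_group: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"Control": 60, "MCI": 60, "AD": 60, "Other": 0}
    )
    n_genes: int = 2000
    anchor_id: str = "NPTX2"
    module_specs: list[ModuleSpec] = dataclasses.field(
        default_factory=lambda: [
            ModuleSpec(
                "plasticity", 40,
                {"Control": 0.60, "MCI": 0.45, "AD": 0.30, "Other": 0.45}, sign=1,
            ),
            ModuleSpec(
                "stress_lysosomal", 40,
                {"Control": 0.30, "MCI": 0.35, "AD": 0.45, "Other": 0.35}, sign=-1,
            ),
        ]
    )
    rna_protein_r: float = 0.37
    anchor_group_shift: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"Control": 0.0, "MCI": -0.4, "AD": -0.8, "Other": 0.0}
    )
    anchor_protein_shift: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"Control": 0.0, "MCI": -0.5, "AD": -1.0, "Other": 0.0}
    )
    protein_subset_fraction: float = 0.01  # 20 proteins of 2000 genes
    protein_sample_fraction: float = 1.0
    peptides_per_protein: int = 3
    peptide_noise_sd: float = 0.3
    missing_rate: float = 0.0
    pmi_protein_coupling: float = 0.0  # optional PMI confounder, off by default
    seed: int = 0

    def validate(self) -> None:
        total = sum(m.size for m in self.module_specs)
        if total > self.n_genes - 1:
            raise ValueError("module sizes exceed n_genes (anchor needs a slot)")
        if not -1 < self.rna_protein_r < 1:
            raise ValueError("rna_protein_r must be strictly inside (-1, 1)")
        for m in self.module_specs:
            for g, rho in m.coupling.items():
                if not -1 < m.sign * rho < 1:
                    raise ValueError(
                        f"infeasible coupling {m.sign * rho} for module {m.name}, group {g}"
                    )
        if not 0 < self.protein_subset_fraction <= 1:
            raise ValueError("protein_subset_fraction must be in (0, 1]")
        if not 0 < self.protein_sample_fraction <= 1:
            raise ValueError("protein_sample_fraction must be in (0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.peptides_per_protein < 1:
            raise ValueError("peptides_per_protein must be >= 1")
        if self.peptide_noise_sd < 0:
            raise ValueError("peptide_noise_sd must be >= 0")


def study_scale_config(seed: int = 0) -> SimConfig:
    """Preset at the full cohort scale: 180/83/218 (+94 Other) samples, 135-sample protein subpanel."""
    cfg = SimConfig(seed=seed)
    cfg.n_per_group = {"Control": 180, "MCI": 83, "AD": 218, "Other": 94}
    cfg.protein_sample_fraction = 135 / 575
    return cfg


@dataclasses.dataclass
class SimTruth:
    """Ground truth of a simulated dataset, for recovery tests."""

    factors: pd.Series  # latent standardized anchor factor per sample
    module_of_gene: dict[str, str]  # gene -> module name or "background"
    coupling_of_gene: dict[str, dict[str, float]]  # gene -> group -> signed rho
    anchor_id: str
    panel_genes: list[str]
    protein_samples: list[str]
    protein_latent: pd.DataFrame  # noiseless-peptide protein layer (panel x protein samples)
    groups: pd.Series  # group label per sample


@dataclasses.dataclass
class SimDataset:
    rna: ExpressionMatrix
    peptides: PeptidePanel
    metadata: pd.DataFrame
    truth: SimTruth


def _metadata_for(groups: pd.Series, rng: np.random.Generator) -> pd.DataFrame:
    n = len(groups)
    age = np.where(
        groups == "Other", rng.normal(45, 8, n),
        rng.normal(82, 7, n),
    ).round(1)
    braak_means = {"Control": 1.5, "MCI": 3.0, "AD": 5.0, "Other": 1.0}
    cerad_means = {"Control": 0.5, "MCI": 1.5, "AD": 2.5, "Other": 0.5}
    braak = np.clip(
        np.rint([rng.normal(braak_means[g], 0.8) for g in groups]), 0, 6
    ).astype(int)
    cerad = np.clip(
        np.rint([rng.normal(cerad_means[g], 0.6) for g in groups]), 0, 3
    ).astype(int)
    return pd.DataFrame(
        {
            "group": groups.to_numpy(),
            "age": age,
            "sex": rng.choice(["F", "M"], size=n),
            "source": rng.choice(SOURCES, size=n),
            "pmi": np.round(rng.lognormal(1.2, 0.5, n), 2),
            "cerad": cerad,
            "braak": braak,
        },
        index=groups.index,
    )


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Generate (rna, peptides, metadata, truth) per the config; seed-deterministic."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    sample_ids: list[str] = []
    group_labels: list[str] = []
    for g, n in cfg.n_per_group.items():
        for i in range(n):
            sample_ids.append(f"{g}_{i + 1:03d}")
            group_labels.append(g)
    groups = pd.Series(group_labels, index=sample_ids, name="group")
    n_samples = len(sample_ids)
    if n_samples < 3:
        raise ValueError("need at least 3 samples in total")

    Z = rng.normal(size=n_samples)  # latent anchor factor, standardized per sample pool
    shift = np.array([cfg.anchor_group_shift.get(g, 0.0) for g in group_labels])

    gene_ids = [cfg.anchor_id]
    module_of_gene = {cfg.anchor_id: "anchor"}
    coupling_of_gene: dict[str, dict[str, float]] = {}
    for m in cfg.module_specs:
        for k in range(m.size):
            gid = f"{m.name.upper()}_{k + 1:04d}"
            gene_ids.append(gid)
            module_of_gene[gid] = m.name
            coupling_of_gene[gid] = {g: m.sign * rho for g, rho in m.coupling.items()}
    n_bg = cfg.n_genes - len(gene_ids)
    for k in range(n_bg):
        gid = f"BG_{k + 1:05d}"
        gene_ids.append(gid)
        module_of_gene[gid] = "background"

    baselines = rng.normal(6.0, 1.5, size=len(gene_ids))  # vst-like log-scale means
    X = np.empty((len(gene_ids), n_samples))
    X[0] = baselines[0] + shift + Z  # the anchor: unit within-group variance
    for i, gid in enumerate(gene_ids[1:], start=1):
        module = module_of_gene[gid]
        eps = rng.normal(size=n_samples)
        if module == "background":
            X[i] = baselines[i] + eps
        else:
            rho = np.array(
                [coupling_of_gene[gid].get(g, 0.0) for g in group_labels]
            )
            X[i] = baselines[i] + rho * Z + np.sqrt(1.0 - rho**2) * eps
    rna = ExpressionMatrix(
        values=pd.DataFrame(X, index=gene_ids, columns=sample_ids), modality="rna"
    )

    # protein panel: anchor first, then module genes round-robin, then background
    n_panel = max(1, round(cfg.protein_subset_fraction * cfg.n_genes))
    panel_genes = [cfg.anchor_id]
    pools = [
        [g for g in gene_ids if module_of_gene[g] == m.name] for m in cfg.module_specs
    ]
    pools.append([g for g in gene_ids if module_of_gene[g] == "background"])
    k = 0
    while len(panel_genes) < n_panel and any(pools):
        pool = pools[k % len(pools)]
        if pool:
            panel_genes.append(pool.pop(0))
        k += 1

    # protein sample subpanel, spread across groups deterministically
    n_prot_samples = max(3, round(cfg.protein_sample_fraction * n_samples))
    if n_prot_samples >= n_samples:
        protein_samples = list(sample_ids)
    else:
        idx = rng.permutation(n_samples)[:n_prot_samples]
        protein_samples = [sample_ids[i] for i in sorted(idx)]
    col_idx = [sample_ids.index(s) for s in protein_samples]

    rho_rp = cfg.rna_protein_r
    prot_shift = np.array(
        [cfg.anchor_protein_shift.get(groups[s], 0.0) for s in protein_samples]
    )
    prot_groups = np.array([groups[s] for s in protein_samples], dtype=object)
    P = np.empty((len(panel_genes), len(protein_samples)))
    for i, gid in enumerate(panel_genes):
        xv = X[gene_ids.index(gid), col_idx]
        # standardize within group so the coupling targets the within-group r;
        # tiny groups fall back to the overall moments
        xz = (xv - xv.mean()) / xv.std()
        for g in set(prot_groups):
            sel = prot_groups == g
            if sel.sum() >= 3 and xv[sel].std() > 0:
                xz[sel] = (xv[sel] - xv[sel].mean()) / xv[sel].std()
        eta = rng.normal(size=len(protein_samples))
        P[i] = rho_rp * xz + np.sqrt(1.0 - rho_rp**2) * eta
        if gid == cfg.anchor_id:
            P[i] = P[i] + prot_shift
    protein_latent = pd.DataFrame(P, index=panel_genes, columns=protein_samples)

    metadata = _metadata_for(groups, rng)
    if cfg.pmi_protein_coupling != 0.0:
        # couple PMI negatively/positively to the last panel proteins (lysosomal-like)
        rho_p = cfg.pmi_protein_coupling
        pz = (protein_latent.iloc[-1] - protein_latent.iloc[-1].mean())
        pz = pz / pz.std()
        pmi = np.round(
            np.exp(1.2 + 0.5 * (rho_p * pz.reindex(metadata.index).fillna(0.0)
                                + np.sqrt(1 - rho_p**2) * rng.normal(size=len(metadata)))),
            2,
        )
        metadata["pmi"] = pmi

    # peptide layer: raw peak areas 2^(protein + noise) * per-peptide constant
    pep_rows = {}
    pep_map = {}
    for gid in panel_genes:
        for j in range(cfg.peptides_per_protein):
            pep = f"{gid}_pep{j + 1}"
            noise = rng.normal(0.0, cfg.peptide_noise_sd, size=len(protein_samples))
            const = 10 ** rng.uniform(4, 6)  # arbitrary peak-area magnitude
            pep_rows[pep] = const * np.power(2.0, protein_latent.loc[gid].to_numpy() + noise)
            pep_map[pep] = gid
    pep_df = pd.DataFrame(pep_rows, index=protein_samples).T
    if cfg.missing_rate > 0:
        drop = rng.random(pep_df.shape) < cfg.missing_rate
        vals = pep_df.to_numpy()
        vals[drop] = np.nan
        pep_df = pd.DataFrame(vals, index=pep_df.index, columns=pep_df.columns)
    peptides = PeptidePanel(abundance=pep_df, peptide_to_protein=pep_map)

    truth = SimTruth(
        factors=pd.Series(Z, index=sample_ids, name="anchor_factor"),
        module_of_gene=module_of_gene,
        coupling_of_gene=coupling_of_gene,
        anchor_id=cfg.anchor_id,
        panel_genes=panel_genes,
        protein_samples=protein_samples,
        protein_latent=protein_latent,
        groups=groups,
    )
    return SimDataset(rna=rna, peptides=peptides, metadata=metadata, truth=truth)


def emit_true_gene_sets(
    truth: SimTruth,
    n_random_sets: int,
    set_size: int,
    seed: int,
    gene_universe: Sequence[str] | None = None,
) -> GeneSetCollection:
    """One gene set per planted module plus uniformly sampled background sets."""
    genes = list(gene_universe) if gene_universe is not None else list(
        truth.module_of_gene
    )
    if set_size > len(genes):
        raise ValueError(f"set_size {set_size} exceeds number of genes {len(genes)}")
    rng = np.random.default_rng(seed)
    background = [g for g in genes if truth.module_of_gene.get(g) == "background"]
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    modules = sorted(
        {m for m in truth.module_of_gene.values() if m not in ("background", "anchor")}
    )
    for m in modules:
        sets[f"module:{m}"] = [g for g, mm in truth.module_of_gene.items() if mm == m]
        desc[f"module:{m}"] = "planted module"
    pool = background if len(background) >= set_size else genes
    for k in range(n_random_sets):
        members = list(rng.choice(pool, size=set_size, replace=False))
        sets[f"random:{k + 1:03d}"] = members
        desc[f"random:{k + 1:03d}"] = "uniform background draw"
    return GeneSetCollection(sets=sets, descriptions=desc)
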