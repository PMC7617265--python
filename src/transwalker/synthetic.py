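"""Seeded multi-omic scenario generator with planted ground truth.

Generates genotype dosages with LD-blocked structure, methylation beta
values carrying planted cis effects (per-allele effect sizes around the
2% absolute-change scale typical of blood meQTLs, explaining ~10% of
methylation variance), a planted trans mechanism
(SNP -> cis TF-gene expression -> TF binding -> methylation at bound
CpGs on other chromosomes), optional cell-composition interaction
effects, a scale-free PPI graph containing the planted TF, and TFBS
interval tracks. Every artifact is a deterministic function of the
scenario config (including its seed).

The generator is a study-conditions emulator, not a cohort model: LD is
a block-copy process, methylation noise is Gaussian-then-clip on the
beta scale, and cell proportions are Dirichlet draws.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as twio

CELL_TYPES = ("CD8T", "CD4T", "NK", "Bcell", "Mono")

# Fixed per-operation seed offsets so each artifact is reproducible on its
# own while all derive from the single scenario seed.
_SEED_GENO = 11
_SEED_SCENARIO = 23
_SEED_METH = 37
_SEED_EXPR = 41
_SEED_COV = 53
_SEED_PPI = 61


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    The defaults are the package's reference study conditions: 600
    samples (split into two cohorts by the pipeline), 60 SNPs in LD
    blocks of 6 across two chromosomes, cis effects of 0.02 per allele
    copy with noise_sd chosen so a cis SNP explains roughly 10% of
    methylation variance, and one planted trans-acting TF bound at 10
    CpGs on the other chromosome.
    """

    n_samples: int = 600
    n_snps: int = 60
    n_cpgs: int = 120
    n_genes: int = 120
    maf_range: tuple[float, float] = (0.2, 0.5)
    cis_effect_beta: float = 0.02
    trans_tf_gene: str = "GENE_TF"
    trans_cpg_count: int = 10
    noise_sd: float = 0.04
    ld_block_size: int = 6
    interaction_cell_type: str | None = None
    seed: int = 0
    # generator-internal knobs
    ld_flip_prob: float = 0.05
    n_cis_pairs: int = 8
    cell_effect_sd: float = 0.02
    tf_snp_coef: float = 1.0          # sentinel dosage -> TF log2 expression
    tf_expr_noise_sd: float = 0.5
    chain_coef: float = 0.08          # TF expression -> bound-CpG methylation
    interaction_beta: float = 0.15
    n_locus_genes: int = 12           # genes within 1 Mb of the sentinel
    n_decoy_tracks: int = 8
    decoy_binding_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.n_samples < 30:
            raise ValueError("n_samples must be >= 30")
        for name in ("n_snps", "n_cpgs", "n_genes", "trans_cpg_count",
                     "ld_block_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.cis_effect_beta <= 1:
            raise ValueError("cis_effect_beta must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if (self.interaction_cell_type is not None
                and self.interaction_cell_type not in CELL_TYPES):
            raise ValueError(f"unknown cell type {self.interaction_cell_type!r}")


@dataclass
class GroundTruth:
    """Ledger of planted effects, used by recovery tests."""

    causal_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    planted_tf: str = ""
    sentinel_snp: str = ""
    bound_cpgs: set[str] = field(default_factory=set)
    locus_genes: list[str] = field(default_factory=list)
    interaction_pairs: list[tuple[str, str, str, float]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        data = {
            "causal_pairs": [list(t) for t in self.causal_pairs],
            "planted_tf": self.planted_tf,
            "sentinel_snp": self.sentinel_snp,
            "bound_cpgs": sorted(self.bound_cpgs),
            "locus_genes": list(self.locus_genes),
            "interaction_pairs": [list(t) for t in self.interaction_pairs],
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            causal_pairs=[(a, b, float(c)) for a, b, c in d["causal_pairs"]],
            planted_tf=d["planted_tf"],
            sentinel_snp=d["sentinel_snp"],
            bound_cpgs=set(d["bound_cpgs"]),
            locus_genes=list(d["locus_genes"]),
            interaction_pairs=[(a, b, c, float(x)) for a, b, c, x in d["interaction_pairs"]],
        )


# ---------------------------------------------------------------------------
# Annotations (deterministic layout on two synthetic chromosomes)

def snp_ids(config: ScenarioConfig) -> list[str]:
    return [f"rs{i:04d}" for i in range(config.n_snps)]


def cpg_ids(config: ScenarioConfig) -> list[str]:
    return [f"cg{j:05d}" for j in range(config.n_cpgs)]


def gene_ids(config: ScenarioConfig) -> list[str]:
    ids = [f"GENE_{k:03d}" for k in range(config.n_genes - 1)]
    return [config.trans_tf_gene] + ids


def generate_snp_annotation(config: ScenarioConfig) -> pd.DataFrame:
    """Place SNPs on chr1/chr2; each LD block spans < 1 Mb, blocks ~0.7 Mb apart."""
    ids = snp_ids(config)
    half = (config.n_snps + 1) // 2
    rows = []
    for i, sid in enumerate(ids):
        chrom = "chr1" if i < half else "chr2"
        local = i if i < half else i - half
        block, within = divmod(local, config.ld_block_size)
        pos = 500_000 + block * 1_200_000 + within * 100_000
        rows.append((chrom, pos, pos + 1, sid))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def generate_cpg_annotation(config: ScenarioConfig) -> pd.DataFrame:
    ids = cpg_ids(config)
    half = (config.n_cpgs + 1) // 2
    rows = []
    for j, cid in enumerate(ids):
        chrom = "chr1" if j < half else "chr2"
        local = j if j < half else j - half
        # >1 Mb spacing: CpGs correlated through a shared trans regulator
        # must not collapse into one methylation locus by the distance rule
        pos = 430_000 + local * 1_100_000
        rows.append((chrom, pos, pos + 1, cid))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _block_of(config: ScenarioConfig, snp_index: int) -> int:
    half = (config.n_snps + 1) // 2
    local = snp_index if snp_index < half else snp_index - half
    return local // config.ld_block_size


# ---------------------------------------------------------------------------
# Genotypes

def generate_genotypes(config: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dosage matrix (samples x SNPs, values {0,1,2}) plus SNP annotation.

    Within an LD block every SNP is a noisy copy of a block seed
    haplotype pair: each allele is flipped independently with
    probability ``ld_flip_prob``, giving tunable within-block R^2.
    """
    rng = np.random.default_rng(config.seed + _SEED_GENO)
    anno = generate_snp_annotation(config)
    ids = list(anno["name"])
    n, m = config.n_samples, config.n_snps
    dos = np.zeros((n, m), dtype=np.int64)
    half = (m + 1) // 2
    for chrom_start, chrom_stop in ((0, half), (half, m)):
        i = chrom_start
        while i < chrom_stop:
            block_cols = list(range(i, min(i + config.ld_block_size, chrom_stop)))
            maf = rng.uniform(*config.maf_range)
            seed_h = rng.random((n, 2)) < maf  # two haplotypes per sample
            for c in block_cols:
                flips = rng.random((n, 2)) < config.ld_flip_prob
                hap = seed_h ^ flips
                dos[:, c] = hap.sum(axis=1)
            i += config.ld_block_size
    samples = [f"S{k:04d}" for k in range(n)]
    return pd.DataFrame(dos, index=samples, columns=ids), anno


# ---------------------------------------------------------------------------
# PPI graph

def generate_ppi(config: ScenarioConfig) -> pd.DataFrame:
    """Scale-free (preferential-attachment) PPI edge list over all gene ids."""
    import networkx as nx

    genes = gene_ids(config)
    g = nx.barabasi_albert_graph(len(genes), 2, seed=config.seed + _SEED_PPI)
    rng = np.random.default_rng(config.seed + _SEED_PPI)
    # random node-to-gene assignment: locus genes must not all be the
    # early (hub) nodes of the preferential-attachment process
    shuffled = list(genes)
    rng.shuffle(shuffled)
    mapping = dict(enumerate(shuffled))
    rows = [(mapping[u], mapping[v], round(float(rng.uniform(0.4, 1.0)), 3))
            for u, v in sorted(g.edges())]
    return pd.DataFrame(rows, columns=["protein_a", "protein_b", "score"])


# ---------------------------------------------------------------------------
# Regulatory scenario (ground truth + gene annotation + TFBS tracks)

def generate_regulatory_scenario(
    config: ScenarioConfig,
    ppi: pd.DataFrame,
) -> tuple[GroundTruth, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Plant the trans mechanism and the cis effects.

    Returns ``(truth, gene_annotation, tfbs_tracks)`` where tracks map a
    DNA-binding-protein id to a BED DataFrame. The planted TF's track
    places an interval within ±50 bp of every bound CpG; decoy proteins
    bind random CpGs genome-wide at ``decoy_binding_rate``.
    """
    rng = np.random.default_rng(config.seed + _SEED_SCENARIO)
    snp_anno = generate_snp_annotation(config)
    cpg_anno = generate_cpg_annotation(config)
    ppi_nodes = set(ppi["protein_a"]) | set(ppi["protein_b"])
    if config.trans_tf_gene not in ppi_nodes:
        raise ValueError(f"planted TF {config.trans_tf_gene!r} absent from PPI graph")

    # sentinel: middle SNP of the first chr1 block
    sentinel_idx = config.ld_block_size // 2
    sentinel = snp_anno.iloc[sentinel_idx]
    truth = GroundTruth(planted_tf=config.trans_tf_gene,
                        sentinel_snp=str(sentinel["name"]))

    # bound CpGs: drawn from chromosomes other than the sentinel's
    trans_mask = cpg_anno["chrom"] != sentinel["chrom"]
    trans_pool = cpg_anno[trans_mask]
    if config.trans_cpg_count > len(trans_pool):
        raise ValueError(
            f"trans_cpg_count={config.trans_cpg_count} exceeds the "
            f"{len(trans_pool)} CpGs on other chromosomes")
    chosen = rng.choice(trans_pool.index.to_numpy(), size=config.trans_cpg_count,
                        replace=False)
    truth.bound_cpgs = set(cpg_anno.loc[sorted(chosen), "name"])

    # cis causal pairs: SNP paired with nearest same-chromosome CpG < 1 Mb,
    # one SNP per LD block, skipping the sentinel's block
    cis_candidates = []
    for i in range(config.n_snps):
        if _block_of(config, i) == _block_of(config, sentinel_idx) and \
                snp_anno.iloc[i]["chrom"] == sentinel["chrom"]:
            continue
        srow = snp_anno.iloc[i]
        same = cpg_anno[(cpg_anno["chrom"] == srow["chrom"])
                        & (~cpg_anno["name"].isin(truth.bound_cpgs))]
        if same.empty:
            continue
        dist = (same["start"] - srow["start"]).abs()
        j = dist.idxmin()
        if dist[j] < 1_000_000:
            cis_candidates.append((i, str(srow["name"]), str(cpg_anno.loc[j, "name"])))
    seen_blocks: set[tuple[str, int]] = set()
    used_cpgs: set[str] = set()
    for i, sid, cid in cis_candidates:
        key = (str(snp_anno.iloc[i]["chrom"]), _block_of(config, i))
        if key in seen_blocks or cid in used_cpgs:
            continue
        seen_blocks.add(key)
        used_cpgs.add(cid)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        truth.causal_pairs.append((sid, cid, sign * config.cis_effect_beta))
        if len(truth.causal_pairs) >= config.n_cis_pairs:
            break

    # interaction pair: first cis pair gains a cell-context modulation
    if config.interaction_cell_type is not None and truth.causal_pairs:
        sid, cid, _ = truth.causal_pairs[0]
        truth.interaction_pairs.append(
            (sid, cid, config.interaction_cell_type, config.interaction_beta))

    # gene annotation: locus genes packed within ±0.5 Mb of the sentinel
    genes = gene_ids(config)
    n_locus = min(config.n_locus_genes, config.n_genes)
    locus = [config.trans_tf_gene] + [g for g in genes
                                      if g != config.trans_tf_gene][: n_locus - 1]
    truth.locus_genes = locus
    rows = []
    for k, gid in enumerate(locus):
        pos = max(10_000, int(sentinel["start"]) - 450_000 + k * 80_000)
        rows.append((str(sentinel["chrom"]), pos, pos + 10_000, gid))
    rest = [g for g in genes if g not in set(locus)]
    for k, gid in enumerate(rest):
        chrom = "chr1" if k % 2 == 0 else "chr2"
        pos = 8_000_000 + (k // 2) * 120_000
        rows.append((chrom, pos, pos + 10_000, gid))
    gene_anno = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    # TFBS tracks
    cpg_pos = cpg_anno.set_index("name")[["chrom", "start"]]
    tracks: dict[str, pd.DataFrame] = {}

    def _intervals(cpg_names: list[str]) -> pd.DataFrame:
        recs = []
        for cname in sorted(cpg_names):
            chrom, pos = cpg_pos.loc[cname, "chrom"], int(cpg_pos.loc[cname, "start"])
            jitter = int(rng.integers(-30, 31))
            start = max(0, pos + jitter - 15)
            recs.append((chrom, start, start + 30, cname))
        df = pd.DataFrame(recs, columns=["chrom", "start", "end", "name"])
        return df.sort_values(["chrom", "start"]).reset_index(drop=True)

    tracks[config.trans_tf_gene] = _intervals(sorted(truth.bound_cpgs))
    # decoys: well-connected non-locus genes binding random CpG subsets
    import networkx as nx
    g = nx.Graph()
    g.add_edges_from(zip(ppi["protein_a"], ppi["protein_b"]))
    degree_sorted = sorted(g.nodes, key=lambda v: (-g.degree[v], v))
    decoys = [v for v in degree_sorted if v not in set(locus)][: config.n_decoy_tracks]
    all_cpgs = list(cpg_anno["name"])
    k_bind = max(2, int(round(config.decoy_binding_rate * len(all_cpgs))))
    for d in decoys:
        bound = rng.choice(all_cpgs, size=min(k_bind, len(all_cpgs)), replace=False)
        tracks[d] = _intervals(sorted(bound))
    return truth, gene_anno, tracks


# ---------------------------------------------------------------------------
# Covariates

def generate_covariates(config: ScenarioConfig) -> pd.DataFrame:
    """Age, sex, five white-cell proportions (Dirichlet) and two batch PCs."""
    rng = np.random.default_rng(config.seed + _SEED_COV)
    n = config.n_samples
    samples = [f"S{k:04d}" for k in range(n)]
    # six blood fractions drawn jointly; the granulocyte share is omitted
    # (as with reference-based estimates), so the five kept proportions
    # do not sum to one and stay full-rank alongside an intercept
    cells = rng.dirichlet([12.0, 25.0, 5.0, 6.0, 8.0, 55.0], size=n)[:, :5]
    df = pd.DataFrame(cells, index=samples, columns=list(CELL_TYPES))
    df.insert(0, "sex", rng.integers(0, 2, size=n).astype(float))
    df.insert(0, "age", rng.uniform(25, 75, size=n).round(1))
    df["batch_pc1"] = rng.normal(0, 1, size=n)
    df["batch_pc2"] = rng.normal(0, 1, size=n)
    return df


# ---------------------------------------------------------------------------
# Methylation and expression

def generate_expression(
    config: ScenarioConfig,
    dosages: pd.DataFrame,
    truth: GroundTruth,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """log2-scale expression; the planted TF depends on the sentinel dosage."""
    rng = np.random.default_rng(config.seed + _SEED_EXPR)
    genes = gene_ids(config)
    n = len(dosages)
    base = rng.uniform(3.0, 8.0, size=len(genes))
    expr = base + rng.normal(0.0, config.tf_expr_noise_sd, size=(n, len(genes)))
    df = pd.DataFrame(expr, index=dosages.index, columns=genes)
    if truth.sentinel_snp in dosages.columns:
        g = dosages[truth.sentinel_snp].to_numpy(float)
        df[truth.planted_tf] = (base[genes.index(truth.planted_tf)]
                                + config.tf_snp_coef * g
                                + rng.normal(0.0, config.tf_expr_noise_sd, size=n))
    return df


def generate_methylation(
    config: ScenarioConfig,
    dosages: pd.DataFrame,
    truth: GroundTruth,
    covariates: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Beta-value matrix with planted cis, trans-chain and interaction effects.

    beta = baseline + Σ(true_beta · dosage) + cell-mixture term
           + chain_coef · centred TF expression (bound CpGs only)
           + interaction terms + N(0, noise_sd), clipped to [0, 1].
    """
    rng = np.random.default_rng(config.seed + _SEED_METH)
    if covariates is None:
        covariates = generate_covariates(config)
    cids = cpg_ids(config)
    n = len(dosages)
    baseline = rng.uniform(0.25, 0.75, size=len(cids))
    beta = np.tile(baseline, (n, 1))

    if config.cell_effect_sd > 0:
        loadings = rng.normal(0.0, config.cell_effect_sd,
                              size=(len(CELL_TYPES), len(cids)))
        props = covariates.loc[dosages.index, list(CELL_TYPES)].to_numpy(float)
        beta += (props - props.mean(axis=0)) @ loadings

    col_index = {c: k for k, c in enumerate(cids)}
    for sid, cid, b in truth.causal_pairs:
        beta[:, col_index[cid]] += b * dosages[sid].to_numpy(float)

    if expression is not None and truth.planted_tf in expression.columns:
        tf = expression.loc[dosages.index, truth.planted_tf].to_numpy(float)
        tf = tf - tf.mean()
        for cid in sorted(truth.bound_cpgs):
            beta[:, col_index[cid]] += config.chain_coef * tf

    props_all = covariates.loc[dosages.index]
    for sid, cid, cell, ib in truth.interaction_pairs:
        ctx = props_all[cell].to_numpy(float)
        ctx = ctx - ctx.mean()
        beta[:, col_index[cid]] += ib * dosages[sid].to_numpy(float) * ctx

    if config.noise_sd > 0:
        beta += rng.normal(0.0, config.noise_sd, size=beta.shape)
    return pd.DataFrame(np.clip(beta, 0.0, 1.0), index=dosages.index, columns=cids)


# ---------------------------------------------------------------------------
# eQTM confounding scenario (used by calibration tests of the eQTM scan)

def generate_eqtm_scenario(
    n_samples: int = 400,
    seed: int = 0,
    cell_loading_meth: float = 1.5,
    cell_loading_expr: float = 8.0,
    direct_coef: float = 0.6,
    noise_sd: float = 0.04,
) -> dict[str, pd.DataFrame | pd.Series]:
    """One confounded and one directly-coupled CpG-gene pair.

    ``cg_conf``/``gene_conf`` both load on CD8T proportion (no direct
    link); ``cg_direct`` drives ``gene_direct`` directly. Used to show
    that the five-cell-type adjustment removes the former association
    and keeps the latter.
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{k:04d}" for k in range(n_samples)]
    props = rng.dirichlet([12.0, 25.0, 5.0, 6.0, 8.0, 55.0], size=n_samples)[:, :5]
    cells = pd.DataFrame(props, index=samples, columns=list(CELL_TYPES))
    cd8 = cells["CD8T"] - cells["CD8T"].mean()
    meth = pd.DataFrame(index=samples)
    meth["cg_conf"] = np.clip(0.5 + cell_loading_meth * cd8
                              + rng.normal(0, noise_sd, n_samples), 0, 1)
    meth["cg_direct"] = np.clip(0.5 + rng.normal(0, noise_sd, n_samples), 0, 1)
    expr = pd.DataFrame(index=samples)
    expr["gene_conf"] = 5.0 + cell_loading_expr * cd8 + rng.normal(0, 0.5, n_samples)
    centred = meth["cg_direct"] - meth["cg_direct"].mean()
    expr["gene_direct"] = 5.0 + direct_coef * centred / centred.std() \
        + rng.normal(0, 0.5, n_samples)
    return {"methylation": meth, "expression": expr, "cells": cells}


# ---------------------------------------------------------------------------
# Fixture bundle

def write_fixture_bundle(config: ScenarioConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate every artifact for a scenario and write it as plain text.

    Layout: TSV matrices (genotypes/methylation/expression/covariates),
    BED annotations (snps/cpgs/genes), one BED per TFBS track under
    ``tfbs/``, PPI edge-list TSV, JSON ground-truth ledger and the YAML
    scenario config. Files round-trip losslessly through :mod:`.io`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tfbs").mkdir(exist_ok=True)

    dosages, snp_anno = generate_genotypes(config)
    ppi = generate_ppi(config)
    truth, gene_anno, tracks = generate_regulatory_scenario(config, ppi)
    covariates = generate_covariates(config)
    expression = generate_expression(config, dosages, truth, covariates)
    methylation = generate_methylation(config, dosages, truth, covariates, expression)
    cpg_anno = generate_cpg_annotation(config)

    paths: dict[str, Path] = {}

    def _save(key: str, fn, *args) -> None:
        paths[key] = out / key
        fn(*args, paths[key])

    _save("genotypes.tsv", twio.write_matrix, dosages.astype(float))
    _save("methylation.tsv", twio.write_matrix, methylation.round(6))
    _save("expression.tsv", twio.write_matrix, expression.round(6))
    _save("covariates.tsv", twio.write_matrix, covariates.round(6))
    _save("snps.bed", twio.write_bed, snp_anno)
    _save("cpgs.bed", twio.write_bed, cpg_anno)
    _save("genes.bed", twio.write_bed, gene_anno)
    _save("ppi.tsv", twio.write_ppi, ppi)
    for prot, track in sorted(tracks.items()):
        key = f"tfbs/{prot}.bed"
        paths[key] = out / key
        twio.write_bed(track, paths[key])
    paths["truth.json"] = out / "truth.json"
    truth.to_json(paths["truth.json"])
    paths["scenario.yaml"] = out / "scenario.yaml"
    data = dataclasses.asdict(config)
    data["maf_range"] = list(data["maf_range"])
    with open(paths["scenario.yaml"], "w") as fh:
        import yaml
        yaml.safe_dump(data, fh, sort_keys=True)
    return paths


def read_fixture_bundle(bundle_dir: str | Path) -> dict:
    """Load a written bundle back into in-memory objects."""
    d = Path(bundle_dir)
    tracks = {p.stem: twio.read_bed(p) for p in sorted((d / "tfbs").glob("*.bed"))}
    import yaml
    with open(d / "scenario.yaml") as fh:
        raw = yaml.safe_load(fh)
    raw["maf_range"] = tuple(raw["maf_range"])
    return {
        "config": ScenarioConfig(**raw),
        "genotypes": twio.read_matrix(d / "genotypes.tsv"),
        "methylation": twio.read_matrix(d / "methylation.tsv"),
        "expression": twio.read_matrix(d / "expression.tsv"),
        "covariates": twio.read_matrix(d / "covariates.tsv"),
        "snps": twio.read_bed(d / "snps.bed"),
        "cpgs": twio.read_bed(d / "cpgs.bed"),
        "genes": twio.read_bed(d / "genes.bed"),
        "ppi": twio.read_ppi(d / "ppi.tsv"),
        "tfbs": tracks,
        "truth": GroundTruth.from_json(d / "truth.json"),
    }
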