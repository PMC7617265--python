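"""End-to-end driver: scan -> replicate/meta -> prune -> TFBS -> walk -> pathway.

Runs the whole analysis chain on a fixture bundle (see
:mod:`.synthetic`): the sample set is split into discovery and
replication cohorts, methylation is residualised on covariates, the
meQTL scan is filtered by the replication rule and meta-analysed,
surviving pairs are reduced to sentinel loci by conditional analysis
and clumping, trans loci are screened for TFBS enrichment, candidates
at each trans locus are ranked by the spectral random walk against
randomised backgrounds, and evidence tiers plus the integrated
correlation network are written per locus. Every output is a plain-text
TSV/JSON file and a manifest records config hash, seed, row counts and
content hashes, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import pathway as pw
from . import pruning, tfbs, walk
from .io import PipelineConfig, child_seeds, file_sha256, write_matrix
from .synthetic import CELL_TYPES, read_fixture_bundle

logger = logging.getLogger(__name__)

METH_COVARIATES = ["age", "sex", *CELL_TYPES, "batch_pc1", "batch_pc2"]
EXPR_COVARIATES = ["age", "sex", "batch_pc1", "batch_pc2"]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs remain on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages on the bundle at ``config.bundle_dir``.

    Returns a dict of in-memory stage results; files land under
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(["tfbs", "walk"], child_seeds(config.seed, 2, "pipeline")))
    results: dict = {"config": config}
    manifest: dict = {"config_hash": config.content_hash(), "seed": config.seed,
                      "outputs": {}, "row_counts": {}}

    def _record(name: str, df: pd.DataFrame) -> None:
        path = out / name
        _write_tsv(df, path)
        manifest["outputs"][name] = file_sha256(path)
        manifest["row_counts"][name] = int(len(df))

    stage = "load"
    try:
        bundle = read_fixture_bundle(config.bundle_dir)
        geno = bundle["genotypes"]
        meth = bundle["methylation"]
        expr = bundle["expression"]
        cov = bundle["covariates"]
        samples = list(geno.index)
        half = len(samples) // 2
        cohort_samples = {config.cohorts[0]: samples[:half],
                         config.cohorts[1]: samples[half:]}

        # ------------------------------------------------------------------
        stage = "scan"
        meth_resid = {}
        scans = {}
        for cname, ss in cohort_samples.items():
            mr = assoc.residualize(meth.loc[ss], cov.loc[ss], METH_COVARIATES)
            meth_resid[cname] = mr
            scan = assoc.qtl_scan(geno.loc[ss], mr, threshold=config.significance)
            scans[cname] = assoc.classify_records(
                scan, bundle["snps"], bundle["cpgs"])
        disc, repl = (scans[c] for c in config.cohorts)
        testable = (~disc["untestable"]) & (~repl["untestable"])
        disc_sig = disc[testable & disc["significant"]]
        rep_match = repl.set_index(["source", "target"]).loc[
            pd.MultiIndex.from_frame(disc_sig[["source", "target"]])].reset_index()
        meta = assoc.replication_filter(disc_sig, rep_match,
                                        replication_p=config.replication_p,
                                        combined_threshold=config.significance)
        meta = assoc.classify_records(meta, bundle["snps"], bundle["cpgs"])
        replicated = meta[meta["replicated"]].reset_index(drop=True)
        results["meta"] = meta
        results["replicated"] = replicated
        _record("meqtl_meta.tsv", meta)
        _record("meqtl_replicated.tsv", replicated)

        # ------------------------------------------------------------------
        stage = "prune"
        meth_resid_all = assoc.residualize(meth, cov, METH_COVARIATES)
        surviving = []
        for cpg, grp in replicated.groupby("target"):
            cands = sorted(grp["source"])
            chosen = pruning.conditional_select_snps(
                geno, meth_resid_all[cpg], cands, threshold=config.significance)
            surviving.extend((s, cpg) for s in chosen)
        surv_keys = pd.MultiIndex.from_tuples(surviving, names=["source", "target"])
        cond = replicated.set_index(["source", "target"]).loc[surv_keys].reset_index()
        results["conditional"] = cond

        snp_pos = bundle["snps"].set_index("name")
        cpg_pos = bundle["cpgs"].set_index("name")
        snp_loci, cpg_loci = {}, {}
        for cat, grp in cond.groupby("category"):
            best_s = grp.groupby("source")["log10p"].min()
            mk = pd.DataFrame({
                "name": best_s.index,
                "chrom": snp_pos.loc[best_s.index, "chrom"].to_numpy(),
                "pos": snp_pos.loc[best_s.index, "start"].to_numpy(),
                "log10p": best_s.to_numpy()})
            r2 = pruning.pairwise_r2(geno, list(best_s.index))
            snp_loci[cat] = pruning.clump_markers(
                mk, r2, config.r2_threshold, config.max_dist)
            best_c = grp.groupby("target")["log10p"].min()
            mkc = pd.DataFrame({
                "name": best_c.index,
                "chrom": cpg_pos.loc[best_c.index, "chrom"].to_numpy(),
                "pos": cpg_pos.loc[best_c.index, "start"].to_numpy(),
                "log10p": best_c.to_numpy()})
            r2c = pruning.pairwise_r2(meth, list(best_c.index))
            cpg_loci[cat] = pruning.clump_markers(
                mkc, r2c, config.r2_threshold, config.max_dist)
        pairs, loci = pruning.assign_sentinel_pairs(
            cond, bundle["snps"], bundle["cpgs"], snp_loci, cpg_loci)
        results["sentinel_pairs"] = pairs
        results["loci"] = loci
        _record("sentinel_pairs.tsv", pairs)
        loci_df = pd.DataFrame([{
            "locus_id": l.locus_id, "category": l.category,
            "sentinel_snp": l.sentinel_snp, "sentinel_cpg": l.sentinel_cpg,
            "n_member_snps": len(l.member_snps), "n_cpgs": len(l.cpg_set),
            "chrom": l.chrom, "start": l.start, "end": l.end,
            "cpg_set": ",".join(sorted(l.cpg_set)),
            "member_snps": ",".join(l.member_snps)} for l in loci])
        _record("loci.tsv", loci_df)

        # ------------------------------------------------------------------
        stage = "tfbs"
        binding = tfbs.overlap_cpg_tfbs(bundle["cpgs"], bundle["tfbs"],
                                        window_bp=config.window_bp)
        meth_stats = pd.DataFrame({"mean": meth.mean(axis=0), "sd": meth.std(axis=0)})
        trans_loci = [l for l in loci if l.category == "trans"]
        enrich = tfbs.locus_tfbs_screen(
            trans_loci, binding, fdr=config.fdr, min_set=config.min_trans_cpgs,
            match_covariates=meth_stats,
            match_tolerances={"mean": 0.05, "sd": 0.05},
            n_resamples=config.n_resamples, rng=seeds["tfbs"])
        results["binding"] = binding
        results["tfbs_enrichment"] = enrich
        _record("tfbs_enrichment.tsv", enrich)

        # ------------------------------------------------------------------
        stage = "eqtl"
        expr_resid = assoc.residualize(expr, cov, EXPR_COVARIATES)
        eqtl_pairs = []
        for locus in trans_loci:
            for gene in pruning.locus_genes(locus, bundle["genes"]):
                if gene in expr.columns:
                    eqtl_pairs.append((locus.sentinel_snp, gene))
        eqtl = assoc.qtl_scan(geno, expr_resid, pairs=eqtl_pairs, threshold=1.0) \
            if eqtl_pairs else pd.DataFrame(
                columns=["source", "target", "beta", "se", "p", "log10p", "n"])
        results["eqtl"] = eqtl
        _record("eqtl.tsv", eqtl)

        # ------------------------------------------------------------------
        stage = "walk"
        ppi = walk.ppi_graph(bundle["ppi"])
        expr_medians = (2.0 ** expr).median(axis=0)
        walk_results = {}
        rng = np.random.default_rng(seeds["walk"])
        for locus in trans_loci:
            genes = pruning.locus_genes(locus, bundle["genes"])
            if len(set(locus.cpg_set)) < config.min_trans_cpgs or not genes:
                continue
            res = walk.run_locus_walk(
                ppi, binding, sorted(locus.cpg_set), genes, meth_stats,
                expression_medians=expr_medians, rpkm_min=config.rpkm_min,
                n_eig=config.n_eig, B=config.n_background, rng=rng)
            walk_results[locus.locus_id] = res
            table = res["table"].reset_index()
            table.insert(0, "locus_id", locus.locus_id)
            _record(f"walk_{locus.locus_id.replace(':', '_')}.tsv", table)
        results["walk"] = walk_results

        # ------------------------------------------------------------------
        stage = "pathway"
        tier_rows = []
        for locus in trans_loci:
            res = walk_results.get(locus.locus_id)
            if res is None:
                continue
            enriched_tracks = set()
            if not enrich.empty:
                mine = enrich[(enrich["locus_id"] == locus.locus_id)
                              & enrich["significant"]
                              & (enrich["odds_ratio"] > 1)]
                enriched_tracks = set(mine["track"])
            eqtl_hits = set()
            if not eqtl.empty:
                mine = eqtl[(eqtl["source"] == locus.sentinel_snp)
                            & (eqtl["p"] < config.eqtl_nominal_p)]
                eqtl_hits = set(mine["target"])
            flags = pd.DataFrame({
                "tf_enriched": [c in enriched_tracks for c in res["candidates"]],
                "cis_eqtl": [c in eqtl_hits for c in res["candidates"]],
                "rw_selected": [c in set(res["selected"])
                                for c in res["candidates"]],
            }, index=pd.Index(res["candidates"], name="candidate"))
            tiers = pw.assign_evidence_tiers(flags)
            tiers = tiers.reset_index()
            tiers.insert(0, "locus_id", locus.locus_id)
            tier_rows.append(tiers)

            if res["selected"]:
                w, w_star = pw.compute_node_weights(
                    res["spectrum"], res["S"], res["selected"])
                q, paths = pw.extract_min_weight_paths(
                    res["graph"], w_star, res["S"], res["selected"])
                sub = pw.candidate_pathway_subgraph(
                    res["graph"], res["candidates"], q, res["S"])
                cohorts = {}
                for cname, ss in cohort_samples.items():
                    cohorts[cname] = {"genotype": geno.loc[ss],
                                      "expression": expr_resid.loc[ss],
                                      "methylation": meth_resid[cname]}
                cis_map = {cid: [locus.sentinel_snp] for cid in res["S"]}
                edges = sorted((min(u, v), max(u, v)) for u, v in sub.edges)
                net = pw.integrated_correlation_network(
                    edges, cohorts, cis_qtl=cis_map, fdr=config.fdr)
                bold = {(r["u"], r["v"]): (r["q"], bool(r["bold"]))
                        for _, r in net.iterrows()} if not net.empty else {}
                graph_doc = {
                    "locus_id": locus.locus_id,
                    "nodes": [{"id": n,
                               "kind": res["graph"].nodes[n].get("kind", "protein"),
                               "w": float(w[n]), "w_star": float(w_star[n]),
                               "in_Q": n in q}
                              for n in sorted(sub.nodes)],
                    "edges": [{"u": u, "v": v,
                               "q": bold.get((u, v), (None, False))[0],
                               "bold": bold.get((u, v), (None, False))[1]}
                              for u, v in edges],
                    "paths": {f"{s}->{c}": p for (s, c), p in sorted(paths.items())},
                }
                gp = out / f"pathway_{locus.locus_id.replace(':', '_')}.json"
                with open(gp, "w") as fh:
                    json.dump(graph_doc, fh, indent=1, sort_keys=True)
                manifest["outputs"][gp.name] = file_sha256(gp)
                if not net.empty:
                    net.insert(0, "locus_id", locus.locus_id)
                    _record(f"network_{locus.locus_id.replace(':', '_')}.tsv", net)
        tiers_all = pd.concat(tier_rows, ignore_index=True) if tier_rows \
            else pd.DataFrame(columns=["locus_id", "candidate", "tf_enriched",
                                       "cis_eqtl", "rw_selected", "tier"])
        results["tiers"] = tiers_all
        _record("evidence_tiers.tsv", tiers_all)

        # ------------------------------------------------------------------
        stage = "iqtl"
        iqtl_pairs = list(zip(replicated["source"], replicated["target"]))
        if iqtl_pairs:
            per_cohort = []
            for cname, ss in cohort_samples.items():
                it = assoc.interaction_scan(
                    geno.loc[ss], meth.loc[ss], cov.loc[ss, "CD8T"],
                    covariates=cov.loc[ss, ["age", "sex"]], pairs=iqtl_pairs)
                it["cohort"] = cname
                per_cohort.append(it)
            iqtl = pd.concat(per_cohort, ignore_index=True)
        else:
            iqtl = pd.DataFrame(columns=["source", "target", "beta", "se", "p",
                                         "log10p", "n", "untestable", "cohort"])
        results["iqtl"] = iqtl
        _record("iqtl.tsv", iqtl)

    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc

    import transwalker
    manifest["versions"] = {
        "transwalker": transwalker.__version__,
        "numpy": np.__version__, "pandas": pd.__version__,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    results["manifest"] = manifest
    return results
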