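"""Conditional analysis and LD clumping to independent sentinel loci.

Two-stage reduction of the redundant SNP-CpG association set:

1. Per CpG, iterative conditional analysis — repeatedly select the most
   strongly associated SNP and re-test the remaining candidates with the
   selected SNPs as additional regressors, keeping only those still
   genome-wide significant.
2. Greedy clumping — repeatedly take the lowest-p unassigned marker as a
   locus head and absorb unassigned markers with R^2 > 0.2 within 1 Mb
   of the head, applied to SNPs and to CpGs within each distance
   category (cis, long-range cis, trans) separately.

Sentinel SNP-CpG pairs are the lowest-p association between a SNP locus
and a CpG locus; trans SNP loci additionally carry the full set S of
their sentinel trans-CpGs for the network modules downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import GENOME_WIDE_P, _p_from_log10, _t_log10p

MAX_CONDITIONAL_ITER = 50


@dataclass
class SentinelLocus:
    """A pruned, independent genetic locus."""

    locus_id: str
    category: str
    sentinel_snp: str
    member_snps: list[str]
    sentinel_cpg: str
    cpg_set: set[str] = field(default_factory=set)
    chrom: str = ""
    start: int = 0
    end: int = 0
    min_log10p: float = 0.0


# ---------------------------------------------------------------------------
# Conditional analysis

def conditional_select_snps(
    dosages: pd.DataFrame,
    methylation: pd.Series,
    candidate_snps: list[str],
    threshold: float = GENOME_WIDE_P,
    max_iter: int = MAX_CONDITIONAL_ITER,
) -> list[str]:
    """Forward conditional selection of independently associated SNPs.

    At each round every remaining candidate is tested with all
    previously selected SNPs included as covariates; candidates still
    below ``threshold`` survive, the lowest-p one (ties broken by
    lexicographic id) is selected, and the round repeats until no
    candidate remains significant. Returns the ordered selection.
    """
    y = methylation.loc[dosages.index].to_numpy(float)
    n = len(y)
    selected: list[str] = []
    remaining = sorted(candidate_snps)
    log10_thr = np.log10(threshold)
    for _ in range(max_iter):
        if not remaining:
            return selected
        base = np.column_stack(
            [np.ones(n)] + [dosages[s].to_numpy(float) for s in selected])
        log10ps = []
        for cand in remaining:
            x = np.column_stack([base, dosages[cand].to_numpy(float)])
            if np.linalg.matrix_rank(x) < x.shape[1] or n <= x.shape[1]:
                log10ps.append(0.0)  # collinear with selected: never significant
                continue
            coef, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ coef
            dfree = n - x.shape[1]
            sigma2 = float(resid @ resid) / dfree
            xtx_inv = np.linalg.inv(x.T @ x)
            se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
            t = coef[-1] / se if se > 0 else 0.0
            log10ps.append(float(_t_log10p(np.array([t]), dfree)[0]))
        log10ps = np.asarray(log10ps)
        ok = log10ps < log10_thr
        if not ok.any():
            return selected
        # lowest p wins; remaining is sorted, argmin keeps the lexicographic tie-break
        best = int(np.argmin(np.where(ok, log10ps, np.inf)))
        selected.append(remaining.pop(best))
    raise RuntimeError(
        f"conditional analysis did not terminate within {max_iter} iterations")


# ---------------------------------------------------------------------------
# Pairwise correlation

def pairwise_r2(values: pd.DataFrame, markers: list[str] | None = None) -> pd.DataFrame:
    """Squared Pearson correlation between marker columns (LD proxy)."""
    cols = list(markers) if markers is not None else list(values.columns)
    sub = values[cols].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(sub, rowvar=False)
    r2 = np.nan_to_num(r, nan=0.0) ** 2
    if len(cols) == 1:
        r2 = np.array([[1.0]])
    return pd.DataFrame(r2, index=cols, columns=cols)


# ---------------------------------------------------------------------------
# Greedy clumping

def clump_markers(
    markers: pd.DataFrame,
    r2: pd.DataFrame,
    r2_threshold: float = 0.2,
    max_dist: int = 1_000_000,
) -> list[dict]:
    """Greedy partition of markers into loci.

    ``markers`` needs columns ``name, chrom, pos, log10p``. Repeatedly
    the lowest-p unassigned marker becomes a head and absorbs unassigned
    markers with R^2 > ``r2_threshold`` and head-to-member distance
    < ``max_dist`` on the same chromosome. Equal p ties break on
    lexicographic id, so the partition is independent of input order.
    """
    if markers["name"].duplicated().any():
        dups = markers.loc[markers["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate marker ids: {dups}")
    df = markers.sort_values(["log10p", "name"], kind="mergesort").reset_index(drop=True)
    unassigned = dict(zip(df["name"], zip(df["chrom"], df["pos"].astype(int))))
    order = list(df["name"])
    loci: list[dict] = []
    assigned: set[str] = set()
    for head in order:
        if head in assigned:
            continue
        hchrom, hpos = unassigned[head]
        members = [head]
        assigned.add(head)
        for other in order:
            if other in assigned:
                continue
            ochrom, opos = unassigned[other]
            if ochrom != hchrom or abs(opos - hpos) >= max_dist:
                continue
            if float(r2.loc[head, other]) > r2_threshold:
                members.append(other)
                assigned.add(other)
        loci.append({"head": head, "members": members, "chrom": hchrom,
                     "head_pos": hpos})
    return loci


# ---------------------------------------------------------------------------
# Sentinel pair assignment

def _trim_span(positions: list[int], sentinel_pos: int, max_span: int = 1_000_000
               ) -> tuple[int, int]:
    lo = min(positions + [sentinel_pos - max_span // 2])
    hi = max(positions + [sentinel_pos + max_span // 2])
    if hi - lo > max_span:
        lo = sentinel_pos - max_span // 2
        hi = sentinel_pos + max_span // 2
    return max(0, lo), hi


def assign_sentinel_pairs(
    records: pd.DataFrame,
    snp_anno: pd.DataFrame,
    cpg_anno: pd.DataFrame,
    snp_loci: dict[str, list[dict]],
    cpg_loci: dict[str, list[dict]],
) -> tuple[pd.DataFrame, list[SentinelLocus]]:
    """Pick the lowest-p pair for every (SNP locus, CpG locus) association.

    ``snp_loci``/``cpg_loci`` map a category to its clumping output.
    Returns the sentinel-pair table and the per-SNP-locus summaries;
    trans loci carry the full set S of their sentinel CpGs and a genomic
    span trimmed to at most 1 Mb around the sentinel SNP.
    """
    spos = snp_anno.set_index("name")
    cpos = cpg_anno.set_index("name")
    pair_rows = []
    loci_out: list[SentinelLocus] = []
    for category in ("cis", "long_range_cis", "trans"):
        sl = snp_loci.get(category, [])
        cl = cpg_loci.get(category, [])
        snp2locus = {m: i for i, loc in enumerate(sl) for m in loc["members"]}
        cpg2locus = {m: i for i, loc in enumerate(cl) for m in loc["members"]}
        recs = records[records["category"] == category]
        recs = recs[recs["source"].isin(snp2locus) & recs["target"].isin(cpg2locus)]
        if recs.empty:
            continue
        recs = recs.assign(
            snp_locus=[snp2locus[s] for s in recs["source"]],
            cpg_locus=[cpg2locus[c] for c in recs["target"]],
        )
        best = (recs.sort_values(["log10p", "source", "target"], kind="mergesort")
                .groupby(["snp_locus", "cpg_locus"], sort=True).head(1))
        for _, row in best.iterrows():
            pair_rows.append({
                "category": category,
                "snp_locus": f"{category}:{int(row['snp_locus'])}",
                "cpg_locus": f"{category}:{int(row['cpg_locus'])}",
                "sentinel_snp": row["source"],
                "sentinel_cpg": row["target"],
                "beta": row["beta"], "se": row["se"],
                "p": row["p"], "log10p": row["log10p"],
            })
        for i, loc in enumerate(sl):
            mine = best[best["snp_locus"] == i]
            if mine.empty:
                continue
            top = mine.sort_values(["log10p", "source"], kind="mergesort").iloc[0]
            sentinel = str(top["source"])
            sent_pos = int(spos.loc[sentinel, "start"])
            member_pos = [int(spos.loc[m, "start"]) for m in loc["members"]]
            lo, hi = _trim_span(member_pos, sent_pos)
            loci_out.append(SentinelLocus(
                locus_id=f"{category}:{i}",
                category=category,
                sentinel_snp=sentinel,
                member_snps=list(loc["members"]),
                sentinel_cpg=str(top["target"]),
                cpg_set=set(mine["target"]),
                chrom=str(spos.loc[sentinel, "chrom"]),
                start=lo, end=hi,
                min_log10p=float(top["log10p"]),
            ))
    pairs = pd.DataFrame(pair_rows)
    return pairs, loci_out


def locus_genes(locus: SentinelLocus, gene_anno: pd.DataFrame) -> list[str]:
    """Genes whose annotated interval overlaps the (<= 1 Mb) locus span."""
    sub = gene_anno[(gene_anno["chrom"] == locus.chrom)
                    & (gene_anno["start"] < locus.end)
                    & (gene_anno["end"] > locus.start)]
    return sorted(sub["name"])
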