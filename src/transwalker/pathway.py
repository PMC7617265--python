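"""Candidate pathways, integrated correlation edges and evidence tiers.

From the random-walk output this module derives per-node visit weights
w_i (diffusion from the trans-CpG set S into node i plus diffusion from
i into the significant candidates C*), inverts them to
w*_i = max(w) - w_i so high-scoring nodes are cheap to traverse, and
extracts minimal-weight paths from every CpG in S to every candidate in
C*; path nodes form the set Q and the candidate pathway is the locus
subgraph induced by C ∪ Q ∪ S. Data-driven correlation edges
(expression/methylation residualised on known cis-QTLs, fixed-effect
Fisher-z meta-analysis across cohorts, BH FDR) are overlaid as bold
edges, and candidates receive the evidence tiers:

    i   cis TF, TFBS-enriched, with a cis-eQTL for the sentinel SNP
    ii  cis TF, TFBS-enriched, without an eQTL
    iii random-walk hit (empirical p < 0.05) with a cis-eQTL
    iv  random-walk hit without a cis-eQTL
    v   singular cis-eQTL with no other evidence
"""

from __future__ import annotations

import heapq
import logging
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .walk import TransitionSpectrum, aggregated_matrix

logger = logging.getLogger(__name__)

TIER_ORDER = ("i", "ii", "iii", "iv", "v")


# ---------------------------------------------------------------------------
# Node weights

def compute_node_weights(
    spectrum: TransitionSpectrum,
    S: Sequence[str],
    c_star: Sequence[str],
) -> tuple[pd.Series, pd.Series]:
    """w_i = Σ_{s∈S} M_si + Σ_{c∈C*} M_ic and w*_i = max(w) - w_i."""
    if not c_star:
        raise ValueError("C* is empty: no pathway to extract")
    nodes = spectrum.nodes
    m_sv = aggregated_matrix(spectrum, list(S), nodes)        # S x V
    m_vc = aggregated_matrix(spectrum, nodes, list(c_star))   # V x C*
    w = pd.Series(m_sv.sum(axis=0).to_numpy() + m_vc.sum(axis=1).to_numpy(),
                  index=nodes)
    w_star = w.max() - w
    return w, w_star


# ---------------------------------------------------------------------------
# Minimal-weight paths

def _dijkstra(
    g: nx.Graph,
    source: str,
    edge_weight: Mapping[tuple[str, str], float],
) -> tuple[dict[str, tuple[float, int]], dict[str, str]]:
    """Dijkstra on (total weight, hop count) with lexicographic
    predecessor tie-break, so paths are unique and order-independent."""
    dist: dict[str, tuple[float, int]] = {source: (0.0, 0)}
    pred: dict[str, str] = {}
    heap: list[tuple[float, int, str]] = [(0.0, 0, source)]
    done: set[str] = set()
    while heap:
        dw, dh, u = heapq.heappop(heap)
        if u in done or (dw, dh) > dist[u]:
            continue
        done.add(u)
        for v in g.neighbors(u):
            if v in done:
                continue
            ew = edge_weight[(u, v)]
            nd = (dw + ew, dh + 1)
            if v not in dist or nd < dist[v]:
                dist[v] = nd
                pred[v] = u
                heapq.heappush(heap, (nd[0], nd[1], v))
            elif nd == dist[v] and u < pred.get(v, u):
                pred[v] = u
    return dist, pred


def extract_min_weight_paths(
    g: nx.Graph,
    w_star: pd.Series,
    S: Sequence[str],
    c_star: Sequence[str],
) -> tuple[set[str], dict[tuple[str, str], list[str]]]:
    """Minimal-total-node-weight path per (s, c) pair; Q = path nodes.

    Node weights become edge weights (w*_u + w*_v)/2 (each endpoint
    contributes half), which preserves the ordering of interior path
    totals; with all weights equal the hop-count tie-break selects the
    shortest path. Unreachable pairs are skipped with a log entry.
    """
    ew = {}
    for u, v in g.edges:
        w = (float(w_star[u]) + float(w_star[v])) / 2.0
        ew[(u, v)] = w
        ew[(v, u)] = w
    paths: dict[tuple[str, str], list[str]] = {}
    q: set[str] = set()
    for s in sorted(set(S)):
        if s not in g:
            continue
        dist, pred = _dijkstra(g, s, ew)
        for c in sorted(set(c_star)):
            if c not in dist:
                logger.warning("no path from %s to %s; pair skipped", s, c)
                continue
            node, path = c, [c]
            while node != s:
                node = pred[node]
                path.append(node)
            path.reverse()
            paths[(s, c)] = path
            q.update(path)
    return q, paths


def candidate_pathway_subgraph(
    g: nx.Graph,
    candidates: Sequence[str],
    q: Iterable[str],
    S: Sequence[str],
) -> nx.Graph:
    """Subgraph of the locus graph induced by C ∪ Q ∪ S."""
    keep = (set(candidates) | set(q) | set(S)) & set(g.nodes)
    return g.subgraph(keep).copy()


# ---------------------------------------------------------------------------
# Integrated correlation network

def _residual_on_snps(values: pd.Series, genotype: pd.DataFrame,
                      snps: Sequence[str]) -> pd.Series:
    present = [s for s in snps if s in genotype.columns]
    if not present:
        return values - values.mean()
    x = np.column_stack([np.ones(len(values)),
                         genotype.loc[values.index, present].to_numpy(float)])
    coef, *_ = np.linalg.lstsq(x, values.to_numpy(float), rcond=None)
    return pd.Series(values.to_numpy(float) - x @ coef, index=values.index)


def _lookup(var: str, cohort: Mapping[str, pd.DataFrame]) -> pd.Series | None:
    for key in ("methylation", "expression", "genotype"):
        frame = cohort.get(key)
        if frame is not None and var in frame.columns:
            return frame[var]
    return None


def integrated_correlation_network(
    edges: Sequence[tuple[str, str]],
    cohorts: Mapping[str, Mapping[str, pd.DataFrame]],
    cis_qtl: Mapping[str, Sequence[str]] | None = None,
    fdr: float = 0.05,
    min_n: int = 30,
) -> pd.DataFrame:
    """Test candidate edges for residual correlation across cohorts.

    Per cohort each expression/methylation variable is residualised on
    its known cis-QTL SNPs (removing correlation driven by shared
    genetic control in cis), Pearson correlations are combined by
    fixed-effect meta-analysis on the Fisher z scale, and BH-adjusted
    q-values flag significant ("bold") edges at ``fdr``.
    """
    cis_qtl = cis_qtl or {}
    rows = []
    for u, v in edges:
        zs, ws, ns = [], [], 0
        skipped = False
        for cname, cohort in cohorts.items():
            xu, xv = _lookup(u, cohort), _lookup(v, cohort)
            if xu is None or xv is None:
                logger.info("edge (%s, %s): variable missing in cohort %s",
                            u, v, cname)
                skipped = True
                break
            common = xu.index.intersection(xv.index)
            if len(common) < min_n:
                logger.warning("cohort %s has %d < %d samples for edge (%s, %s)",
                               cname, len(common), min_n, u, v)
            geno = cohort.get("genotype", pd.DataFrame(index=common))
            ru = _residual_on_snps(xu.loc[common], geno, cis_qtl.get(u, []))
            rv = _residual_on_snps(xv.loc[common], geno, cis_qtl.get(v, []))
            if ru.std() == 0 or rv.std() == 0:
                skipped = True
                break
            r = float(np.corrcoef(ru, rv)[0, 1])
            r = np.clip(r, -0.999999, 0.999999)
            n = len(common)
            if n <= 3:
                skipped = True
                break
            zs.append(np.arctanh(r))
            ws.append(n - 3.0)
            ns += n
        if skipped or not zs:
            continue
        z_c = float(np.dot(ws, zs) / np.sum(ws))
        se_c = 1.0 / np.sqrt(np.sum(ws))
        zstat = z_c / se_c
        p = 2.0 * float(stats.norm.sf(abs(zstat)))
        rows.append({"u": u, "v": v, "r": float(np.tanh(z_c)), "z": zstat,
                     "p": p, "n": ns})
    out = pd.DataFrame(rows)
    if out.empty:
        out["q"] = []
        out["bold"] = []
        return out
    _, q, _, _ = multipletests(out["p"], method="fdr_bh")
    out["q"] = q
    out["bold"] = out["q"] < fdr
    return out


# ---------------------------------------------------------------------------
# Evidence tiers

def tier_of(tf_enriched: bool, cis_eqtl: bool, rw_selected: bool) -> str | None:
    """Highest applicable evidence tier for one candidate's flag tuple."""
    if tf_enriched and cis_eqtl:
        return "i"
    if tf_enriched:
        return "ii"
    if rw_selected and cis_eqtl:
        return "iii"
    if rw_selected:
        return "iv"
    if cis_eqtl:
        return "v"
    return None


def assign_evidence_tiers(flags: pd.DataFrame) -> pd.DataFrame:
    """Tier every candidate from its evidence flags.

    ``flags`` is indexed by candidate gene id with boolean columns
    ``tf_enriched`` (the gene's TFBS track is enriched in the locus'
    trans-CpG set), ``cis_eqtl`` (sentinel-SNP eQTL at nominal p < 0.01)
    and ``rw_selected`` (member of C*). Output is sorted best tier first.
    """
    out = flags.copy()
    out["tier"] = [tier_of(bool(r["tf_enriched"]), bool(r["cis_eqtl"]),
                           bool(r["rw_selected"]))
                   for _, r in flags.iterrows()]
    rank = {t: i for i, t in enumerate(TIER_ORDER)}
    out["tier_rank"] = [rank.get(t, len(TIER_ORDER)) for t in out["tier"]]
    out = out.sort_index().sort_values("tier_rank", kind="mergesort")
    return out.drop(columns="tier_rank")
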