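"""Spectral random-walk prioritisation of candidate genes at trans loci.

The locus graph joins the expressed-protein PPI network (largest
connected component) with the locus' trans-CpG set S, each CpG attached
to the DNA-binding proteins whose binding sites cover it. On this graph
the symmetric transition matrix

    t_ij = a_ij / sqrt(d(i) d(j))

has top eigenvalue 1 with eigenvector proportional to sqrt(d) (the
stationary component). Summing walk probabilities over all path lengths
with the stationary component removed gives the aggregated transition
matrix

    M = Σ_{t>=0} (T - ψ0 ψ0ᵀ)^t  restricted off the stationary component
      = Σ_{i>=1} λ_i / (1 - λ_i) · ψ_i ψ_iᵀ,

equal to the closed form (I - T + ψ0 ψ0ᵀ)^{-1} - I off the diagonal's
identity contribution; the spectral form is truncated to the leading
``n_eig`` eigenpairs for large graphs. A candidate gene c at the locus
scores p_c = |S|^{-1} Σ_{s∈S} M_sc, and significance is assessed against
B randomised graphs built from CpG sets matched on methylation mean and
standard deviation, using the empirical exceedance of each score over
the per-replicate maximum candidate score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

logger = logging.getLogger(__name__)

DEFAULT_N_EIG = 500
DEFAULT_B = 100
DENSE_LIMIT = 500
_UNITY_TOL = 1e-10


# ---------------------------------------------------------------------------
# Graph construction

def ppi_graph(edges: pd.DataFrame) -> nx.Graph:
    """Simple undirected PPI graph from an edge-list DataFrame."""
    g = nx.Graph()
    for a, b in zip(edges["protein_a"], edges["protein_b"]):
        if a != b:
            g.add_edge(a, b)
    return g


def filter_expressed(
    g: nx.Graph,
    expression_medians: pd.Series | None,
    rpkm_min: float = 0.1,
) -> nx.Graph:
    """Restrict to expressed proteins, then take the largest connected component."""
    if expression_medians is not None:
        keep = {n for n in g.nodes
                if n in expression_medians.index
                and expression_medians[n] > rpkm_min}
        g = g.subgraph(keep).copy()
    if g.number_of_nodes() == 0:
        raise ValueError("no proteins remain after the expression filter")
    largest = max(nx.connected_components(g), key=lambda cc: (len(cc), sorted(cc)[0]))
    return g.subgraph(largest).copy()


def build_locus_graph(
    ppi: nx.Graph,
    binding: pd.DataFrame,
    S: Iterable[str],
    locus_gene_list: Sequence[str],
    expression_medians: pd.Series | None = None,
    rpkm_min: float = 0.1,
    warn_dropped: bool = True,
) -> tuple[nx.Graph, list[str], list[str]]:
    """Locus graph G = (V_P + S, E_P + E_D(S)) and candidates C.

    CpGs in S whose binding proteins are absent from the filtered PPI
    are dropped with a warning (they would disconnect the graph).
    Returns ``(graph, candidates, dropped_cpgs)``.
    """
    base = filter_expressed(ppi, expression_medians, rpkm_min)
    g = base.copy()
    nx.set_node_attributes(g, "protein", "kind")
    dropped: list[str] = []
    attached = 0
    for s in sorted(set(S)):
        binders = []
        if s in binding.index:
            binders = [p for p in binding.columns
                       if binding.loc[s, p] and p in base]
        if not binders:
            dropped.append(s)
            continue
        g.add_node(s, kind="cpg")
        for p in binders:
            g.add_edge(s, p)
        attached += 1
    if dropped:
        logger.log(logging.WARNING if warn_dropped else logging.DEBUG,
                   "dropped %d CpG(s) with no binding protein in the "
                   "network: %s", len(dropped), dropped[:5])
    if attached == 0:
        raise ValueError("every CpG in S lacks a binding protein in the network")
    candidates = sorted(set(locus_gene_list) & set(base.nodes))
    if not candidates:
        raise ValueError("no candidate in network: locus genes absent from "
                         "the filtered PPI component")
    return g, candidates, dropped


# ---------------------------------------------------------------------------
# Spectrum

@dataclass
class TransitionSpectrum:
    """Leading eigenpairs of the symmetric transition matrix."""

    nodes: list[str]
    eigvals: np.ndarray      # descending; eigvals[0] == 1
    eigvecs: np.ndarray      # columns are orthonormal eigenvectors
    degrees: np.ndarray

    @property
    def index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}


def transition_matrix(g: nx.Graph, nodes: list[str]) -> tuple[sp.csr_matrix, np.ndarray]:
    a = nx.to_scipy_sparse_array(g, nodelist=nodes, format="csr", dtype=float)
    d = np.asarray(a.sum(axis=1)).ravel()
    if np.any(d == 0):
        raise ValueError("isolated node in locus graph")
    inv_sqrt = 1.0 / np.sqrt(d)
    t = sp.diags(inv_sqrt) @ a @ sp.diags(inv_sqrt)
    return sp.csr_matrix(t), d


def transition_spectrum(g: nx.Graph, n_eig: int = DEFAULT_N_EIG) -> TransitionSpectrum:
    """Top eigenpairs of T = D^{-1/2} A D^{-1/2} (by algebraic value).

    Verifies that the graph is connected, that λ0 = 1 to 1e-8 and that
    ψ0 matches sqrt(d)/||sqrt(d)|| up to sign to 1e-6. Graphs below 500
    nodes use the dense solver; larger graphs use the iterative sparse
    solver with a fixed start vector for determinism.
    """
    if n_eig < 2:
        raise ValueError("n_eig must be >= 2")
    if not nx.is_connected(g):
        raise ValueError("locus graph is disconnected")
    nodes = sorted(g.nodes)
    t, d = transition_matrix(g, nodes)
    nv = len(nodes)
    k = min(n_eig, nv)
    if nv < DENSE_LIMIT:
        vals, vecs = scipy.linalg.eigh(t.toarray())
        vals, vecs = vals[::-1][:k], vecs[:, ::-1][:, :k]
    else:
        k = min(k, nv - 1)
        v0 = np.ones(nv) / np.sqrt(nv)
        try:
            vals, vecs = spla.eigsh(t, k=k, which="LA", v0=v0)
        except spla.ArpackNoConvergence as exc:
            raise RuntimeError(
                f"eigensolver failed to converge: {len(exc.eigenvalues)}/{k} "
                f"eigenpairs found on a {nv}-node graph") from exc
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
    if abs(vals[0] - 1.0) > 1e-8:
        raise ValueError(f"top eigenvalue {vals[0]!r} != 1; graph not connected?")
    psi0_ref = np.sqrt(d)
    psi0_ref /= np.linalg.norm(psi0_ref)
    psi0 = vecs[:, 0]
    if psi0 @ psi0_ref < 0:
        vecs[:, 0] = -psi0
        psi0 = vecs[:, 0]
    if np.max(np.abs(psi0 - psi0_ref)) > 1e-6:
        raise ValueError("stationary eigenvector does not match sqrt(degree)")
    return TransitionSpectrum(nodes=nodes, eigvals=vals, eigvecs=vecs, degrees=d)


# ---------------------------------------------------------------------------
# Aggregated transition matrix and scores

def aggregated_matrix(
    spectrum: TransitionSpectrum,
    rows: Sequence[str],
    cols: Sequence[str],
) -> pd.DataFrame:
    """Submatrix of M = Σ_{i>=1} λ_i/(1-λ_i) ψ_i ψ_iᵀ on rows x cols.

    The stationary eigenpair is excluded; any further eigenvalue at 1
    (within 1e-10) indicates a disconnected graph and raises.
    """
    lam = spectrum.eigvals[1:]
    if lam.size and np.any(lam >= 1.0 - _UNITY_TOL):
        raise ValueError("eigenvalue 1 with multiplicity > 1: disconnected graph")
    idx = spectrum.index
    missing = [r for r in rows if r not in idx] + [c for c in cols if c not in idx]
    if missing:
        raise KeyError(f"nodes absent from spectrum: {missing[:5]}")
    ri = [idx[r] for r in rows]
    ci = [idx[c] for c in cols]
    coef = lam / (1.0 - lam)
    vr = spectrum.eigvecs[ri, 1:]
    vc = spectrum.eigvecs[ci, 1:]
    m = (vr * coef) @ vc.T
    return pd.DataFrame(m, index=list(rows), columns=list(cols))


def score_candidates(m_sc: pd.DataFrame) -> pd.Series:
    """p_c = |S|^{-1} Σ_s M_sc: mean aggregated transition per candidate."""
    if m_sc.empty:
        raise ValueError("empty S x C matrix")
    return m_sc.mean(axis=0)


# ---------------------------------------------------------------------------
# Randomised backgrounds

def _bin_labels(meth_stats: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Matching bins: methylation mean in width-0.05 bins, sd in pool
    deciles. Returns (joint bin, mean-only bin) labels."""
    mean_bin = np.floor(meth_stats["mean"].to_numpy(float) / 0.05).astype(int)
    sd = meth_stats["sd"].to_numpy(float)
    deciles = np.quantile(sd, np.linspace(0, 1, 11)[1:-1])
    sd_bin = np.searchsorted(deciles, sd, side="right")
    joint = pd.Series([f"{m}|{s}" for m, s in zip(mean_bin, sd_bin)],
                      index=meth_stats.index)
    mean_only = pd.Series([f"{m}" for m in mean_bin], index=meth_stats.index)
    return joint, mean_only


def sample_matched_cpg_sets(
    S: Sequence[str],
    meth_stats: pd.DataFrame,
    n_sets: int,
    rng: np.random.Generator,
) -> list[list[str]]:
    """Draw CpG sets of size |S| matched on methylation (mean, sd) bins.

    ``meth_stats`` indexes every background-eligible CpG with columns
    ``mean`` and ``sd``; members of S are excluded from the pool. A
    member whose joint (mean, sd) bin holds no pool candidates falls
    back to matching on the mean bin alone (small pools cannot always
    support the joint match); with the mean bin also empty, raises with
    a bin-occupancy report.
    """
    joint, mean_only = _bin_labels(meth_stats)
    pool_mask = ~meth_stats.index.isin(S)

    def _occupants(bins: pd.Series) -> dict[str, np.ndarray]:
        return {b: meth_stats.index[pool_mask & (bins == b).to_numpy()].to_numpy()
                for b in bins.unique()}

    by_joint = _occupants(joint)
    by_mean = _occupants(mean_only)
    by_bin: dict[str, np.ndarray] = {}
    member_bins = []
    for s in S:
        if s not in joint.index:
            raise KeyError(f"CpG {s!r} missing from methylation summary")
        b = joint[s]
        if len(by_joint.get(b, ())) > 0:
            by_bin[b] = by_joint[b]
        else:
            b = f"mean:{mean_only[s]}"
            cand = by_mean.get(mean_only[s], np.array([], dtype=object))
            if len(cand) == 0:
                occupancy = {k: len(v) for k, v in sorted(by_mean.items())}
                raise ValueError(
                    f"no matched pool CpGs (even by mean bin) for {s!r}; "
                    f"mean-bin occupancy: {occupancy}")
            by_bin[b] = cand
        member_bins.append(b)
    sets: list[list[str]] = []
    for _ in range(n_sets):
        used: set[str] = set()
        drawn: list[str] = []
        for b in member_bins:
            cand = [c for c in by_bin[b] if c not in used]
            if not cand:  # bin exhausted inside this draw: sample with the
                cand = list(by_bin[b])  # bin's full pool as a fallback
            pick = cand[int(rng.integers(len(cand)))]
            used.add(pick)
            drawn.append(pick)
        sets.append(drawn)
    return sets


def randomized_background(
    ppi_component: nx.Graph,
    binding: pd.DataFrame,
    S: Sequence[str],
    candidates: Sequence[str],
    meth_stats: pd.DataFrame,
    B: int = DEFAULT_B,
    n_eig: int = DEFAULT_N_EIG,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Candidate scores on B randomised locus graphs (rows) x C (columns).

    Each replicate resamples |S| CpGs matched on methylation mean/sd,
    attaches them to the same PPI component, and recomputes the spectral
    scores. Replicates where every resampled CpG lacks a binding protein
    score zero for all candidates.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sets = sample_matched_cpg_sets(list(S), meth_stats, B, rng)
    out = np.zeros((B, len(candidates)))
    for b, s_b in enumerate(sets):
        try:
            g_b, _, _ = build_locus_graph(ppi_component, binding, s_b,
                                          list(candidates), warn_dropped=False)
        except ValueError:
            continue  # no attachable CpGs: null replicate scores stay 0
        spec = transition_spectrum(g_b, n_eig=n_eig)
        kept = [s for s in s_b if s in spec.index]
        m = aggregated_matrix(spec, kept, list(candidates))
        out[b] = score_candidates(m).to_numpy()
    return pd.DataFrame(out, columns=list(candidates))


def empirical_candidate_pvalues(
    scores: pd.Series,
    background: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Empirical p per candidate against the background maxima.

    p_c = (1 + #{b : max_{c'} p^b_{c'} >= p_c}) / (B + 1); the selected
    set C* holds candidates with p < ``alpha``.
    """
    bmax = background.max(axis=1).to_numpy(float)
    B = len(bmax)
    rows = []
    for c, s in scores.items():
        p = (1.0 + int((bmax >= s).sum())) / (B + 1.0)
        rows.append({"candidate": c, "score": float(s), "empirical_p": p,
                     "selected": p < alpha})
    return pd.DataFrame(rows).set_index("candidate")


# ---------------------------------------------------------------------------
# One-call convenience

def run_locus_walk(
    ppi: nx.Graph,
    binding: pd.DataFrame,
    S: Sequence[str],
    locus_gene_list: Sequence[str],
    meth_stats: pd.DataFrame,
    expression_medians: pd.Series | None = None,
    rpkm_min: float = 0.1,
    n_eig: int = DEFAULT_N_EIG,
    B: int = DEFAULT_B,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Full walk for one locus: graph, scores, backgrounds, C*."""
    g, candidates, dropped = build_locus_graph(
        ppi, binding, S, locus_gene_list, expression_medians, rpkm_min)
    spec = transition_spectrum(g, n_eig=n_eig)
    kept_S = [s for s in S if s in spec.index]
    m = aggregated_matrix(spec, kept_S, candidates)
    scores = score_candidates(m)
    base = filter_expressed(ppi, expression_medians, rpkm_min)
    bg = randomized_background(base, binding, kept_S, candidates, meth_stats,
                               B=B, n_eig=n_eig, rng=rng)
    table = empirical_candidate_pvalues(scores, bg)
    return {"graph": g, "spectrum": spec, "candidates": candidates,
            "S": kept_S, "dropped": dropped, "M": m, "scores": scores,
            "background": bg, "table": table,
            "selected": sorted(table.index[table["selected"]])}
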