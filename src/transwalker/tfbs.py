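"""TFBS overlap, Fisher enrichment and matched-resampling nulls.

A CpG counts as bound by a DNA-binding protein when a binding-site
interval lies within a 100 bp window centred on the CpG (±50 bp).
Enrichment of a sentinel locus' trans-CpG set against the background of
all tested CpGs uses the two-sided Fisher exact test with
Benjamini-Hochberg FDR across the whole screen; only CpG sets large
enough that their smallest achievable Fisher p clears an adjusted
threshold are testable (operationally, sets of >= 5 trans-CpGs).
Empirical calibration resamples CpG sets of equal size matched on
methylation summary covariates.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_WINDOW_BP = 50
MIN_TRANS_CPGS = 5


# ---------------------------------------------------------------------------
# Binding matrix

def _overlaps_point(intervals: pd.DataFrame, positions: np.ndarray,
                    window: int) -> np.ndarray:
    """True where any half-open interval intersects the closed window
    [pos - window, pos + window] around each position."""
    if intervals.empty:
        return np.zeros(len(positions), dtype=bool)
    starts = intervals["start"].to_numpy(np.int64)
    ends = intervals["end"].to_numpy(np.int64)
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    max_end = np.maximum.accumulate(ends)
    idx = np.searchsorted(starts, positions + window, side="right")
    out = np.zeros(len(positions), dtype=bool)
    nz = idx > 0
    out[nz] = max_end[idx[nz] - 1] > positions[nz] - window
    return out


def overlap_cpg_tfbs(
    cpg_anno: pd.DataFrame,
    tracks: dict[str, pd.DataFrame],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """CpG x protein boolean binding matrix under the ±``window_bp`` rule.

    CpGs are single-bp features (``start`` is the 0-based position);
    track intervals are 0-based half-open. The result is invariant to
    interval order and to splitting intervals into touching halves.
    """
    cpgs = cpg_anno.reset_index(drop=True)
    mat = pd.DataFrame(False, index=list(cpgs["name"]), columns=sorted(tracks))
    for prot in sorted(tracks):
        track = tracks[prot]
        for chrom, sub in cpgs.groupby("chrom"):
            tsub = track[track["chrom"] == chrom] if not track.empty else track
            hits = _overlaps_point(tsub, sub["start"].to_numpy(np.int64), window_bp)
            mat.loc[sub["name"].to_numpy(), prot] = hits
    return mat


# ---------------------------------------------------------------------------
# Testability rule

def min_detectable_set_size(K: int, N: int, alpha_adj: float) -> int | None:
    """Smallest set size k whose best-case one-sided Fisher p beats alpha.

    With K bound CpGs in a background of N, the smallest achievable
    one-sided Fisher p for a size-k set is attained when all k members
    are bound: p_min(k) = C(K,k)/C(N,k) = Π_{i<k} (K-i)/(N-i), strictly
    decreasing in k. Returns None ("untestable") when no k <= K works.
    """
    if not 0 < K < N:
        raise ValueError("need 0 < K < N")
    if not 0 < alpha_adj < 1:
        raise ValueError("alpha_adj must be in (0, 1)")
    p = 1.0
    for k in range(1, K + 1):
        p *= (K - k + 1) / (N - k + 1)
        if p < alpha_adj:
            return k
    return None


# ---------------------------------------------------------------------------
# Fisher exact test

def fisher_enrichment(
    set_bound: int, set_size: int, bg_bound: int, bg_size: int
) -> dict:
    """Two-sided Fisher exact test for binding enrichment of a CpG set.

    Odds ratio is the sample OR ``ad/bc`` with a Haldane 0.5 correction
    on zero cells (flagged). Background counts must exclude the set.
    """
    a, b = set_bound, set_size - set_bound
    c, d = bg_bound, bg_size - bg_bound
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = 0 in (a, b, c, d)
    if corrected:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = a, b, c, d
    return {
        "set_bound": a, "set_unbound": b,
        "bg_bound": c, "bg_unbound": d,
        "odds_ratio": (aa * dd) / (bb * cc),
        "fisher_p": float(p),
        "zero_cell_corrected": corrected,
    }


# ---------------------------------------------------------------------------
# Matched resampling

def draw_matched_sets(
    observed: Sequence[str],
    pool: pd.DataFrame,
    tolerances: dict[str, float],
    n_resamples: int,
    rng: np.random.Generator,
    max_retries: int = 20,
) -> list[list[str]]:
    """Draw ``n_resamples`` sets matched member-wise on covariates.

    For each observed member the candidate pool is every non-observed
    row within the tolerance band on every matching covariate; each draw
    picks one candidate per member without replacement inside the draw.
    Raises (naming the member) when a member has no matched candidate.
    """
    obs = list(observed)
    pool_ids = pool.index.to_numpy()
    available = ~pool.index.isin(obs)
    candidates: list[np.ndarray] = []
    for member in obs:
        ok = available.copy()
        for cov, tol in tolerances.items():
            ok &= (pool[cov] - pool.loc[member, cov]).abs().to_numpy() <= tol
        cand = pool_ids[ok]
        if len(cand) == 0:
            raise ValueError(f"no matched background candidates for {member!r}")
        candidates.append(cand)
    draws: list[list[str]] = []
    order0 = np.argsort([len(c) for c in candidates], kind="mergesort")
    for _ in range(n_resamples):
        for _attempt in range(max_retries):
            used: set[str] = set()
            picked: dict[int, str] = {}
            ok = True
            for i in order0:  # scarcest members first
                cand = candidates[i]
                free = [c for c in cand if c not in used]
                if not free:
                    ok = False
                    break
                choice = free[int(rng.integers(len(free)))]
                picked[i] = choice
                used.add(choice)
            if ok:
                draws.append([picked[i] for i in range(len(obs))])
                break
        else:
            raise ValueError("could not draw a matched set without replacement; "
                             "pool too small for the tolerance bands")
    return draws


def matched_resampling_null(
    observed: Sequence[str],
    pool: pd.DataFrame,
    tolerances: dict[str, float],
    statistic: Callable[[Sequence[str]], float],
    n_resamples: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Empirical p for a set statistic against matched resampled sets.

    ``p = (1 + #{draws with statistic >= observed}) / (n_resamples + 1)``
    (add-one convention; p is never zero).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    obs_stat = float(statistic(list(observed)))
    draws = draw_matched_sets(observed, pool, tolerances, n_resamples, rng)
    null = np.array([statistic(d) for d in draws], float)
    p = (1.0 + int((null >= obs_stat).sum())) / (n_resamples + 1.0)
    return {"observed": obs_stat, "empirical_p": p, "null": null}


# ---------------------------------------------------------------------------
# Locus screen

def locus_tfbs_screen(
    loci: Iterable,
    binding: pd.DataFrame,
    fdr: float = 0.05,
    min_set: int = MIN_TRANS_CPGS,
    match_covariates: pd.DataFrame | None = None,
    match_tolerances: dict[str, float] | None = None,
    n_resamples: int = 0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Fisher enrichment of every testable trans locus against every track.

    Loci (objects with ``locus_id`` and ``cpg_set``) enter the screen
    only when at least ``min_set`` of their trans-CpGs are present in
    the binding matrix. Benjamini-Hochberg q-values are computed across
    all (locus, track) tests. With ``n_resamples > 0`` and matching
    covariates, an empirical p from size- and covariate-matched CpG
    resampling is added per test.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    universe = binding.index
    rows = []
    for locus in loci:
        cpg_set = sorted(set(locus.cpg_set) & set(universe))
        if len(cpg_set) < min_set:
            continue
        in_set = binding.index.isin(cpg_set)
        null_draws = None
        if n_resamples > 0 and match_covariates is not None:
            tol = match_tolerances or {c: 0.05 for c in match_covariates.columns}
            null_draws = draw_matched_sets(
                cpg_set, match_covariates.loc[universe], tol, n_resamples, rng)
        for track in binding.columns:
            col = binding[track].to_numpy(bool)
            res = fisher_enrichment(
                int(col[in_set].sum()), int(in_set.sum()),
                int(col[~in_set].sum()), int((~in_set).sum()))
            emp = np.nan
            if null_draws is not None:
                bound_lookup = binding[track]
                null = np.array([int(bound_lookup.loc[d].sum()) for d in null_draws])
                emp = (1.0 + int((null >= res["set_bound"]).sum())) / (len(null) + 1.0)
            rows.append({"locus_id": locus.locus_id, "track": track,
                         **res, "empirical_p": emp})
    out = pd.DataFrame(rows)
    if out.empty:
        out["fdr_q"] = []
        out["significant"] = []
        return out
    _, q, _, _ = multipletests(out["fisher_p"], method="fdr_bh")
    out["fdr_q"] = q
    out["significant"] = out["fdr_q"] < fdr
    return out
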