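"""Pairwise linear-model association scans and two-cohort meta-analysis.

Implements the QTL machinery of a blood meQTL study: covariate
residualization, SNP-CpG (meQTL), SNP-gene (eQTL) and CpG-gene (eQTM)
scans as simple per-pair ordinary least squares, genotype-by-context
interaction scans (iQTL), fixed-effect inverse-variance meta-analysis
across cohorts, and the replication rule (consistent direction,
replication p < 0.05, combined p < 1e-14).

p-values come from the t reference in single-cohort scans and from the
normal z in meta-analysis; every p is stored alongside log10(p)
(computed on the log scale) so genome-wide thresholds like 1e-14 remain
exact after underflow.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GENOME_WIDE_P = 1e-14
CIS_WINDOW = 1_000_000
LN10 = np.log(10.0)


def _t_log10p(t: np.ndarray, df: int | np.ndarray) -> np.ndarray:
    """Two-sided log10 p from a t statistic, safe far below underflow."""
    return (np.log(2.0) + stats.t.logsf(np.abs(t), df)) / LN10


def _z_log10p(z: np.ndarray) -> np.ndarray:
    return (np.log(2.0) + stats.norm.logsf(np.abs(z))) / LN10


def _p_from_log10(log10p: np.ndarray) -> np.ndarray:
    with np.errstate(under="ignore"):
        return np.power(10.0, np.minimum(log10p, 0.0))


# ---------------------------------------------------------------------------
# Residualization

def residualize(
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """OLS residuals of every outcome column on the covariate design.

    An intercept is always included. Raises on missing covariate values
    and on a rank-deficient design, naming the collinear columns.
    """
    names = list(covariate_names) if covariate_names is not None \
        else list(covariates.columns)
    cov = covariates.loc[outcomes.index, names]
    if cov.isna().any().any():
        bad = cov.columns[cov.isna().any()].tolist()
        raise ValueError(f"missing values in covariates {bad}")
    x = np.column_stack([np.ones(len(cov)), cov.to_numpy(float)])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        kept = [0]
        collinear = []
        for j in range(1, x.shape[1]):
            trial = x[:, kept + [j]]
            if np.linalg.matrix_rank(trial) > len(kept):
                kept.append(j)
            else:
                collinear.append(names[j - 1])
        raise ValueError(f"rank-deficient covariate design; collinear columns: "
                         f"{collinear}")
    y = outcomes.to_numpy(float)
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    return pd.DataFrame(resid, index=outcomes.index, columns=outcomes.columns)


# ---------------------------------------------------------------------------
# Simple-regression scan

def _pairwise_ols(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorised simple OLS per aligned column pair of g and y (no NaN)."""
    n = g.shape[0]
    gc = g - g.mean(axis=0)
    yc = y - y.mean(axis=0)
    sgg = (gc * gc).sum(axis=0)
    sgy = (gc * yc).sum(axis=0)
    syy = (yc * yc).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sgy / sgg
        sse = np.maximum(syy - beta * sgy, 0.0)
        sigma2 = sse / (n - 2)
        se = np.sqrt(sigma2 / sgg)
        t = beta / se
    return beta, se, t, sgg


def qtl_scan(
    predictors: pd.DataFrame,
    outcomes: pd.DataFrame,
    pairs: Iterable[tuple[str, str]] | None = None,
    threshold: float = GENOME_WIDE_P,
) -> pd.DataFrame:
    """Per-pair simple linear regression ``outcome ~ predictor``.

    ``pairs`` gives explicit (predictor, outcome) id pairs; when None
    every predictor is tested against every outcome. Zero-variance
    predictors are kept in the output flagged ``untestable`` rather than
    dropped. Missing values are handled pairwise-complete.
    """
    common = predictors.index.intersection(outcomes.index)
    gmat = predictors.loc[common]
    ymat = outcomes.loc[common]
    if pairs is None:
        pair_list = [(p, o) for p in predictors.columns for o in outcomes.columns]
    else:
        pair_list = list(pairs)
    src = [p for p, _ in pair_list]
    tgt = [o for _, o in pair_list]
    g = gmat[src].to_numpy(float)
    y = ymat[tgt].to_numpy(float)

    has_nan = np.isnan(g).any() or np.isnan(y).any()
    if not has_nan:
        n = np.full(len(pair_list), len(common))
        beta, se, t, sgg = _pairwise_ols(g, y)
    else:
        beta = np.empty(len(pair_list))
        se = np.empty(len(pair_list))
        t = np.empty(len(pair_list))
        sgg = np.empty(len(pair_list))
        n = np.empty(len(pair_list), dtype=int)
        for k in range(len(pair_list)):
            mask = ~(np.isnan(g[:, k]) | np.isnan(y[:, k]))
            n[k] = int(mask.sum())
            b, s, tt, sg = _pairwise_ols(g[mask, k:k + 1], y[mask, k:k + 1])
            beta[k], se[k], t[k], sgg[k] = b[0], s[0], tt[0], sg[0]

    untestable = (sgg <= 0) | (n < 4)
    dfree = np.maximum(n - 2, 1)
    log10p = np.where(untestable, np.nan, _t_log10p(np.where(untestable, 0, t), dfree))
    p = _p_from_log10(log10p)
    out = pd.DataFrame({
        "source": src,
        "target": tgt,
        "beta": np.where(untestable, np.nan, beta),
        "se": np.where(untestable, np.nan, se),
        "p": p,
        "log10p": log10p,
        "n": n,
        "untestable": untestable,
    })
    out["significant"] = (~out["untestable"]) & (out["log10p"] < np.log10(threshold))
    return out


# ---------------------------------------------------------------------------
# Category classification

def classify_pair_category(snp_row: pd.Series | dict, cpg_row: pd.Series | dict) -> str:
    """cis (< 1 Mb, same chromosome), long_range_cis (same chromosome
    otherwise) or trans (different chromosomes). Exactly 1 Mb apart is
    long_range_cis (the < 1 Mb rule is strict)."""
    for row, what in ((snp_row, "SNP"), (cpg_row, "CpG")):
        if row is None or "chrom" not in row or "start" not in row:
            raise ValueError(f"missing {what} annotation")
    if snp_row["chrom"] != cpg_row["chrom"]:
        return "trans"
    if abs(int(snp_row["start"]) - int(cpg_row["start"])) < CIS_WINDOW:
        return "cis"
    return "long_range_cis"


def classify_records(
    records: pd.DataFrame,
    source_anno: pd.DataFrame,
    target_anno: pd.DataFrame,
) -> pd.DataFrame:
    """Vectorised category column for a scan result table."""
    s = source_anno.set_index("name")
    t = target_anno.set_index("name")
    missing = set(records["source"]) - set(s.index)
    missing |= set(records["target"]) - set(t.index)
    if missing:
        raise ValueError(f"missing annotation for {sorted(missing)[:5]}")
    schrom = s.loc[records["source"], "chrom"].to_numpy()
    tchrom = t.loc[records["target"], "chrom"].to_numpy()
    spos = s.loc[records["source"], "start"].to_numpy(np.int64)
    tpos = t.loc[records["target"], "start"].to_numpy(np.int64)
    same = schrom == tchrom
    near = np.abs(spos - tpos) < CIS_WINDOW
    cat = np.where(~same, "trans", np.where(near, "cis", "long_range_cis"))
    out = records.copy()
    out["category"] = cat
    return out


# ---------------------------------------------------------------------------
# Meta-analysis and replication

def meta_analyse(frames: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effect inverse-variance meta-analysis over >= 2 cohorts.

    Frames must share (source, target) pairs. Combined effect
    ``beta_c = Σ w_i beta_i / Σ w_i`` with ``w_i = 1/se_i^2``,
    ``se_c = 1/sqrt(Σ w_i)``; p from the normal z. Cochran's Q is
    reported informationally (no random-effects model).
    """
    if len(frames) < 2:
        raise ValueError("meta-analysis needs >= 2 cohorts")
    keyed = [f.set_index(["source", "target"]) for f in frames]
    idx = keyed[0].index
    for k in keyed[1:]:
        if not idx.equals(k.index):
            idx = idx.intersection(k.index)
    betas = np.column_stack([k.loc[idx, "beta"].to_numpy(float) for k in keyed])
    ses = np.column_stack([k.loc[idx, "se"].to_numpy(float) for k in keyed])
    if np.any(ses <= 0) or np.any(np.isnan(ses)):
        raise ValueError("non-positive or missing standard error in meta-analysis")
    w = 1.0 / ses**2
    beta_c = (w * betas).sum(axis=1) / w.sum(axis=1)
    se_c = 1.0 / np.sqrt(w.sum(axis=1))
    z = beta_c / se_c
    log10p = _z_log10p(z)
    q = (w * (betas - beta_c[:, None]) ** 2).sum(axis=1)
    out = pd.DataFrame(index=idx).reset_index()
    out["beta"] = beta_c
    out["se"] = se_c
    out["p"] = _p_from_log10(log10p)
    out["log10p"] = log10p
    out["q_het"] = q
    for i, k in enumerate(keyed):
        out[f"beta_cohort{i}"] = k.loc[idx, "beta"].to_numpy(float)
        out[f"p_cohort{i}"] = k.loc[idx, "p"].to_numpy(float)
    out["n"] = np.column_stack(
        [k.loc[idx, "n"].to_numpy(int) for k in keyed]).sum(axis=1)
    return out


def meta_fixed(betas: Sequence[float], ses: Sequence[float]) -> tuple[float, float, float]:
    """Scalar fixed-effect combination; returns (beta, se, p)."""
    b = np.asarray(betas, float)
    s = np.asarray(ses, float)
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / s**2
    beta_c = float((w * b).sum() / w.sum())
    se_c = float(1.0 / np.sqrt(w.sum()))
    p = float(_p_from_log10(np.array([_z_log10p(np.array([beta_c / se_c]))[0]]))[0])
    return beta_c, se_c, p


def replication_filter(
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
    replication_p: float = 0.05,
    combined_threshold: float = GENOME_WIDE_P,
) -> pd.DataFrame:
    """Replication rule: same effect direction, replication p below
    ``replication_p`` and combined (meta) p below ``combined_threshold``.

    Returns the meta-analysed table with a boolean ``replicated`` column.
    """
    meta = meta_analyse([discovery, replication])
    same_sign = np.sign(meta["beta_cohort0"]) == np.sign(meta["beta_cohort1"])
    same_sign &= meta["beta_cohort0"] != 0
    rep_ok = meta["p_cohort1"] < replication_p
    comb_ok = meta["log10p"] < np.log10(combined_threshold)
    meta["replicated"] = same_sign & rep_ok & comb_ok
    return meta


# ---------------------------------------------------------------------------
# Interaction (iQTL) scan

def interaction_scan(
    dosages: pd.DataFrame,
    methylation: pd.DataFrame,
    context: pd.Series,
    covariates: pd.DataFrame | None = None,
    pairs: Iterable[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Genotype-by-context interaction: ``y ~ g + c + g*c (+ covariates)``.

    Reports the interaction-term coefficient, its standard error and
    two-sided t p-value per (SNP, CpG) pair. Degenerate designs (e.g.
    the product collinear with main effects) are flagged untestable.
    """
    common = dosages.index.intersection(methylation.index)
    ctx = context.loc[common].to_numpy(float)
    if pairs is None:
        pair_list = [(s, c) for s in dosages.columns for c in methylation.columns]
    else:
        pair_list = list(pairs)
    xtra = covariates.loc[common].to_numpy(float) if covariates is not None \
        else np.empty((len(common), 0))
    rows = []
    for sid, cid in pair_list:
        g = dosages.loc[common, sid].to_numpy(float)
        y = methylation.loc[common, cid].to_numpy(float)
        x = np.column_stack([np.ones_like(g), g, ctx, g * ctx, xtra])
        mask = ~(np.isnan(x).any(axis=1) | np.isnan(y))
        xm, ym = x[mask], y[mask]
        nn = int(mask.sum())
        rank = np.linalg.matrix_rank(xm) if nn else 0
        if nn <= x.shape[1] + 1 or rank < x.shape[1]:
            rows.append((sid, cid, np.nan, np.nan, np.nan, np.nan, nn, True))
            continue
        coef, _, _, _ = np.linalg.lstsq(xm, ym, rcond=None)
        resid = ym - xm @ coef
        dfree = nn - x.shape[1]
        sigma2 = float(resid @ resid) / dfree
        xtx_inv = np.linalg.inv(xm.T @ xm)
        se = np.sqrt(sigma2 * xtx_inv[3, 3])
        t = coef[3] / se if se > 0 else np.nan
        l10 = float(_t_log10p(np.array([t]), dfree)[0])
        rows.append((sid, cid, float(coef[3]), float(se),
                     float(_p_from_log10(np.array([l10]))[0]), l10, nn, False))
    return pd.DataFrame(rows, columns=["source", "target", "beta", "se", "p",
                                       "log10p", "n", "untestable"])


# ---------------------------------------------------------------------------
# eQTM scan

def eqtm_scan(
    methylation_residuals: pd.DataFrame,
    expression_residuals: pd.DataFrame,
    pairs: Iterable[tuple[str, str]] | None = None,
    adjust_cells: bool = False,
    cell_proportions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """CpG-gene association: ``gene_residuals ~ cpg_residuals``.

    With ``adjust_cells`` the CpG residuals are first regressed on the
    five white-cell proportion estimates (CD8T, CD4T, NK, Bcell, Mono),
    removing associations that merely track cell composition.
    """
    meth = methylation_residuals
    if adjust_cells:
        if cell_proportions is None:
            raise ValueError("adjust_cells requires cell_proportions")
        from .synthetic import CELL_TYPES
        missing = [c for c in CELL_TYPES if c not in cell_proportions.columns]
        if missing:
            raise ValueError(f"cell_proportions missing columns {missing}")
        cells = cell_proportions.loc[meth.index, list(CELL_TYPES)]
        # zero-variance proportions contribute nothing; drop to keep full rank
        keep = [c for c in cells.columns if cells[c].nunique() > 1]
        if keep:
            meth = residualize(meth, cells, keep)
    if pairs is None:
        pair_list = [(c, g) for c in meth.columns
                     for g in expression_residuals.columns]
    else:
        pair_list = list(pairs)
    return qtl_scan(meth, expression_residuals, pairs=pair_list, threshold=1.0)
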