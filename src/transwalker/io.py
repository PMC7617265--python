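"""Readers/writers for the plain-text formats the pipeline consumes.

Conventions
-----------
* BED intervals are 0-based, half-open ``[start, end)``; point features
  (CpGs, SNPs) occupy a single base, ``end = start + 1``.
* Matrix TSVs carry samples in rows: the first column holds sample ids,
  the header row holds feature ids.
* p-values are serialised together with a ``log10p`` companion so that
  values below the float64 underflow limit survive a text round-trip.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

BED_COLUMNS = ("chrom", "start", "end", "name", "score", "strand")


class FormatError(ValueError):
    """Malformed input file (carries a line number where possible)."""


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 3-6 column BED file into a DataFrame sorted by (chrom, start).

    Returns columns ``chrom, start, end`` plus ``name/score/strand`` when
    present. Coordinates are validated: integer, ``0 <= start < end``.
    """
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            if ncols is None:
                ncols = min(len(parts), 6)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start {start}")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            rows.append(tuple(parts[:ncols]))
    if not rows:
        return pd.DataFrame(columns=list(BED_COLUMNS[:3]))
    df = pd.DataFrame(rows, columns=list(BED_COLUMNS[: ncols or 3]))
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write a BED DataFrame sorted by (chrom, start), tab-separated, no header."""
    out = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Matrices

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a samples x features TSV matrix (first column = sample ids).

    ``NA`` tokens become NaN (missingness is handled pairwise downstream).
    Duplicate sample or feature ids, or ragged rows, raise ``FormatError``.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or unparsable TSV: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate sample ids {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate feature ids {dups}")
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


# ---------------------------------------------------------------------------
# PPI edge list

def read_ppi(path: str | Path, min_score: float | None = None) -> pd.DataFrame:
    """Read a STRING-style edge list TSV: protein_a, protein_b, score."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_a", "protein_b"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    if min_score is not None and "score" in df.columns:
        df = df[df["score"] >= min_score].reset_index(drop=True)
    return df


def write_ppi(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pipeline configuration

@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run.

    Threshold defaults follow the study design: genome-wide significance
    1e-14, replication at 0.05, clumping R^2 0.2 within 1 Mb, TFBS window
    ±50 bp, 500 eigenvectors, 100 randomised background graphs, 10,000
    matched resamples, FDR 0.05.
    """

    bundle_dir: str = "."
    out_dir: str = "results"
    significance: float = 1e-14
    replication_p: float = 0.05
    r2_threshold: float = 0.2
    max_dist: int = 1_000_000
    window_bp: int = 50
    n_eig: int = 500
    n_background: int = 100
    n_resamples: int = 10_000
    fdr: float = 0.05
    min_trans_cpgs: int = 5
    eqtl_nominal_p: float = 0.01
    rpkm_min: float = 0.1
    seed: int = 0
    cohorts: tuple[str, ...] = ("discovery", "replication")

    def __post_init__(self) -> None:
        for name in ("significance", "replication_p", "r2_threshold", "fdr",
                     "eqtl_nominal_p"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        for name in ("max_dist", "window_bp", "n_eig", "n_background",
                     "n_resamples", "min_trans_cpgs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cohorts" in raw:
            raw["cohorts"] = tuple(raw["cohorts"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["cohorts"] = list(data["cohorts"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def content_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so the same
        analysis in a different directory hashes identically)."""
        data = dataclasses.asdict(self)
        data.pop("bundle_dir")
        data.pop("out_dir")
        payload = json.dumps(data, sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Seeding

def child_seeds(master_seed: int, n: int, stream: str = "") -> list[int]:
    """Expand one master seed into ``n`` independent child seeds.

    Uses ``numpy.random.SeedSequence`` spawning keyed additionally on a
    stream label, so independent pipeline stages keep their seeds when
    other stages are re-ordered. All seeds are < 2**31.
    """
    label = int.from_bytes(hashlib.sha256(stream.encode()).digest()[:4], "big")
    ss = np.random.SeedSequence([master_seed, label])
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
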