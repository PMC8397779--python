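"""Readers and writers for the plain-text exchange formats, plus run config.

Contact matrices travel as whitespace-delimited COO triplets
``bin1_start bin2_start count`` (optionally gzipped); intervals as BED,
tracks as bedGraph, loops as BEDPE. All coordinates are 0-based half-open.
Readers are lossless round trips on valid input.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeSpec
from .matrix import ContactMatrix

log = logging.getLogger("mitohic.io")


class FormatError(ValueError):
    """Malformed on-disk input."""


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# contact matrices
# ---------------------------------------------------------------------------

def read_contact_matrix(path, genome: GenomeSpec, chrom: str) -> ContactMatrix:
    """Read COO triplets ``bin1_start bin2_start count`` for one chromosome."""
    bs = genome.bin_size
    length = genome.chromsizes[chrom]
    n_bins = genome.n_bins(chrom)
    rows, cols, vals = [], [], []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            try:
                a, b = int(parts[0]), int(parts[1])
                v = float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if a % bs or b % bs:
                raise FormatError(
                    f"{path}:{lineno}: bin start not a multiple of bin size {bs}"
                )
            if v < 0:
                raise FormatError(f"{path}:{lineno}: negative count")
            if a >= length or b >= length:
                raise FormatError(f"{path}:{lineno}: bin beyond chromosome end ({length})")
            rows.append(a // bs)
            cols.append(b // bs)
            vals.append(v)
    return ContactMatrix.from_triplets(chrom, bs, n_bins, rows, cols, vals)


def write_contact_matrix(matrix: ContactMatrix, path) -> None:
    rows, cols, vals = matrix.triplets()
    bs = matrix.bin_size
    with _open(path, "wt") as fh:
        for i, j, v in zip(rows, cols, vals):
            v = int(v) if float(v).is_integer() else v
            fh.write(f"{i * bs}\t{j * bs}\t{v}\n")


# ---------------------------------------------------------------------------
# intervals and tracks
# ---------------------------------------------------------------------------

BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path, genome: GenomeSpec | None = None) -> pd.DataFrame:
    """Read BED3/BED6 into a DataFrame; extra columns are preserved verbatim."""
    records = []
    ncols = 0
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            if genome is not None and chrom not in genome.chromsizes:
                log.warning("%s:%d: unknown chromosome %s, skipped", path, lineno, chrom)
                continue
            records.append([chrom, start, end] + parts[3:])
            ncols = max(ncols, len(parts))
    cols = BED_COLS[:ncols] + [f"col{k}" for k in range(7, ncols + 1)]
    df = pd.DataFrame(records, columns=cols if records else cols[:3])
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    with _open(path, "wt") as fh:
        for _, row in df.iterrows():
            fh.write("\t".join(str(v) for v in row.tolist()) + "\n")


def read_bedgraph(path, genome: GenomeSpec | None = None) -> pd.DataFrame:
    """Read a bedGraph into columns chrom/start/end/value."""
    records = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            if genome is not None and chrom not in genome.chromsizes:
                log.warning("%s:%d: unknown chromosome %s, skipped", path, lineno, chrom)
                continue
            records.append((chrom, start, end, value))
    return pd.DataFrame(records, columns=["chrom", "start", "end", "value"])


def write_bedgraph(df: pd.DataFrame, path) -> None:
    with _open(path, "wt") as fh:
        for chrom, start, end, value in df[["chrom", "start", "end", "value"]].itertuples(
            index=False
        ):
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def bin_track(df: pd.DataFrame, genome: GenomeSpec, bin_size: int) -> dict[str, np.ndarray]:
    """Coverage-weighted mean of a bedGraph over fixed-size bins.

    A constant value over a fully covered bin yields exactly that value;
    uncovered stretches contribute zero.
    """
    out = {}
    for chrom in genome.chroms:
        n = -(-genome.chromsizes[chrom] // bin_size)
        acc = np.zeros(n)
        sub = df[df["chrom"] == chrom]
        for start, end, value in sub[["start", "end", "value"]].itertuples(index=False):
            b0, b1 = start // bin_size, (end - 1) // bin_size
            for b in range(b0, b1 + 1):
                lo = max(start, b * bin_size)
                hi = min(end, (b + 1) * bin_size, genome.chromsizes[chrom])
                if hi > lo:
                    acc[b] += value * (hi - lo)
        width = np.full(n, float(bin_size))
        width[-1] = genome.chromsizes[chrom] - (n - 1) * bin_size
        out[chrom] = acc / width
    return out


BEDPE_COLS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
]


def read_bedpe(path, genome: GenomeSpec | None = None) -> pd.DataFrame:
    records = []
    ncols = 0
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: BEDPE needs >= 6 fields")
            row = [
                parts[0], int(parts[1]), int(parts[2]),
                parts[3], int(parts[4]), int(parts[5]),
            ] + parts[6:]
            if row[2] <= row[1] or row[5] <= row[4]:
                raise FormatError(f"{path}:{lineno}: end <= start")
            if genome is not None and (
                row[0] not in genome.chromsizes or row[3] not in genome.chromsizes
            ):
                log.warning("%s:%d: unknown chromosome, skipped", path, lineno)
                continue
            records.append(row)
            ncols = max(ncols, len(parts))
    cols = BEDPE_COLS[:ncols] + [f"col{k}" for k in range(11, ncols + 1)]
    return pd.DataFrame(records, columns=cols if records else cols[:6])


def write_bedpe(df: pd.DataFrame, path) -> None:
    with _open(path, "wt") as fh:
        for _, row in df.iterrows():
            fh.write("\t".join(str(v) for v in row.tolist()) + "\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with its default.

    Defaults are the values used throughout the analysis; any key can be
    overridden from the YAML config.
    """

    # masking / balancing
    mask_low_quantile: float = 0.02
    kr_tol: float = 1e-6
    kr_max_iter: int = 1000
    # compartments
    compartment_bin_size: int = 100_000
    tier_bin_size: int = 50_000
    saddle_sections: int = 50
    saddle_top_fraction: float = 0.2
    rs_max_distance: int = 125_000_000
    tier_flank: int = 250_000
    tier_shuffle_n: int = 500
    # insulation / domains
    insulation_window_bins: int = 12
    insulation_offset_bins: int = 1
    insulation_min_counts: float = 12.0
    boundary_window_kb: float = 120.0
    boundary_merge_bp: int = 80_000
    boundary_remerge_bp: int = 20_000
    boundary_adjust_bins: int = 6
    domain_overlap_bins: int = 8
    min_domain_bp: int = 100_000
    ada_min_domain_bp: int = 150_000
    ada_max_oe: float = 30.0
    ada_min_outer_nonzero: int = 5
    ada_min_inner_nonzero: int = 10
    ada_dynamic_fold: float = 1.25
    domain_prominence: float = 0.2
    subdomain_prominence: float = 0.1
    subdomain_cap_bp: int = 500_000
    boundary_kmeans_k: int = 5
    kmeans_restarts: int = 50
    transition_flank_bp: int = 50_000
    transition_extreme_fraction: float = 0.2
    # loops
    donut_inner_diam_10kb: int = 4
    donut_outer_diam_10kb: int = 16
    donut_fdr_10kb: float = 0.2
    donut_inner_diam_25kb: int = 1
    donut_outer_diam_25kb: int = 6
    donut_fdr_25kb: float = 0.01
    loop_max_distance: int = 2_000_000
    artifact_max_samples: int = 6
    cluster_radius_bp: int = 20_000
    singleton_max_q: float = 0.02
    anchor_window_bp: int = 30_000
    recovery_min_oe: float = 1.5
    recovery_min_obs: float = 10.0
    recovery_prometa_top_fraction: float = 0.05
    apa_min_loop_bp: int = 100_000
    apa_window_bins: int = 10
    loop_kmeans_k: int = 4
    # transcription
    gene_body_offset: int = 500
    min_gene_length: int = 1_000
    promoter_flank: int = 250
    promoter_low_quantile: float = 0.10
    activation_fold: float = 1.5
    de_padj: float = 0.05
    de_fold: float = 1.25
    # CRE / ABC
    abc_max_distance: int = 5_000_000
    abc_thresholds: tuple = (0.01, 0.02, 0.03, 0.04, 0.05)
    abc_threshold_main: float = 0.04
    ep_fdr: float = 0.1
    # misc
    seed: int = 0


@dataclass
class RunConfig:
    genome: GenomeSpec
    samples: list[str]
    params: PipelineConfig
    paths: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unset keys take documented defaults."""
    with _open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("genome", "samples"):
        if key not in raw:
            raise ConfigError(f"missing required config key: {key!r}")
    g = raw["genome"]
    for key in ("chromsizes", "bin_size"):
        if key not in g:
            raise ConfigError(f"missing required config key: genome.{key}")
    genome = GenomeSpec(
        {str(c): int(v) for c, v in g["chromsizes"].items()},
        int(g["bin_size"]),
        tuple(g.get("excluded", ())),
    )
    params = PipelineConfig()
    known = {f.name for f in fields(PipelineConfig)}
    for key, val in (raw.get("params") or {}).items():
        if key not in known:
            raise ConfigError(f"unknown parameter {key!r}")
        if isinstance(val, list):
            val = tuple(val)
        setattr(params, key, val)
    paths = raw.get("paths") or {}
    mat_bin = raw.get("matrix_bin_size")
    if mat_bin is not None and int(mat_bin) != genome.bin_size:
        raise ConfigError(
            f"matrix bin size {mat_bin} contradicts genome bin size {genome.bin_size}"
        )
    return RunConfig(genome, list(raw["samples"]), params, paths)


def setup_logging(level: str = "INFO") -> None:
    """Single structured log for the whole run."""
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
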