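"""Genome layout and sample-design primitives shared by every stage."""

from __future__ import annotations

from dataclasses import dataclass, field

#: Cell-cycle stages in temporal order (prometaphase through late G1).
STAGES = ("prometa", "ana_telo", "early_G1", "mid_G1", "late_G1")

#: Treatment conditions. ``auxin`` denotes acute CTCF degradation,
#: ``triptolide`` transcription-initiation inhibition.
CONDITIONS = ("control", "auxin", "triptolide", "auxin_triptolide")

#: Stages considered post-mitotic for filters that contrast against prometa.
POST_MITOTIC_STAGES = ("ana_telo", "early_G1", "mid_G1", "late_G1")


class GenomeError(ValueError):
    """Invalid genome description."""


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names/lengths plus the working bin size.

    Coordinates are 0-based half-open throughout; a position ``p`` falls in
    bin ``p // bin_size``.
    """

    chromsizes: dict[str, int]
    bin_size: int
    excluded: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise GenomeError(f"bin size must be positive, got {self.bin_size}")
        for chrom, length in self.chromsizes.items():
            if length <= 0:
                raise GenomeError(f"{chrom}: length must be positive, got {length}")
        unknown = set(self.excluded) - set(self.chromsizes)
        if unknown:
            raise GenomeError(f"excluded chromosomes not in genome: {sorted(unknown)}")

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self.chromsizes)

    def analysis_chroms(self) -> tuple[str, ...]:
        """Chromosomes retained after applying the exclusion list."""
        return tuple(c for c in self.chromsizes if c not in self.excluded)

    def n_bins(self, chrom: str) -> int:
        length = self.chromsizes[chrom]
        return -(-length // self.bin_size)

    def with_bin_size(self, bin_size: int) -> "GenomeSpec":
        return GenomeSpec(dict(self.chromsizes), bin_size, self.excluded)

    def bin_of(self, pos: int) -> int:
        return pos // self.bin_size


@dataclass(frozen=True, order=True)
class SampleKey:
    """One Hi-C/ChIP sample: stage x condition x replicate.

    ``replicate`` is a 1-based integer, or 0 for the replicate-merged sample.
    """

    stage: str
    condition: str
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )
        if self.replicate < 0:
            raise ValueError("replicate must be >= 0 (0 = merged)")

    @property
    def merged(self) -> bool:
        return self.replicate == 0

    def as_merged(self) -> "SampleKey":
        return SampleKey(self.stage, self.condition, 0)

    def label(self) -> str:
        rep = "merged" if self.merged else f"rep{self.replicate}"
        return f"{self.stage}_{self.condition}_{rep}"

    @classmethod
    def from_label(cls, label: str) -> "SampleKey":
        stage, condition, rep = label.rsplit("_", 2) if False else _split_label(label)
        return cls(stage, condition, rep)


def _split_label(label: str) -> tuple[str, str, int]:
    parts = label.split("_")
    # stage names may contain one underscore (ana_telo, early_G1, ...)
    for i in range(1, len(parts)):
        stage = "_".join(parts[:i])
        if stage in STAGES:
            rest = parts[i:]
            if len(rest) == 2 and rest[0] in CONDITIONS:
                cond, rep = rest
            elif len(rest) == 3 and "_".join(rest[:2]) in CONDITIONS:
                cond, rep = "_".join(rest[:2]), rest[2]
            else:
                continue
            repnum = 0 if rep == "merged" else int(rep.removeprefix("rep"))
            return stage, cond, repnum
    raise ValueError(f"cannot parse sample label {label!r}")


def full_design(
    stages=("prometa", "ana_telo", "early_G1", "mid_G1"),
    conditions=("control", "auxin"),
    n_replicates: int = 2,
) -> list[SampleKey]:
    """Enumerate the replicate-level sample keys of a complete design."""
    return [
        SampleKey(s, c, r)
        for s in stages
        for c in conditions
        for r in range(1, n_replicates + 1)
    ]


def merged_design(design: list[SampleKey]) -> list[SampleKey]:
    """Unique replicate-merged keys of a replicate-level design, in order."""
    seen: dict[SampleKey, None] = {}
    for key in design:
        seen.setdefault(key.as_merged())
    return list(seen)
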