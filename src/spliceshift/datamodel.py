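"""Core domain types shared by every analysis stage.

Coordinates are 0-based half-open (BED dialect) throughout; 1-based
annotation-style numbering appears only in display labels.  All sequence
handling is on the RNA-sense alphabet (ACGU); DNA letters are accepted on
input and T is aliased to U.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

ASE_TYPES = ("ES", "IR", "A5", "A3", "MX")
CONDITIONS = ("control", "silenced")
COHORT_GROUPS = ("ERpos_tumor", "ERneg_tumor", "normal")

RNA_ALPHABET = "ACGU"
_LETTER_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3,
                 "a": 0, "c": 1, "g": 2, "u": 3, "t": 3}

_COMPLEMENT = str.maketrans("ACGUacgu", "UGCAugca")


def to_rna(seq: str) -> str:
    """Normalize a nucleotide string to the upper-case RNA alphabet."""
    return seq.upper().replace("T", "U")


def reverse_complement(seq: str) -> str:
    """Reverse complement on the RNA alphabet (input may be DNA)."""
    return to_rna(seq).translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode ACGU/ACGT into integer codes 0..3; unknown letters become -1."""
    return np.array([_LETTER_INDEX.get(c, -1) for c in seq], dtype=np.int64)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strand-agnostic half-open intersection test."""
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    def extended(self, pad: int, bound: int | None = None) -> "GenomicInterval":
        """Pad both sides by ``pad`` nt, clipping at 0 and optionally ``bound``."""
        start = max(0, self.start - pad)
        end = self.end + pad if bound is None else min(self.end + pad, bound)
        return GenomicInterval(self.chrom, start, end, self.strand)


@dataclass
class IsoformAnnotation:
    """Structural annotation carried with each isoform.

    These fields stand in for external annotators (ORF prediction, Pfam,
    NMD classification): the pipeline consumes them, it never computes
    them from sequence.
    """

    orf_length: int = 0
    utr5_length: int = 0
    utr3_length: int = 0
    n_domains: int = 0
    has_intron_retention: bool = False
    coding: bool = True
    nmd_sensitive: bool = False


@dataclass
class IsoformQuant:
    """Per-isoform expression across samples with a parent-gene link."""

    isoform_id: str
    gene_id: str
    tpm: dict[str, float]
    counts: dict[str, int] = field(default_factory=dict)
    annotation: IsoformAnnotation = field(default_factory=IsoformAnnotation)

    def tpm_vector(self, samples: list[str]) -> np.ndarray:
        return np.array([self.tpm[s] for s in samples], dtype=float)


@dataclass
class SplicingEvent:
    """A typed alternative-splicing event with junction-read support.

    ``regions`` maps role labels ("alt" — or "alt1"/"alt2" for MX —
    "upstream_exon", "downstream_exon") to intervals.  PSI is derived,
    never stored raw; missing PSI (inc+skip == 0) is NaN.
    """

    event_id: str
    gene_id: str
    ase_type: str
    regions: dict[str, GenomicInterval]
    inc_counts: dict[str, int]
    skip_counts: dict[str, int]
    inc_eff_len: int = 2
    skip_eff_len: int = 1
    dpsi: float = math.nan
    pvalue: float = math.nan
    adj_pvalue: float = math.nan

    def __post_init__(self):
        if self.ase_type not in ASE_TYPES:
            raise ValueError(f"unknown ASE type {self.ase_type!r}")
        n_alt = sum(1 for k in self.regions if k.startswith("alt"))
        if self.ase_type == "MX":
            if n_alt != 2:
                raise ValueError("MX events carry exactly two alternative regions")
        elif n_alt != 1:
            raise ValueError(f"{self.ase_type} events carry one alternative region")

    @property
    def samples(self) -> list[str]:
        return list(self.inc_counts)

    def alt_regions(self) -> list[GenomicInterval]:
        return [v for k, v in sorted(self.regions.items()) if k.startswith("alt")]

    def psi(self, sample: str) -> float:
        """Length-normalized PSI for one sample; NaN when unsupported."""
        inc = self.inc_counts[sample]
        skip = self.skip_counts[sample]
        if inc < 0 or skip < 0:
            raise ValueError(f"negative junction counts for {self.event_id}")
        if inc + skip == 0:
            return math.nan
        inc_n = inc / self.inc_eff_len
        skip_n = skip / self.skip_eff_len
        return inc_n / (inc_n + skip_n)

    def psi_vector(self, samples: list[str] | None = None) -> np.ndarray:
        samples = samples if samples is not None else self.samples
        return np.array([self.psi(s) for s in samples], dtype=float)


@dataclass
class MotifModel:
    """RBP binding preference as a position probability matrix.

    ``pwm`` is L x 4 over ACGU with rows summing to 1 (after pseudocount);
    ``score_threshold`` is the discretized log-odds bin threshold derived
    from the background null (see :mod:`spliceshift.motifs`), None until
    computed, and ``math.inf`` for unscannable motifs.
    """

    motif_id: str
    rbp_name: str
    pwm: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    score_threshold: float | None = None

    def __post_init__(self):
        self.pwm = np.asarray(self.pwm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
            raise ValueError("pwm must be an L x 4 matrix")
        if np.any(self.pwm <= 0) or np.any(self.pwm > 1):
            raise ValueError("pwm probabilities must lie in (0, 1]")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("pwm rows must each sum to 1")

    def __len__(self) -> int:
        return self.pwm.shape[0]

    def consensus(self) -> str:
        return "".join(RNA_ALPHABET[i] for i in self.pwm.argmax(axis=1))


@dataclass
class CohortSample:
    """One pseudo-cohort sample: group, marker expression, PSI, survival."""

    sample_id: str
    group: str
    marker_expr: float
    psi_by_event: dict[str, float] = field(default_factory=dict)
    os_time: float = math.nan
    os_event: bool = False
    dfs_time: float = math.nan
    dfs_event: bool = False

    def __post_init__(self):
        if self.group not in COHORT_GROUPS:
            raise ValueError(f"unknown cohort group {self.group!r}")
        for name in ("os", "dfs"):
            t = getattr(self, f"{name}_time")
            if getattr(self, f"{name}_event") and not math.isfinite(t):
                raise ValueError(
                    f"{self.sample_id}: {name} event flag set without a finite time")
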