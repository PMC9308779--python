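"""Core domain types shared across the pipeline.

The central record is :class:`VariantCall`, one called blood somatic variant
with its read support and provenance. Collections of calls flow through the
reverse-calling filter cascade, into SBS96 catalogs, and finally into
donor-level clonal-hematopoiesis (CH) classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: (sample_id, chrom, pos, ref, alt) — the identity of a call across call sets.
VariantKey = tuple[str, str, int, str, str]

#: (chrom, pos, ref, alt) — the identity of a variant across donors/resources.
SiteKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class VariantCall:
    """One called blood variant.

    Coordinates are 1-based (VCF convention); interval logic elsewhere uses
    0-based half-open coordinates internally.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt_reads: Optional[int]
    depth: Optional[int]
    vaf: float
    caller_pass: bool
    sample_id: str
    gene: Optional[str] = None
    consequence: Optional[str] = None  # nonsilent | silent | noncoding
    germline_called: bool = False  # also found by a one-sample germline calling

    def __post_init__(self) -> None:
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"VAF out of [0,1]: {self.vaf}")
        if self.alt_reads is not None and self.depth is not None:
            if self.alt_reads > self.depth:
                raise ValueError("alt_reads exceeds depth")

    @property
    def key(self) -> VariantKey:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)

    @property
    def site_key(self) -> SiteKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def with_(self, **kw) -> "VariantCall":
        return replace(self, **kw)


@dataclass
class DonorProfile:
    """Donor metadata plus (optionally) their paired call sets.

    ``truth`` holds the simulator's ground-truth block (is_CH, driver gene,
    clone fraction, true HSC mutation count) and is only ever present for
    synthetic donors — the pipeline never reads it.
    """

    donor_id: str
    age: float
    sex: str
    cancer_type: str = "unknown"
    treatments: frozenset[str] = frozenset()
    cohort: str = "metastasis"  # primary | metastasis | targeted
    blood_calls: list[VariantCall] = field(default_factory=list)
    tumor_calls: list[VariantCall] = field(default_factory=list)
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        self.treatments = frozenset(self.treatments)


@dataclass
class MutationCatalog:
    """Per-sample counts over the 96 pyrimidine-centric trinucleotide channels."""

    sample_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("catalog must have exactly 96 channels")
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class SignatureProfile:
    """A 96-channel probability vector (sums to 1)."""

    name: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (96,):
            raise ValueError("signature must have exactly 96 channels")
        if (self.probs < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        s = self.probs.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"signature probabilities must sum to 1 (got {s})")

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray) -> "SignatureProfile":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero profile")
        return cls(name=name, probs=counts / total)


@dataclass
class CascadeStep:
    name: str
    variants_in: int
    variants_out: int

    def __post_init__(self) -> None:
        if self.variants_out > self.variants_in:
            raise ValueError(
                f"step {self.name}: variants_out > variants_in "
                f"({self.variants_out} > {self.variants_in})"
            )


@dataclass
class CascadeReport:
    """Ordered per-step ledger of the filter cascade."""

    steps: list[CascadeStep] = field(default_factory=list)
    removed_samples: list[str] = field(default_factory=list)
    hypermutator_threshold: Optional[float] = None

    def add(self, name: str, n_in: int, n_out: int) -> None:
        self.steps.append(CascadeStep(name, n_in, n_out))

    def as_rows(self) -> list[tuple[str, int, int]]:
        return [(s.name, s.variants_in, s.variants_out) for s in self.steps]


@dataclass
class Catalog:
    """A labelled call set (full / mutect / mosaic)."""

    label: str
    calls: list[VariantCall]


@dataclass(frozen=True)
class CompendiumGene:
    symbol: str
    tier: str  # known_CH | myeloid_driver | discovered_primary_metastasis | discovered_targeted
    evidence: str = ""

    TIERS = (
        "known_CH",
        "myeloid_driver",
        "discovered_primary_metastasis",
        "discovered_targeted",
    )

    def __post_init__(self) -> None:
        if self.tier not in self.TIERS:
            raise ValueError(f"unknown compendium tier: {self.tier}")


@dataclass
class CHCall:
    """Per-donor CH classification with its basis."""

    donor_id: str
    is_CH: bool
    basis: str  # known_gene_germline_calling | known_gene_reverse_calling |
    #             discovered_gene | targeted_gene | rate_threshold | none
    driver_mutations: list[VariantCall] = field(default_factory=list)
    hsc_rate_per_year: float = 0.0

    def __post_init__(self) -> None:
        if self.is_CH != (self.basis != "none"):
            raise ValueError("is_CH must be equivalent to basis != 'none'")


@dataclass
class RegressionResult:
    term: str
    coefficient: float
    ci95: tuple[float, float]
    p_value: float
    q_value: Optional[float] = None
    flagged: Optional[str] = None

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.coefficient <= hi) and self.flagged is None:
            raise ValueError("coefficient outside its own CI")
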