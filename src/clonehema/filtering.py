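"""The reverse-calling filter cascade.

Raw blood-vs-tumor ("reverse") variant calls are turned into the *full*,
*mutect* and *mosaic* somatic catalogs by an ordered sequence of filters:

1. basic read support: caller PASS, >= 2 supporting reads, VAF < 0.5;
2. low-mappability mask removal;
3. merging of contiguous SNVs into double-base substitutions (DBS);
4. panel-of-normals / population allele-frequency removal;
5. common-SNP removal;
6. segmental-duplication / simple-repeat / masked-region removal;
7. exclusion of hypermutator samples above the 97.5th burden percentile.

Every step is monotone (its output is a subset of its input) and the cascade
writes a per-step ledger (:class:`~clonehema.types.CascadeReport`).
All frequency comparisons are strict ("greater than"); ties are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .types import Catalog, CascadeReport, SiteKey, VariantCall

logger = logging.getLogger(__name__)

#: Strict population-frequency cutoffs per resource label.
POPULATION_CUTOFFS = {"PoN_TCGA": 0.002, "PoN_HMF": 0.008, "gnomAD": 0.0003}

MASK_NAMES = ("low_mappability", "segdup", "simple_repeat", "masked")


@dataclass
class MaskSet:
    """Named genomic interval collections (0-based half-open per chromosome)."""

    low_mappability: dict[str, IntervalTree] = field(default_factory=dict)
    segdup: dict[str, IntervalTree] = field(default_factory=dict)
    simple_repeat: dict[str, IntervalTree] = field(default_factory=dict)
    masked: dict[str, IntervalTree] = field(default_factory=dict)

    def collections(self, names: Optional[Sequence[str]] = None):
        for name in names or MASK_NAMES:
            yield name, getattr(self, name)


@dataclass
class FrequencyResource:
    """Variant-keyed cohort frequencies or population MAFs."""

    label: str  # PoN_TCGA | PoN_HMF | gnomAD | common_snp | ...
    freqs: dict[SiteKey, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [v for v in self.freqs.values() if not (0.0 <= v <= 1.0)]
        if bad:
            raise ValueError(f"{self.label}: frequencies outside [0,1]")

    def get(self, key: SiteKey) -> float:
        return self.freqs.get(key, 0.0)

    def __contains__(self, key: SiteKey) -> bool:
        return key in self.freqs


# ---------------------------------------------------------------- steps


def basic_filters(calls: Sequence[VariantCall]) -> list[VariantCall]:
    """Keep caller-PASS calls with >= 2 supporting reads and VAF < 0.5."""
    kept = []
    for c in calls:
        if c.alt_reads is None:
            logger.debug("rejected %s: missing read support", c.key)
            continue
        if c.caller_pass and c.alt_reads >= 2 and c.vaf < 0.5:
            kept.append(c)
    return kept


def _overlaps(call: VariantCall, trees: Mapping[str, IntervalTree]) -> bool:
    tree = trees.get(call.chrom)
    if tree is None:
        return False
    start0 = call.pos - 1
    return bool(tree.overlap(start0, start0 + len(call.ref)))


def mask_filter(
    calls: Sequence[VariantCall],
    masks: MaskSet,
    which: Optional[Sequence[str]] = None,
) -> list[VariantCall]:
    """Remove calls intersecting any interval of the selected mask tracks."""
    collections = list(masks.collections(which))
    missing: set[str] = set()
    kept = []
    for c in calls:
        hit = False
        for _, trees in collections:
            if c.chrom not in trees and trees:
                if c.chrom not in missing:
                    missing.add(c.chrom)
                    logger.info("chromosome %s absent from mask; treated as unmasked", c.chrom)
            if _overlaps(c, trees):
                hit = True
                break
        if not hit:
            kept.append(c)
    return kept


def merge_dbs(calls: Sequence[VariantCall]) -> list[VariantCall]:
    """Merge contiguous same-sample SNVs into double-base substitutions.

    Left-greedy over runs of adjacent SNVs: a triplet becomes one DBS plus
    one SNV. The merged record's VAF is the mean of the pair.
    """
    by_key = sorted(calls, key=lambda c: (c.sample_id, c.chrom, c.pos))
    out: list[VariantCall] = []
    i = 0
    while i < len(by_key):
        a = by_key[i]
        b = by_key[i + 1] if i + 1 < len(by_key) else None
        if (
            b is not None
            and a.is_snv
            and b.is_snv
            and a.sample_id == b.sample_id
            and a.chrom == b.chrom
            and b.pos == a.pos + 1
        ):
            alt_reads = depth = None
            if None not in (a.alt_reads, b.alt_reads, a.depth, b.depth):
                alt_reads = int(round((a.alt_reads + b.alt_reads) / 2))
                depth = int(round((a.depth + b.depth) / 2))
            out.append(VariantCall(
                chrom=a.chrom, pos=a.pos, ref=a.ref + b.ref, alt=a.alt + b.alt,
                alt_reads=alt_reads, depth=depth, vaf=(a.vaf + b.vaf) / 2,
                caller_pass=a.caller_pass and b.caller_pass,
                sample_id=a.sample_id, gene=a.gene or b.gene,
                consequence=a.consequence,
                germline_called=a.germline_called or b.germline_called,
            ))
            i += 2
        else:
            out.append(a)
            i += 1
    return out


def pon_filter(
    calls: Sequence[VariantCall],
    pon: Optional[FrequencyResource],
    hotspot_keys: Sequence[SiteKey] = (),
    population: Sequence[FrequencyResource] = (),
) -> list[VariantCall]:
    """Panel-of-normals and population allele-frequency removal.

    A call is removed when its PoN cohort frequency strictly exceeds the
    maximum PoN frequency among the driver hotspot keys (DNMT3A R882H /
    JAK2 V617F by default upstream; frequency 0 when absent), or when its
    frequency in any population resource strictly exceeds that resource's
    cutoff (PoN_TCGA 0.002, PoN_HMF 0.008, gnomAD 0.0003).
    """
    threshold = 0.0
    if pon is not None:
        threshold = max((pon.get(k) for k in hotspot_keys), default=0.0)
    cutoffs = []
    for res in population:
        if res.label not in POPULATION_CUTOFFS:
            raise KeyError(f"unknown frequency resource label: {res.label}")
        cutoffs.append((res, POPULATION_CUTOFFS[res.label]))
    kept = []
    for c in calls:
        k = c.site_key
        if pon is not None and pon.get(k) > threshold:
            continue
        if any(res.get(k) > cut for res, cut in cutoffs):
            continue
        kept.append(c)
    return kept


def common_snp_filter(
    calls: Sequence[VariantCall], snp_sets: Sequence[FrequencyResource]
) -> list[VariantCall]:
    """Remove calls whose (chrom,pos,ref,alt) key appears in any SNP set."""
    return [c for c in calls if not any(c.site_key in s for s in snp_sets)]


def hypermutator_threshold(counts: Mapping[str, int]) -> float:
    """97.5th percentile (linear interpolation) of per-sample burden."""
    return float(np.percentile(list(counts.values()), 97.5, method="linear"))


def hypermutator_filter(
    per_sample_counts: Mapping[str, int],
    threshold: Optional[float] = None,
) -> tuple[set[str], list[str], float]:
    """Samples retained after excluding burdens strictly above the 97.5th
    percentile of the cohort (removed samples reported).

    An explicitly supplied ``threshold`` (e.g. recorded from a previous run
    of the cascade) overrides the recomputed percentile, which makes the
    exclusion idempotent relative to the original cohort distribution.
    """
    samples = set(per_sample_counts)
    if len(samples) < 2:
        logger.warning("single-sample cohort: hypermutator exclusion skipped")
        return samples, [], float("inf")
    if threshold is None:
        threshold = hypermutator_threshold(per_sample_counts)
    removed = sorted(s for s, n in per_sample_counts.items() if n > threshold)
    return samples - set(removed), removed, threshold


def intersect_callsets(
    full: Sequence[VariantCall], other: Sequence[VariantCall], label: str
) -> Catalog:
    """Subset of ``full`` whose keys also occur in ``other``; annotations of
    ``full`` are preserved and the catalog is stamped with ``label``."""
    other_keys = {c.key for c in other}
    return Catalog(label=label, calls=[c for c in full if c.key in other_keys])


# ---------------------------------------------------------------- cascade


@dataclass
class CascadeResources:
    masks: MaskSet = field(default_factory=MaskSet)
    pon: Optional[FrequencyResource] = None
    hotspot_keys: Sequence[SiteKey] = ()
    population: Sequence[FrequencyResource] = ()
    snp_sets: Sequence[FrequencyResource] = ()


def run_cascade(
    calls: Sequence[VariantCall],
    resources: Optional[CascadeResources] = None,
    mutect_calls: Optional[Sequence[VariantCall]] = None,
    mosaic_calls: Optional[Sequence[VariantCall]] = None,
    hypermutator_thresh: Optional[float] = None,
) -> tuple[Catalog, Optional[Catalog], Optional[Catalog], CascadeReport]:
    """Run the full filter cascade and derive the mutect/mosaic catalogs.

    Returns (full, mutect, mosaic, report); the mutect/mosaic catalogs are
    ``None`` when the corresponding second call set is not supplied.
    """
    res = resources or CascadeResources()
    report = CascadeReport()
    current = list(calls)

    def step(name: str, fn) -> None:
        nonlocal current
        n_in = len(current)
        try:
            current = fn(current)
        except Exception as exc:  # surface which step failed
            raise RuntimeError(f"cascade step '{name}' failed: {exc}") from exc
        if len(current) > n_in:
            raise RuntimeError(f"cascade step '{name}' is not monotone")
        report.add(name, n_in, len(current))

    step("basic", basic_filters)
    step("mappability", lambda c: mask_filter(c, res.masks, ["low_mappability"]))
    step("dbs_merge", merge_dbs)
    step("pon_population", lambda c: pon_filter(
        c, res.pon, res.hotspot_keys, res.population))
    step("common_snp", lambda c: common_snp_filter(c, res.snp_sets))
    step("region_masks", lambda c: mask_filter(
        c, res.masks, ["segdup", "simple_repeat", "masked"]))

    n_in = len(current)
    counts: dict[str, int] = {}
    for c in current:
        counts[c.sample_id] = counts.get(c.sample_id, 0) + 1
    if counts:
        retained, removed, thresh = hypermutator_filter(counts, hypermutator_thresh)
        current = [c for c in current if c.sample_id in retained]
        report.removed_samples = removed
        report.hypermutator_threshold = thresh
    report.add("hypermutator", n_in, len(current))

    full = Catalog(label="full", calls=current)
    mutect = (intersect_callsets(current, mutect_calls, "mutect")
              if mutect_calls is not None else None)
    mosaic = (intersect_callsets(current, mosaic_calls, "mosaic")
              if mosaic_calls is not None else None)
    return full, mutect, mosaic, report
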