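"""Donor-level clonal-hematopoiesis classification.

A donor is a CH case when they carry a nonsilent mutation in a compendium
driver gene, with the basis ranked by how the gene entered the compendium
(known CH gene found by germline calling, known CH gene found by reverse
calling, gene discovered in the primary/metastasis cohorts, gene discovered
in the targeted cohort). Among driver-mutated donors the median rate of
hematopoiesis mutations per year of age is computed; driverless donors whose
rate strictly exceeds that median are additionally called CH by the
rate-threshold basis.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import CHCall, CompendiumGene, DonorProfile, VariantCall

logger = logging.getLogger(__name__)

#: Cumulative-bar ordering of classification bases (highest priority first).
BASIS_ORDER = (
    "known_gene_germline_calling",
    "known_gene_reverse_calling",
    "discovered_gene",
    "targeted_gene",
    "rate_threshold",
)

NONSILENT = {"nonsilent", "missense", "nonsense", "frameshift", "splice",
             "inframe_indel"}


def discovery_input_filter(calls: Sequence[VariantCall]) -> list[VariantCall]:
    """Drop calls with VAF strictly above 0.4 before driver discovery."""
    return [c for c in calls if c.vaf <= 0.4]


def expression_vetting(expression_values: Sequence[float], cutoff: float = 15.0) -> bool:
    """A gene counts as expressed when the maximum fpkm across cells is
    strictly above the cutoff (default 15 fpkm)."""
    values = list(expression_values)
    if not values:
        raise ValueError("no expression values supplied")
    return max(values) > cutoff


def hsc_rate_per_year(hsc_exposure: float, age: float) -> float:
    """Hematopoiesis mutations per year of age: HSC exposure / age."""
    if age <= 0:
        raise ValueError("age must be positive")
    return hsc_exposure / age


def _basis_for(call: VariantCall, tier: str) -> str:
    if tier == "known_CH":
        return ("known_gene_germline_calling" if call.germline_called
                else "known_gene_reverse_calling")
    if tier in ("myeloid_driver", "discovered_primary_metastasis"):
        return "discovered_gene"
    return "targeted_gene"  # discovered_targeted


def classify_cohort(
    donors: Sequence[DonorProfile],
    calls: Mapping[str, Sequence[VariantCall]],
    compendium: Sequence[CompendiumGene],
    hsc_exposures: Mapping[str, float],
) -> tuple[list[CHCall], dict[str, int]]:
    """Classify every donor and report cumulative per-basis counts.

    ``calls`` maps donor_id to that donor's filtered blood calls;
    ``hsc_exposures`` maps donor_id to the fitted HSC-signature exposure
    (mutation count). Returns (per-donor CH calls, cumulative counts in the
    BASIS_ORDER tier ordering).
    """
    tiers = {g.symbol: g.tier for g in compendium}
    priority = {b: i for i, b in enumerate(BASIS_ORDER)}

    provisional: list[CHCall] = []
    driver_rates: list[float] = []
    for d in donors:
        rate = hsc_rate_per_year(hsc_exposures.get(d.donor_id, 0.0), d.age)
        driver_muts = [
            c for c in calls.get(d.donor_id, ())
            if c.gene in tiers and (c.consequence in NONSILENT)
        ]
        if driver_muts:
            basis = min(
                (_basis_for(c, tiers[c.gene]) for c in driver_muts),
                key=priority.__getitem__,
            )
            provisional.append(CHCall(d.donor_id, True, basis, driver_muts, rate))
            driver_rates.append(rate)
        else:
            provisional.append(CHCall(d.donor_id, False, "none", [], rate))

    median_rate: Optional[float] = None
    if driver_rates:
        median_rate = float(np.median(driver_rates))
    else:
        logger.warning("no driver-mutated donors: rate-threshold rule skipped")

    final: list[CHCall] = []
    for call in provisional:
        if (not call.is_CH and median_rate is not None
                and call.hsc_rate_per_year > median_rate):
            call = CHCall(call.donor_id, True, "rate_threshold", [],
                          call.hsc_rate_per_year)
        final.append(call)

    cumulative: dict[str, int] = {}
    running = 0
    for basis in BASIS_ORDER:
        running += sum(1 for c in final if c.basis == basis)
        cumulative[basis] = running
    return final, cumulative


def cooccurrence(donor_gene_matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Jaccard index and co-mutation frequency of gene columns.

    Input is a binary donors x genes matrix. The Jaccard index of a pair
    involving a gene mutated in zero donors is reported as NaN.
    """
    M = donor_gene_matrix.astype(bool)
    genes = list(M.columns)
    n = len(M)
    jac = pd.DataFrame(np.nan, index=genes, columns=genes, dtype=float)
    freq = pd.DataFrame(0.0, index=genes, columns=genes, dtype=float)
    mutated = {g: int(M[g].sum()) for g in genes}
    for a in genes:
        for b in genes:
            inter = int((M[a] & M[b]).sum())
            union = int((M[a] | M[b]).sum())
            if mutated[a] > 0 and mutated[b] > 0:
                jac.loc[a, b] = inter / union
            freq.loc[a, b] = inter / n if n else 0.0
    return jac, freq


def mutation_multiplicity(donor_gene_matrix: pd.DataFrame) -> pd.Series:
    """Fraction of mutated donors by number of mutated compendium genes."""
    counts = donor_gene_matrix.astype(bool).sum(axis=1)
    counts = counts[counts >= 1]
    if counts.empty:
        return pd.Series(dtype=float)
    hist = counts.value_counts().sort_index()
    return hist / hist.sum()
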