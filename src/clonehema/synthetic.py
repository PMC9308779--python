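"""Synthetic paired blood/tumor cohorts with the structure the analysis assumes.

The real study data (dbGaP/HMF paired samples) are access-controlled, so the
downstream stages are exercised on simulated cohorts that reproduce the
generative assumptions of the analysis:

* CH donors carry one driver mutation at a configurable hotspot plus
  hitchhiking passenger mutations drawn from the HSC signature, at a VAF of
  clone_fraction / 2 (heterozygous mutations in the expanded clone), with an
  expected passenger count of ``age * hsc_rate``;
* non-CH donors carry only sequencing-artifact mutations and germline-variant
  leakage;
* germline leaks are present in both the blood and the tumor call set (the
  reverse-calling premise is that tumor-shared variants are germline);
* read support is Binomial(depth, VAF) with depth ~ Poisson(mean_depth).

Ground truth is stored on the donor separately from the emitted call sets so
the pipeline cannot see it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from . import io as chio
from .channels import CHANNELS, COMPLEMENT, revcomp
from .reference import artifact_profiles, hsc_like_profile
from .types import DonorProfile, SignatureProfile, VariantCall

_SEXES = ("female", "male")
_CANCER_TYPES = ("breast", "lung", "colorectal", "prostate", "melanoma")
TREATMENT_CLASSES = ("cytotoxic", "non_cytotoxic", "platinum")


@dataclass(frozen=True)
class DriverHotspot:
    """A named driver hotspot locus on the synthetic genome.

    Gene symbols imitate recurrent CH hotspots (DNMT3A R882H, JAK2 V617F) in
    name only; coordinates live on the synthetic reference.
    """

    gene: str
    chrom: str
    pos: int  # 1-based


DEFAULT_DRIVERS = (
    DriverHotspot("DNMT3A", "1", 25_000),
    DriverHotspot("JAK2", "2", 50_000),
)


@dataclass
class CohortConfig:
    n_donors: int = 300
    age_range: tuple[float, float] = (30, 80)
    ch_prevalence: float = 0.15
    #: detectable clone-amplified HSC mutations per year of donor age
    hsc_rate: float = 1.0
    clone_fraction_range: tuple[float, float] = (0.05, 0.4)
    mean_depth: float = 40.0
    germline_leak_rate: float = 5.0
    #: (profile, (min,max) mutations per donor) per artifact signature
    artifact_signatures: list[tuple[SignatureProfile, tuple[int, int]]] = field(
        default_factory=lambda: [(p, (10, 60)) for p in artifact_profiles()]
    )
    #: fraction of donors whose artifact burden is inflated (unreliable,
    #: hypermutator-like samples that the 97.5th-percentile burden exclusion
    #: downstream exists to remove) and the burden multiplier range
    hypermutator_rate: float = 0.03
    hypermutator_boost: tuple[float, float] = (10.0, 30.0)
    driver_genes: tuple[DriverHotspot, ...] = DEFAULT_DRIVERS
    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 150_000, "2": 150_000}
    )

    def __post_init__(self) -> None:
        if not (0.0 <= self.ch_prevalence <= 1.0):
            raise ValueError("ch_prevalence must be in [0,1]")
        lo, hi = self.clone_fraction_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("clone fractions must be in (0,1]")
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")
        if self.age_range[0] <= 0:
            raise ValueError("ages must be positive")


class SyntheticReference:
    """A seeded random genome with trinucleotide-context lookup.

    Provides ``context(chrom, pos)`` (the reference 3-mer centered on a
    1-based position) and sampling of positions whose context matches a
    requested trinucleotide, which lets the simulator place channel-assigned
    mutations consistently with catalog construction downstream.
    """

    def __init__(self, chrom_lengths: dict[str, int], seed: int):
        rng = np.random.default_rng([seed, 0xC0FFEE])
        self.chrom_lengths = dict(chrom_lengths)
        self.sequences: dict[str, str] = {}
        self._by_context: dict[str, list[tuple[str, int]]] = {}
        bases = np.array(list("ACGT"))
        for chrom, length in self.chrom_lengths.items():
            seq = "".join(bases[rng.integers(0, 4, size=length)])
            self.sequences[chrom] = seq
            for i in range(1, length - 1):  # centers, 0-based
                tri = seq[i - 1 : i + 2]
                self._by_context.setdefault(tri, []).append((chrom, i + 1))

    def context(self, chrom: str, pos: int) -> str:
        seq = self.sequences[chrom]
        if not (2 <= pos <= len(seq) - 1):
            raise ValueError(f"position {pos} has no full trinucleotide context")
        return seq[pos - 2 : pos + 1]

    def base(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos - 1]

    def sample_position(self, trinucleotide: str, rng: np.random.Generator) -> tuple[str, int]:
        sites = self._by_context.get(trinucleotide)
        if not sites:
            raise ValueError(f"no site with context {trinucleotide}")
        return sites[rng.integers(len(sites))]


@dataclass
class Cohort:
    config: CohortConfig
    donors: list[DonorProfile]
    reference: Optional[SyntheticReference] = None

    def context_provider(self):
        ref = self.reference
        return lambda chrom, pos: ref.context(chrom, pos)


def sample_mutations_from_signature(
    profile: Union[SignatureProfile, np.ndarray],
    n: int,
    context_weights: Optional[np.ndarray] = None,
    rng_seed: Union[int, np.random.Generator] = 0,
) -> np.ndarray:
    """Draw ``n`` channel assignments from a 96-channel signature.

    ``context_weights`` scales each channel by the genome availability of its
    trinucleotide context (uniform by default). Returns an int array of
    channel indices, length exactly ``n``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    probs = profile.probs if isinstance(profile, SignatureProfile) else np.asarray(profile, float)
    if probs.shape != (96,):
        raise ValueError("profile must have 96 channels")
    if (probs < 0).any():
        raise ValueError("profile has negative entries")
    total = probs.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError("profile must sum to 1")
    w = probs.copy()
    if context_weights is not None:
        w = w * np.asarray(context_weights, float)
        if w.sum() <= 0:
            raise ValueError("context weights annihilate the profile")
    w = w / w.sum()
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    counts = rng.multinomial(n, w)
    return np.repeat(np.arange(96), counts)


def _channel_site(
    channel: int, reference: SyntheticReference, rng: np.random.Generator
) -> tuple[str, int, str, str]:
    """Place a channel on the genome: (chrom, pos, ref, alt), 1-based."""
    label = CHANNELS[channel]  # e.g. "A[C>T]G"
    tri = label[0] + label[2] + label[6]
    alt = label[4]
    if rng.random() < 0.5:  # purine strand: exercise reverse-complement collapse
        tri, alt = revcomp(tri), COMPLEMENT[alt]
    chrom, pos = reference.sample_position(tri, rng)
    return chrom, pos, tri[1], alt


def _read_support(
    vaf_true: float, mean_depth: float, rng: np.random.Generator
) -> tuple[int, int]:
    depth = max(1, int(rng.poisson(mean_depth)))
    alt = int(rng.binomial(depth, vaf_true))
    return alt, depth


def simulate_donor(config: CohortConfig, donor_index: int,
                   reference: Optional[SyntheticReference] = None) -> DonorProfile:
    """Simulate one donor with paired blood and tumor-reference call sets."""
    if reference is None:
        reference = SyntheticReference(config.chrom_lengths, config.seed)
    rng = np.random.default_rng([config.seed, 1 + donor_index])
    donor_id = f"D{donor_index:04d}"

    age = float(rng.integers(int(config.age_range[0]), int(config.age_range[1]) + 1))
    sex = _SEXES[rng.integers(2)]
    cancer_type = _CANCER_TYPES[rng.integers(len(_CANCER_TYPES))]
    treatments = set()
    if rng.random() < 0.4:
        treatments.add("cytotoxic")
        if rng.random() < 0.5:
            treatments.add("platinum")
    if rng.random() < 0.5:
        treatments.add("non_cytotoxic")

    is_ch = bool(rng.random() < config.ch_prevalence)
    used: set[tuple[str, int]] = set()
    blood: list[VariantCall] = []
    tumor: list[VariantCall] = []

    def place(channel: int) -> Optional[tuple[str, int, str, str]]:
        for _ in range(20):
            chrom, pos, ref_b, alt_b = _channel_site(channel, reference, rng)
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                return chrom, pos, ref_b, alt_b
        return None

    is_hyper = bool(rng.random() < config.hypermutator_rate)
    truth: dict = {"is_CH": is_ch, "driver_gene": "", "clone_fraction": 0.0,
                   "true_hsc_count": 0, "is_hypermutator": is_hyper}

    hsc = hsc_like_profile()
    if is_ch:
        lo, hi = config.clone_fraction_range
        clone_fraction = float(rng.uniform(lo, hi))
        vaf_clone = clone_fraction / 2.0
        hotspot = config.driver_genes[rng.integers(len(config.driver_genes))]
        ref_b = reference.base(hotspot.chrom, hotspot.pos)
        alt_b = "ACGT"[("ACGT".index(ref_b) + 1) % 4]
        used.add((hotspot.chrom, hotspot.pos))
        alt, depth = _read_support(vaf_clone, config.mean_depth, rng)
        if alt >= 1:
            blood.append(VariantCall(
                chrom=hotspot.chrom, pos=hotspot.pos, ref=ref_b, alt=alt_b,
                alt_reads=alt, depth=depth, vaf=alt / depth, caller_pass=True,
                sample_id=donor_id, gene=hotspot.gene, consequence="nonsilent",
            ))
        n_hsc = int(rng.poisson(age * config.hsc_rate))
        truth.update(driver_gene=hotspot.gene, clone_fraction=clone_fraction,
                     true_hsc_count=n_hsc)
        for ch in sample_mutations_from_signature(hsc, n_hsc, rng_seed=rng):
            site = place(int(ch))
            if site is None:
                continue
            chrom, pos, r, a = site
            alt, depth = _read_support(vaf_clone, config.mean_depth, rng)
            if alt < 1:
                continue
            blood.append(VariantCall(
                chrom=chrom, pos=pos, ref=r, alt=a, alt_reads=alt, depth=depth,
                vaf=alt / depth, caller_pass=bool(rng.random() < 0.97),
                sample_id=donor_id, consequence="noncoding",
            ))

    for profile, (lo_n, hi_n) in config.artifact_signatures:
        n_art = int(rng.integers(lo_n, hi_n + 1))
        if is_hyper:
            n_art = int(n_art * rng.uniform(*config.hypermutator_boost))
        for ch in sample_mutations_from_signature(profile, n_art, rng_seed=rng):
            site = place(int(ch))
            if site is None:
                continue
            chrom, pos, r, a = site
            vaf_true = float(rng.uniform(0.05, 0.25))
            alt, depth = _read_support(vaf_true, config.mean_depth, rng)
            if alt < 1:
                continue
            blood.append(VariantCall(
                chrom=chrom, pos=pos, ref=r, alt=a, alt_reads=alt, depth=depth,
                vaf=alt / depth, caller_pass=bool(rng.random() < 0.9),
                sample_id=donor_id, consequence="noncoding",
            ))

    n_leak = int(rng.poisson(config.germline_leak_rate))
    for _ in range(n_leak):
        ch = int(rng.integers(96))
        site = place(ch)
        if site is None:
            continue
        chrom, pos, r, a = site
        alt, depth = _read_support(0.5, config.mean_depth, rng)
        if alt < 1:
            continue
        call = VariantCall(
            chrom=chrom, pos=pos, ref=r, alt=a, alt_reads=alt, depth=depth,
            vaf=alt / depth, caller_pass=True, sample_id=donor_id,
            consequence="noncoding", germline_called=True,
        )
        blood.append(call)
        t_alt, t_depth = _read_support(0.5, config.mean_depth, rng)
        t_alt = max(1, t_alt)
        tumor.append(call.with_(alt_reads=t_alt, depth=t_depth,
                                vaf=t_alt / t_depth))

    order = {name: i for i, name in enumerate(config.chrom_lengths)}
    blood.sort(key=lambda c: (order[c.chrom], c.pos))
    tumor.sort(key=lambda c: (order[c.chrom], c.pos))
    return DonorProfile(
        donor_id=donor_id, age=age, sex=sex, cancer_type=cancer_type,
        treatments=frozenset(treatments), cohort="metastasis",
        blood_calls=blood, tumor_calls=tumor, truth=truth,
    )


def simulate_cohort(config: CohortConfig) -> Cohort:
    reference = SyntheticReference(config.chrom_lengths, config.seed)
    donors = [simulate_donor(config, i, reference) for i in range(config.n_donors)]
    return Cohort(config=config, donors=donors, reference=reference)


def save_config(config: CohortConfig, path: str) -> None:
    """Write a CohortConfig as a YAML key-value file (artifact signatures
    are referenced by name; custom profiles are not serialized)."""
    import yaml

    data = {
        "n_donors": config.n_donors,
        "age_range": list(config.age_range),
        "ch_prevalence": config.ch_prevalence,
        "hsc_rate": config.hsc_rate,
        "clone_fraction_range": list(config.clone_fraction_range),
        "mean_depth": config.mean_depth,
        "germline_leak_rate": config.germline_leak_rate,
        "hypermutator_rate": config.hypermutator_rate,
        "hypermutator_boost": list(config.hypermutator_boost),
        "artifact_burden_ranges": [list(r) for _, r in config.artifact_signatures],
        "driver_genes": [{"gene": d.gene, "chrom": d.chrom, "pos": d.pos}
                         for d in config.driver_genes],
        "seed": config.seed,
        "chrom_lengths": dict(config.chrom_lengths),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_config(path: str) -> CohortConfig:
    """Read a YAML key-value file written by :func:`save_config`."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    profiles = artifact_profiles()
    ranges = data.pop("artifact_burden_ranges",
                      [[10, 60]] * len(profiles))
    data["artifact_signatures"] = [
        (p, tuple(r)) for p, r in zip(profiles, ranges)
    ]
    data["age_range"] = tuple(data["age_range"])
    data["clone_fraction_range"] = tuple(data["clone_fraction_range"])
    data["hypermutator_boost"] = tuple(data["hypermutator_boost"])
    data["driver_genes"] = tuple(
        DriverHotspot(d["gene"], str(d["chrom"]), int(d["pos"]))
        for d in data["driver_genes"]
    )
    return CohortConfig(**data)


def planted_mixture_catalogs(
    n_samples: int = 300,
    n_mutations: tuple[int, int] = (150, 500),
    hsc_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[list["MutationCatalog"], "SignatureProfile", list[SignatureProfile]]:
    """SBS96 catalogs mixing the HSC-like profile with two artifact profiles.

    Each sample draws 150-500 mutations; the HSC-signature share averages
    ``hsc_fraction`` but varies per sample (uniform on hsc_fraction +- 0.2),
    with the remainder split randomly between the two artifact profiles —
    per-sample variation in signature activity is what makes the mixture
    identifiable to NMF, as in real cohorts where clone sizes and artifact
    burdens differ between donors. Returns (catalogs, HSC profile, artifact
    profiles).
    """
    from .types import MutationCatalog

    rng = np.random.default_rng([seed, 0x516])
    hsc = hsc_like_profile()
    arts = artifact_profiles()
    catalogs = []
    for i in range(n_samples):
        n = int(rng.integers(n_mutations[0], n_mutations[1] + 1))
        fh = float(rng.uniform(hsc_fraction - 0.2, hsc_fraction + 0.2))
        split = float(rng.uniform(0.0, 1.0))
        n_h = int(round(fh * n))
        n_1 = int(round((1 - fh) * split * n))
        n_2 = n - n_h - n_1
        counts = (
            rng.multinomial(n_h, hsc.probs)
            + rng.multinomial(n_1, arts[0].probs)
            + rng.multinomial(n_2, arts[1].probs)
        )
        catalogs.append(MutationCatalog(f"S{i:04d}", counts))
    return catalogs, hsc, arts


# ---------------------------------------------------------------- persistence


def write_cohort(cohort: Cohort, out_dir: str) -> None:
    """Write per-donor VCF pairs plus metadata and truth TSVs."""
    if not cohort.donors:
        raise ValueError("cannot write an empty cohort")
    chio.ensure_dir(out_dir)
    contigs = cohort.config.chrom_lengths
    meta_rows, truth_rows = [], []
    for d in cohort.donors:
        chio.write_vcf(d.blood_calls, f"{out_dir}/{d.donor_id}.blood.vcf",
                       d.donor_id, contigs)
        chio.write_vcf(d.tumor_calls, f"{out_dir}/{d.donor_id}.tumor.vcf",
                       d.donor_id, contigs)
        row = {"donor_id": d.donor_id, "age": d.age, "sex": d.sex,
               "cancer_type": d.cancer_type, "cohort": d.cohort}
        for t in TREATMENT_CLASSES:
            row[t] = t in d.treatments
        meta_rows.append(row)
        t = d.truth or {}
        truth_rows.append({
            "donor_id": d.donor_id,
            "is_CH": t.get("is_CH", False),
            "driver_gene": t.get("driver_gene", ""),
            "clone_fraction": t.get("clone_fraction", 0.0),
            "true_hsc_count": t.get("true_hsc_count", 0),
            "is_hypermutator": t.get("is_hypermutator", False),
        })
    import pandas as pd

    pd.DataFrame(meta_rows).to_csv(f"{out_dir}/metadata.tsv", sep="\t", index=False)
    pd.DataFrame(truth_rows).to_csv(f"{out_dir}/truth.tsv", sep="\t",
                                    index=False, float_format="%.17g")


def read_cohort(out_dir: str) -> Cohort:
    """Round-trip read of :func:`write_cohort` output (no reference genome)."""
    import pandas as pd

    meta = pd.read_csv(f"{out_dir}/metadata.tsv", sep="\t")
    truth = pd.read_csv(f"{out_dir}/truth.tsv", sep="\t",
                        float_precision="round_trip").set_index("donor_id")
    donors = []
    for r in meta.itertuples():
        t = truth.loc[r.donor_id]
        driver = t.driver_gene if isinstance(t.driver_gene, str) else ""
        donors.append(DonorProfile(
            donor_id=r.donor_id, age=float(r.age), sex=r.sex,
            cancer_type=r.cancer_type, cohort=r.cohort,
            treatments=frozenset(t for t in TREATMENT_CLASSES if getattr(r, t)),
            blood_calls=chio.read_vcf(f"{out_dir}/{r.donor_id}.blood.vcf"),
            tumor_calls=chio.read_vcf(f"{out_dir}/{r.donor_id}.tumor.vcf"),
            truth={"is_CH": bool(t.is_CH), "driver_gene": driver,
                   "clone_fraction": float(t.clone_fraction),
                   "true_hsc_count": int(t.true_hsc_count),
                   "is_hypermutator": bool(t.is_hypermutator)},
        ))
    return Cohort(config=CohortConfig(n_donors=len(donors)), donors=donors)
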