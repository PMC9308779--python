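"""Reverse-calling filter cascade: step semantics, oracles, invariants."""

from __future__ import annotations

import numpy as np
import pytest
from intervaltree import IntervalTree

from clonehema import filtering
from clonehema.filtering import (
    CascadeResources,
    FrequencyResource,
    MaskSet,
    basic_filters,
    common_snp_filter,
    hypermutator_filter,
    intersect_callsets,
    mask_filter,
    merge_dbs,
    pon_filter,
    run_cascade,
)

from conftest import make_call, random_calls


# ---------------------------------------------------------------- basic


@pytest.mark.parametrize(
    "alt_reads,vaf,caller_pass,kept",
    [
        (2, 0.49, True, True),   # minimal read support, sub-germline VAF
        (1, 0.10, True, False),  # below support threshold
        (2, 0.50, True, False),  # VAF < 0.5 is strict
        (10, 0.25, False, False),  # caller did not PASS
        (None, 0.25, True, False),  # missing read support rejected
    ],
)
def test_basic_filter_boundaries(alt_reads, vaf, caller_pass, kept):
    depth = None if alt_reads is None else 100
    c = make_call(alt_reads=alt_reads, depth=depth, vaf=vaf,
                  caller_pass=caller_pass)
    assert (c in basic_filters([c])) == kept


# ---------------------------------------------------------------- masks


def _trees(*ivs):
    out: dict[str, IntervalTree] = {}
    for chrom, s, e in ivs:
        out.setdefault(chrom, IntervalTree()).addi(s, e)
    return out


def test_mask_coordinate_convention():
    # 1-based variant position 100 is the 0-based point 99, inside [99, 100)
    masks = MaskSet(low_mappability=_trees(("1", 99, 100)))
    assert mask_filter([make_call(pos=100)], masks, ["low_mappability"]) == []
    assert mask_filter([make_call(pos=99)], masks, ["low_mappability"]) != []


def test_empty_maskset_is_identity():
    calls = [make_call(pos=p) for p in (5, 50, 500)]
    assert mask_filter(calls, MaskSet()) == calls


def test_mask_filter_matches_naive_interval_scan():
    rng = np.random.default_rng(42)
    calls = random_calls(rng, 1000)
    intervals = [(str(rng.integers(1, 3)), int(s), int(s + rng.integers(1, 50)))
                 for s in rng.integers(0, 10_000, size=60)]
    masks = MaskSet(segdup=_trees(*intervals))

    def naive_hit(c):
        p0 = c.pos - 1
        return any(ch == c.chrom and s < p0 + 1 and p0 < e
                   for ch, s, e in intervals)

    expected = [c for c in calls if not naive_hit(c)]
    assert mask_filter(calls, masks, ["segdup"]) == expected


# ---------------------------------------------------------------- DBS merge


def test_adjacent_snvs_merge_into_dbs():
    a = make_call(pos=10, ref="C", alt="T", vaf=0.2)
    b = make_call(pos=11, ref="G", alt="A", vaf=0.3)
    (merged,) = merge_dbs([a, b])
    assert (merged.ref, merged.alt, merged.pos) == ("CG", "TA", 10)
    assert merged.vaf == pytest.approx(0.25)


def test_non_adjacent_and_cross_sample_snvs_not_merged():
    assert len(merge_dbs([make_call(pos=10), make_call(pos=12)])) == 2
    assert len(merge_dbs([make_call(pos=10, sample_id="A"),
                          make_call(pos=11, sample_id="B")])) == 2


def test_triplet_merges_left_greedy():
    calls = [make_call(pos=p) for p in (10, 11, 12)]
    out = sorted(merge_dbs(calls), key=lambda c: c.pos)
    assert [(c.pos, len(c.ref)) for c in out] == [(10, 2), (12, 1)]


def test_merge_count_matches_adjacency_enumeration():
    rng = np.random.default_rng(7)
    for _ in range(20):
        calls = random_calls(rng, 200, chrom_len=300)  # dense -> adjacencies
        # oracle: left-greedy pair count per (sample, chrom) position run
        keys = sorted({(c.sample_id, c.chrom, c.pos) for c in calls})
        n_pairs = 0
        by_group: dict[tuple, list[int]] = {}
        for s, ch, p in keys:
            by_group.setdefault((s, ch), []).append(p)
        dedup = {k: sorted(set(v)) for k, v in by_group.items()}
        for positions in dedup.values():
            i = 0
            while i < len(positions) - 1:
                if positions[i + 1] == positions[i] + 1:
                    n_pairs += 1
                    i += 2
                else:
                    i += 1
        # dedupe calls at identical keys for the comparison
        uniq = list({(c.sample_id, c.chrom, c.pos): c for c in calls}.values())
        merged = merge_dbs(uniq)
        assert len(merged) == len(uniq) - n_pairs
        assert sum(1 for c in merged if len(c.ref) == 2) == n_pairs


# ---------------------------------------------------------------- PoN / SNP


def _res(label, **freqs):
    return FrequencyResource(label, {k: v for k, v in freqs.items()})


def test_population_cutoffs_are_strict():
    site = ("1", 100, "C", "T")
    c = make_call()
    gnomad = FrequencyResource("gnomAD", {site: 0.0004})
    assert pon_filter([c], None, population=[gnomad]) == []
    hmf = FrequencyResource("PoN_HMF", {site: 0.008})  # exactly the cutoff
    assert pon_filter([c], None, population=[hmf]) == [c]


def test_hotspot_relative_pon_threshold():
    hotspot = ("2", 25_000, "C", "T")
    common = ("1", 100, "C", "T")
    pon = FrequencyResource("PoN_HMF", {hotspot: 0.004, common: 0.0041})
    c = make_call()
    assert pon_filter([c], pon, hotspot_keys=[hotspot]) == []
    pon_tie = FrequencyResource("PoN_HMF", {hotspot: 0.004, common: 0.004})
    assert pon_filter([c], pon_tie, hotspot_keys=[hotspot]) == [c]


def test_variant_absent_from_resources_is_kept():
    c = make_call()
    assert pon_filter([c], FrequencyResource("PoN_TCGA", {}),
                      population=[FrequencyResource("gnomAD", {})]) == [c]


def test_unknown_resource_label_fails():
    with pytest.raises(KeyError):
        pon_filter([make_call()], None,
                   population=[FrequencyResource("mystery", {})])


def test_common_snp_filter_is_allele_aware():
    snps = [FrequencyResource("common_snp", {("1", 100, "C", "T"): 0.1})]
    assert common_snp_filter([make_call(alt="T")], snps) == []
    kept = common_snp_filter([make_call(alt="G")], snps)
    assert len(kept) == 1


def test_common_snp_filter_matches_set_lookup():
    rng = np.random.default_rng(3)
    calls = random_calls(rng, 500)
    listed = {c.site_key for c in calls[::3]}
    snps = [FrequencyResource("common_snp", {k: 0.5 for k in listed})]
    expected = [c for c in calls if c.site_key not in listed]
    assert common_snp_filter(calls, snps) == expected


# ---------------------------------------------------------------- hypermutator


def test_hypermutator_removes_extreme_sample():
    counts = {f"S{i}": 10 for i in range(39)}
    counts["HYP"] = 1000
    retained, removed, _ = hypermutator_filter(counts)
    assert removed == ["HYP"] and "HYP" not in retained


def test_equal_burdens_remove_nobody():
    counts = {f"S{i}": 7 for i in range(20)}
    retained, removed, _ = hypermutator_filter(counts)
    assert removed == [] and len(retained) == 20


def test_hypermutator_matches_sorted_percentile_oracle():
    counts = {f"S{i}": i + 1 for i in range(1000)}
    # oracle: linear-interpolation percentile computed by hand
    vals = sorted(counts.values())
    pos = 0.975 * (len(vals) - 1)
    lo = int(np.floor(pos))
    p975 = vals[lo] + (pos - lo) * (vals[lo + 1] - vals[lo])
    expected = sorted(s for s, n in counts.items() if n > p975)
    _, removed, thresh = hypermutator_filter(counts)
    assert removed == expected
    assert thresh == pytest.approx(p975)


def test_single_sample_cohort_not_excluded():
    retained, removed, _ = hypermutator_filter({"only": 999})
    assert retained == {"only"} and removed == []


# ---------------------------------------------------------------- intersection


def test_intersection_identity_and_empty():
    rng = np.random.default_rng(5)
    full = random_calls(rng, 50)
    assert intersect_callsets(full, full, "mutect").calls == full
    assert intersect_callsets(full, [], "mosaic").calls == []


def test_intersection_matches_nested_loop():
    rng = np.random.default_rng(6)
    full = random_calls(rng, 300)
    other = random_calls(rng, 300)
    expected = [c for c in full if any(c.key == o.key for o in other)]
    got = intersect_callsets(full, other, "mutect")
    assert got.calls == expected and got.label == "mutect"


# ---------------------------------------------------------------- cascade


def test_cascade_noop_on_clean_input():
    calls = [make_call(pos=10 * (i + 1), sample_id=f"S{i % 4}",
                       alt_reads=5, depth=40, vaf=5 / 40)
             for i in range(20)]
    full, _, _, report = run_cascade(calls)
    assert full.calls == merge_dbs(calls)  # nothing adjacent -> unchanged
    assert all(s.variants_in == s.variants_out for s in report.steps)


def test_cascade_report_counts_chain():
    rng = np.random.default_rng(11)
    calls = random_calls(rng, 400)
    _, _, _, report = run_cascade(calls)
    rows = report.as_rows()
    for (_, _, out_prev), (_, in_next, _) in zip(rows, rows[1:]):
        assert out_prev == in_next


def test_cascade_idempotent_given_recorded_threshold():
    rng = np.random.default_rng(12)
    calls = random_calls(rng, 600)
    full, _, _, report = run_cascade(calls)
    again, _, _, report2 = run_cascade(
        full.calls, hypermutator_thresh=report.hypermutator_threshold)
    assert again.calls == full.calls
    assert all(s.variants_in == s.variants_out for s in report2.steps)


def test_cascade_derives_nested_mutect_and_mosaic_catalogs():
    rng = np.random.default_rng(13)
    calls = random_calls(rng, 300)
    mutect = calls[::2]
    mosaic = calls[::4]
    full, cm, cmo, _ = run_cascade(calls, mutect_calls=mutect,
                                   mosaic_calls=mosaic)
    full_keys = {c.key for c in full.calls}
    assert cm.label == "mutect" and cmo.label == "mosaic"
    assert {c.key for c in cm.calls} == full_keys & {c.key for c in mutect}
    assert {c.key for c in cmo.calls} == full_keys & {c.key for c in mosaic}
    # calls[::4] is a subset of calls[::2], so the catalogs nest
    assert {c.key for c in cmo.calls} <= {c.key for c in cm.calls}


def test_germline_leak_recovery_with_truth_pon(small_cohort):
    """With a PoN built from the cohort's tumor call sets (the germline
    leaks, by the reverse-calling premise), >= 95% of leaked germline calls
    are removed while >= 90% of supported clone mutations survive."""
    donors = small_cohort.donors
    allcalls = [c for d in donors for c in d.blood_calls]
    site_counts: dict = {}
    for d in donors:
        for c in d.tumor_calls:
            site_counts[c.site_key] = site_counts.get(c.site_key, 0) + 1
    pon = FrequencyResource(
        "PoN_HMF", {k: v / len(donors) for k, v in site_counts.items()})
    full, _, _, rep = run_cascade(allcalls, CascadeResources(pon=pon))
    kept_keys = {c.key for c in full.calls}
    removed_samples = set(rep.removed_samples)

    leaks = [c for c in allcalls if c.germline_called and c.caller_pass
             and c.alt_reads >= 2 and c.vaf < 0.5]
    assert leaks, "fixture must contain supported germline leaks"
    leak_removed = sum(1 for c in leaks if c.key not in kept_keys)
    assert leak_removed / len(leaks) >= 0.95

    clones = [c for d in donors if d.truth["is_CH"]
              for c in d.blood_calls
              if not c.germline_called and c.caller_pass
              and c.alt_reads >= 2 and c.vaf < 0.5
              and d.donor_id not in removed_samples]
    survived = sum(1 for c in clones if c.key in kept_keys)
    assert survived / len(clones) >= 0.90


def test_cascade_aborts_with_step_name():
    bad = FrequencyResource("not_a_label", {})
    res = CascadeResources(population=[bad])
    with pytest.raises(RuntimeError, match="pon_population"):
        run_cascade([make_call()], res)
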