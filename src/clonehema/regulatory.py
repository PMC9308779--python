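"""Variant-centric TF-motif disruption/creation scanning.

Non-coding blood mutations falling inside H3K27ac peaks that overlap an
enhancer targeting a CH driver gene are expanded +-15 bp, and the binding
affinity of the reference and alternate haplotype windows is evaluated
against position weight matrices under an exact score-to-p-value map: the
null distribution of the log-odds score of a random background k-mer is
computed by dynamic-programming convolution over motif positions at a fixed
score granularity. A variant whose reference window is significant at
alpha = 1e-4 while the mutant window is not is a binding-site disruption;
the opposite pattern is a creation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .channels import revcomp
from .types import VariantCall

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
DEFAULT_ALPHA = 1e-4
DEFAULT_GRANULARITY = 1e-3
DEFAULT_PSEUDOCOUNT = 0.001


@dataclass
class PWM:
    """Position weight matrix with background model.

    ``matrix`` is positions x 4 (A,C,G,T) base probabilities; rows sum to 1.
    A pseudocount is added to every cell (rows renormalized) before taking
    log2 odds against the background.
    """

    tf_name: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be positions x 4")
        if self.matrix.shape[0] < 1:
            raise ValueError("PWM must have at least one position")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must sum to 1")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        if (self.background <= 0).any() and self.pseudocount <= 0:
            raise ValueError("zero background frequency requires a pseudocount")

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])

    def log_odds(self) -> np.ndarray:
        """log2((p + pc)/sum vs background), positions x 4."""
        p = self.matrix + self.pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        bg = self.background + (self.pseudocount if (self.background <= 0).any() else 0.0)
        bg = bg / bg.sum()
        return np.log2(p / bg)


@dataclass
class ScorePValueTable:
    """Exact map from quantized log-odds score to p-value.

    ``int_scores`` are the per-position per-base scores in granularity
    units; ``tail[i]`` is P(random background k-mer scores >= min_total + i).
    """

    granularity: float
    int_scores: np.ndarray  # positions x 4, int64
    min_total: int
    tail: np.ndarray

    def pvalue_int(self, int_score: int) -> float:
        i = int_score - self.min_total
        if i <= 0:
            return 1.0
        if i >= len(self.tail):
            return 0.0
        return float(self.tail[i])

    def pvalue(self, score: float) -> float:
        return self.pvalue_int(int(round(score / self.granularity)))


def score_pvalue_table(
    pwm: PWM, granularity: float = DEFAULT_GRANULARITY
) -> ScorePValueTable:
    """DP convolution of per-position score distributions under the
    background model; p(s) = P(score >= s), monotone non-increasing."""
    lod = pwm.log_odds()
    ints = np.round(lod / granularity).astype(np.int64)
    bg = pwm.background / pwm.background.sum()

    min_total = int(ints.min(axis=1).sum())
    max_total = int(ints.max(axis=1).sum())
    dist = np.zeros(max_total - min_total + 1)
    # running support is [cur_min, cur_min + len - 1]
    cur_min = 0
    cur = np.array([1.0])
    for row in ints:
        lo, hi = int(row.min()), int(row.max())
        new = np.zeros(len(cur) + hi - lo)
        for b in range(4):
            off = int(row[b]) - lo
            new[off:off + len(cur)] += cur * bg[b]
        cur = new
        cur_min += lo
    dist[: len(cur)] = cur  # cur_min == min_total by construction
    tail = np.cumsum(dist[::-1])[::-1]
    return ScorePValueTable(
        granularity=granularity, int_scores=ints, min_total=min_total, tail=tail
    )


def _best_pvalue(table: ScorePValueTable, window: str) -> Optional[float]:
    """Minimum p-value over all offsets and both strands; None if the window
    is shorter than the motif."""
    L = table.int_scores.shape[0]
    best: Optional[float] = None
    for seq in (window.upper(), revcomp(window)):
        n = len(seq)
        if n < L:
            continue
        for off in range(n - L + 1):
            kmer = seq[off:off + L]
            if any(b not in _BASE_IDX for b in kmer):
                continue
            s = int(sum(table.int_scores[i, _BASE_IDX[b]]
                        for i, b in enumerate(kmer)))
            p = table.pvalue_int(s)
            if best is None or p < best:
                best = p
    return best


def scan_variant(
    pwm: PWM,
    ref_window: str,
    alt_window: str,
    table: Optional[ScorePValueTable] = None,
    granularity: float = DEFAULT_GRANULARITY,
) -> Optional[tuple[float, float]]:
    """(p_ref, p_alt): best match p-value of each haplotype window against
    the motif, over all offsets and both strands. None when the windows are
    shorter than the motif (motif skipped for this variant)."""
    if table is None:
        table = score_pvalue_table(pwm, granularity)
    p_ref = _best_pvalue(table, ref_window)
    p_alt = _best_pvalue(table, alt_window)
    if p_ref is None or p_alt is None:
        return None
    return p_ref, p_alt


def classify_binding_change(
    p_ref: float, p_alt: float, alpha: float = DEFAULT_ALPHA
) -> str:
    """Disruption when only the reference binds significantly; creation when
    only the mutant does; otherwise none."""
    if p_ref < alpha <= p_alt:
        return "disruption"
    if p_alt < alpha <= p_ref:
        return "creation"
    return "none"


@dataclass
class BindingEvent:
    variant_key: tuple
    tf_name: str
    p_ref: float
    p_alt: float
    verdict: str
    target_gene: Optional[str] = None


def variant_windows(
    variant: VariantCall,
    sequence_provider,
    flank: int = 15,
) -> tuple[str, str]:
    """Reference and alternate haplotype windows, variant +-``flank`` bp.

    ``sequence_provider(chrom, start, end)`` returns the reference sequence
    over the 1-based inclusive range; the alternate window substitutes the
    alternate base at the variant position.
    """
    start = variant.pos - flank
    end = variant.pos + flank
    ref_win = sequence_provider(variant.chrom, start, end)
    mid = variant.pos - start
    alt_win = ref_win[:mid] + variant.alt + ref_win[mid + len(variant.ref):]
    return ref_win, alt_win


def filter_regulatory_context(
    mutations: Sequence[VariantCall],
    h3k27ac: Mapping[str, IntervalTree],
    enhancers: Mapping[str, IntervalTree],
    expressed_tfs: Iterable[str],
    compendium_genes: Iterable[str],
) -> tuple[list[dict], int]:
    """Build the motif-scan worklist.

    A mutation qualifies when it falls inside an H3K27ac peak AND an
    enhancer whose annotated target gene belongs to the CH driver
    compendium; qualifying mutations are scanned only against TFs expressed
    in CD34+ cells. Returns (worklist, count of enhancer hits skipped for a
    missing target-gene annotation).
    """
    tfs = sorted(set(expressed_tfs))
    compendium = set(compendium_genes)
    worklist: list[dict] = []
    skipped_no_target = 0
    for m in mutations:
        p0 = m.pos - 1
        peaks = h3k27ac.get(m.chrom)
        if peaks is None or not peaks.overlap(p0, p0 + 1):
            continue
        enh_tree = enhancers.get(m.chrom)
        if enh_tree is None:
            continue
        targets = set()
        for iv in enh_tree.overlap(p0, p0 + 1):
            if iv.data is None:
                skipped_no_target += 1
                continue
            targets.add(iv.data)
        targets &= compendium
        for gene in sorted(targets):
            worklist.append({"mutation": m, "target_gene": gene, "tfs": tfs})
    return worklist, skipped_no_target


def scan_worklist(
    worklist: Sequence[dict],
    pwms: Mapping[str, PWM],
    sequence_provider,
    alpha: float = DEFAULT_ALPHA,
    flank: int = 15,
    granularity: float = DEFAULT_GRANULARITY,
) -> list[BindingEvent]:
    """Scan every (mutation, target gene) worklist entry against the
    expressed-TF motifs and keep disruption/creation verdicts."""
    tables = {name: score_pvalue_table(p, granularity) for name, p in pwms.items()}
    events: list[BindingEvent] = []
    for entry in worklist:
        m: VariantCall = entry["mutation"]
        ref_win, alt_win = variant_windows(m, sequence_provider, flank)
        for tf in entry["tfs"]:
            if tf not in pwms:
                continue
            result = scan_variant(pwms[tf], ref_win, alt_win, table=tables[tf])
            if result is None:
                continue
            p_ref, p_alt = result
            verdict = classify_binding_change(p_ref, p_alt, alpha)
            if verdict != "none":
                events.append(BindingEvent(
                    variant_key=m.site_key, tf_name=tf, p_ref=p_ref,
                    p_alt=p_alt, verdict=verdict,
                    target_gene=entry["target_gene"],
                ))
    return events
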