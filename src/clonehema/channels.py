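"""The SBS96 channel scheme.

Single-base substitutions are classified by the pyrimidine-centric change
(C>A, C>G, C>T, T>A, T>C, T>G) and the 5'/3' flanking reference bases, in the
conventional COSMIC order: substitution-major, then 5' base, then 3' base,
each in A,C,G,T order. Purine-reference variants are reverse-complemented
onto the pyrimidine strand.
"""

from __future__ import annotations

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")

#: Channel labels like "A[C>A]A", length 96, in canonical order.
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(CHANNELS)}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def channel_of(trinucleotide: str, alt: str) -> int:
    """Channel index for a substitution.

    ``trinucleotide`` is the reference 3-mer centered on the mutated base and
    ``alt`` the alternate allele on the reference strand. Raises ValueError
    for non-ACGT context (e.g. an N) or a non-substitution.
    """
    tri = trinucleotide.upper()
    alt = alt.upper()
    if len(tri) != 3 or any(b not in "ACGT" for b in tri) or alt not in "ACGT":
        raise ValueError(f"invalid context/alt: {trinucleotide}/{alt}")
    ref = tri[1]
    if ref == alt:
        raise ValueError("ref equals alt")
    if ref in "GA":  # collapse onto the pyrimidine strand
        tri = revcomp(tri)
        alt = COMPLEMENT[alt]
        ref = tri[1]
    return CHANNEL_INDEX[f"{tri[0]}[{ref}>{alt}]{tri[2]}"]
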