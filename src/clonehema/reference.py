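"""Packaged reference signature profiles.

The profiles here are synthetic stand-ins generated deterministically in
code; no measured signature table ships with the package. They reproduce the
qualitative shape of the profiles they emulate, which is what the simulator
and the extraction tests need:

* :func:`hsc_like_profile` — the hematopoietic-stem-cell (HSC) mutational
  signature accumulated by normal HSC divisions: a broad, flat, clock-like
  profile over all channels with elevated C>T at CpG sites and a raised T>C
  component (the SBS1 + SBS5-like blood profile).
* :func:`artifact_profiles` — two sharply concentrated substitution profiles
  of the kind produced by sequencing artifacts (an oxidative-damage-like C>A
  skew and a T>A skew), dissimilar to the HSC profile (cosine < 0.4) and to
  each other.
"""

from __future__ import annotations

import numpy as np

from .channels import CHANNELS
from .types import SignatureProfile


def hsc_like_profile() -> SignatureProfile:
    """Synthetic HSC-like signature: flat background + CpG C>T + T>C."""
    w = np.ones(96)
    for i, ch in enumerate(CHANNELS):
        sub = ch[2:5]
        if sub == "T>C":
            w[i] += 2.0
        if sub == "C>T":
            w[i] += 1.5
            if ch[6] == "G":  # N[C>T]G — deamination at methylated CpG
                w[i] += 8.0
    # mild deterministic 5'-base modulation so no two channels tie exactly
    w *= 1.0 + 0.1 * np.cos(np.arange(96) * 0.7)
    return SignatureProfile.from_counts("HSC_like", w)


def _concentrated(name: str, sub: str) -> SignatureProfile:
    w = np.zeros(96)
    block = [i for i, ch in enumerate(CHANNELS) if ch[2:5] == sub]
    for rank, i in enumerate(block):
        w[i] = np.exp(-0.6 * rank)
    return SignatureProfile.from_counts(name, w)


def artifact_profiles() -> list[SignatureProfile]:
    """Two synthetic sequencing-artifact-like profiles (C>A and T>A skews)."""
    return [
        _concentrated("artifact_CA", "C>A"),
        _concentrated("artifact_TA", "T>A"),
    ]
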