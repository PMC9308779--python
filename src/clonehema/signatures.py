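"""SBS96 mutational-signature construction, extraction and refitting.

Catalog construction collapses every single-base substitution onto the
pyrimidine-centric 96-channel scheme. De novo extraction follows the
bootstrapped-NMF convention: each sample's catalog is resampled
multinomially at its own total, factorized by multiplicative-update NMF
under the generalized Kullback-Leibler objective, the per-bootstrap
solutions are clustered by cosine matching, and the number of signatures k
is chosen to maximize the mean silhouette of the clustered solutions.
Per-sample exposures (mutation counts attributed to each signature) are
refit by non-negative least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import nnls
from sklearn.metrics import silhouette_samples

from .channels import channel_of
from .types import MutationCatalog, SignatureProfile, VariantCall

logger = logging.getLogger(__name__)

_EPS = 1e-12


# ---------------------------------------------------------------- catalogs


def build_catalog(
    mutations: Sequence[VariantCall],
    context_provider: Callable[[str, int], str],
) -> tuple[dict[str, MutationCatalog], int]:
    """Per-sample SBS96 catalogs from SNV calls.

    ``context_provider(chrom, pos)`` must return the reference trinucleotide
    centered on the (1-based) variant position. Non-SNVs and variants whose
    context contains an N are skipped; the skipped count is returned so the
    catalog-sum-equals-usable-SNVs invariant can be audited.
    """
    catalogs: dict[str, np.ndarray] = {}
    skipped = 0
    for m in mutations:
        if not m.is_snv:
            skipped += 1
            continue
        try:
            tri = context_provider(m.chrom, m.pos)
            ch = channel_of(tri, m.alt)
        except (ValueError, KeyError):
            skipped += 1
            continue
        catalogs.setdefault(m.sample_id, np.zeros(96))[ch] += 1
    return (
        {s: MutationCatalog(s, v) for s, v in catalogs.items()},
        skipped,
    )


def compute_hsc_signature(
    healthy_catalogs: Sequence[MutationCatalog], name: str = "HSC"
) -> SignatureProfile:
    """Average of per-sample channel frequencies across healthy donors.

    Each donor's catalog is normalized to its own total first, so every
    donor contributes equally regardless of burden.
    """
    normalized = []
    for c in healthy_catalogs:
        if c.total <= 0:
            logger.warning("zero-total catalog %s excluded from HSC signature", c.sample_id)
            continue
        normalized.append(c.counts / c.total)
    if not normalized:
        raise ValueError("no usable catalogs")
    return SignatureProfile(name, np.mean(normalized, axis=0))


def cosine_similarity(a, b) -> float:
    """Cosine similarity between two 96-channel non-negative vectors."""
    va = a.probs if isinstance(a, SignatureProfile) else np.asarray(a, float)
    vb = b.probs if isinstance(b, SignatureProfile) else np.asarray(b, float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(va, vb) / (na * nb))


# ---------------------------------------------------------------- NMF core


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    return float(
        (V[mask] * np.log(V[mask] / np.maximum(WH[mask], _EPS))).sum()
        - V.sum() + WH.sum()
    )


def nmf_kl(
    V: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 1000,
    tol: float = 1e-6,
    objective: str = "kl",
    callback: Optional[Callable[[float], None]] = None,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Multiplicative-update NMF of V (channels x samples) at rank k.

    Minimizes the generalized KL divergence by default (``objective="fro"``
    switches to the Frobenius updates). Returns (W, H, final objective,
    converged); W columns are normalized to sum 1 with the scale absorbed
    into H, so W columns are signature probability vectors.
    """
    n, m = V.shape
    W = rng.uniform(0.1, 1.0, size=(n, k))
    H = rng.uniform(0.1, 1.0, size=(k, m))
    W /= W.sum(axis=0, keepdims=True)
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        if objective == "kl":
            WH = np.maximum(W @ H, _EPS)
            W *= (V / WH) @ H.T / np.maximum(H.sum(axis=1), _EPS)
            WH = np.maximum(W @ H, _EPS)
            H *= W.T @ (V / WH) / np.maximum(W.sum(axis=0), _EPS)[:, None]
            obj = _kl_divergence(V, np.maximum(W @ H, _EPS))
        elif objective == "fro":
            W *= (V @ H.T) / np.maximum(W @ H @ H.T, _EPS)
            H *= (W.T @ V) / np.maximum(W.T @ W @ H, _EPS)
            obj = float(np.linalg.norm(V - W @ H) ** 2)
        else:
            raise ValueError(f"unknown objective: {objective}")
        if callback is not None:
            callback(obj)
        if np.isfinite(prev) and prev - obj <= tol * max(abs(obj), 1.0):
            converged = True
            break
        prev = obj
    scale = np.maximum(W.sum(axis=0), _EPS)
    W = W / scale
    H = H * scale[:, None]
    return W, H, obj, converged


# ---------------------------------------------------------------- extraction


@dataclass
class ExtractionResult:
    signatures: list[SignatureProfile]
    exposures: np.ndarray  # samples x signatures, mutation counts
    sample_ids: list[str]
    k: int
    stability: np.ndarray  # per-signature mean silhouette
    reconstruction_error: float
    k_diagnostics: dict[int, tuple[float, float]] = field(default_factory=dict)
    non_converged: int = 0


def _greedy_match(cands: np.ndarray, centroids: np.ndarray) -> list[int]:
    """Greedy cosine assignment of k candidate signatures to k centroids."""
    k = centroids.shape[1]
    sim = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            sim[i, j] = cosine_similarity(cands[:, i], centroids[:, j])
    assign = [-1] * k
    used_r, used_c = set(), set()
    for _ in range(k):
        best = None
        for i in range(k):
            if i in used_r:
                continue
            for j in range(k):
                if j in used_c:
                    continue
                if best is None or sim[i, j] > sim[best[0], best[1]]:
                    best = (i, j)
        used_r.add(best[0])
        used_c.add(best[1])
        assign[best[0]] = best[1]
    return assign


def extract_signatures(
    catalogs: Sequence[MutationCatalog],
    k_range: Sequence[int] = (2, 3, 4),
    n_bootstrap: int = 100,
    min_mutations: int = 100,
    seed: int = 0,
    max_iter: int = 1000,
    objective: str = "kl",
    stability_tolerance: float = 0.02,
) -> ExtractionResult:
    """Bootstrapped NMF signature extraction with silhouette-based k choice.

    Samples with total <= ``min_mutations`` are excluded (strict "more than"
    threshold). Per bootstrap, every sample's catalog is resampled
    multinomially at its own total and factorized; solutions are clustered
    across bootstraps by greedy cosine matching to running centroids and
    consensus signatures are the cluster centroids. k is chosen to maximize
    the mean silhouette subject to decreasing reconstruction error: among
    the k whose mean silhouette lies within ``stability_tolerance`` of the
    best (solutions equally reproducible across bootstraps), the lowest
    reconstruction error wins; exact ties go to the smaller k.
    """
    used = [c for c in catalogs if c.total > min_mutations]
    k_range = sorted(set(int(k) for k in k_range))
    if not used or len(used) < 2 * max(k_range):
        raise ValueError(
            f"need at least {2 * max(k_range)} samples with more than "
            f"{min_mutations} mutations; have {len(used)}"
        )
    V = np.stack([c.counts for c in used], axis=1)  # 96 x S
    sample_ids = [c.sample_id for c in used]
    totals = V.sum(axis=0).astype(int)

    candidates: list[dict] = []
    diagnostics: dict[int, tuple[float, float]] = {}
    for k in k_range:
        sigs_all = []  # collected signatures, 96-vectors
        labels_all = []
        centroids = None
        counts = np.zeros(k)
        n_nc = 0
        for b in range(n_bootstrap):
            rng = np.random.default_rng([seed, k, b])
            Vb = np.stack(
                [rng.multinomial(totals[j], np.maximum(V[:, j], _EPS) / max(totals[j], 1))
                 if totals[j] > 0 else V[:, j]
                 for j in range(V.shape[1])],
                axis=1,
            ).astype(float)
            W, H, _, conv = nmf_kl(Vb, k, rng, max_iter=max_iter, objective=objective)
            if not conv:
                n_nc += 1
            if centroids is None:
                centroids = W.copy()
                counts[:] = 1
                assign = list(range(k))
            else:
                assign = _greedy_match(W, centroids)
                for i, j in enumerate(assign):
                    counts[j] += 1
                    centroids[:, j] += (W[:, i] - centroids[:, j]) / counts[j]
            for i, j in enumerate(assign):
                sigs_all.append(W[:, i])
                labels_all.append(j)
        X = np.stack(sigs_all)
        labels = np.asarray(labels_all)
        if k == 1 or len(set(labels_all)) < 2:
            sil_per = np.ones(k)
            mean_sil = 1.0
        else:
            sil = silhouette_samples(X, labels, metric="cosine")
            sil_per = np.array([sil[labels == j].mean() for j in range(k)])
            mean_sil = float(sil_per.mean())
        consensus = centroids / centroids.sum(axis=0, keepdims=True)
        # refit exposures of the real catalogs on the consensus signatures
        expo = np.stack([nnls(consensus, V[:, j])[0] for j in range(V.shape[1])])
        err = float(np.linalg.norm(V - consensus @ expo.T) / np.linalg.norm(V))
        diagnostics[k] = (mean_sil, err)
        candidates.append({"k": k, "sil": mean_sil, "sil_per": sil_per,
                           "err": err, "consensus": consensus, "expo": expo,
                           "n_nc": n_nc})
    max_sil = max(c["sil"] for c in candidates)
    stable = [c for c in candidates if c["sil"] >= max_sil - stability_tolerance]
    best = min(stable, key=lambda c: (c["err"], c["k"]))
    if best["n_nc"]:
        logger.warning("%d bootstrap factorizations hit max_iter without converging",
                       best["n_nc"])
    signatures = [
        SignatureProfile.from_counts(f"extracted_{i}", best["consensus"][:, i])
        for i in range(best["k"])
    ]
    return ExtractionResult(
        signatures=signatures,
        exposures=best["expo"],
        sample_ids=sample_ids,
        k=best["k"],
        stability=best["sil_per"],
        reconstruction_error=best["err"],
        k_diagnostics=diagnostics,
        non_converged=best["n_nc"],
    )


# ---------------------------------------------------------------- refitting


def fit_exposures(
    catalog: MutationCatalog, signatures: Sequence[SignatureProfile]
) -> tuple[np.ndarray, float, bool]:
    """Non-negative least-squares attribution of a catalog to signatures.

    Returns (exposures in mutation counts, residual norm, collinearity
    flag). Near-duplicate signatures (pairwise cosine > 0.999) are flagged
    but still fit.
    """
    if not signatures:
        raise ValueError("need at least one signature")
    A = np.stack([s.probs for s in signatures], axis=1)
    collinear = False
    for i in range(len(signatures)):
        for j in range(i + 1, len(signatures)):
            if cosine_similarity(A[:, i], A[:, j]) > 0.999:
                collinear = True
    x, rnorm = nnls(A, catalog.counts)
    return x, float(rnorm), collinear


def match_to_reference(
    extracted: Sequence[SignatureProfile],
    reference: Sequence[SignatureProfile],
    artifact_names: Sequence[str] = (),
    artifact_threshold: float = 0.85,
) -> list[dict]:
    """Pair each extracted signature with its maximum-cosine reference.

    References whose names are listed in ``artifact_names`` flag the match
    as a putative sequencing artifact when the similarity exceeds
    ``artifact_threshold``.
    """
    if not reference:
        raise ValueError("reference set must be nonempty")
    artifact_names = set(artifact_names)
    out = []
    for e in extracted:
        sims = [cosine_similarity(e, r) for r in reference]
        j = int(np.argmax(sims))
        out.append({
            "extracted": e.name,
            "reference": reference[j].name,
            "cosine": sims[j],
            "artifact": (reference[j].name in artifact_names
                         and sims[j] >= artifact_threshold),
        })
    return out
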