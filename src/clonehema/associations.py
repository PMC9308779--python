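"""Association analyses: CH vs age/sex/treatment, gene-level treatment
effects with Benjamini-Hochberg correction, and the age-exposure trend."""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import pearsonr
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .types import CHCall, DonorProfile, RegressionResult

logger = logging.getLogger(__name__)


def _logit_fit(y: pd.Series, X: pd.DataFrame) -> Optional[sm.Logit]:
    """Maximum-likelihood logistic fit; None when degenerate/separated."""
    if y.nunique() < 2:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y.astype(float), sm.add_constant(X.astype(float))).fit(
                disp=0, maxiter=200
            )
        except (PerfectSeparationError, np.linalg.LinAlgError):
            return None
    if not np.isfinite(res.bse).all() or (res.bse > 1e3).any():
        return None  # quasi-separation: Wald machinery meaningless
    return res


def _results_from_fit(res, terms: Sequence[str]) -> list[RegressionResult]:
    ci = res.conf_int()
    return [
        RegressionResult(
            term=t,
            coefficient=float(res.params[t]),
            ci95=(float(ci.loc[t, 0]), float(ci.loc[t, 1])),
            p_value=float(res.pvalues[t]),
        )
        for t in terms
    ]


def fit_ch_model(
    donors: Sequence[DonorProfile], ch_calls: Sequence[CHCall]
) -> list[RegressionResult]:
    """Multivariable logistic regression of CH status on age, sex and
    cytotoxic / non-cytotoxic treatment exposure.

    Perfect separation or a degenerate outcome yields a single flagged
    result with the estimates withheld.
    """
    status = {c.donor_id: c.is_CH for c in ch_calls}
    df = pd.DataFrame({
        "is_CH": [bool(status.get(d.donor_id, False)) for d in donors],
        "age": [d.age for d in donors],
        "sex_male": [1.0 if d.sex == "male" else 0.0 for d in donors],
        "cytotoxic": [1.0 if "cytotoxic" in d.treatments else 0.0 for d in donors],
        "non_cytotoxic": [1.0 if "non_cytotoxic" in d.treatments else 0.0
                          for d in donors],
    })
    terms = ["age", "sex_male", "cytotoxic", "non_cytotoxic"]
    res = _logit_fit(df["is_CH"], df[terms])
    if res is None:
        return [RegressionResult("model", 0.0, (0.0, 0.0), 1.0,
                                 flagged="degenerate_or_separated")]
    return _results_from_fit(res, terms)


def gene_treatment_associations(
    donor_gene_matrix: pd.DataFrame,
    treatment_flags: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
    genes: Optional[Sequence[str]] = None,
    min_mutated: int = 5,
) -> pd.DataFrame:
    """Per-gene logistic fits (mutated ~ treatment + age + sex) with BH
    q-values computed within each treatment family.

    ``donor_gene_matrix`` is binary donors x genes; ``treatment_flags`` is
    binary donors x treatments on the same index; ``covariates`` optionally
    supplies age/sex columns. Genes mutated in fewer than ``min_mutated``
    donors are skipped and reported with NaN estimates.
    """
    if treatment_flags.shape[1] == 0:
        raise ValueError("no treatment columns supplied")
    genes = list(genes) if genes is not None else list(donor_gene_matrix.columns)
    rows = []
    for treatment in treatment_flags.columns:
        t = treatment_flags[treatment].astype(float)
        if t.nunique() < 2:
            raise ValueError(f"treatment column '{treatment}' is constant")
        for gene in genes:
            y = donor_gene_matrix[gene].astype(float)
            if y.sum() < min_mutated:
                rows.append({"treatment": treatment, "gene": gene,
                             "coefficient": np.nan, "p_value": np.nan,
                             "skipped": True})
                continue
            X = pd.DataFrame({"treatment": t})
            if covariates is not None:
                X = pd.concat([X, covariates], axis=1)
            res = _logit_fit(y, X)
            if res is None:
                rows.append({"treatment": treatment, "gene": gene,
                             "coefficient": np.nan, "p_value": np.nan,
                             "skipped": True})
                continue
            ci = res.conf_int()
            rows.append({
                "treatment": treatment, "gene": gene,
                "coefficient": float(res.params["treatment"]),
                "ci_low": float(ci.loc["treatment", 0]),
                "ci_high": float(ci.loc["treatment", 1]),
                "p_value": float(res.pvalues["treatment"]),
                "skipped": False,
            })
    out = pd.DataFrame(rows)
    out["q_value"] = np.nan
    for treatment in treatment_flags.columns:
        fam = out.index[(out["treatment"] == treatment) & ~out["p_value"].isna()]
        if len(fam):
            out.loc[fam, "q_value"] = multipletests(
                out.loc[fam, "p_value"].to_numpy(), method="fdr_bh"
            )[1]
    return out


def age_exposure_trend(
    exposures: Sequence[float],
    ages: Sequence[float],
    bin_width: float = 5.0,
) -> dict:
    """Binned mean +- sd of HSC exposure by age, plus the Pearson r and p
    computed on the unbinned data."""
    exposures = np.asarray(exposures, float)
    ages = np.asarray(ages, float)
    if (ages <= 0).any():
        raise ValueError("ages must be positive")
    r, p = pearsonr(ages, exposures)
    lo = np.floor(ages.min() / bin_width) * bin_width
    edges = np.arange(lo, ages.max() + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
        logger.warning("all ages fall in one bin")
    idx = np.clip(np.digitize(ages, edges) - 1, 0, len(edges) - 2)
    bins = []
    for b in range(len(edges) - 1):
        sel = idx == b
        if sel.any():
            bins.append({
                "age_low": float(edges[b]), "age_high": float(edges[b + 1]),
                "n": int(sel.sum()),
                "mean": float(exposures[sel].mean()),
                "sd": float(exposures[sel].std(ddof=0)),
            })
    return {"pearson_r": float(r), "p_value": float(p), "bins": bins}
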