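"""Competitive-index and proliferation statistics for symbiosis assays.

A competitive index (CI) compares a test strain with a reference strain
co-inoculated on plants: the ratio of the two strains in an output
compartment (pooled nodule colonies, nodule occupancy, culture medium or
rhizosphere washes) divided by their ratio in the inoculum.  CI > 1 means
the test strain outcompeted the reference.  Significance against CI = 1
uses a one-sided Student t-test — on the inverse CIs when every replicate
exceeds 1, otherwise on the CIs in the direction of the sample mean — with
Benjamini–Hochberg correction across strains.  Within-host proliferation
(single-strain colony counts per nodule) is compared between a mutant and
its parent with a two-sided Wilcoxon rank-sum test, and summarised as the
mean gain factor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CIObservation",
    "CITestResult",
    "InsufficientDataError",
    "competitive_index",
    "ci_significance",
    "bh_adjust",
    "proliferation_comparison",
    "summarize_ci",
]

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Too few replicates to run the requested test."""


@dataclass(frozen=True)
class CIObservation:
    """Paired output/inoculum counts of a test and a reference strain."""

    test_out: float
    ref_out: float
    test_in: float
    ref_in: float
    replicate: str = ""
    strain: str = ""
    assay: str = ""

    def __post_init__(self) -> None:
        for name in ("test_out", "ref_out", "test_in", "ref_in"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def competitive_index(obs: CIObservation) -> float:
    """CI = (test_out / ref_out) / (test_in / ref_in).

    Scale-invariant in the counts.  Returns NaN (undefined-CI marker) with a
    logged diagnostic when a denominator is zero; callers exclude undefined
    CIs from summaries rather than imputing them.
    """
    if obs.ref_out == 0 or obs.ref_in == 0 or obs.test_in == 0:
        logger.warning(
            "undefined CI for strain=%r replicate=%r: zero count in "
            "ref_out=%s ref_in=%s test_in=%s",
            obs.strain, obs.replicate, obs.ref_out, obs.ref_in, obs.test_in,
        )
        return math.nan
    return (obs.test_out / obs.ref_out) / (obs.test_in / obs.ref_in)


@dataclass(frozen=True)
class CITestResult:
    p: float
    branch: Literal["inverse", "direct"]
    direction: Literal["greater", "less"]


def ci_significance(cis: Sequence[float], log_transform: bool = False) -> CITestResult:
    """One-sided t-test of replicate CIs against the neutral value 1.

    When every CI exceeds 1, the CIs are inverted and the inverses tested
    below 1 (so a strongly competitive strain with right-skewed CIs is
    assessed on the better-behaved reciprocal scale).  Otherwise the CIs are
    tested directly, one-sided in the direction of the sample mean; the
    branch taken is reported alongside the P value.  ``log_transform``
    optionally tests log CIs against 0 instead.
    """
    values = np.asarray(cis, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 3:
        raise InsufficientDataError("at least 3 replicate CIs are required")
    if (values <= 0).any() and log_transform:
        raise ValueError("log transform requires strictly positive CIs")
    if (values > 1).all():
        branch: Literal["inverse", "direct"] = "inverse"
        sample = 1.0 / values
        direction: Literal["greater", "less"] = "less"
    else:
        branch = "direct"
        sample = values
        direction = "greater" if values.mean() > 1 else "less"
    null = 1.0
    if log_transform:
        sample = np.log(sample)
        null = 0.0
    if np.ptp(sample) == 0:  # degenerate, zero variance
        if sample[0] == null:
            p = 1.0
        else:
            deviates = sample[0] > null if direction == "greater" else sample[0] < null
            p = 0.0 if deviates else 1.0
    else:
        p = float(stats.ttest_1samp(sample, null, alternative=direction).pvalue)
    return CITestResult(p=p, branch=branch, direction=direction)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted P values, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def proliferation_comparison(
    mutant: Sequence[float], parent: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of per-nodule counts.

    Returns (raw P, gain factor), the gain factor being the ratio of mean
    mutant to mean parent counts.
    """
    a = np.asarray(mutant, dtype=float)
    b = np.asarray(parent, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError("at least 3 values per group are required")
    if np.array_equal(np.sort(a), np.sort(b)):
        p = 1.0  # identical samples carry no evidence either way
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    gain = float(a.mean() / b.mean())
    return p, gain


def summarize_ci(
    observations: pd.DataFrame, alpha: float = 0.05, log_transform: bool = False
) -> pd.DataFrame:
    """Per-strain CI summary with BH-adjusted verdicts.

    ``observations`` uses the assay TSV dialect (columns strain, assay,
    replicate, test_out, ref_out, test_in, ref_in).  Undefined CIs (zero
    reference or inoculum counts) are excluded from the mean with a logged
    count.  Verdicts at level ``alpha``: *beneficial* (mean CI > 1),
    *deleterious* (mean CI < 1) or *neutral*.
    """
    rows = []
    for (strain, assay), grp in observations.groupby(["strain", "assay"], sort=True):
        cis = np.array(
            [
                competitive_index(
                    CIObservation(
                        test_out=r.test_out, ref_out=r.ref_out,
                        test_in=r.test_in, ref_in=r.ref_in,
                        replicate=str(r.replicate), strain=str(strain),
                        assay=str(assay),
                    )
                )
                for r in grp.itertuples()
            ]
        )
        n_undef = int(np.isnan(cis).sum())
        if n_undef:
            logger.warning(
                "strain %r assay %r: %d undefined CI(s) excluded", strain, assay, n_undef
            )
        defined = cis[~np.isnan(cis)]
        test = ci_significance(defined, log_transform=log_transform)
        rows.append(
            {
                "strain": strain,
                "assay": assay,
                "n_replicates": defined.size,
                "n_undefined": n_undef,
                "mean_ci": float(defined.mean()),
                "p": test.p,
                "test_branch": test.branch,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    verdict = np.where(
        (out["p_adj"] < alpha) & (out["mean_ci"] > 1), "beneficial",
        np.where((out["p_adj"] < alpha) & (out["mean_ci"] < 1), "deleterious", "neutral"),
    )
    out["verdict"] = verdict
    return out
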