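"""Active-mitosis signature derivation and single-sample enrichment scoring.

The anchor gene (GSG2/HASPIN in the motivating application) is expressed
throughout the cell cycle, so its level alone is a weak mitotic-activity
readout.  Instead, a signature is derived from a candidate gene set (e.g. a
mitotic cell-cycle collection) by keeping genes that are (i) positively
correlated with the anchor across tumor samples and (ii) elevated in tumors
versus matched normals, both at a Benjamini-Hochberg FDR.  Each sample is
then scored against the signature by single-sample GSEA (ssGSEA): genes are
ranked by within-sample expression and the score is the integrated gap
between the weighted in-set and uniform out-of-set cumulative distributions
(the integral form, not the max-deviation ES).  The range-normalized score
across a cohort is the active mitosis signature enrichment score (AMSES).

Because the in-set weights are powers of the rank (not of the raw
expression), ssGSEA here depends only on within-sample ranks and is
invariant to any strictly monotone transform of the expression values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import ExpressionCohort

__all__ = [
    "GeneSignature",
    "ScoreVector",
    "TrendTestResult",
    "EmptySignatureError",
    "derive_signature",
    "ssgsea_score",
    "amses",
    "score_vs_stage",
]


class EmptySignatureError(ValueError):
    """No candidate survived both filters; carries per-filter survivor counts."""

    def __init__(self, n_corr_survivors: int, n_elevation_survivors: int):
        self.n_corr_survivors = n_corr_survivors
        self.n_elevation_survivors = n_elevation_survivors
        super().__init__(
            "empty signature: "
            f"{n_corr_survivors} candidates passed the correlation filter, "
            f"{n_elevation_survivors} passed the elevation filter, "
            "0 passed both"
        )


@dataclass
class GeneSignature:
    """A derived gene signature plus how it was obtained."""

    genes: frozenset[str]
    derivation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError("signature must be nonempty")


@dataclass
class ScoreVector:
    """Per-sample enrichment scores, raw and (optionally) range-normalized."""

    raw: pd.Series
    normalized: Optional[pd.Series]
    normalization: str  # "range-normalized" or "raw"
    truth_spearman: Optional[float] = None  # diagnostic vs planted activity


def derive_signature(
    cohort: ExpressionCohort,
    anchor: str,
    candidate_set: Iterable[str],
    corr_method: str = "spearman",
    fdr_cut: float = 0.05,
    elevation_fdr: float = 0.05,
) -> GeneSignature:
    """Derive the anchor-correlated, tumor-elevated signature.

    Candidates are tested across tumor samples for positive correlation with
    the anchor (Spearman by default, one-sided) and, on matched tumor-normal
    pairs, for elevation (one-sided paired Wilcoxon signed-rank).  Each
    filter is Benjamini-Hochberg adjusted across candidates; a gene must
    pass both.  The anchor is never a member of the returned set.
    """
    if corr_method not in ("spearman", "pearson"):
        raise ValueError("corr_method must be 'spearman' or 'pearson'")
    if anchor not in cohort.values.index:
        raise ValueError(f"anchor gene {anchor!r} not in cohort")
    candidates = sorted((set(candidate_set) & set(cohort.genes)) - {anchor})
    if not candidates:
        raise ValueError("candidate_set does not intersect the cohort genes")
    if len(cohort.pairing) < 3:
        raise ValueError("need at least 3 tumor/normal pairs")

    tumor = cohort.tumor_matrix()
    normal = cohort.normal_matrix()[tumor.columns]
    anchor_vec = tumor.loc[anchor].to_numpy()

    corr_fn = stats.spearmanr if corr_method == "spearman" else stats.pearsonr
    corr_p = np.empty(len(candidates))
    corr_r = np.empty(len(candidates))
    for i, g in enumerate(candidates):
        r, p = corr_fn(anchor_vec, tumor.loc[g].to_numpy(), alternative="greater")
        corr_r[i], corr_p[i] = r, p
    corr_pass = multipletests(corr_p, method="fdr_bh")[1] <= fdr_cut
    corr_pass &= corr_r > 0

    elev_p = np.empty(len(candidates))
    for i, g in enumerate(candidates):
        diff = tumor.loc[g].to_numpy() - normal.loc[g].to_numpy()
        if np.allclose(diff, 0.0):
            elev_p[i] = 1.0
            continue
        elev_p[i] = stats.wilcoxon(diff, alternative="greater").pvalue
    elev_pass = multipletests(elev_p, method="fdr_bh")[1] <= elevation_fdr

    keep = [g for g, a, b in zip(candidates, corr_pass, elev_pass) if a and b]
    if not keep:
        raise EmptySignatureError(int(corr_pass.sum()), int(elev_pass.sum()))
    return GeneSignature(
        genes=frozenset(keep),
        derivation={
            "anchor": anchor,
            "corr_method": corr_method,
            "fdr_cut": fdr_cut,
            "elevation_fdr": elevation_fdr,
            "elevation_test": "paired one-sided Wilcoxon signed-rank",
            "n_candidates": len(candidates),
            "n_corr_survivors": int(corr_pass.sum()),
            "n_elevation_survivors": int(elev_pass.sum()),
        },
    )


def ssgsea_score(
    sample_expression: pd.Series,
    signature: GeneSignature | Iterable[str],
    tau: float = 0.25,
) -> float:
    """Single-sample GSEA score of one sample against one gene set.

    Genes are ordered by descending expression (gene-id tie-break); with N
    genes and k in the set, position i (1 = top) carries rank-weight
    (N - i + 1).  In-set positions step the in-set CDF by rank-weight^tau
    normalized over in-set genes; out-of-set positions step the out-of-set
    CDF by 1/(N - k).  The score is the sum over all N positions of
    (cumulative_in - cumulative_out).
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    genes = set(signature.genes) if isinstance(signature, GeneSignature) else set(signature)
    expr = sample_expression
    # descending expression, gene-id tie-break (lexsort: last key is primary)
    order = np.lexsort((expr.index.to_numpy(), -expr.to_numpy(dtype=float)))
    in_set = expr.index.isin(genes).astype(bool)[order]
    n, k = len(expr), int(in_set.sum())
    if k == 0:
        raise ValueError("signature does not overlap the sample's gene universe")
    if k == n:
        raise ValueError("signature covers the whole gene universe")
    rank_weight = np.arange(n, 0, -1, dtype=float) ** tau
    w_in = np.where(in_set, rank_weight, 0.0)
    cum_in = np.cumsum(w_in) / w_in.sum()
    cum_out = np.cumsum(~in_set) / (n - k)
    return float(np.sum(cum_in - cum_out))


def amses(
    cohort: ExpressionCohort,
    signature: GeneSignature | Iterable[str],
    tau: float = 0.25,
) -> ScoreVector:
    """Score every sample of a cohort by ssGSEA and range-normalize to [0, 1].

    When the cohort carries planted truth, the Spearman correlation between
    the tumor-sample scores and the planted latent activity is attached as a
    diagnostic.  A cohort with fewer than two distinct raw scores cannot be
    range-normalized and is returned raw with a warning.
    """
    raw = pd.Series(
        {s: ssgsea_score(cohort.values[s], signature, tau) for s in cohort.values.columns}
    )
    lo, hi = raw.min(), raw.max()
    if hi > lo:
        normalized = (raw - lo) / (hi - lo)
        tag = "range-normalized"
    else:
        warnings.warn("cannot range-normalize: all raw scores identical")
        normalized = None
        tag = "raw"
    truth_rho = None
    if cohort.truth is not None:
        tumor_samples = cohort.samples_of("tumor")
        patients = [cohort.sample_patient[s] for s in tumor_samples]
        rho, _ = stats.spearmanr(
            raw[tumor_samples].to_numpy(),
            cohort.truth.activity[patients].to_numpy(),
        )
        truth_rho = float(rho)
    return ScoreVector(raw=raw, normalized=normalized, normalization=tag,
                       truth_spearman=truth_rho)


@dataclass(frozen=True)
class TrendTestResult:
    statistic: float
    p_value: float
    n_permutations: int


def _jt_statistic(values: np.ndarray, group_codes: np.ndarray) -> float:
    """Jonckheere-Terpstra statistic: pairwise concordance across ordered groups."""
    lt = values[:, None] < values[None, :]
    eq = values[:, None] == values[None, :]
    pair = group_codes[:, None] < group_codes[None, :]
    return float((lt & pair).sum() + 0.5 * (eq & pair).sum())


def score_vs_stage(
    scores: pd.Series | ScoreVector,
    stages: pd.Series,
    stage_order: Optional[Sequence] = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> TrendTestResult:
    """Ordered trend of scores across stage groups (Jonckheere-Terpstra).

    The statistic counts score pairs concordant with the stage ordering
    (ties count half); the one-sided p-value (increasing trend) comes from
    label permutations with the stated seed.  Every stage group must contain
    at least two samples.
    """
    if isinstance(scores, ScoreVector):
        scores = scores.normalized if scores.normalized is not None else scores.raw
    scores, stages = scores.align(stages, join="inner")
    order = list(stage_order) if stage_order is not None else sorted(stages.unique())
    if len(order) < 2:
        raise ValueError("need at least two stage groups")
    counts = stages.value_counts()
    small = [s for s in order if counts.get(s, 0) < 2]
    if small:
        raise ValueError(f"stage groups with <2 samples: {small}")
    codes = stages.map({s: i for i, s in enumerate(order)}).to_numpy()
    vals = scores.to_numpy(dtype=float)

    observed = _jt_statistic(vals, codes)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _jt_statistic(vals, perm) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return TrendTestResult(statistic=observed, p_value=p, n_permutations=n_permutations)
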