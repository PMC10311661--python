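"""Connectivity-map style transcriptomic matching and chemical similarity.

Implements the weighted Kolmogorov-Smirnov enrichment statistic over a
ranked gene profile, the two-sided connectivity score (wtcs) between a
reference profile and an up/down query signature, a preranked permutation
GSEA p-value, and the Tanimoto coefficient on binary fingerprints — the
scoring half of a connectivity-map query against a user-supplied profile
collection (the reference corpus itself is out of scope).

The running-sum statistic: walking down the ranked list, positions in the
gene set increment the sum by |score|^w normalized over set members, and
positions outside decrement by 1/(N - k).  The enrichment score (ES) is the
signed maximum deviation from zero.  Because the running sum is piecewise
linear between hits, its extrema occur only immediately after a hit (maxima)
or immediately before one (minima); ``weighted_ks_es`` evaluates exactly
those candidate points, which is equivalent to the full O(N) walk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RankedProfile",
    "QuerySignature",
    "Fingerprint",
    "weighted_ks_es",
    "wtcs",
    "preranked_gsea",
    "tanimoto",
    "rank_candidates",
]


@dataclass
class RankedProfile:
    """Genes ordered by a signed differential statistic, largest first.

    Ties in score are broken by gene id (lexicographic, ascending) so the
    ranking is bit-reproducible.
    """

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene ids must be unique")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be nonincreasing; use from_scores()")

    @classmethod
    def from_scores(cls, scores: Mapping[str, float] | pd.Series) -> "RankedProfile":
        """Sort a gene -> score mapping into a ranked profile."""
        s = pd.Series(scores, dtype=float)
        order = sorted(range(len(s)), key=lambda i: (-s.iloc[i], s.index[i]))
        return cls([str(s.index[i]) for i in order], s.to_numpy()[order])

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class QuerySignature:
    """An up/down differential-expression query signature."""

    up_set: frozenset[str]
    down_set: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "up_set", frozenset(self.up_set))
        object.__setattr__(self, "down_set", frozenset(self.down_set))
        if self.up_set & self.down_set:
            raise ValueError("up_set and down_set must be disjoint")
        if not self.up_set or not self.down_set:
            raise ValueError("up_set and down_set must both be nonempty")


@dataclass(frozen=True)
class Fingerprint:
    """A binary molecular fingerprint stored as its set-bit indices."""

    id: str
    bits: frozenset[int]
    n_bits: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", frozenset(self.bits))
        if any(b < 0 or b >= self.n_bits for b in self.bits):
            raise ValueError("bit index out of range")


def _hit_positions(profile: RankedProfile, gene_set: Iterable[str]) -> np.ndarray:
    gene_set = set(gene_set)
    pos = np.fromiter(
        (i for i, g in enumerate(profile.genes) if g in gene_set), dtype=np.int64
    )
    n = len(profile)
    if pos.size == 0:
        raise ValueError("gene set does not intersect the profile")
    if pos.size == n:
        raise ValueError("gene set covers the whole profile; ES undefined")
    return pos


def _es_from_positions(
    pos: np.ndarray, scores: np.ndarray, n: int, weight_exponent: float
) -> float:
    """ES given 0-based hit positions; extrema checked at hit boundaries."""
    k = pos.size
    w = np.abs(scores[pos]) ** weight_exponent
    total = w.sum()
    if total == 0:  # all hit scores are zero: fall back to unweighted steps
        w = np.ones(k)
        total = float(k)
    cum_in = np.cumsum(w) / total
    # misses seen up to and including position pos[j] (1-based rank pos+1)
    misses = (pos + 1) - np.arange(1, k + 1)
    miss_frac = misses / (n - k)
    after = cum_in - miss_frac            # running sum just after each hit
    before = np.concatenate(([0.0], cum_in[:-1])) - miss_frac  # just before
    pos_ext = after.max()
    neg_ext = before.min()
    # ties between equal-magnitude extrema resolve to the positive one
    # (tolerance absorbs summation-order rounding)
    return float(pos_ext if pos_ext >= -neg_ext - 1e-12 else neg_ext)


def weighted_ks_es(
    profile: RankedProfile,
    gene_set: Iterable[str],
    weight_exponent: float = 1.0,
) -> float:
    """Weighted KS enrichment score of ``gene_set`` in a ranked profile.

    Parameters
    ----------
    profile
        Ranked profile (most up-regulated gene first).
    gene_set
        Gene ids to test; must intersect the profile but not cover it.
    weight_exponent
        w >= 0.  w=0 gives the classic unweighted KS statistic; w=1 the
        connectivity-map convention weighting hits by |score|.

    Returns
    -------
    float in [-1, 1]: signed maximum deviation of the running sum.
    """
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be >= 0")
    pos = _hit_positions(profile, gene_set)
    return _es_from_positions(pos, profile.scores, len(profile), weight_exponent)


def wtcs(
    profile: RankedProfile,
    query: QuerySignature,
    weight_exponent: float = 1.0,
) -> float:
    """Two-sided connectivity score between a profile and an up/down query.

    wtcs = (ES_up - ES_down) / 2 when the two enrichment scores have opposite
    signs, else 0 (a same-sign pair carries no directional connectivity).
    Positive wtcs: the profile mimics the query perturbation; negative:
    it opposes it.
    """
    es_up = weighted_ks_es(profile, query.up_set, weight_exponent)
    es_down = weighted_ks_es(profile, query.down_set, weight_exponent)
    if np.sign(es_up) == np.sign(es_down):
        return 0.0
    return float((es_up - es_down) / 2.0)


def preranked_gsea(
    profile: RankedProfile,
    gene_set: Iterable[str],
    weight_exponent: float = 1.0,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Enrichment score with a gene-label permutation p-value.

    Permutations redraw the hit positions uniformly (shuffling gene labels);
    significance uses the add-one estimator

        p = (1 + #{ |ES*| >= |ES| }) / (1 + n_permutations),

    so p is bounded below by 1/(n_permutations + 1).
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    pos = _hit_positions(profile, gene_set)
    n, k = len(profile), pos.size
    es = _es_from_positions(pos, profile.scores, n, weight_exponent)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = np.sort(rng.choice(n, size=k, replace=False))
        es_star = _es_from_positions(perm, profile.scores, n, weight_exponent)
        if abs(es_star) >= abs(es):
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return es, p


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) coefficient |A∩B| / |A∪B| on binary fingerprints."""
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprint lengths differ")
    union = a.bits | b.bits
    if not union:
        raise ValueError("both fingerprints empty; Tanimoto undefined (0/0)")
    return len(a.bits & b.bits) / len(union)


def rank_candidates(
    profiles: Mapping[str, RankedProfile],
    query: QuerySignature,
    weight_exponent: float = 1.0,
    fingerprints: Optional[Mapping[str, Fingerprint]] = None,
    query_fp: Optional[Fingerprint] = None,
) -> pd.DataFrame:
    """Rank candidate compounds by connectivity, annotated with Tanimoto.

    One row per compound: ``wtcs``, ``tanimoto`` (NaN when the compound has
    no fingerprint or no query fingerprint was given) and ``combined_rank``
    (mean of the wtcs rank and the tanimoto rank, wtcs rank alone when
    tanimoto is missing).  Sorted by wtcs descending with compound-id
    tie-break.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    ids = sorted(profiles)
    scores = [wtcs(profiles[c], query, weight_exponent) for c in ids]
    tans = []
    for c in ids:
        if fingerprints is not None and query_fp is not None and c in fingerprints:
            tans.append(tanimoto(query_fp, fingerprints[c]))
        else:
            tans.append(np.nan)
    df = pd.DataFrame({"compound": ids, "wtcs": scores, "tanimoto": tans})
    wr = df["wtcs"].rank(ascending=False, method="average")
    tr = df["tanimoto"].rank(ascending=False, method="average")
    df["combined_rank"] = np.where(df["tanimoto"].isna(), wr, (wr + tr) / 2.0)
    df = df.sort_values(
        ["wtcs", "compound"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return df
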