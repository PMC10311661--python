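"""Kinome selectivity scoring from competition-binding %Ctrl tables.

Competition-binding panels (e.g. scanMAX) report, for each kinase, the
percent of a control probe signal remaining in the presence of the test
compound: low %Ctrl means strong binding.  The selectivity score

    S(x) = (# nonmutant kinases with %Ctrl < x) / (# nonmutant kinases tested)

summarizes how promiscuous a compound is at threshold ``x`` (conventionally
x = 10, written S(10)).  Mutant kinase constructs are excluded from both the
numerator and the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "KinomeEntry",
    "KinomeProfile",
    "SelectivityScore",
    "s_score",
    "call_hits",
    "selectivity_curve",
]


@dataclass(frozen=True)
class KinomeEntry:
    """One kinase row of a competition-binding table."""

    kinase: str
    pct_ctrl: float
    is_mutant: bool = False


@dataclass
class KinomeProfile:
    """A full-panel %Ctrl profile for one compound at one concentration."""

    entries: list[KinomeEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.kinase for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("kinase ids must be unique")
        for e in self.entries:
            if e.pct_ctrl < 0:
                raise ValueError(f"negative pct_ctrl for {e.kinase!r}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "KinomeProfile":
        """Build from a DataFrame with columns kinase, pctCtrl, is_mutant."""
        entries = [
            KinomeEntry(str(r.kinase), float(r.pctCtrl), bool(r.is_mutant))
            for r in df.itertuples(index=False)
        ]
        return cls(entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kinase": [e.kinase for e in self.entries],
                "pctCtrl": [e.pct_ctrl for e in self.entries],
                "is_mutant": [e.is_mutant for e in self.entries],
            }
        )

    def nonmutant(self) -> list[KinomeEntry]:
        return [e for e in self.entries if not e.is_mutant]


@dataclass(frozen=True)
class SelectivityScore:
    """S(x) as an exact fraction plus the conventional 3-decimal rounding."""

    n_hits: int
    n_tested: int
    threshold: float

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.n_hits, self.n_tested)

    @property
    def value(self) -> float:
        return self.n_hits / self.n_tested

    @property
    def rounded(self) -> float:
        return round(self.value, 3)


def s_score(profile: KinomeProfile, threshold: float) -> SelectivityScore:
    """Selectivity score S(threshold) over the nonmutant kinases.

    The inequality is strict (`pct_ctrl < threshold`); kinases exactly at the
    threshold are not hits.  Raises ``ValueError`` when the profile contains
    no nonmutant kinase.
    """
    nonmut = profile.nonmutant()
    if not nonmut:
        raise ValueError("profile has no nonmutant kinases; S(x) undefined")
    hits = sum(1 for e in nonmut if e.pct_ctrl < threshold)
    return SelectivityScore(n_hits=hits, n_tested=len(nonmut), threshold=threshold)


def call_hits(profile: KinomeProfile, threshold: float) -> list[str]:
    """Nonmutant kinases bound below ``threshold`` %Ctrl.

    Sorted ascending by pct_ctrl, ties broken by kinase id, so the strongest
    binders come first and the order is bit-reproducible.
    """
    nonmut = profile.nonmutant()
    if not nonmut:
        raise ValueError("profile has no nonmutant kinases")
    hits = [e for e in nonmut if e.pct_ctrl < threshold]
    hits.sort(key=lambda e: (e.pct_ctrl, e.kinase))
    return [e.kinase for e in hits]


def selectivity_curve(
    profile: KinomeProfile, thresholds: Sequence[float]
) -> pd.DataFrame:
    """S(x) at each threshold of a sorted list (the generalization of S(10)).

    Returns a DataFrame with columns ``threshold`` and ``s_score``; the score
    column is nondecreasing because S(x) counts a strict lower tail.
    """
    thr = list(thresholds)
    if any(t <= 0 for t in thr):
        raise ValueError("thresholds must be positive")
    if thr != sorted(thr):
        raise ValueError("thresholds must be sorted ascending")
    rows = [(t, s_score(profile, t).value) for t in thr]
    return pd.DataFrame(rows, columns=["threshold", "s_score"])
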