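"""Synthetic inputs with planted ground truth for the discovery pipeline.

Every generator here emulates the statistical structure one analysis stage
assumes, with the planted truth recorded so recovery can be tested:

* paired tumor/normal expression cohorts in which a latent per-patient
  mitotic-activity factor drives a block of signature genes, an anchor gene
  (the GSG2 role), and the survival hazard — optionally with an extra
  synthetic-lethal hazard when anchor and partner expression are jointly low;
* kinome %Ctrl tables with an exact planted hit count;
* median-effect dose-response curves and fixed-ratio combinations with a
  controllable Loewe-interaction multiplier (1 = additive, <1 synergistic);
* binary fingerprint families with controllable within-family bit overlap.

All randomness flows through ``numpy.random.default_rng(seed)``; equal seeds
give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .connectivity import Fingerprint, QuerySignature, RankedProfile
from .kinome import KinomeEntry, KinomeProfile
from .synergy import DoseResponse

__all__ = [
    "CohortParams",
    "CohortTruth",
    "ExpressionCohort",
    "DoseResponseParams",
    "generate_cohort",
    "generate_kinome_profile",
    "generate_dose_response",
    "generate_combination",
    "generate_fingerprints",
    "generate_reference_profiles",
]

#: baseline exponential hazard (per day): median survival ~4 years at
#: zero latent activity, a realistic oncology-cohort scale.
BASELINE_HAZARD = math.log(2) / 1500.0


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the paired tumor/normal cohort generator.

    Defaults mirror the pan-cancer cohort the downstream analyses target:
    681 patients, a 126-gene mitotic signature anchored on GSG2, unit factor
    loading, one-unit tumor elevation of signature genes, gaussian noise of
    sd 0.5 on the log-like expression scale, a moderate prognostic effect of
    the latent activity (0.5 log-hazard per unit) and 30% censoring.
    """

    n_patients: int = 681
    n_genes: int = 2000
    n_signature_genes: int = 126
    anchor_gene: str = "GSG2"
    factor_loading: float = 1.0
    tumor_shift: float = 1.0
    hazard_beta: float = 0.5
    sl_partner_gene: Optional[str] = None
    sl_interaction_beta: float = 0.0
    censor_rate: float = 0.3
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signature_genes >= self.n_genes:
            raise ValueError("n_signature_genes must be < n_genes")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.factor_loading < 0:
            raise ValueError("factor_loading must be >= 0")


@dataclass
class CohortTruth:
    """Planted ground truth carried by synthetic cohorts only."""

    signature_genes: list[str]
    activity: pd.Series  # per patient
    anchor_gene: str
    sl_partner_gene: Optional[str]


@dataclass
class ExpressionCohort:
    """Gene x sample expression with pairing, survival and optional truth.

    ``values``: DataFrame genes x samples.  ``condition``: per-sample label
    in {tumor, normal}.  ``pairing``: normal-sample id -> tumor-sample id.
    ``survival``: DataFrame indexed by patient with columns time (days) and
    event (1 = death, 0 = censored).
    """

    values: pd.DataFrame
    condition: pd.Series
    pairing: dict[str, str]
    survival: pd.DataFrame
    sample_patient: pd.Series
    truth: Optional[CohortTruth] = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix has missing values")
        if (self.survival["time"] <= 0).any():
            raise ValueError("survival times must be strictly positive")
        cond = self.condition
        for nrm, tum in self.pairing.items():
            if nrm not in cond.index or tum not in cond.index:
                raise ValueError("pairing references unknown samples")
            if not (cond[nrm] == "normal" and cond[tum] == "tumor"):
                raise ValueError("pairing must link a normal to a tumor sample")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def samples_of(self, condition: str) -> list[str]:
        return list(self.condition.index[self.condition == condition])

    def tumor_matrix(self) -> pd.DataFrame:
        """Genes x patients matrix of tumor-sample expression."""
        cols = self.samples_of("tumor")
        mat = self.values[cols].copy()
        mat.columns = [self.sample_patient[c] for c in cols]
        return mat

    def normal_matrix(self) -> pd.DataFrame:
        """Genes x patients matrix of matched-normal expression."""
        cols = self.samples_of("normal")
        mat = self.values[cols].copy()
        mat.columns = [self.sample_patient[c] for c in cols]
        return mat


def generate_cohort(params: CohortParams) -> ExpressionCohort:
    """Simulate a paired tumor/normal cohort with planted mitotic activity.

    Each patient i carries a latent activity a_i ~ N(0, 1).  In the tumor
    sample, signature genes and the anchor gene follow
    ``factor_loading * a_i + tumor_shift + N(0, noise_sd)``; every other
    gene, and all genes in the matched normal, are pure N(0, noise_sd)
    noise.  Survival is exponential with hazard
    ``BASELINE_HAZARD * exp(hazard_beta * a_i + sl_interaction_beta * I_i)``
    where I_i indicates that both anchor and partner tumor expression fall
    below their cohort medians; censoring is independent administrative
    censoring hitting a ``censor_rate`` fraction of patients in expectation.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    patients = [f"P{i:04d}" for i in range(p.n_patients)]

    background = [f"G{i:05d}" for i in range(p.n_genes - 1)]
    genes = [p.anchor_gene] + background
    if p.sl_partner_gene is not None:
        if p.sl_partner_gene == p.anchor_gene:
            raise ValueError("sl_partner_gene must differ from anchor_gene")
        genes[1] = p.sl_partner_gene
        background = genes[1:]
    # signature genes drawn from the background, never the anchor/partner
    pool = background[1:] if p.sl_partner_gene is not None else background
    sig_idx = rng.choice(len(pool), size=p.n_signature_genes, replace=False)
    signature = sorted(pool[i] for i in sig_idx)

    activity = rng.standard_normal(p.n_patients)
    gene_pos = {g: i for i, g in enumerate(genes)}
    loaded_rows = np.array([gene_pos[g] for g in [p.anchor_gene] + signature])

    tumor = rng.normal(0.0, p.noise_sd, size=(p.n_genes, p.n_patients))
    normal = rng.normal(0.0, p.noise_sd, size=(p.n_genes, p.n_patients))
    tumor[loaded_rows, :] += p.factor_loading * activity + p.tumor_shift

    t_samples = [f"{pt}-T" for pt in patients]
    n_samples = [f"{pt}-N" for pt in patients]
    values = pd.DataFrame(
        np.hstack([tumor, normal]), index=genes, columns=t_samples + n_samples
    )
    values.index.name = "gene"
    condition = pd.Series(
        ["tumor"] * p.n_patients + ["normal"] * p.n_patients,
        index=t_samples + n_samples,
    )
    sample_patient = pd.Series(patients + patients, index=t_samples + n_samples)
    pairing = dict(zip(n_samples, t_samples))

    log_hazard = p.hazard_beta * activity
    if p.sl_partner_gene is not None and p.sl_interaction_beta != 0.0:
        anchor_expr = tumor[gene_pos[p.anchor_gene], :]
        partner_expr = tumor[gene_pos[p.sl_partner_gene], :]
        both_low = (anchor_expr < np.median(anchor_expr)) & (
            partner_expr < np.median(partner_expr)
        )
        log_hazard = log_hazard + p.sl_interaction_beta * both_low
    rate = BASELINE_HAZARD * np.exp(log_hazard)
    t_event = rng.exponential(1.0 / rate)
    censored = rng.random(p.n_patients) < p.censor_rate
    u = 1.0 - rng.random(p.n_patients)  # in (0, 1]
    time = np.where(censored, t_event * u, t_event)
    survival = pd.DataFrame(
        {"time": time, "event": (~censored).astype(int)}, index=patients
    )
    survival.index.name = "patient"

    truth = CohortTruth(
        signature_genes=signature,
        activity=pd.Series(activity, index=patients),
        anchor_gene=p.anchor_gene,
        sl_partner_gene=p.sl_partner_gene,
    )
    return ExpressionCohort(
        values=values,
        condition=condition,
        pairing=pairing,
        survival=survival,
        sample_patient=sample_patient,
        truth=truth,
    )


def generate_kinome_profile(
    n_kinases: int,
    n_mutant: int,
    n_hits: int,
    threshold: float = 10.0,
    seed: int = 0,
) -> KinomeProfile:
    """Kinome %Ctrl table with exactly ``n_hits`` planted nonmutant hits.

    Hit kinases get %Ctrl drawn uniformly in [0, threshold); all other
    kinases (and all mutants' values) lie at or above the threshold.
    """
    if n_hits > n_kinases - n_mutant:
        raise ValueError("n_hits cannot exceed the number of nonmutant kinases")
    if n_mutant > n_kinases:
        raise ValueError("n_mutant cannot exceed n_kinases")
    rng = np.random.default_rng(seed)
    ids = [f"KIN{i:04d}" for i in range(n_kinases)]
    mutant_idx = set(rng.choice(n_kinases, size=n_mutant, replace=False).tolist())
    nonmutant = [i for i in range(n_kinases) if i not in mutant_idx]
    hit_idx = set(
        np.asarray(nonmutant)[
            rng.choice(len(nonmutant), size=n_hits, replace=False)
        ].tolist()
        if n_hits
        else []
    )
    entries = []
    for i, kid in enumerate(ids):
        if i in hit_idx:
            pct = float(rng.uniform(0.0, threshold))
        else:
            pct = float(rng.uniform(threshold, 120.0))
        entries.append(KinomeEntry(kid, pct, is_mutant=i in mutant_idx))
    return KinomeProfile(entries)


@dataclass(frozen=True)
class DoseResponseParams:
    """Median-effect parameters for a simulated single agent."""

    drug: str
    m: float
    dm: float
    doses: tuple[float, ...]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m <= 0 or self.dm <= 0:
            raise ValueError("m and Dm must be > 0")
        if any(d <= 0 for d in self.doses):
            raise ValueError("doses must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _median_effect_fa(dose: np.ndarray, m: float, dm: float) -> np.ndarray:
    r = (dose / dm) ** m
    return r / (1.0 + r)


def _add_logit_noise(fa: np.ndarray, noise_sd: float, rng) -> np.ndarray:
    if noise_sd == 0.0:
        return fa
    z = np.log10(fa / (1.0 - fa)) + rng.normal(0.0, noise_sd, size=fa.shape)
    return 10.0**z / (1.0 + 10.0**z)


def generate_dose_response(params: DoseResponseParams) -> DoseResponse:
    """Single-agent fa(D) = (D/Dm)^m / (1 + (D/Dm)^m), noisy on the logit scale."""
    rng = np.random.default_rng(params.seed)
    doses = np.asarray(params.doses, dtype=float)
    fa = _median_effect_fa(doses, params.m, params.dm)
    fa = _add_logit_noise(fa, params.noise_sd, rng)
    data = pd.DataFrame(
        {"dose1": doses, "dose2": np.nan, "fa": fa, "flag": ""}
    )
    return DoseResponse(drugs=(params.drug,), data=data)


def generate_combination(
    params_drug1: DoseResponseParams,
    params_drug2: DoseResponseParams,
    combo_alpha: float = 1.0,
    ratio: tuple[float, float] = (1.0, 1.0),
    doses: Optional[Sequence[float]] = None,
    dose_pairs: Optional[Sequence[tuple[float, float]]] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DoseResponse:
    """Simulate a drug pair with a planted Loewe-interaction multiplier.

    At each dose pair (d1, d2), the generated fraction affected solves

        d1 / Dx1(fa) + d2 / Dx2(fa) = combo_alpha,

    so a downstream combination index computed from the true single-agent
    curves equals ``combo_alpha`` exactly in the noiseless case (<1 planted
    synergy, 1 additivity, >1 antagonism).  Dose pairs come either from
    explicit ``dose_pairs`` or from total ``doses`` split at the fixed
    ``ratio``.  A dose pair whose root solve fails is kept as a flagged row
    rather than silently clamped.
    """
    if combo_alpha <= 0:
        raise ValueError("combo_alpha must be > 0")
    if dose_pairs is None:
        if doses is None:
            raise ValueError("provide either doses (with ratio) or dose_pairs")
        r1, r2 = ratio
        if r1 < 0 or r2 < 0 or r1 + r2 == 0:
            raise ValueError("ratio components must be nonnegative, not both zero")
        frac1 = r1 / (r1 + r2)
        dose_pairs = [(d * frac1, d * (1.0 - frac1)) for d in doses]
    rng = np.random.default_rng(seed)
    p1, p2 = params_drug1, params_drug2
    rows = []
    for d1, d2 in dose_pairs:
        if d1 < 0 or d2 < 0 or d1 + d2 <= 0:
            raise ValueError("dose pair components must be nonnegative, not both zero")

        def excess(fa: float) -> float:
            total = 0.0
            if d1 > 0:
                total += d1 / (p1.dm * (fa / (1.0 - fa)) ** (1.0 / p1.m))
            if d2 > 0:
                total += d2 / (p2.dm * (fa / (1.0 - fa)) ** (1.0 / p2.m))
            return total - combo_alpha

        flag = ""
        fa = math.nan
        try:
            fa = brentq(excess, 1e-12, 1.0 - 1e-12, xtol=1e-15, rtol=8.9e-16)
        except ValueError:
            flag = "no fa solution in (0, 1)"
        if flag == "":
            fa = float(
                _add_logit_noise(np.array([fa]), noise_sd, rng)[0]
            )
        rows.append((d1 if d1 > 0 else math.nan, d2, fa, flag))
    # single-agent-like rows with d1 == 0 are not expected here; keep d1 > 0
    data = pd.DataFrame(rows, columns=["dose1", "dose2", "fa", "flag"])
    return DoseResponse(drugs=(p1.drug, p2.drug), data=data)


def generate_fingerprints(
    n_molecules: int,
    n_bits: int,
    family_overlap: float,
    seed: int = 0,
    n_families: int = 5,
    density: float = 0.5,
) -> list[Fingerprint]:
    """Fingerprint families with a controllable shared-bit fraction.

    The bit space is partitioned into ``n_families`` contiguous blocks, one
    per family, so cross-family Tanimoto is exactly 0.  Within a family's
    block, each bit is a shared "core" bit with probability
    ``density * family_overlap`` and otherwise a per-molecule private bit
    with probability chosen so the total expected density is ``density``;
    hence a molecule's set bits are core with expected fraction
    ``family_overlap`` (1 → identical fingerprints within a family).
    Molecule ids are ``F{family}_M{index}``.
    """
    if n_bits <= 0:
        raise ValueError("n_bits must be > 0")
    if not 0.0 <= family_overlap <= 1.0:
        raise ValueError("family_overlap must be in [0, 1]")
    if not 0.0 < density <= 1.0:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    block = n_bits // n_families
    if block == 0:
        raise ValueError("n_bits too small for n_families")
    core_p = density * family_overlap
    private_p = (density - core_p) / (1.0 - core_p) if core_p < 1.0 else 0.0
    fps: list[Fingerprint] = []
    for i in range(n_molecules):
        fam = i % n_families
        # per-family core pattern must be reproducible across its members
        fam_rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31) + fam)
        core = fam_rng.random(block) < core_p
        private = rng.random(block) < private_p
        bits = np.flatnonzero(core | (~core & private)) + fam * block
        fps.append(Fingerprint(f"F{fam}_M{i:03d}", frozenset(bits.tolist()), n_bits))
    return fps


def generate_reference_profiles(
    genes: Sequence[str],
    query: QuerySignature,
    n_decoys: int = 20,
    planted_id: str = "planted",
    effect: float = 3.0,
    seed: int = 0,
) -> dict[str, RankedProfile]:
    """Reference profile collection with one planted connectivity hit.

    The planted compound's profile shifts the query's up genes up by
    ``effect`` and down genes down by ``effect`` on top of standard-normal
    scores; decoys are pure noise.  Feeds connectivity retrieval tests and
    the pipeline demo.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    profiles: dict[str, RankedProfile] = {}
    scores = pd.Series(rng.standard_normal(len(genes)), index=genes)
    scores[scores.index.isin(query.up_set)] += effect
    scores[scores.index.isin(query.down_set)] -= effect
    profiles[planted_id] = RankedProfile.from_scores(scores)
    for j in range(n_decoys):
        s = pd.Series(rng.standard_normal(len(genes)), index=genes)
        profiles[f"decoy{j:03d}"] = RankedProfile.from_scores(s)
    return profiles
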