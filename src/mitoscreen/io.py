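"""Plain-text readers and writers for every pipeline artifact.

Formats
-------
expression.tsv   genes as rows, header row of sample ids
samples.tsv      sample, patient, condition
survival.tsv     patient, time, event
*.gmt            one gene set per line: name <TAB> description <TAB> genes...
kinome .csv      kinase, pctCtrl, is_mutant
dose .csv        drug, dose1, dose2, fa  (dose2 empty for single agents)
fingerprints     id <TAB> hex bitstring (4 bits per hex digit, bit 0 = MSB)
ranked profile   gene <TAB> score
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .connectivity import Fingerprint, RankedProfile
from .kinome import KinomeProfile
from .synergy import DoseResponse
from .synthetic import CohortTruth, ExpressionCohort

__all__ = [
    "write_cohort",
    "read_cohort",
    "read_gmt",
    "write_gmt",
    "read_kinome_csv",
    "write_kinome_csv",
    "read_dose_response_csv",
    "write_dose_response_csv",
    "read_fingerprints",
    "write_fingerprints",
    "read_ranked_profile",
    "write_ranked_profile",
]


# ---------------------------------------------------------------- cohorts

def write_cohort(cohort: ExpressionCohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr = cohort.values.copy()
    expr.index.name = "gene"
    expr.to_csv(out / "expression.tsv", sep="\t")
    ann = pd.DataFrame(
        {
            "sample": cohort.condition.index,
            "patient": [cohort.sample_patient[s] for s in cohort.condition.index],
            "condition": cohort.condition.to_numpy(),
        }
    )
    ann.to_csv(out / "samples.tsv", sep="\t", index=False)
    surv = cohort.survival.reset_index()
    surv.to_csv(out / "survival.tsv", sep="\t", index=False)
    if cohort.truth is not None:
        truth = {
            "signature_genes": cohort.truth.signature_genes,
            "activity": cohort.truth.activity.to_dict(),
            "anchor_gene": cohort.truth.anchor_gene,
            "sl_partner_gene": cohort.truth.sl_partner_gene,
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1))


def read_cohort(in_dir: str | Path) -> ExpressionCohort:
    src = Path(in_dir)
    values = pd.read_csv(src / "expression.tsv", sep="\t", index_col="gene")
    ann = pd.read_csv(src / "samples.tsv", sep="\t", dtype=str)
    condition = pd.Series(ann["condition"].to_numpy(), index=ann["sample"])
    sample_patient = pd.Series(ann["patient"].to_numpy(), index=ann["sample"])
    surv = pd.read_csv(src / "survival.tsv", sep="\t").set_index("patient")
    by_patient = ann.pivot(index="patient", columns="condition", values="sample")
    pairing = {
        r.normal: r.tumor
        for r in by_patient.itertuples()
        if isinstance(r.normal, str) and isinstance(r.tumor, str)
    }
    truth = None
    truth_path = src / "truth.json"
    if truth_path.exists():
        t = json.loads(truth_path.read_text())
        truth = CohortTruth(
            signature_genes=list(t["signature_genes"]),
            activity=pd.Series(t["activity"]),
            anchor_gene=t["anchor_gene"],
            sl_partner_gene=t.get("sl_partner_gene"),
        )
    return ExpressionCohort(
        values=values,
        condition=condition,
        pairing=pairing,
        survival=surv,
        sample_patient=sample_patient,
        truth=truth,
    )


# ------------------------------------------------------------------- GMT

def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """GMT file -> {set name: (description, [genes])}."""
    sets: dict[str, tuple[str, list[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = (fields[1], [g for g in fields[2:] if g])
    return sets


def write_gmt(sets: Mapping[str, tuple[str, Iterable[str]]], path: str | Path) -> None:
    lines = [
        "\t".join([name, desc, *sorted(map(str, genes))])
        for name, (desc, genes) in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- kinome

def write_kinome_csv(profile: KinomeProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, index=False)


def read_kinome_csv(path: str | Path) -> KinomeProfile:
    return KinomeProfile.from_frame(pd.read_csv(path))


# --------------------------------------------------------- dose-response

def write_dose_response_csv(dr: DoseResponse, path: str | Path) -> None:
    df = dr.data.copy()
    df.insert(0, "drug", "+".join(dr.drugs))
    df.to_csv(path, index=False)


def read_dose_response_csv(path: str | Path) -> DoseResponse:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    drugs = tuple(str(df["drug"].iloc[0]).split("+"))
    data = df[["dose1", "dose2", "fa"]].astype(float).copy()
    data["flag"] = df["flag"].fillna("").astype(str) if "flag" in df else ""
    return DoseResponse(drugs=drugs, data=data)


# ------------------------------------------------------------ fingerprints

def _fp_to_hex(fp: Fingerprint) -> str:
    n_nibbles = -(-fp.n_bits // 4)
    val = 0
    for b in fp.bits:
        val |= 1 << (n_nibbles * 4 - 1 - b)
    return format(val, f"0{n_nibbles}x")


def _fp_from_hex(fp_id: str, hexstr: str) -> Fingerprint:
    n_bits = 4 * len(hexstr)
    val = int(hexstr, 16)
    bits = frozenset(
        i for i in range(n_bits) if (val >> (n_bits - 1 - i)) & 1
    )
    return Fingerprint(fp_id, bits, n_bits)


def write_fingerprints(fps: Iterable[Fingerprint], path: str | Path) -> None:
    """`id<TAB>hex` lines; n_bits is padded up to a multiple of 4."""
    lines = [f"{fp.id}\t{_fp_to_hex(fp)}" for fp in fps]
    Path(path).write_text("\n".join(lines) + "\n")


def read_fingerprints(path: str | Path) -> dict[str, Fingerprint]:
    fps: dict[str, Fingerprint] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fp_id, hexstr = line.split("\t")
        fps[fp_id] = _fp_from_hex(fp_id, hexstr)
    return fps


# --------------------------------------------------------- ranked profiles

def write_ranked_profile(profile: RankedProfile, path: str | Path) -> None:
    pd.DataFrame({"gene": profile.genes, "score": profile.scores}).to_csv(
        path, sep="\t", index=False
    )


def read_ranked_profile(path: str | Path) -> RankedProfile:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    return RankedProfile.from_scores(pd.Series(df["score"].to_numpy(), index=df["gene"]))
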