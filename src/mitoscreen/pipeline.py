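"""End-to-end orchestration of the discovery chain on a YAML config.

``run_discovery`` executes the toggled stages — simulate, connect, kinome,
amses, slscreen, synergy — on synthetic inputs with planted truth, writes
every stage artifact as plain text under the configured output directory,
and finishes with a manifest (parameters, output sha256 hashes, key results,
package version).  The manifest is a pure function of (config, seed, code
version): re-running with the same config reproduces identical hashes.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import __version__, connectivity, io, kinome, mitosis, survival, synergy, synthetic

__all__ = ["DEFAULT_CONFIG", "load_config", "run_discovery"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 7,
    "out_dir": "mitoscreen_run",
    "stages": {
        "simulate": True,
        "connect": True,
        "kinome": True,
        "amses": True,
        "slscreen": True,
        "synergy": True,
    },
    "cohort": {
        "n_patients": 150,
        "n_genes": 500,
        "n_signature_genes": 40,
        "anchor_gene": "GSG2",
        "factor_loading": 1.0,
        "tumor_shift": 1.0,
        "hazard_beta": 0.5,
        "sl_partner_gene": "PLK1",
        "sl_interaction_beta": 1.2,
        "censor_rate": 0.3,
        "noise_sd": 0.5,
    },
    "connect": {
        "n_query_genes": 15,
        "n_decoys": 10,
        "weight_exponent": 1.0,
        "n_bits": 512,
        "n_families": 4,
        "family_overlap": 0.7,
    },
    "kinome": {"n_kinases": 403, "n_mutant": 0, "n_hits": 17, "threshold": 10.0},
    "amses": {
        "tau": 0.25,
        "corr_method": "spearman",
        "fdr_cut": 0.05,
        "elevation_fdr": 0.05,
        "n_candidate_decoys": 60,
    },
    "slscreen": {"split": "median", "n_decoy_candidates": 10},
    "synergy": {
        "drug1": {"name": "LJ", "m": 1.2, "dm": 300.0,
                  "doses": [50.0, 100.0, 200.0, 400.0, 800.0, 1600.0]},
        "drug2": {"name": "BI", "m": 1.5, "dm": 4.0,
                  "doses": [0.5, 1.0, 2.0, 4.0, 8.0, 16.0]},
        "combo_alpha": 0.5,
        "noise_sd": 0.02,
        "combo_doses_1": [250.0, 500.0],
        "combo_doses_2": [1.0, 3.0, 5.0],
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: Optional[str | Path] = None) -> dict[str, Any]:
    """Load a YAML config on top of the explicit defaults."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    user = yaml.safe_load(Path(path).read_text()) or {}
    return _merge(DEFAULT_CONFIG, user)


def _stage_seed(seed: int, idx: int) -> int:
    return int((seed * 1000003 + idx) % 2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_discovery(
    config: dict[str, Any] | str | Path,
    out_dir: Optional[str | Path] = None,
) -> dict[str, Any]:
    """Run the toggled stages and return (and write) the run manifest.

    A stage failure raises with the failing stage named; artifacts written
    before the failure are retained.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else _merge(DEFAULT_CONFIG, config)
    seed = int(cfg["seed"])
    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    manifest: dict[str, Any] = {
        "config": cfg,
        "seed": seed,
        "version": __version__,
        "outputs": {},
        "results": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": _sha256(path),
        }

    cohort = None
    current = "simulate"
    try:
        # ---------------------------------------------------------- simulate
        if stages.get("simulate"):
            cc = cfg["cohort"]
            cohort = synthetic.generate_cohort(
                synthetic.CohortParams(seed=_stage_seed(seed, 0), **cc)
            )
            io.write_cohort(cohort, out / "cohort")
            for f in ("expression.tsv", "samples.tsv", "survival.tsv", "truth.json"):
                record(f"cohort/{f}", out / "cohort" / f)

            kc = cfg["kinome"]
            profile = synthetic.generate_kinome_profile(
                n_kinases=kc["n_kinases"], n_mutant=kc["n_mutant"],
                n_hits=kc["n_hits"], threshold=kc["threshold"],
                seed=_stage_seed(seed, 1),
            )
            io.write_kinome_csv(profile, out / "kinome.csv")
            record("kinome.csv", out / "kinome.csv")

            sc = cfg["synergy"]
            p1 = synthetic.DoseResponseParams(
                drug=sc["drug1"]["name"], m=sc["drug1"]["m"], dm=sc["drug1"]["dm"],
                doses=tuple(sc["drug1"]["doses"]), noise_sd=sc["noise_sd"],
                seed=_stage_seed(seed, 2),
            )
            p2 = synthetic.DoseResponseParams(
                drug=sc["drug2"]["name"], m=sc["drug2"]["m"], dm=sc["drug2"]["dm"],
                doses=tuple(sc["drug2"]["doses"]), noise_sd=sc["noise_sd"],
                seed=_stage_seed(seed, 3),
            )
            pairs = [(d1, d2) for d1 in sc["combo_doses_1"] for d2 in sc["combo_doses_2"]]
            combo = synthetic.generate_combination(
                p1, p2, combo_alpha=sc["combo_alpha"], dose_pairs=pairs,
                noise_sd=sc["noise_sd"], seed=_stage_seed(seed, 4),
            )
            io.write_dose_response_csv(synthetic.generate_dose_response(p1), out / "dose_drug1.csv")
            io.write_dose_response_csv(synthetic.generate_dose_response(p2), out / "dose_drug2.csv")
            io.write_dose_response_csv(combo, out / "dose_combo.csv")
            for f in ("dose_drug1.csv", "dose_drug2.csv", "dose_combo.csv"):
                record(f, out / f)

        if cohort is None:
            cohort = io.read_cohort(out / "cohort")
        truth = cohort.truth

        # ----------------------------------------------------------- connect
        current = "connect"
        if stages.get("connect"):
            nc = cfg["connect"]
            rng = np.random.default_rng(_stage_seed(seed, 5))
            sig = truth.signature_genes
            up = sorted(rng.choice(sig, size=min(nc["n_query_genes"], len(sig)),
                                   replace=False).tolist())
            non_sig = sorted(set(cohort.genes) - set(sig) - {truth.anchor_gene})
            down = sorted(rng.choice(non_sig, size=nc["n_query_genes"],
                                     replace=False).tolist())
            query = connectivity.QuerySignature(frozenset(up), frozenset(down))
            profiles = synthetic.generate_reference_profiles(
                cohort.genes, query, n_decoys=nc["n_decoys"],
                planted_id="planted", seed=_stage_seed(seed, 6),
            )
            fps = synthetic.generate_fingerprints(
                n_molecules=nc["n_families"] + nc["n_decoys"] + 1,
                n_bits=nc["n_bits"],
                family_overlap=nc["family_overlap"], seed=_stage_seed(seed, 7),
                n_families=nc["n_families"],
            )
            # families are assigned round-robin, so fps[0] and
            # fps[n_families] belong to family 0: the query fingerprint and
            # the planted compound share a family, decoys rotate through the
            # rest.
            compound_ids = ["planted"] + [f"decoy{j:03d}" for j in range(nc["n_decoys"])]
            query_fp = connectivity.Fingerprint("query", fps[0].bits, fps[0].n_bits)
            fp_map = {
                cid: connectivity.Fingerprint(cid, fp.bits, fp.n_bits)
                for cid, fp in zip(compound_ids, fps[nc["n_families"]:])
            }
            io.write_fingerprints(list(fp_map.values()) + [query_fp], out / "fingerprints.txt")
            record("fingerprints.txt", out / "fingerprints.txt")
            ranking = connectivity.rank_candidates(
                profiles, query, weight_exponent=nc["weight_exponent"],
                fingerprints=fp_map, query_fp=query_fp,
            )
            ranking.to_csv(out / "connectivity_ranking.tsv", sep="\t", index=False)
            record("connectivity_ranking.tsv", out / "connectivity_ranking.tsv")
            manifest["results"]["connect_top_compound"] = str(ranking["compound"].iloc[0])
            manifest["results"]["connect_planted_combined_rank"] = float(
                ranking.loc[ranking["compound"] == "planted", "combined_rank"].iloc[0]
            )

        # ------------------------------------------------------------ kinome
        current = "kinome"
        if stages.get("kinome"):
            profile = io.read_kinome_csv(out / "kinome.csv")
            thr = cfg["kinome"]["threshold"]
            score = kinome.s_score(profile, thr)
            curve = kinome.selectivity_curve(profile, [1.0, thr, 35.0])
            curve.to_csv(out / "selectivity.tsv", sep="\t", index=False)
            record("selectivity.tsv", out / "selectivity.tsv")
            hits = kinome.call_hits(profile, thr)
            (out / "kinome_hits.txt").write_text("\n".join(hits) + "\n")
            record("kinome_hits.txt", out / "kinome_hits.txt")
            manifest["results"]["s_score"] = score.rounded
            manifest["results"]["n_kinome_hits"] = score.n_hits

        # ------------------------------------------------------------- amses
        current = "amses"
        if stages.get("amses"):
            ac = cfg["amses"]
            rng = np.random.default_rng(_stage_seed(seed, 8))
            decoy_pool = sorted(
                set(cohort.genes) - set(truth.signature_genes) - {truth.anchor_gene}
            )
            candidates = set(truth.signature_genes) | set(
                rng.choice(decoy_pool, size=min(ac["n_candidate_decoys"], len(decoy_pool)),
                           replace=False).tolist()
            )
            signature = mitosis.derive_signature(
                cohort, truth.anchor_gene, candidates,
                corr_method=ac["corr_method"], fdr_cut=ac["fdr_cut"],
                elevation_fdr=ac["elevation_fdr"],
            )
            io.write_gmt(
                {"active_mitosis": (json.dumps(signature.derivation), signature.genes)},
                out / "signature.gmt",
            )
            record("signature.gmt", out / "signature.gmt")
            scores = mitosis.amses(cohort, signature, tau=ac["tau"])
            sdf = scores.raw.rename("raw").to_frame()
            if scores.normalized is not None:
                sdf["normalized"] = scores.normalized
            sdf.index.name = "sample"
            sdf.to_csv(out / "amses.tsv", sep="\t")
            record("amses.tsv", out / "amses.tsv")
            planted = set(truth.signature_genes)
            recovered = set(signature.genes)
            manifest["results"]["signature_size"] = len(recovered)
            manifest["results"]["signature_recall"] = len(planted & recovered) / len(planted)
            manifest["results"]["amses_truth_spearman"] = scores.truth_spearman

        # ---------------------------------------------------------- slscreen
        current = "slscreen"
        if stages.get("slscreen"):
            slc = cfg["slscreen"]
            rng = np.random.default_rng(_stage_seed(seed, 9))
            decoy_pool = sorted(
                set(cohort.genes) - set(truth.signature_genes)
                - {truth.anchor_gene, truth.sl_partner_gene}
            )
            cand = set(
                rng.choice(decoy_pool, size=slc["n_decoy_candidates"], replace=False).tolist()
            )
            if truth.sl_partner_gene is not None:
                cand.add(truth.sl_partner_gene)
            screen = survival.stratified_sl_screen(
                cohort, truth.anchor_gene, cand, split=slc["split"]
            )
            screen.table.to_csv(out / "sl_screen.tsv", sep="\t")
            record("sl_screen.tsv", out / "sl_screen.tsv")
            manifest["results"]["sl_partners_called"] = screen.partners()
            if truth.sl_partner_gene is not None:
                manifest["results"]["planted_sl_partner_recovered"] = (
                    truth.sl_partner_gene in screen.partners()
                )

        # ----------------------------------------------------------- synergy
        current = "synergy"
        if stages.get("synergy"):
            single1 = io.read_dose_response_csv(out / "dose_drug1.csv")
            single2 = io.read_dose_response_csv(out / "dose_drug2.csv")
            combo = io.read_dose_response_csv(out / "dose_combo.csv")
            facit = synergy.fa_ci_table(single1, single2, combo)
            facit.table.to_csv(out / "fa_ci.tsv", sep="\t", index=False)
            record("fa_ci.tsv", out / "fa_ci.tsv")
            valid_ci = facit.table.loc[facit.table["flag"] == "", "ci"]
            manifest["results"]["mean_ci"] = float(valid_ci.mean())
            manifest["results"]["all_ci_below_one"] = bool((valid_ci < 1).all())
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
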