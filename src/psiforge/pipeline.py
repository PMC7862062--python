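"""End-to-end orchestration of the synthetic study.

``run_pipeline`` executes the enabled stages in dependency order —

    simulate → psi_quant / snorna_expr / screen → diff_psi → integration

— writing headered TSVs plus a machine-readable ``report.json``. All
randomness derives from the single master seed, so re-running with the
same config reproduces every output byte-identically. A stage failure
halts only its dependents; the report marks them skipped.

The bundled demo configuration wires the stages together the way the
emulated study is wired: the up-regulated H/ACA snoRNAs from the count
simulation guide the rRNA sites whose pseudouridylation is shifted upward
in the tumour condition, including a three-site hotspot, so the
integration stage has a real signal to find.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
import traceback
from dataclasses import asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from psiforge import diff_psi, integrate, io, psi_quant, screen, snorna_expr, synthetic

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised with every detected configuration problem at once."""


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "stages": {
        "simulate": True,
        "psi": True,
        "diff_psi": True,
        "snorna": True,
        "screen": True,
        "integration": True,
    },
    "psi": {
        "molecules": {"18S-like": 600, "28S-like": 800},
        "n_sites_per_molecule": 15,
        "baseline_stoichiometry": 0.35,
        "termination_efficiency": 0.9,
        "background_stop_rate": 0.005,
        "mean_read_length": 80,
        "coverage": 150,
        "offset": 0,
        "min_coverage": 20,
        "n_pairs": 5,
        "tumor_shift": 0.12,
        "pair_jitter_sd": 0.02,
        "hotspot_positions": [105, 109, 119],
    },
    "counts": {
        "n_cd": 40,
        "n_haca": 30,
        "n_pairs": 7,
        "dispersion": 0.1,
        "pair_effect_sd": 0.15,
        "n_upregulated": 9,
        "fold_change": 4.0,
        "total_mapped_reads": 300000,
        "lfc_threshold": 1.5,
        "p_threshold": 0.05,
    },
    "screen": {
        "n_null_targets": 60,
        "n_hit_targets": 3,
        "hit_fitness": -0.3,
        "grnas_per_target": 3,
        "n_nontargeting": 30,
        "depth": 200000,
        "timepoints": [0, 3, 5, 9],
        "replicates": 2,
        "doublings_per_day": 1.0,
        "day": 9,
        "n_perm": 1000,
        "fdr_threshold": 0.8,
    },
    "integration": {"mode": "fisher", "n_perm": 1000, "p_threshold": 0.05},
}


def _check_unknown(given: dict, defaults: dict, prefix: str, errors: list[str]) -> None:
    for key, val in given.items():
        if key not in defaults:
            errors.append(f"unknown config key: {prefix}{key}")
        elif isinstance(defaults[key], dict) and key != "molecules":
            if not isinstance(val, dict):
                errors.append(f"{prefix}{key} must be a mapping")
            else:
                _check_unknown(val, defaults[key], f"{prefix}{key}.", errors)


def _merge(defaults: dict, given: dict) -> dict:
    out = copy.deepcopy(defaults)
    for key, val in given.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict) and key != "molecules":
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def validate_config(config: dict | str | os.PathLike) -> dict:
    """Validate a pipeline config (dict or YAML path); collect every error.

    Unknown keys are rejected (typo guard); numeric parameters are range
    checked. Returns the validated config merged over the defaults.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    errors: list[str] = []
    _check_unknown(config, DEFAULT_CONFIG, "", errors)
    cfg = _merge(DEFAULT_CONFIG, config)

    def check(cond: bool, msg: str) -> None:
        if not cond:
            errors.append(msg)

    check(isinstance(cfg["seed"], int) and cfg["seed"] >= 0, "seed must be a non-negative integer")
    p = cfg["psi"]
    check(p["coverage"] > 0, "psi.coverage must be > 0")
    check(p["min_coverage"] >= 1, "psi.min_coverage must be >= 1")
    check(p["offset"] in (0, 1), "psi.offset must be 0 or 1")
    check(0 <= p["background_stop_rate"] <= 0.05, "psi.background_stop_rate must be in [0, 0.05]")
    check(0 <= p["termination_efficiency"] <= 1, "psi.termination_efficiency must be in [0, 1]")
    check(0 <= p["baseline_stoichiometry"] <= 1, "psi.baseline_stoichiometry must be in [0, 1]")
    check(p["n_pairs"] >= 3, "psi.n_pairs must be >= 3")
    check(all(v >= 200 for v in p["molecules"].values()), "psi.molecules lengths must be >= 200")
    c = cfg["counts"]
    check(c["fold_change"] > 0, "counts.fold_change must be > 0")
    check(c["dispersion"] > 0, "counts.dispersion must be > 0")
    check(c["n_pairs"] >= 3, "counts.n_pairs must be >= 3")
    s = cfg["screen"]
    check(abs(s["hit_fitness"]) < 1, "screen.hit_fitness must satisfy |s| < 1")
    check(s["depth"] > 0, "screen.depth must be > 0")
    check(s["n_perm"] >= 1000, "screen.n_perm must be >= 1000")
    check(0 in s["timepoints"], "screen.timepoints must include day 0")
    check(s["day"] in s["timepoints"], "screen.day must be one of screen.timepoints")
    check(cfg["integration"]["mode"] in ("fisher", "permutation"),
          "integration.mode must be 'fisher' or 'permutation'")
    if errors:
        raise ConfigError("invalid pipeline config:\n  - " + "\n  - ".join(errors))
    return cfg


def config_hash(cfg: dict) -> str:
    blob = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def init_config(path: str | os.PathLike) -> None:
    """Write the demo configuration to ``path`` (validates unchanged)."""
    with open(path, "w") as fh:
        yaml.safe_dump(DEFAULT_CONFIG, fh, sort_keys=True)


def _demo_sites(cfg: dict, upregulated: list[str]) -> list[synthetic.PsiSite]:
    """Lay out Ψ sites; up-regulated snoRNAs guide the first sites (incl. hotspot)."""
    p = cfg["psi"]
    molecules = list(p["molecules"])
    positions: list[tuple[str, int]] = [(molecules[0], pos) for pos in p["hotspot_positions"]]
    for mol in molecules:
        length = p["molecules"][mol]
        pos = 160
        while len([x for x in positions if x[0] == mol]) < p["n_sites_per_molecule"] and pos < length - 20:
            if (mol, pos) not in positions:
                positions.append((mol, pos))
            pos += 30
    guides = list(upregulated)
    n_haca = cfg["counts"]["n_haca"]
    all_haca = [f"SNORA_{i:03d}" for i in range(1, n_haca + 1)]
    guides += [g for g in all_haca if g not in guides]
    sites = []
    for i, (mol, pos) in enumerate(positions):
        guide = guides[i] if i < len(guides) else ""
        sites.append(
            synthetic.PsiSite(mol, pos, cfg["psi"]["baseline_stoichiometry"], guide)
        )
    return sites


def run_pipeline(config: dict | str | os.PathLike, outdir: str | os.PathLike) -> dict:
    """Run the enabled stages; return the run report (also written as JSON)."""
    cfg = validate_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config_hash(cfg), "seed": cfg["seed"]}
    report: dict[str, Any] = {
        "config_hash": meta["config_hash"],
        "seed": cfg["seed"],
        "parameters": cfg,
        "stages": {},
        "warnings": [],
    }
    state: dict[str, Any] = {}

    def run_stage(name: str, deps: list[str], fn) -> None:
        stage_report: dict[str, Any] = {"status": "ok", "records": {}}
        if not cfg["stages"].get(name, True):
            stage_report["status"] = "disabled"
        elif any(report["stages"].get(d, {}).get("status") not in ("ok",) for d in deps):
            stage_report["status"] = "skipped"
            stage_report["reason"] = "upstream stage unavailable"
        else:
            try:
                fn(stage_report)
            except Exception as exc:  # halt downstream dependents only
                stage_report["status"] = "failed"
                stage_report["error"] = f"{type(exc).__name__}: {exc}"
                logger.error("stage %s failed:\n%s", name, traceback.format_exc())
        report["stages"][name] = stage_report

    # ---- simulate -------------------------------------------------------
    def do_simulate(rep: dict) -> None:
        sim_dir = out / "simulate"
        (sim_dir / "reads").mkdir(parents=True, exist_ok=True)
        seed = cfg["seed"]
        ccfg = synthetic.SimCountConfig(
            n_cd=cfg["counts"]["n_cd"], n_haca=cfg["counts"]["n_haca"],
            n_pairs=cfg["counts"]["n_pairs"], dispersion=cfg["counts"]["dispersion"],
            pair_effect_sd=cfg["counts"]["pair_effect_sd"],
            n_upregulated=cfg["counts"]["n_upregulated"],
            fold_change=cfg["counts"]["fold_change"],
            total_mapped_reads=cfg["counts"]["total_mapped_reads"], seed=seed,
        )
        counts, totals, cdesign, truth = synthetic.simulate_snorna_counts(ccfg)
        io.write_tsv(counts.reset_index(), sim_dir / "snorna_counts.tsv", meta)
        io.write_tsv(totals.reset_index(), sim_dir / "snorna_totals.tsv", meta)
        io.write_tsv(cdesign, sim_dir / "snorna_design.tsv", meta)
        io.write_tsv(truth, sim_dir / "snorna_truth.tsv", meta)
        upregulated = truth.loc[truth["upregulated"], "snorna"].tolist()

        p = cfg["psi"]
        sites = _demo_sites(cfg, upregulated)
        pcfg = synthetic.SimPsiConfig(
            molecule_lengths=dict(p["molecules"]), sites=sites,
            termination_efficiency=p["termination_efficiency"],
            background_stop_rate=p["background_stop_rate"],
            mean_read_length=p["mean_read_length"], coverage=p["coverage"],
            termination_offset=p["offset"], seed=seed,
        )
        sequences, site_table = synthetic.make_reference(pcfg)
        io.write_fasta(sequences, sim_dir / "reference.fa")
        io.write_tsv(site_table, sim_dir / "sites.tsv", meta)
        shift = {
            (s.molecule, s.position): p["tumor_shift"]
            for s in sites if s.guide in set(upregulated)
        }
        sample_reads, pdesign = synthetic.simulate_paired_psi_samples(
            pcfg, p["n_pairs"], shift_a=shift, pair_jitter_sd=p["pair_jitter_sd"]
        )
        for sample_id, reads in sample_reads.items():
            io.write_sam(sim_dir / "reads" / f"{sample_id}.sam", pcfg.molecule_lengths,
                         reads, sequences)
        io.write_tsv(pdesign, sim_dir / "psi_design.tsv", meta)

        guide_map = site_table.loc[site_table["guides"] != "", ["guides", "site_id"]]
        guide_map = guide_map.rename(columns={"guides": "snorna"})
        io.write_tsv(guide_map, sim_dir / "guide_map.tsv", meta)

        s = cfg["screen"]
        targets = [
            synthetic.TargetSpec(f"HIT_{i:02d}", s["grnas_per_target"], s["hit_fitness"])
            for i in range(1, s["n_hit_targets"] + 1)
        ] + [
            synthetic.TargetSpec(f"NULL_{i:03d}", s["grnas_per_target"], 0.0)
            for i in range(1, s["n_null_targets"] + 1)
        ]
        scfg = synthetic.SimScreenConfig(
            targets=targets, n_nontargeting=s["n_nontargeting"],
            timepoints_days=tuple(s["timepoints"]), doublings_per_day=s["doublings_per_day"],
            replicates=s["replicates"], depth=s["depth"], seed=seed,
        )
        stable, struth = synthetic.simulate_screen_counts(scfg)
        io.write_tsv(stable, sim_dir / "screen_counts.tsv", meta)
        io.write_tsv(struth, sim_dir / "screen_truth.tsv", meta)
        state.update(sim_dir=sim_dir, pcfg=pcfg, site_table=site_table, pdesign=pdesign,
                     counts=counts, totals=totals, cdesign=cdesign, truth=truth,
                     stable=stable, guide_map=guide_map)
        rep["records"] = {
            "psi_samples": len(sample_reads),
            "psi_reads": int(sum(len(r) for r in sample_reads.values())),
            "snornas": len(counts),
            "grnas": len(stable),
        }

    run_stage("simulate", [], do_simulate)

    # ---- psi_quant ------------------------------------------------------
    def do_psi(rep: dict) -> None:
        psi_dir = out / "psi"
        psi_dir.mkdir(exist_ok=True)
        p = cfg["psi"]
        profiles = []
        sam_dir = state["sim_dir"] / "reads"
        for sam in sorted(sam_dir.glob("*.sam")):
            profiles.append(psi_quant.build_profile(sam, state["pcfg"].molecule_lengths,
                                                    sample_id=sam.stem))
        matrix = psi_quant.build_ratio_matrix(
            profiles, state["site_table"], offset=p["offset"], min_coverage=p["min_coverage"]
        )
        psi_quant.write_ratio_matrix(matrix, psi_dir / "psi_matrix.tsv", meta)
        io.write_tsv(matrix.coverage.reset_index(), psi_dir / "coverage.tsv", meta)
        state["matrix"] = matrix
        rep["records"] = {
            "sites": len(matrix.values), "samples": len(matrix.samples),
            "missing_cells": int(matrix.values.isna().sum().sum()),
        }

    run_stage("psi", ["simulate"], do_psi)

    # ---- diff_psi -------------------------------------------------------
    def do_diff(rep: dict) -> None:
        dd = out / "diff_psi"
        dd.mkdir(exist_ok=True)
        matrix, pdesign = state["matrix"], state["pdesign"]
        tests = diff_psi.site_tests(matrix, pdesign)
        io.write_tsv(tests.reset_index(), dd / "site_tests.tsv", meta)
        hp = cfg["psi"]["hotspot_positions"]
        mol = list(cfg["psi"]["molecules"])[0]
        hot = diff_psi.hotspot_test(matrix, pdesign, mol, hp)
        io.write_tsv(pd.DataFrame([asdict(hot)]), dd / "hotspot.tsv", meta)
        guided = matrix.sites.loc[matrix.sites["guides"] != "", "site_id"].tolist()
        shift_rows = []
        for label, subset in (("all", None), ("guided", guided)):
            res = diff_psi.global_shift_test(
                matrix, pdesign["sample_a"].tolist(), pdesign["sample_b"].tolist(),
                site_subset=subset,
            )
            shift_rows.append({"subset": label, **asdict(res)})
        io.write_tsv(pd.DataFrame(shift_rows), dd / "global_shift.tsv", meta)
        state["site_tests"] = tests
        rep["records"] = {"sites_tested": int(tests["tested"].sum()),
                          "significant_sites": int(tests["significant"].sum()),
                          "hotspot_p": hot.p_value}

    run_stage("diff_psi", ["psi"], do_diff)

    # ---- snorna ---------------------------------------------------------
    def do_snorna(rep: dict) -> None:
        sd = out / "snorna"
        sd.mkdir(exist_ok=True)
        counts, totals, truth = state["counts"], state["totals"], state["truth"]
        classes = truth.set_index("snorna")["sno_class"]
        fractions = snorna_expr.class_fractions(counts, classes, totals)
        io.write_tsv(fractions, sd / "class_fractions.tsv", meta)
        volcano = snorna_expr.paired_de(
            counts, totals, state["cdesign"],
            lfc_threshold=cfg["counts"]["lfc_threshold"],
            p_threshold=cfg["counts"]["p_threshold"],
        )
        io.write_tsv(volcano.reset_index(), sd / "volcano.tsv", meta)
        state["volcano"] = volcano
        rep["records"] = {"snornas": len(volcano),
                          "enriched": int((volcano["status"] == "enriched").sum()),
                          "depleted": int((volcano["status"] == "depleted").sum())}

    run_stage("snorna", ["simulate"], do_snorna)

    # ---- screen ---------------------------------------------------------
    def do_screen(rep: dict) -> None:
        sd = out / "screen"
        sd.mkdir(exist_ok=True)
        s = cfg["screen"]
        table = state["stable"]
        norm = screen.normalize_counts(table)
        lfcs = {}
        for rep_i in range(1, s["replicates"] + 1):
            lfcs[f"r{rep_i}"] = screen.grna_lfc(norm, s["day"], rep_i)
        lfc_df = pd.DataFrame(lfcs)
        io.write_tsv(lfc_df.reset_index(), sd / "lfc.tsv", meta)
        corr_rows = []
        if s["replicates"] >= 2:
            corr = screen.replicate_correlation(lfcs["r1"], lfcs["r2"])
            corr_rows.append(asdict(corr))
            io.write_tsv(pd.DataFrame(corr_rows), sd / "replicate_correlation.tsv", meta)
        target_map = table.set_index("grna")["target"]
        selection = screen.aggregate_targets(
            lfc_df, target_map, n_perm=s["n_perm"], seed=cfg["seed"],
            fdr_threshold=s["fdr_threshold"],
        )
        io.write_tsv(selection.reset_index(), sd / "target_selection.tsv", meta)
        state["selection"] = selection
        rep["records"] = {
            "grnas": len(lfc_df), "targets": len(selection),
            "negative_calls": int((selection["direction"] == "negative").sum()),
            "positive_calls": int((selection["direction"] == "positive").sum()),
            "replicate_r": corr_rows[0]["r"] if corr_rows else None,
        }

    run_stage("screen", ["simulate"], do_screen)

    # ---- integration ----------------------------------------------------
    def do_integration(rep: dict) -> None:
        idir = out / "integration"
        idir.mkdir(exist_ok=True)
        linked = integrate.join_results(state["volcano"], state["site_tests"],
                                        state["guide_map"])
        io.write_tsv(linked, idir / "linked.tsv", meta)
        icfg = cfg["integration"]
        res = integrate.concordance_test(
            linked, mode=icfg["mode"], n_perm=icfg["n_perm"], seed=cfg["seed"],
            p_threshold=icfg["p_threshold"],
        )
        io.write_tsv(pd.DataFrame([{
            "a_linked_hyper": res.table[0], "b_linked_not": res.table[1],
            "c_unlinked_hyper": res.table[2], "d_rest": res.table[3],
            "odds_ratio": res.odds_ratio, "p_value": res.p_value,
            "mode": res.mode, "n_sites": res.n_sites, "degenerate": res.degenerate,
        }]), idir / "concordance.tsv", meta)
        rep["records"] = {"linked_rows": int(linked["linked"].sum()),
                          "concordance_p": res.p_value,
                          "odds_ratio": res.odds_ratio}

    run_stage("integration", ["diff_psi", "snorna"], do_integration)

    report["stages_ok"] = all(
        st["status"] in ("ok", "disabled") for st in report["stages"].values()
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report
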