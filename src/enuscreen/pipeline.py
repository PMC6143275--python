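"""End-to-end driver: simulate -> filter -> burden -> linkage -> cross.

Each stage consumes a named RNG substream spawned from the master seed, so a
stage can be reproduced in isolation, and the run manifest records every
input/output path with a checksum: identical config + seed implies identical
manifest checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from enuscreen.burden import burden_analysis, burden_table, manhattan_plot
from enuscreen.config import RunConfig
from enuscreen.crosses import (
    binomial_allele_test,
    bundled_cross_table,
    load_cross_table,
    penetrance_estimate,
    rescue_allele_fisher,
)
from enuscreen.filtering import filter_enu_candidates, load_variants, spectrum_summary
from enuscreen.linkage import cosegregation_test, informative_meioses, linkage_power, lod_two_point
from enuscreen.simulate import (
    Annotation,
    ScreenConfig,
    SpectrumConfig,
    build_annotation,
    simulate_rescue_pedigree,
    simulate_screen,
    write_cohort,
)

__all__ = ["run_pipeline", "validate_formats", "stage_seed"]

log = logging.getLogger("enuscreen")

STAGES = ("simulate", "filter", "burden", "linkage", "cross")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence([int(master_seed), idx])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the five analysis stages and return the run manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log.info("master seed %d; non-default parameters: %s",
             config.seed, config.non_default_items() or "(none)")
    from enuscreen import __version__

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }

    stage = "simulate"
    try:
        sim = config.simulate
        sim_seed = stage_seed(config.seed, "simulate")
        annotation = build_annotation(sim.n_genes, seed=sim_seed)
        rng = np.random.default_rng(np.random.SeedSequence([sim_seed, 1]))
        suppressors = {
            str(g): sim.penetrance
            for g in rng.choice(annotation.gene_ids, size=sim.n_suppressor_genes, replace=False)
        }
        screen_cfg = ScreenConfig(
            n_g1_mice=sim.n_g1_mice,
            suppressor_genes=suppressors,
            phenocopy_rate=sim.phenocopy_rate,
            de_novo_rate=sim.de_novo_rate,
            artifact_rate=sim.artifact_rate,
            depth_mean=sim.depth_mean,
            low_coverage_fraction=sim.low_coverage_fraction,
            female_fraction=sim.female_fraction,
            seed=sim_seed,
        )
        spectrum = SpectrumConfig(exonic_rate_lambda=sim.exonic_rate_lambda)
        cohort = simulate_screen(screen_cfg, spectrum, annotation)
        paths = write_cohort(
            cohort,
            out_dir / "cohort.vcf",
            out_dir / "truth.tsv",
            out_dir / "annotation.tsv",
            out_dir / "cohort.ped.tsv",
        )
        manifest["stages"]["simulate"] = {
            "seed": sim_seed,
            "outputs": {k: {"path": p, "sha256": _sha256(Path(p))} for k, p in paths.items()},
            "n_mice": len(cohort.mice),
            "n_variants": len(cohort.all_variants()),
        }

        stage = "filter"
        records = load_variants(paths["vcf"], annotation=annotation,
                                expected_samples=cohort.mouse_ids)
        candidates = filter_enu_candidates(records, min_depth=config.filter.min_depth,
                                           include_stoploss=config.filter.include_stoploss)
        cand_path = out_dir / "candidates.tsv"
        candidates.to_tsv(cand_path)
        sexes = {m.mouse_id: m.sex for m in cohort.mice}
        summary = spectrum_summary(candidates, sexes)
        summary_path = out_dir / "filter_summary.json"
        summary_path.write_text(json.dumps({
            "n_candidates": len(candidates),
            "removal_counts": candidates.removal_counts(),
            "mean_per_mouse": summary.mean_per_mouse,
            "mean_deleterious_per_mouse": summary.mean_deleterious_per_mouse,
            "class_fractions": {k: float(v) for k, v in summary.class_fractions.items()},
            "sub_fractions": {k: float(v) for k, v in summary.sub_fractions.items()},
            "x_female_male_ratio": summary.x_female_male_ratio,
        }, indent=2))
        manifest["stages"]["filter"] = {
            "outputs": {
                "candidates": {"path": str(cand_path), "sha256": _sha256(cand_path)},
                "summary": {"path": str(summary_path), "sha256": _sha256(summary_path)},
            },
            "n_candidates": len(candidates),
        }

        stage = "burden"
        burden_seed = stage_seed(config.seed, "burden")
        result = burden_analysis(candidates, annotation,
                                 n_perm=config.burden.n_perm, seed=burden_seed)
        table = burden_table(result, fdr_lines=tuple(config.burden.fdr_lines))
        burden_path = out_dir / "burden.tsv"
        table.to_csv(burden_path, sep="\t", index=False)
        plot_path = out_dir / "burden_manhattan.png"
        if not table.empty:
            manhattan_plot(table, plot_path, fdr_lines=tuple(config.burden.fdr_lines))
        manifest["stages"]["burden"] = {
            "seed": burden_seed,
            "outputs": {"table": {"path": str(burden_path), "sha256": _sha256(burden_path)}},
            "n_perm": config.burden.n_perm,
            "n_genes_tested": int(len(table)),
        }

        stage = "linkage"
        link_seed = stage_seed(config.seed, "linkage")
        lp = config.linkage
        rescue_founders = [m for m in cohort.mice if m.rescue_status]
        founder = rescue_founders[0] if rescue_founders else cohort.mice[0]
        ped = simulate_rescue_pedigree(
            founder.mouse_id, lp.n_offspring_per_generation, lp.theta_marker_trait,
            generations=lp.generations, rng=np.random.default_rng(link_seed),
        )
        rescues = informative_meioses(ped, group="rescues")
        litters = informative_meioses(ped, group="littermates")
        rows = []
        pooled = rescues + litters
        if pooled.n:
            res = lod_two_point(pooled, threshold=lp.lod_threshold)
            rows.append({"marker": "suppressor_marker", "theta_hat": res.theta_hat,
                         "max_lod": res.max_lod, "significant": res.significant})
        link_path = out_dir / "linkage.tsv"
        pd.DataFrame(rows).to_csv(link_path, sep="\t", index=False)
        coseg = None
        if rescues.n:
            c = cosegregation_test(rescues, litters, lp.theta_marker_trait)
            coseg = {"fisher_p": c.fisher_p, "binomial_p": c.binomial_p,
                     "table": [list(r) for r in c.table]}
        power = linkage_power(
            {"n_meioses": max(pooled.n, 1)}, lp.power_n_markers,
            list(np.linspace(0, 100, lp.power_n_markers)), lp.power_theta_true,
            n_sim=lp.power_n_sim, lod_threshold=lp.lod_threshold, seed=link_seed,
        )
        coseg_path = out_dir / "cosegregation.json"
        coseg_path.write_text(json.dumps({
            "cosegregation": coseg,
            "power": {"power": power.power, "ci": [power.ci_low, power.ci_high],
                      "n_sim": power.n_sim, "n_meioses": power.n_meioses},
        }, indent=2))
        manifest["stages"]["linkage"] = {
            "seed": link_seed,
            "outputs": {
                "linkage": {"path": str(link_path), "sha256": _sha256(link_path)},
                "cosegregation": {"path": str(coseg_path), "sha256": _sha256(coseg_path)},
            },
        }

        stage = "cross"
        crosses = (load_cross_table(config.cross.table) if config.cross.table
                   else bundled_cross_table())
        rows = []
        for cross in crosses:
            fisher = rescue_allele_fisher(cross)
            row = {
                "name": cross.name,
                "n_total": cross.n_total,
                "rescues_with": cross.rescues_with,
                "rescues_without": cross.rescues_without,
                "fisher_p": fisher.p_value,
                "degenerate": fisher.degenerate,
            }
            if cross.n_rescues:
                row["binomial_p"] = binomial_allele_test(cross.rescues_with, cross.rescues_without)
                pen = penetrance_estimate(cross)
                row.update(penetrance=pen.estimate, penetrance_ci_low=pen.ci_low,
                           penetrance_ci_high=pen.ci_high)
            rows.append(row)
        cross_path = out_dir / "crosses.tsv"
        pd.DataFrame(rows).to_csv(cross_path, sep="\t", index=False)
        manifest["stages"]["cross"] = {
            "outputs": {"crosses": {"path": str(cross_path), "sha256": _sha256(cross_path)}},
        }
    except Exception:
        log.exception("pipeline aborted in stage %r (partial outputs kept in %s)",
                      stage, out_dir)
        raise

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def validate_formats(paths: dict) -> list[dict]:
    """Check pipeline input files; returns a machine-readable issue list.

    ``paths`` may contain ``vcf``, ``annotation``, and ``ped`` entries.
    Issues are data, not exceptions: an empty list means the files are
    usable by every stage.
    """
    issues: list[dict] = []
    vcf_path = paths.get("vcf")
    if vcf_path:
        declared = set()
        with open(vcf_path) as fh:
            for line in fh:
                if not line.startswith("##"):
                    break
                if line.startswith("##FORMAT=<ID="):
                    declared.add(line.split("##FORMAT=<ID=")[1].split(",")[0])
        if "GT" not in declared:
            issues.append({"file": str(vcf_path), "issue": "GT FORMAT field missing; genotype filter impossible"})
        if "DP" not in declared:
            issues.append({"file": str(vcf_path), "issue": "depth field missing; >=6X filter impossible"})
    ann_path = paths.get("annotation")
    if ann_path:
        try:
            Annotation.from_tsv(ann_path)
        except (ValueError, KeyError) as exc:
            issues.append({"file": str(ann_path), "issue": f"annotation unreadable: {exc}"})
    ped_path = paths.get("ped")
    if ped_path:
        ped = pd.read_csv(ped_path, sep="\t", dtype=str)
        required = {"family", "id", "sire", "dam", "sex"}
        missing = required - set(ped.columns)
        if missing:
            issues.append({"file": str(ped_path), "issue": f"PED columns missing: {sorted(missing)}"})
        else:
            ids = set(ped["id"])
            external = {"0", "G0", "G0_dam", "F5LL-ext", ""}
            for i, row in enumerate(ped.itertuples(), start=2):
                for parent in (row.sire, row.dam):
                    if pd.notna(parent) and parent not in ids and parent not in external:
                        issues.append({
                            "file": str(ped_path), "row": i,
                            "issue": f"orphan parent id {parent!r}",
                        })
    return issues
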