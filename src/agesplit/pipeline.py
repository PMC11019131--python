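"""End-to-end orchestration: simulate (optional) -> DE -> proteome -> integrate -> TFBS.

Stages are file-to-file transforms over TSV/FASTA intermediates, so partial
reruns can start from any stage's outputs. A JSON manifest records seeds,
thresholds and per-stage row counts for reproducibility.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as asio
from . import integrate, proteome, rnaseq, synthetic, tfbs

log = logging.getLogger("agesplit")

CONTRASTS = (("YP", "YH"), ("OP", "YH"), ("OP", "YP"))


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run.

    With ``simulate=True`` inputs are generated into ``output_dir/fixtures``
    from the default study design; otherwise the four input paths must point
    at existing files.
    """

    output_dir: str = "agesplit_run"
    simulate: bool = True
    counts_path: str | None = None
    lengths_path: str | None = None
    samples_path: str | None = None
    proteins_path: str | None = None
    promoters_path: str | None = None
    pwms_path: str | None = None
    padj: float = 0.01
    fold_change: float = 1.25
    tpm: float = 1.0
    q_threshold: float = 0.05
    tukey_threshold: float = 0.05
    presence_fraction: float = 0.70
    n_background: int = 5000
    max_freq: float = tfbs.DEFAULT_MAX_FREQ
    ci: float = 0.99
    background_padj: float = 0.4
    seed: int = 0
    design: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return the full list of range/consistency violations (empty = ok)."""
    errors = []
    for name, lo, hi in (
        ("padj", 0.0, 1.0),
        ("q_threshold", 0.0, 1.0),
        ("tukey_threshold", 0.0, 1.0),
        ("background_padj", 0.0, 1.0),
        ("ci", 0.5, 1.0),
    ):
        v = getattr(config, name)
        if not lo < v < hi:
            errors.append(f"{name}={v} outside ({lo}, {hi})")
    if config.fold_change < 1.0:
        errors.append(f"fold_change={config.fold_change} must be >= 1")
    if not 0 < config.presence_fraction <= 1:
        errors.append(f"presence_fraction={config.presence_fraction} outside (0, 1]")
    if config.n_background < 1:
        errors.append("n_background must be >= 1")
    if config.max_freq <= 0:
        errors.append("max_freq must be > 0")
    if not config.simulate:
        for name in ("counts_path", "lengths_path", "samples_path", "proteins_path"):
            p = getattr(config, name)
            if p is None:
                errors.append(f"{name} required when simulate=False")
            elif not Path(p).exists():
                errors.append(f"{name}: no such file: {p}")
    return errors


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest dict (also written to disk)."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(outdir / "run.log")
    log.addHandler(fh)
    manifest: dict = {
        "seed": config.seed,
        "thresholds": {
            k: getattr(config, k)
            for k in ("padj", "fold_change", "tpm", "q_threshold", "tukey_threshold",
                      "presence_fraction", "n_background", "max_freq", "ci",
                      "background_padj")
        },
        "stages": {},
    }
    t0 = time.time()

    def stage(name):
        log.info("[%s] start (t=%.1fs)", name, time.time() - t0)

    try:
        # -- inputs -------------------------------------------------------
        stage("inputs")
        pwm_set = None
        if config.pwms_path:
            pwm_set = tfbs.read_transfac(config.pwms_path)
        if config.simulate:
            design = synthetic.StudyDesign(**{"seed": config.seed, **config.design})
            pwm = pwm_set.pwms[0] if pwm_set is not None and len(pwm_set) else None
            study = synthetic.simulate_study(design, pwm=pwm)
            fixdir = outdir / "fixtures"
            synthetic.write_fixtures(study, fixdir)
            cm, pm = study.counts, study.proteins
            promoters = study.promoters
        else:
            cm = asio.read_counts(config.counts_path, config.lengths_path,
                                  config.samples_path)
            pm = asio.read_proteins(config.proteins_path, config.samples_path)
            promoters = (
                asio.read_promoters(config.promoters_path)
                if config.promoters_path else None
            )

        # -- RNA-seq DE ---------------------------------------------------
        stage("rnaseq_de")
        sf = rnaseq.size_factors(cm.counts)
        disp = rnaseq.estimate_dispersion(cm.counts, sf, cm.groups)
        tpm = rnaseq.compute_tpm(cm.counts, cm.gene_lengths)
        th = {"padj": config.padj, "fold_change": config.fold_change,
              "tpm": config.tpm}
        de = {}
        for num, den in CONTRASTS:
            res = rnaseq.call_degs(
                rnaseq.wald_test(cm.counts, sf, disp, cm.groups, (num, den)),
                tpm, cm.groups, (num, den), th,
            )
            de[(num, den)] = res
            asio.write_table(res, outdir / f"de_{num}_vs_{den}.tsv", "gene_id")
            manifest["stages"][f"de_{num}_vs_{den}"] = {
                "rows": len(res),
                "up": int((res["deg_status"] == "up").sum()),
                "down": int((res["deg_status"] == "down").sum()),
            }

        # -- proteome -----------------------------------------------------
        stage("proteome_de")
        pm_n = proteome.filter_proteins(
            proteome.batch_normalize(pm), config.presence_fraction
        )
        prot = proteome.anova_tukey(
            pm_n, q_threshold=config.q_threshold,
            tukey_threshold=config.tukey_threshold,
        )
        asio.write_table(prot, outdir / "protein_de.tsv", "protein_id")
        manifest["stages"]["protein_de"] = {
            "rows": len(prot),
            "testable": int(prot["testable"].sum()),
        }

        # -- integration --------------------------------------------------
        stage("integrate")
        detected = pm.intensities.index
        status = {
            pair: proteome.pairwise_status(prot, pair)
            for pair in (("OP", "YP"), ("OP", "YH"), ("YP", "YH"))
        }
        concordance = integrate.classify_concordance(
            de[("OP", "YH")]["deg_status"], status[("OP", "YH")]
        )
        asio.write_table(concordance, outdir / "concordance_OP_vs_YH.tsv", "gene_id")
        primary = integrate.select_primary_aging(
            de[("OP", "YP")], de[("OP", "YH")],
            status[("OP", "YP")], status[("OP", "YH")],
            detected_proteins=detected,
        )
        asio.write_table(primary, outdir / "primary_aging.tsv", "gene_id")
        manifest["stages"]["primary_aging"] = {
            "rows": len(primary),
            "up": int((primary["direction"] == "up").sum()),
            "down": int((primary["direction"] == "down").sum()),
        }
        coords, varfrac = integrate.pca_qc(tpm)
        asio.write_table(coords, outdir / "pca.tsv", "sample_id")
        z, gm = integrate.trajectory_zscores(
            tpm.loc[primary.index.intersection(tpm.index)], cm.groups
        )
        asio.write_table(gm, outdir / "trajectory_group_means.tsv", "gene_id")

        # -- TFBS enrichment ---------------------------------------------
        if promoters is not None and pwm_set is not None and len(pwm_set) > 1:
            stage("tfbs_enrich")
            non_de = [
                g for g in promoters.sequences
                if all(
                    (g in d.index) and (pd.isna(d.loc[g, "padj"])
                                        or d.loc[g, "padj"] > config.background_padj)
                    for d in de.values()
                )
            ]
            fg_genes = [g for g in primary.index if g in promoters.sequences
                        and primary.loc[g, "direction"] == "down"]
            if fg_genes and non_de:
                fg = synthetic.PromoterSet(
                    {g: promoters.sequences[g] for g in fg_genes}, "foreground"
                )
                pool = synthetic.PromoterSet(
                    {g: promoters.sequences[g] for g in non_de}, "background_pool"
                )
                bg = tfbs.sample_background(pool, config.n_background, config.seed)
                records = tfbs.enrichment_scan(
                    pwm_set, fg, bg, config.max_freq, config.ci
                )
                tf_tpm = None
                op_cols = [s for s in tpm.columns if cm.groups[s] == "OP"]
                name_to_gene = {p.tf_name: p.tf_name for p in pwm_set}
                present = [t for t in name_to_gene if t in tpm.index]
                if present:
                    tf_tpm = tpm.loc[present, op_cols].mean(axis=1)
                final = tfbs.collapse_and_filter(records, tf_tpm)
                asio.write_table(final, outdir / "tfbs_enrichment.tsv")
                manifest["stages"]["tfbs_enrichment"] = {
                    "rows": len(final),
                    "significant": int(final.get(
                        "significant", pd.Series(dtype=bool)).sum()),
                }
    except Exception as exc:  # noqa: BLE001 - re-tag with the failing stage
        raise RuntimeError(f"pipeline failed: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()

    manifest["runtime_s"] = round(time.time() - t0, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
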