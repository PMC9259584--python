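"""End-to-end pipeline orchestration.

Runs the stages in order — simulate, panel-of-normals + filter, CCF,
association, age enrichment, survival, validation — writing each stage's
outputs under one output directory with deterministic names, and a
manifest listing SHA-256 hashes of every artifact.  Rerunning with the
same configuration and seed reproduces the hashes bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import age, assoc, clonality, filtering, io, simulate, survival, validation

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one full pipeline run."""

    outdir: str = "blcohort_out"
    seed: int = 0
    n_pediatric: int = 191
    n_adult: int = 97
    n_perm: int = 5000
    q_threshold: float = 0.1
    clonality_threshold: float = 0.9
    comparisons: tuple = ("pediatric_vs_adult", "female_vs_male")
    age_genes: tuple = ("ID3", "BCL2", "MYC", "TP53", "SMARCA4")
    survival_gene: str = "TP53"
    sanger_regions: int = 8
    sanger_fn: int = 2
    sanger_fp: int = 3
    simulate_only: bool = False
    log_level: str = "INFO"
    cohort_overrides: dict = field(default_factory=dict)  # extra CohortConfig kwargs

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the artifact manifest (name -> sha256)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline seed=%d config_hash=%s", config.seed, config.config_hash())

    stage = "simulate"
    try:
        cohort_cfg = simulate.CohortConfig(
            n_pediatric=config.n_pediatric, n_adult=config.n_adult,
            seed=config.seed, **config.cohort_overrides,
        )
        sc = simulate.simulate_cohort(cohort_cfg)
        io.write_clinical(sc.clinical, out / "clinical.tsv")
        io.write_variants_tsv(sc.variants, out / "variants_raw.tsv")
        io.write_variants_tsv(sc.normals, out / "normals.tsv")
        io.write_purity_cn(sc.purity_cn, out / "purity.tsv", out / "segments.tsv")
        if config.simulate_only:
            return _manifest(out, config)

        stage = "filter"
        pon = filtering.build_pon(sc.normals, min_support=2)
        fcfg = filtering.FilterConfig(pon=pon)
        called, retention = filtering.apply_filter_hierarchy(sc.variants, fcfg)
        retention.to_csv(out / "retention.tsv", sep="\t", index=False)
        io.write_variants_tsv(called, out / "called.tsv")

        stage = "ccf"
        records, n_skipped = clonality.ccf_table(
            called, sc.purity_cn, threshold=config.clonality_threshold
        )
        pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in records],
                "chrom": [r.variant_key[0] for r in records],
                "pos": [r.variant_key[1] for r in records],
                "vaf": [r.vaf_f for r in records],
                "ccf": [r.ccf_f for r in records],
                "cn_tumor": [r.n_cn_tumor_used for r in records],
                "clonal": [r.clonal for r in records],
            }
        ).to_csv(out / "ccf.tsv", sep="\t", index=False)

        stage = "associate"
        somatic = [v for v in called if v.gene]
        matrix = assoc.build_matrix(somatic, sc.clinical)
        for comparison in config.comparisons:
            results = assoc.run_comparisons(matrix, comparison,
                                            q_threshold=config.q_threshold)
            assoc.results_frame(results).to_csv(
                out / f"assoc_{comparison}.tsv", sep="\t", index=False
            )

        stage = "age_enrich"
        ages = matrix.clinical["age_years"].to_numpy()
        rows = []
        for gene in config.age_genes:
            if gene not in matrix.counts.index:
                continue
            mutated = matrix.indicator.loc[gene].to_numpy().astype(bool)
            if mutated.sum() in (0, len(mutated)):
                continue
            for tail in ("young", "old"):
                r = age.age_rank_enrichment(
                    ages, mutated, tail=tail, n_perm=config.n_perm,
                    seed=config.seed, gene=gene,
                )
                rows.append({"gene": gene, "tail": tail, "es": r.es,
                             "p_perm": r.p_perm, "n_perm": r.n_perm})
        pd.DataFrame(rows).to_csv(out / "age_enrichment.tsv", sep="\t", index=False)

        stage = "survival"
        cl = matrix.clinical
        carrier = matrix.indicator.loc[config.survival_gene].to_numpy().astype(bool)
        ped = (cl["cohort"] == "pediatric").to_numpy()
        time = cl["followup_years"].to_numpy()[ped]
        event = np.where(cl["event"].to_numpy()[ped] == "none",
                         survival.CENSORED, cl["event"].to_numpy()[ped])
        grp = np.where(carrier[ped], "mutant", "wildtype")
        lr = survival.logrank_test(time, event != survival.CENSORED, grp)
        gr = survival.gray_test(time, event, grp, "relapse_progression")
        curves = []
        for label in ("mutant", "wildtype"):
            sel = grp == label
            cif = survival.cumulative_incidence(time[sel], event[sel],
                                                "relapse_progression", group=label)
            curves.append(
                pd.DataFrame({"group": label, "time": cif.times,
                              "cif": cif.cif, "se": cif.se})
            )
        pd.concat(curves).to_csv(out / "cif_relapse.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"test": "logrank", "statistic": lr.statistic, "p": lr.p},
             {"test": "gray", "statistic": gr.statistic, "p": gr.p}]
        ).to_csv(out / "survival_tests.tsv", sep="\t", index=False)

        stage = "validate"
        st = simulate.simulate_sanger_truth(
            somatic, n_regions=config.sanger_regions,
            fn_injected=config.sanger_fn, fp_injected=config.sanger_fp,
            seed=config.seed,
        )
        report = validation.reconcile(
            st["sanger_calls"], st["pipeline_calls"], st["covered_regions"]
        )
        (out / "validation.txt").write_text(report.summary() + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return _manifest(out, config)


def _manifest(out: Path, config: PipelineConfig) -> dict:
    manifest = {
        p.name: io.file_sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    payload = {"seed": config.seed, "config_hash": config.config_hash(),
               "config": config.to_dict(), "artifacts": manifest}
    (out / "manifest.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return manifest
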