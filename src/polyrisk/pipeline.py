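"""End-to-end orchestration: ingest/simulate -> QC -> split -> associate ->
LD screen -> risk score -> evaluate, with table-shaped reports.

The stages run in the replication-study order: candidate SNPs are tested
and effect sizes estimated on the discovery half only; the risk score is
built from those discovery estimates and evaluated exclusively on the
testing half.  Nothing from the testing set can influence SNP selection or
OR estimation — the discovery/testing firewall that makes the evaluation
honest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assoc import (
    MODEL_SEX_AGE,
    MODEL_SEX_AGE_APOE,
    AssociationResult,
    association_table,
    results_frame,
    select_significant,
)
from .cohort import (
    CASE,
    CohortDataset,
    FrequencyTable,
    read_cohort,
    split_discovery_testing,
    summarize_cohort,
)
from .evaluate import (
    auc_mann_whitney,
    combined_model_scores,
    delong_compare,
    roc_coordinates,
    stratified_evaluation,
)
from .grs import build_risk_table, compute_grs, grs_frame, modified_grs_snps
from .ld import apoe_as_biallelic, ld_screen
from .qc import QCThresholds, filter_snps, filter_subjects
from .simulate import SimulationConfig, default_config, simulate_cohort

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a full run needs; YAML-loadable, CLI-overridable."""

    out_dir: str = "polyrisk_run"
    # input: either the three cohort files, or a simulation config
    phenotype_path: str | None = None
    variant_path: str | None = None
    genotype_path: str | None = None
    dialect: str = "tsv"
    simulate: SimulationConfig | None = None
    freq_table_path: str | None = None
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    alpha: float = 0.05
    split_fraction: float = 0.5
    split_seed: int = 1
    r2_threshold: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0,1]")
        paths = (self.phenotype_path, self.variant_path, self.genotype_path)
        if any(paths) and not all(paths):
            raise ValueError(
                "phenotype_path, variant_path and genotype_path must be "
                "given together"
            )
        if all(p is None for p in paths) and self.simulate is None:
            self.simulate = default_config()
        for p in (*paths, self.freq_table_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a mapping")
        if "thresholds" in raw:
            raw["thresholds"] = QCThresholds(**raw["thresholds"])
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = _simulation_config_from_dict(raw["simulate"])
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _simulation_config_from_dict(d: dict) -> SimulationConfig:
    from .simulate import ApoeSim, CovariateSim, SnpSim

    kwargs = dict(d)
    if "snps" in kwargs:
        kwargs["snps"] = tuple(SnpSim(**s) for s in kwargs["snps"])
    if "apoe" in kwargs:
        apoe = dict(kwargs["apoe"])
        if "weak_tags" in apoe:
            apoe["weak_tags"] = tuple(tuple(t) for t in apoe["weak_tags"])
        kwargs["apoe"] = ApoeSim(**apoe)
    if "covariates" in kwargs:
        kwargs["covariates"] = CovariateSim(**kwargs["covariates"])
    base = default_config()
    if "snps" not in kwargs:
        kwargs["snps"] = base.snps
    return SimulationConfig(**kwargs)


@dataclass
class RunManifest:
    versions: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    status: str = "incomplete"
    failed_stage: str | None = None

    def write(self, path: Path) -> None:
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
        tmp.replace(path)  # atomic on POSIX


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_all(cfg: RunConfig) -> RunManifest:
    """Execute the full analysis; returns the manifest, writes all reports.

    Any stage failure aborts with :class:`PipelineStageError` naming the
    stage, after persisting the partial manifest.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        versions={
            "polyrisk": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        seeds={
            "split_seed": cfg.split_seed,
            "simulate_seed": cfg.simulate.seed if cfg.simulate else None,
        },
    )
    manifest_path = out / "manifest.json"
    t_start = time.perf_counter()
    state: dict = {}

    def stage(name):
        def deco(fn):
            nonlocal state
            t0 = time.perf_counter()
            try:
                counts = fn() or {}
            except Exception as exc:
                manifest.status = "failed"
                manifest.failed_stage = name
                manifest.write(manifest_path)
                raise PipelineStageError(name, exc) from exc
            manifest.stages.append(
                {"stage": name, "seconds": round(time.perf_counter() - t0, 3), **counts}
            )
            return counts

        return deco

    @stage("input")
    def _input():
        if cfg.simulate is not None:
            ds, truth = simulate_cohort(cfg.simulate)
            (out / "truth.json").write_text(
                json.dumps(truth.to_dict(), indent=2, default=str)
            )
            manifest.outputs["truth"] = str(out / "truth.json")
        else:
            for key, p in (
                ("phenotypes", cfg.phenotype_path),
                ("variants", cfg.variant_path),
                ("genotypes", cfg.genotype_path),
            ):
                manifest.input_digests[key] = _digest(p)
            ds = read_cohort(
                cfg.phenotype_path, cfg.variant_path, cfg.genotype_path, cfg.dialect
            )
        state["ds"] = ds
        return {"subjects": ds.n_subjects, "snps": ds.n_variants}

    @stage("qc_subjects")
    def _qc_subjects():
        ds, rep = filter_subjects(state["ds"], cfg.thresholds)
        state["ds"], state["qc_subj"] = ds, rep
        return {"subjects": ds.n_subjects, "removed": len(rep.removed_subjects)}

    @stage("qc_snps")
    def _qc_snps():
        ds, rep = filter_snps(state["ds"], cfg.thresholds)
        state["ds"] = ds
        rep.removed_subjects = state["qc_subj"].removed_subjects
        paths = rep.write_tsv(out)
        manifest.outputs.update({k: str(v) for k, v in paths.items()})
        return {"snps": ds.n_variants, "removed": len(rep.removed_snps)}

    @stage("summary")
    def _summary():
        table1 = summarize_cohort(state["ds"])
        p = out / "table1_characteristics.tsv"
        table1.round(6).to_csv(p, sep="\t")
        manifest.outputs["table1"] = str(p)
        return {}

    @stage("split")
    def _split():
        disc, test = split_discovery_testing(
            state["ds"], cfg.split_fraction, cfg.split_seed
        )
        state["discovery"], state["testing"] = disc, test
        return {
            "discovery_subjects": disc.n_subjects,
            "testing_subjects": test.n_subjects,
        }

    @stage("association")
    def _association():
        results = association_table(state["discovery"])
        state["assoc"] = results
        p = out / "table2_association.tsv"
        report_association_table(state["discovery"], results).to_csv(
            p, sep="\t", index=False
        )
        manifest.outputs["table2"] = str(p)
        return {"results": len(results)}

    @stage("ld_screen")
    def _ld():
        disc = state["discovery"]
        significant = select_significant(state["assoc"], cfg.alpha, MODEL_SEX_AGE)
        state["significant"] = significant
        target = apoe_as_biallelic(disc.subjects)
        if significant and not np.isnan(target).all():
            ld = ld_screen(disc, target, significant, cfg.r2_threshold)
        else:
            ld = pd.DataFrame(columns=["snp_id", "r2", "flagged", "n_used", "D_prime"])
        state["ld"] = ld
        p = out / "ld_screen.tsv"
        ld.to_csv(p, sep="\t", index=False)
        manifest.outputs["ld"] = str(p)
        return {"significant": len(significant), "flagged": int(ld["flagged"].sum()) if len(ld) else 0}

    @stage("risk_tables")
    def _risk_tables():
        significant = state["significant"]
        if not significant:
            logger.warning("no significant SNPs at alpha=%s: no GRS computed", cfg.alpha)
            state["risk_full"] = state["risk_mod"] = None
            return {"full": 0, "modified": 0}
        disc = state["discovery"]
        if cfg.freq_table_path:
            freqs = FrequencyTable.read_tsv(cfg.freq_table_path)
        else:
            # no external reference panel: expand discovery control-arm
            # allele frequencies under HWE
            logger.info("no frequency table supplied; using control-arm HWE expansion")
            ctrl = disc.subset(np.flatnonzero(~disc.status_mask(CASE)))
            pfreqs = {}
            for snp in significant:
                d = ctrl.dosage_vector(snp)
                d = d[~np.isnan(d)]
                pfreqs[snp] = float(d.sum() / (2 * d.size))
            freqs = FrequencyTable.from_hwe(pfreqs)
        state["freqs"] = freqs
        state["risk_full"] = build_risk_table(state["assoc"], freqs, significant)
        mod_snps = modified_grs_snps(
            state["assoc"], state["ld"], cfg.alpha, cfg.r2_threshold
        )
        state["risk_mod"] = (
            build_risk_table(state["assoc"], freqs, mod_snps) if mod_snps else None
        )
        state["risk_full"].frame().to_csv(out / "risk_table_full.tsv", sep="\t", index=False)
        if state["risk_mod"]:
            state["risk_mod"].frame().to_csv(
                out / "risk_table_modified.tsv", sep="\t", index=False
            )
        return {
            "full": len(state["risk_full"]),
            "modified": len(state["risk_mod"]) if state["risk_mod"] else 0,
        }

    @stage("grs")
    def _grs():
        if state["risk_full"] is None:
            return {"profiles": 0}
        test_set = state["testing"]
        state["grs_full"] = compute_grs(test_set, state["risk_full"])
        grs_frame(state["grs_full"]).to_csv(out / "grs_full.tsv", sep="\t", index=False)
        if state["risk_mod"]:
            state["grs_mod"] = compute_grs(test_set, state["risk_mod"])
            grs_frame(state["grs_mod"]).to_csv(
                out / "grs_modified.tsv", sep="\t", index=False
            )
        return {"profiles": len(state["grs_full"])}

    @stage("evaluation")
    def _evaluation():
        if state["risk_full"] is None:
            return {}
        test_set = state["testing"]
        blocks = [stratified_evaluation(test_set, state["grs_full"], "grs_full")]
        if state.get("grs_mod"):
            blocks.append(stratified_evaluation(test_set, state["grs_mod"], "grs_modified"))
        table3 = pd.concat(blocks, ignore_index=True)
        p = out / "table3_evaluation.tsv"
        table3.to_csv(p, sep="\t", index=False)
        manifest.outputs["table3"] = str(p)
        state["table3"] = table3

        # combined modified-GRS + APOE marker vs APOE alone
        grs_scores = state.get("grs_mod") or state["grs_full"]
        has_apoe = [s.e4_carrier is not None for s in test_set.subjects]
        if any(has_apoe):
            combined, labels = combined_model_scores(test_set, grs_scores)
            by_id = {p_.subject_id: p_.grs for p_ in grs_scores}
            # same subject filter (and order) as combined_model_scores
            apoe_marker = np.array(
                [
                    float(s.e4_carrier)
                    for s in test_set.subjects
                    if s.subject_id in by_id and s.e4_carrier is not None
                ]
            )
            comparison = delong_compare(combined, apoe_marker, labels)
            state["delong"] = comparison
            roc = []
            for name, scores in (("combined", combined), ("apoe", apoe_marker)):
                coords = roc_coordinates(scores[labels == 1], scores[labels == 0])
                coords.insert(0, "marker", name)
                roc.append(coords)
            pd.concat(roc, ignore_index=True).to_csv(
                out / "roc_coordinates.tsv", sep="\t", index=False
            )
            (out / "delong.json").write_text(
                json.dumps(dataclasses.asdict(comparison), indent=2)
            )
            manifest.outputs["delong"] = str(out / "delong.json")
            return {
                "auc_combined": round(comparison.auc_a, 4),
                "auc_apoe": round(comparison.auc_b, 4),
            }
        return {}

    manifest.status = "ok"
    manifest.stages.append(
        {"stage": "total", "seconds": round(time.perf_counter() - t_start, 3)}
    )
    manifest.write(manifest_path)
    state["manifest"] = manifest
    run_all.last_state = state  # debugging/introspection hook
    return manifest


def report_association_table(
    ds: CohortDataset, results: list[AssociationResult]
) -> pd.DataFrame:
    """Association report with one row per SNP and both covariate models.

    Columns mirror the conventional replication-study layout: chromosome,
    SNP, position, gene, risk allele, per-arm allele frequencies, then
    OR (95% CI) and p for the sex+age model and the APOE-adjusted model —
    full precision columns plus display-rounded OR(CI) strings.
    """
    frame = results_frame(results)
    meta = ds.variant_frame().set_index("snp_id")
    rows = []
    for snp_id in frame["snp_id"].unique():
        sub = frame[frame.snp_id == snp_id].set_index("model")
        v = meta.loc[snp_id]
        row = {
            "chr": v.chromosome,
            "snp": snp_id,
            "position": v.position,
            "gene": v.gene_label,
            "risk_allele": v.risk_allele,
        }
        first = sub.iloc[0]
        row["freq_cases"] = first.allele_freq_cases
        row["freq_controls"] = first.allele_freq_controls
        for model, label in ((MODEL_SEX_AGE, "sex_age"), (MODEL_SEX_AGE_APOE, "sex_age_apoe")):
            if model in sub.index:
                r = sub.loc[model]
                row[f"or_{label}"] = r.allelic_or
                row[f"ci_low_{label}"] = r.ci_low
                row[f"ci_high_{label}"] = r.ci_high
                row[f"p_{label}"] = r.p_wald
                row[f"or_ci_{label}"] = (
                    f"{r.allelic_or:.2f}({r.ci_low:.2f}-{r.ci_high:.2f})"
                    if r.flag == ""
                    else f"flagged:{r.flag}"
                )
        rows.append(row)
    return pd.DataFrame(rows)
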