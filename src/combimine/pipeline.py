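"""End-to-end pipeline orchestration with a structured config and manifest.

Stages run in dependency order — simulate, qc, match, mine, permute,
evaluate, architecture, annotate, stratify, gwas, replicate — each writing
its artifacts into the run directory; a manifest records the config, the
derived per-stage seeds and per-stage record counts.  Re-running with an
identical config reproduces identical outputs.

All stage seeds derive from the single global seed via
``numpy.random.SeedSequence(seed, spawn_key=(stage_index,))``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import architecture as arch
from . import evaluation as ev
from . import stratify as strat
from .annotation import AnnotationParams, annotate_signatures
from .io import (
    GenotypeMatrix,
    MatchingSpec,
    QcParams,
    match_controls,
    qc_filter,
    read_covariates,
    read_genotypes,
    write_covariates,
    write_genotypes,
)
from .mining import (
    FeatureState,
    MiningParams,
    Signature,
    mine_signatures,
    signatures_to_json,
    signatures_to_tsv,
)
from .permutation import ValidationParams, compute_p1000, validate_signatures
from .simulate import CohortSpec, PlantedSignatureSpec, generate_cohort
from .stats import ContingencyTable2x2
from .stratify import GwasParams

logger = logging.getLogger("combimine")

STAGES = (
    "simulate", "qc", "match", "mine", "permute", "evaluate",
    "architecture", "annotate", "stratify", "gwas", "replicate",
)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]


@dataclass
class PipelineConfig:
    outdir: str = "combimine_run"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # either a simulation spec ...
    cohort: dict = field(default_factory=dict)
    # ... or file inputs
    genotypes_path: str | None = None
    genotypes_format: str | None = None
    covariates_path: str | None = None
    case_ids_path: str | None = None
    gene_model_path: str | None = None
    mining: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    matching: dict = field(default_factory=dict)
    annotation: dict = field(default_factory=dict)
    gwas: dict = field(default_factory=dict)
    critical_min: int = 2
    rf_trees: int = 500

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        ss = np.random.SeedSequence(self.seed, spawn_key=(idx,))
        return int(ss.generate_state(1)[0] % (2**31))


def _cohort_spec(cfg: PipelineConfig) -> CohortSpec:
    d = dict(cfg.cohort)
    planted = [
        PlantedSignatureSpec(**p) if isinstance(p, dict) else p
        for p in d.pop("planted", [])
    ]
    d.setdefault("seed", cfg.stage_seed("simulate"))
    return CohortSpec(planted=tuple(planted), **d)


def signatures_from_json(records: list[dict]) -> list[Signature]:
    out = []
    for r in records:
        states = tuple(
            sorted(FeatureState(s["snp_id"], int(s["genotype"])) for s in r["states"])
        )
        case_ids = frozenset(r["case_ids"])
        control_ids = frozenset(r["control_ids"])
        a, c = r["case_carriers"], r["control_carriers"]
        n_cases = r.get("n_cases", a + r.get("case_noncarriers", 0))
        out.append(
            Signature(
                states=states,
                table=ContingencyTable2x2(
                    a, r.get("case_noncarriers", max(n_cases - a, 0)), c,
                    r.get("control_noncarriers", 0),
                ),
                odds_ratio=r["odds_ratio"],
                p_value=r["p_value"],
                case_prevalence=r["case_prevalence"],
                case_ids=case_ids,
                control_ids=control_ids,
            )
        )
    return out


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the enabled stages in order; returns the run directory."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(cfg),
        "stage_seeds": {s: cfg.stage_seed(s) for s in cfg.stages},
        "stages": {},
    }
    state: dict = {}

    def record(stage: str, **counts):
        manifest["stages"][stage] = {
            "completed": True,
            "elapsed_s": round(time.time() - t0, 3),
            **counts,
        }
        logger.info("stage %s done: %s", stage, counts)

    for stage in STAGES:
        if stage not in cfg.stages:
            manifest["stages"][stage] = {"completed": False}
            continue
        t0 = time.time()
        try:
            if stage == "simulate":
                spec = _cohort_spec(cfg)
                gm, cov, genes, truth = generate_cohort(spec)
                write_genotypes(gm, outdir / "genotypes.tsv", "tsv")
                write_genotypes(gm, outdir / "genotypes.vcf", "vcf")
                write_covariates(cov, outdir / "covariates.tsv")
                genes.to_gff3(outdir / "genes.gff3")
                truth.to_json(outdir / "truth.json")
                state.update(gm=gm, covariates=cov, genes=genes, truth=truth)
                record(stage, n_samples=gm.n_samples, n_snps=gm.n_snps)
            elif stage == "qc":
                gm = _require_gm(state, cfg)
                gm, rep = qc_filter(gm, QcParams(**cfg.qc))
                rep.to_json(outdir / "qc_report.json")
                state["gm"] = gm
                record(stage, n_samples=gm.n_samples, n_snps=gm.n_snps)
            elif stage == "match":
                gm = _require_gm(state, cfg)
                cov = state.get("covariates")
                if cov is None and cfg.covariates_path:
                    cov = read_covariates(cfg.covariates_path)
                    state["covariates"] = cov
                mspec = MatchingSpec(
                    seed=cfg.stage_seed("match"), **cfg.matching
                )
                case_cov = cov.loc[cov.index.isin(gm.sample_ids[gm.is_case])]
                pool_cov = cov.loc[cov.index.isin(gm.sample_ids[~gm.is_case])]
                selected = match_controls(case_cov, pool_cov, mspec)
                (outdir / "matched_controls.txt").write_text(
                    "\n".join(map(str, selected)) + "\n"
                )
                keep = set(map(str, selected)) | set(map(str, gm.sample_ids[gm.is_case]))
                state["gm"] = gm.subset_samples(
                    np.array([str(s) in keep for s in gm.sample_ids])
                )
                record(stage, n_controls_selected=len(selected))
            elif stage == "mine":
                gm = _require_gm(state, cfg)
                mp = MiningParams(seed=cfg.stage_seed("mine"), **cfg.mining)
                sigs = mine_signatures(gm, mp)
                state.update(signatures=sigs, mining_params=mp)
                signatures_to_tsv(sigs, outdir / "signatures.tsv")
                (outdir / "signatures.json").write_text(
                    json.dumps(signatures_to_json(sigs), indent=1) + "\n"
                )
                record(stage, n_signatures=len(sigs))
            elif stage == "permute":
                gm = _require_gm(state, cfg)
                sigs = state["signatures"]
                vp = ValidationParams(
                    seed=cfg.stage_seed("permute"),
                    mining=state.get("mining_params", MiningParams(**cfg.mining)),
                    **cfg.validation,
                )
                report = compute_p1000(sigs, gm, vp)
                validated = validate_signatures(sigs, report, vp)
                report.to_tsv(outdir / "permutation_report.tsv")
                (outdir / "validated_signatures.json").write_text(
                    json.dumps(signatures_to_json(validated), indent=1) + "\n"
                )
                state.update(validated=validated, perm_report=report)
                record(stage, n_validated=len(validated))
            elif stage == "evaluate":
                gm = _require_gm(state, cfg)
                validated = state.get("validated", state.get("signatures", []))
                if validated:
                    critical = ev.find_critical_snps(validated, cfg.critical_min)
                else:
                    critical = {}
                if critical:
                    scores = ev.score_critical_snps(
                        gm, critical, n_trees=cfg.rf_trees,
                        seed=cfg.stage_seed("evaluate"),
                    )
                else:
                    scores = []
                ev.scores_to_tsv(scores, outdir / "critical_snps.tsv")
                state["critical_scores"] = scores
                record(stage, n_critical=len(scores))
            elif stage == "architecture":
                gm = _require_gm(state, cfg)
                validated = state.get("validated") or []
                if validated:
                    graph = arch.build_architecture(validated)
                    comms = arch.detect_communities(
                        graph, seed=cfg.stage_seed("architecture")
                    )
                    comms = [arch.community_stats(c, gm) for c in comms]
                    _write_architecture(outdir, graph, comms, validated, gm)
                    state["communities"] = comms
                    record(stage, n_communities=len(comms))
                else:
                    state["communities"] = []
                    record(stage, n_communities=0)
            elif stage == "annotate":
                genes = state.get("genes")
                if genes is None and cfg.gene_model_path:
                    from .annotation import GeneModel

                    p = Path(cfg.gene_model_path)
                    genes = (
                        GeneModel.from_bed12(p)
                        if p.suffix == ".bed"
                        else GeneModel.from_gff3(p)
                    )
                validated = state.get("validated") or []
                gm = _require_gm(state, cfg)
                if genes is not None and validated:
                    table, unassigned = annotate_signatures(
                        validated, gm.snp_meta,
                        genes, AnnotationParams(**cfg.annotation),
                    )
                    table.to_csv(outdir / "gene_assignments.tsv", sep="\t", index=False)
                    (outdir / "unassigned_snps.txt").write_text(
                        "\n".join(unassigned) + ("\n" if unassigned else "")
                    )
                    state["assignments"] = table
                    scores = state.get("critical_scores") or []
                    if scores:
                        prio = ev.prioritize_genes(scores, table)
                        with open(outdir / "gene_priorities.tsv", "w") as fh:
                            fh.write("gene_id\tcumulative_score\tsnp_ids\n")
                            for g in prio:
                                fh.write(
                                    f"{g.gene_id}\t{g.cumulative_score:.17g}\t"
                                    + ",".join(g.snp_ids) + "\n"
                                )
                    record(stage, n_assignments=len(table), n_unassigned=len(unassigned))
                else:
                    record(stage, n_assignments=0, n_unassigned=0)
            elif stage == "stratify":
                gm = _require_gm(state, cfg)
                cov = state.get("covariates")
                comms = state.get("communities") or []
                rows = []
                if cov is not None:
                    all_cases = set(map(str, gm.sample_ids[gm.is_case]))
                    for c in comms:
                        if not c.case_set or set(map(str, c.case_set)) == all_cases:
                            continue
                        rows.extend(
                            strat.profile_subgroup(
                                c.case_set, all_cases,
                                cov.loc[cov.index.astype(str).isin(all_cases)],
                                subgroup_id=f"community_{c.id}",
                            )
                        )
                    pd.DataFrame([dataclasses.asdict(r) for r in rows]).to_csv(
                        outdir / "enrichment.tsv", sep="\t", index=False
                    )
                record(stage, n_enrichment_rows=len(rows))
            elif stage == "gwas":
                gm = _require_gm(state, cfg)
                gp = GwasParams(**cfg.gwas)
                res = strat.single_snp_gwas(gm, gp)
                res.to_csv(outdir / "gwas.tsv", sep="\t", index=False)
                record(
                    stage,
                    n_snps=len(res),
                    n_significant=int(res["significant"].sum()),
                )
            elif stage == "replicate":
                # a second disjoint synthetic cohort with the same planted
                # structure, searched over the discovery SNPs only
                validated = state.get("validated") or []
                if not validated or not cfg.cohort:
                    record(stage, n_replicated=0)
                    continue
                spec = _cohort_spec(cfg)
                spec2 = dataclasses.replace(spec, seed=cfg.stage_seed("replicate"))
                gm2, *_ = generate_cohort(spec2)
                refs = sorted({snp for s in validated for snp in s.snp_ids})
                rep = strat.replicate_in_cohort(
                    refs, gm2,
                    mining_params=state.get("mining_params", MiningParams()),
                    validation_params=ValidationParams(
                        seed=cfg.stage_seed("replicate"),
                        mining=state.get("mining_params", MiningParams()),
                        **cfg.validation,
                    ),
                )
                (outdir / "replication.json").write_text(
                    json.dumps(
                        {"replicated": rep["replicated"],
                         "untestable": rep["untestable"],
                         "n_validated_signatures": len(rep["signatures"])},
                        indent=2,
                    )
                    + "\n"
                )
                record(stage, n_replicated=len(rep["replicated"]))
        except Exception:
            manifest["stages"][stage] = {"completed": False, "failed": True}
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            logger.exception("stage %s failed; partial outputs retained", stage)
            raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outdir


def _require_gm(state: dict, cfg: PipelineConfig) -> GenotypeMatrix:
    if "gm" in state:
        return state["gm"]
    if cfg.genotypes_path is None:
        raise ValueError("no genotype input: enable the simulate stage or set genotypes_path")
    case_ids = None
    if cfg.case_ids_path:
        case_ids = Path(cfg.case_ids_path).read_text().split()
    gm = read_genotypes(cfg.genotypes_path, cfg.genotypes_format, case_ids=case_ids)
    state["gm"] = gm
    if cfg.covariates_path and "covariates" not in state:
        state["covariates"] = read_covariates(cfg.covariates_path)
    return gm


def _write_architecture(outdir: Path, graph, comms, validated, gm) -> None:
    with open(outdir / "architecture_edges.tsv", "w") as fh:
        fh.write("state_a\tstate_b\tweight\n")
        for u, v, d in sorted(
            graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))
        ):
            fh.write(f"{u}\t{v}\t{d['weight']:.17g}\n")
    payload = [
        {
            "id": c.id,
            "states": [str(s) for s in c.states],
            "n_signatures": len(c.signatures),
            "n_cases_represented": c.n_cases_represented,
            "odds_ratio": c.odds_ratio,
            "p_value": c.p_value,
        }
        for c in comms
    ]
    (outdir / "communities.json").write_text(json.dumps(payload, indent=2) + "\n")
    if len(comms) >= 2:
        m = arch.overlap_matrix(comms)
        pd.DataFrame(
            m,
            index=[f"community_{c.id}" for c in comms],
            columns=[f"community_{c.id}" for c in comms],
        ).to_csv(outdir / "community_overlap.tsv", sep="\t")
    frac = arch.cases_represented(validated, gm)
    (outdir / "cases_represented.json").write_text(
        json.dumps({"fraction": frac, "percent": 100 * frac}) + "\n"
    )
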