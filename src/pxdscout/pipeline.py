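"""End-to-end orchestration: annotate -> filter per case -> intersect ->
genotype/segregate -> conservation, from one YAML config.

The report is deterministic for a fixed config and seed: keys are emitted in
a stable order and floats with six significant digits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional

import pandas as pd
import yaml

from . import io as pxio
from .annotate import ConsequenceCall, annotate_variant
from .conservation import column_composition, tolerated_states
from .filtering import (CandidateSet, ControlVariantStore, GenomeObservation,
                        candidate_trajectory, filter_candidates,
                        intersect_cases, summarize_candidates)
from .genome import GeneIndex, InputError, ReferenceAssembly, Variant
from .genotyping import CallerParams, call_genotypes, segregation_check

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters for one full pipeline run."""

    reference: Path
    gene_models: Path
    case_vcfs: List[Path]
    control_vcfs: List[Path] = field(default_factory=list)
    cohort: Optional[Path] = None
    alignment: Optional[Path] = None
    alignment_focal_column: int = 1
    variant_aa: Optional[str] = None
    splice_window: int = 2
    caller: CallerParams = field(default_factory=CallerParams)
    seed: int = 0
    output_dir: Path = Path("pxdscout-results")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        caller = CallerParams(**raw.get("caller", {}))
        cfg = cls(
            reference=Path(raw["reference"]),
            gene_models=Path(raw["gene_models"]),
            case_vcfs=[Path(p) for p in raw["case_vcfs"]],
            control_vcfs=[Path(p) for p in raw.get("control_vcfs", [])],
            cohort=Path(raw["cohort"]) if raw.get("cohort") else None,
            alignment=Path(raw["alignment"]) if raw.get("alignment") else None,
            alignment_focal_column=int(raw.get("alignment_focal_column", 1)),
            variant_aa=raw.get("variant_aa"),
            splice_window=int(raw.get("splice_window", 2)),
            caller=caller,
            seed=int(raw.get("seed", 0)),
            output_dir=Path(raw.get("output_dir", "pxdscout-results")),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in [self.reference, self.gene_models, *self.case_vcfs,
                  *self.control_vcfs, self.cohort, self.alignment]:
            if p is not None and not Path(p).exists():
                raise InputError(f"configured input does not exist: {p}")
        if not self.case_vcfs:
            raise InputError("config lists no case VCFs")


def annotate_observations(assembly: ReferenceAssembly, index: GeneIndex,
                          observations: List[GenomeObservation],
                          splice_window: int = 2) -> Dict[Variant, ConsequenceCall]:
    """Consequence calls for the union of all variants in the given genomes."""
    annotations: Dict[Variant, ConsequenceCall] = {}
    for obs in observations:
        for v in obs.calls:
            if v not in annotations:
                annotations[v] = annotate_variant(assembly, index, v, splice_window)
    return annotations


def run_pipeline(config: RunConfig, strict: bool = False) -> Dict:
    """Execute the full discovery analysis and write the report files.

    Returns the machine-readable report; raises only on malformed inputs.
    With ``strict`` an empty cross-case intersection raises as well.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        log.info("stage: %s", name)

    stage("load inputs")
    assembly = pxio.read_fasta_assembly(config.reference)
    genes = pxio.read_gene_models(config.gene_models)
    index = GeneIndex(genes)
    cases = [pxio.read_genome_vcf(p, assembly, "case") for p in config.case_vcfs]
    controls = [pxio.read_genome_vcf(p, assembly, "control") for p in config.control_vcfs]
    if not controls:
        log.warning("no control VCFs configured; the absent-from-controls "
                    "criterion is vacuous")

    stage("annotate")
    annotations = annotate_observations(assembly, index, cases, config.splice_window)

    stage("filter")
    store = ControlVariantStore()
    for ctl in controls:
        store.add_genome(ctl)
    candidate_sets: List[CandidateSet] = []
    report: Dict = {"cases": {}, "n_controls": len(store)}
    for case in cases:
        cand = filter_candidates(case, store, annotations)
        candidate_sets.append(cand)
        n_var, n_gene = summarize_candidates(cand)
        report["cases"][case.genome_id] = {
            "n_variants_total": len(case.calls),
            "n_candidates": n_var,
            "n_genes": n_gene,
        }
        pxio.write_candidates_tsv(cand, out / f"candidates_{case.genome_id}.tsv")
        pxio.write_genome_vcf(
            GenomeObservation(case.genome_id, "case", dict(case.calls)),
            assembly, out / f"annotated_{case.genome_id}.vcf", annotations,
        )

    stage("trajectory")
    if controls:
        traj = candidate_trajectory(cases[0], controls, annotations)
        pxio.write_trajectory_csv(traj, out / "trajectory.csv")
        report["trajectory"] = traj

    stage("intersect")
    if len(candidate_sets) >= 2:
        inter = intersect_cases(candidate_sets)
        pxio.write_candidates_tsv(inter, out / "intersection.tsv")
        report["intersection"] = [
            {
                "contig": v.contig, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "gene": c.gene_id, "category": c.category.value,
                "hgvs_c": c.hgvs_c, "hgvs_p": c.hgvs_p,
            }
            for v, c in sorted(inter.variants.items())
        ]
        if strict and not inter.variants:
            raise InputError("candidate intersection is empty (strict mode)")

    if config.cohort is not None:
        stage("cohort genotyping")
        cohort = pxio.read_cohort_tsv(config.cohort)
        if "genotype" not in cohort.columns:
            records = pxio.fluorescence_records(cohort)
            cohort = cohort.assign(genotype=call_genotypes(records, config.caller))
        seg = segregation_check(cohort)
        seg.to_frame().to_csv(out / "segregation.tsv", sep="\t", index=False)
        report["segregation"] = {
            "consistent_recessive": seg.consistent_recessive,
            "fisher_p": float(f"{seg.fisher_p:.6g}"),
            "allele_freq_controls": float(f"{seg.allele_freq_controls:.6g}"),
            "n_affected_called": seg.n_affected_called,
            "n_controls_called": seg.n_controls_called,
            "strata": {
                b: {
                    "affected_hom_alt": s.n_affected_hom_alt,
                    "affected_other": s.n_affected_other,
                    "control_hom_alt": s.n_control_hom_alt,
                    "control_het": s.n_control_het,
                    "control_hom_ref": s.n_control_hom_ref,
                    "allele_freq_controls": float(f"{s.allele_freq_controls:.6g}"),
                }
                for b, s in seg.strata.items()
            },
        }

    if config.alignment is not None:
        stage("conservation")
        alignment = pxio.read_alignment_fasta(config.alignment, config.alignment_focal_column)
        comp = column_composition(alignment)
        tolerated = sorted(tolerated_states(alignment, min_count=1))
        report["conservation"] = {
            "composition": dict(sorted(comp.counts.items())),
            "n_gaps": comp.n_gaps,
            "n_species": comp.n_rows,
            "tolerated": tolerated,
        }
        if config.variant_aa:
            report["conservation"]["variant_aa"] = config.variant_aa
            report["conservation"]["variant_aa_observed"] = (
                config.variant_aa.upper() in tolerated
            )

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    (out / "report.txt").write_text(render_report(report))
    return report


def render_report(report: Mapping) -> str:
    """Human-readable summary of a pipeline report."""
    lines = ["pxdscout run summary", "====================", ""]
    lines.append(f"control genomes in store: {report.get('n_controls', 0)}")
    for cid, c in report.get("cases", {}).items():
        lines.append(
            f"case {cid}: {c['n_variants_total']} variants -> "
            f"{c['n_candidates']} candidates in {c['n_genes']} genes"
        )
    if "trajectory" in report:
        traj = report["trajectory"]
        lines.append(f"trajectory (first case): {' '.join(str(t) for t in traj)}")
    if "intersection" in report:
        inter = report["intersection"]
        lines.append(f"variants common to all cases: {len(inter)}")
        for r in inter:
            lines.append(
                f"  {r['contig']}:{r['pos']} {r['ref']}>{r['alt']} "
                f"{r['gene']} {r['category']} {r['hgvs_c']} {r['hgvs_p']}"
            )
    if "segregation" in report:
        seg = report["segregation"]
        lines.append(
            f"segregation: consistent_recessive={seg['consistent_recessive']} "
            f"fisher_p={seg['fisher_p']} "
            f"control allele freq={seg['allele_freq_controls']}"
        )
    if "conservation" in report:
        cons = report["conservation"]
        comp = " ".join(f"{k}:{v}" for k, v in cons["composition"].items())
        lines.append(f"conservation column: {comp} (gaps {cons['n_gaps']})")
        if "variant_aa" in cons:
            status = "observed" if cons["variant_aa_observed"] else "never observed"
            lines.append(f"  variant residue {cons['variant_aa']}: {status} across species")
    return "\n".join(lines) + "\n"
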