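"""Run configuration, stage orchestration, and report writing.

A :class:`RunConfig` gathers every tunable constant with defaults equal to
the study's stated values (rarity threshold 0.01, |%CFC| >= 60, error factor
0.85, intensity floor 1,000, onset age 25, theta grid 0..0.5).  ``run``
executes one named stage (or all of them on a fresh synthetic cohort) and
returns a :class:`RunReport` whose JSON/TSV serialisation is deterministic
given the seeds echoed inside it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .arrays import (
    global_normalize,
    hit_filter,
    hits_to_frame,
    read_spot_table,
    spots_from_replicates,
)
from .datasets import load_table4_spots
from .linkage import DEFAULT_THETA_GRID, DiseaseModel, LinkageResult, cosegregation_check, elod, lod_score
from .pedigree import Pedigree, read_genotypes, read_ped, write_ped
from .prioritize import CascadeConfig, run_cascade
from .simulate import ArraySimSpec, CohortSpec, generate_array_dataset, simulate_family_cohort, write_variant_table, choose_sequenced_ids

log = logging.getLogger("pedvar")


@dataclass
class ArrayFilterConfig:
    cfc_min: float = 60.0
    error_factor: float = 0.85
    intensity_min: float = 1000.0


@dataclass
class RunConfig:
    seed: int = 0
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    disease_model: DiseaseModel = field(default_factory=DiseaseModel)
    theta_grid: Tuple[float, ...] = DEFAULT_THETA_GRID
    array_filter: ArrayFilterConfig = field(default_factory=ArrayFilterConfig)
    cohort_n_variants: int = 2000
    marker_alt_freq: float = 1e-4
    married_in_ids: Tuple[str, ...] = ()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
        if "cascade" in raw:
            cfg.cascade = CascadeConfig(**raw["cascade"])
        if "disease_model" in raw:
            dm = dict(raw["disease_model"])
            if "penetrance" in dm:
                dm["penetrance"] = tuple(dm["penetrance"])
            cfg.disease_model = DiseaseModel(**dm)
        if "theta_grid" in raw:
            cfg.theta_grid = tuple(float(t) for t in raw["theta_grid"])
        if "array_filter" in raw:
            cfg.array_filter = ArrayFilterConfig(**raw["array_filter"])
        if "cohort_n_variants" in raw:
            cfg.cohort_n_variants = int(raw["cohort_n_variants"])
        if "marker_alt_freq" in raw:
            cfg.marker_alt_freq = float(raw["marker_alt_freq"])
        if "married_in_ids" in raw:
            cfg.married_in_ids = tuple(raw["married_in_ids"])
        return cfg

    def echo(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    version: str
    command: str
    config: dict
    seeds: Dict[str, int] = field(default_factory=dict)
    trace: List[Tuple[str, int, int]] = field(default_factory=list)
    candidates: List[dict] = field(default_factory=list)
    linkage: List[dict] = field(default_factory=list)
    hits: List[dict] = field(default_factory=list)
    extra: Dict[str, object] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "version": self.version,
            "command": self.command,
            "config": self.config,
            "seeds": self.seeds,
            "trace": [list(s) for s in self.trace],
            "candidates": self.candidates,
            "linkage": self.linkage,
            "hits": self.hits,
            "extra": self.extra,
        }


def write_report(report: RunReport, out_dir, formats: Sequence[str] = ("json", "tsv")) -> List[Path]:
    """Serialise a report; floats that are %CFC or LOD render with 2 decimals in TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    if "json" in formats:
        p = out / "report.json"
        p.write_text(json.dumps(report.as_dict(), indent=2, ensure_ascii=False, sort_keys=True) + "\n")
        written.append(p)
    if "tsv" in formats:
        if report.candidates:
            p = out / "candidates.tsv"
            pd.DataFrame(report.candidates).to_csv(p, sep="\t", index=False)
            written.append(p)
        if report.linkage:
            rows = []
            for res in report.linkage:
                for theta, lod in zip(res["theta_grid"], res["lod"]):
                    rows.append(
                        {"variant_id": res["variant_id"], "theta": theta, "lod": f"{lod:.2f}"}
                    )
            p = out / "lod_table.tsv"
            pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
            written.append(p)
        if report.hits:
            p = out / "hits.tsv"
            df = pd.DataFrame(report.hits)
            if "cfc_pct" in df:
                df["cfc_pct"] = df["cfc_pct"].map(lambda x: f"{x:.2f}")
            df.to_csv(p, sep="\t", index=False)
            written.append(p)
    return written


def _candidate_rows(candidates) -> List[dict]:
    rows = []
    for r in candidates:
        rows.append(
            {
                "variant_id": r.variant_id,
                "gene": r.gene,
                "hgvs_c": r.annotation.hgvs_c if r.annotation else "",
                "hgvs_p": (r.annotation.hgvs_p or "") if r.annotation else "",
                "consequence": r.consequence or "",
                "af_pop": "" if r.af_pop is None else f"{r.af_pop:.6g}",
                "damaging_count": "" if r.damaging_count is None else r.damaging_count,
            }
        )
    return rows


def run(
    command: str,
    config: RunConfig,
    *,
    out_dir="pedvar_out",
    ped_path=None,
    vcf_path=None,
    genotypes_path=None,
    array_tsv=None,
    sequenced_ids: Optional[Sequence[str]] = None,
) -> RunReport:
    """Execute one pipeline stage (``simulate``, ``prioritize``, ``linkage``,
    ``arrayhits``) or ``all`` of them on a seeded synthetic cohort."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(version=__version__, command=command, config=config.echo(), seeds={"seed": config.seed})

    if command == "simulate":
        _stage_simulate(config, out, report)
    elif command == "prioritize":
        if ped_path is None or vcf_path is None:
            raise ValueError("prioritize needs --ped and --vcf")
        _stage_prioritize(config, read_ped(ped_path), vcf_path, sequenced_ids, report)
    elif command == "linkage":
        if ped_path is None or genotypes_path is None:
            raise ValueError("linkage needs --ped and a genotype TSV")
        _stage_linkage(config, read_ped(ped_path), read_genotypes(genotypes_path), report)
    elif command == "arrayhits":
        _stage_arrayhits(config, array_tsv, report)
    elif command == "all":
        ped, vcf = _stage_simulate(config, out, report)
        _stage_prioritize(config, ped, vcf, sequenced_ids, report)
        genotypes = read_genotypes(out / "genotypes.tsv")
        _stage_linkage(config, ped, genotypes, report)
        _stage_arrayhits(config, out / "array_raw.tsv", report)
    else:
        raise ValueError(f"unknown command {command!r}")

    log.info("%s finished in %.1fs", command, time.time() - t0)
    return report


def _stage_simulate(config: RunConfig, out: Path, report: RunReport):
    spec = CohortSpec(
        disease_model=config.disease_model, n_variants=config.cohort_n_variants, seed=config.seed
    )
    cohort = simulate_family_cohort(spec)
    ped_path = out / "family.ped"
    write_ped(cohort.pedigree, ped_path)
    vcf_path = out / "variants.vcf"
    planted_id = write_variant_table(cohort, vcf_path)
    with open(out / "genotypes.tsv", "w") as fh:
        fh.write("individual_id\tvariant_id\tcall\n")
        for iid in cohort.pedigree.ids():
            fh.write(f"{iid}\t{planted_id}\t{cohort.planted_genotypes.call(iid)}\n")
    arr_spec = ArraySimSpec(seed=config.seed)
    tidy, truth = generate_array_dataset(arr_spec)
    tidy.to_csv(out / "array_raw.tsv", sep="\t", index=False)
    (out / "truth.json").write_text(
        json.dumps({"planted_variant": planted_id, "array_hits": sorted(truth)}, indent=2) + "\n"
    )
    report.extra["planted_variant"] = planted_id
    report.extra["n_members"] = len(cohort.pedigree)
    log.info("simulated cohort: %d members, %d variants", len(cohort.pedigree), spec.n_variants)
    return cohort.pedigree, vcf_path


def _stage_prioritize(config, ped, vcf_path, sequenced_ids, report):
    if sequenced_ids is None:
        thr = config.disease_model.onset_age_threshold
        sequenced_ids = [
            m.iid
            for m in ped.members
            if m.affection != "unknown" and (m.age_years is None or m.age_years >= thr)
        ]
    candidates, trace = run_cascade(vcf_path, ped, sequenced_ids, config=config.cascade)
    report.trace = list(trace.stages)
    report.candidates = _candidate_rows(candidates)
    for name, n_in, n_out in trace.stages:
        log.info("stage %-18s %7d -> %7d", name, n_in, n_out)


def _stage_linkage(config, ped, genotypes, report):
    for vid in sorted(genotypes):
        marker = genotypes[vid]
        res = lod_score(
            ped,
            marker,
            config.disease_model,
            theta_grid=config.theta_grid,
            marker_alt_freq=config.marker_alt_freq,
            married_in_ids=config.married_in_ids,
        )
        coseg = cosegregation_check(ped, marker, config.disease_model, config.married_in_ids)
        d = res.as_dict()
        d["cosegregates"] = coseg.cosegregates
        d["discordant_ids"] = coseg.discordant_ids
        d["exempted_ids"] = [list(e) for e in coseg.exempted_ids]
        report.linkage.append(d)
        log.info("%s: max LOD %.2f at theta=%.2f", vid, res.max_lod, res.theta_at_max)


def _stage_arrayhits(config, array_tsv, report):
    af = config.array_filter
    if array_tsv is None:
        spots, _ = load_table4_spots()
    else:
        peek = pd.read_csv(array_tsv, sep="\t", nrows=1)
        if "sample" in peek.columns:  # raw tidy replicate table
            tidy = pd.read_csv(array_tsv, sep="\t")
            normed, _ = global_normalize(tidy)
            spots = spots_from_replicates(normed, "control", "treatment")
        else:
            spots = read_spot_table(array_tsv)
    hits = hit_filter(spots, cfc_min=af.cfc_min, error_factor=af.error_factor, intensity_min=af.intensity_min)
    report.hits = hits_to_frame(hits).to_dict("records")
    log.info("array: %d spots, %d hits", len(hits), sum(1 for h in hits if h.is_hit))
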