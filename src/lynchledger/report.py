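"""Summary tables and the end-to-end pipeline.

The descriptive outputs are tidy tables rather than rendered figures:
per-year test totals by scope, gene-combination proportions among
patients' first full-gene episodes, the per-year result breakdown on the
P > LP > VUS > abnormal-unclassified > normal scale with classification
availability, linkage strata, and the cancer-timing site table.
Descriptive tables use calendar years (2001–2019 by default); coverage
tables use financial years.

:func:`run_pipeline` chains every stage — synthetic generation,
pseudonymisation at ingest, dialect harmonisation, episode construction,
registry linkage, coverage imputation, summarisation — and writes a
manifest recording the seed, a key fingerprint (never the key) and the
row counts flowing through each stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .coverage import (CoverageEstimate, adjust_audit, combine_totals,
                       compute_adjustment_factor, financial_year,
                       interpolate_pre_audit, AUDIT_FIRST_YEAR)
from .episodes import TestEpisode, build_episodes, gene_combination
from .harmonise import (BUILTIN_DIALECTS, SIGNIFICANCE_ORDER, map_extract,
                        write_cdm)
from .linkage import (LinkageReport, assign_timing, group_icd10, link_records,
                      pseudonymise_registry, read_registry)
from .synthgen import (GeneratorConfig, generate_patients, write_audit_counts,
                       write_lab_extracts, write_registry, write_truth_ledger)

__all__ = ["SummaryBundle", "PipelineConfig", "summarise", "run_pipeline",
           "observed_counts_by_lab_year"]

DEFAULT_YEAR_RANGE = (2001, 2019)


@dataclass
class SummaryBundle:
    per_year_totals: pd.DataFrame
    gene_combinations: pd.DataFrame
    result_breakdown: pd.DataFrame
    linkage_strata: dict[str, int]
    cancer_timing: pd.DataFrame
    unique_patients: int = 0
    repeat_episode_patients: int = 0

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.per_year_totals.to_csv(outdir / "per_year_totals.csv", index=False)
        self.gene_combinations.to_csv(outdir / "gene_combinations.csv", index=False)
        self.result_breakdown.to_csv(outdir / "result_breakdown.csv", index=False)
        self.cancer_timing.to_csv(outdir / "cancer_timing.csv", index=False)
        (outdir / "linkage_strata.json").write_text(
            json.dumps({"strata": self.linkage_strata,
                        "unique_patients": self.unique_patients,
                        "repeat_episode_patients": self.repeat_episode_patients},
                       indent=2, sort_keys=True))


def _in_range(year: int, year_range: tuple[int, int]) -> bool:
    return year_range[0] <= year <= year_range[1]


def summarise(episodes: Sequence[TestEpisode],
              linkage_report: LinkageReport | None = None,
              timing_flags: dict | None = None,
              year_range: tuple[int, int] = DEFAULT_YEAR_RANGE) -> SummaryBundle:
    """Build the descriptive tables from the episode and linkage outputs.

    Gene-combination proportions include only each patient's first test
    episode (full-gene scope); the result breakdown counts every
    full-gene episode in its own calendar year, so a patient with two
    episodes appears in both years but once in the unique-patient total.
    Every proportion row sums to one.
    """
    eps = [e for e in episodes if _in_range(e.episode_date.year, year_range)]

    rows = [{"year": e.episode_date.year, "scope": e.scope} for e in eps]
    if rows:
        totals = (pd.DataFrame(rows).value_counts(["year", "scope"])
                  .unstack(fill_value=0).reset_index())
        for col in ("full_gene", "targeted"):
            if col not in totals:
                totals[col] = 0
        totals["total"] = totals["full_gene"] + totals["targeted"]
        totals = totals[["year", "full_gene", "targeted", "total"]]
    else:
        totals = pd.DataFrame(columns=["year", "full_gene", "targeted", "total"])

    # first episode per patient, full-gene only, for gene combinations
    first_by_patient: dict[tuple, TestEpisode] = {}
    for e in sorted(episodes, key=lambda e: e.episode_date):
        first_by_patient.setdefault(e.patient_key(), e)
    combo_rows = [
        {"year": e.episode_date.year, "combination": gene_combination(e)}
        for e in first_by_patient.values()
        if e.scope == "full_gene" and _in_range(e.episode_date.year, year_range)
    ]
    if combo_rows:
        combos = (pd.DataFrame(combo_rows).groupby(["year", "combination"])
                  .size().rename("n").reset_index())
        combos["proportion"] = combos["n"] / combos.groupby("year")["n"].transform("sum")
    else:
        combos = pd.DataFrame(columns=["year", "combination", "n", "proportion"])

    result_rows = [
        {"year": e.episode_date.year, "result": e.most_significant}
        for e in eps if e.scope == "full_gene"
    ]
    if result_rows:
        res = (pd.DataFrame(result_rows).groupby(["year", "result"])
               .size().rename("n").reset_index())
        res = (res.pivot(index="year", columns="result", values="n")
               .fillna(0).astype(int))
        for cat in SIGNIFICANCE_ORDER:
            if cat not in res:
                res[cat] = 0
        res = res[list(SIGNIFICANCE_ORDER)].reset_index()
        year_total = res[list(SIGNIFICANCE_ORDER)].sum(axis=1)
        for cat in SIGNIFICANCE_ORDER:
            res[f"prop_{cat}"] = res[cat] / year_total
        abnormal = res[["abnormal_unclassified", "VUS", "LP", "P"]].sum(axis=1)
        classified = res[["VUS", "LP", "P"]].sum(axis=1)
        avail = 100.0 * classified / abnormal
        res["classification_available_pct"] = avail.where(abnormal > 0, 0.0)
    else:
        res = pd.DataFrame(columns=["year", *SIGNIFICANCE_ORDER])

    strata = dict(linkage_report.strata) if linkage_report else {}

    timing_rows = []
    if linkage_report is not None:
        for lc in linkage_report.linked:
            if lc.timing is None:
                continue
            timing_rows.append({"site_group": group_icd10(lc.entry.icd10),
                                "timing": lc.timing})
    if timing_rows:
        timing = (pd.DataFrame(timing_rows)
                  .value_counts(["site_group", "timing"]).rename("n")
                  .reset_index().sort_values(["site_group", "timing"])
                  .reset_index(drop=True))
    else:
        timing = pd.DataFrame(columns=["site_group", "timing", "n"])

    episode_count: dict[tuple, int] = {}
    for e in episodes:
        episode_count[e.patient_key()] = episode_count.get(e.patient_key(), 0) + 1
    return SummaryBundle(
        per_year_totals=totals,
        gene_combinations=combos,
        result_breakdown=res,
        linkage_strata=strata,
        cancer_timing=timing,
        unique_patients=len(episode_count),
        repeat_episode_patients=sum(1 for n in episode_count.values() if n > 1),
    )


# --------------------------------------------------------------------------
# Pipeline

class PipelineConfig(BaseModel):
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    key: str = "lynchledger-demo-key"
    outdir: str = "pipeline_out"
    year_range: tuple[int, int] = DEFAULT_YEAR_RANGE


def observed_counts_by_lab_year(records) -> tuple[dict, dict]:
    """Test-level observed counts per (lab, financial year): total and
    full-gene.  Gene rows of one test share a laboratory, pseudonym pair
    and authorisation date and are counted once."""
    seen: set[tuple] = set()
    total: dict[tuple[str, int], int] = {}
    fullgene: dict[tuple[str, int], int] = {}
    for r in records:
        test_key = (r.lab_code, r.pseudo_id1, r.pseudo_id2, r.authorised_date)
        if test_key in seen:
            continue
        seen.add(test_key)
        key = (r.lab_code, financial_year(r.authorised_date))
        total[key] = total.get(key, 0) + 1
        if r.scope == "full_gene":
            fullgene[key] = fullgene.get(key, 0) + 1
    return total, fullgene


def impute_coverage(observed: dict, observed_fullgene: dict,
                    audit: dict[tuple[str, int], int]) -> CoverageEstimate:
    """Full audit-based imputation: per-laboratory adjustment factors from
    overlap years, down-adjustment of pre-submission audit years, flat
    pre-audit back-fill for laboratories already audited in 1998."""
    labs = sorted({lab for lab, _ in list(observed) + list(audit)})
    adjusted: dict[tuple[str, int], int] = {}
    interpolated: dict[tuple[str, int], int] = {}
    for lab in labs:
        obs_lab = {fy: n for (code, fy), n in observed.items() if code == lab}
        audit_lab = {fy: n for (code, fy), n in audit.items() if code == lab}
        if not audit_lab:
            continue
        factor = compute_adjustment_factor(obs_lab, audit_lab)
        if factor is None:
            continue
        first_obs = min(obs_lab) if obs_lab else None
        adj = adjust_audit(audit_lab, factor, first_obs)
        for fy, n in adj.items():
            adjusted[(lab, fy)] = n
        # audited in the first audit year -> assume active through 1996
        active_from = 1996 if AUDIT_FIRST_YEAR in audit_lab else AUDIT_FIRST_YEAR
        for fy, n in interpolate_pre_audit(adj, active_from).items():
            interpolated[(lab, fy)] = n
    return combine_totals(observed, adjusted, interpolated, observed_fullgene)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage end to end; returns the manifest dict.

    Writes, under ``config.outdir``: the synthetic extracts, registry,
    audit and truth ledger (``synthetic/``); the harmonised CDM and
    quarantine files; the episode table; linkage outputs; the coverage
    summary; and the descriptive tables (``summary/``).
    """
    outdir = Path(config.outdir)
    synth_dir = outdir / "synthetic"
    synth_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    patients = generate_patients(config.generator)
    extract_paths = write_lab_extracts(patients, config.generator, synth_dir)
    n_registry = write_registry(patients, synth_dir / "registry_raw.csv")
    audit = write_audit_counts(patients, config.generator, synth_dir / "audit.csv")
    write_truth_ledger(patients, config.generator, synth_dir / "truth_ledger.jsonl")
    counts["patients"] = len(patients)
    counts["planted_tests"] = sum(len(p.planted_tests) for p in patients)
    counts["registry_rows"] = n_registry

    records = []
    quarantined = []
    for lab in config.generator.labs:
        spec = BUILTIN_DIALECTS[lab.dialect]
        result = map_extract(extract_paths[lab.lab_code], spec, config.key,
                             lab_code=lab.lab_code)
        records.extend(result.records)
        quarantined.extend(result.quarantined)
    write_cdm(records, outdir / "cdm.csv", outdir / "cdm.jsonl")
    with open(outdir / "quarantine.jsonl", "w") as fh:
        for q in quarantined:
            fh.write(json.dumps({"row": q.row_number, "reason": q.reason},
                                sort_keys=True) + "\n")
    counts["cdm_records"] = len(records)
    counts["quarantined_rows"] = len(quarantined)

    episodes = build_episodes(records)
    counts["episodes"] = len(episodes)

    pseudonymise_registry(synth_dir / "registry_raw.csv", config.key,
                          outdir / "registry_pseudonymised.csv")
    registry = read_registry(outdir / "registry_pseudonymised.csv")
    link_report = link_records(episodes, registry)
    timing_flags = assign_timing(link_report.linked, episodes)
    counts["linked_cancers"] = len(link_report.linked)

    observed, observed_fg = observed_counts_by_lab_year(records)
    estimate = impute_coverage(observed, observed_fg, audit)
    (outdir / "coverage.json").write_text(json.dumps({
        "observed_total": estimate.observed_total,
        "consensus_total": estimate.consensus_total,
        "full_gene_total": estimate.full_gene_total,
        "targeted_total": estimate.targeted_total,
        "coverage_pct": estimate.coverage_pct,
        "carriers_fullgene": estimate.carriers_fullgene,
        "carriers_cascade": estimate.carriers_cascade,
        "carrier_fraction_pct": estimate.carrier_fraction_pct,
    }, indent=2, sort_keys=True))

    bundle = summarise(episodes, link_report, timing_flags,
                       year_range=config.year_range)
    bundle.write(outdir / "summary")

    manifest = {
        "version": __version__,
        "seed": config.generator.seed,
        "key_fingerprint": hashlib.sha256(
            config.key.encode()).hexdigest()[:12],
        "counts": counts,
        "coverage_pct": estimate.coverage_pct,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return manifest
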