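"""National coverage imputation and carrier-yield arithmetic.

Patient-level submissions only reach back as far as each laboratory's
information system allowed, so the observed dataset under-counts early
national activity.  An annual laboratory-level audit (financial years
1998–2016) counts every MMR analysis but is inflated for some
laboratories by out-of-scope activity (other nations, private work,
MSI tumour screens).  This module:

1. derives a per-laboratory *adjustment factor* from the years where
   observed and audit counts overlap (pooled ratio, clamped to (0, 1]);
2. down-adjusts audit counts for each laboratory's pre-submission years;
3. back-fills the two pre-audit financial years (1996, 1997) flat from
   the earliest adjusted year, for laboratories already active then;
4. combines observed, adjusted and interpolated counts into a consensus
   national series and a coverage percentage; and
5. turns the national full-gene and targeted (cascade) totals into
   expected carrier yields using the observed detection rates, and into
   the fraction of the predicted national carrier population found.

Financial years run 1 April–31 March and are labelled by starting year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping

AUDIT_FIRST_YEAR = 1998
AUDIT_LAST_YEAR = 2016  # inclusive, fy 2016 = Apr 2016–Mar 2017
PRE_AUDIT_YEARS = (1996, 1997)

#: observed detection rates used for carrier-yield estimation:
#: P/LP rate on full-gene analyses, abnormal rate on targeted analyses
DEFAULT_RATE_FULLGENE = 0.15
DEFAULT_RATE_TARGETED = 0.45

#: population-prevalence defaults for the carrier-fraction bound
DEFAULT_PREVALENCE_DENOMINATOR = 279
DEFAULT_POPULATION = 56_000_000

__all__ = [
    "financial_year",
    "CoverageEstimate",
    "compute_adjustment_factor",
    "adjust_audit",
    "interpolate_pre_audit",
    "combine_totals",
    "estimate_carriers",
    "carrier_fraction",
]


def financial_year(d: date) -> int:
    """Financial year (1 April–31 March) labelled by its starting year."""
    return d.year if d.month >= 4 else d.year - 1


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class CoverageEstimate:
    """Per-laboratory, per-financial-year consensus counts and national
    totals with carrier-yield derivations."""

    table: dict[tuple[str, int], dict] = field(default_factory=dict)
    observed_total: int = 0
    consensus_total: int = 0
    full_gene_total: int = 0
    targeted_total: int = 0
    coverage_pct: float = 0.0
    carriers_fullgene: int = 0
    carriers_cascade: int = 0
    carrier_fraction_pct: float = 0.0

    @property
    def grand_total(self) -> int:
        return self.full_gene_total + self.targeted_total


def compute_adjustment_factor(observed: Mapping[int, int],
                              audit: Mapping[int, int]) -> float | None:
    """Pooled observed/audit ratio over overlap years, clamped to (0, 1].

    Overlap years are those with an observed count and a positive audit
    count.  The pooled ratio (sum of observed over sum of audit) damps
    single-year noise relative to a mean of per-year ratios.  Returns
    None when no overlap year exists (laboratory flagged upstream).
    """
    overlap = [y for y in observed if audit.get(y, 0) > 0]
    if not overlap:
        return None
    total_obs = sum(observed[y] for y in overlap)
    total_audit = sum(audit[y] for y in overlap)
    return min(1.0, total_obs / total_audit)


def adjust_audit(audit: Mapping[int, int], factor: float,
                 first_observed_year: int | None) -> dict[int, int]:
    """Down-adjust a laboratory's audit counts for pre-submission years.

    Only years before the laboratory's earliest observed submission are
    adjusted — observed patient-level counts win wherever they exist.
    """
    if factor is None:
        raise ValueError("adjustment factor required")
    cutoff = first_observed_year if first_observed_year is not None else 10**6
    return {y: _round_half_up(c * factor)
            for y, c in sorted(audit.items()) if y < cutoff}


def interpolate_pre_audit(adjusted: Mapping[int, int],
                          active_from: int) -> dict[int, int]:
    """Flat back-fill of the pre-audit financial years 1996 and 1997.

    Each missing pre-audit year in which the laboratory was already
    active receives the laboratory's earliest available adjusted annual
    count.  Laboratories first active from 1998 onwards get no rows.
    """
    if active_from >= AUDIT_FIRST_YEAR or not adjusted:
        return {}
    earliest = adjusted[min(adjusted)]
    return {y: earliest for y in PRE_AUDIT_YEARS if y >= active_from}


def combine_totals(observed: Mapping[tuple[str, int], int],
                   adjusted: Mapping[tuple[str, int], int],
                   interpolated: Mapping[tuple[str, int], int] | None = None,
                   observed_fullgene: Mapping[tuple[str, int], int] | None = None,
                   rate_fullgene: float = DEFAULT_RATE_FULLGENE,
                   rate_targeted: float = DEFAULT_RATE_TARGETED,
                   prevalence_denominator: int = DEFAULT_PREVALENCE_DENOMINATOR,
                   population: int = DEFAULT_POPULATION) -> CoverageEstimate:
    """Merge observed, adjusted and interpolated lab-year counts.

    Consensus per lab-year = observed where available, else the
    adjusted/interpolated estimate; a lab-year present in observed and in
    either estimate stream is a double-count and a hard failure.  The
    full-gene/targeted split of estimated years is not present in the
    audit; it is apportioned by each laboratory's observed full-gene
    share (the overall share when a laboratory has no observed years).
    """
    interpolated = interpolated or {}
    est = CoverageEstimate()
    dupes = (set(observed) & set(adjusted)) | (set(observed) & set(interpolated))
    if dupes:
        raise ValueError(f"lab-years counted twice: {sorted(dupes)[:5]}")

    observed_fullgene = observed_fullgene or {}
    lab_obs: dict[str, int] = {}
    lab_fg: dict[str, int] = {}
    for (lab, year), n in observed.items():
        lab_obs[lab] = lab_obs.get(lab, 0) + n
        lab_fg[lab] = lab_fg.get(lab, 0) + observed_fullgene.get((lab, year), 0)
    total_obs = sum(lab_obs.values())
    global_share = (sum(lab_fg.values()) / total_obs) if total_obs else 0.0

    fg_exact = 0.0
    for source, kind in ((observed, "observed"), (adjusted, "adjusted"),
                         (interpolated, "interpolated")):
        for (lab, year), n in source.items():
            est.table[(lab, year)] = {"kind": kind, "consensus_count": n}
            est.consensus_total += n
            if kind == "observed":
                est.observed_total += n
                fg_exact += observed_fullgene.get((lab, year), 0)
            else:
                share = (lab_fg[lab] / lab_obs[lab]) if lab_obs.get(lab) \
                    else global_share
                fg_exact += n * share

    est.full_gene_total = _round_half_up(fg_exact)
    est.targeted_total = est.consensus_total - est.full_gene_total
    est.coverage_pct = (100.0 * est.observed_total / est.consensus_total
                        if est.consensus_total else 0.0)
    est.carriers_fullgene, est.carriers_cascade = estimate_carriers(
        est.full_gene_total, est.targeted_total, rate_fullgene, rate_targeted)
    est.carrier_fraction_pct = carrier_fraction(
        est.carriers_fullgene + est.carriers_cascade,
        prevalence_denominator, population)
    return est


def estimate_carriers(full_gene_total: int, targeted_total: int,
                      rate_fullgene: float = DEFAULT_RATE_FULLGENE,
                      rate_targeted: float = DEFAULT_RATE_TARGETED,
                      ) -> tuple[int, int]:
    """Expected pathogenic-variant carriers detected by each testing arm.

    Full-gene analyses yield carriers at the observed P/LP detection
    rate; targeted (cascade) analyses at the observed abnormal rate.
    Counts are rounded half-up at this final step only.
    """
    for r in (rate_fullgene, rate_targeted):
        if not 0.0 <= r <= 1.0:
            raise ValueError("detection rates must lie in [0, 1]")
    return (_round_half_up(full_gene_total * rate_fullgene),
            _round_half_up(targeted_total * rate_targeted))


def carrier_fraction(carriers_total: int, prevalence_denominator: int,
                     population: int) -> float:
    """Detected carriers as a percentage of the predicted carrier
    population (population / prevalence denominator)."""
    if prevalence_denominator <= 0 or population <= 0:
        raise ValueError("prevalence denominator and population must be positive")
    predicted = population / prevalence_denominator
    return 100.0 * carriers_total / predicted
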