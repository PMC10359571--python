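"""Test-episode construction.

A patient may have several per-gene records spread over days or months —
one sample analysed for four genes, a reflex dosage analysis a few weeks
later, a confirmatory repeat.  These are collapsed into *test episodes*:
records are sorted by authorisation date and grouped greedily, a record
joining the open episode while it falls within 365 days of the episode's
anchor (earliest) date, otherwise opening a new episode.  The anchor date
is the episode date.  Each episode carries the union of genes analysed,
the laboratory set, a scope, and the single most significant result under
the severity hierarchy P > LP > VUS > abnormal-unclassified > normal.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Sequence

from .harmonise import MMR_GENES, SIGNIFICANCE_ORDER, CdmRecord

EPISODE_WINDOW_DAYS = 365

__all__ = [
    "TestEpisode",
    "collapse_episodes",
    "deduplicate",
    "most_significant_result",
    "classify_scope",
    "gene_combination",
    "build_episodes",
]


@dataclass
class TestEpisode:
    pseudo_id1: str | None
    pseudo_id2: str | None
    episode_date: date
    lab_codes: set[str] = field(default_factory=set)
    scope: str = "full_gene"
    scope_derived: bool = False
    genes: tuple[str, ...] = ()
    member_records: list[CdmRecord] = field(default_factory=list)
    most_significant: str = "normal"
    #: grouping key assigned by build_episodes; distinguishes unlinkable
    #: patients, who all share an absent pseudonym pair
    patient_ref: tuple | None = None

    @property
    def report_date(self) -> date:
        """Latest report date among members (episode date when none given)."""
        dates = [r.report_date for r in self.member_records if r.report_date]
        return max(dates) if dates else self.episode_date

    def patient_key(self) -> tuple:
        return self.patient_ref if self.patient_ref is not None \
            else (self.pseudo_id1, self.pseudo_id2)


def most_significant_result(member_results: Iterable[str]) -> str:
    """Maximum under the total order P > LP > VUS > abnormal_unclassified >
    normal; raises on empty input."""
    # benign / likely benign member results rank as normal
    results = ["normal" if r in ("B", "LB") else r for r in member_results]
    if not results:
        raise ValueError("most_significant_result requires at least one result")
    unknown = set(results) - set(SIGNIFICANCE_ORDER)
    if unknown:
        raise ValueError(f"unknown result categories: {sorted(unknown)}")
    return max(results, key=SIGNIFICANCE_ORDER.index)


def deduplicate(records: Sequence[CdmRecord]) -> list[CdmRecord]:
    """Drop exact repeats of (pseudonyms, gene, date, variant, classification).

    Repeat submissions of the same result (e.g. a record present in two
    extract refreshes) reduce to one; genuinely different variants on the
    same day are kept.
    """
    seen: set[tuple] = set()
    out: list[CdmRecord] = []
    for r in records:
        key = (r.pseudo_id1, r.pseudo_id2, r.gene, r.authorised_date,
               r.variant_cdna, r.cnv_text, r.classification)
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


def classify_scope(members: Sequence[CdmRecord]) -> tuple[str, bool]:
    """Episode scope and whether it had to be derived.

    The source extract's test-type field wins when any member carries a
    mapped (non-derived) scope; targeted takes precedence there since a
    predictive test joined with a reflex analysis is still a targeted
    contact.  Otherwise the episode-level derivation applies: a
    multi-gene record set is a full-gene screen; a single-gene set keeps
    the per-record derivation, flagged as derived.
    """
    mapped = {r.scope for r in members if not r.scope_derived}
    if mapped:
        return ("targeted" if "targeted" in mapped else "full_gene"), False
    genes = {r.gene for r in members}
    if len(genes) > 1:
        return "full_gene", True
    return members[0].scope, True


def collapse_episodes(records: Sequence[CdmRecord]) -> list[TestEpisode]:
    """Collapse one patient's records into anchored 365-day episodes.

    All records must share the same pseudonym pair.  Greedy anchoring:
    after date-sorting, the first record opens an episode; each subsequent
    record joins while its date is within 365 days of the episode's
    earliest (anchor) date, else it opens a new episode.  Every record
    lands in exactly one episode.
    """
    if not records:
        return []
    keys = {(r.pseudo_id1, r.pseudo_id2) for r in records}
    if len(keys) > 1:
        raise ValueError("collapse_episodes takes records of a single patient")
    ordered = sorted(records, key=lambda r: r.authorised_date)
    episodes: list[TestEpisode] = []
    current: list[CdmRecord] = []
    anchor: date | None = None
    for rec in ordered:
        if anchor is None or (rec.authorised_date - anchor).days > EPISODE_WINDOW_DAYS:
            if current:
                episodes.append(_finish(current, anchor))
            current, anchor = [], rec.authorised_date
        current.append(rec)
    episodes.append(_finish(current, anchor))
    return episodes


def _finish(members: list[CdmRecord], anchor: date) -> TestEpisode:
    scope, derived = classify_scope(members)
    genes = tuple(g for g in MMR_GENES if g in {r.gene for r in members})
    return TestEpisode(
        pseudo_id1=members[0].pseudo_id1,
        pseudo_id2=members[0].pseudo_id2,
        episode_date=anchor,
        lab_codes={r.lab_code for r in members},
        scope=scope,
        scope_derived=derived,
        genes=genes,
        member_records=list(members),
        most_significant=most_significant_result(r.significance() for r in members),
    )


def gene_combination(episode: TestEpisode) -> str:
    """Canonical gene-set label, e.g. ``MLH1+MSH2`` — defined for
    full-gene episodes."""
    if episode.scope != "full_gene":
        raise ValueError("gene_combination applies to full-gene episodes")
    return "+".join(episode.genes)


def build_episodes(records: Sequence[CdmRecord]) -> list[TestEpisode]:
    """Deduplicate then collapse a whole cohort, patient by patient.

    Records with no pseudonyms at all cannot be grouped across rows and
    are treated as one synthetic patient per (lab, date) — they stay in
    the episode table but are unlinkable.
    """
    deduped = deduplicate(records)
    by_patient: dict[tuple, list[CdmRecord]] = defaultdict(list)
    for r in deduped:
        if r.pseudo_id1 is None and r.pseudo_id2 is None:
            # no cross-row identity: records of one extract row share
            # (lab, date) and stay together; distinct unlinkable patients
            # tested the same day at the same lab cannot be separated
            key = ("__unlinkable__", r.lab_code, r.authorised_date)
        else:
            key = (r.pseudo_id1, r.pseudo_id2)
        by_patient[key].append(r)
    episodes: list[TestEpisode] = []
    for key, recs in by_patient.items():
        for ep in collapse_episodes(recs):
            ep.patient_ref = key
            episodes.append(ep)
    episodes.sort(key=lambda e: (e.episode_date, e.pseudo_id1 or "", e.pseudo_id2 or ""))
    return episodes
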