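"""Deterministic linkage of test episodes to the pseudonymised cancer registry.

Both sides carry the same keyed pseudonym pair (pseudo-ID1 from the NHS
number, pseudo-ID2 from DOB + postcode).  Linkage is exact: match on
pseudo-ID1 wherever both sides have one, fall back to pseudo-ID2, and
record patients with neither as unlinkable.  Linked cancers are then
classified as diagnosed before or after the report date of the patient's
first test episode, and grouped by ICD-10 site (colorectal C18–C20,
uterine C54–C55, other).
"""

from __future__ import annotations

import csv
import re
from collections import defaultdict
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

from .episodes import TestEpisode
from .pseudonym import PseudonymPair, linkage_stratum

__all__ = [
    "RegistryEntry",
    "LinkedCancer",
    "link_records",
    "assign_timing",
    "group_icd10",
    "read_registry",
]

_ICD10_RE = re.compile(r"^[CD]\d{2}(?:\.\d{1,2})?$")


@dataclass(frozen=True)
class RegistryEntry:
    pseudo_id1: str | None
    pseudo_id2: str | None
    icd10: str
    diagnosis_date: date

    def __post_init__(self) -> None:
        if not _ICD10_RE.match(self.icd10):
            raise ValueError(f"malformed ICD-10 code: {self.icd10!r}")


@dataclass
class LinkedCancer:
    patient_key: tuple[str | None, str | None]
    entry: RegistryEntry
    matched_on: str  # "id1" | "id2"
    timing: str | None = None  # "before_test" | "after_test"


@dataclass
class LinkageReport:
    strata: dict[str, int]
    conflicts: int
    linked: list[LinkedCancer]


def group_icd10(code: str) -> str:
    """C18–C20 → colorectal, C54–C55 → uterine, other malignant → other."""
    code = code.strip().upper()
    if not _ICD10_RE.match(code):
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    stem = int(code[1:3])
    if code[0] == "C" and 18 <= stem <= 20:
        return "colorectal"
    if code[0] == "C" and 54 <= stem <= 55:
        return "uterine"
    return "other"


def link_records(episodes: Sequence[TestEpisode],
                 registry: Sequence[RegistryEntry]) -> LinkageReport:
    """Match patients to registry entries via pseudo-ID1, else pseudo-ID2.

    The stratum report counts unique patients by available pseudonyms
    (both / id1_only / id2_only / none).  When a patient's pseudo-ID1
    matches a registry entry whose pseudo-ID2 disagrees with the
    patient's, the conflict is counted and the ID1 match kept — the NHS
    number is the stronger identifier.
    """
    patients: dict[tuple, PseudonymPair] = {}
    for ep in episodes:
        patients.setdefault(ep.patient_key(),
                            PseudonymPair(ep.pseudo_id1, ep.pseudo_id2))

    strata: dict[str, int] = {"both": 0, "id1_only": 0, "id2_only": 0, "none": 0}
    for pair in patients.values():
        strata[linkage_stratum(pair)] += 1

    by_id1: dict[str, list[RegistryEntry]] = defaultdict(list)
    by_id2: dict[str, list[RegistryEntry]] = defaultdict(list)
    for entry in registry:
        if entry.pseudo_id1:
            by_id1[entry.pseudo_id1].append(entry)
        if entry.pseudo_id2:
            by_id2[entry.pseudo_id2].append(entry)

    linked: list[LinkedCancer] = []
    conflicts = 0
    for key, pair in patients.items():
        if pair.pseudo_id1 and pair.pseudo_id1 in by_id1:
            for entry in by_id1[pair.pseudo_id1]:
                if (entry.pseudo_id2 and pair.pseudo_id2
                        and entry.pseudo_id2 != pair.pseudo_id2):
                    conflicts += 1  # id1 wins
                linked.append(LinkedCancer(key, entry, "id1"))
        elif pair.pseudo_id2 and pair.pseudo_id2 in by_id2:
            for entry in by_id2[pair.pseudo_id2]:
                linked.append(LinkedCancer(key, entry, "id2"))
    return LinkageReport(strata=strata, conflicts=conflicts, linked=linked)


def assign_timing(linked: Iterable[LinkedCancer],
                  episodes: Sequence[TestEpisode]) -> dict[tuple, str]:
    """Date each linked cancer against the first test episode's report date.

    A diagnosis strictly after the reference date is ``after_test``;
    on or before it, ``before_test`` (diagnoses on the reference date
    count as pre-test).  Returns per-patient flags ``pre_only`` /
    ``post_only`` / ``both`` over patients with at least one dated,
    linked cancer; cancers without a diagnosis date are excluded.
    """
    first_episode: dict[tuple, TestEpisode] = {}
    for ep in sorted(episodes, key=lambda e: e.episode_date):
        first_episode.setdefault(ep.patient_key(), ep)

    seen: dict[tuple, set[str]] = defaultdict(set)
    for lc in linked:
        ep = first_episode.get(lc.patient_key)
        if ep is None or lc.entry.diagnosis_date is None:
            continue
        reference = ep.report_date
        lc.timing = ("after_test" if lc.entry.diagnosis_date > reference
                     else "before_test")
        seen[lc.patient_key].add(lc.timing)

    flags: dict[tuple, str] = {}
    for key, kinds in seen.items():
        if kinds == {"before_test"}:
            flags[key] = "pre_only"
        elif kinds == {"after_test"}:
            flags[key] = "post_only"
        else:
            flags[key] = "both"
    return flags


def pseudonymise_registry(raw_csv: str | Path, key: bytes | str,
                          out_csv: str | Path) -> int:
    """Recreate the pseudonym pair from registry-held identifiers.

    The registry arrives with raw identifiers (nhs_number, dob,
    postcode); the same keyed derivation used at laboratory ingest is
    applied so both sides share tokens, and raw identifiers are dropped.
    Returns the number of rows written.
    """
    from .pseudonym import make_pair

    n = 0
    with open(raw_csv, newline="") as fin, open(out_csv, "w", newline="") as fout:
        writer = csv.DictWriter(fout, fieldnames=[
            "pseudo_id1", "pseudo_id2", "icd10", "diagnosis_date"])
        writer.writeheader()
        for row in csv.DictReader(fin):
            pair = make_pair(row.get("nhs_number") or None,
                             row.get("dob") or None,
                             row.get("postcode") or None, key)
            writer.writerow({
                "pseudo_id1": pair.pseudo_id1 or "",
                "pseudo_id2": pair.pseudo_id2 or "",
                "icd10": row["icd10"],
                "diagnosis_date": row["diagnosis_date"],
            })
            n += 1
    return n


def read_registry(path: str | Path) -> list[RegistryEntry]:
    """Load a pseudonymised registry CSV (pseudo_id1, pseudo_id2, icd10,
    diagnosis_date)."""
    out: list[RegistryEntry] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(RegistryEntry(
                pseudo_id1=row.get("pseudo_id1") or None,
                pseudo_id2=row.get("pseudo_id2") or None,
                icd10=row["icd10"],
                diagnosis_date=date.fromisoformat(row["diagnosis_date"]),
            ))
    return out
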