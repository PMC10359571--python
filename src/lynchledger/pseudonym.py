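"""Keyed pseudonymisation and identifier stripping.

Patient-level laboratory records arrive carrying raw identifiers (NHS
number, date of birth, postcode).  To permit deterministic linkage to the
cancer registry without ever moving raw identifiers downstream, two
reproducible pseudonyms are derived at ingest:

* **pseudo-ID1** — keyed digest of the (validated) NHS number;
* **pseudo-ID2** — keyed digest of date of birth + postcode.

Both are HMAC-SHA256 under a run-scoped secret key, truncated to
:data:`TOKEN_LENGTH` hex characters.  The same (input, key) pair always
yields the same token; without the key the token is irreversible.  After
pseudonym creation the raw identifiers are removed and every remaining
string field (including free-text report wording) is scanned for surviving
identifier patterns — finding one is a hard privacy failure.
"""

from __future__ import annotations

import hashlib
import hmac
import re
from dataclasses import dataclass
from datetime import date
from typing import Any, Mapping

__all__ = [
    "PseudonymPair",
    "IdentifierLeakError",
    "validate_nhs_number",
    "make_pseudo_id1",
    "make_pseudo_id2",
    "strip_identifiers",
    "scrub_text",
    "linkage_stratum",
]

TOKEN_LENGTH = 32

#: raw-identifier fields removed by :func:`strip_identifiers`
IDENTIFIER_FIELDS = ("nhs_number", "dob", "postcode")

# Digit runs of length 10 (NHS-number shaped), allowing internal spaces,
# and UK postcode outcode+incode shapes.  Dates in ISO or DD/MM/YYYY form
# are also treated as potential DOB leaks inside free text.
_NHS_LIKE = re.compile(r"\b\d(?:[ \-]?\d){9}\b")
_POSTCODE_LIKE = re.compile(r"\b[A-Z]{1,2}\d{1,2}[A-Z]?\s*\d[A-Z]{2}\b")
_DATE_LIKE = re.compile(r"\b(?:\d{4}-\d{2}-\d{2}|\d{2}/\d{2}/\d{4})\b")

_REDACTION = "[REDACTED]"


class IdentifierLeakError(RuntimeError):
    """A raw identifier survived pseudonymisation (privacy contract breach)."""


@dataclass(frozen=True)
class PseudonymPair:
    """The two linkage tokens carried by every pseudonymised record.

    ``pseudo_id1`` is present iff a valid NHS number was supplied;
    ``pseudo_id2`` iff both DOB and postcode were supplied.
    """

    pseudo_id1: str | None = None
    pseudo_id2: str | None = None

    @property
    def linkable(self) -> bool:
        return self.pseudo_id1 is not None or self.pseudo_id2 is not None


def _canonical_nhs(s: str) -> str:
    return re.sub(r"[ \-]", "", s or "")


def validate_nhs_number(s: str) -> bool:
    """Check an NHS number against the standard mod-11 check digit.

    The first nine digits are weighted 10..2, summed, and the check digit
    must equal ``11 - (sum mod 11)`` with 11 mapping to 0 and 10 marking
    the number invalid.  Returns False on any malformed input.
    """
    if not isinstance(s, str):
        return False
    digits = _canonical_nhs(s)
    if len(digits) != 10 or not digits.isdigit():
        return False
    weighted = sum(int(d) * w for d, w in zip(digits[:9], range(10, 1, -1)))
    check = 11 - (weighted % 11)
    if check == 11:
        check = 0
    if check == 10:
        return False
    return check == int(digits[9])


def _digest(message: str, key: bytes | str) -> str:
    if isinstance(key, str):
        key = key.encode("utf-8")
    if not key:
        raise ValueError("pseudonymisation key must be non-empty")
    mac = hmac.new(key, message.encode("utf-8"), hashlib.sha256)
    return mac.hexdigest()[:TOKEN_LENGTH]


def make_pseudo_id1(nhs_number: str, key: bytes | str) -> str | None:
    """Keyed digest of the canonicalised NHS number; None if invalid."""
    if not validate_nhs_number(nhs_number):
        return None
    return _digest("ID1|" + _canonical_nhs(nhs_number), key)


def make_pseudo_id2(dob: date | str | None, postcode: str | None, key: bytes | str) -> str | None:
    """Keyed digest of ``YYYY-MM-DD|POSTCODE``; None if either part missing.

    The postcode is upper-cased with all internal whitespace removed, the
    DOB rendered as an ISO date, so formatting differences between the
    laboratory extract and the registry cannot defeat linkage.
    """
    if dob is None or postcode is None or str(postcode).strip() == "":
        return None
    if isinstance(dob, date):
        dob_iso = dob.isoformat()
    else:
        dob_iso = str(dob).strip()
        # accept DD/MM/YYYY as supplied by one laboratory dialect
        m = re.fullmatch(r"(\d{2})/(\d{2})/(\d{4})", dob_iso)
        if m:
            dob_iso = f"{m.group(3)}-{m.group(2)}-{m.group(1)}"
        if not re.fullmatch(r"\d{4}-\d{2}-\d{2}", dob_iso):
            return None
    canon_pc = re.sub(r"\s+", "", str(postcode)).upper()
    return _digest("ID2|" + dob_iso + "|" + canon_pc, key)


def make_pair(nhs_number: str | None, dob: date | str | None, postcode: str | None,
              key: bytes | str) -> PseudonymPair:
    """Convenience constructor applying both derivations."""
    return PseudonymPair(
        pseudo_id1=make_pseudo_id1(nhs_number, key) if nhs_number else None,
        pseudo_id2=make_pseudo_id2(dob, postcode, key),
    )


def scrub_text(text: str) -> tuple[str, bool]:
    """Redact identifier-shaped substrings from free text.

    Returns ``(clean_text, leaked)`` where *leaked* reports whether any
    NHS-number-like digit run, postcode-shaped token or date string was
    found (and replaced).
    """
    leaked = False
    for pattern in (_NHS_LIKE, _POSTCODE_LIKE, _DATE_LIKE):
        text, n = pattern.subn(_REDACTION, text)
        leaked = leaked or n > 0
    return text, leaked


def strip_identifiers(raw_record: Mapping[str, Any], pair: PseudonymPair,
                      *, redact_free_text: bool = True) -> dict[str, Any]:
    """Replace raw identifiers with the pseudonym pair.

    Every non-identifier string field of the output is scanned for
    surviving identifier patterns.  Free-text fields are redacted in
    place when ``redact_free_text`` (the default); a leak in a structured
    field, or any leak with redaction disabled, raises
    :class:`IdentifierLeakError` — records must never move downstream
    carrying raw identifiers.
    """
    out: dict[str, Any] = {"pseudo_id1": pair.pseudo_id1, "pseudo_id2": pair.pseudo_id2}
    for field, value in raw_record.items():
        if field in IDENTIFIER_FIELDS:
            continue
        if isinstance(value, str):
            clean, leaked = scrub_text(value)
            if leaked:
                if not redact_free_text or field not in ("source_text", "report_text"):
                    raise IdentifierLeakError(
                        f"identifier pattern survived in field {field!r}")
                value = clean
        out[field] = value
    out["unlinkable"] = not pair.linkable
    return out


def linkage_stratum(pair: PseudonymPair) -> str:
    """Classify a record as ``both`` / ``id1_only`` / ``id2_only`` / ``none``."""
    if pair.pseudo_id1 and pair.pseudo_id2:
        return "both"
    if pair.pseudo_id1:
        return "id1_only"
    if pair.pseudo_id2:
        return "id2_only"
    return "none"
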