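"""Rule-based exclusion filters.

Each filter is an independent, idempotent function mapping a record
collection to a list of :class:`ViolationFlag`; it reads only the fields its
rule names, so filters can run in any order or in isolation.

Boundary conventions follow the protocol wording exactly: overdoses flag at
strictly more than the maximum (10 passes, 11 fails), speeders at strictly
under the minimum (7.0 minutes passes, 6.99 fails). Missing data never
flags — absence of evidence is not fraud evidence — with one conservative
exception: an IP string that cannot be parsed at all is flagged as
unresolvable.
"""

from __future__ import annotations

import ipaddress
import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

from .config import DEFAULT_MEDICAID_FLAGGED_BRACKETS
from .records import (
    BOROUGHS,
    CURRENTLY_HOMELESS,
    DEFAULT_FICTITIOUS_DRUG,
    RespondentRecord,
    ViolationCategory,
)

ALLOWED_IP_COUNTRIES = frozenset({"US", "CA"})

DEFAULT_IMPOSSIBLE_PAIRS = frozenset({
    ("alcohol", "inject"),
    ("inhalants", "inject"),
    ("marijuana", "inject"),
    ("synthetic cannabinoids", "inject"),
})

#: Bulk-created bot mailbox: letters-only local part ending in >= 5 digits.
EMAIL_BOT_PATTERN = re.compile(r"^[A-Za-z]+[0-9]{5,}$")


@dataclass(frozen=True)
class ViolationFlag:
    record_id: str
    category: ViolationCategory
    detail: str = ""


def column_country_resolver(record: RespondentRecord) -> Optional[str]:
    """Packaged resolver: read the exported ip_country column (no live GeoIP)."""
    return record.ip_country


def _valid_ipv4(ip: Optional[str]) -> bool:
    if ip is None:
        return False
    try:
        ipaddress.IPv4Address(ip)
    except (ipaddress.AddressValueError, ValueError):
        return False
    return True


def flag_foreign_ip(
    records: Sequence[RespondentRecord],
    resolver: Callable[[RespondentRecord], Optional[str]] = column_country_resolver,
) -> list[ViolationFlag]:
    """Flag submissions whose IP resolves outside the US or Canada.

    A missing country resolution is tolerated; a malformed IP string is
    flagged conservatively with detail "unresolvable".
    """
    flags = []
    for record in records:
        if record.ip_address is not None and not _valid_ipv4(record.ip_address):
            flags.append(ViolationFlag(record.record_id,
                                       ViolationCategory.FOREIGN_IP,
                                       "unresolvable"))
            continue
        country = resolver(record)
        if country is not None and country not in ALLOWED_IP_COUNTRIES:
            flags.append(ViolationFlag(record.record_id,
                                       ViolationCategory.FOREIGN_IP, country))
    return flags


def flag_duplicates(records: Sequence[RespondentRecord],
                    policy: str = "keep-first") -> list[ViolationFlag]:
    """Flag records sharing an IP or a (non-missing) email address.

    Under ``keep-first`` every group member except the earliest submission is
    flagged; under ``drop-all`` all members are. Ties on timestamp break by
    record_id. A record in both an IP and an email group is flagged once.
    """
    if policy not in ("keep-first", "drop-all"):
        raise ValueError(f"unknown duplicate policy {policy!r}")
    groups: dict[tuple, list[RespondentRecord]] = defaultdict(list)
    for record in records:
        if record.ip_address is not None:
            groups[("ip", record.ip_address)].append(record)
        if record.email is not None:
            groups[("email", record.email)].append(record)

    flagged: dict[str, str] = {}
    for (kind, value), members in groups.items():
        if len(members) < 2:
            continue
        members = sorted(members, key=lambda r: (r.submitted_at, r.record_id))
        offenders = members if policy == "drop-all" else members[1:]
        for record in offenders:
            flagged.setdefault(
                record.record_id,
                f"shared {kind} {value} with {members[0].record_id}",
            )
    order = {r.record_id: i for i, r in enumerate(records)}
    return [
        ViolationFlag(rid, ViolationCategory.DUPLICATE_IP_EMAIL, detail)
        for rid, detail in sorted(flagged.items(), key=lambda kv: order[kv[0]])
    ]


def flag_fictitious_drug(records: Sequence[RespondentRecord],
                         fictitious_drug: str = DEFAULT_FICTITIOUS_DRUG
                         ) -> list[ViolationFlag]:
    """Flag endorsement of the nonexistent checklist drug."""
    return [
        ViolationFlag(r.record_id, ViolationCategory.FICTITIOUS_DRUG,
                      fictitious_drug)
        for r in records
        if any(s == fictitious_drug for s, _ in r.substance_use)
    ]


def flag_zip(records: Sequence[RespondentRecord],
             lookup: dict) -> list[ViolationFlag]:
    """Validate home and work ZIPs against the borough lookup.

    For each side (home; work only when the respondent reports working in the
    city): a present ZIP absent from the lookup is INVALID_ZIP; a present ZIP
    mapping to a different borough than reported is ZIP_BOROUGH_MISMATCH.
    Checks apply only when the reported borough is one of the five boroughs
    (an out-of-city ZIP cannot be validated), and respondents reporting
    current homelessness are exempt from home-side flags, since homelessness
    can explain a missing or invalid home ZIP.
    """
    flags = []
    for record in records:
        homeless = record.homelessness_status == CURRENTLY_HOMELESS
        sides = []
        if not homeless:
            sides.append((record.home_borough, record.home_zip, "home"))
        if record.works_in_nyc:
            sides.append((record.work_borough, record.work_zip, "work"))
        for borough, zip_code, side in sides:
            if borough not in BOROUGHS or zip_code is None:
                continue
            mapped = lookup.get(zip_code)
            if mapped is None:
                flags.append(ViolationFlag(record.record_id,
                                           ViolationCategory.INVALID_ZIP,
                                           f"{side} ZIP {zip_code}"))
            elif mapped != borough:
                flags.append(ViolationFlag(
                    record.record_id, ViolationCategory.ZIP_BOROUGH_MISMATCH,
                    f"{side} ZIP {zip_code} is in {mapped}, not {borough}"))
    return flags


def flag_improbable_use(records: Sequence[RespondentRecord],
                        impossible_pairs: Iterable = DEFAULT_IMPOSSIBLE_PAIRS
                        ) -> list[ViolationFlag]:
    """Flag impossible substance/route combinations (e.g. injecting alcohol)."""
    impossible = frozenset(impossible_pairs)
    flags = []
    for record in records:
        hit = record.substance_use & impossible
        if hit:
            detail = "; ".join(f"{s} by {r}" for s, r in sorted(hit))
            flags.append(ViolationFlag(record.record_id,
                                       ViolationCategory.IMPROBABLE_USE, detail))
    return flags


def flag_overdose_outlier(records: Sequence[RespondentRecord],
                          max_lifetime: int = 10) -> list[ViolationFlag]:
    """Flag strictly more than ``max_lifetime`` lifetime overdoses."""
    return [
        ViolationFlag(r.record_id, ViolationCategory.OVERDOSE_OUTLIER,
                      str(r.lifetime_overdoses))
        for r in records
        if r.lifetime_overdoses is not None and r.lifetime_overdoses > max_lifetime
    ]


def flag_speeders(records: Sequence[RespondentRecord],
                  min_minutes: float = 7.0) -> list[ViolationFlag]:
    """Flag completion strictly under ``min_minutes`` (7.0 exactly passes)."""
    return [
        ViolationFlag(r.record_id, ViolationCategory.SPEEDER,
                      f"{r.duration_minutes:g} min")
        for r in records
        if r.duration_minutes is not None and r.duration_minutes < min_minutes
    ]


def flag_demographic_inconsistency(
    records: Sequence[RespondentRecord],
    flagged_brackets: Iterable = DEFAULT_MEDICAID_FLAGGED_BRACKETS,
) -> list[ViolationFlag]:
    """Flag Medicaid coverage with household income above eligibility."""
    above = frozenset(flagged_brackets)
    return [
        ViolationFlag(r.record_id,
                      ViolationCategory.DEMOGRAPHIC_INCONSISTENCY,
                      f"Medicaid with income {r.income_bracket}")
        for r in records
        if r.insurance_type == "Medicaid" and r.income_bracket in above
    ]


_NORMALIZE_RE = re.compile(r"[^\w\s]")


def normalize_text(text: str) -> str:
    """Case-fold, strip punctuation, collapse whitespace."""
    return " ".join(_NORMALIZE_RE.sub(" ", text.casefold()).split())


def flag_open_text(records: Sequence[RespondentRecord],
                   phrase_blocklist: Iterable,
                   min_duplicate_length: int = 12) -> list[ViolationFlag]:
    """Flag suspicious open-ended answers.

    An answer flags if, after normalization, it (a) matches a blocklist
    phrase, or (b) is an exact duplicate of another record's answer to the
    same question and is at least ``min_duplicate_length`` characters long
    (short generic answers like "yes" are not duplication evidence).
    """
    blocked = {normalize_text(p) for p in phrase_blocklist}
    by_answer: dict[tuple, list[str]] = defaultdict(list)
    for record in records:
        for qid, answer in record.open_text.items():
            by_answer[(qid, normalize_text(answer))].append(record.record_id)

    flagged: dict[str, str] = {}
    for record in records:
        for qid, answer in record.open_text.items():
            norm = normalize_text(answer)
            if norm in blocked:
                flagged.setdefault(record.record_id,
                                   f"blocklisted phrase in {qid!r}")
            elif (len(norm) >= min_duplicate_length
                  and len(by_answer[(qid, norm)]) > 1):
                flagged.setdefault(record.record_id,
                                   f"answer to {qid!r} duplicated verbatim")
    order = {r.record_id: i for i, r in enumerate(records)}
    return [
        ViolationFlag(rid, ViolationCategory.SUSPICIOUS_OPEN_TEXT, detail)
        for rid, detail in sorted(flagged.items(), key=lambda kv: order[kv[0]])
    ]


def flag_email_pattern(records: Sequence[RespondentRecord]) -> list[ViolationFlag]:
    """Flag bulk-creator style addresses: random letters ending in >= 5 digits."""
    flags = []
    for record in records:
        if record.email is None or "@" not in record.email:
            continue
        local = record.email.split("@", 1)[0]
        if EMAIL_BOT_PATTERN.match(local):
            flags.append(ViolationFlag(record.record_id,
                                       ViolationCategory.EMAIL_PATTERN,
                                       record.email))
    return flags


def flag_honeypot(records: Sequence[RespondentRecord]) -> list[ViolationFlag]:
    """Flag answered hidden (honeypot) items — bot evidence reported
    separately from the violation tally surface."""
    return [
        ViolationFlag(r.record_id, ViolationCategory.HONEYPOT,
                      "hidden item answered")
        for r in records
        if r.honeypot_answered
    ]
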