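"""The six Research Domain Criteria (RDoC) functioning domains.

RDoC is the NIMH dimensional framework that classifies mental-health
functioning into six domains instead of DSM diagnostic categories. The label
set is closed: every dictionary entry, classification and cohort summary in
this package refers to exactly these six members.
"""

from __future__ import annotations

import enum


class RdocDomain(str, enum.Enum):
    """One of the six RDoC functioning domains."""

    NEGATIVE_VALENCE = "negative_valence"
    POSITIVE_VALENCE = "positive_valence"
    COGNITIVE = "cognitive"
    SOCIAL_PROCESSES = "social_processes"
    AROUSAL_REGULATORY = "arousal_regulatory"
    SENSORIMOTOR = "sensorimotor"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical ordering used for tables and reports.
ALL_DOMAINS: tuple[RdocDomain, ...] = tuple(RdocDomain)


def parse_domains(raw: str, sep: str = "|") -> frozenset[RdocDomain]:
    """Parse a separator-joined domain field (e.g. ``"negative_valence|cognitive"``).

    Raises ``ValueError`` naming the offending label if any token is not one of
    the six domains; empty tokens are ignored.
    """
    out = set()
    for tok in raw.split(sep):
        tok = tok.strip().lower()
        if not tok:
            continue
        try:
            out.add(RdocDomain(tok))
        except ValueError:
            raise ValueError(f"unknown RDoC domain label: {tok!r}") from None
    return frozenset(out)


def format_domains(domains: frozenset[RdocDomain] | set[RdocDomain], sep: str = "|") -> str:
    """Serialize a domain set in canonical order."""
    return sep.join(d.value for d in ALL_DOMAINS if d in domains)
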