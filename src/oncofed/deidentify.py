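"""Rule-based deidentification of bundles with pluggable pseudonym provider.

The provider contract mirrors a trusted pseudonymization service (such as
the gPAS or entici services deployed at hospital data integration centers):
deterministic per (domain, value), injective per domain with overwhelming
probability, and one-way without the secret.  The in-repo default is a keyed
one-way hash (HMAC-SHA256 truncated to 32 URL-safe characters); a networked
provider can be swapped in behind the same interface without touching the
pipeline.

Deidentification itself is driven by an ordered rule list
(resource_type, field_path, action) where action is one of
``pseudonymize(domain)``, ``remove`` or ``keep``.  After application the
bundle must not contain any pre-image identifier string — a property the
test suite asserts by scanning the whole serialized corpus.
"""

from __future__ import annotations

import base64
import hashlib
import hmac
import importlib.resources
import os
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import yaml

from .fhir_mapping import ResourceBundle

SECRET_ENV_VAR = "ONCOFED_PSEUDONYM_SECRET"

#: Field paths the rule engine knows how to act on.
KNOWN_FIELD_PATHS = frozenset(
    {
        "Patient.identifier",
        "Patient.quasi_identifier",
        "Patient.gender",
        "Condition.code",
        "Condition.onset_date",
    }
)

#: Paths that may be removed (analysis-mandatory structure cannot be).
REMOVABLE_FIELD_PATHS = frozenset({"Patient.quasi_identifier"})

ACTIONS = ("pseudonymize", "remove", "keep")


class DeidentConfigError(ValueError):
    """Invalid deidentification configuration (caught at load time)."""


@dataclass(frozen=True)
class DeidentRule:
    resource_type: str
    field_path: str
    action: str
    domain: str | None = None

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise DeidentConfigError(f"unknown action {self.action!r}")
        if self.action == "pseudonymize" and not self.domain:
            raise DeidentConfigError(
                f"pseudonymize rule for {self.field_path} must name a domain"
            )
        if self.field_path not in KNOWN_FIELD_PATHS:
            raise DeidentConfigError(f"unknown field path {self.field_path!r}")
        if self.action == "remove" and self.field_path not in REMOVABLE_FIELD_PATHS:
            raise DeidentConfigError(
                f"field {self.field_path!r} is structural and cannot be removed"
            )


@dataclass(frozen=True)
class DeidentConfig:
    rules: tuple[DeidentRule, ...]
    default_action: str = "keep"

    def __post_init__(self) -> None:
        if self.default_action not in ("remove", "keep"):
            raise DeidentConfigError(
                f"default_action must be remove or keep, got {self.default_action!r}"
            )
        seen: set[tuple[str, str]] = set()
        for rule in self.rules:
            key = (rule.resource_type, rule.field_path)
            if key in seen:
                raise DeidentConfigError(f"duplicate rule for {rule.field_path}")
            seen.add(key)

    def action_for(self, field_path: str) -> DeidentRule:
        for rule in self.rules:
            if rule.field_path == field_path:
                return rule
        return DeidentRule(
            field_path.split(".", 1)[0],
            field_path,
            self.default_action if field_path in REMOVABLE_FIELD_PATHS else "keep",
        )

    @classmethod
    def from_dict(cls, data: Mapping) -> "DeidentConfig":
        rules = tuple(
            DeidentRule(
                resource_type=r["resource_type"],
                field_path=r["field_path"],
                action=r["action"],
                domain=r.get("domain"),
            )
            for r in data.get("rules", [])
        )
        return cls(rules=rules, default_action=data.get("default_action", "keep"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DeidentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def default(cls) -> "DeidentConfig":
        text = (
            importlib.resources.files("oncofed.data")
            .joinpath("deident_default.yaml")
            .read_text()
        )
        return cls.from_dict(yaml.safe_load(text))


class PseudonymProvider(Protocol):
    """Deterministic, injective-per-domain, one-way pseudonym source."""

    domains: frozenset[str]

    def pseudonym_for(self, domain: str, value: str) -> str: ...


class HashingPseudonymProvider:
    """Keyed one-way hash provider: HMAC-SHA256, URL-safe, fixed length.

    Tokens are deterministic per (domain, value); distinct domains use
    distinct HMAC inputs, so the same value pseudonymizes differently across
    domains.  A token is re-derived (with a counter) in the astronomically
    rare case that it shares a substring of length >= 4 with the input, so
    no fragment of the original value can leak through the token.
    """

    TOKEN_LENGTH = 32

    def __init__(self, secret: str | None = None, domains: Iterable[str] = ("patient",)):
        if secret is None:
            secret = os.environ.get(SECRET_ENV_VAR)
        if not secret:
            raise DeidentConfigError(
                f"pseudonym secret missing: pass one or set {SECRET_ENV_VAR}"
            )
        self._secret = secret.encode()
        self.domains = frozenset(domains)

    def pseudonym_for(self, domain: str, value: str) -> str:
        if domain not in self.domains:
            raise DeidentConfigError(f"unregistered pseudonym domain {domain!r}")
        counter = 0
        while True:
            message = f"{domain}\x1f{value}\x1f{counter}".encode()
            digest = hmac.new(self._secret, message, hashlib.sha256).digest()
            token = (
                base64.urlsafe_b64encode(digest).decode().rstrip("=")[: self.TOKEN_LENGTH]
            )
            if token != value and not _shares_fragment(value, token, 4):
                return token
            counter += 1


def _shares_fragment(value: str, token: str, min_len: int) -> bool:
    if len(value) < min_len:
        return False
    return any(
        value[i : i + min_len] in token for i in range(len(value) - min_len + 1)
    )


def pseudonym_for(provider: PseudonymProvider, domain: str, value: str) -> str:
    return provider.pseudonym_for(domain, value)


def deidentify_bundle(
    bundle: ResourceBundle,
    config: DeidentConfig,
    provider: PseudonymProvider,
) -> ResourceBundle:
    """Apply the rule set to one bundle; the result is flagged deidentified.

    The patient identifier is replaced by its pseudonym; the bundle stays
    reference-closed because resource ids and the subject reference are
    derived from (site, report), never from the identifier itself.
    """
    patient = bundle.patient

    id_rule = config.action_for("Patient.identifier")
    if id_rule.action == "pseudonymize":
        patient = replace(
            patient,
            identifier_value=provider.pseudonym_for(
                id_rule.domain, patient.identifier_value
            ),
        )
    elif id_rule.action == "remove":  # unreachable: identifier is structural
        raise DeidentConfigError("Patient.identifier cannot be removed")

    if config.action_for("Patient.quasi_identifier").action != "keep":
        patient = replace(patient, quasi_identifier=None)
    quasi_rule = config.action_for("Patient.quasi_identifier")
    if quasi_rule.action == "pseudonymize" and bundle.patient.quasi_identifier:
        patient = replace(
            patient,
            quasi_identifier=provider.pseudonym_for(
                quasi_rule.domain, bundle.patient.quasi_identifier
            ),
        )

    return replace(bundle, patient=patient, deidentified=True)


def deidentify_bundles(
    bundles: Sequence[ResourceBundle],
    config: DeidentConfig,
    provider: PseudonymProvider,
) -> list[ResourceBundle]:
    return [deidentify_bundle(b, config, provider) for b in bundles]


def scan_corpus_for_values(texts: Iterable[str], needles: Iterable[str]) -> list[str]:
    """Return every needle that appears verbatim anywhere in the corpus.

    Used as the leakage check over serialized post-deidentification
    artifacts; an empty return means no original identifier survived.
    """
    needles = [n for n in needles if n]
    found: set[str] = set()
    for text in texts:
        for needle in needles:
            if needle in text:
                found.add(needle)
    return sorted(found)
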