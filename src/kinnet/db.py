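"""Optional online acquisition: KEGG REST pathways and BRENDA enzyme
parameters, with a mandatory offline cache mode.

Every request is keyed by the sha256 of a canonical request string;
responses are cached as raw bytes under that key, so recorded responses
(or programmatically written fixtures) serve tests without any network.
In offline mode no transport is ever invoked.  The live BRENDA client
normalizes the SOAP response into a canonical JSON byte form before
caching, so the cache format is uniform across live and fixture entries.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Optional, Sequence

from .errors import FetchError, LookupErrorKN, ValidationError
from .model import Model

KEGG_REST_URL = "https://rest.kegg.jp/get/{pathway_id}/kgml"
BRENDA_ENDPOINT = "https://www.brenda-enzymes.org/soap/brenda_server.php"

_EC_RE = re.compile(r"^\d+\.\d+\.\d+\.(\d+|n\d+|-)$")

PARAMETER_KINDS = ("Km", "kcat", "Vmax", "Ki")

Transport = Callable[[str, Optional[bytes]], bytes]


def _default_transport(url: str, payload: Optional[bytes] = None) -> bytes:
    import urllib.request

    req = urllib.request.Request(
        url,
        data=payload,
        headers={"User-Agent": "kinnet/0.1"},
    )
    with urllib.request.urlopen(req, timeout=30) as resp:  # pragma: no cover
        return resp.read()


def _cache_path(cache_dir, request_key: str) -> Path:
    digest = hashlib.sha256(request_key.encode()).hexdigest()
    return Path(cache_dir) / f"{digest[:24]}.bin"


def _cache_read(cache_dir, request_key: str) -> Optional[bytes]:
    p = _cache_path(cache_dir, request_key)
    return p.read_bytes() if p.exists() else None


def _cache_write(cache_dir, request_key: str, data: bytes) -> None:
    Path(cache_dir).mkdir(parents=True, exist_ok=True)
    _cache_path(cache_dir, request_key).write_bytes(data)


# -- KEGG ----------------------------------------------------------------------


def kegg_request_key(organism: str, pathway_id: str) -> str:
    return f"kegg:{organism}:{pathway_id}"


def fetch_kegg_pathway(
    organism: str,
    pathway_id: str,
    cache_dir,
    offline: bool = False,
    transport: Optional[Transport] = None,
) -> bytes:
    """KGML content of an organism-specific pathway, cache-first.

    In offline mode only the cache is consulted and a cold cache raises
    :class:`FetchError`; a live fetch writes the cache so repeated calls
    are byte-identical.
    """
    key = kegg_request_key(organism, pathway_id)
    cached = _cache_read(cache_dir, key)
    if cached is not None:
        return cached
    if offline:
        raise FetchError(
            f"offline mode and no cached copy of {pathway_id} in {cache_dir}"
        )
    transport = transport or _default_transport
    try:
        data = transport(KEGG_REST_URL.format(pathway_id=pathway_id), None)
    except Exception as exc:
        raise FetchError(f"cannot fetch {pathway_id}: {exc}") from exc
    if not data or b"<pathway" not in data:
        raise FetchError(f"pathway {pathway_id!r} not found or not KGML")
    _cache_write(cache_dir, key, data)
    return data


def write_kegg_fixture(cache_dir, organism: str, pathway_id: str, kgml: bytes) -> None:
    """Seed the cache with KGML content (for offline fixtures)."""
    _cache_write(cache_dir, kegg_request_key(organism, pathway_id), kgml)


# -- BRENDA --------------------------------------------------------------------


@dataclass(frozen=True)
class BrendaEntry:
    """One enzyme functional parameter record with its assay conditions."""

    ec_number: str
    organism: str
    parameter_kind: str  # Km | kcat | Vmax | Ki
    value: float
    units: str
    ph: Optional[float] = None
    temperature: Optional[float] = None  # Celsius
    pubmed_link: str = ""

    def __post_init__(self):
        if not _EC_RE.match(self.ec_number):
            raise ValidationError(f"malformed EC number {self.ec_number!r}")
        if self.parameter_kind not in PARAMETER_KINDS:
            raise ValidationError(
                f"parameter kind must be one of {PARAMETER_KINDS}, "
                f"got {self.parameter_kind!r}"
            )
        if not self.value > 0:
            raise ValidationError(f"parameter value must be > 0, got {self.value}")


def brenda_request_key(ec_number: str, parameter_kind: str) -> str:
    return f"brenda:{ec_number}:{parameter_kind}"


def query_brenda(
    ec_number: str,
    organism: Optional[str] = None,
    parameter_kind: str = "Km",
    credentials: Optional[tuple[str, str]] = None,
    cache_dir=None,
    offline: bool = False,
    transport: Optional[Transport] = None,
    sort_by: Optional[str] = None,
) -> list[BrendaEntry]:
    """All entries for an EC number and parameter kind, organism-filtered.

    The request retrieves every matching entry for the EC number; the
    organism filter is applied client-side afterwards, so narrowing the
    organism never re-queries.  Results can be sorted by ``value``,
    ``ph`` or ``temperature``.
    """
    if not _EC_RE.match(ec_number):
        raise ValidationError(f"malformed EC number {ec_number!r}")
    if parameter_kind not in PARAMETER_KINDS:
        raise ValidationError(f"unknown parameter kind {parameter_kind!r}")
    key = brenda_request_key(ec_number, parameter_kind)
    raw = _cache_read(cache_dir, key) if cache_dir is not None else None
    if raw is None:
        if offline:
            raise FetchError(
                f"offline mode and no cached {parameter_kind} entries for "
                f"{ec_number} in {cache_dir}"
            )
        if credentials is None:
            raise FetchError("live BRENDA queries require (email, password) credentials")
        raw = _soap_query(ec_number, parameter_kind, credentials, transport)
        if cache_dir is not None:
            _cache_write(cache_dir, key, raw)
    entries = [BrendaEntry(**d) for d in json.loads(raw.decode())]
    if organism is not None:
        entries = [e for e in entries if e.organism == organism]
    if sort_by is not None:
        if sort_by not in ("value", "ph", "temperature"):
            raise ValidationError(f"cannot sort by {sort_by!r}")
        entries.sort(key=lambda e: (getattr(e, sort_by) is None,
                                    getattr(e, sort_by)))
    return entries


def write_brenda_fixture(
    cache_dir, ec_number: str, parameter_kind: str, entries: Sequence[BrendaEntry]
) -> None:
    """Seed the cache with entries in the canonical JSON byte form."""
    raw = json.dumps([asdict(e) for e in entries], sort_keys=True).encode()
    _cache_write(cache_dir, brenda_request_key(ec_number, parameter_kind), raw)


_BRENDA_METHOD = {
    "Km": "getKmValue",
    "kcat": "getTurnoverNumber",
    "Vmax": "getSpecificActivity",
    "Ki": "getKiValue",
}

_BRENDA_FIELD = {
    "Km": "kmValue",
    "kcat": "turnoverNumber",
    "Vmax": "specificActivity",
    "Ki": "kiValue",
}

_BRENDA_UNITS = {"Km": "mM", "kcat": "1/s", "Vmax": "µmol/min/mg", "Ki": "mM"}


def _soap_query(
    ec_number: str,
    parameter_kind: str,
    credentials: tuple[str, str],
    transport: Optional[Transport],
) -> bytes:
    """Best-effort live SOAP query, normalized to canonical JSON bytes."""
    email, password = credentials
    password_hash = hashlib.sha256(password.encode()).hexdigest()
    method = _BRENDA_METHOD[parameter_kind]
    params = f"{email},{password_hash},ecNumber*{ec_number},organism*"
    envelope = f"""<?xml version="1.0" encoding="UTF-8"?>
<SOAP-ENV:Envelope xmlns:SOAP-ENV="http://schemas.xmlsoap.org/soap/envelope/"
                   xmlns:tns="http://soapinterop.org/">
  <SOAP-ENV:Body>
    <tns:{method}>
      <parameters xsi:type="xsd:string"
                  xmlns:xsi="http://www.w3.org/2001/XMLSchema-instance"
                  xmlns:xsd="http://www.w3.org/2001/XMLSchema">{params}</parameters>
    </tns:{method}>
  </SOAP-ENV:Body>
</SOAP-ENV:Envelope>"""
    transport = transport or _default_transport
    try:
        response = transport(BRENDA_ENDPOINT, envelope.encode())
    except Exception as exc:
        raise FetchError(f"BRENDA query failed: {exc}") from exc
    return _parse_soap_response(response, ec_number, parameter_kind)


def _parse_soap_response(response: bytes, ec_number: str, parameter_kind: str) -> bytes:
    """BRENDA's '#'-delimited record strings -> canonical JSON bytes."""
    from lxml import etree

    root = etree.fromstring(response)
    text = "".join(root.itertext())
    field = _BRENDA_FIELD[parameter_kind]
    entries = []
    for record in text.split("!"):
        fields = dict(
            kv.split("*", 1) for kv in record.split("#") if "*" in kv
        )
        if field not in fields:
            continue
        try:
            value = float(fields[field])
        except ValueError:
            continue
        if value <= 0:
            continue
        entries.append(
            {
                "ec_number": ec_number,
                "organism": fields.get("organism", ""),
                "parameter_kind": parameter_kind,
                "value": value,
                "units": _BRENDA_UNITS[parameter_kind],
                "ph": _maybe_float(fields.get("ph")),
                "temperature": _maybe_float(fields.get("temperature")),
                "pubmed_link": (
                    f"https://pubmed.ncbi.nlm.nih.gov/{fields['literature']}/"
                    if fields.get("literature")
                    else ""
                ),
            }
        )
    return json.dumps(entries, sort_keys=True).encode()


def _maybe_float(s: Optional[str]) -> Optional[float]:
    try:
        return float(s) if s not in (None, "", "-") else None
    except ValueError:
        return None


# -- parameter assignment ------------------------------------------------------

#: multiplicative factors to nM for concentration-like units
_TO_NM = {"M": 1e9, "mM": 1e6, "uM": 1e3, "µM": 1e3, "nM": 1.0, "pM": 1e-3}

#: units that need no conversion (time-based rate constants)
_UNITLESS_OK = {"1/s", "s^-1", "1/min", ""}


def convert_units(value: float, from_units: str, to_units: str) -> float:
    """Convert a concentration-like value between molar units."""
    if from_units == to_units or from_units in _UNITLESS_OK:
        return value
    if from_units in _TO_NM and to_units in _TO_NM:
        return value * _TO_NM[from_units] / _TO_NM[to_units]
    raise ValidationError(
        f"no known conversion from {from_units!r} to {to_units!r}"
    )


def assign_parameter(
    model: Model, reaction_id: str, slot: str, entry: BrendaEntry
) -> Model:
    """Set one rate-law parameter slot from a database entry.

    The value is unit-converted to the model's concentration unit where
    applicable, and the entry's provenance (EC number, organism, PubMed
    link, original value/units) is recorded on the reaction.  Exactly one
    slot changes; everything else is untouched.
    """
    r = model.reaction(reaction_id)
    if r.rate_law is None or slot not in r.rate_law.parameter_slots:
        available = list(r.rate_law.parameter_slots) if r.rate_law else []
        raise LookupErrorKN(
            f"reaction {reaction_id!r} has no parameter slot {slot!r}; "
            f"available: {available}"
        )
    value = convert_units(entry.value, entry.units, model.concentration_unit)
    r.parameter_values[slot] = value
    r.provenance[slot] = {
        "source": "BRENDA",
        "ec_number": entry.ec_number,
        "organism": entry.organism,
        "parameter_kind": entry.parameter_kind,
        "original_value": entry.value,
        "original_units": entry.units,
        "ph": entry.ph,
        "temperature": entry.temperature,
        "pubmed_link": entry.pubmed_link,
    }
    return model


def rank_entries(
    entries: Sequence[BrendaEntry],
    preferred_organisms: Sequence[str] = (),
    ph_window: Optional[tuple[float, float]] = None,
    temperature_window: Optional[tuple[float, float]] = None,
) -> list[BrendaEntry]:
    """Helper ranking of query results by user-defined filters.

    Entries from preferred organisms (in preference order) come first,
    then entries inside the pH / temperature windows.  This aids, but
    never replaces, user selection.
    """

    def score(e: BrendaEntry):
        org = (
            preferred_organisms.index(e.organism)
            if e.organism in preferred_organisms
            else len(preferred_organisms)
        )
        ph_ok = 0 if (
            ph_window is None
            or (e.ph is not None and ph_window[0] <= e.ph <= ph_window[1])
        ) else 1
        t_ok = 0 if (
            temperature_window is None
            or (
                e.temperature is not None
                and temperature_window[0] <= e.temperature <= temperature_window[1]
            )
        ) else 1
        return (org, ph_ok, t_ok, e.value)

    return sorted(entries, key=score)
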