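"""REST client for an RxNorm-style drug terminology service.

Implements the same backend contract as the fixture store over the public
REST endpoints (``ndcstatus``, ``rxcui/{rxcui}/properties``,
``rxcui/{rxcui}/related?tty=...``, ``rxcui/{rxcui}/allProperties``), with a
persistent JSON response cache and a bounded request rate. The transport is
injectable, which supports fully offline record/replay operation:
:func:`make_recorded_transport` turns any fixture snapshot into a transport
serving the service's JSON shapes, so the client can be exercised and
validated without a network.

Attribute structure is not served whole by the REST interface; the client
assembles it from the ingredient and dose-form relations, the
AVAILABLE_STRENGTH attribute (strength parts are listed in the service's
alphabetical-ingredient order), a leading ``"N ("`` pattern in pack names,
and a small lexicon of qualitative name qualifiers.
"""

from __future__ import annotations

import json
import re
import time
import urllib.error
import urllib.request
from pathlib import Path
from typing import Callable

from .errors import BackendUnavailable, ResolutionError, UnknownConcept
from .ndc import NdcCode
from .terminology import (
    CLINICAL_TTYS,
    FixtureTerminology,
    RxConcept,
    ScdAttributes,
)

__all__ = ["RxNormClient", "make_recorded_transport", "DEFAULT_BASE_URL", "QUALIFIER_LEXICON"]

DEFAULT_BASE_URL = "https://rxnav.nlm.nih.gov/REST"

#: Qualitative distinctions recognized in concept names (case-insensitive).
QUALIFIER_LEXICON = ("osmotic", "sugar-free", "24 hr", "12 hr")

#: Vocabulary sources considered curated (within the terminology's own scope).
CURATED_SOURCES = frozenset({"RXNORM"})

_PACK_RE = re.compile(r"^\s*\{?\s*(\d+)\s*\(")

Transport = Callable[[str], str]


def _urllib_transport(url: str) -> str:
    with urllib.request.urlopen(url, timeout=30) as resp:
        return resp.read().decode("utf-8")


class RxNormClient:
    """Terminology backend over HTTP with caching, retries and rate limiting."""

    def __init__(
        self,
        base_url: str = DEFAULT_BASE_URL,
        cache_path: str | Path | None = None,
        min_interval: float = 0.05,
        max_retries: int = 3,
        backoff: float = 0.5,
        transport: Transport | None = None,
        qualifier_lexicon: tuple[str, ...] = QUALIFIER_LEXICON,
    ):
        self.base_url = base_url.rstrip("/")
        self.cache_path = Path(cache_path) if cache_path else None
        self.min_interval = min_interval
        self.max_retries = max_retries
        self.backoff = backoff
        self.transport = transport or _urllib_transport
        self.qualifier_lexicon = tuple(q.casefold() for q in qualifier_lexicon)
        self._cache: dict[str, dict] = {}
        self._dirty = 0
        self._last_request = 0.0
        if self.cache_path and self.cache_path.exists():
            self._cache = json.loads(self.cache_path.read_text())

    # -- plumbing ------------------------------------------------------------

    def _get(self, endpoint: str) -> dict:
        """Fetch ``{base_url}/{endpoint}`` as JSON, via the persistent cache."""
        if endpoint in self._cache:
            return self._cache[endpoint]
        url = f"{self.base_url}/{endpoint}"
        delay = self.backoff
        last_exc: Exception | None = None
        for _ in range(self.max_retries):
            wait = self.min_interval - (time.monotonic() - self._last_request)
            if wait > 0:
                time.sleep(wait)
            try:
                self._last_request = time.monotonic()
                body = self.transport(url)
                payload = json.loads(body)
                self._cache[endpoint] = payload
                self._dirty += 1
                if self._dirty >= 100:
                    self.flush()
                return payload
            except (urllib.error.URLError, OSError, TimeoutError, json.JSONDecodeError) as exc:
                last_exc = exc
                time.sleep(delay)
                delay *= 2
        raise BackendUnavailable(f"GET {url} failed after {self.max_retries} attempts") from last_exc

    def flush(self) -> None:
        if self.cache_path and self._dirty:
            tmp = self.cache_path.with_suffix(".tmp")
            tmp.write_text(json.dumps(self._cache))
            tmp.replace(self.cache_path)
            self._dirty = 0

    def close(self) -> None:
        self.flush()

    def __enter__(self) -> "RxNormClient":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- backend contract ----------------------------------------------------

    def _curated(self, rxcui: str) -> bool:
        payload = self._get(f"rxcui/{rxcui}/allProperties.json?prop=SOURCES")
        props = (payload.get("propConceptGroup") or {}).get("propConcept") or []
        sources = {p.get("propValue", "") for p in props}
        return bool(sources & CURATED_SOURCES)

    def _concept(self, rxcui: str) -> RxConcept:
        payload = self._get(f"rxcui/{rxcui}/properties.json")
        props = payload.get("properties")
        if not props:
            raise UnknownConcept(f"rxcui {rxcui} not known to the service")
        return RxConcept(
            rxcui=str(props["rxcui"]),
            tty=props.get("tty", "OTHER"),
            name=props.get("name", ""),
            status="active",
            curated=self._curated(rxcui),
        )

    def ndc_to_concept(self, ndc: NdcCode | str) -> RxConcept | None:
        key = ndc.normalized if isinstance(ndc, NdcCode) else str(ndc)
        payload = self._get(f"ndcstatus.json?ndc={key}")
        status = payload.get("ndcStatus") or {}
        rxcui = status.get("rxcui") or ""
        if not rxcui:
            return None
        return self._concept(rxcui)

    def _related(self, rxcui: str, ttys: str) -> list[dict]:
        payload = self._get(f"rxcui/{rxcui}/related.json?tty={ttys}")
        groups = (payload.get("relatedGroup") or {}).get("conceptGroup") or []
        out: list[dict] = []
        for g in groups:
            out.extend(g.get("conceptProperties") or [])
        return out

    def resolve_to_scds(self, concept: RxConcept) -> frozenset[str]:
        # a retired concept handed in from elsewhere: follow its remap first
        while concept.status == "remapped" and concept.remapped_to:
            concept = self._concept(concept.remapped_to)
        if concept.tty in CLINICAL_TTYS:
            return frozenset({concept.rxcui})
        if not concept.curated:
            return frozenset({concept.rxcui})
        ttys = "GPCK+SCD" if concept.tty == "BPCK" else "SCD"
        related = self._related(concept.rxcui, ttys)
        out = frozenset(str(p["rxcui"]) for p in related)
        if not out:
            raise ResolutionError(
                f"{concept.tty} {concept.rxcui} has no related clinical drug concept"
            )
        return out

    def get_scd_attributes(self, scd_rxcui: str) -> ScdAttributes:
        concept = self._concept(scd_rxcui)
        if not concept.curated:
            return ScdAttributes(scd_rxcui=scd_rxcui, curated=False)
        ingredients = sorted(p["name"] for p in self._related(scd_rxcui, "IN"))
        forms = [p["name"] for p in self._related(scd_rxcui, "DF")]
        payload = self._get(f"rxcui/{scd_rxcui}/allProperties.json?prop=ATTRIBUTES")
        props = (payload.get("propConceptGroup") or {}).get("propConcept") or []
        strength_text = next(
            (p["propValue"] for p in props if p.get("propName") == "AVAILABLE_STRENGTH"), ""
        )
        strengths: dict[str, tuple[float, str]] = {}
        # multi-ingredient parts are " / "-separated; a bare "/" may belong
        # to a unit such as "mg/mL"
        parts = [p.strip() for p in strength_text.split(" / ") if p.strip()]
        for ing, part in zip(ingredients, parts):
            value, _, unit = part.partition(" ")
            strengths[ing] = (float(value), unit.strip())
        name_cf = concept.name.casefold()
        quals = frozenset(q for q in self.qualifier_lexicon if q in name_cf)
        pack_match = _PACK_RE.match(concept.name)
        return ScdAttributes(
            scd_rxcui=scd_rxcui,
            ingredients=frozenset(ingredients),
            strengths=strengths,
            dose_form=forms[0] if forms else "",
            pack_quantity=int(pack_match.group(1)) if pack_match else None,
            qualifiers=quals,
        )


# --- record/replay ---------------------------------------------------------


def _fmt_num(value: float) -> str:
    return f"{value:g}"


def make_recorded_transport(
    snapshot: FixtureTerminology, base_url: str = DEFAULT_BASE_URL
) -> Transport:
    """Build a transport serving the REST JSON shapes from a fixture snapshot.

    The returned callable answers exactly the endpoints :class:`RxNormClient`
    issues, computed from the snapshot's tables; unknown URLs raise
    ``urllib.error.URLError`` like a dead endpoint would. Useful both for
    offline tests of the client and for replaying a captured snapshot.
    """
    base = base_url.rstrip("/") + "/"

    def respond(url: str) -> str:
        if not url.startswith(base):
            raise urllib.error.URLError(f"unexpected URL {url}")
        endpoint = url[len(base) :]

        if endpoint.startswith("ndcstatus.json?ndc="):
            ndc = endpoint.split("=", 1)[1]
            concept = snapshot.ndc_to_concept(ndc)
            mapping = {m.ndc: m for m in snapshot.ndc_mappings()}.get(ndc)
            status = (mapping.ndc_status if mapping else "unknown").capitalize()
            body = {"ndcStatus": {"ndc11": ndc, "status": status}}
            if concept is not None:
                body["ndcStatus"]["rxcui"] = concept.rxcui
            return json.dumps(body)

        m = re.match(r"rxcui/([^/]+)/properties\.json$", endpoint)
        if m:
            try:
                c = snapshot.concept(m.group(1))
            except UnknownConcept:
                return json.dumps({})
            return json.dumps(
                {"properties": {"rxcui": c.rxcui, "name": c.name, "tty": c.tty}}
            )

        m = re.match(r"rxcui/([^/]+)/allProperties\.json\?prop=(\w+)$", endpoint)
        if m:
            rxcui, prop = m.groups()
            try:
                c = snapshot.concept(rxcui)
            except UnknownConcept:
                return json.dumps({})
            props: list[dict] = []
            if prop == "SOURCES":
                source = "RXNORM" if c.curated else "EXTVOCAB"
                props.append({"propName": "SOURCE", "propValue": source})
            elif prop == "ATTRIBUTES" and snapshot.has_attributes(rxcui):
                attrs = snapshot.get_scd_attributes(rxcui)
                text = " / ".join(
                    f"{_fmt_num(attrs.strengths[ing][0])} {attrs.strengths[ing][1]}"
                    for ing in sorted(attrs.ingredients)
                )
                if text:
                    props.append({"propName": "AVAILABLE_STRENGTH", "propValue": text})
            return json.dumps({"propConceptGroup": {"propConcept": props}})

        m = re.match(r"rxcui/([^/]+)/related\.json\?tty=([\w+]+)$", endpoint)
        if m:
            rxcui, ttys_text = m.groups()
            ttys = set(ttys_text.split("+"))
            try:
                snapshot.concept(rxcui)
            except UnknownConcept:
                return json.dumps({})
            groups: dict[str, list[dict]] = {}
            if ttys & {"IN", "DF"}:
                if snapshot.has_attributes(rxcui):
                    attrs = snapshot.get_scd_attributes(rxcui)
                    if "IN" in ttys:
                        groups["IN"] = [
                            {"rxcui": f"IN{i}", "name": ing, "tty": "IN"}
                            for i, ing in enumerate(sorted(attrs.ingredients))
                        ]
                    if "DF" in ttys and attrs.dose_form:
                        groups["DF"] = [
                            {"rxcui": "DF0", "name": attrs.dose_form, "tty": "DF"}
                        ]
            else:
                for rel, _relation in snapshot.related_of(rxcui):
                    try:
                        rc = snapshot.concept(rel)
                    except UnknownConcept:
                        continue
                    if rc.tty in ttys:
                        groups.setdefault(rc.tty, []).append(
                            {"rxcui": rc.rxcui, "name": rc.name, "tty": rc.tty}
                        )
            return json.dumps(
                {
                    "relatedGroup": {
                        "conceptGroup": [
                            {"tty": tty, "conceptProperties": lst}
                            for tty, lst in groups.items()
                        ]
                    }
                }
            )

        raise urllib.error.URLError(f"unhandled endpoint {endpoint}")

    return respond
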