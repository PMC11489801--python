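"""Offline confidence-rated geocoding against a local gazetteer.

Given a US-style street address, the geocoder finds the best-matching
gazetteer record and returns its coordinates plus an integer rating from 0
(very high confidence — the normalized query exactly equals the record) to
100 (very low confidence).  Everything runs locally: the gazetteer is a
plain table, no address ever leaves the process.

The match score is a weighted component agreement over the parsed address:

====================  =======  =========================
component             weight   comparison
====================  =======  =========================
house number          0.30     exact
street name           0.40     Jaro-Winkler similarity
street type           0.10     exact (after expansion)
city                  0.10     exact
state                 0.05     exact
ZIP                   0.05     exact
====================  =======  =========================

``rating = round(100 * (1 - score))``; scores below the 0.5 floor return no
match.  A component absent from both query and record counts as agreement;
absent from only one side counts as disagreement.  This formula is this
package's own auditable contract for the 0-100 scale, not a claim of
equivalence with any particular street-database geocoder.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .geometry import GeoPoint

# postal abbreviation -> expanded street type / word
ABBREVIATIONS = {
    "st": "street",
    "ave": "avenue",
    "av": "avenue",
    "blvd": "boulevard",
    "rd": "road",
    "dr": "drive",
    "ln": "lane",
    "ct": "court",
    "pl": "place",
    "pkwy": "parkway",
    "hwy": "highway",
    "sq": "square",
    "ter": "terrace",
    "cir": "circle",
    "trl": "trail",
    "wy": "way",
}

STREET_TYPES = frozenset(ABBREVIATIONS.values()) | {"way", "alley", "plaza", "loop", "row"}

# leading/trailing country designations are dropped during normalization
_COUNTRY_SUFFIXES = (("united", "states", "of", "america"), ("united", "states"), ("usa",), ("u", "s", "a"))

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def normalize_address(raw: str) -> list[str]:
    """Deterministic lowercase tokenization with abbreviation expansion.

    Punctuation is stripped, postal abbreviations are expanded (``ave`` ->
    ``avenue``), and a trailing country designation is dropped.  Idempotent:
    expanded words are never abbreviations themselves.
    """
    if raw is None or not str(raw).strip():
        raise ValidationError("address is empty")
    tokens = _TOKEN_RE.findall(str(raw).lower())
    tokens = [ABBREVIATIONS.get(t, t) for t in tokens]
    for suffix in _COUNTRY_SUFFIXES:
        if len(tokens) > len(suffix) and tuple(tokens[-len(suffix):]) == suffix:
            tokens = tokens[: -len(suffix)]
            break
    if not tokens:
        raise ValidationError(f"address {raw!r} contains no usable tokens")
    return tokens


@dataclass(frozen=True)
class AddressComponents:
    house_number: str = ""
    street_name: str = ""
    street_type: str = ""
    city: str = ""
    state: str = ""
    zip: str = ""

    @property
    def tokens(self) -> list[str]:
        out = []
        for part in (self.house_number, self.street_name, self.street_type, self.city, self.state, self.zip):
            out.extend(part.split())
        return out


def parse_address(raw: str) -> AddressComponents:
    """Split a free-text US address into matchable components.

    Uses comma structure when present (street part, city, state+ZIP);
    otherwise falls back to positional heuristics on the token list.
    """
    groups = [normalize_address(g) for g in str(raw).split(",") if _TOKEN_RE.search(g.lower())]
    # drop groups that are only a country designation ("..., United States")
    groups = [g for g in groups if g and tuple(g) not in _COUNTRY_SUFFIXES]
    if not groups:
        raise ValidationError(f"address {raw!r} contains no usable tokens")

    if len(groups) >= 2:
        street_tokens = groups[0]
        tail = [t for g in groups[1:] for t in g]
    else:
        street_tokens, tail = groups[0], []

    house = ""
    if street_tokens and street_tokens[0].isdigit():
        house, street_tokens = street_tokens[0], street_tokens[1:]
    stype = ""
    if street_tokens and street_tokens[-1] in STREET_TYPES:
        stype, street_tokens = street_tokens[-1], street_tokens[:-1]

    if not tail and street_tokens:
        # single-group fallback: peel ZIP / state / city from the end
        tail, street_tokens2 = [], list(street_tokens)
        if street_tokens2 and re.fullmatch(r"\d{5}", street_tokens2[-1]):
            tail.insert(0, street_tokens2.pop())
        if street_tokens2 and re.fullmatch(r"[a-z]{2}", street_tokens2[-1]) and street_tokens2[-1] not in ("ne", "nw", "se", "sw"):
            tail.insert(0, street_tokens2.pop())
        if not stype:
            for i in range(len(street_tokens2) - 1, -1, -1):
                if street_tokens2[i] in STREET_TYPES:
                    stype = street_tokens2[i]
                    tail = street_tokens2[i + 1:] + tail
                    street_tokens2 = street_tokens2[:i]
                    break
        street_tokens = street_tokens2

    zip_code, state, city_tokens = "", "", []
    for t in tail:
        if not zip_code and re.fullmatch(r"\d{5}", t):
            zip_code = t
        elif not state and re.fullmatch(r"[a-z]{2}", t) and t not in ("ne", "nw", "se", "sw"):
            state = t
        else:
            city_tokens.append(t)

    return AddressComponents(
        house_number=house,
        street_name=" ".join(street_tokens),
        street_type=stype,
        city=" ".join(city_tokens),
        state=state,
        zip=zip_code,
    )


@dataclass(frozen=True)
class GazetteerRecord:
    """One normalized street-address record with its coordinates."""

    house_number: str
    street: str
    street_type: str
    city: str
    state: str
    zip: str
    point: GeoPoint

    def __post_init__(self):
        for f in ("house_number", "street", "street_type", "city", "state", "zip"):
            v = str(getattr(self, f)).strip().lower()
            toks = [ABBREVIATIONS.get(t, t) for t in _TOKEN_RE.findall(v)]
            object.__setattr__(self, f, " ".join(toks))

    @property
    def components(self) -> AddressComponents:
        return AddressComponents(self.house_number, self.street, self.street_type, self.city, self.state, self.zip)

    @property
    def tokens(self) -> list[str]:
        return self.components.tokens

    @property
    def address(self) -> str:
        return " ".join(self.tokens)


def jaro_winkler(a: str, b: str, prefix_scale: float = 0.1) -> float:
    """Jaro-Winkler string similarity in [0, 1]."""
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    la, lb = len(a), len(b)
    window = max(la, lb) // 2 - 1
    match_a = [False] * la
    match_b = [False] * lb
    matches = 0
    for i, ca in enumerate(a):
        lo, hi = max(0, i - window), min(lb, i + window + 1)
        for j in range(lo, hi):
            if not match_b[j] and b[j] == ca:
                match_a[i] = match_b[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    sa = [ca for ca, m in zip(a, match_a) if m]
    sb = [cb for cb, m in zip(b, match_b) if m]
    transpositions = sum(x != y for x, y in zip(sa, sb)) // 2
    jaro = (matches / la + matches / lb + (matches - transpositions) / matches) / 3.0
    prefix = 0
    for ca, cb in zip(a[:4], b[:4]):
        if ca != cb:
            break
        prefix += 1
    return jaro + prefix * prefix_scale * (1.0 - jaro)


_WEIGHTS = (
    ("house_number", 0.30, "exact"),
    ("street_name", 0.40, "jw"),
    ("street_type", 0.10, "exact"),
    ("city", 0.10, "exact"),
    ("state", 0.05, "exact"),
    ("zip", 0.05, "exact"),
)

MATCH_FLOOR = 0.5


def similarity(query: AddressComponents, record: GazetteerRecord) -> float:
    """Weighted component agreement between a parsed query and a record."""
    rec = record.components
    rec_map = {
        "house_number": rec.house_number,
        "street_name": rec.street_name,
        "street_type": rec.street_type,
        "city": rec.city,
        "state": rec.state,
        "zip": rec.zip,
    }
    q_map = {
        "house_number": query.house_number,
        "street_name": query.street_name,
        "street_type": query.street_type,
        "city": query.city,
        "state": query.state,
        "zip": query.zip,
    }
    score = 0.0
    for name, weight, mode in _WEIGHTS:
        q, r = q_map[name], rec_map[name]
        if not q and not r:
            score += weight
        elif not q or not r:
            pass
        elif mode == "exact":
            score += weight if q == r else 0.0
        else:
            score += weight * jaro_winkler(q, r)
    return score


@dataclass(frozen=True)
class GeocodeResult:
    query: str
    point: GeoPoint | None
    rating: int | None
    matched_record: GazetteerRecord | None

    @property
    def matched(self) -> bool:
        return self.point is not None


def geocode(raw: str, gazetteer: list[GazetteerRecord]) -> GeocodeResult:
    """Resolve one address against the gazetteer.

    Best score wins; ties break lexicographically by the record's
    normalized address so results are deterministic.  No record at or above
    the 0.5 floor, or an empty gazetteer, yields a no-match result.
    """
    query = parse_address(raw)
    best: tuple[float, str] | None = None
    best_rec: GazetteerRecord | None = None
    for rec in gazetteer:
        s = similarity(query, rec)
        key = (-s, rec.address)
        if best is None or key < best:
            best, best_rec = key, rec
    if best_rec is None or -best[0] < MATCH_FLOOR:
        return GeocodeResult(query=raw, point=None, rating=None, matched_record=None)
    score = -best[0]
    rating = int(round(100.0 * (1.0 - score)))
    if rating == 0 and normalize_address(raw) != best_rec.tokens:
        rating = 1  # reserve 0 strictly for exact normalized matches
    rating = max(0, min(100, rating))
    return GeocodeResult(query=raw, point=best_rec.point, rating=rating, matched_record=best_rec)


def geocode_table(addresses: pd.DataFrame, gazetteer: list[GazetteerRecord]) -> pd.DataFrame:
    """Batch geocode a table with ``location_id`` and ``address`` columns."""
    rows = []
    for rec in addresses.itertuples(index=False):
        res = geocode(rec.address, gazetteer)
        rows.append(
            {
                "location_id": rec.location_id,
                "address": rec.address,
                "lat": res.point.lat if res.matched else float("nan"),
                "lon": res.point.lon if res.matched else float("nan"),
                "rating": res.rating if res.matched else pd.NA,
                "matched_address": res.matched_record.address if res.matched else "",
            }
        )
    out = pd.DataFrame(rows, columns=["location_id", "address", "lat", "lon", "rating", "matched_address"])
    out["rating"] = out["rating"].astype("Int64")
    return out


REPORT_COLUMNS = ["query", "matched_address", "lat", "lon", "rating", "flagged"]


def export_verification_report(results: list[GeocodeResult], rating_threshold: int = 10) -> pd.DataFrame:
    """Reviewable verification table, worst matches first.

    ``flagged`` is True when the rating exceeds the threshold or the address
    failed to match at all; the analyst edits flagged addresses and
    re-geocodes.  Sorted so unmatched rows come first, then by descending
    rating.
    """
    rows = []
    for res in results:
        rows.append(
            {
                "query": res.query,
                "matched_address": res.matched_record.address if res.matched else "",
                "lat": res.point.lat if res.matched else float("nan"),
                "lon": res.point.lon if res.matched else float("nan"),
                "rating": res.rating if res.matched else pd.NA,
                "flagged": (not res.matched) or res.rating > rating_threshold,
            }
        )
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if len(report):
        report["rating"] = report["rating"].astype("Int64")
        report = report.sort_values(
            ["rating", "query"], ascending=[False, True], na_position="first", kind="stable"
        ).reset_index(drop=True)
    return report
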