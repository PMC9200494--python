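"""Canonical acupoint ontology and name standardization.

The registry holds the 141 acupoints that occur in the published ALS
acupuncture prescription corpus: WHO alphanumeric code, pinyin name,
meridian, body region, and the corpus-wide occurrence count. A separate
synonym table resolves spelling variants and a handful of documented
misprints in the source literature to canonical codes.

Canonical code format: uppercase, no internal whitespace, hyphen retained
for extra points (``LI4``, ``EX-B2``, ``EX-HN12``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Mapping

import pandas as pd

__all__ = [
    "AcupointRecord",
    "MeridianInfo",
    "Registry",
    "RegistryError",
    "StandardizationError",
    "load_registry",
    "MERIDIANS",
    "REGIONS",
    "YANG_MERIDIANS",
    "YIN_MERIDIANS",
]

YANG_MERIDIANS = frozenset({"LI", "ST", "BL", "GB", "SJ", "SI"})
YIN_MERIDIANS = frozenset({"LU", "SP", "HT", "KI", "PC", "LR"})
VESSEL_MERIDIANS = frozenset({"DU", "RN"})

#: Body-region slugs, ordered as conventionally reported.
REGIONS = (
    "lower-limbs",
    "upper-limbs",
    "back-lumbar",
    "head-face-neck",
    "chest-abdomen",
)

_MERIDIAN_NAMES = {
    "LI": "Large Intestine Meridian of Hand Yangming",
    "ST": "Stomach Meridian of Foot Yangming",
    "BL": "Bladder Meridian of Foot Taiyang",
    "GB": "Gallbladder Meridian of Foot Shaoyang",
    "SJ": "Sanjiao Meridian of Hand Shaoyang",
    "SI": "Small Intestine Meridian of Hand Taiyang",
    "LU": "Lung Meridian of Hand Taiyin",
    "SP": "Spleen Meridian of Foot Taiyin",
    "HT": "Heart Meridian of Hand Shaoyin",
    "KI": "Kidney Meridian of Foot Shaoyin",
    "PC": "Pericardium Meridian of Hand Jueyin",
    "LR": "Liver Meridian of Foot Jueyin",
    "DU": "Governor Vessel",
    "RN": "Conception Vessel",
    "EX": "Extra points",
}


class RegistryError(Exception):
    """Raised when the packaged fixture is missing or inconsistent."""


class StandardizationError(KeyError):
    """Raised when a raw acupoint name cannot be resolved to a code."""

    def __init__(self, raw: str):
        super().__init__(raw)
        self.raw = raw

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"cannot standardize acupoint name: {self.raw!r}"


@dataclass(frozen=True)
class AcupointRecord:
    """One WHO-coded acupoint with its corpus frequency."""

    code: str
    pinyin: str
    meridian: str
    region: str
    corpus_frequency: int

    def __post_init__(self) -> None:
        if self.corpus_frequency < 0:
            raise ValueError("corpus_frequency must be nonnegative")
        if (self.meridian == "EX") != self.code.startswith("EX"):
            raise ValueError(
                f"meridian EX iff code starts with EX: {self.code}/{self.meridian}"
            )


@dataclass(frozen=True)
class MeridianInfo:
    code: str
    full_name: str
    polarity: str  # yang | yin | vessel | extra


def _polarity(meridian: str) -> str:
    if meridian in YANG_MERIDIANS:
        return "yang"
    if meridian in YIN_MERIDIANS:
        return "yin"
    if meridian in VESSEL_MERIDIANS:
        return "vessel"
    return "extra"


MERIDIANS: Mapping[str, MeridianInfo] = {
    code: MeridianInfo(code, name, _polarity(code))
    for code, name in _MERIDIAN_NAMES.items()
}

# Codes look like a meridian prefix plus a number, with an optional EX body
# segment: LI4, ST36, EX-B2, EX-HN12. Raw sources write "LI 4", "EX-B 2",
# "EX-HN 20" etc.; normalization collapses the internal whitespace.
_CODE_RE = re.compile(r"^(EX-[A-Z]+|[A-Z]{2})\s*-?\s*(\d+)$")
_PAREN_RE = re.compile(r"^(.*?)\s*\(\s*([^()]*)\s*\)$")


class Registry:
    """Lookup table over :class:`AcupointRecord` plus name standardization."""

    def __init__(self, records: list[AcupointRecord], synonyms: Mapping[str, str]):
        self._records: dict[str, AcupointRecord] = {}
        for rec in records:
            if rec.code in self._records:
                raise RegistryError(f"duplicate code in fixture: {rec.code}")
            self._records[rec.code] = rec
        # Bare pinyin names resolve only when unambiguous (e.g. "Futu" is
        # both ST32 and LI18 and must carry its code).
        by_name: dict[str, set[str]] = {}
        for rec in records:
            by_name.setdefault(rec.pinyin.lower(), set()).add(rec.code)
        self._pinyin = {k: next(iter(v)) for k, v in by_name.items() if len(v) == 1}
        self._ambiguous = {k for k, v in by_name.items() if len(v) > 1}
        self._synonyms = {self._normalize_text(k): v for k, v in synonyms.items()}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[AcupointRecord]:
        return iter(self._records.values())

    def __contains__(self, code: str) -> bool:
        return code in self._records

    def lookup(self, code: str) -> AcupointRecord:
        try:
            return self._records[code]
        except KeyError:
            raise StandardizationError(code) from None

    @property
    def codes(self) -> list[str]:
        return sorted(self._records)

    def frequencies(self) -> dict[str, int]:
        """Corpus occurrence counts keyed by code."""
        return {rec.code: rec.corpus_frequency for rec in self}

    def meridian_of(self, code: str) -> str:
        return self.lookup(code).meridian

    def region_of(self, code: str) -> str:
        return self.lookup(code).region

    # -- standardization ----------------------------------------------------
    @staticmethod
    def _normalize_text(raw: str) -> str:
        return " ".join(raw.split()).lower()

    def _try_code(self, token: str) -> str | None:
        m = _CODE_RE.match(token.strip().upper())
        if not m:
            return None
        prefix, number = m.groups()
        code = f"{prefix}{int(number)}"
        return code if code in self._records else None

    def _try_name(self, token: str) -> str | None:
        return self._pinyin.get(self._normalize_text(token))

    def standardize_code(self, raw: str) -> str:
        """Resolve a free-text acupoint name or code to its canonical code.

        Resolution order: explicit synonym table (misprint fixes), code
        normalization ("LI 4" -> "LI4"), then "Name (CODE)" composites where
        either part may resolve, then a unique pinyin name. Unknown or
        ambiguous names raise :class:`StandardizationError` rather than
        guessing.
        """
        if not isinstance(raw, str) or not raw.strip():
            raise StandardizationError(raw)
        key = self._normalize_text(raw)
        if key in self._synonyms:
            return self._synonyms[key]
        code = self._try_code(raw)
        if code:
            return code
        m = _PAREN_RE.match(raw.strip())
        if m:
            name_part, code_part = m.groups()
            code = self._try_code(code_part)
            if code:
                return code
            code = self._try_name(name_part)
            if code:
                return code
        code = self._try_name(raw)
        if code:
            return code
        raise StandardizationError(raw)


def _read_packaged_tsv(name: str) -> pd.DataFrame:
    ref = resources.files("acumine.data").joinpath(name)
    try:
        with resources.as_file(ref) as path:
            return pd.read_csv(path, sep="\t", dtype=str)
    except FileNotFoundError as exc:
        raise RegistryError(f"packaged fixture missing: {name}") from exc


def load_registry() -> Registry:
    """Load the packaged 141-acupoint fixture and synonym table."""
    df = _read_packaged_tsv("acupoints.tsv")
    expected = {"code", "pinyin", "meridian", "region", "frequency"}
    if set(df.columns) != expected:
        raise RegistryError("acupoints.tsv: unexpected columns")
    records = [
        AcupointRecord(
            code=row.code,
            pinyin=row.pinyin,
            meridian=row.meridian,
            region=row.region,
            corpus_frequency=int(row.frequency),
        )
        for row in df.itertuples()
    ]
    syn = _read_packaged_tsv("synonyms.tsv")
    registry = Registry(records, dict(zip(syn["raw"], syn["code"])))
    for rec in registry:
        if rec.region not in REGIONS:
            raise RegistryError(f"unknown region {rec.region!r} for {rec.code}")
        if rec.meridian not in MERIDIANS:
            raise RegistryError(f"unknown meridian {rec.meridian!r} for {rec.code}")
    return registry


def claimed_meridian_totals() -> pd.DataFrame:
    """Meridian row totals as printed in the source frequency table.

    Kept separate from the per-acupoint fixture because two printed rows do
    not reconcile with their own per-acupoint listings; the per-acupoint
    region table is the canonical source and these totals are reference
    values only.
    """
    df = _read_packaged_tsv("claimed_meridian_totals.tsv")
    return df.astype(
        {"claimed_frequency": int, "claimed_acupoint_number": int}
    ).set_index("meridian")
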