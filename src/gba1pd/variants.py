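"""GBA1 variant parsing, nomenclature and severity classification.

Variants are named on the primary translation product of transcript
NM_001005742, which includes the 39-residue signal peptide; the legacy
Gaucher-disease literature numbers the mature protein instead (p.L483P is
legacy L444P).  Severity follows the Parkinson's-disease field convention
(Hoglinger-based): SEVERE > MILD > RISK > VUS > BENIGN, with synonymous
variants outside splice regions left unclassified.

Recombinant alleles arising from GBA1/GBAP1 gene conversion (most commonly
RecNciI = p.L483P + p.A495P + p.V499V on one haplotype) are detected from
phased co-occurrence and carry their own severity.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

__all__ = [
    "Severity",
    "ClassSource",
    "VariantClass",
    "Consequence",
    "Zygosity",
    "GbaVariant",
    "ComplexAllele",
    "KnownVariantCatalog",
    "HgvsParseError",
    "ParsedSite",
    "parse_hgvs_p",
    "to_mature_numbering",
    "classify_variant",
    "detect_complex_alleles",
    "carrier_class",
    "collapse_carrier_events",
    "load_catalog",
]

SIGNAL_PEPTIDE_LENGTH = 39


class Severity(IntEnum):
    """Severity classes, totally ordered SEVERE > MILD > RISK > VUS > BENIGN."""

    SEVERE = 5
    MILD = 4
    RISK = 3
    VUS = 2
    BENIGN = 1
    SYNONYMOUS_UNCLASSIFIED = 0


class ClassSource(Enum):
    HOGLINGER = "hoglinger"
    CLINVAR_FALLBACK = "clinvar_fallback"
    PROPOSED = "proposed"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class VariantClass:
    severity: Severity
    source: ClassSource = ClassSource.UNKNOWN


class Consequence(Enum):
    MISSENSE = "missense"
    STOP_GAIN = "stop_gain"
    SYNONYMOUS = "synonymous"
    SPLICE_REGION = "splice_region"
    INTRONIC = "intronic"
    UTR = "utr"


class Zygosity(Enum):
    HET = "het"
    HOM = "hom"


class HgvsParseError(ValueError):
    """Raised for protein HGVS strings this module cannot interpret."""


@dataclass(frozen=True)
class ParsedSite:
    """A protein substitution site: reference residue, position, alternate.

    ``alt`` is ``"*"`` for a stop gain and equals ``ref`` for a synonymous
    change.  Position is on the full translation product (signal peptide
    included).
    """

    ref: str
    position: int
    alt: str

    @property
    def is_stop_gain(self) -> bool:
        return self.alt == "*"

    @property
    def is_synonymous(self) -> bool:
        return self.alt == self.ref


@dataclass
class GbaVariant:
    """One GBA1 variant observed in one individual."""

    hgvs_p: Optional[str] = None
    hgvs_c: Optional[str] = None
    rsid: Optional[str] = None
    consequence: Optional[Consequence] = None
    zygosity: Zygosity = Zygosity.HET
    phase_group: Optional[str] = None
    maf_nfe: Optional[float] = None
    qual: Optional[float] = None

    def __post_init__(self) -> None:
        if self.hgvs_p is None and self.hgvs_c is None:
            raise ValueError("variant needs hgvs_p or hgvs_c")
        if self.maf_nfe is not None and not 0.0 <= self.maf_nfe <= 1.0:
            raise ValueError(f"maf_nfe outside [0,1]: {self.maf_nfe}")
        if self.hgvs_p is not None:
            site = parse_hgvs_p(self.hgvs_p)
            if self.consequence is None:
                if site.is_stop_gain:
                    self.consequence = Consequence.STOP_GAIN
                elif site.is_synonymous:
                    self.consequence = Consequence.SYNONYMOUS
                else:
                    self.consequence = Consequence.MISSENSE
            elif self.consequence is Consequence.SYNONYMOUS and not site.is_synonymous:
                raise ValueError(f"{self.hgvs_p} is not synonymous")

    @property
    def key(self) -> str:
        """Catalog lookup key: protein name when present, else nucleotide."""
        return self.hgvs_p if self.hgvs_p is not None else self.hgvs_c  # type: ignore[return-value]

    @property
    def site(self) -> Optional[ParsedSite]:
        return parse_hgvs_p(self.hgvs_p) if self.hgvs_p else None


@dataclass(frozen=True)
class ComplexAllele:
    """A recombinant allele: several variants on one haplotype, one class."""

    name: str
    components: frozenset[str]
    severity: VariantClass

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("complex allele with no components")


_AA3TO1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}

_ONE_LETTER = re.compile(r"^p\.(?:\()?([A-Z])(\d+)([A-Z]|\*|X)(?:\))?$")
_THREE_LETTER = re.compile(r"^p\.(?:\()?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|\*)(?:\))?$")


def parse_hgvs_p(text: str) -> ParsedSite:
    """Parse a protein-level substitution like ``p.L483P`` or ``p.Arg398Ter``.

    Accepts one-letter and three-letter residue codes, ``*``/``X``/``Ter``
    stop gains, and synonymous changes (``p.T408T``).  Anything else raises
    :class:`HgvsParseError` naming the offending token.
    """
    if not isinstance(text, str) or not text.startswith("p."):
        raise HgvsParseError(f"not a protein HGVS string: {text!r}")
    m = _ONE_LETTER.match(text)
    if m:
        ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if alt == "X":
            alt = "*"
        return _checked_site(ref, pos, alt, text)
    m = _THREE_LETTER.match(text)
    if m:
        try:
            ref = _AA3TO1[m.group(1)]
            alt = "*" if m.group(3) == "*" else _AA3TO1[m.group(3)]
        except KeyError as exc:
            raise HgvsParseError(f"unknown residue code {exc.args[0]!r} in {text!r}") from None
        return _checked_site(ref, int(m.group(2)), alt, text)
    raise HgvsParseError(f"malformed protein HGVS: {text!r}")


def _checked_site(ref: str, pos: int, alt: str, text: str) -> ParsedSite:
    if pos < 1:
        raise HgvsParseError(f"position must be >= 1 in {text!r}")
    if ref == "*":
        raise HgvsParseError(f"reference residue cannot be a stop in {text!r}")
    return ParsedSite(ref=ref, position=pos, alt=alt)


def to_mature_numbering(position_full: int) -> Optional[int]:
    """Map a full-translation position to mature-protein numbering.

    Returns ``position_full - 39`` for positions past the signal peptide and
    ``None`` (unmapped) for positions inside it.  This is the offset between
    NM_001005742 numbering and the legacy Gaucher literature (483 -> 444).
    """
    if position_full < 1:
        raise ValueError(f"position must be >= 1, got {position_full}")
    if position_full <= SIGNAL_PEPTIDE_LENGTH:
        return None
    return position_full - SIGNAL_PEPTIDE_LENGTH


@dataclass
class KnownVariantCatalog:
    """Lookup table of variants with literature severity classes."""

    entries: Mapping[str, VariantClass]
    complex_alleles: Sequence[ComplexAllele] = field(default_factory=tuple)

    def get(self, key: str) -> Optional[VariantClass]:
        return self.entries.get(key)

    def complex_allele(self, name: str) -> Optional[ComplexAllele]:
        for allele in self.complex_alleles:
            if allele.name == name:
                return allele
        return None

    def pathogenic_sites(self) -> dict[str, VariantClass]:
        """Protein variants classed severe or mild (used as structural anchors)."""
        return {
            k: v
            for k, v in self.entries.items()
            if k.startswith("p.") and v.severity in (Severity.SEVERE, Severity.MILD)
        }


_DATA_PACKAGE = "gba1pd"


def load_catalog(
    table_path: Optional[Path] = None, complex_path: Optional[Path] = None
) -> KnownVariantCatalog:
    """Load the packaged (or a user-supplied) known-variant catalog.

    The TSV needs columns hgvs_p, hgvs_c, rsid, class, source; rows with an
    unrecognized class are rejected at load time rather than skipped.
    """
    if table_path is None:
        with resources.files(_DATA_PACKAGE).joinpath("data/known_variants.tsv").open() as fh:
            table = pd.read_csv(fh, sep="\t", dtype=str).fillna("")
    else:
        table = pd.read_csv(table_path, sep="\t", dtype=str).fillna("")
    required = {"hgvs_p", "hgvs_c", "rsid", "class", "source"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"catalog table missing columns: {sorted(missing)}")
    entries: dict[str, VariantClass] = {}
    for _, row in table.iterrows():
        try:
            severity = Severity[row["class"].upper()]
        except KeyError:
            raise ValueError(f"unknown severity class {row['class']!r} in catalog") from None
        try:
            source = ClassSource[(row["source"] or "HOGLINGER").upper()]
        except KeyError:
            raise ValueError(f"unknown class source {row['source']!r} in catalog") from None
        key = row["hgvs_p"] or row["hgvs_c"]
        if not key:
            raise ValueError("catalog row without hgvs_p or hgvs_c")
        entries[key] = VariantClass(severity=severity, source=source)

    if complex_path is None:
        with resources.files(_DATA_PACKAGE).joinpath("data/complex_alleles.yaml").open() as fh:
            spec = yaml.safe_load(fh)
    else:
        spec = yaml.safe_load(Path(complex_path).read_text())
    alleles = tuple(
        ComplexAllele(
            name=item["name"],
            components=frozenset(item["components"]),
            severity=VariantClass(
                Severity[item["severity"].upper()], ClassSource.HOGLINGER
            ),
        )
        for item in spec["complex_alleles"]
    )
    return KnownVariantCatalog(entries=entries, complex_alleles=alleles)


def classify_variant(
    variant: GbaVariant,
    catalog: KnownVariantCatalog,
    clinvar_label: Optional[str] = None,
) -> VariantClass:
    """Classify one variant: catalog first, then the ClinVar fallback.

    A catalog hit always wins.  Otherwise an exonic or splice-region variant
    annotated pathogenic in ClinVar is SEVERE; a synonymous variant outside a
    splice region stays unclassified; everything else is a VUS.
    """
    hit = catalog.get(variant.key)
    if hit is not None:
        return hit
    cons = variant.consequence
    if cons is Consequence.SYNONYMOUS:
        return VariantClass(Severity.SYNONYMOUS_UNCLASSIFIED, ClassSource.UNKNOWN)
    exonic_or_splice = cons in (
        Consequence.MISSENSE,
        Consequence.STOP_GAIN,
        Consequence.SPLICE_REGION,
        None,
    )
    if exonic_or_splice and clinvar_label and _is_pathogenic_label(clinvar_label):
        return VariantClass(Severity.SEVERE, ClassSource.CLINVAR_FALLBACK)
    return VariantClass(Severity.VUS, ClassSource.UNKNOWN)


def _is_pathogenic_label(label: str) -> bool:
    low = label.lower()
    return "pathogenic" in low and "conflicting" not in low and not low.startswith("non")


class AmbiguousPhaseWarning(UserWarning):
    """Multi-variant sample without phase: complex alleles cannot be named."""


def detect_complex_alleles(
    variants: Sequence[GbaVariant], catalog: KnownVariantCatalog
) -> list[ComplexAllele]:
    """Name complex (recombinant) alleles among one sample's variants.

    An allele is reported only when *all* of its components carry the same
    ``phase_group``; partial component sets remain plain co-occurring
    variants.  If several variants co-occur without phase information, an
    :class:`AmbiguousPhaseWarning` is emitted and nothing is named.
    """
    if len(variants) > 1 and any(v.phase_group is None for v in variants):
        warnings.warn(
            "multi-variant sample without complete phase; complex alleles not called",
            AmbiguousPhaseWarning,
            stacklevel=2,
        )
        return []
    by_phase: dict[str, set[str]] = {}
    for v in variants:
        if v.phase_group is not None and v.hgvs_p is not None:
            by_phase.setdefault(v.phase_group, set()).add(v.hgvs_p)
    matches = []
    for allele in catalog.complex_alleles:
        if any(allele.components <= group for group in by_phase.values()):
            matches.append(allele)
    return matches


def collapse_carrier_events(
    variants: Sequence[GbaVariant], catalog: KnownVariantCatalog
) -> set[str]:
    """Collapse a sample's variants into carrier events.

    Components of a detected complex allele are replaced by the allele name;
    every other variant contributes its own identifier.  This is the unit the
    concordance layer counts, so a RecNciI carrier is one event whether the
    input lists the named allele or its three phased components.
    """
    names = {v.key for v in variants}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", AmbiguousPhaseWarning)
        matched = detect_complex_alleles(variants, catalog)
    for allele in matched:
        names -= allele.components
        names.add(allele.name)
    return names


def carrier_class(classes: Iterable[VariantClass]) -> VariantClass:
    """Carrier-level class: the maximum severity among a person's variants.

    Complex alleles contribute their own class; homozygosity does not change
    the class; duplicates and input order are irrelevant.
    """
    classes = list(classes)
    if not classes:
        raise ValueError("carrier_class needs at least one classified variant")
    return max(classes, key=lambda c: c.severity)
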