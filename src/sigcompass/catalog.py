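"""Signature catalog: definitions, validation, queries.

A catalog is a set of :class:`SignatureDefinition` objects, each persisted as
one JSON document plus a shared ``index.json``.  The packaged default catalog
transcribes the published collection's metadata table; a subset of entries
additionally carries full gene lists (``genes_available=True``) and only those
can be scored.
"""

from __future__ import annotations

import difflib
import json
import re
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from sigcompass.errors import (
    CatalogLookupError,
    ConfigurationError,
    DuplicateSignatureError,
    SignatureValidationError,
)

VALID_METHODS = frozenset(
    {"weighted_sum", "zscore_mean", "up_down_diff", "ssgsea", "ips_composite", "consensus_centroid"}
)
VALID_SCALES = frozenset({"counts", "cpm", "fpkm", "tpm", "log"})
VALID_INPUT_TYPES = frozenset({"sequencing", "microarray"})
VALID_DIRECTIONS = frozenset({"up", "down", "none"})

#: Free-text tissue aliases: query token -> token actually searched for in
#: the tumor-type strings.  Matching itself is case-insensitive substring.
TISSUE_ALIASES: Mapping[str, str] = {
    "ovary": "ovarian",
    "ovaries": "ovarian",
    "brain": "glio",  # glioma / glioblastoma
    "kidney": "renal",
    "skin": "melanoma",
    "lung cancer": "lung",
    "breast cancer": "breast",
}

_SYMBOL_RE = re.compile(r"^\S+$")
_NAME_RE = re.compile(r"^[A-Za-z][A-Za-z0-9]*(?:_[A-Za-z0-9\-]+)*$")


@dataclass(frozen=True)
class SignatureGene:
    """One gene of a signature with optional weight/attributes."""

    symbol: str
    direction: str = "none"
    weight: float | None = None
    class_label: str | None = None
    sub_class: str | None = None

    def to_dict(self) -> dict:
        d: dict = {"symbol": self.symbol, "direction": self.direction}
        if self.weight is not None:
            d["weight"] = self.weight
        if self.class_label is not None:
            d["class_label"] = self.class_label
        if self.sub_class is not None:
            d["sub_class"] = self.sub_class
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SignatureGene":
        return cls(
            symbol=str(d["symbol"]),
            direction=str(d.get("direction", "none")),
            weight=None if d.get("weight") is None else float(d["weight"]),
            class_label=d.get("class_label"),
            sub_class=d.get("sub_class"),
        )


@dataclass(frozen=True)
class SignatureDefinition:
    """One catalog entry: metadata plus (optionally) its gene list."""

    name: str
    topic: str
    tumor_types: tuple[str, ...]
    first_author: str
    reference_id: str
    input_types: frozenset[str]
    required_scale: str
    method: str
    genes: tuple[SignatureGene, ...] = ()
    centroids: pd.DataFrame | None = None  # gene x subtype, consensus_centroid only
    genes_available: bool = True

    def __post_init__(self):
        object.__setattr__(self, "tumor_types", tuple(self.tumor_types))
        object.__setattr__(self, "input_types", frozenset(self.input_types))
        object.__setattr__(self, "genes", tuple(self.genes))

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def gene_symbols(self) -> list[str]:
        return [g.symbol for g in self.genes]

    def is_pan_cancer(self) -> bool:
        return any("pan-cancer" in t.lower() for t in self.tumor_types)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "topic": self.topic,
            "tumor_types": list(self.tumor_types),
            "first_author": self.first_author,
            "reference_id": self.reference_id,
            "input_types": sorted(self.input_types),
            "required_scale": self.required_scale,
            "method": self.method,
            "genes_available": self.genes_available,
            "genes": [g.to_dict() for g in self.genes],
        }
        if self.centroids is not None:
            d["centroids"] = {
                "genes": list(self.centroids.index),
                "subtypes": list(self.centroids.columns),
                "values": self.centroids.to_numpy().tolist(),
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SignatureDefinition":
        centroids = None
        if d.get("centroids") is not None:
            c = d["centroids"]
            centroids = pd.DataFrame(c["values"], index=c["genes"], columns=c["subtypes"], dtype=float)
        return cls(
            name=str(d["name"]),
            topic=str(d["topic"]),
            tumor_types=tuple(d["tumor_types"]),
            first_author=str(d["first_author"]),
            reference_id=str(d["reference_id"]),
            input_types=frozenset(d["input_types"]),
            required_scale=str(d["required_scale"]),
            method=str(d["method"]),
            genes=tuple(SignatureGene.from_dict(g) for g in d.get("genes", [])),
            centroids=centroids,
            genes_available=bool(d.get("genes_available", True)),
        )

    def normalized(self) -> "SignatureDefinition":
        """Uppercase gene symbols; collapse duplicates keeping the first entry."""
        seen: dict[str, SignatureGene] = {}
        dropped = []
        for g in self.genes:
            sym = g.symbol.upper()
            if sym in seen:
                dropped.append(sym)
            else:
                seen[sym] = replace(g, symbol=sym)
        if dropped:
            warnings.warn(
                f"{self.name}: duplicate gene symbols after uppercasing collapsed: "
                f"{sorted(set(dropped))}",
                stacklevel=2,
            )
        centroids = self.centroids
        if centroids is not None:
            centroids = centroids.copy()
            centroids.index = [str(i).upper() for i in centroids.index]
            centroids = centroids[~centroids.index.duplicated(keep="first")]
        return replace(self, genes=tuple(seen.values()), centroids=centroids)


@dataclass
class ValidationCheck:
    criterion: str
    passed: bool
    message: str


@dataclass
class ValidationReport:
    """Pass/fail per machine-checkable inclusion criterion."""

    signature_name: str
    checks: list[ValidationCheck] = field(default_factory=list)
    removed_genes: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return all(c.passed for c in self.checks)

    @property
    def n_genes_retained(self) -> int:
        return self._n_retained

    def summary(self) -> str:
        lines = []
        for c in self.checks:
            lines.append(f"[{'PASS' if c.passed else 'FAIL'}] {c.criterion}: {c.message}")
        for w in self.warnings:
            lines.append(f"[WARN] {w}")
        return "\n".join(lines)


def validate_signature(sig: SignatureDefinition) -> ValidationReport:
    """Check a definition against the machine-checkable inclusion criteria.

    Returns a report; never raises.  Genes whose symbol is not well formed
    (empty or containing whitespace) are flagged for removal rather than
    failing the whole definition, provided at least one well-formed gene
    remains.
    """
    report = ValidationReport(signature_name=sig.name)
    checks = report.checks

    well_formed = [g for g in sig.genes if _SYMBOL_RE.match(g.symbol or "")]
    report.removed_genes = [g.symbol for g in sig.genes if g not in well_formed]
    report._n_retained = len(well_formed)

    if sig.genes_available:
        checks.append(
            ValidationCheck(
                "gene_list",
                bool(well_formed),
                f"{len(well_formed)} well-formed gene symbols retained, "
                f"{len(report.removed_genes)} flagged for removal"
                if sig.genes
                else "gene list is empty: a clear gene list is required",
            )
        )
    else:
        checks.append(
            ValidationCheck("gene_list", True, "metadata-only entry (gene list not packaged)")
        )

    method_ok = sig.method in VALID_METHODS
    msg = f"method {sig.method!r}"
    if method_ok and sig.genes_available:
        if sig.method == "weighted_sum":
            bad = [g.symbol for g in well_formed if g.weight is None or not _finite(g.weight)]
            if bad:
                method_ok, msg = False, f"weighted_sum requires a finite weight per gene; missing: {bad[:5]}"
        elif sig.method == "up_down_diff":
            if not any(g.direction == "up" for g in well_formed):
                method_ok, msg = False, "up_down_diff requires at least one gene with direction=up"
        elif sig.method == "consensus_centroid":
            if sig.centroids is None or sig.centroids.shape[1] < 2:
                method_ok, msg = False, "consensus_centroid requires a centroid matrix with >=2 subtypes"
        elif sig.method == "ips_composite":
            bad = [g.symbol for g in well_formed if g.class_label is None or g.weight is None]
            if bad:
                method_ok, msg = False, f"ips_composite requires class_label and weight per gene; missing: {bad[:5]}"
    checks.append(ValidationCheck("method", method_ok, msg))

    checks.append(
        ValidationCheck(
            "input_scale",
            sig.required_scale in VALID_SCALES,
            f"required input scale {sig.required_scale!r}",
        )
    )
    checks.append(
        ValidationCheck(
            "input_types",
            bool(sig.input_types) and sig.input_types <= VALID_INPUT_TYPES,
            f"input types {sorted(sig.input_types)}",
        )
    )
    checks.append(
        ValidationCheck("name", bool(_NAME_RE.match(sig.name or "")), f"name {sig.name!r}")
    )
    if "_" not in sig.name:
        report.warnings.append(
            f"name {sig.name!r} does not follow the Topic_Author convention"
        )
    bad_dir = [g.symbol for g in sig.genes if g.direction not in VALID_DIRECTIONS]
    if bad_dir:
        checks.append(ValidationCheck("directions", False, f"invalid directions on {bad_dir[:5]}"))
    return report


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


@dataclass
class CatalogFilter:
    """Conjunctive selection over catalog metadata; all fields optional."""

    topic: str | None = None
    tissue: str | None = None
    input_type: str | None = None
    name_pattern: str | None = None
    include_pan: bool = True

    @classmethod
    def from_mapping(cls, d: Mapping) -> "CatalogFilter":
        known = {"topic", "tissue", "input_type", "name_pattern", "include_pan"}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(
                f"unknown filter field(s): {sorted(unknown)}; valid fields: {sorted(known)}"
            )
        return cls(**d)


class Catalog:
    """Ordered, name-keyed collection of signature definitions."""

    def __init__(self, definitions: Iterable[SignatureDefinition] = ()):
        self._defs: dict[str, SignatureDefinition] = {}
        for d in definitions:
            self.register(d)

    def __len__(self) -> int:
        return len(self._defs)

    def __contains__(self, name: str) -> bool:
        return name in self._defs

    def __iter__(self) -> Iterator[SignatureDefinition]:
        return iter(self._defs.values())

    @property
    def names(self) -> list[str]:
        return sorted(self._defs)

    def register(self, sig: SignatureDefinition) -> "Catalog":
        """Validate and add a definition; duplicate names are rejected."""
        if sig.name in self._defs:
            raise DuplicateSignatureError(f"signature {sig.name!r} already registered")
        report = validate_signature(sig)
        if not report.valid:
            raise SignatureValidationError(report)
        self._defs[sig.name] = sig.normalized()
        return self

    def get(self, name: str) -> SignatureDefinition:
        try:
            return self._defs[name]
        except KeyError:
            suggestions = difflib.get_close_matches(name, self._defs, n=3, cutoff=0.5)
            raise CatalogLookupError(name, suggestions) from None

    def topics(self) -> list[str]:
        return sorted({d.topic for d in self._defs.values()})

    def available_signatures(self, filt: CatalogFilter | None = None) -> pd.DataFrame:
        """Return one metadata row per matching definition, sorted by name.

        Matching is conjunctive across filter fields.  Tissue matching is a
        case-insensitive substring test over the tumor-type strings after
        alias expansion; pan-cancer entries match every tissue query when
        ``include_pan`` is set.
        """
        filt = filt or CatalogFilter()
        defs = list(self._defs.values())

        if filt.topic is not None:
            valid = self.topics()
            if filt.topic not in valid:
                warnings.warn(
                    f"unknown topic {filt.topic!r}; valid topics: {valid}", stacklevel=2
                )
                defs = []
            else:
                defs = [d for d in defs if d.topic == filt.topic]
        if filt.tissue is not None:
            defs = [d for d in defs if _tissue_matches(d, filt.tissue, filt.include_pan)]
        if filt.input_type is not None:
            if filt.input_type not in VALID_INPUT_TYPES:
                raise ConfigurationError(
                    f"unknown input_type {filt.input_type!r}; valid: {sorted(VALID_INPUT_TYPES)}"
                )
            defs = [d for d in defs if filt.input_type in d.input_types]
        if filt.name_pattern is not None:
            rx = re.compile(filt.name_pattern, re.IGNORECASE)
            defs = [d for d in defs if rx.search(d.name)]

        rows = [
            {
                "name": d.name,
                "topic": d.topic,
                "tumor_types": "; ".join(d.tumor_types),
                "first_author": d.first_author,
                "reference_id": d.reference_id,
                "input_types": ", ".join(sorted(d.input_types)),
                "required_scale": d.required_scale,
                "method": d.method,
                "n_genes": d.n_genes,
                "genes_available": d.genes_available,
            }
            for d in sorted(defs, key=lambda d: d.name)
        ]
        cols = [
            "name", "topic", "tumor_types", "first_author", "reference_id",
            "input_types", "required_scale", "method", "n_genes", "genes_available",
        ]
        return pd.DataFrame(rows, columns=cols)

    # -- persistence ---------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write one JSON document per signature plus an index file."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        index = []
        for name in self.names:
            fname = f"{name}.json"
            with open(directory / fname, "w", encoding="utf-8") as fh:
                json.dump(self._defs[name].to_dict(), fh, indent=1, sort_keys=True)
                fh.write("\n")
            index.append(fname)
        with open(directory / "index.json", "w", encoding="utf-8") as fh:
            json.dump({"signatures": index}, fh, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, directory: str | Path) -> "Catalog":
        directory = Path(directory)
        with open(directory / "index.json", encoding="utf-8") as fh:
            index = json.load(fh)["signatures"]
        cat = cls()
        for fname in index:
            with open(directory / fname, encoding="utf-8") as fh:
                cat.register(SignatureDefinition.from_dict(json.load(fh)))
        return cat


def _tissue_matches(sig: SignatureDefinition, tissue: str, include_pan: bool) -> bool:
    if sig.is_pan_cancer():
        return include_pan
    needle = TISSUE_ALIASES.get(tissue.lower().strip(), tissue.lower().strip())
    return any(needle in t.lower() for t in sig.tumor_types)


# module-level convenience wrappers mirroring the functional interface

def available_signatures(catalog: Catalog, filt: CatalogFilter | None = None) -> pd.DataFrame:
    return catalog.available_signatures(filt)


def get_signature(catalog: Catalog, name: str) -> SignatureDefinition:
    return catalog.get(name)


def register_signature(catalog: Catalog, sig: SignatureDefinition) -> Catalog:
    return catalog.register(sig)


def load_default_catalog() -> Catalog:
    """Load the packaged catalog (published metadata table + fixture gene lists)."""
    root = resources.files("sigcompass").joinpath("data", "catalog")
    with resources.as_file(root) as path:
        return Catalog.load(path)
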