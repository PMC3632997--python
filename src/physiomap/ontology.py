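"""Mini-registry of physics-of-biology ontology terms and composite annotations.

The registry is a small, local stand-in for the ontologies a semantic
simulation framework draws on: physical-property terms (force, amount,
flow rate) organised by biophysical domain (fluid, chemical, electrical,
diffusion), plus a handful of anatomical and chemical entity terms used by
the bundled example models.  Terms carry local CURIEs (``opbx:``, ``fmax:``,
``chebix:``) with an ``external_iri`` slot for reconciliation against the
real OPB/FMA/ChEBI identifiers.

A *composite annotation* attaches a physical property to the entity that
bears it, optionally refined by structural relations, e.g. the chemical
amount of glucose contained in the cytosol.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

__all__ = [
    "Category",
    "PropertyClass",
    "OntologyTerm",
    "BearerLink",
    "CompositeAnnotation",
    "TermRegistry",
    "RegistryError",
    "load_registry",
    "is_subclass_of",
    "classify_property",
    "annotations_equivalent",
    "bearers_equivalent",
]

STRUCTURAL_RELATIONS = ("none", "part-of", "contained-in", "connected-to")


class Category(str, Enum):
    PROPERTY = "property"
    ENTITY = "entity"
    PROCESS = "process"
    DEPENDENCY = "dependency"
    DOMAIN = "domain"


class PropertyClass(str, Enum):
    """Coarse classification of a physical-property term."""

    FLOW_RATE = "flow-rate"
    FORCE = "force"
    AMOUNT = "amount"
    OTHER = "other"


# Anchor terms for classification.
FLOW_RATE_ROOT = "opbx:DynamicalFlowRate"
FORCE_ROOT = "opbx:ForceProperty"
AMOUNT_ROOT = "opbx:AmountProperty"

_CLASS_ROOTS = {
    FLOW_RATE_ROOT: PropertyClass.FLOW_RATE,
    FORCE_ROOT: PropertyClass.FORCE,
    AMOUNT_ROOT: PropertyClass.AMOUNT,
}


class RegistryError(ValueError):
    """Malformed registry file or dangling term reference."""


@dataclass(frozen=True)
class OntologyTerm:
    id: str
    label: str
    parent_id: str | None = None
    category: Category = Category.ENTITY
    domain_id: str | None = None
    external_iri: str | None = None


@dataclass(frozen=True)
class BearerLink:
    """One element of a bearer chain: an entity term and how it refines the base."""

    term_id: str
    relation: str = "none"

    def __post_init__(self) -> None:
        if self.relation not in STRUCTURAL_RELATIONS:
            raise ValueError(f"unknown structural relation {self.relation!r}")


@dataclass(frozen=True)
class CompositeAnnotation:
    """A physical property borne by a (chain-refined) physical entity.

    The first bearer element is the base entity; subsequent elements refine
    it structurally (``part-of``, ``contained-in``).  Entities with no
    ontology mapping carry a ``free_label`` instead of a bearer chain.
    """

    property_term: str
    bearer: tuple[BearerLink, ...] = ()
    free_label: str | None = None

    def __post_init__(self) -> None:
        if not self.bearer and self.free_label is None:
            raise ValueError("composite annotation needs a bearer chain or a free label")
        if self.bearer and self.bearer[0].relation != "none":
            raise ValueError("first bearer element is the base entity (relation 'none')")

    def bearer_key(self) -> tuple:
        """Hashable identity of the borne entity (ignores the property term)."""
        if self.bearer:
            return tuple((b.term_id, b.relation) for b in self.bearer)
        return ("label", _normalize_label(self.free_label or ""))


def _normalize_label(label: str) -> str:
    return re.sub(r"\s+", " ", label.strip()).lower()


class TermRegistry:
    """Rooted forest of ontology terms with subsumption and property classification."""

    def __init__(self, terms: Mapping[str, OntologyTerm]):
        self.terms: dict[str, OntologyTerm] = dict(terms)
        self._check_integrity()
        self.roots = sorted(t.id for t in self.terms.values() if t.parent_id is None)
        self._iri_index = {
            t.external_iri: t.id for t in self.terms.values() if t.external_iri
        }

    def _check_integrity(self) -> None:
        for term in self.terms.values():
            if term.parent_id is not None and term.parent_id not in self.terms:
                raise RegistryError(
                    f"term {term.id}: parent {term.parent_id} not in registry"
                )
            if term.domain_id is not None and term.domain_id not in self.terms:
                raise RegistryError(
                    f"term {term.id}: domain {term.domain_id} not in registry"
                )
        for term in self.terms.values():  # parent links must be acyclic
            seen = set()
            cur: str | None = term.id
            while cur is not None:
                if cur in seen:
                    raise RegistryError(f"cycle in parent chain at {cur}")
                seen.add(cur)
                cur = self.terms[cur].parent_id

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def get(self, term_id: str) -> OntologyTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise KeyError(f"unknown ontology term {term_id!r}") from None

    def ancestors(self, term_id: str) -> Iterator[str]:
        """Yield term_id and then each ancestor up to the root."""
        cur: str | None = self.get(term_id).id
        while cur is not None:
            yield cur
            cur = self.terms[cur].parent_id

    def term_for_iri(self, iri: str) -> str | None:
        return self._iri_index.get(iri)

    def label(self, term_id: str) -> str:
        return self.get(term_id).label


def load_registry(path: str | Path | None = None) -> TermRegistry:
    """Load a term registry from a TSV table (the shipped default when path is None).

    Columns: id, label, parent, category, domain, iri; ``-`` marks an empty slot.
    """
    if path is None:
        source = resources.files("physiomap.data").joinpath("registry.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise RegistryError("empty registry file")
    header = lines[0].rstrip("\n").split("\t")
    expected = ["id", "label", "parent", "category", "domain", "iri"]
    if header != expected:
        raise RegistryError(f"bad registry header {header!r}, expected {expected!r}")
    terms: dict[str, OntologyTerm] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 6:
            raise RegistryError(f"line {lineno}: expected 6 columns, got {len(fields)}")
        tid, label, parent, category, domain, iri = (f.strip() for f in fields)
        if not tid or not label:
            raise RegistryError(f"line {lineno}: id and label are required")
        if tid in terms:
            raise RegistryError(f"line {lineno}: duplicate term id {tid}")
        try:
            cat = Category(category)
        except ValueError:
            raise RegistryError(
                f"line {lineno}: unknown category {category!r}"
            ) from None
        terms[tid] = OntologyTerm(
            id=tid,
            label=label,
            parent_id=None if parent == "-" else parent,
            category=cat,
            domain_id=None if domain == "-" else domain,
            external_iri=None if iri == "-" else iri,
        )
    return TermRegistry(terms)


def is_subclass_of(registry: TermRegistry, term_id: str, ancestor_id: str) -> bool:
    """True iff ancestor_id is on term_id's parent chain (reflexive)."""
    registry.get(ancestor_id)
    return any(a == ancestor_id for a in registry.ancestors(term_id))


def classify_property(
    registry: TermRegistry, term_id: str
) -> tuple[PropertyClass, str | None]:
    """Classify a property term as flow-rate/force/amount/other with its domain.

    The class is decided by the nearest ancestor among the dynamical flow
    rate, force property and amount property subtrees; the biophysical
    domain is taken from the term itself or the nearest ancestor carrying one.
    """
    term = registry.get(term_id)
    if term.category is not Category.PROPERTY:
        raise ValueError(f"{term_id} has category {term.category.value}, not property")
    pclass = PropertyClass.OTHER
    domain: str | None = None
    for ancestor in registry.ancestors(term_id):
        if pclass is PropertyClass.OTHER and ancestor in _CLASS_ROOTS:
            pclass = _CLASS_ROOTS[ancestor]
        if domain is None:
            domain = registry.get(ancestor).domain_id
    if pclass is PropertyClass.OTHER:
        domain = None
    return pclass, domain


def annotations_equivalent(a: CompositeAnnotation, b: CompositeAnnotation) -> bool:
    """Exact equivalence: same property term and element-wise equal bearer chains.

    When both annotations lack bearer chains, free labels are compared
    case-insensitively after whitespace normalisation.
    """
    if a.property_term != b.property_term:
        return False
    if a.bearer or b.bearer:
        return a.bearer == b.bearer
    return _normalize_label(a.free_label or "") == _normalize_label(b.free_label or "")


def bearers_equivalent(a: CompositeAnnotation, b: CompositeAnnotation) -> bool:
    """Equivalence of the borne entity alone, ignoring the property term.

    This is the identity used for entity nodes: the fluid pressure and the
    fluid volume of the same portion of blood describe one entity.
    """
    return a.bearer_key() == b.bearer_key()
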