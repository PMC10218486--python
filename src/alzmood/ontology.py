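"""Build, query, and serialize the Alzheimer mood ontology.

The ontology is a rooted, acyclic subclass hierarchy of named classes with
object properties, per-class annotations, and typed individuals.  Two
canonical fixtures ship with the package:

* ``taxonomy_full`` -- the seven-class / thirty-six-subclass observational
  taxonomy (patients, states of mind, activity patterns, gerontological
  center areas, cognition, activity/rest, nutrition);
* ``schema_owl`` -- the operational OWL schema (Patient, Scene, Pattern,
  State) used for instance attachment and rule-based reasoning, with an
  "at-least-one" object property linking each State subclass to the
  activity Patterns that may evidence it.

Serialization goes through rdflib to RDF/XML or Turtle; round-tripping
preserves the model's logical content (classes, edges, properties,
annotations, individuals) exactly.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

from rdflib import BNode, Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD

from alzmood.labels import Mood

#: IRI namespace for every entity this package mints.
AM = Namespace("https://w3id.org/alzmood#")

#: Synthetic top concept mirroring owl:Thing; single root of every model.
ROOT = "Thing"

#: Mood concepts attached as annotations to the State-of-mind subclasses,
#: written from the clinical conceptualizations used in the study domain.
MOOD_CONCEPTS: dict[Mood, str] = {
    Mood.DISORIENTED: (
        "Loss of the capacity to recognise familiar places or faces, or "
        "confusion about one's own position."
    ),
    Mood.NERVOUS: (
        "Repetitive acts such as re-asking questions, returning to the same "
        "topic, or redoing completed tasks; interruption of these routines "
        "produces worry and anxiousness."
    ),
    Mood.BORED: (
        "Reluctance to engage in recreational or social activities the "
        "person traditionally carried out; demotivation and lack of interest."
    ),
    Mood.WANDERING: (
        "Sustained walking without direction, sense, or spatial orientation."
    ),
    Mood.DEPRESSED: (
        "Loss of capacity for motor activity together with deterioration of "
        "memory for the execution of voluntary acts."
    ),
}

#: Class-label spellings of the mood subclasses in the full taxonomy fixture.
TAXONOMY_MOOD_LABELS: dict[str, Mood] = {
    "Disoriented": Mood.DISORIENTED,
    "Nervous": Mood.NERVOUS,
    "Boring": Mood.BORED,
    "Wander": Mood.WANDERING,
    "Depressed": Mood.DEPRESSED,
}

#: State-class spellings in the operational schema fixture.
SCHEMA_MOOD_LABELS: dict[str, Mood] = {
    "Disoriented": Mood.DISORIENTED,
    "Nervous": Mood.NERVOUS,
    "Bored": Mood.BORED,
    "Wandered": Mood.WANDERING,
    "Depressed": Mood.DEPRESSED,
}

#: State subclass -> Pattern subclasses allowed by the at-least-one property.
SCHEMA_STATE_PATTERNS: dict[str, tuple[str, ...]] = {
    "Bored": ("Sitting", "Standing"),
    "Disoriented": ("Sitting", "Standing"),
    "Depressed": ("Sitting",),
    "Wandered": ("Walking",),
    "Nervous": ("Sitting", "Standing"),
}


class OntologyError(ValueError):
    """Invariant violation in an ontology model."""


class OntologyParseError(OntologyError):
    """Raised when an OWL document cannot be loaded into a valid model."""


def iri_fragment(label: str) -> str:
    """Deterministic label -> IRI-fragment mapping.

    Whitespace, "/" and every other non-alphanumeric character map to "_";
    runs collapse to a single underscore.  Labels are preserved separately
    via rdfs:label so the mapping need not be invertible, only injective
    over any one model (enforced at build time).
    """
    frag = re.sub(r"[^A-Za-z0-9]+", "_", label).strip("_")
    if not frag:
        raise OntologyError(f"label {label!r} has no IRI-safe characters")
    return frag


@dataclass(frozen=True)
class ObjectProperty:
    """An object property edge of the schema.

    ``cardinality_kind`` is "min1" for the at-least-one construct (an
    owl:minQualifiedCardinality-1 restriction on the domain class) or
    "plain" for a simple domain/range declaration.
    """

    name: str
    domain: str
    range: str
    cardinality_kind: str = "min1"

    def __post_init__(self) -> None:
        if self.cardinality_kind not in ("min1", "plain"):
            raise OntologyError(f"unknown cardinality kind {self.cardinality_kind!r}")


@dataclass
class TaxonomyTable:
    """Two-column (class, subclass) specification in document order."""

    rows: list[tuple[str, str]]

    def validate(self) -> None:
        seen_pairs: set[tuple[str, str]] = set()
        parent_of: dict[str, str] = {}
        for cls, sub in self.rows:
            if not cls:
                raise OntologyError("empty class name in taxonomy row")
            if (cls, sub) in seen_pairs:
                raise OntologyError(f"duplicate taxonomy pair ({cls!r}, {sub!r})")
            seen_pairs.add((cls, sub))
            if sub:
                if sub in parent_of and parent_of[sub] != cls:
                    raise OntologyError(
                        f"subclass {sub!r} listed under both "
                        f"{parent_of[sub]!r} and {cls!r}"
                    )
                parent_of[sub] = cls

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "TaxonomyTable":
        """Read a UTF-8 CSV with required header ``class,subclass``."""
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                raise OntologyError(f"{path}: empty taxonomy file") from None
            if [h.strip().lower() for h in header[:2]] != ["class", "subclass"]:
                raise OntologyError(
                    f"{path}: expected header 'class,subclass', got {header!r}"
                )
            rows = [(r[0].strip(), r[1].strip()) for r in reader if r and r[0].strip()]
        table = cls(rows)
        table.validate()
        return table


@dataclass
class OntologyModel:
    """Named classes, acyclic subclass edges, properties, and individuals.

    ``subclass_edges`` holds (child, parent) pairs; every class is reachable
    from the single ``root``.  Acyclicity is re-checked on every mutation.
    """

    classes: set[str] = field(default_factory=set)
    subclass_edges: set[tuple[str, str]] = field(default_factory=set)
    object_properties: set[ObjectProperty] = field(default_factory=set)
    annotations: dict[str, str] = field(default_factory=dict)
    individuals: set[tuple[str, str]] = field(default_factory=set)
    root: str = ROOT

    def __post_init__(self) -> None:
        self.classes.add(self.root)

    # -- mutation -----------------------------------------------------------

    def add_class(self, name: str, parent: str | None = None) -> None:
        if not name:
            raise OntologyError("class name must be nonempty")
        self.classes.add(name)
        if parent is not None:
            self.add_subclass_edge(name, parent)

    def add_subclass_edge(self, child: str, parent: str) -> None:
        for n in (child, parent):
            if n not in self.classes:
                raise OntologyError(f"unknown class {n!r}")
        self.subclass_edges.add((child, parent))
        if self._has_cycle():
            self.subclass_edges.discard((child, parent))
            raise OntologyError(
                f"edge {child!r} -> {parent!r} would create a subclass cycle"
            )

    def add_object_property(self, prop: ObjectProperty) -> None:
        for n in (prop.domain, prop.range):
            if n not in self.classes:
                raise OntologyError(f"object property {prop.name!r}: unknown class {n!r}")
        self.object_properties.add(prop)

    def add_annotation(self, cls: str, text: str) -> None:
        if cls not in self.classes:
            raise OntologyError(f"cannot annotate unknown class {cls!r}")
        self.annotations[cls] = text

    def add_individual(self, name: str, asserted_class: str) -> None:
        if asserted_class not in self.classes:
            raise OntologyError(
                f"individual {name!r}: unknown asserted class {asserted_class!r}"
            )
        self.individuals.add((name, asserted_class))

    # -- queries ------------------------------------------------------------

    def parents(self, cls: str) -> set[str]:
        return {p for c, p in self.subclass_edges if c == cls}

    def children(self, cls: str) -> set[str]:
        return {c for c, p in self.subclass_edges if p == cls}

    def individual_class(self, name: str) -> str:
        for ind, cls in self.individuals:
            if ind == name:
                return cls
        raise OntologyError(f"unknown individual {name!r}")

    def _has_cycle(self) -> bool:
        # Kahn topological sort over the subclass digraph.
        indeg: dict[str, int] = {c: 0 for c in self.classes}
        adj: dict[str, list[str]] = {c: [] for c in self.classes}
        for child, parent in self.subclass_edges:
            adj[parent].append(child)
            indeg[child] += 1
        queue = [c for c, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            node = queue.pop()
            seen += 1
            for nxt in adj[node]:
                indeg[nxt] -= 1
                if indeg[nxt] == 0:
                    queue.append(nxt)
        return seen != len(self.classes)

    def validate(self) -> None:
        """Check every structural invariant; raise OntologyError on failure."""
        if self.root not in self.classes:
            raise OntologyError("root class missing from class set")
        if self._has_cycle():
            raise OntologyError("subclass graph contains a cycle")
        reachable = {self.root}
        frontier = [self.root]
        while frontier:
            node = frontier.pop()
            for child in self.children(node):
                if child not in reachable:
                    reachable.add(child)
                    frontier.append(child)
        unreachable = self.classes - reachable
        if unreachable:
            raise OntologyError(f"classes unreachable from root: {sorted(unreachable)}")
        for name, cls in self.individuals:
            if cls not in self.classes:
                raise OntologyError(f"individual {name!r} typed by unknown class {cls!r}")
        for prop in self.object_properties:
            for n in (prop.domain, prop.range):
                if n not in self.classes:
                    raise OntologyError(f"property {prop.name!r} references unknown class {n!r}")
        frags: dict[str, str] = {}
        for label in self.classes:
            frag = iri_fragment(label)
            if frag in frags and frags[frag] != label:
                raise OntologyError(
                    f"labels {frags[frag]!r} and {label!r} collide on IRI fragment {frag!r}"
                )
            frags[frag] = label

    def logical_content(self):
        """Hashable snapshot of the model's logical content, for equality tests."""
        return (
            frozenset(self.classes),
            frozenset(self.subclass_edges),
            frozenset(self.object_properties),
            frozenset(self.annotations.items()),
            frozenset(self.individuals),
            self.root,
        )


# -- construction ----------------------------------------------------------


def build_taxonomy(spec: TaxonomyTable) -> OntologyModel:
    """Build a model from a (class, subclass) table.

    Each distinct class becomes a direct child of the root; each subclass a
    child of its class.  Mood-concept annotations are attached to any
    State-of-mind subclasses recognised by spelling.  The build is
    deterministic and independent of row order within a class.
    """
    spec.validate()
    model = OntologyModel()
    for cls, _ in spec.rows:
        if cls not in model.classes:
            model.add_class(cls, parent=model.root)
    for cls, sub in spec.rows:
        if sub:
            model.add_class(sub, parent=cls)
    for label, mood in {**TAXONOMY_MOOD_LABELS, **SCHEMA_MOOD_LABELS}.items():
        if label in model.classes and model.root not in model.parents(label):
            model.add_annotation(label, MOOD_CONCEPTS[mood])
    model.validate()
    return model


def load_taxonomy_fixture(name: str = "taxonomy_full") -> TaxonomyTable:
    """Load a bundled taxonomy fixture: ``taxonomy_full`` or ``schema_owl``."""
    ref = resources.files("alzmood") / "fixtures" / f"{name}.csv"
    with resources.as_file(ref) as path:
        return TaxonomyTable.from_csv(path)


def build_schema(with_state_property: bool = True) -> OntologyModel:
    """Build the operational OWL schema (Patient, Scene, Pattern, State).

    When ``with_state_property`` is set, each State subclass gains a
    min-cardinality-1 ``hasPattern`` property to each activity Pattern that
    may evidence it (e.g. Wandered -> Walking).
    """
    model = build_taxonomy(load_taxonomy_fixture("schema_owl"))
    if with_state_property:
        for state, patterns in SCHEMA_STATE_PATTERNS.items():
            for pattern in patterns:
                model.add_object_property(
                    ObjectProperty("hasPattern", state, pattern, "min1")
                )
    model.validate()
    return model


# -- reasoning services ----------------------------------------------------


def is_subclass_of(model: OntologyModel, a: str, b: str) -> bool:
    """True iff ``b`` is reachable from ``a`` via subclass edges (reflexive)."""
    for n in (a, b):
        if n not in model.classes:
            raise OntologyError(f"unknown class {n!r}")
    if a == b:
        return True
    frontier = [a]
    seen = {a}
    while frontier:
        node = frontier.pop()
        for parent in model.parents(node):
            if parent == b:
                return True
            if parent not in seen:
                seen.add(parent)
                frontier.append(parent)
    return False


def inferred_hierarchy(model: OntologyModel) -> set[tuple[str, str]]:
    """Transitive closure of the subclass edges (irreflexive pairs only)."""
    closure: set[tuple[str, str]] = set()
    for cls in model.classes:
        frontier = [cls]
        seen: set[str] = set()
        while frontier:
            node = frontier.pop()
            for parent in model.parents(node):
                if parent not in seen:
                    seen.add(parent)
                    closure.add((cls, parent))
                    frontier.append(parent)
    return closure


# -- serialization ---------------------------------------------------------

_DIALECTS = {"rdfxml": "xml", "turtle": "turtle"}


def _class_iri(label: str) -> URIRef:
    return AM[iri_fragment(label)]


def serialize_ontology(model: OntologyModel, dialect: str = "rdfxml") -> str:
    """Serialize a model to an OWL document (RDF/XML or Turtle)."""
    if dialect not in _DIALECTS:
        raise OntologyError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    model.validate()
    g = Graph()
    g.bind("am", AM)
    g.bind("owl", OWL)
    g.add((AM[""], RDF.type, OWL.Ontology))
    for cls in model.classes:
        iri = _class_iri(cls)
        g.add((iri, RDF.type, OWL.Class))
        g.add((iri, RDFS.label, Literal(cls)))
    for child, parent in model.subclass_edges:
        g.add((_class_iri(child), RDFS.subClassOf, _class_iri(parent)))
    for cls, text in model.annotations.items():
        g.add((_class_iri(cls), RDFS.comment, Literal(text)))
    for name, cls in model.individuals:
        iri = AM[iri_fragment(name)]
        g.add((iri, RDF.type, OWL.NamedIndividual))
        g.add((iri, RDF.type, _class_iri(cls)))
        g.add((iri, RDFS.label, Literal(name)))
    for prop in model.object_properties:
        p_iri = AM[iri_fragment(prop.name)]
        g.add((p_iri, RDF.type, OWL.ObjectProperty))
        g.add((p_iri, RDFS.label, Literal(prop.name)))
        if prop.cardinality_kind == "min1":
            restriction = BNode()
            g.add((restriction, RDF.type, OWL.Restriction))
            g.add((restriction, OWL.onProperty, p_iri))
            g.add(
                (
                    restriction,
                    OWL.minQualifiedCardinality,
                    Literal(1, datatype=XSD.nonNegativeInteger),
                )
            )
            g.add((restriction, OWL.onClass, _class_iri(prop.range)))
            g.add((_class_iri(prop.domain), RDFS.subClassOf, restriction))
        else:
            g.add((p_iri, RDFS.domain, _class_iri(prop.domain)))
            g.add((p_iri, RDFS.range, _class_iri(prop.range)))
    return g.serialize(format=_DIALECTS[dialect])


def parse_ontology(document: str, dialect: str | None = None) -> OntologyModel:
    """Parse an OWL document back into a model, enforcing all invariants.

    ``dialect`` may be "rdfxml", "turtle", or None to auto-detect.  Malformed
    documents raise OntologyParseError carrying the parser's position report;
    well-formed documents violating model invariants (e.g. subclass cycles)
    are rejected too.
    """
    g = Graph()
    formats = [_DIALECTS[dialect]] if dialect else ["xml", "turtle"]
    last_err: Exception | None = None
    for fmt in formats:
        try:
            g = Graph()
            g.parse(data=document, format=fmt)
            last_err = None
            break
        except Exception as exc:  # rdflib raises format-specific errors
            last_err = exc
    if last_err is not None:
        raise OntologyParseError(f"cannot parse OWL document: {last_err}") from last_err

    labels: dict[URIRef, str] = {
        s: str(o) for s, o in g.subject_objects(RDFS.label) if isinstance(s, URIRef)
    }

    def name_of(iri: URIRef) -> str:
        if iri in labels:
            return labels[iri]
        text = str(iri)
        return text.rsplit("#", 1)[-1].rsplit("/", 1)[-1]

    class_iris = {s for s in g.subjects(RDF.type, OWL.Class) if isinstance(s, URIRef)}
    model = OntologyModel()
    named: dict[URIRef, str] = {iri: name_of(iri) for iri in class_iris}
    root_name = ROOT if ROOT in named.values() else ROOT
    model.root = root_name
    model.classes = set(named.values()) | {root_name}

    restrictions: dict[BNode, dict] = {}
    for s in g.subjects(RDF.type, OWL.Restriction):
        if isinstance(s, BNode):
            restrictions[s] = {
                "prop": g.value(s, OWL.onProperty),
                "range": g.value(s, OWL.onClass),
            }

    for child, parent in g.subject_objects(RDFS.subClassOf):
        if not isinstance(child, URIRef) or child not in named:
            continue
        if isinstance(parent, URIRef) and parent in named:
            model.subclass_edges.add((named[child], named[parent]))
        elif isinstance(parent, BNode) and parent in restrictions:
            info = restrictions[parent]
            if info["prop"] is not None and info["range"] in named:
                model.object_properties.add(
                    ObjectProperty(
                        name_of(info["prop"]), named[child], named[info["range"]], "min1"
                    )
                )

    for p in g.subjects(RDF.type, OWL.ObjectProperty):
        domain, rng = g.value(p, RDFS.domain), g.value(p, RDFS.range)
        if domain in named and rng in named:
            model.object_properties.add(
                ObjectProperty(name_of(p), named[domain], named[rng], "plain")
            )

    for cls_iri, comment in g.subject_objects(RDFS.comment):
        if cls_iri in named:
            model.annotations[named[cls_iri]] = str(comment)

    for ind in g.subjects(RDF.type, OWL.NamedIndividual):
        for t in g.objects(ind, RDF.type):
            if t in named:
                model.individuals.add((name_of(ind), named[t]))

    try:
        model.validate()
    except OntologyError as exc:
        raise OntologyParseError(f"document violates model invariants: {exc}") from exc
    return model


# -- graph export ----------------------------------------------------------


def to_dot(model: OntologyModel) -> str:
    """Static DOT export of the subclass hierarchy for external rendering."""
    lines = ["digraph ontology {", '  rankdir="BT";']
    for cls in sorted(model.classes):
        lines.append(f'  "{cls}" [shape=box];')
    for child, parent in sorted(model.subclass_edges):
        lines.append(f'  "{child}" -> "{parent}";')
    for name, cls in sorted(model.individuals):
        lines.append(f'  "{name}" [shape=ellipse,style=dashed];')
        lines.append(f'  "{name}" -> "{cls}" [style=dotted];')
    lines.append("}")
    return "\n".join(lines)
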