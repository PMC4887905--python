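"""Disease ontology with annotation-derived information content.

The ontology is a rooted DAG built from MeSH-style dot-separated tree numbers
(``term<TAB>tree_number``; several numbers per term mean several parents).
Term probabilities are estimated from the miRNA-disease association table:
each (miRNA, disease) pair is one annotation, propagated once to every
ancestor, so ``P(term) = propagated_count(term) / propagated_count(root)``.
Terms that never appear in an annotation receive the smallest positive count
(add-one smoothing) so their information content is finite.

Semantic similarity between two terms x and y is Lin's measure

    sim(x, y) = 2 * log P(D0) / (log P(x) + log P(y))

where D0 is the most informative (lowest-probability) common ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import log
from pathlib import Path
from typing import Iterable, Mapping

from .io import FormatError, normalize_disease

__all__ = ["ROOT", "DiseaseOntology", "build_ontology", "mica", "lin_similarity"]

#: id of the virtual root placed above every top-level tree number
ROOT = "__root__"


@dataclass
class DiseaseOntology:
    """Rooted DAG of disease terms with annotation-derived probabilities."""

    parents: dict[str, set[str]]
    annotation_count: dict[str, int]
    propagated_count: dict[str, int]
    total: int
    probability: dict[str, float]
    _ancestors: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    @property
    def terms(self) -> set[str]:
        return set(self.parents) | {ROOT}

    def __contains__(self, term: str) -> bool:
        return term == ROOT or term in self.parents

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` including itself (root always included)."""
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        if term == ROOT:
            result = frozenset({ROOT})
        elif term not in self.parents:
            raise KeyError(term)
        else:
            seen: set[str] = set()
            stack = [term]
            while stack:
                node = stack.pop()
                if node in seen:
                    continue
                seen.add(node)
                if node != ROOT:
                    stack.extend(self.parents.get(node, {ROOT}))
            seen.add(ROOT)
            result = frozenset(seen)
        self._ancestors[term] = result
        return result

    def validate(self) -> None:
        if abs(self.probability[ROOT] - 1.0) > 1e-12:
            raise ValueError("root probability must be 1")
        for term, parents in self.parents.items():
            if term in self.ancestors(term) - {term} or term in {
                p for p in parents if p == term
            }:
                raise ValueError(f"cycle through {term}")
            for parent in parents:
                if self.probability[term] > self.probability[parent] + 1e-12:
                    raise ValueError(f"P({term}) > P(parent {parent})")


def _parse_tree_file(path: str | Path) -> dict[str, set[str]]:
    codes: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected term<TAB>tree_number")
            term, code = normalize_disease(fields[0]), fields[1].strip()
            if not code:
                raise FormatError(f"{path}:{lineno}: empty tree number")
            codes.setdefault(term, set()).add(code)
    return codes


def build_ontology(
    tree_file: str | Path | Mapping[str, Iterable[str]] | None,
    associations: Mapping[str, Iterable[str]],
) -> DiseaseOntology:
    """Build the ontology from a tree-number file and the association table.

    ``tree_file`` may also be an in-memory ``term -> tree numbers`` mapping
    (used by tests), or ``None`` for a flat ontology. Diseases that occur in
    ``associations`` but carry no tree number are attached directly to the
    root; they end up with similarity 0 to every other term.
    """
    if tree_file is None:
        codes: dict[str, set[str]] = {}
    elif isinstance(tree_file, (str, Path)):
        codes = _parse_tree_file(tree_file)
    else:
        codes = {normalize_disease(t): set(cs) for t, cs in tree_file.items()}

    code_owner: dict[str, str] = {}
    for term, term_codes in sorted(codes.items()):
        for code in term_codes:
            other = code_owner.setdefault(code, term)
            if other != term:
                raise FormatError(f"tree number {code} claimed by both {other!r} and {term!r}")

    parents: dict[str, set[str]] = {term: set() for term in codes}
    for term, term_codes in codes.items():
        for code in term_codes:
            parent = ROOT
            parts = code.split(".")
            for cut in range(len(parts) - 1, 0, -1):
                owner = code_owner.get(".".join(parts[:cut]))
                if owner is not None and owner != term:
                    parent = owner
                    break
            parents[term].add(parent)

    # annotated diseases missing from the tree become root-attached orphans
    annotation_count: dict[str, int] = {term: 0 for term in parents}
    for diseases in associations.values():
        for disease in diseases:
            disease = normalize_disease(disease)
            if disease not in parents:
                parents[disease] = {ROOT}
                annotation_count[disease] = 0
            annotation_count[disease] += 1

    ontology = DiseaseOntology(
        parents=parents,
        annotation_count=annotation_count,
        propagated_count={},
        total=0,
        probability={},
    )
    # cycle guard before using ancestors for propagation
    for term in parents:
        ontology.ancestors(term)

    propagated = {term: 0 for term in parents}
    propagated[ROOT] = 0
    for term, count in annotation_count.items():
        if count:
            for ancestor in ontology.ancestors(term):
                propagated[ancestor] += count

    total = max(propagated[ROOT], 1)
    probability = {
        term: min(1.0, max(count, 1) / total) for term, count in propagated.items()
    }
    probability[ROOT] = 1.0

    ontology.propagated_count = propagated
    ontology.total = total
    ontology.probability = probability
    ontology.validate()
    return ontology


def mica(ontology: DiseaseOntology, x: str, y: str) -> str:
    """Most informative common ancestor: the shared ancestor with minimal P.

    The root is always a shared ancestor, so the result is total. Probability
    ties are broken in favor of the more specific term (deeper ancestry),
    then by term id, for determinism.
    """
    common = ontology.ancestors(x) & ontology.ancestors(y)
    return min(
        common,
        key=lambda t: (ontology.probability[t], -len(ontology.ancestors(t)), t),
    )


def lin_similarity(ontology: DiseaseOntology, x: str, y: str) -> float:
    """Lin similarity in [0, 1]; symmetric; 1 on identical terms.

    When both terms sit at probability 1 the denominator degenerates to 0;
    the similarity is then defined as 0 for distinct terms.
    """
    if x not in ontology or y not in ontology:
        raise KeyError(f"unknown term {x if x not in ontology else y!r}")
    if x == y:
        return 1.0
    denom = log(ontology.probability[x]) + log(ontology.probability[y])
    if denom == 0.0:
        return 0.0
    sim = 2.0 * log(ontology.probability[mica(ontology, x, y)]) / denom
    return min(1.0, max(0.0, sim))
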