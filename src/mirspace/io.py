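"""Readers, writers and the internal data model for all input formats.

Input formats are deliberately plain text:

* associations  -- TSV ``mirna<TAB>disease[<TAB>pmid]``
* locations     -- GFF3, 1-based inclusive coordinates, id from ``Name=`` or ``ID=``
* families      -- TSV ``mirna<TAB>family``
* abstracts     -- TSV ``mirna<TAB>text`` or a directory of per-miRNA text files
* targets       -- TSV ``mirna<TAB>gene``
* mature map    -- TSV ``stem_loop_id<TAB>mature_group_id``

Coordinates are stored 1-based inclusive (GFF3 convention) throughout; all
distance arithmetic in :mod:`mirspace.features` assumes this.

Several stem-loop records may produce the same mature miRNA; such records are
merged into one group carrying the union of their annotations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

__all__ = [
    "FormatError",
    "MirnaRecord",
    "Dataset",
    "tokenize",
    "load_associations",
    "load_locations",
    "load_families",
    "load_abstracts",
    "load_targets",
    "load_mature_map",
    "merge_stem_loops",
    "build_dataset",
    "load_bundle",
    "write_associations",
    "write_locations",
    "write_families",
    "write_abstracts",
    "write_targets",
    "write_tree",
]

#: (chromosome, strand, start, end); start/end 1-based inclusive.
Location = tuple[str, str, int, int]

_TOKEN_RE = re.compile(r"[a-zA-Z]{3,}")


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


def tokenize(text: str) -> list[str]:
    """Lowercase alphabetic tokens of length >= 3, stop words removed."""
    return [t for t in _TOKEN_RE.findall(text.lower()) if t not in ENGLISH_STOP_WORDS]


def normalize_disease(name: str) -> str:
    return " ".join(name.strip().lower().split())


@dataclass
class MirnaRecord:
    """All annotations attached to one (merged) miRNA."""

    id: str
    locations: list[Location] = field(default_factory=list)
    family: str | None = None
    abstract_text: str = ""
    diseases: set[str] = field(default_factory=set)
    targets: set[str] = field(default_factory=set)

    def validate(self) -> None:
        for chrom, strand, start, end in self.locations:
            if strand not in ("+", "-"):
                raise ValueError(f"{self.id}: bad strand {strand!r}")
            if start > end:
                raise ValueError(f"{self.id}: start {start} > end {end} on {chrom}")


@dataclass
class Dataset:
    """A fully merged collection of miRNA records plus the global id lists.

    The list lengths define the matrix dimensions: m miRNAs, d diseases,
    t genes, f families, w vocabulary words.
    """

    mirnas: list[MirnaRecord]
    diseases: list[str]
    genes: list[str]
    families: list[str]
    vocabulary: list[str]

    @property
    def mirna_ids(self) -> list[str]:
        return [rec.id for rec in self.mirnas]

    def validate(self) -> None:
        ids = self.mirna_ids
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate miRNA ids in dataset")
        diseases, genes, families = set(self.diseases), set(self.genes), set(self.families)
        for rec in self.mirnas:
            rec.validate()
            if not rec.diseases <= diseases:
                raise ValueError(f"{rec.id}: diseases missing from global list")
            if not rec.targets <= genes:
                raise ValueError(f"{rec.id}: targets missing from global list")
            if rec.family is not None and rec.family not in families:
                raise ValueError(f"{rec.id}: family {rec.family!r} missing from global list")


def _iter_rows(path: Path, min_cols: int, what: str) -> Iterator[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise FormatError(
                    f"{path}:{lineno}: {what} needs >= {min_cols} tab-separated "
                    f"columns, got {len(fields)}"
                )
            yield lineno, fields


def load_associations(path: str | Path) -> dict[str, set[str]]:
    """Load the miRNA-disease association table.

    Duplicate (mirna, disease) rows collapse to a single association; disease
    names are normalized (lowercased, whitespace-trimmed). An empty file
    yields an empty map.
    """
    out: dict[str, set[str]] = {}
    for _, fields in _iter_rows(Path(path), 2, "association row"):
        mirna, disease = fields[0].strip(), normalize_disease(fields[1])
        if not mirna or not disease:
            continue
        out.setdefault(mirna, set()).add(disease)
    return out


def load_locations(path: str | Path) -> dict[str, list[Location]]:
    """Load miRNA genomic locations from GFF3 (1-based inclusive)."""
    path = Path(path)
    out: dict[str, list[Location]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: GFF3 line has {len(cols)} columns, expected 9")
            seqid, _, _, start_s, end_s, _, strand, _, attrs = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            if end < start:
                raise FormatError(f"{path}:{lineno}: end {end} < start {start}")
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            name = attr_map.get("Name") or attr_map.get("ID")
            if not name:
                raise FormatError(f"{path}:{lineno}: no Name= or ID= attribute")
            out.setdefault(name.strip(), []).append((seqid, strand, start, end))
    return out


def load_families(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for lineno, fields in _iter_rows(Path(path), 2, "family row"):
        mirna, family = fields[0].strip(), fields[1].strip()
        if mirna in out and out[mirna] != family:
            raise FormatError(
                f"{path}:{lineno}: conflicting families for {mirna}: "
                f"{out[mirna]!r} vs {family!r}"
            )
        out[mirna] = family
    return out


def load_abstracts(path: str | Path) -> dict[str, str]:
    """Load abstracts from a TSV (``mirna<TAB>text``) or a directory of files."""
    path = Path(path)
    out: dict[str, str] = {}
    if path.is_dir():
        for child in sorted(path.iterdir()):
            if child.is_file():
                out[child.name] = child.read_text(encoding="utf-8")
        return out
    for _, fields in _iter_rows(path, 2, "abstract row"):
        mirna, text = fields[0].strip(), fields[1]
        out[mirna] = out[mirna] + "\n" + text if mirna in out else text
    return out


def load_targets(path: str | Path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for _, fields in _iter_rows(Path(path), 2, "target row"):
        out.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return out


def load_mature_map(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for _, fields in _iter_rows(Path(path), 2, "mature-map row"):
        out[fields[0].strip()] = fields[1].strip()
    return out


def merge_stem_loops(
    records: Iterable[MirnaRecord], mature_map: Mapping[str, str] | None = None
) -> list[MirnaRecord]:
    """Merge stem-loop records that produce the same mature miRNA.

    ``mature_map`` assigns stem-loop ids to canonical group ids; ids absent
    from the map are their own group. Per group: union of diseases, targets
    and locations; concatenation of abstracts (in member-id order); the family
    is taken from any member, and two members with different families raise.
    """
    mature_map = mature_map or {}
    groups: dict[str, list[MirnaRecord]] = {}
    for rec in records:
        groups.setdefault(mature_map.get(rec.id, rec.id), []).append(rec)

    merged: list[MirnaRecord] = []
    for gid in sorted(groups):
        members = sorted(groups[gid], key=lambda r: r.id)
        families = {r.family for r in members if r.family is not None}
        if len(families) > 1:
            raise ValueError(
                f"group {gid}: conflicting families {sorted(families)} "
                f"among members {[r.id for r in members]}"
            )
        locations = sorted({loc for r in members for loc in r.locations})
        abstracts = "\n".join(r.abstract_text for r in members if r.abstract_text)
        merged.append(
            MirnaRecord(
                id=gid,
                locations=list(locations),
                family=next(iter(families)) if families else None,
                abstract_text=abstracts,
                diseases=set().union(*(r.diseases for r in members)),
                targets=set().union(*(r.targets for r in members)),
            )
        )
    return merged


def build_dataset(
    associations: Mapping[str, set[str]],
    locations: Mapping[str, list[Location]] | None = None,
    families: Mapping[str, str] | None = None,
    abstracts: Mapping[str, str] | None = None,
    targets: Mapping[str, set[str]] | None = None,
    mature_map: Mapping[str, str] | None = None,
) -> Dataset:
    """Assemble raw per-source tables into a merged, validated :class:`Dataset`."""
    locations = locations or {}
    families = families or {}
    abstracts = abstracts or {}
    targets = targets or {}

    ids = (
        set(associations) | set(locations) | set(families) | set(abstracts) | set(targets)
    )
    raw = [
        MirnaRecord(
            id=mid,
            locations=list(locations.get(mid, [])),
            family=families.get(mid),
            abstract_text=abstracts.get(mid, ""),
            diseases=set(associations.get(mid, set())),
            targets=set(targets.get(mid, set())),
        )
        for mid in sorted(ids)
    ]
    mirnas = merge_stem_loops(raw, mature_map)

    vocabulary = sorted({tok for rec in mirnas for tok in tokenize(rec.abstract_text)})
    dataset = Dataset(
        mirnas=mirnas,
        diseases=sorted({d for rec in mirnas for d in rec.diseases}),
        genes=sorted({g for rec in mirnas for g in rec.targets}),
        families=sorted({rec.family for rec in mirnas if rec.family is not None}),
        vocabulary=vocabulary,
    )
    dataset.validate()
    return dataset


#: conventional file names inside an input bundle directory
BUNDLE_FILES = {
    "associations": "associations.tsv",
    "locations": "locations.gff3",
    "families": "families.tsv",
    "abstracts": "abstracts.tsv",
    "targets": "targets.tsv",
    "tree": "tree.tsv",
    "mature_map": "mature_map.tsv",
}


def load_bundle(directory: str | Path) -> Dataset:
    """Load a bundle directory written by the generator (or hand-assembled)."""
    directory = Path(directory)

    def maybe(loader, key):
        p = directory / BUNDLE_FILES[key]
        return loader(p) if p.exists() else None

    associations = maybe(load_associations, "associations")
    if associations is None:
        raise FormatError(f"{directory}: missing {BUNDLE_FILES['associations']}")
    return build_dataset(
        associations,
        locations=maybe(load_locations, "locations"),
        families=maybe(load_families, "families"),
        abstracts=maybe(load_abstracts, "abstracts"),
        targets=maybe(load_targets, "targets"),
        mature_map=maybe(load_mature_map, "mature_map"),
    )


# ---------------------------------------------------------------------------
# writers (used by the synthetic generator and round-trip tests)

def write_associations(
    associations: Mapping[str, Iterable[str]],
    path: str | Path,
    pmids: Mapping[tuple[str, str], str] | None = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# mirna\tdisease\tpmid\n")
        for mirna in sorted(associations):
            for disease in sorted(associations[mirna]):
                pmid = (pmids or {}).get((mirna, disease), "")
                fh.write(f"{mirna}\t{disease}\t{pmid}\n".rstrip() + "\n")


def write_locations(locations: Mapping[str, Iterable[Location]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for mirna in sorted(locations):
            for chrom, strand, start, end in sorted(locations[mirna]):
                fh.write(
                    f"{chrom}\t.\tmiRNA\t{start}\t{end}\t.\t{strand}\t.\t"
                    f"ID={mirna};Name={mirna}\n"
                )


def write_families(families: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for mirna in sorted(families):
            fh.write(f"{mirna}\t{families[mirna]}\n")


def write_abstracts(abstracts: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for mirna in sorted(abstracts):
            text = " ".join(abstracts[mirna].split())
            fh.write(f"{mirna}\t{text}\n")


def write_targets(targets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for mirna in sorted(targets):
            for gene in sorted(targets[mirna]):
                fh.write(f"{mirna}\t{gene}\n")


def write_tree(codes: Mapping[str, Iterable[str]], path: str | Path) -> None:
    """Write a term<TAB>tree_number file (one line per tree number)."""
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(codes):
            for code in sorted(codes[term]):
                fh.write(f"{term}\t{code}\n")
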