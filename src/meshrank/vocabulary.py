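"""Controlled-vocabulary model: descriptors, hierarchy, frequency ranking.

A vocabulary is a set of descriptors (main headings), each carrying a
preferred name, entry-term synonyms, and one or more dot-delimited tree
numbers placing it in the subject hierarchy.  The parent of tree number
``A.B.C`` is ``A.B``; ancestry is strict dot-prefix containment, so a
descriptor may have ancestors along several branches at once.

Two interchange dialects are supported:

* ``mesh-xml`` — descriptor-record XML (``DescriptorUI``,
  ``DescriptorName``, ``TreeNumberList``, concept ``TermList``);
* ``tsv`` — a five-column flat dialect defined by this package
  (id, preferred name, pipe-separated synonyms, pipe-separated tree
  numbers, check-tag flag), convenient for fixtures and tests.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from lxml import etree


@dataclass
class Descriptor:
    """One controlled-vocabulary term (main heading)."""

    descriptor_id: str
    preferred_name: str
    synonyms: list[str] = field(default_factory=list)
    tree_numbers: list[str] = field(default_factory=list)
    is_check_tag: bool = False

    def all_names(self) -> list[str]:
        """Preferred name plus synonyms (lookup unions them)."""
        return [self.preferred_name, *self.synonyms]


def _parent_tree(tree_number: str) -> str | None:
    head, _, _ = tree_number.rpartition(".")
    return head or None


class Vocabulary:
    """Keyed descriptor collection with hierarchy and frequency queries."""

    def __init__(self, descriptors: list[Descriptor]):
        self.descriptors: dict[str, Descriptor] = {}
        for d in descriptors:
            if d.descriptor_id in self.descriptors:
                raise ValueError(f"duplicate descriptor id {d.descriptor_id!r}")
            for tn in d.tree_numbers:
                if not tn or any(not part for part in tn.split(".")):
                    raise ValueError(
                        f"descriptor {d.descriptor_id!r}: bad tree number {tn!r}"
                    )
            self.descriptors[d.descriptor_id] = d
        if not self.descriptors:
            raise ValueError("vocabulary is empty")
        # tree-number -> parent tree-number (roots absent)
        self.parent_map: dict[str, str] = {}
        self._tree_to_id: dict[str, str] = {}
        for d in self.descriptors.values():
            for tn in d.tree_numbers:
                parent = _parent_tree(tn)
                if parent is not None:
                    self.parent_map[tn] = parent
                self._tree_to_id[tn] = d.descriptor_id
        self.label_frequency: dict[str, int] = {}

    def __len__(self) -> int:
        return len(self.descriptors)

    def __contains__(self, descriptor_id: str) -> bool:
        return descriptor_id in self.descriptors

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Vocabulary):
            return NotImplemented
        return self.descriptors == other.descriptors

    def get(self, descriptor_id: str) -> Descriptor:
        try:
            return self.descriptors[descriptor_id]
        except KeyError:
            raise KeyError(f"unknown descriptor id {descriptor_id!r}") from None

    def ancestors(self, descriptor_id: str) -> set[str]:
        """Descriptor ids whose tree numbers strictly prefix any of this one's."""
        out: set[str] = set()
        for tn in self.get(descriptor_id).tree_numbers:
            parent = _parent_tree(tn)
            while parent is not None:
                owner = self._tree_to_id.get(parent)
                if owner is not None and owner != descriptor_id:
                    out.add(owner)
                parent = _parent_tree(parent)
        return out

    def descendants(self, descriptor_id: str) -> set[str]:
        prefixes = self.get(descriptor_id).tree_numbers
        out: set[str] = set()
        for tn, owner in self._tree_to_id.items():
            if owner == descriptor_id:
                continue
            if any(tn.startswith(p + ".") for p in prefixes):
                out.add(owner)
        return out

    def check_tags(self) -> set[str]:
        return {d.descriptor_id for d in self.descriptors.values() if d.is_check_tag}

    def set_label_frequencies(self, freqs: dict[str, int]) -> None:
        self.label_frequency = dict(freqs)


def is_ancestor(vocab: Vocabulary, a: str, b: str) -> bool:
    """True iff some tree number of *a* strictly dot-prefixes one of *b*."""
    trees_a = vocab.get(a).tree_numbers
    trees_b = vocab.get(b).tree_numbers
    return any(tb.startswith(ta + ".") for ta in trees_a for tb in trees_b)


def top_frequent_labels(vocab: Vocabulary, n: int) -> list[str]:
    """The *n* most frequently annotated descriptor ids.

    Ordering is non-increasing frequency, ties broken lexicographically
    by id.  Requesting more labels than exist returns all of them.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ids = sorted(
        vocab.descriptors,
        key=lambda d: (-vocab.label_frequency.get(d, 0), d),
    )
    return ids[:n]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _load_tsv(path: str, check_tags: set[str] | None) -> Vocabulary:
    descriptors = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 5 tab-separated columns, "
                    f"got {len(parts)}"
                )
            did, name, syns, trees, flag = parts
            descriptors.append(
                Descriptor(
                    descriptor_id=did,
                    preferred_name=name,
                    synonyms=[s for s in syns.split("|") if s],
                    tree_numbers=[t for t in trees.split("|") if t],
                    is_check_tag=flag == "1",
                )
            )
    if not descriptors:
        raise ValueError(f"{path}: no descriptors found")
    vocab = Vocabulary(descriptors)
    if check_tags is not None:
        _apply_check_tags(vocab, check_tags)
    return vocab


def _load_mesh_xml(path: str, check_tags: set[str] | None) -> Vocabulary:
    try:
        tree = etree.parse(path)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"{path}: malformed XML: {exc}") from exc
    descriptors = []
    for rec in tree.iter("DescriptorRecord"):
        ui = rec.findtext("DescriptorUI")
        name = rec.findtext("DescriptorName/String")
        if not ui or not name:
            raise ValueError(
                f"{path}: DescriptorRecord at line "
                f"{rec.sourceline} lacks DescriptorUI/DescriptorName"
            )
        tree_numbers = [
            tn.text for tn in rec.findall("TreeNumberList/TreeNumber") if tn.text
        ]
        synonyms = []
        for term in rec.findall(".//TermList/Term/String"):
            if term.text and term.text != name and term.text not in synonyms:
                synonyms.append(term.text)
        descriptors.append(
            Descriptor(
                descriptor_id=ui,
                preferred_name=name,
                synonyms=synonyms,
                tree_numbers=tree_numbers,
            )
        )
    if not descriptors:
        raise ValueError(f"{path}: no DescriptorRecord elements found")
    vocab = Vocabulary(descriptors)
    if check_tags is not None:
        _apply_check_tags(vocab, check_tags)
    return vocab


def _apply_check_tags(vocab: Vocabulary, check_tags: set[str]) -> None:
    """Flag check tags by id or preferred name (configuration-driven)."""
    for d in vocab.descriptors.values():
        if d.descriptor_id in check_tags or d.preferred_name in check_tags:
            d.is_check_tag = True


def load_vocabulary(
    path: str | os.PathLike,
    dialect: str = "tsv",
    check_tags: set[str] | None = None,
) -> Vocabulary:
    """Load and validate a vocabulary from *path*.

    ``dialect`` is ``"tsv"`` or ``"mesh-xml"``.  ``check_tags``
    optionally names (by id or preferred name) the descriptors to flag
    as check tags; the TSV dialect also carries the flag inline.
    """
    path = os.fspath(path)
    if dialect == "tsv":
        return _load_tsv(path, check_tags)
    if dialect == "mesh-xml":
        return _load_mesh_xml(path, check_tags)
    raise ValueError(f"unknown vocabulary dialect {dialect!r}")


def save_vocabulary_tsv(vocab: Vocabulary, path: str | os.PathLike) -> None:
    """Write the TSV dialect (stable id order; round-trips losslessly)."""
    with open(path, "w", encoding="utf-8") as fh:
        for did in sorted(vocab.descriptors):
            d = vocab.descriptors[did]
            fh.write(
                "\t".join(
                    [
                        d.descriptor_id,
                        d.preferred_name,
                        "|".join(d.synonyms),
                        "|".join(d.tree_numbers),
                        "1" if d.is_check_tag else "0",
                    ]
                )
                + "\n"
            )
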