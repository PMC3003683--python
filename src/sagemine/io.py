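"""Readers and writers for SAGE text dialects.

Two formats live here:

``.lib`` — one SAGE library. Header lines ``#key: value`` carry the
identity and chemistry of the library (``id``, ``title``, ``tissue``,
``tag_type``, ``enzyme``; ``total_count`` is written informationally and
always recomputed on read). Body lines are ``TAG<TAB>count``.

Tag-to-gene mapping — a headerless 5-column TSV in the style of the
SAGEmap distribution files: tag sequence, mapping score, gene symbol,
UniGene cluster ID, UniGene cluster title. One tag may map to several
genes; per-tag annotation lists are kept sorted by descending mapping
score, ties broken by gene symbol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

from .errors import ParseError, ValidationError

TAG_ALPHABET = frozenset("ACGT")
VALID_TAG_TYPES = (10, 11, 17, 21)
VALID_ENZYMES = ("NlaIII", "Sau3A")

_HEADER_KEYS = ("id", "title", "tissue", "tag_type", "enzyme")


def validate_tag(tag: str, tag_type: int) -> str:
    """Check a tag sequence against the library chemistry; return it uppercased.

    A valid tag is over {A, C, G, T} and exactly ``tag_type`` bases long
    (10, 11, 17 or 21 depending on the SAGE protocol and anchoring enzyme).
    """
    if tag_type not in VALID_TAG_TYPES:
        raise ValidationError(f"tag_type must be one of {VALID_TAG_TYPES}, got {tag_type!r}")
    up = tag.upper()
    if len(up) != tag_type:
        raise ValidationError(f"tag {tag!r} has length {len(tag)}, expected {tag_type}")
    if not set(up) <= TAG_ALPHABET:
        raise ValidationError(f"tag {tag!r} contains characters outside A/C/G/T")
    return up


@dataclass
class SageLibrary:
    """One SAGE library: identity, chemistry and the tag -> raw count table."""

    library_id: str
    counts: dict[str, int] = field(default_factory=dict)
    title: str = ""
    tissue: str = ""
    tag_type: int = 10
    enzyme: str = "NlaIII"

    @property
    def total_count(self) -> int:
        """Total tags sequenced, always the sum of the count table."""
        return sum(self.counts.values())

    @property
    def kinds_of_tag(self) -> int:
        """Number of distinct (unrepeated) tag sequences."""
        return len(self.counts)

    def validate(self) -> None:
        if self.enzyme not in VALID_ENZYMES:
            raise ValidationError(
                f"enzyme must be one of {VALID_ENZYMES}, got {self.enzyme!r}"
            )
        for tag, count in self.counts.items():
            if validate_tag(tag, self.tag_type) != tag:
                raise ValidationError(f"tag {tag!r} is not stored uppercase")
            if not isinstance(count, int) or count < 0:
                raise ValidationError(
                    f"count for tag {tag!r} must be a non-negative integer, got {count!r}"
                )


def read_lib(path) -> SageLibrary:
    """Read a ``.lib`` file.

    Duplicate tag lines are summed (with a warning); lowercase tags are
    accepted and uppercased (with a warning). ``total_count`` is recomputed
    from the body regardless of any header claim.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    counts: dict[str, int] = {}
    warned_dup = False
    warned_case = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw_line in enumerate(fh, start=1):
            line = raw_line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if ":" not in line:
                    raise ParseError(
                        f"malformed header line {line!r} (expected '#key: value')",
                        path=path, line=lineno,
                    )
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"malformed body line {line!r} (expected 'TAG<TAB>count')",
                    path=path, line=lineno,
                )
            tag_raw, count_str = parts
            try:
                count = int(count_str)
            except ValueError:
                raise ParseError(
                    f"count {count_str!r} is not an integer", path=path, line=lineno
                ) from None
            if count < 0:
                raise ValidationError(f"negative count {count} for tag {tag_raw!r} [{path}:{lineno}]")
            tag_type = _header_tag_type(meta, path)
            tag = validate_tag(tag_raw, tag_type)
            if tag != tag_raw and not warned_case:
                warnings.warn(f"{path}: lowercase tags uppercased on read", stacklevel=2)
                warned_case = True
            if tag in counts:
                if not warned_dup:
                    warnings.warn(f"{path}: duplicate tag lines summed", stacklevel=2)
                    warned_dup = True
                counts[tag] += count
            else:
                counts[tag] = count
    if "id" not in meta:
        raise ParseError("missing required header key 'id'", path=path)
    lib = SageLibrary(
        library_id=meta["id"],
        counts=counts,
        title=meta.get("title", ""),
        tissue=meta.get("tissue", ""),
        tag_type=_header_tag_type(meta, path),
        enzyme=meta.get("enzyme", "NlaIII"),
    )
    lib.validate()
    return lib


def _header_tag_type(meta: dict[str, str], path) -> int:
    raw = meta.get("tag_type", "10")
    try:
        tag_type = int(raw)
    except ValueError:
        raise ParseError(f"tag_type {raw!r} is not an integer", path=path) from None
    if tag_type not in VALID_TAG_TYPES:
        raise ValidationError(f"tag_type must be one of {VALID_TAG_TYPES}, got {tag_type} [{path}]")
    return tag_type


def write_lib(lib: SageLibrary, path) -> None:
    """Write a ``.lib`` file in canonical form (tags lexicographically sorted)."""
    lib.validate()
    path = Path(path)
    lines = [
        f"#id: {lib.library_id}",
        f"#title: {lib.title}",
        f"#tissue: {lib.tissue}",
        f"#tag_type: {lib.tag_type}",
        f"#enzyme: {lib.enzyme}",
        f"#total_count: {lib.total_count}",
    ]
    lines.extend(f"{tag}\t{lib.counts[tag]}" for tag in sorted(lib.counts))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


class GeneAnnotation(NamedTuple):
    """One tag-to-gene record: SAGEmap-style annotation of a tag."""

    mapping_score: float
    gene_symbol: str
    unigene_cluster_id: str
    unigene_cluster_title: str


@dataclass
class TagGeneMap:
    """Tag -> gene annotations (one-to-many), per-tag lists kept sorted."""

    records: dict[str, list[GeneAnnotation]] = field(default_factory=dict)

    def sort(self) -> None:
        for tag in self.records:
            self.records[tag].sort(key=lambda a: (-a.mapping_score, a.gene_symbol))

    def __len__(self) -> int:
        return len(self.records)


def read_tag_gene_map(path) -> TagGeneMap:
    """Read a headerless 5-column tag-to-gene TSV into a :class:`TagGeneMap`."""
    path = Path(path)
    records: dict[str, list[GeneAnnotation]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw_line in enumerate(fh, start=1):
            line = raw_line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ParseError(
                    f"expected 5 TAB-separated columns, found {len(parts)}",
                    path=path, line=lineno,
                )
            tag, score_str, symbol, uid, title = parts
            try:
                score = float(score_str)
            except ValueError:
                raise ValidationError(
                    f"mapping score {score_str!r} is not numeric [{path}:{lineno}]"
                ) from None
            records.setdefault(tag.upper(), []).append(
                GeneAnnotation(score, symbol, uid, title)
            )
    tgm = TagGeneMap(records)
    tgm.sort()
    return tgm


def write_tag_gene_map(tgm: TagGeneMap, path) -> None:
    """Write the 5-column TSV, tags sorted, per-tag lists in canonical order."""
    path = Path(path)
    tgm.sort()
    lines = []
    for tag in sorted(tgm.records):
        for ann in tgm.records[tag]:
            score = ann.mapping_score
            score_str = str(int(score)) if float(score).is_integer() else repr(score)
            lines.append(
                f"{tag}\t{score_str}\t{ann.gene_symbol}\t{ann.unigene_cluster_id}\t{ann.unigene_cluster_title}"
            )
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
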