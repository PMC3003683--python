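"""Tag-to-gene and tag-to-library query services.

Forward queries take a tag sequence and return its gene annotations or
the libraries expressing it; reverse queries search the annotation table
by gene symbol, UniGene cluster ID (case-insensitive exact match) or
UniGene cluster title (case-insensitive substring).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .io import GeneAnnotation, SageLibrary, TagGeneMap, VALID_TAG_TYPES, TAG_ALPHABET
from .matrix import tpm

QUERY_FIELDS = ("gene_symbol", "unigene_id", "unigene_title")


@dataclass(frozen=True)
class LibraryHit:
    """One library expressing a queried tag."""

    library_id: str
    library_name: str
    tag_count: int
    kinds_of_tag: int
    total_tag_count: int
    tpm: float


def _check_tag(tag: str) -> str:
    up = tag.upper()
    if len(up) not in VALID_TAG_TYPES or not set(up) <= TAG_ALPHABET:
        raise ValidationError(
            f"{tag!r} is not a valid SAGE tag (A/C/G/T, length in {VALID_TAG_TYPES})"
        )
    return up


def tag_to_gene(tag: str, tgm: TagGeneMap) -> list[GeneAnnotation]:
    """All gene annotations of one tag, best mapping score first."""
    return list(tgm.records.get(_check_tag(tag), []))


def query_by(field: str, value: str, tgm: TagGeneMap) -> list[tuple[str, GeneAnnotation]]:
    """Reverse search of the tag-to-gene table.

    ``gene_symbol`` and ``unigene_id`` match exactly (case-insensitive);
    ``unigene_title`` matches as a case-insensitive substring. Results are
    sorted by tag, then by the per-tag annotation order.
    """
    if field not in QUERY_FIELDS:
        raise ValidationError(f"unknown query field {field!r}; expected one of {QUERY_FIELDS}")
    if not value:
        raise ValidationError("query value must be non-empty")
    needle = value.casefold()
    hits: list[tuple[str, GeneAnnotation]] = []
    for tag in sorted(tgm.records):
        for ann in tgm.records[tag]:
            if field == "gene_symbol":
                ok = ann.gene_symbol.casefold() == needle
            elif field == "unigene_id":
                ok = ann.unigene_cluster_id.casefold() == needle
            else:
                ok = needle in ann.unigene_cluster_title.casefold()
            if ok:
                hits.append((tag, ann))
    return hits


def tag_to_library(tag: str, libs: list[SageLibrary]) -> list[LibraryHit]:
    """Libraries in which the tag was detected, highest TPM first.

    Each hit reports the raw tag count, the library's number of distinct
    tag kinds, its total tag count, and the tag's TPM there.
    """
    if not libs:
        raise ValidationError("at least one library is required")
    up = _check_tag(tag)
    hits = []
    for lib in libs:
        count = lib.counts.get(up, 0)
        if count > 0:
            hits.append(
                LibraryHit(
                    library_id=lib.library_id,
                    library_name=lib.title,
                    tag_count=count,
                    kinds_of_tag=lib.kinds_of_tag,
                    total_tag_count=lib.total_count,
                    tpm=tpm(count, lib.total_count),
                )
            )
    hits.sort(key=lambda h: (-h.tpm, h.library_id))
    return hits


def filter_libraries(
    libs: list[SageLibrary],
    tissue: str | None = None,
    keyword: str | None = None,
) -> list[SageLibrary]:
    """Narrow a library list by tissue and/or free-text keyword.

    The tissue filter is a case-insensitive exact match on the tissue
    field; the keyword is a case-insensitive substring over title, tissue
    and library id. Both filters compose conjunctively; ``None`` disables
    a filter.
    """
    out = list(libs)
    if tissue is not None:
        t = tissue.casefold()
        out = [lib for lib in out if lib.tissue.casefold() == t]
    if keyword is not None:
        k = keyword.casefold()
        out = [
            lib
            for lib in out
            if k in (lib.title + " " + lib.tissue + " " + lib.library_id).casefold()
        ]
    return out
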