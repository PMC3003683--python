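"""The tag x library expression matrix S.

Libraries are merged into a dense matrix whose rows are the union of all
member tag sets and whose columns are the libraries, in input order. The
element s_ij is the expression of tag i in library j in tags per million
(TPM): raw count x 1e6 / library total. Raw counts are the stored
quantity — TPM is always derived — so a persisted matrix can distinguish
"expressed at zero TPM because absent" from "not detected", and so a
re-read matrix reproduces s_ij to full precision.

The ``.matrix`` file dialect: one ``#lib`` metadata line per library
(TAB-separated ``key=value`` pairs), then a TSV body whose first column is
the tag and whose remaining columns are raw counts, one per library.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    IncompatibleLibrariesError,
    ParseError,
    ValidationError,
)
from .io import SageLibrary

TPM_SCALE = 1_000_000


def tpm(count: int, total: int) -> float:
    """Tags-per-million normalization of one raw count.

    Parameters
    ----------
    count : non-negative raw tag count
    total : total tag count of the library; must be >= 1

    Returns
    -------
    count * 1e6 / total
    """
    if total < 1:
        raise DomainError("TPM is undefined for a library with total count 0")
    if count < 0:
        raise ValidationError(f"negative count {count}")
    return count * TPM_SCALE / total


@dataclass
class LibMeta:
    """Per-library metadata carried alongside the matrix."""

    title: str
    tissue: str
    tag_type: int
    enzyme: str
    total_count: int


@dataclass
class ExpressionMatrix:
    """Tag x library matrix of raw counts with derived TPM values.

    Attributes
    ----------
    raw : pandas.DataFrame
        Integer raw counts, index = tags (lexicographic), columns = library
        ids in input order. 0 means the tag was not detected.
    tpm : pandas.DataFrame
        Parallel float table of TPM values; every non-empty column sums to
        one million.
    lib_meta : dict
        library_id -> :class:`LibMeta`.
    """

    raw: pd.DataFrame
    tpm: pd.DataFrame
    lib_meta: dict[str, LibMeta]

    @property
    def tags(self) -> list[str]:
        return list(self.raw.index)

    @property
    def libraries(self) -> list[str]:
        return list(self.raw.columns)

    def min_positive_tpm(self, library_id: str) -> float:
        """Smallest strictly positive TPM in one column.

        This is the substitute denominator used by the fold computation
        when a tag is undetected in the denominator library.
        """
        col = self.tpm[library_id].to_numpy()
        pos = col[col > 0]
        if pos.size == 0:
            raise DomainError(f"library {library_id!r} has no positive TPM values")
        return float(pos.min())


def build_matrix(libs: list[SageLibrary]) -> ExpressionMatrix:
    """Merge SAGE libraries into one expression matrix.

    All libraries must share one tag type and one anchoring enzyme, and
    must have distinct ids. Rows are the sorted union of all tag sets;
    a tag absent from a library gets raw count 0 there.
    """
    if not libs:
        raise ValidationError("at least one library is required")
    ids = [lib.library_id for lib in libs]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate library ids in {ids}")
    tag_types = {lib.tag_type for lib in libs}
    enzymes = {lib.enzyme for lib in libs}
    if len(tag_types) > 1 or len(enzymes) > 1:
        raise IncompatibleLibrariesError(
            f"libraries mix tag types {sorted(tag_types)} / enzymes {sorted(enzymes)}"
        )
    all_tags = sorted(set().union(*(lib.counts.keys() for lib in libs)))
    raw = pd.DataFrame(
        {lib.library_id: [lib.counts.get(t, 0) for t in all_tags] for lib in libs},
        index=pd.Index(all_tags, name="tag"),
        dtype=np.int64,
    )
    meta = {
        lib.library_id: LibMeta(
            lib.title, lib.tissue, lib.tag_type, lib.enzyme, lib.total_count
        )
        for lib in libs
    }
    return ExpressionMatrix(raw=raw, tpm=_derive_tpm(raw, meta), lib_meta=meta)


def _derive_tpm(raw: pd.DataFrame, meta: dict[str, LibMeta]) -> pd.DataFrame:
    totals = np.array([meta[c].total_count for c in raw.columns], dtype=float)
    safe = np.where(totals > 0, totals, 1.0)  # empty column stays all-zero
    # (count * 1e6) / total, matching the scalar tpm() definition bit for bit
    return (raw.astype(float) * TPM_SCALE) / safe


def write_matrix(m: ExpressionMatrix, path) -> None:
    """Persist the matrix (raw counts + per-library metadata) as text."""
    path = Path(path)
    lines = []
    for lib_id in m.libraries:
        meta = m.lib_meta[lib_id]
        lines.append(
            "#lib\t" + "\t".join(
                [
                    f"id={lib_id}",
                    f"title={meta.title}",
                    f"tissue={meta.tissue}",
                    f"tag_type={meta.tag_type}",
                    f"enzyme={meta.enzyme}",
                    f"total_count={meta.total_count}",
                ]
            )
        )
    lines.append("tag\t" + "\t".join(m.libraries))
    for tag, row in zip(m.raw.index, m.raw.to_numpy()):
        lines.append(tag + "\t" + "\t".join(str(int(v)) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_matrix(path) -> ExpressionMatrix:
    """Read a ``.matrix`` file; TPM is recomputed from the stored raw counts."""
    path = Path(path)
    meta: dict[str, LibMeta] = {}
    order: list[str] = []
    header: list[str] | None = None
    tags: list[str] = []
    rows: list[list[int]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw_line in enumerate(fh, start=1):
            line = raw_line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#lib\t"):
                fields = dict(
                    part.split("=", 1) for part in line.split("\t")[1:] if "=" in part
                )
                try:
                    lib_id = fields["id"]
                    meta[lib_id] = LibMeta(
                        title=fields.get("title", ""),
                        tissue=fields.get("tissue", ""),
                        tag_type=int(fields["tag_type"]),
                        enzyme=fields["enzyme"],
                        total_count=int(fields["total_count"]),
                    )
                except (KeyError, ValueError) as exc:
                    raise ParseError(
                        f"bad #lib metadata line ({exc})", path=path, line=lineno
                    ) from None
                order.append(lib_id)
                continue
            if header is None:
                cols = line.split("\t")
                if cols[:1] != ["tag"]:
                    raise ParseError(
                        "body must start with a 'tag<TAB>...' column header",
                        path=path, line=lineno,
                    )
                header = cols[1:]
                if header != order:
                    raise ParseError(
                        f"body columns {header} do not match #lib metadata blocks {order}",
                        path=path, line=lineno,
                    )
                continue
            parts = line.split("\t")
            if len(parts) != len(header) + 1:
                raise ParseError(
                    f"row has {len(parts)} columns, expected {len(header) + 1}",
                    path=path, line=lineno,
                )
            try:
                rows.append([int(v) for v in parts[1:]])
            except ValueError:
                raise ParseError("non-integer raw count", path=path, line=lineno) from None
            tags.append(parts[0])
    if header is None:
        raise ParseError("matrix file has no body", path=path)
    raw = pd.DataFrame(
        rows, index=pd.Index(tags, name="tag"), columns=header, dtype=np.int64
    )
    for lib_id in header:
        body_total = int(raw[lib_id].sum())
        if body_total != meta[lib_id].total_count:
            raise ParseError(
                f"library {lib_id!r}: metadata total_count={meta[lib_id].total_count} "
                f"but body columns sum to {body_total}",
                path=path,
            )
    return ExpressionMatrix(raw=raw, tpm=_derive_tpm(raw, meta), lib_meta=meta)
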