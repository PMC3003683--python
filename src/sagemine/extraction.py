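"""Set-theoretic cross-tissue extraction over a condition pool.

The mining engine evaluates a pool of pairwise case-vs-control screens
("conditions"). Each condition names two libraries in the matrix, an
operator, a fold factor and an inclusion flag:

* ``GT`` ("more than"): tags whose adjusted fold A/B is at least the
  factor, with the tag detected in A;
* ``LT`` ("less than"): tags whose adjusted fold B/A is at least the
  factor, with the tag detected in B;
* ``NOT_IN``: tags present (raw count > 0) in A and absent from B.

Each condition yields a tag set Tm. The mined result is the intersection
of the included conditions' sets minus the union of the excluded ones:
with every condition included this is the common-marker set; with one
tissue's conditions included and the rest excluded it is that tissue's
specific set. Reversing every GT to LT mines suppressor candidates
(down in every case).

Fold values divide TPM in the numerator library by TPM in the
denominator library with two zero-handling rules: a zero numerator keeps
the fold at zero, and a zero denominator is replaced by the smallest
positive TPM in the denominator library (so presence against absence is
finite but large).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, ParseError, ValidationError
from .matrix import ExpressionMatrix

TOP_N_DEFAULT = 10
TOP_N_MAX = 100

#: fold-cell provenance flags
FLAG_NORMAL = "normal"
FLAG_ZERO_NUMERATOR = "zero_numerator"
FLAG_ADJUSTED_DENOMINATOR = "adjusted_denominator"
FLAG_BOTH_ZERO = "both_zero"

SCALES = ("linear", "log2", "log10", "sqrt")


class Op(str, Enum):
    """Screening operator of one condition."""

    GT = ">"
    LT = "<"
    NOT_IN = "!="


@dataclass(frozen=True)
class Condition:
    """One pairwise screen: (library A, operator, factor, library B, inclusion)."""

    lib_a: str
    op: Op
    factor: float
    lib_b: str
    inclusion: bool = True
    label: str = ""

    def __post_init__(self):
        if self.lib_a == self.lib_b:
            raise ValidationError(f"condition compares {self.lib_a!r} with itself")
        if self.op in (Op.GT, Op.LT) and self.factor < 1:
            raise ValidationError(
                f"fold factor must be >= 1 for {self.op.value!r}, got {self.factor}"
            )


@dataclass(frozen=True)
class TagSet:
    """Tags satisfying one condition (Tm)."""

    condition_index: int
    members: frozenset[str]


@dataclass
class FoldMatrix:
    """Tag x condition table of adjusted fold values with provenance flags."""

    fold: pd.DataFrame
    flags: pd.DataFrame
    conditions: list[Condition]

    @property
    def tags(self) -> list[str]:
        return list(self.fold.index)


@dataclass
class ExtractionResult:
    """Outcome of mining a condition pool: ranked tags plus supporting tables."""

    mined: list[str]
    per_condition_sets: list[TagSet]
    fold_matrix: FoldMatrix
    scores: dict[str, float]


def fold(
    m: ExpressionMatrix, tag: str, lib_num: str, lib_den: str
) -> tuple[float, str]:
    """Adjusted fold of one tag: TPM in ``lib_num`` over TPM in ``lib_den``.

    Zero handling: a zero numerator yields fold 0 (flag ``zero_numerator``,
    or ``both_zero`` when the denominator is also zero); a zero denominator
    alone is replaced by the smallest positive TPM of the denominator
    library (flag ``adjusted_denominator``).
    """
    if tag not in m.raw.index:
        raise ValidationError(f"tag {tag!r} not in matrix")
    num = float(m.tpm.at[tag, lib_num])
    den = float(m.tpm.at[tag, lib_den])
    if num == 0.0:
        return 0.0, (FLAG_BOTH_ZERO if den == 0.0 else FLAG_ZERO_NUMERATOR)
    if den == 0.0:
        return num / m.min_positive_tpm(lib_den), FLAG_ADJUSTED_DENOMINATOR
    return num / den, FLAG_NORMAL


def fold_column(
    m: ExpressionMatrix, lib_num: str, lib_den: str
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`fold` over every tag; returns (folds, flags)."""
    num = m.tpm[lib_num].to_numpy(dtype=float)
    den = m.tpm[lib_den].to_numpy(dtype=float)
    flags = np.full(num.shape, FLAG_NORMAL, dtype=object)
    flags[num == 0] = FLAG_ZERO_NUMERATOR
    flags[(num == 0) & (den == 0)] = FLAG_BOTH_ZERO
    need_adjust = (num > 0) & (den == 0)
    flags[need_adjust] = FLAG_ADJUSTED_DENOMINATOR
    den_eff = den.copy()
    if need_adjust.any():
        den_eff[need_adjust] = m.min_positive_tpm(lib_den)
    out = np.zeros_like(num)
    nz = num > 0
    out[nz] = num[nz] / den_eff[nz]
    return out, flags


def evaluate_condition(
    m: ExpressionMatrix, c: Condition, index: int = 0
) -> TagSet:
    """Tag set Tm of one condition against the matrix."""
    for lib in (c.lib_a, c.lib_b):
        if lib not in m.raw.columns:
            raise ValidationError(f"library {lib!r} not in matrix")
    tags = np.asarray(m.raw.index)
    if c.op is Op.GT:
        folds, _ = fold_column(m, c.lib_a, c.lib_b)
        mask = (folds >= c.factor) & (m.tpm[c.lib_a].to_numpy() > 0)
    elif c.op is Op.LT:
        folds, _ = fold_column(m, c.lib_b, c.lib_a)
        mask = (folds >= c.factor) & (m.tpm[c.lib_b].to_numpy() > 0)
    elif c.op is Op.NOT_IN:
        mask = (m.raw[c.lib_a].to_numpy() > 0) & (m.raw[c.lib_b].to_numpy() == 0)
    else:  # pragma: no cover - Enum exhausts the cases
        raise ValidationError(f"unknown operator {c.op!r}")
    return TagSet(condition_index=index, members=frozenset(tags[mask]))


def build_fold_matrix(
    m: ExpressionMatrix, pool: list[Condition], tags: list[str] | None = None
) -> FoldMatrix:
    """Fold table over all conditions, rows restricted to ``tags`` if given.

    Column direction follows the condition's reading: GT and NOT_IN
    columns are A/B, LT columns are B/A (so a satisfied condition always
    shows a large fold).
    """
    index = pd.Index(m.raw.index if tags is None else tags, name="tag")
    fold_cols, flag_cols = {}, {}
    for k, c in enumerate(pool):
        num, den = (c.lib_b, c.lib_a) if c.op is Op.LT else (c.lib_a, c.lib_b)
        folds, flags = fold_column(m, num, den)
        col = pd.Series(folds, index=m.raw.index).loc[index]
        flg = pd.Series(flags, index=m.raw.index).loc[index]
        name = f"{k}:{c.lib_a}{c.op.value}{c.lib_b}"
        fold_cols[name] = col
        flag_cols[name] = flg
    return FoldMatrix(
        fold=pd.DataFrame(fold_cols, index=index),
        flags=pd.DataFrame(flag_cols, index=index),
        conditions=list(pool),
    )


def score_tags(fm: FoldMatrix, included: set[int]) -> dict[str, float]:
    """Ranking score per tag: sum of fold values over the included conditions."""
    if not included:
        raise ConfigurationError("at least one included condition is required")
    cols = [fm.fold.columns[k] for k in sorted(included)]
    sums = fm.fold[cols].sum(axis=1)
    return {tag: float(s) for tag, s in sums.items()}


def extract(
    m: ExpressionMatrix, pool: list[Condition], top_n: int = TOP_N_DEFAULT
) -> ExtractionResult:
    """Mine the condition pool.

    mined = (intersection of included Tm) minus (union of excluded Tm),
    ranked by descending score (sum of folds over included conditions,
    ties broken lexicographically by tag) and truncated to ``top_n``
    (at most 100).
    """
    if not 1 <= top_n <= TOP_N_MAX:
        raise ValidationError(f"top_n must be in [1, {TOP_N_MAX}], got {top_n}")
    if not pool:
        raise ConfigurationError("empty condition pool")
    sets = [evaluate_condition(m, c, index=k) for k, c in enumerate(pool)]
    included = {k for k, c in enumerate(pool) if c.inclusion}
    if not included:
        raise ConfigurationError("no condition has inclusion=yes")
    mined_set: set[str] = set(m.raw.index)
    for k in included:
        mined_set &= sets[k].members
    for k, c in enumerate(pool):
        if not c.inclusion:
            mined_set -= sets[k].members
    fm_all = build_fold_matrix(m, pool, tags=sorted(mined_set))
    scores = score_tags(fm_all, included) if mined_set else {}
    order = sorted(mined_set, key=lambda t: (-scores[t], t))[:top_n]
    fm = FoldMatrix(
        fold=fm_all.fold.loc[order],
        flags=fm_all.flags.loc[order],
        conditions=fm_all.conditions,
    )
    return ExtractionResult(
        mined=order,
        per_condition_sets=sets,
        fold_matrix=fm,
        scores={t: scores[t] for t in order},
    )


def scale_transform(values, scale: str):
    """Apply one of the four display scales elementwise.

    linear: x; log2: log2(1+x); log10: log10(1+x); sqrt: sqrt(x).
    The +1 shift keeps zero finite — TPM and fold tables legitimately
    contain zeros. All four transforms are monotone non-decreasing, so
    they preserve the ranking of values.
    """
    if scale not in SCALES:
        raise ValidationError(f"unknown scale {scale!r}; expected one of {SCALES}")
    arr = np.asarray(values, dtype=float) if not isinstance(values, pd.DataFrame) else values
    if (np.asarray(arr) < 0).any():
        raise ValidationError("scale transforms are defined for non-negative values")
    if scale == "linear":
        out = arr * 1.0
    elif scale == "log2":
        out = np.log1p(arr) / np.log(2)  # log1p keeps tiny values distinct from 0
    elif scale == "log10":
        out = np.log1p(arr) / np.log(10)
    else:
        out = np.sqrt(arr)
    return out


def set_inclusion(
    pool: list[Condition], included_labels: set[str] | None = None
) -> list[Condition]:
    """Copy of the pool with inclusion=yes exactly for the given labels.

    ``included_labels=None`` includes every condition (common-marker
    mining); otherwise conditions whose label is in the set are included
    and all others excluded (tissue-specific mining).
    """
    if included_labels is None:
        return [replace(c, inclusion=True) for c in pool]
    return [replace(c, inclusion=c.label in included_labels) for c in pool]


def flip_operators(pool: list[Condition]) -> list[Condition]:
    """Swap every GT with LT (NOT_IN unchanged): the suppressor-mining dual."""
    swap = {Op.GT: Op.LT, Op.LT: Op.GT}
    return [replace(c, op=swap.get(c.op, c.op)) for c in pool]


_OP_FROM_TEXT = {op.value: op for op in Op}


def read_condition_pool(path) -> list[Condition]:
    """Read a condition-pool config: one condition per line,
    ``lib_a<TAB>op<TAB>factor<TAB>lib_b<TAB>Y|N<TAB>label``; ``#`` comments allowed."""
    path = Path(path)
    pool: list[Condition] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw_line in enumerate(fh, start=1):
            line = raw_line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(
                    f"expected 6 TAB-separated fields, found {len(parts)}",
                    path=path, line=lineno,
                )
            lib_a, op_str, factor_str, lib_b, incl_str, label = parts
            if op_str not in _OP_FROM_TEXT:
                raise ParseError(f"unknown operator {op_str!r}", path=path, line=lineno)
            if incl_str not in ("Y", "N"):
                raise ParseError(
                    f"inclusion must be Y or N, got {incl_str!r}", path=path, line=lineno
                )
            try:
                factor = float(factor_str)
            except ValueError:
                raise ParseError(
                    f"factor {factor_str!r} is not numeric", path=path, line=lineno
                ) from None
            pool.append(
                Condition(lib_a, _OP_FROM_TEXT[op_str], factor, lib_b,
                          inclusion=incl_str == "Y", label=label)
            )
    return pool


def write_condition_pool(pool: list[Condition], path) -> None:
    path = Path(path)
    lines = [
        f"{c.lib_a}\t{c.op.value}\t{c.factor:g}\t{c.lib_b}\t{'Y' if c.inclusion else 'N'}\t{c.label}"
        for c in pool
    ]
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
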