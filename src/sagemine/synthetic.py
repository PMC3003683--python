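"""Synthetic SAGE libraries with planted differential expression.

The generator emulates a multi-tissue case/control SAGE study (the
canonical four-tissue colon / ovary / pancreas / breast design): each
tissue contributes case and control libraries sampled as multinomial
draws of ``library_depth`` tags from an underlying transcript-frequency
pool. Background tags have identical expected frequency in cases and
controls; planted tags perturb the case pools only:

* common markers — up ``marker_fold``-fold in every case library;
* tissue-specific markers — up ``marker_fold``-fold only in their own
  tissue's case libraries;
* common suppressors — down ``marker_fold``-fold in every case library.

Folds are applied to expected frequencies before sampling, so realized
folds fluctuate around the planted value. Alongside the libraries the
generator emits the matching condition pool (each case library screened
against its tissue control with the "more than" operator) and the ground
truth, giving every downstream module a fixture with a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .io import SageLibrary, write_lib
from .extraction import Condition, Op, write_condition_pool
from .matrix import build_matrix, write_matrix

TISSUE_NAMES = ("colon", "ovary", "pancreas", "breast")
_BASES = np.array(list("ACGT"))


@dataclass
class PlantSpec:
    """Parameters of one synthetic study.

    Defaults describe a four-tissue design with two case and one control
    library per tissue, 1000 background tags, eight-fold planted effects
    and 50,000 tags sequenced per library.
    """

    n_tissues: int = 4
    libs_per_tissue: tuple[int, int] = (2, 1)  # (n_case, n_control)
    n_background_tags: int = 1000
    n_common_markers: int = 10
    n_specific_per_tissue: int = 5
    n_common_suppressors: int = 5
    marker_fold: float = 8.0
    library_depth: int = 50_000
    tag_type: int = 10
    seed: int = 0

    def validate(self) -> None:
        n_case, n_ctrl = self.libs_per_tissue
        for name, v in [
            ("n_tissues", self.n_tissues), ("n_case", n_case), ("n_control", n_ctrl),
            ("n_background_tags", self.n_background_tags),
            ("n_common_markers", self.n_common_markers),
            ("n_specific_per_tissue", self.n_specific_per_tissue),
            ("n_common_suppressors", self.n_common_suppressors),
        ]:
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
        if self.n_tissues < 1 or n_case < 1 or n_ctrl < 1:
            raise ValidationError("need at least one tissue with one case and one control")
        if self.marker_fold < 2:
            raise ValidationError(f"marker_fold must be >= 2, got {self.marker_fold}")
        if self.library_depth < 1:
            raise ValidationError("library_depth must be positive")
        if self.n_tags_total > 4 ** self.tag_type:
            raise ValidationError(
                f"{self.n_tags_total} planted+background tags exceed the "
                f"{4 ** self.tag_type} possible {self.tag_type}-mers"
            )

    @property
    def n_tags_total(self) -> int:
        return (
            self.n_background_tags
            + self.n_common_markers
            + self.n_tissues * self.n_specific_per_tissue
            + self.n_common_suppressors
        )


@dataclass
class GroundTruth:
    """The planted answer key; the three collections are pairwise disjoint."""

    common_markers: frozenset[str]
    specific_markers: dict[str, frozenset[str]] = field(default_factory=dict)
    suppressors: frozenset[str] = frozenset()

    @property
    def all_specific(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for s in self.specific_markers.values():
            out |= s
        return out


def tissue_names(n: int) -> list[str]:
    return [TISSUE_NAMES[i] if i < len(TISSUE_NAMES) else f"tissue{i + 1}" for i in range(n)]


def _draw_tags(rng: np.random.Generator, n: int, tag_type: int) -> list[str]:
    tags: list[str] = []
    seen: set[str] = set()
    while len(tags) < n:
        block = _BASES[rng.integers(0, 4, size=(max(n - len(tags), 16), tag_type))]
        for row in block:
            tag = "".join(row)
            if tag not in seen:
                seen.add(tag)
                tags.append(tag)
                if len(tags) == n:
                    break
    return tags


def generate(
    spec: PlantSpec,
) -> tuple[list[SageLibrary], GroundTruth, list[Condition]]:
    """Sample the synthetic study defined by ``spec``.

    Returns the libraries (cases then control(s), tissue by tissue), the
    ground truth, and the all-inclusive condition pool (factor =
    ``marker_fold / 2``, labelled by tissue). Deterministic given the
    spec, including its seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tissues = tissue_names(spec.n_tissues)
    n_case, n_ctrl = spec.libs_per_tissue

    tags = _draw_tags(rng, spec.n_tags_total, spec.tag_type)
    pos = 0

    def take(n: int) -> list[str]:
        nonlocal pos
        out = tags[pos:pos + n]
        pos += n
        return out

    common = take(spec.n_common_markers)
    specific = {t: take(spec.n_specific_per_tissue) for t in tissues}
    suppressors = take(spec.n_common_suppressors)
    background = take(spec.n_background_tags)

    tag_order = np.array(common + sum(specific.values(), []) + suppressors + background)
    base_w = np.ones(tag_order.size)
    if spec.n_background_tags:
        base_w[-spec.n_background_tags:] = rng.uniform(
            0.5, 1.5, size=spec.n_background_tags
        )

    idx = {t: i for i, t in enumerate(tag_order)}
    common_idx = np.array([idx[t] for t in common], dtype=int)
    supp_idx = np.array([idx[t] for t in suppressors], dtype=int)
    spec_idx = {ts: np.array([idx[t] for t in specific[ts]], dtype=int) for ts in tissues}

    libs: list[SageLibrary] = []
    pool: list[Condition] = []
    for ts in tissues:
        case_ids = [f"{ts.upper()}_CASE{k + 1}" for k in range(n_case)]
        ctrl_ids = [f"{ts.upper()}_CTRL{k + 1}" for k in range(n_ctrl)]
        for role, lib_ids in (("case", case_ids), ("control", ctrl_ids)):
            for lib_id in lib_ids:
                w = base_w.copy()
                if role == "case":
                    w[common_idx] *= spec.marker_fold
                    w[spec_idx[ts]] *= spec.marker_fold
                    w[supp_idx] /= spec.marker_fold
                counts = rng.multinomial(spec.library_depth, w / w.sum())
                nz = counts > 0
                libs.append(
                    SageLibrary(
                        library_id=lib_id,
                        counts=dict(zip(tag_order[nz], (int(c) for c in counts[nz]))),
                        title=f"synthetic {ts} {role} library {lib_id}",
                        tissue=ts,
                        tag_type=spec.tag_type,
                    )
                )
        for k, case_id in enumerate(case_ids):
            pool.append(
                Condition(
                    lib_a=case_id,
                    op=Op.GT,
                    factor=spec.marker_fold / 2,
                    lib_b=ctrl_ids[k % n_ctrl],
                    inclusion=True,
                    label=ts,
                )
            )

    truth = GroundTruth(
        common_markers=frozenset(common),
        specific_markers={t: frozenset(specific[t]) for t in tissues},
        suppressors=frozenset(suppressors),
    )
    return libs, truth, pool


def write_fixture_set(
    libs: list[SageLibrary],
    truth: GroundTruth,
    pool: list[Condition],
    outdir,
) -> dict[str, Path]:
    """Write the full fixture set: per-library ``.lib`` files, the merged
    ``.matrix`` file, the condition-pool config and a ground-truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for lib in libs:
        p = outdir / f"{lib.library_id}.lib"
        write_lib(lib, p)
        paths[lib.library_id] = p
    matrix_path = outdir / "study.matrix"
    write_matrix(build_matrix(libs), matrix_path)
    paths["matrix"] = matrix_path
    pool_path = outdir / "conditions.tsv"
    write_condition_pool(pool, pool_path)
    paths["pool"] = pool_path
    truth_path = outdir / "ground_truth.tsv"
    lines = [f"{t}\tcommon_marker\t" for t in sorted(truth.common_markers)]
    for ts in sorted(truth.specific_markers):
        lines += [f"{t}\tspecific_marker\t{ts}" for t in sorted(truth.specific_markers[ts])]
    lines += [f"{t}\tsuppressor\t" for t in sorted(truth.suppressors)]
    truth_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    paths["truth"] = truth_path
    return paths
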