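import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sagemine import ExpressionMatrix, LibMeta, SageLibrary

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# valid 10-mers used across tests
T1, T2, T3, T4 = "AAAAAAAAAA", "CCCCCCCCCC", "GGGGGGGGGG", "TTTTTTTTTT"


@pytest.fixture
def tiny_libs():
    """Two small libraries with overlapping tag sets (totals 4 and 4)."""
    a = SageLibrary("LIBA", {T1: 2, T2: 2}, title="lib A", tissue="brain")
    b = SageLibrary("LIBB", {T2: 1, T3: 3}, title="lib B", tissue="colon")
    return [a, b]


def make_matrix_from_tpm(tpm_cols: dict, raw_cols: dict | None = None) -> ExpressionMatrix:
    """Build an ExpressionMatrix directly from stated TPM values.

    For operation-level tests whose expected values are written in TPM
    terms; raw defaults to 1 where TPM > 0 (detected) else 0.
    """
    tpm = pd.DataFrame(tpm_cols, dtype=float)
    tpm.index.name = "tag"
    if raw_cols is None:
        raw = (tpm > 0).astype(np.int64)
    else:
        raw = pd.DataFrame(raw_cols, dtype=np.int64)
        raw.index.name = "tag"
    meta = {
        c: LibMeta(title=c, tissue="", tag_type=10, enzyme="NlaIII",
                   total_count=int(raw[c].sum()))
        for c in tpm.columns
    }
    return ExpressionMatrix(raw=raw, tpm=tpm, lib_meta=meta)


@pytest.fixture
def gt_lt_matrix():
    """TPM A=[100,50,0], B=[10,50,5] over three tags."""
    return make_matrix_from_tpm(
        {"A": {T1: 100.0, T2: 50.0, T3: 0.0}, "B": {T1: 10.0, T2: 50.0, T3: 5.0}}
    )


@pytest.fixture
def gene_map_file(tmp_path):
    """Tag-to-gene fixture: known multi-gene tags plus a title-searchable row."""
    rows = [
        ("GGCCCTGAGC", "5", "POLR2L", "Hs.441072", "polymerase (RNA) II polypeptide L"),
        ("GGCCCTGAGC", "5", "MEA1", "Hs.289114", "male-enhanced antigen 1"),
        ("AAAAACCAGA", "5", "SOD1", "Hs.443914", "superoxide dismutase 1, soluble"),
        ("AAAAACCAGA", "3", "BVES", "Hs.94499", "blood vessel epicardial substance"),
        ("AATATGTGGG", "5", "COX6C", "Hs.351875", "cytochrome c oxidase subunit VIc"),
    ]
    path = tmp_path / "tag2gene.tsv"
    path.write_text("\n".join("\t".join(r) for r in rows) + "\n", encoding="utf-8")
    return path


def libs_to_count_dicts(libs):
    """SageLibrary list -> the plain-dict form the brute-force oracle uses."""
    return {lib.library_id: dict(lib.counts) for lib in libs}


def random_instance(rng: np.random.Generator):
    """One random small extraction instance: libraries + condition pool.

    Up to 50 tags, 6 libraries and 6 conditions; sparse counts (zeros
    common) so all the fold zero-handling branches are exercised. Every
    library keeps at least one positive count and at least one condition
    is included.
    """
    n_tags = int(rng.integers(2, 51))
    n_libs = int(rng.integers(2, 7))
    n_conds = int(rng.integers(1, 7))
    bases = np.array(list("ACGT"))
    tags = []
    while len(set(tags)) < n_tags:
        tags = ["".join(bases[rng.integers(0, 4, 10)]) for _ in range(n_tags)]
    tags = sorted(set(tags))
    lib_ids = [f"L{i}" for i in range(n_libs)]
    libs = []
    for lib_id in lib_ids:
        counts = {
            t: int(c)
            for t, c in zip(tags, rng.integers(0, 21, len(tags)))
            if c > 0 and rng.random() > 0.35
        }
        if not counts:
            counts = {tags[int(rng.integers(0, len(tags)))]: 1}
        libs.append(SageLibrary(lib_id, counts))
    ops = [">", "<", "!="]
    pool = []
    for k in range(n_conds):
        a, b = rng.choice(n_libs, size=2, replace=False)
        op = ops[int(rng.integers(0, 3))]
        factor = float(rng.uniform(1.0, 5.0))
        inclusion = bool(rng.random() < 0.7) if k else True
        pool.append((lib_ids[a], op, factor, lib_ids[b], inclusion))
    if not any(c[4] for c in pool):
        pool[0] = pool[0][:4] + (True,)
    return libs, pool
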