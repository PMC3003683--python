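"""Brute-force reference for the extraction engine.

Everything here is computed per tag with plain scalar arithmetic from raw
count dictionaries — no numpy, no pandas, no code shared with the
implementation under test. Libraries are ``{lib_id: {tag: count}}``;
conditions are ``(lib_a, op, factor, lib_b, inclusion)`` tuples with op
one of ">", "<", "!=".
"""

from __future__ import annotations


def oracle_tpm(counts: dict, lib: str, tag: str) -> float:
    table = counts[lib]
    total = sum(table.values())
    return table.get(tag, 0) * 1_000_000 / total


def oracle_min_positive_tpm(counts: dict, lib: str) -> float:
    table = counts[lib]
    total = sum(table.values())
    positives = [c * 1_000_000 / total for c in table.values() if c > 0]
    return min(positives)


def oracle_fold(counts: dict, tag: str, lib_num: str, lib_den: str) -> float:
    num = oracle_tpm(counts, lib_num, tag)
    den = oracle_tpm(counts, lib_den, tag)
    if num == 0:
        return 0.0
    if den == 0:
        return num / oracle_min_positive_tpm(counts, lib_den)
    return num / den


def oracle_condition_members(counts: dict, all_tags, cond) -> set:
    lib_a, op, factor, lib_b, _incl = cond
    members = set()
    for tag in all_tags:
        if op == ">":
            ok = (
                oracle_tpm(counts, lib_a, tag) > 0
                and oracle_fold(counts, tag, lib_a, lib_b) >= factor
            )
        elif op == "<":
            ok = (
                oracle_tpm(counts, lib_b, tag) > 0
                and oracle_fold(counts, tag, lib_b, lib_a) >= factor
            )
        elif op == "!=":
            ok = counts[lib_a].get(tag, 0) > 0 and counts[lib_b].get(tag, 0) == 0
        else:
            raise ValueError(op)
        if ok:
            members.add(tag)
    return members


def oracle_extract(counts: dict, all_tags, pool, top_n: int):
    """Mined tags in rank order, plus every per-condition member set."""
    sets = [oracle_condition_members(counts, all_tags, c) for c in pool]
    mined = set(all_tags)
    for s, cond in zip(sets, pool):
        if cond[4]:
            mined &= s
    for s, cond in zip(sets, pool):
        if not cond[4]:
            mined -= s
    scores = {}
    for tag in mined:
        total = 0.0
        for (lib_a, op, _f, lib_b, incl) in pool:
            if not incl:
                continue
            if op == "<":
                total += oracle_fold(counts, tag, lib_b, lib_a)
            else:
                total += oracle_fold(counts, tag, lib_a, lib_b)
        scores[tag] = total
    order = sorted(mined, key=lambda t: (-scores[t], t))
    return order[:top_n], sets
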