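"""Thin wrappers around edlib pairwise alignment used across modules.

Conventions: ``query`` is the reference-side sequence, ``target`` the
derived-side one.  In parsed alignment ops, ``=``/``X`` consume one base of
each, ``D`` consumes a target base only (insertion in the target) and ``I``
consumes a query base only (deletion from the target).
"""

from __future__ import annotations

import re

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def align_path(query: str, target: str, mode: str = "NW",
               k: int = -1) -> tuple[int, tuple[int, int], list[tuple[str, int]]]:
    """Align and return (edit_distance, target (start, end+1), cigar ops).

    mode "NW" is global; "HW" is infix (target ends free), used to locate a
    query inside a longer target.  Returns distance -1 when ``k`` is set and
    no alignment within ``k`` exists.
    """
    res = edlib.align(query, target, mode=mode, task="path", k=k)
    if res["editDistance"] < 0:
        return -1, (0, 0), []
    loc = res["locations"][0]
    ops = [(op, int(n)) for n, op in _CIGAR_RE.findall(res["cigar"])]
    return res["editDistance"], (loc[0], loc[1] + 1), _canonicalize(ops)


def _canonicalize(ops: list[tuple[str, int]]) -> list[tuple[str, int]]:
    """Rewrite adjacent insertion/deletion runs as mismatch columns.

    An adjacent I/D pair has the same edit cost as substitutions, and edlib
    may emit either; the substitution form avoids spurious frameshift calls
    downstream.
    """
    out: list[tuple[str, int]] = []
    for op, n in ops:
        while (n and out and out[-1][0] in "ID" and op in "ID"
               and out[-1][0] != op):
            prev_op, prev_n = out.pop()
            m = min(prev_n, n)
            if prev_n - m:
                out.append((prev_op, prev_n - m))
            if out and out[-1][0] == "X":
                out[-1] = ("X", out[-1][1] + m)
            else:
                out.append(("X", m))
            n -= m
        if n:
            if out and out[-1][0] == op:
                out[-1] = (op, out[-1][1] + n)
            else:
                out.append((op, n))
    return out


def normalize_paired_indels(query: str, target: str,
                            ops: list[tuple[str, int]], t_start: int = 0,
                            max_sep: int = 30) -> list[tuple[str, int]]:
    """Rewrite equal-length I/D pairs separated by <= max_sep columns as
    substitution columns when that does not raise the edit cost.

    Two nearby substitutions can be represented by an optimal alignment as
    an insertion plus a deletion; genuine compensating indel pairs are kept
    because their columnwise (ungapped) cost is higher.
    """
    out: list[tuple[str, int]] = []
    qi, ti = 0, t_start
    i = 0
    ops = list(ops)
    while i < len(ops):
        op, n = ops[i]
        if op in "ID":
            q2 = qi + (n if op == "I" else 0)
            t2 = ti + (n if op == "D" else 0)
            sep = 0
            j = i + 1
            while (j < len(ops) and ops[j][0] in "=XM"
                   and sep + ops[j][1] <= max_sep):
                sep += ops[j][1]
                q2 += ops[j][1]
                t2 += ops[j][1]
                j += 1
            if (j < len(ops) and ops[j][0] in "ID" and ops[j][0] != op
                    and ops[j][1] == n):
                q_end = q2 + (n if ops[j][0] == "I" else 0)
                t_end = t2 + (n if ops[j][0] == "D" else 0)
                seg_q = query[qi:q_end]
                seg_t = target[ti:t_end]
                if len(seg_q) == len(seg_t):
                    ham = sum(a != b for a, b in zip(seg_q, seg_t))
                    cost = 2 * n + sum(m for o, m in ops[i + 1 : j]
                                       if o == "X")
                    if ham <= cost:
                        for a, b in zip(seg_q, seg_t):
                            out.append(("=" if a == b else "X", 1))
                        qi, ti = q_end, t_end
                        i = j + 1
                        continue
        out.append((op, n))
        if op in "=XM":
            qi += n
            ti += n
        elif op == "I":
            qi += n
        else:
            ti += n
        i += 1
    merged: list[tuple[str, int]] = []
    for op, n in out:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return merged


def absorb_terminal_query_gaps(query: str, target: str, t0: int, t1: int,
                               ops: list[tuple[str, int]]
                               ) -> tuple[int, int, list[tuple[str, int]]]:
    """In an infix (HW) alignment, rewrite query-gap runs at either end of
    the path as aligned columns against the adjacent free target bases.

    A terminal ``I`` run costs its length; aligning those query bases
    column-by-column against the unused target flank costs no more, and
    avoids spurious terminal indel calls.
    """
    ops = list(ops)
    while ops and ops[0][0] == "I" and t0 >= ops[0][1]:
        n = ops.pop(0)[1]
        cols = [("=" if a == b else "X", 1)
                for a, b in zip(query[:n], target[t0 - n : t0])]
        ops = cols + ops
        t0 -= n
    while ops and ops[-1][0] == "I" and t1 + ops[-1][1] <= len(target):
        n = ops.pop()[1]
        q_tail = query[len(query) - n :]
        cols = [("=" if a == b else "X", 1)
                for a, b in zip(q_tail, target[t1 : t1 + n])]
        ops = ops + cols
        t1 += n
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return t0, t1, merged


def edit_distance(a: str, b: str, k: int = -1) -> int:
    return edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]


def project_target_onto_query(
    query: str, target: str, ops: list[tuple[str, int]], target_start: int = 0
) -> tuple[list[str], list[tuple[int, str]]]:
    """Per-query-position target bases plus insertions.

    Returns ``(proj, insertions)`` where ``proj[i]`` is the target base
    aligned to query position ``i`` ('-' for a deletion) and ``insertions``
    lists ``(query_pos, inserted_target_seq)`` for target-only runs, keyed by
    the query position *before which* the run sits.
    """
    proj = ["-"] * len(query)
    insertions: list[tuple[int, str]] = []
    qi, ti = 0, target_start
    for op, n in ops:
        if op in "=XM":
            for _ in range(n):
                proj[qi] = target[ti]
                qi += 1
                ti += 1
        elif op == "I":
            qi += n
        elif op == "D":
            insertions.append((qi, target[ti : ti + n]))
            ti += n
    return proj, insertions


def alignment_identity(ops: list[tuple[str, int]]) -> float:
    """Matches divided by alignment columns."""
    match = sum(n for op, n in ops if op == "=")
    total = sum(n for _, n in ops)
    return match / total if total else 0.0
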