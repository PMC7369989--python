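"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library's own code paths: motif scanning by
explicit window checks, alignment by exhaustive enumeration of all gapped
alignments with affine scoring, and interval membership by a quadratic
all-pairs scan.
"""

from __future__ import annotations

DIAG, UP, LEFT = 0, 1, 2


def brute_exxr(seq: str) -> list[int]:
    return [
        i
        for i in range(len(seq) - 3)
        if seq[i] == "E" and seq[i + 3] == "R"
    ]


def brute_cxg(seq: str) -> list[int]:
    return [
        i
        for i in range(len(seq) - 2)
        if seq[i] == "C" and seq[i + 2] == "G"
    ]


def enumerate_alignments(m: int, n: int):
    """All op sequences (DIAG/UP/LEFT) aligning m query and n ref residues."""
    stack = [((), 0, 0)]
    while stack:
        ops, i, j = stack.pop()
        if i == m and j == n:
            yield ops
            continue
        if i < m and j < n:
            stack.append((ops + (DIAG,), i + 1, j + 1))
        if i < m:
            stack.append((ops + (UP,), i + 1, j))
        if j < n:
            stack.append((ops + (LEFT,), i, j + 1))


def affine_score(a: str, b: str, ops, scheme) -> float:
    """Score an op sequence: gap of length k costs open + (k-1) * extend."""
    sub = scheme.submatrix
    score = 0.0
    i = j = 0
    prev = None
    for op in ops:
        if op == DIAG:
            score += sub[ord(a[i]) - 65, ord(b[j]) - 65]
            i += 1
            j += 1
        elif op == UP:
            score -= scheme.gap_extend if prev == UP else scheme.gap_open
            i += 1
        else:
            score -= scheme.gap_extend if prev == LEFT else scheme.gap_open
            j += 1
        prev = op
    return score


def best_alignment(a: str, b: str, scheme):
    """The optimal-score alignment preferred by right-to-left greedy choice.

    Among all optimal alignments, picks the one whose reversed op sequence is
    lexicographically greatest under the ranking diagonal > up > left — the
    same tie-break the production traceback applies.
    """
    rank = {DIAG: 2, UP: 1, LEFT: 0}
    best_key = None
    best_ops = None
    for ops in enumerate_alignments(len(a), len(b)):
        key = (affine_score(a, b, ops, scheme), tuple(rank[o] for o in reversed(ops)))
        if best_key is None or key > best_key:
            best_key = key
            best_ops = ops
    return best_ops, best_key[0]


def ops_of_result(result) -> tuple[int, ...]:
    """Recover the op sequence from an AlignmentResult's gapped strings."""
    ops = []
    for x, y in zip(result.aligned_query, result.aligned_ref):
        if x != "-" and y != "-":
            ops.append(DIAG)
        elif y == "-":
            ops.append(UP)
        else:
            ops.append(LEFT)
    return tuple(ops)


def brute_memberships(genes, clusters, overlap="any"):
    """Quadratic all-pairs interval membership check."""
    out = set()
    for g in genes:
        for c in clusters:
            if g.species_id != c.species_id or g.contig != c.contig:
                continue
            if overlap == "contained":
                hit = c.start <= g.start and g.end <= c.end
            else:
                hit = g.start <= c.end and c.start <= g.end
            if hit:
                out.add((g.species_id, g.gene_id, c.cluster_id))
    return out
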