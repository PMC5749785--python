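"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity from its definition (exhaustive
enumeration or plain dynamic programming), sharing no code path with the
implementation it checks.
"""

from __future__ import annotations

import itertools

from plastodecay import trees as t
from plastodecay.genestate import GAP, MATCH, MISMATCH
from plastodecay.plastome import revcomp

MISSING = {"?", "-"}


# ---------------------------------------------------------------------------
# Parsimony: exhaustive internal-state assignment
# ---------------------------------------------------------------------------

def _rooted_nodes_edges(tree: t.PhyloTree):
    root = (tree.root if tree.rooted
            else t.root_on_leaf_edge(tree, tree.leaf_labels()[0]).root)
    nodes, edges = [], []

    def walk(node, depth):
        nodes.append((node, depth))
        for child in node.children:
            edges.append((node, child, depth + 1))
            walk(child, depth + 1)

    walk(root, 0)
    return root, nodes, edges


def fitch_length_oracle(tree: t.PhyloTree, rows: dict[str, str]) -> int:
    """Minimum mutation count by enumerating every internal-state
    assignment (missing-data leaves are free as well)."""
    root, nodes, edges = _rooted_nodes_edges(tree)
    n_char = len(next(iter(rows.values())))
    total = 0
    for j in range(n_char):
        sym = {taxon: rows[taxon][j] for taxon in rows}
        alphabet = sorted({s for s in sym.values() if s not in MISSING})
        if len(alphabet) <= 1:
            continue
        fixed, free = {}, []
        for node, _ in nodes:
            if node.is_leaf and sym[node.label] not in MISSING:
                fixed[id(node)] = sym[node.label]
            else:
                free.append(node)
        best = None
        for combo in itertools.product(alphabet, repeat=len(free)):
            assign = dict(fixed)
            for node, state in zip(free, combo):
                assign[id(node)] = state
            cost = sum(1 for a, b, _ in edges
                       if assign[id(a)] != assign[id(b)])
            if best is None or cost < best:
                best = cost
        total += best
    return total


def acctran_oracle(tree_rooted: t.PhyloTree, column: dict[str, str]):
    """All-minimal-reconstruction enumeration for one character on a rooted
    tree; returns (min steps, lexicographically smallest sorted tuple of
    change depths). Depth of a change is the edge count from the root to
    the branch's child."""
    root, nodes, edges = _rooted_nodes_edges(tree_rooted)
    alphabet = sorted({s for s in column.values() if s not in MISSING})
    if len(alphabet) <= 1:
        return 0, ()
    fixed, free = {}, []
    for node, _ in nodes:
        if node.is_leaf and column[node.label] not in MISSING:
            fixed[id(node)] = column[node.label]
        else:
            free.append(node)
    best = None
    for combo in itertools.product(alphabet, repeat=len(free)):
        assign = dict(fixed)
        for node, state in zip(free, combo):
            assign[id(node)] = state
        depths = tuple(sorted(depth for a, b, depth in edges
                              if assign[id(a)] != assign[id(b)]))
        key = (len(depths), depths)
        if best is None or key < best:
            best = key
    return best


# ---------------------------------------------------------------------------
# Local alignment: plain-Python Smith-Waterman with identical scoring
# ---------------------------------------------------------------------------

def _sw_best_py(ref: str, query: list[str]):
    m, n = len(ref), len(query)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        row, prev = H[i], H[i - 1]
        rbase = ref[i - 1]
        for j in range(1, n + 1):
            qbase = query[j - 1]
            sub = MATCH if (rbase == qbase and rbase in "ACGT"
                            and qbase in "ACGT") else MISMATCH
            val = max(0, prev[j - 1] + sub, prev[j] + GAP, row[j - 1] + GAP)
            row[j] = val
            if val > best:          # strict >: first maximum in row-major
                best, bi, bj = val, i, j
    if best <= 0:
        return None
    pairs = []
    matches = 0
    i, j = bi, bj
    while i > 0 and j > 0 and H[i][j] > 0:
        sub = MATCH if (ref[i - 1] == query[j - 1] and ref[i - 1] in "ACGT"
                        and query[j - 1] in "ACGT") else MISMATCH
        if H[i][j] == H[i - 1][j - 1] + sub:
            pairs.append((i - 1, j - 1))
            matches += sub == MATCH
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] + GAP:
            pairs.append((i - 1, None))
            i -= 1
        else:
            pairs.append((None, j - 1))
            j -= 1
    pairs.reverse()
    return {"score": best, "ref_start": i, "ref_end": bi,
            "q_start": j, "q_end": bj, "matches": matches,
            "n_cols": len(pairs)}


def locate_gene_oracle(genome: str, ref: str, min_len=25, min_identity=0.70,
                       min_score=40, max_hits=50):
    """Greedy masked rescan with a dict-based SW; returns interval tuples
    (query_start, query_end, ref_start, ref_end, strand)."""
    out = []
    n = len(genome)
    for strand in "+-":
        text = genome if strand == "+" else revcomp(genome)
        work = list(text)
        for _ in range(max_hits):
            best = _sw_best_py(ref, work)
            if best is None or best["score"] < min_score:
                break
            js, je = best["q_start"], best["q_end"]
            identity = best["matches"] / best["n_cols"]
            if strand == "+":
                qs, qe = js, je
            else:
                qs, qe = n - je, n - js
            if best["n_cols"] >= min_len and identity >= min_identity:
                out.append((qs, qe, best["ref_start"], best["ref_end"],
                            strand))
            for x in range(js, je):
                work[x] = "x"
    return sorted(out)


# ---------------------------------------------------------------------------
# Repeats
# ---------------------------------------------------------------------------

def ssr_oracle(seq: str, thresholds: dict[int, int]):
    """Enumerate every (position, period) maximal perfect tandem run."""
    seq = seq.upper()
    n = len(seq)

    def minimal_period(unit):
        for p in range(1, len(unit)):
            if len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p):
                return p
        return len(unit)

    candidates = []
    for p, min_copies in sorted(thresholds.items()):
        for start in range(n - p):
            # maximal: cannot extend left
            if start >= 1 and seq[start - 1] == seq[start - 1 + p]:
                continue
            # grow the periodic stretch rightward
            stretch = p
            while start + stretch < n and \
                    seq[start + stretch] == seq[start + stretch - p]:
                stretch += 1
            if stretch < 2 * p:     # fewer than two full copies
                continue
            copies = stretch // p
            unit = seq[start:start + p]
            if copies >= min_copies and minimal_period(unit) == p \
                    and "N" not in unit:
                candidates.append((p, start, start + p * copies, unit,
                                   copies))
    # dedup: keep smallest-period run among overlapping reports
    candidates.sort(key=lambda c: (c[0], c[1]))
    kept = []
    for c in candidates:
        if not any(k[0] < c[0] and k[1] < c[2] and c[1] < k[2] for k in kept):
            kept.append(c)
    return sorted((start, end, unit, copies)
                  for _, start, end, unit, copies in kept)


def long_repeat_oracle(seq: str, min_len=30, h=3, min_identity=0.90):
    """All-diagonal exhaustive maximal-window enumeration (direct and
    palindromic), mirroring the published definition."""
    seq = seq.upper()
    n = len(seq)
    rc = revcomp(seq)

    def windows_on(mism):
        # exhaustive: every (lo, hi) window, checked for <= h mismatches
        # and literal non-extendability on both sides
        span = len(mism)
        prefix = [0]
        for bad in mism:
            prefix.append(prefix[-1] + bad)

        def count(lo, hi):  # mismatches in [lo, hi)
            return prefix[hi] - prefix[lo]

        out = set()
        lo = 0
        for lo in range(span):
            if mism[lo] and lo and not mism[lo - 1]:
                continue  # cheap skip: never optimal to start on a mismatch
            hi = lo
            while hi < span and count(lo, hi + 1) <= h:
                hi += 1
            if hi - lo < min_len:
                continue
            k = count(lo, hi)
            left_ext = lo > 0 and count(lo - 1, hi) <= h
            right_ext = hi < span and count(lo, hi + 1) <= h
            if left_ext or right_ext:
                continue
            if 1.0 - k / (hi - lo) >= min_identity:
                out.add((lo, hi, k))
        return out

    def best_per_group(windows):
        out, group = [], []
        for w in sorted(windows):
            if group and w[0] < max(x[1] for x in group):
                group.append(w)
            else:
                if group:
                    out.append(min(group,
                                   key=lambda x: (-(x[1] - x[0] - x[2]),
                                                  x[2], x[0])))
                group = [w]
        if group:
            out.append(min(group, key=lambda x: (-(x[1] - x[0] - x[2]),
                                                 x[2], x[0])))
        return out

    results = set()
    for d in range(1, n):
        span = n - d
        if span < min_len:
            break
        mism = [seq[i] != seq[i + d] or seq[i] == "N" for i in range(span)]
        for lo, hi, k in best_per_group(windows_on(mism)):
            results.add(("direct", (lo, hi), (lo + d, hi + d), k))
    pal = {}
    for d in range(-(n - 1), n):
        lo_t, hi_t = max(0, -d), min(n, n - d)
        if hi_t - lo_t < min_len:
            continue
        mism = [seq[i] != rc[i + d] or seq[i] == "N"
                for i in range(lo_t, hi_t)]
        for wlo, whi, k in best_per_group(windows_on(mism)):
            lo, hi = lo_t + wlo, lo_t + whi
            a = (lo, hi)
            b = (n - (hi + d), n - (lo + d))
            if a == b:
                continue
            first, second = sorted([a, b])
            pal.setdefault(("palindromic", first, second), k)
    # merge mirror palindromic windows overlapping in both intervals
    def overlaps(a, b):
        return a[0] < b[1] and b[0] < a[1]

    pal_hits = sorted(pal.items(),
                      key=lambda kv: (-((kv[0][2][1] - kv[0][2][0]) - kv[1]),
                                      kv[1], kv[0][1]))
    kept = []
    for (kind, a, b), k in pal_hits:
        if not any(overlaps(a, ka) and overlaps(b, kb)
                   for _, ka, kb in kept):
            kept.append((kind, a, b))
            results.add((kind, a, b, k))
    return results
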