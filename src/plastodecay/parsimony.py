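"""Maximum-parsimony engine.

Fitch length, exact search (exhaustive enumeration and branch-and-bound),
heuristic search (random addition + TBR), strict consensus, consistency and
retention indices, nonparametric bootstrap, and ACCTRAN character-change
mapping for unordered characters with unit costs.

Missing ``?`` and inapplicable ``-`` entries are treated as fully ambiguous
(the whole state alphabet) unless a matrix is built with ``gap_as_state``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from . import trees as _t
from ._rng import stream

MISSING = {"?", "-"}
_INF = (10 ** 9, ())


# ---------------------------------------------------------------------------
# Character matrix
# ---------------------------------------------------------------------------

class CharacterMatrix:
    """Rectangular taxa x characters matrix with unordered state alphabets.

    Parameters
    ----------
    rows:
        Mapping of taxon label to its character sequence (string or list of
        single-character state symbols).
    gap_as_state:
        When True, ``-`` is coded as an ordinary state instead of missing.
    """

    def __init__(self, rows: dict[str, Sequence[str]], gap_as_state: bool = False):
        if not rows:
            raise ValueError("empty matrix")
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise ValueError("matrix is not rectangular")
        self.taxa: list[str] = list(rows)
        self.gap_as_state = gap_as_state
        self.n_characters = lengths.pop()
        self._rows = {t: [str(s) for s in rows[t]] for t in self.taxa}

        self.alphabets: list[tuple[str, ...]] = []
        masks = np.zeros((len(self.taxa), self.n_characters), dtype=np.int64)
        for j in range(self.n_characters):
            observed = sorted({self._rows[t][j] for t in self.taxa}
                              - (MISSING - ({"-"} if gap_as_state else set())))
            alphabet = tuple(observed)
            self.alphabets.append(alphabet)
            full = (1 << max(len(alphabet), 1)) - 1
            for i, t in enumerate(self.taxa):
                sym = self._rows[t][j]
                if sym in MISSING and not (gap_as_state and sym == "-"):
                    masks[i, j] = full
                else:
                    masks[i, j] = 1 << alphabet.index(sym)
        self.masks = masks

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_alignment(cls, rows: dict[str, str], gap_as_state: bool = False,
                       normalize: bool = True) -> "CharacterMatrix":
        """Build from aligned nucleotide rows; ``N`` is coded as missing."""
        if normalize:
            rows = {t: s.upper().replace("N", "?") for t, s in rows.items()}
        return cls(rows, gap_as_state=gap_as_state)

    @classmethod
    def from_tsv(cls, path, gap_as_state: bool = False) -> "CharacterMatrix":
        """Read a TSV with a ``taxon`` column and one column per character."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        first = df.columns[0]
        rows = {r[first]: [r[c] for c in df.columns[1:]]
                for _, r in df.iterrows()}
        return cls(rows, gap_as_state=gap_as_state)

    @classmethod
    def from_nexus(cls, path, gap_as_state: bool = False) -> "CharacterMatrix":
        import dendropy

        mat = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
        rows = {}
        for taxon in mat.taxon_namespace:
            rows[taxon.label] = [str(c) for c in mat[taxon].symbols_as_list()]
        return cls(rows, gap_as_state=gap_as_state)

    # -- utilities -------------------------------------------------------
    def row(self, taxon: str) -> list[str]:
        return list(self._rows[taxon])

    def column(self, j: int) -> list[str]:
        return [self._rows[t][j] for t in self.taxa]

    def resample_characters(self, rng: np.random.Generator) -> "CharacterMatrix":
        """Bootstrap pseudoreplicate: characters drawn with replacement."""
        idx = rng.integers(0, self.n_characters, size=self.n_characters)
        rows = {t: [self._rows[t][j] for j in idx] for t in self.taxa}
        return CharacterMatrix(rows, gap_as_state=self.gap_as_state)

    def subset_taxa(self, taxa: Sequence[str]) -> "CharacterMatrix":
        return CharacterMatrix({t: self._rows[t] for t in taxa},
                               gap_as_state=self.gap_as_state)

    def to_nexus(self) -> str:
        symbols = sorted({s for a in self.alphabets for s in a})
        width = max(len(t) for t in self.taxa) + 2
        lines = ["#NEXUS", "", "BEGIN DATA;",
                 f"  DIMENSIONS NTAX={len(self.taxa)} NCHAR={self.n_characters};",
                 "  FORMAT DATATYPE=STANDARD SYMBOLS=\"{}\" MISSING=? GAP=-;"
                 .format("".join(symbols)),
                 "  MATRIX"]
        for t in self.taxa:
            name = t.replace(" ", "_")
            lines.append(f"    {name:<{width}}{''.join(self._rows[t])}")
        lines += ["  ;", "END;", ""]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Fitch length
# ---------------------------------------------------------------------------

def _binary_rooting(tree: _t.PhyloTree) -> _t.Node:
    """A strictly binary rooted view of the tree (Fitch needs binary nodes)."""
    root = tree.root
    if all(len(n.children) in (0, 2) for n in root.walk()):
        return root
    first_leaf = root.leaves()[0].label
    return _t.root_on_leaf_edge(tree, first_leaf).root


def _fitch_masks(root: _t.Node, leaf_masks: dict[str, np.ndarray],
                 n_char: int) -> tuple[np.ndarray, np.ndarray]:
    """Bottom-up Fitch pass; returns (per-character steps, root state sets)."""
    steps = np.zeros(n_char, dtype=np.int64)

    def down(node: _t.Node) -> np.ndarray:
        if node.is_leaf:
            return leaf_masks[node.label]
        cur = down(node.children[0])
        for child in node.children[1:]:
            other = down(child)
            inter = cur & other
            union_needed = inter == 0
            steps[union_needed] += 1
            cur = np.where(union_needed, cur | other, inter)
        return cur

    root_sets = down(root)
    return steps, root_sets


def fitch_length(tree: _t.PhyloTree, matrix: CharacterMatrix,
                 per_character: bool = False):
    """Minimum mutation count of ``matrix`` on ``tree`` (Fitch, unordered)."""
    tree_leaves = set(tree.leaf_labels())
    if tree_leaves != set(matrix.taxa):
        raise ValueError("tree and matrix leaf sets differ")
    leaf_masks = {t: matrix.masks[i] for i, t in enumerate(matrix.taxa)}
    root = _binary_rooting(tree)
    steps, _ = _fitch_masks(root, leaf_masks, matrix.n_characters)
    return steps if per_character else int(steps.sum())


# ---------------------------------------------------------------------------
# CI / RI
# ---------------------------------------------------------------------------

def _char_mgs(matrix: CharacterMatrix, tree: _t.PhyloTree) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-character (min steps m, observed steps s, max steps g)."""
    s = fitch_length(tree, matrix, per_character=True)
    m = np.zeros(matrix.n_characters, dtype=np.int64)
    g = np.zeros(matrix.n_characters, dtype=np.int64)
    for j in range(matrix.n_characters):
        counts: dict[str, int] = {}
        for t in matrix.taxa:
            sym = matrix._rows[t][j]
            if sym in MISSING and not (matrix.gap_as_state and sym == "-"):
                continue
            counts[sym] = counts.get(sym, 0) + 1
        if not counts:
            continue
        m[j] = len(counts) - 1
        g[j] = sum(counts.values()) - max(counts.values())
    return m, s, g


def ci_ri(matrix: CharacterMatrix, tree: _t.PhyloTree,
          informative_only: bool = False) -> tuple[float, Optional[float]]:
    """Consistency and retention indices on ``tree``.

    CI = sum(m)/sum(s) (1.0 when sum(s)=0); RI = (G-S)/(G-M), or None when
    G = M (undefined). With ``informative_only`` the sums run over
    parsimony-informative characters only (PAUP's alternative convention).
    """
    m, s, g = _char_mgs(matrix, tree)
    if informative_only:
        keep = g > m  # characters where homoplasy is even possible
        m, s, g = m[keep], s[keep], g[keep]
    M, S, G = int(m.sum()), int(s.sum()), int(g.sum())
    ci = 1.0 if S == 0 else M / S
    ri = None if G == M else (G - S) / (G - M)
    return ci, ri


# ---------------------------------------------------------------------------
# Tree search
# ---------------------------------------------------------------------------

@dataclass
class SearchResult:
    min_length: int
    trees: list[_t.PhyloTree]
    method: str
    ci: float = 0.0
    ri: Optional[float] = None
    n_trees_examined: int = 0


def _dedup(trees: Iterable[_t.PhyloTree]) -> list[_t.PhyloTree]:
    seen = set()
    out = []
    for tr in trees:
        key = tr.topology_key()
        if key not in seen:
            seen.add(key)
            out.append(tr)
    return out


def _addition_order(matrix: CharacterMatrix) -> list[str]:
    """Max-mini flavoured addition order: most conflicting taxa first."""
    taxa = matrix.taxa
    diff = {}
    for a, b in itertools.combinations(taxa, 2):
        ra, rb = matrix._rows[a], matrix._rows[b]
        d = sum(1 for x, y in zip(ra, rb)
                if x != y and x not in MISSING and y not in MISSING)
        diff[a] = diff.get(a, 0) + d
        diff[b] = diff.get(b, 0) + d
    return sorted(taxa, key=lambda t: (-diff.get(t, 0), taxa.index(t)))


def _rooted_base(order: Sequence[str]) -> _t.Node:
    """Three-leaf start, rooted on the first taxon's pendant edge."""
    return _t.Node(children=[
        _t.Node(label=order[0]),
        _t.Node(children=[_t.Node(label=order[1]), _t.Node(label=order[2])])])


def _insertion_edges(root: _t.Node) -> list[tuple[_t.Node, int]]:
    """Rooted-binary edges standing for distinct unrooted edges: the two
    root edges are one unrooted edge, so the first is excluded."""
    return [(parent, i) for parent, i in _t._edge_list(root)
            if not (parent is root and i == 0)]


def _unroot(root: _t.Node) -> _t.Node:
    """Collapse a degree-2 root into the conventional degree-3 form."""
    if len(root.children) != 2:
        return root
    a, b = root.children
    inner, leaf = (a, b) if a.children else (b, a)
    if not inner.children:
        return root  # two-leaf tree; leave as is
    return _t.Node(children=[leaf] + inner.children)


def _partial_length(root: _t.Node, leaf_masks: dict[str, np.ndarray],
                    n_char: int) -> int:
    steps, _ = _fitch_masks(root, leaf_masks, n_char)
    return int(steps.sum())


def _stepwise_addition(matrix: CharacterMatrix, order: Sequence[str],
                       leaf_masks: Optional[dict] = None) -> _t.PhyloTree:
    """Greedy stepwise-addition tree for an initial upper bound."""
    if leaf_masks is None:
        leaf_masks = {t: matrix.masks[i] for i, t in enumerate(matrix.taxa)}
    root = _rooted_base(order)
    for label in order[3:]:
        best = None
        n_edges = len(_insertion_edges(root))
        for idx in range(n_edges):
            cand = root.copy()
            parent, cidx = _insertion_edges(cand)[idx]
            _t._attach_on_edge(cand, parent, cidx, _t.Node(label=label))
            length = _partial_length(cand, leaf_masks, matrix.n_characters)
            if best is None or length < best[0]:
                best = (length, cand)
        root = best[1]
    return _t.PhyloTree(_unroot(root))


def _search_exhaustive(matrix: CharacterMatrix) -> SearchResult:
    best_len = None
    best: list[_t.PhyloTree] = []
    examined = 0
    for tree in _t.all_topologies(matrix.taxa):
        examined += 1
        length = fitch_length(tree, matrix)
        if best_len is None or length < best_len:
            best_len, best = length, [tree]
        elif length == best_len:
            best.append(tree)
    return SearchResult(best_len, _dedup(best), "exhaustive",
                        n_trees_examined=examined)


def _suffix_state_bounds(matrix: CharacterMatrix,
                         order: Sequence[str]) -> list[int]:
    """Lower bound on extra steps when only ``order[:k]`` are placed:
    every state seen solely among the remaining taxa must still arise at
    least once. Indexed by k (number of taxa already in the tree)."""
    per_taxon_states: dict[str, list[set]] = {}
    for taxon in order:
        row = matrix._rows[taxon]
        per_taxon_states[taxon] = [
            {row[j]} if row[j] not in MISSING or
            (matrix.gap_as_state and row[j] == "-") else set()
            for j in range(matrix.n_characters)]
    bounds = [0] * (len(order) + 1)
    for k in range(3, len(order)):
        extra = 0
        for j in range(matrix.n_characters):
            placed = set().union(*(per_taxon_states[t][j] for t in order[:k]))
            coming = set().union(*(per_taxon_states[t][j] for t in order[k:]))
            extra += len(coming - placed)
        bounds[k] = extra
    return bounds


def _search_branch_and_bound(matrix: CharacterMatrix) -> SearchResult:
    order = _addition_order(matrix)
    leaf_masks = {t: matrix.masks[i] for i, t in enumerate(matrix.taxa)}
    n_char = matrix.n_characters
    bound = fitch_length(_stepwise_addition(matrix, order, leaf_masks),
                         matrix)
    suffix = _suffix_state_bounds(matrix, order)
    state = {"best": bound, "trees": [], "examined": 0}

    def recurse(root: _t.Node, remaining: list[str]) -> None:
        length = _partial_length(root, leaf_masks, n_char)
        placed = len(matrix.taxa) - len(remaining)
        # adding taxa never removes steps; unseen states each cost >= 1
        if length + suffix[placed] > state["best"]:
            return
        if not remaining:
            state["examined"] += 1
            tree = _t.PhyloTree(_unroot(root.copy()))
            if length < state["best"]:
                state["best"], state["trees"] = length, [tree]
            elif length == state["best"]:
                state["trees"].append(tree)
            return
        label, rest = remaining[0], remaining[1:]
        for idx in range(len(_insertion_edges(root))):
            cand = root.copy()
            parent, cidx = _insertion_edges(cand)[idx]
            _t._attach_on_edge(cand, parent, cidx, _t.Node(label=label))
            recurse(cand, rest)

    recurse(_rooted_base(order), order[3:])
    return SearchResult(state["best"], _dedup(state["trees"]),
                        "branch_and_bound",
                        n_trees_examined=state["examined"])


# -- TBR -------------------------------------------------------------------

def _tree_to_graph(tree: _t.PhyloTree):
    edges: set[frozenset] = set()
    labels: dict[int, str] = {}
    counter = itertools.count()
    ids: dict[int, int] = {}

    def nid(node: _t.Node) -> int:
        if id(node) not in ids:
            ids[id(node)] = next(counter)
            if node.is_leaf:
                labels[ids[id(node)]] = node.label
        return ids[id(node)]

    for node in tree.root.walk():
        for child in node.children:
            edges.add(frozenset((nid(node), nid(child))))
    return edges, labels, next(counter)


def _graph_to_tree(edges: set[frozenset], labels: dict[int, str]) -> _t.PhyloTree:
    adj: dict[int, set[int]] = {}
    for e in edges:
        a, b = tuple(e)
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    start = next(n for n in adj if n in labels)

    def build(node: int, parent: Optional[int]) -> _t.Node:
        kids = [build(c, node) for c in sorted(adj[node]) if c != parent]
        if not kids:
            return _t.Node(label=labels[node])
        return _t.Node(children=kids)

    anchor_leaf = _t.Node(label=labels[start])
    neighbour = next(iter(adj[start]))
    rest = build(neighbour, start)
    children = rest.children if len(rest.children) > 1 else [rest]
    return _t.PhyloTree(_t.Node(children=[anchor_leaf] + children))


def _suppress_degree2(edges: set[frozenset], labels: dict[int, str]) -> None:
    changed = True
    while changed:
        changed = False
        adj: dict[int, set[int]] = {}
        for e in edges:
            a, b = tuple(e)
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        for node, nbrs in adj.items():
            if len(nbrs) == 2 and node not in labels:
                x, y = tuple(nbrs)
                edges.discard(frozenset((node, x)))
                edges.discard(frozenset((node, y)))
                edges.add(frozenset((x, y)))
                changed = True
                break


def tbr_neighbors(tree: _t.PhyloTree) -> Iterator[_t.PhyloTree]:
    """All tree-bisection-reconnection neighbours of an unrooted topology."""
    edges, labels, next_id = _tree_to_graph(tree)
    own_key = tree.topology_key()
    seen = {own_key}
    for cut in list(edges):
        remaining = set(edges) - {cut}
        adj: dict[int, set[int]] = {}
        for e in remaining:
            a, b = tuple(e)
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        u, v = tuple(cut)

        def component(seed: int) -> set[int]:
            comp, frontier = {seed}, [seed]
            while frontier:
                node = frontier.pop()
                for nbr in adj.get(node, ()):
                    if nbr not in comp:
                        comp.add(nbr)
                        frontier.append(nbr)
            return comp

        comp_u, comp_v = component(u), component(v)

        def prepare(comp: set[int]) -> tuple[set[frozenset], list]:
            sub = {e for e in remaining if e <= comp}
            lab = {n: labels[n] for n in comp if n in labels}
            _suppress_degree2(sub, lab)
            if not sub:  # single node component
                (node,) = [n for n in comp if n in labels] or [next(iter(comp))]
                return sub, [node]
            return sub, list(sub)

        sub_u, attach_u = prepare(comp_u)
        sub_v, attach_v = prepare(comp_v)
        counter = itertools.count(next_id)
        for a in attach_u:
            for b in attach_v:
                new_edges = set(sub_u) | set(sub_v)

                def endpoint(att, new_edges):
                    if isinstance(att, frozenset):
                        mid = next(counter)
                        x, y = tuple(att)
                        new_edges.discard(att)
                        new_edges.add(frozenset((x, mid)))
                        new_edges.add(frozenset((mid, y)))
                        return mid
                    return att

                pa = endpoint(a, new_edges)
                pb = endpoint(b, new_edges)
                new_edges.add(frozenset((pa, pb)))
                cand = _graph_to_tree(new_edges, labels)
                key = cand.topology_key()
                if key not in seen:
                    seen.add(key)
                    yield cand


def _search_heuristic(matrix: CharacterMatrix, n_replicates: int,
                      rng: np.random.Generator) -> SearchResult:
    best_len = None
    best: list[_t.PhyloTree] = []
    examined = 0
    taxa = list(matrix.taxa)
    for _ in range(n_replicates):
        order = list(taxa)
        rng.shuffle(order)
        current = _stepwise_addition(matrix, order)
        current_len = fitch_length(current, matrix)
        improving = True
        while improving:
            improving = False
            for cand in tbr_neighbors(current):
                examined += 1
                length = fitch_length(cand, matrix)
                if length < current_len:
                    current, current_len = cand, length
                    improving = True
                    break
        if best_len is None or current_len < best_len:
            best_len, best = current_len, [current]
        elif current_len == best_len:
            best.append(current)
        # collect co-optimal neighbours at the local optimum
        for cand in tbr_neighbors(current):
            if fitch_length(cand, matrix) == best_len:
                best.append(cand)
    return SearchResult(best_len, _dedup(best), "heuristic",
                        n_trees_examined=examined)


def search_mp(matrix: CharacterMatrix, method: str = "branch_and_bound",
              seed: int = 0, n_replicates: int = 20) -> SearchResult:
    """Find all most-parsimonious topologies for ``matrix``.

    ``exhaustive`` and ``branch_and_bound`` guarantee the global optimum;
    the heuristic runs ``n_replicates`` random-addition replicates with TBR
    branch swapping.
    """
    n = len(matrix.taxa)
    if n < 4:
        raise ValueError("need at least 4 taxa for a tree search")
    if method == "exhaustive":
        if n > 9:
            raise ValueError("exhaustive search limited to 9 taxa; "
                             "use branch_and_bound or heuristic")
        result = _search_exhaustive(matrix)
    elif method in ("branch_and_bound", "bb"):
        if n > 16:
            raise ValueError("branch_and_bound limited to 16 taxa; "
                             "use method='heuristic'")
        result = _search_branch_and_bound(matrix)
    elif method == "heuristic":
        result = _search_heuristic(matrix, n_replicates,
                                   stream(seed, "search_mp.heuristic"))
    else:
        raise ValueError(f"unknown search method {method!r}")
    result.ci, result.ri = ci_ri(matrix, result.trees[0])
    return result


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(matrix: CharacterMatrix, n_reps: int = 100,
                      method: str = "branch_and_bound", seed: int = 0,
                      n_replicates: int = 5) -> dict[frozenset, float]:
    """Bipartition support (%) over character-resampling pseudoreplicates.

    A bipartition scores in a replicate when the strict consensus of that
    replicate's MP trees contains it.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = stream(seed, "bootstrap_support")
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        boot = matrix.resample_characters(rng)
        res = search_mp(boot, method=method, seed=int(rng.integers(2 ** 31)),
                        n_replicates=n_replicates)
        consensus = _t.strict_consensus(res.trees)
        for split in consensus.splits():
            counts[split] = counts.get(split, 0) + 1
    return {split: 100.0 * c / n_reps for split, c in counts.items()}


# ---------------------------------------------------------------------------
# ACCTRAN change mapping
# ---------------------------------------------------------------------------

@dataclass
class CharacterChange:
    character: int
    branch: frozenset          # leaf set below the branch
    branch_name: str
    from_state: str
    to_state: str
    depth: int                 # edges from the root to the branch's child


def _acctran_column(root: _t.Node, leaf_mask: dict[str, int],
                    alphabet: tuple[str, ...], character: int) -> list[CharacterChange]:
    """Minimal reconstruction with changes packed as rootward as possible.

    Among all minimum-change assignments the one minimizing the ascending
    sorted tuple of change depths (lexicographic comparison) is selected;
    ties between states resolve to the lower state index. Reversals near
    the root therefore beat parallel gains deeper in the tree.
    """
    k = len(alphabet)
    if k <= 1:
        return []
    states = range(k)
    cost: dict[int, list] = {}
    choice: dict[int, list] = {}

    def down(node: _t.Node, depth: int) -> None:
        if node.is_leaf:
            mask = leaf_mask[node.label]
            cost[id(node)] = [(0, ()) if (mask >> s) & 1 else _INF
                              for s in states]
            return
        for child in node.children:
            down(child, depth + 1)
        node_cost, node_choice = [], []
        for s in states:
            total_steps, merged = 0, []
            picks = []
            for child in node.children:
                best = None
                best_t = None
                for t in states:
                    cs, ct = cost[id(child)][t]
                    if cs >= _INF[0]:
                        continue
                    if t != s:
                        cand = (cs + 1, tuple(sorted(ct + (depth + 1,))))
                    else:
                        cand = (cs, ct)
                    if best is None or cand < best:
                        best, best_t = cand, t
                if best is None:
                    best, best_t = _INF, None
                total_steps += best[0]
                merged.extend(best[1])
                picks.append(best_t)
            node_cost.append((total_steps, tuple(sorted(merged))))
            node_choice.append(picks)
        cost[id(node)] = node_cost
        choice[id(node)] = node_choice

    down(root, 0)
    root_costs = cost[id(root)]
    root_state = min(states, key=lambda s: (root_costs[s], s))

    changes: list[CharacterChange] = []

    def up(node: _t.Node, state: int, depth: int) -> None:
        if node.is_leaf:
            return
        for child, child_state in zip(node.children, choice[id(node)][state]):
            if child_state != state:
                below = frozenset(n.label for n in child.leaves())
                name = (child.label if child.is_leaf
                        else "{" + ",".join(sorted(below)) + "}")
                changes.append(CharacterChange(
                    character, below, name, alphabet[state],
                    alphabet[child_state], depth + 1))
            up(child, child_state, depth + 1)

    up(root, root_state, 0)
    return changes


def acctran_map(tree: _t.PhyloTree, matrix: CharacterMatrix,
                outgroup: Optional[str] = None) -> list[list[CharacterChange]]:
    """Per-character ACCTRAN change lists on a tree rooted on ``outgroup``."""
    if outgroup is not None:
        rooted = _t.root_on_outgroup(tree, outgroup)
    elif tree.rooted:
        rooted = tree
    else:
        raise ValueError("an outgroup is required to root the tree")
    if set(rooted.leaf_labels()) != set(matrix.taxa):
        raise ValueError("tree and matrix leaf sets differ")
    out = []
    for j in range(matrix.n_characters):
        leaf_mask = {t: int(matrix.masks[i, j]) for i, t in enumerate(matrix.taxa)}
        out.append(_acctran_column(rooted.root, leaf_mask,
                                   matrix.alphabets[j], j))
    return out
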