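"""Independent brute-force oracles used by the tests.

Everything here is written against the underlying mathematics only — plain
Python lists, exact ``math.fsum`` accumulation, exhaustive enumeration —
and never calls into the package's learners, so agreement between the two
routes is meaningful.
"""

from __future__ import annotations

import math
from itertools import product


def half_log_ratio(wp: float, wn: float, eps: float = 1.0) -> float:
    return 0.5 * math.log((wp + eps) / (wn + eps))


class OracleNode:
    """Prediction node: additive value plus attached splits."""

    def __init__(self, value: float):
        self.value = value
        self.splits: list[tuple[int, float, "OracleNode", "OracleNode"]] = []


def oracle_fit_adtree(X, y, item_ids, iterations: int, eps: float = 1.0) -> OracleNode:
    """Reference boosting loop with exhaustive candidate enumeration.

    ``X``: list of score rows, ``y``: ±1 labels.  Candidates are every
    (prediction node, item, midpoint-threshold) triple; Z is computed by
    formula with fsum; ties resolve to lowest item id, lowest threshold,
    earliest-created node.
    """
    n = len(y)
    w = [1.0] * n
    wp = math.fsum(w[i] for i in range(n) if y[i] > 0)
    wn = math.fsum(w[i] for i in range(n) if y[i] < 0)
    root_val = half_log_ratio(wp, wn, eps)
    w = [w[i] * math.exp(-y[i] * root_val) for i in range(n)]
    root = OracleNode(root_val)
    nodes: list[tuple[OracleNode, list[int]]] = [(root, list(range(n)))]

    for _ in range(iterations):
        total = math.fsum(w)
        candidates = []
        for node_idx, (_, reach) in enumerate(nodes):
            if not reach:
                continue
            w_in = math.fsum(w[i] for i in reach)
            w_out = total - w_in
            for j, item_id in enumerate(item_ids):
                vals = sorted({X[i][j] for i in reach})
                for lo, hi in zip(vals, vals[1:]):
                    thr = (lo + hi) / 2.0
                    low = [i for i in reach if X[i][j] < thr]
                    high = [i for i in reach if X[i][j] >= thr]
                    wpl = math.fsum(w[i] for i in low if y[i] > 0)
                    wnl = math.fsum(w[i] for i in low if y[i] < 0)
                    wph = math.fsum(w[i] for i in high if y[i] > 0)
                    wnh = math.fsum(w[i] for i in high if y[i] < 0)
                    z = 2.0 * (math.sqrt(wpl * wnl) + math.sqrt(wph * wnh)) + w_out
                    candidates.append(
                        (z, (item_id, thr, node_idx), j, low, high, wpl, wnl, wph, wnh)
                    )
        if not candidates:
            break
        z_min = min(c[0] for c in candidates)
        tol = 1e-9 * max(1.0, abs(z_min))
        best = min((c for c in candidates if c[0] <= z_min + tol), key=lambda c: c[1])
        _, (item_id, thr, node_idx), j, low, high, wpl, wnl, wph, wnh = best
        lo_node = OracleNode(half_log_ratio(wpl, wnl, eps))
        hi_node = OracleNode(half_log_ratio(wph, wnh, eps))
        nodes[node_idx][0].splits.append((item_id, thr, lo_node, hi_node))
        for i in low:
            w[i] *= math.exp(-y[i] * lo_node.value)
        for i in high:
            w[i] *= math.exp(-y[i] * hi_node.value)
        nodes.append((lo_node, low))
        nodes.append((hi_node, high))
    return root


def oracle_predict(node: OracleNode, x: dict[int, float]) -> float:
    """Path-enumeration scorer: sum every reached prediction value."""
    total = node.value
    for item_id, thr, lo, hi in node.splits:
        total += oracle_predict(lo if x[item_id] < thr else hi, x)
    return total


def same_tree(oracle: OracleNode, node, rtol: float = 1e-9) -> bool:
    """Structural equality between an oracle tree and a fitted model node."""
    if not math.isclose(oracle.value, node.value, rel_tol=rtol, abs_tol=1e-12):
        return False
    if len(oracle.splits) != len(node.children):
        return False
    for (item_id, thr, lo, hi), sp in zip(oracle.splits, node.children):
        if sp.item_id != item_id or sp.threshold != thr:
            return False
        if not (same_tree(lo, sp.low_child, rtol) and same_tree(hi, sp.high_child, rtol)):
            return False
    return True


def oracle_exponential_loss(root: OracleNode, X, y, item_ids) -> float:
    rows = [dict(zip(item_ids, row)) for row in X]
    return math.fsum(math.exp(-yi * oracle_predict(root, xi)) for xi, yi in zip(rows, y))


def oracle_best_stump_errors(X, y) -> int:
    """Exhaustive minimum training errors over all stumps (including the
    constant majority stump)."""
    n = len(y)
    n_pos = sum(1 for v in y if v > 0)
    best = min(n_pos, n - n_pos)
    n_items = len(X[0]) if n else 0
    for j in range(n_items):
        vals = sorted({X[i][j] for i in range(n)})
        for lo, hi in zip(vals, vals[1:]):
            thr = (lo + hi) / 2.0
            for lab_low, lab_high in product((-1, 1), repeat=2):
                err = sum(
                    1
                    for i in range(n)
                    if (lab_low if X[i][j] < thr else lab_high) != y[i]
                )
                best = min(best, err)
    return best


def oracle_best_oner_errors(X, y) -> int:
    """Exhaustive minimum training errors over one-attribute value rules."""
    n = len(y)
    best = None
    for j in range(len(X[0])):
        err = 0
        for v in {X[i][j] for i in range(n)}:
            pos = sum(1 for i in range(n) if X[i][j] == v and y[i] > 0)
            neg = sum(1 for i in range(n) if X[i][j] == v and y[i] < 0)
            err += min(pos, neg)
        best = err if best is None else min(best, err)
    return best


def enumerate_compositions(m: int, total: int) -> list[tuple[int, ...]]:
    """All score vectors in {0,1,2}^m summing to ``total``."""
    return [c for c in product((0, 1, 2), repeat=m) if sum(c) == total]
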