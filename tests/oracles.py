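"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package's vectorised paths: path
enumeration is a recursive DFS, geometry uses arccos/normal-vector
constructions, and the attention oracle is a plain per-path Python loop.
"""

import numpy as np


def dfs_simple_paths(bonds, n_atoms, k):
    """All directed simple paths with exactly k edges, by recursive DFS."""
    adj = {i: set() for i in range(n_atoms)}
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)

    out = []

    def extend(path):
        if len(path) == k + 1:
            out.append(tuple(path))
            return
        for nxt in adj[path[-1]]:
            if nxt not in path:
                extend(path + [nxt])

    for start in range(n_atoms):
        extend([start])
    return sorted(out)


def distance_oracle(positions, i, j):
    return float(np.sqrt(sum((positions[i][c] - positions[j][c]) ** 2 for c in range(3))))


def angle_oracle(positions, i, m, j):
    u = positions[i] - positions[m]
    v = positions[j] - positions[m]
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def dihedral_oracle(positions, i, a, b, j):
    """Signed dihedral via plane normals and an arccos + sign construction."""
    b0 = positions[a] - positions[i]
    b1 = positions[b] - positions[a]
    b2 = positions[j] - positions[b]
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    c = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    phi = np.arccos(np.clip(c, -1.0, 1.0))
    if np.dot(np.cross(n1, n2), b1) < 0:
        phi = -phi
    return float(phi)


def dense_attention_oracle(params_hop, h, paths, basis, k, cfg, edge_type=None):
    """Dense per-path loop over the k-hop attention definition.

    Returns (scores, weights, pre-mix hop output) with the same conventions
    as ffinet.model.khop_attention.
    """
    from ffinet.model import positional_encoding

    n, hid = h.shape
    H = cfg.n_heads
    dh = hid // H
    hp = h * positional_encoding(k, hid)
    P = len(paths)
    e = np.zeros((P, H))
    for pi, p in enumerate(paths):
        for head in range(H):
            sl = slice(head * dh, (head + 1) * dh)
            s = np.zeros(dh)
            for pos, atom in enumerate(p):
                s = s + hp[atom, sl] @ params_hop["W_r"][pos, head]
            if k == 1:
                if edge_type is not None and edge_type[pi] == 1:
                    z = params_hop["W_k_n"][head] @ basis[pi, 2:]
                else:
                    z = params_hop["W_k_b"][head] @ basis[pi, :2]
            else:
                z = params_hop["W_k"][head] @ basis[pi]
            v = s * z
            v = np.where(v >= 0, v, cfg.leaky_slope * v)
            e[pi, head] = params_hop["a"][head] @ v
    alpha = np.zeros_like(e)
    for tgt in {p[0] for p in paths}:
        rows = [pi for pi, p in enumerate(paths) if p[0] == tgt]
        ex = np.exp(e[rows] - e[rows].max(axis=0))
        alpha[rows] = ex / ex.sum(axis=0)
    o = np.zeros((n, H, dh))
    for pi, p in enumerate(paths):
        for head in range(H):
            sl = slice(head * dh, (head + 1) * dh)
            o[p[0], head] += alpha[pi, head] * (hp[p[-1], sl] @ params_hop["W_r"][k, head])
    return e, alpha, o.reshape(n, hid)


def roc_auc_oracle(labels, scores):
    """Brute force over all positive/negative pairs (ties count 1/2)."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_connected_graph(rng, n_max=12):
    """Random connected simple graph: spanning tree + random extra edges."""
    n = int(rng.integers(2, n_max + 1))
    edges = set()
    for v in range(1, n):
        u = int(rng.integers(v))
        edges.add((u, v))
    n_extra = int(rng.integers(0, n))
    for _ in range(n_extra):
        u, v = rng.choice(n, size=2, replace=False)
        edges.add((min(u, v), max(u, v)))
    return sorted(edges), n
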