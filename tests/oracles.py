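"""Independent reference implementations used only to check the package.

Each oracle is written against the mathematical definition, by a
different algorithm than the implementation it checks: per-bit loops for
Tanimoto, all-pairs recursive path search on an adjacency list for path
enumeration, a full-matrix Gotoh DP for local alignment, exact rational
pair counting for AUC and an explicit threshold sweep for AUPR.
"""
from __future__ import annotations

from fractions import Fraction

from Bio.Align import substitution_matrices


def tanimoto_bitloop(bits_a, bits_b) -> float:
    """Per-bit loop over two equal-length 0/1 sequences."""
    a = b = ab = 0
    for x, y in zip(bits_a, bits_b, strict=True):
        a += int(x)
        b += int(y)
        ab += int(x) and int(y)
    if a == 0 and b == 0:
        return 1.0
    return ab / (a + b - ab)


def all_paths_dfs(atom_tokens: dict[int, str], bonds: dict[tuple[int, int], str],
                  max_atoms: int = 7, min_atoms: int = 2) -> set[str]:
    """Enumerate canonical linear paths from an explicit adjacency list.

    ``atom_tokens`` maps atom index -> token; ``bonds`` maps unordered
    index pairs (i < j) -> bond token. Searches every ordered pair of
    endpoints for simple paths, then canonicalizes; quadratic and slow,
    which is fine for <= 12-atom fixtures.
    """
    adj: dict[int, list[int]] = {i: [] for i in atom_tokens}
    for (i, j) in bonds:
        adj[i].append(j)
        adj[j].append(i)

    def bond_tok(i, j):
        return bonds[(i, j) if i < j else (j, i)]

    found: set[str] = set()

    def walk(path: list[int]):
        if len(path) >= min_atoms:
            toks = [atom_tokens[path[0]]]
            for a, c in zip(path, path[1:]):
                toks.append(bond_tok(a, c))
                toks.append(atom_tokens[c])
            s = "".join(toks)
            found.add(min(s, "".join(reversed(toks))))
        if len(path) == max_atoms:
            return
        for nxt in adj[path[-1]]:
            if nxt not in path:
                path.append(nxt)
                walk(path)
                path.pop()

    for start in atom_tokens:
        walk([start])
    return found


def rdkit_adjacency(mol):
    """Adjacency-list view of an RDKit molecule in the path token alphabet
    (heavy atoms only), for feeding :func:`all_paths_dfs`."""
    from rdkit import Chem

    bond_tok = {Chem.BondType.SINGLE: "-", Chem.BondType.DOUBLE: "=",
                Chem.BondType.TRIPLE: "#", Chem.BondType.AROMATIC: ":"}
    atoms = {}
    for a in mol.GetAtoms():
        if a.GetAtomicNum() == 1:
            continue
        t = a.GetSymbol().lower() if a.GetIsAromatic() else a.GetSymbol()
        q = a.GetFormalCharge()
        if q > 0:
            t += "+" if q == 1 else f"+{q}"
        elif q < 0:
            t += "-" if q == -1 else f"{q}"
        atoms[a.GetIdx()] = t
    bonds = {}
    for bd in mol.GetBonds():
        i, j = bd.GetBeginAtomIdx(), bd.GetEndAtomIdx()
        if i in atoms and j in atoms:
            bonds[(min(i, j), max(i, j))] = bond_tok[bd.GetBondType()]
    return atoms, bonds


def blosum62_x0():
    """BLOSUM62 lookup with X scoring 0 against everything."""
    mat = substitution_matrices.load("BLOSUM62")
    def score(a: str, c: str) -> float:
        if a == "X" or c == "X":
            return 0.0
        return float(mat[a][c])
    return score


def gotoh_local(seq_a: str, seq_b: str, gap_open: float = 10.0,
                gap_extend: float = 1.0, score=None) -> float:
    """Full-matrix affine-gap local alignment DP (Gotoh three-state).

    A gap of length L costs ``gap_open + gap_extend * L``; the score of
    the empty alignment is 0.
    """
    if score is None:
        score = blosum62_x0()
    n, m = len(seq_a), len(seq_b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in seq_a (move along b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in seq_b
    best = 0.0
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + score(seq_a[i - 1], seq_b[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def auc_pair_count(scores, labels) -> Fraction:
    """Exact Mann-Whitney AUC by comparing every positive/negative pair."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = Fraction(0)
    for p in pos:
        for q in neg:
            if p > q:
                total += 1
            elif p == q:
                total += Fraction(1, 2)
    return total / (len(pos) * len(neg))


def aupr_threshold_sweep(scores, labels) -> float:
    """AUPR by explicit sweep over every distinct score threshold,
    step-interpolating precision over recall increments."""
    n_pos = sum(1 for l in labels if l)
    pts = []  # (recall, precision) at each threshold, descending
    for thr in sorted(set(scores), reverse=True):
        tp = sum(1 for s, l in zip(scores, labels) if s >= thr and l)
        fp = sum(1 for s, l in zip(scores, labels) if s >= thr and not l)
        pts.append((tp / n_pos, tp / (tp + fp)))
    area, prev_r = 0.0, 0.0
    for r, p in pts:
        area += (r - prev_r) * p
        prev_r = r
    return area
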