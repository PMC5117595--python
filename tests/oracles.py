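"""Independent test-side oracles.

The kinship oracle computes coefficients of kinship by enumerating
ancestral paths (Wright's path-counting rule) rather than by the tabular
recursion the package uses, so the two can be compared as genuinely
different algorithms.
"""

from __future__ import annotations

from pedvc.pedio import Pedigree


def _ascending_paths(ped: Pedigree, start: str):
    """All simple ascending paths (node lists) from ``start`` following
    parent links, including the trivial path [start]."""
    paths = []

    def walk(path):
        paths.append(list(path))
        for pid in ped.parents(path[-1]):
            if pid is not None and pid not in path:
                walk(path + [pid])

    walk([start])
    return paths


def kinship_path_counting(ped: Pedigree, i: str, j: str) -> float:
    """Coefficient of kinship by summing (1/2)^(n_i + n_j + 1) (1 + F_A)
    over all pairs of ascending paths from i and j that meet only at their
    shared common ancestor A."""
    if i == j:
        return 0.5 * (1.0 + inbreeding_path_counting(ped, i))
    total = 0.0
    paths_i = _ascending_paths(ped, i)
    paths_j = _ascending_paths(ped, j)
    for pi in paths_i:
        for pj in paths_j:
            if pi[-1] != pj[-1]:
                continue
            a = pi[-1]
            # the two paths may share no node other than the ancestor
            if set(pi[:-1]) & set(pj):
                continue
            if set(pj[:-1]) & set(pi):
                continue
            n = (len(pi) - 1) + (len(pj) - 1)
            total += 0.5 ** (n + 1) * (1.0 + inbreeding_path_counting(ped, a))
    return total


def inbreeding_path_counting(ped: Pedigree, iid: str) -> float:
    """F_i = kinship(father, mother), itself by path counting."""
    fid, mid = ped.parents(iid)
    if fid is None or mid is None:
        return 0.0
    return kinship_path_counting(ped, fid, mid)


def additive_path_counting(ped: Pedigree, i: str, j: str) -> float:
    """Additive relationship a_ij = 2 * kinship (diagonal: 1 + F)."""
    if i == j:
        return 1.0 + inbreeding_path_counting(ped, i)
    return 2.0 * kinship_path_counting(ped, i, j)
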