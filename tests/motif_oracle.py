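"""Brute-force motif participation counts by exhaustive tuple enumeration."""

from itertools import combinations, permutations

import pandas as pd


def brute_force_motifs(edges: set[tuple[str, str]], nodes: list[str]):
    """O(n^3)/O(n^4) enumeration of FFL, 3-chain and diamond participation.

    FFL: ordered distinct (a, b, c) with a->b, a->c, b->c. 3-chain: ordered
    distinct (a, b, c) with a->b, b->c. Diamond: distinct (a, {b, c}, d)
    with a->b, a->c, b->d, c->d and the mid pair unordered.
    """
    ffl = {n: 0 for n in nodes}
    chain = {n: 0 for n in nodes}
    diamond = {n: 0 for n in nodes}
    for a, b, c in permutations(nodes, 3):
        if (a, b) in edges and (b, c) in edges:
            chain[a] += 1
            chain[b] += 1
            chain[c] += 1
            if (a, c) in edges:
                ffl[a] += 1
                ffl[b] += 1
                ffl[c] += 1
    for a in nodes:
        for b, c in combinations([n for n in nodes if n != a], 2):
            if (a, b) in edges and (a, c) in edges:
                for d in nodes:
                    if d in (a, b, c):
                        continue
                    if (b, d) in edges and (c, d) in edges:
                        diamond[a] += 1
                        diamond[b] += 1
                        diamond[c] += 1
                        diamond[d] += 1
    return (
        pd.Series(ffl),
        pd.Series(diamond),
        pd.Series(chain),
    )
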