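"""Independent small-scale oracles shared by the unit and acceptance tests.

These deliberately avoid the package's own computational paths: rational
arithmetic for the exact HWE test, allele-drop Monte Carlo for pedigree
relatedness.
"""

import math

import numpy as np

from ducksel.simdata import Pedigree, UNKNOWN


def hwe_bruteforce(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p-value via rational arithmetic over every configuration."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_a, 2 * n - n_a)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        num = (
            math.factorial(n) * 2**h * math.factorial(rare) * math.factorial(2 * n - rare)
        )
        den = (
            math.factorial(h) * math.factorial(hom_rare) * math.factorial(hom_common)
            * math.factorial(2 * n)
        )
        probs[h] = num / den
    total = sum(probs.values())
    obs = probs[n_Aa] / total
    return sum(p / total for p in probs.values() if p / total <= obs * (1 + 1e-12))


def gene_drop_relationship(ped: Pedigree, n_drops: int, seed: int = 0) -> np.ndarray:
    """Average realized additive relationship from Monte-Carlo allele drops.

    Founders get unique allele labels; alleles descend by independent fair
    picks; the additive relationship is twice the average IBD probability of
    a random allele pair.
    """
    rng = np.random.default_rng(seed)
    ids = ped.ids
    alleles = {}
    next_label = 0
    for ind, sire, dam in ped.records:
        pair = np.empty((2, n_drops), dtype=np.int64)
        for slot, parent in enumerate((sire, dam)):
            if parent == UNKNOWN:
                pair[slot] = next_label
                next_label += 1
            else:
                pick = rng.integers(0, 2, size=n_drops)
                pair[slot] = alleles[parent][pick, np.arange(n_drops)]
        alleles[ind] = pair
    n = len(ids)
    A = np.zeros((n, n))
    for a, ia in enumerate(ids):
        for b, ib in enumerate(ids[: a + 1]):
            x, y = alleles[ia], alleles[ib]
            ibd = sum((x[i] == y[j]).mean() for i in range(2) for j in range(2)) / 4.0
            A[a, b] = A[b, a] = 2 * ibd
    return A


THREE_GENERATION_PEDIGREE = Pedigree([
    ("f1", UNKNOWN, UNKNOWN), ("f2", UNKNOWN, UNKNOWN),
    ("f3", UNKNOWN, UNKNOWN), ("f4", UNKNOWN, UNKNOWN),
    ("a", "f1", "f2"), ("b", "f1", "f2"), ("c", "f3", "f4"),
    ("x", "a", "c"), ("y", "b", "c"), ("z", "x", "y"),
])
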