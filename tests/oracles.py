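"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: folding enumerates
every nested structure explicitly, the uORF/TOP enumerators walk codons by
index, and the ANOVA oracles compute sums of squares directly (or go
through statsmodels' linear-model route).
"""

import numpy as np

PAIR_E = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}
STOPS = {"UAA", "UAG", "UGA"}


def enumerate_structures(seq, i=None, j=None):
    """Yield the energy of every nested structure of seq[i..j] (inclusive),
    with hairpin loops of >= 3 unpaired nt. Exponential; use only n <= ~14."""
    if i is None:
        i, j = 0, len(seq) - 1
    if i > j:
        yield 0.0
        return
    # case 1: i unpaired
    yield from enumerate_structures(seq, i + 1, j)
    # case 2: i paired with k
    for k in range(i + 4, j + 1):
        e = PAIR_E.get((seq[i], seq[k]))
        if e is None:
            continue
        for inner in enumerate_structures(seq, i + 1, k - 1):
            for outer in enumerate_structures(seq, k + 1, j):
                yield e + inner + outer


def brute_min_energy(seq: str) -> float:
    return min(enumerate_structures(seq))


def brute_uorfs(utr5: str, min_codons: int = 2):
    """All (start, end) uORFs by explicit codon walking."""
    found = []
    for s in range(len(utr5) - 2):
        if utr5[s : s + 3] != "AUG":
            continue
        p = s + 3
        while p + 3 <= len(utr5):
            if utr5[p : p + 3] in STOPS:
                if (p + 3 - s) // 3 >= min_codons:
                    found.append((s, p + 3))
                break
            p += 3
    return found


def brute_top(leader: str, min_tract: int = 4) -> bool:
    if not leader.startswith("C"):
        return False
    k = 1
    while k < len(leader) and leader[k] in ("C", "U"):
        k += 1
    return (k - 1) >= min_tract


def oneway_f_oracle(samples: list[np.ndarray]) -> tuple[float, int, int]:
    """One-way ANOVA F by direct sums of squares."""
    all_vals = np.concatenate(samples)
    grand = all_vals.mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b = len(samples) - 1
    df_w = len(all_vals) - len(samples)
    return (ssb / df_b) / (ssw / df_w), df_b, df_w


def twoway_f_oracle(table: np.ndarray):
    """Two-way ANOVA without replication via statsmodels' linear-model route."""
    import pandas as pd
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    r, c = table.shape
    df = pd.DataFrame(
        {
            "y": table.ravel(),
            "row": np.repeat(np.arange(r), c).astype(str),
            "col": np.tile(np.arange(c), r).astype(str),
        }
    )
    fit = ols("y ~ C(row) + C(col)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    return float(tab.loc["C(row)", "F"]), float(tab.loc["C(col)", "F"])
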