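"""Independent brute-force oracles for the metric definitions.

Everything here is written from the definitions in plain Python loops and
dictionaries, deliberately sharing no code with the package (the genetic
code is rebuilt directly from Biopython's table).  These are the reference
implementations the package must agree with.
"""
from __future__ import annotations

import math

from Bio.Data import CodonTable

BASES = "TCAG"
_TABLE = CodonTable.unambiguous_dna_by_id[11]
STOPS = set(_TABLE.stop_codons)
AA_OF = dict(_TABLE.forward_table)

FAMILIES: dict[str, list[str]] = {}
for _c, _aa in AA_OF.items():
    FAMILIES.setdefault(_aa, []).append(_c)
for _aa in FAMILIES:
    FAMILIES[_aa].sort(key=lambda c: (BASES.index(c[0]), BASES.index(c[1]), BASES.index(c[2])))

INFORMATIVE = [
    c
    for a in BASES
    for b in BASES
    for d in BASES
    for c in [a + b + d]
    if c not in STOPS and c not in ("ATG", "TGG")
]


def split_codons(seq: str, drop_terminal_stop: bool = True) -> list[str]:
    assert len(seq) % 3 == 0
    cods = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if drop_terminal_stop and cods and cods[-1] in STOPS:
        cods.pop()
    return [c for c in cods if all(b in "ACGT" for b in c)]


def sense_counts(seq: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for c in split_codons(seq):
        if c not in STOPS:
            counts[c] = counts.get(c, 0) + 1
    return counts


def positional_freqs(counts: dict[str, int]) -> list[dict[str, float]]:
    n = sum(counts.values())
    out = []
    for p in range(3):
        freq = {b: 0.0 for b in "ACGT"}
        for codon, k in counts.items():
            freq[codon[p]] += k
        out.append({b: v / n for b, v in freq.items()})
    return out


def rscu_oracle(seq: str) -> dict[str, float]:
    """codon -> count / (family mean); NaN for unused families."""
    counts = sense_counts(seq)
    out = {}
    for aa, codons in FAMILIES.items():
        if len(codons) < 2:
            continue
        total = sum(counts.get(c, 0) for c in codons)
        for c in codons:
            if c in ("ATG", "TGG"):
                continue
            out[c] = (
                counts.get(c, 0) / (total / len(codons)) if total > 0 else math.nan
            )
    return out


def _combine(f2: list, f3: float | None, f4: list, f6: list) -> float:
    if not f2 or not f4 or not f6:
        return math.nan
    m2 = sum(f2) / len(f2)
    m4 = sum(f4) / len(f4)
    m6 = sum(f6) / len(f6)
    if f3 is None:
        f3 = (m2 + m4) / 2.0
    nc = 2.0 + 9.0 / m2 + 1.0 / f3 + 5.0 / m4 + 3.0 / m6
    return min(nc, 61.0)


def nc_oracle(seq: str) -> float:
    counts = sense_counts(seq)
    f2, f4, f6, f3 = [], [], [], None
    for aa, codons in FAMILIES.items():
        m = len(codons)
        if m < 2:
            continue
        n = sum(counts.get(c, 0) for c in codons)
        if n < 2:
            continue
        sum_p2 = sum((counts.get(c, 0) / n) ** 2 for c in codons)
        f = (n * sum_p2 - 1.0) / (n - 1.0)
        if f <= 0:
            continue
        if m == 3:
            f3 = f
        else:
            {2: f2, 4: f4, 6: f6}[m].append(f)
    return _combine(f2, f3, f4, f6)


def ncprime_oracle(seq: str) -> float:
    counts = sense_counts(seq)
    freqs = positional_freqs(counts)
    f2, f4, f6, f3 = [], [], [], None
    for aa, codons in FAMILIES.items():
        m = len(codons)
        if m < 2:
            continue
        n = sum(counts.get(c, 0) for c in codons)
        if n < 2:
            continue
        raw = [freqs[0][c[0]] * freqs[1][c[1]] * freqs[2][c[2]] for c in codons]
        total = sum(raw)
        if total <= 0:
            continue
        p_hat = [r / total for r in raw]
        if any(p == 0 and counts.get(c, 0) > 0 for p, c in zip(p_hat, codons)):
            f = 1.0
        else:
            chi2 = sum(
                (counts.get(c, 0) - n * p) ** 2 / (n * p)
                for p, c in zip(p_hat, codons)
                if p > 0
            )
            f = (chi2 + n - m) / (m * (n - 1.0))
        if f <= 0:
            continue
        f = min(f, 1.0)
        if m == 3:
            f3 = f
        else:
            {2: f2, 4: f4, 6: f6}[m].append(f)
    return _combine(f2, f3, f4, f6)


def cosine_oracle(x, y) -> float:
    pairs = [(a, b) for a, b in zip(x, y) if not (math.isnan(a) or math.isnan(b))]
    dot = sum(a * b for a, b in pairs)
    nx = math.sqrt(sum(a * a for a, _ in pairs))
    ny = math.sqrt(sum(b * b for _, b in pairs))
    return dot / (nx * ny)


def cdc_oracle(seq: str) -> float:
    counts = sense_counts(seq)
    n = sum(counts.values())
    freqs = positional_freqs(counts)
    expected = {}
    for a in BASES:
        for b in BASES:
            for d in BASES:
                codon = a + b + d
                if codon in STOPS:
                    continue
                prob = 1.0
                for p, base in enumerate(codon):
                    gc = freqs[p]["G"] + freqs[p]["C"]
                    ag = freqs[p]["A"] + freqs[p]["G"]
                    prob *= {
                        "G": gc * ag,
                        "C": gc * (1 - ag),
                        "A": (1 - gc) * ag,
                        "T": (1 - gc) * (1 - ag),
                    }[base]
                expected[codon] = prob
    z = sum(expected.values())
    sense = sorted(expected)
    obs = [counts.get(c, 0) / n for c in sense]
    exp = [expected[c] / z for c in sense]
    return 1.0 - cosine_oracle(obs, exp)


def average_ranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        rank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = rank
        i = j + 1
    return ranks


def pearson_oracle(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def spearman_oracle(x, y) -> float:
    return pearson_oracle(average_ranks(list(x)), average_ranks(list(y)))


def anova_oracle(groups) -> float:
    groups = [list(g) for g in groups]
    n_total = sum(len(g) for g in groups)
    grand = sum(sum(g) for g in groups) / n_total
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(
        sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups
    )
    if ss_within == 0:
        return 0.0 if ss_between == 0 else math.inf
    return (ss_between / (len(groups) - 1)) / (ss_within / (n_total - len(groups)))


def ols_oracle(x, y) -> tuple[float, float, float]:
    """(slope, intercept, pearson r) by the closed-form least squares."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    slope = sxy / sxx
    return slope, my - slope * mx, pearson_oracle(x, y)


def ca_oracle(matrix):
    """Correspondence analysis via the eigendecomposition route.

    Returns (inertia_fractions, row_gram) where row_gram is the Gram matrix
    F F^T of row principal coordinates — a rotation/sign-free fingerprint.
    """
    import numpy as np

    M = np.asarray(matrix, dtype=float)
    P = M / M.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    eigvals = np.linalg.eigvalsh(S.T @ S)[::-1]
    rank = min(M.shape) - 1
    eigvals = np.clip(eigvals[:rank], 0, None)
    fractions = eigvals / eigvals.sum()
    gram = (S @ S.T) / np.sqrt(np.outer(r, r))
    return fractions, gram
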