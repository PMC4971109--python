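"""Per-gene codon-usage quantities.

Implements codon counting, positional GC contents, RSCU over the 59
informative codons, CAI (Sharp-Li relative-adaptiveness weights), Wright's
effective number of codons Nc, its composition-corrected variant Nc', the
codon deviation coefficient CDC, the (61-X)/41 rescaling onto [0, 1], and
the cosine similarity used for tRNA comparisons.

All estimators operate on a :class:`CodonCounts` summary so that every
metric is invariant to codon order by construction.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import UndefinedInputError, ValidationError
from .genetic_code import (
    BASE_INDEX,
    CODON_INDEX,
    CODONS,
    GeneticCode,
    POSITION_ONEHOT,
    standard_code,
)
from .io_formats import GeneRecord

logger = logging.getLogger(__name__)

# 256-entry LUT: ASCII byte -> base index in TCAG order, 255 for anything else
_BASE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    _BASE_LUT[ord(_b)] = _i


@dataclass
class CodonCounts:
    """64-cell codon counts plus positional nucleotide counts.

    ``counts`` covers every decodable codon including internal stops;
    ``n_codons`` and ``pos_counts`` cover sense codons only, so stop codons
    never leak into GC or composition estimates.
    """

    counts: np.ndarray                      # (64,) int64 in CODONS order
    n_codons: int                           # sense codons counted
    pos_counts: np.ndarray = field(repr=False)  # (3,4) int64, TCAG order

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        return CodonCounts(
            counts=self.counts + other.counts,
            n_codons=self.n_codons + other.n_codons,
            pos_counts=self.pos_counts + other.pos_counts,
        )


def count_codons(
    record: GeneRecord | str,
    drop_terminal_stop: bool = True,
    code: GeneticCode | None = None,
) -> CodonCounts:
    """Count non-overlapping in-frame codons.

    Codons containing N (or any non-ACGT base) are excluded from the counts
    entirely; a terminal stop codon is dropped when requested.
    """
    code = code or standard_code()
    seq = record.sequence if isinstance(record, GeneRecord) else record
    if len(seq) == 0 or len(seq) % 3 != 0:
        raise ValidationError(f"sequence length {len(seq)} is not a positive multiple of 3")
    base_idx = _BASE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    triplets = base_idx.reshape(-1, 3)
    valid = (triplets != 255).all(axis=1)
    codon_idx = (
        triplets[:, 0].astype(np.int64) * 16
        + triplets[:, 1].astype(np.int64) * 4
        + triplets[:, 2].astype(np.int64)
    )
    if drop_terminal_stop and valid[-1] and not code.sense_mask[codon_idx[-1]]:
        valid[-1] = False
    counts = np.bincount(codon_idx[valid], minlength=64)
    sense = counts * code.sense_mask
    pos_counts = np.einsum("i,ipb->pb", sense, POSITION_ONEHOT)
    return CodonCounts(counts=counts, n_codons=int(sense.sum()), pos_counts=pos_counts)


@dataclass(frozen=True)
class GCContents:
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float


def gc_contents(counts: CodonCounts) -> GCContents:
    """Positional G+C fractions over counted sense codons.

    ``gc`` is the mean over the three positions; ``gc12`` the mean of the
    first two.
    """
    if counts.n_codons < 1:
        raise UndefinedInputError("GC content of a gene with no counted codons")
    pos = counts.pos_counts / counts.n_codons
    gc_by_pos = pos[:, BASE_INDEX["G"]] + pos[:, BASE_INDEX["C"]]
    gc1, gc2, gc3 = (float(x) for x in gc_by_pos)
    return GCContents(
        gc=float(gc_by_pos.mean()), gc1=gc1, gc2=gc2, gc3=gc3, gc12=(gc1 + gc2) / 2.0
    )


def rscu(counts: CodonCounts, code: GeneticCode | None = None) -> np.ndarray:
    """RSCU over the 59 informative codons, in informative-codon order.

    A codon's count divided by the mean count of its synonymous family;
    families with zero total usage yield NaN (missing), never zero.
    """
    code = code or standard_code()
    values = np.full(64, np.nan)
    for aa, idx in code.family_indices.items():
        if len(idx) < 2:
            continue
        total = counts.counts[idx].sum()
        if total > 0:
            values[idx] = counts.counts[idx] / (total / len(idx))
    return values[code.informative_index]


def cai_weights(
    reference: CodonCounts,
    pseudocount: float = 0.5,
    code: GeneticCode | None = None,
) -> np.ndarray:
    """Relative-adaptiveness weights from an aggregated reference count table.

    Per family, w_c = (count_c + pseudocount) / (max family count +
    pseudocount), so the most-used codon of every family has weight 1.
    Returned as a 64-vector (NaN for stops; 1.0 for the singleton ATG/TGG
    families, which never enter CAI).
    """
    code = code or standard_code()
    if reference.n_codons == 0:
        raise ValidationError("empty CAI reference set")
    w = np.full(64, np.nan)
    for aa, idx in code.family_indices.items():
        if len(idx) < 2:
            w[idx] = 1.0
            continue
        c = reference.counts[idx].astype(float)
        w[idx] = (c + pseudocount) / (c.max() + pseudocount)
    return w


def cai(
    counts: CodonCounts, weights: np.ndarray, code: GeneticCode | None = None
) -> float:
    """Geometric mean of weights over the gene's codons, excluding ATG, TGG
    and stops."""
    code = code or standard_code()
    eligible = code.sense_mask.copy()
    for singleton in ("ATG", "TGG"):
        eligible[CODON_INDEX[singleton]] = False
    c = counts.counts * eligible
    total = c.sum()
    if total == 0:
        raise UndefinedInputError("gene has no codons from degenerate families")
    with np.errstate(divide="ignore"):
        logw = np.where(c > 0, np.log(np.where(c > 0, weights, 1.0)), 0.0)
    return float(np.exp((c * logw).sum() / total))


def _family_stats(counts: CodonCounts, code: GeneticCode):
    """Yield (aa, family_size, family_total, family_counts) for families of
    size >= 2."""
    for aa, idx in code.family_indices.items():
        if len(idx) < 2:
            continue
        c = counts.counts[idx].astype(float)
        yield aa, len(idx), float(c.sum()), c


def _combine_class_means(
    f_by_class: dict[int, list[float]], f_ile: float | None
) -> float:
    """Wright's combination 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 with Ile imputation
    and the 61 cap; NaN when a required class has no usable family."""
    means = {}
    for k in (2, 4, 6):
        vals = f_by_class.get(k, [])
        if not vals:
            return float("nan")
        means[k] = sum(vals) / len(vals)
    f3 = f_ile if f_ile is not None else (means[2] + means[4]) / 2.0
    nc = 2.0 + 9.0 / means[2] + 1.0 / f3 + 5.0 / means[4] + 3.0 / means[6]
    return min(nc, 61.0)


def nc_wright(counts: CodonCounts, code: GeneticCode | None = None) -> float:
    """Wright's effective number of codons.

    Family homozygosity F = (n * sum p^2 - 1)/(n - 1) for families with
    n >= 2 codons and F > 0; class means combined as 2 + 9/F2 + 1/F3 +
    5/F4 + 3/F6; the Ile class is imputed as (F2 + F4)/2 when unusable;
    capped at 61.  Returns NaN when any other class has no usable family.
    """
    code = code or standard_code()
    f_by_class: dict[int, list[float]] = {}
    f_ile = None
    for aa, m, n, c in _family_stats(counts, code):
        if n < 2:
            continue
        p = c / n
        f_hat = (n * float(np.dot(p, p)) - 1.0) / (n - 1.0)
        if f_hat <= 0:
            continue
        if m == 3:
            f_ile = f_hat
        else:
            f_by_class.setdefault(m, []).append(f_hat)
    return _combine_class_means(f_by_class, f_ile)


def _composition_expected(
    counts: CodonCounts, idx: np.ndarray
) -> np.ndarray | None:
    """Null codon probabilities for one family from the gene's own positional
    base composition, renormalized within the family; None if degenerate."""
    if counts.n_codons == 0:
        return None
    q = counts.pos_counts / counts.n_codons       # (3,4) positional base freqs
    raw = np.ones(len(idx))
    for j, ci in enumerate(idx):
        for p in range(3):
            raw[j] *= q[p] @ POSITION_ONEHOT[ci, p]
    total = raw.sum()
    if total <= 0:
        return None
    return raw / total


def nc_prime(counts: CodonCounts, code: GeneticCode | None = None) -> float:
    """Composition-corrected Nc (Novembre-style).

    Per family, F is replaced by F_hat = (chi2 + n - m)/(m*(n-1)) where the
    chi-square compares observed codon counts with those expected under the
    gene's positional nucleotide composition.  F_hat is clipped to (0, 1];
    class combination, Ile imputation and the 61 cap follow nc_wright.
    """
    code = code or standard_code()
    f_by_class: dict[int, list[float]] = {}
    f_ile = None
    for aa, m, n, c in _family_stats(counts, code):
        if n < 2:
            continue
        p_hat = _composition_expected(counts, code.family_indices[aa])
        if p_hat is None:
            continue
        expected = n * p_hat
        if np.any((expected == 0) & (c > 0)):
            f_hat = 1.0  # observed mass where the null puts none: maximal deviation
        else:
            mask = expected > 0
            chi2 = float(((c[mask] - expected[mask]) ** 2 / expected[mask]).sum())
            f_hat = (chi2 + n - m) / (m * (n - 1.0))
        if f_hat <= 0:
            continue
        f_hat = min(f_hat, 1.0)
        if m == 3:
            f_ile = f_hat
        else:
            f_by_class.setdefault(m, []).append(f_hat)
    return _combine_class_means(f_by_class, f_ile)


def cdc(counts: CodonCounts, code: GeneticCode | None = None) -> float:
    """Codon deviation coefficient: 1 minus the cosine between observed codon
    usage and usage expected from positional GC and purine contents."""
    code = code or standard_code()
    if counts.n_codons < 1:
        raise UndefinedInputError("CDC of a gene with no counted codons")
    pos = counts.pos_counts / counts.n_codons
    gc = pos[:, BASE_INDEX["G"]] + pos[:, BASE_INDEX["C"]]
    ag = pos[:, BASE_INDEX["A"]] + pos[:, BASE_INDEX["G"]]
    # expected base probabilities per position, TCAG order
    p_base = np.stack(
        [(1 - gc) * (1 - ag), gc * (1 - ag), (1 - gc) * ag, gc * ag], axis=1
    )
    expected = np.ones(64)
    for p in range(3):
        expected *= POSITION_ONEHOT[:, p, :] @ p_base[p]
    expected = expected * code.sense_mask
    total = expected.sum()
    if total <= 0:
        raise UndefinedInputError("expected codon mass falls entirely on stop codons")
    expected /= total
    observed = (counts.counts * code.sense_mask) / counts.n_codons
    value = 1.0 - cosine_similarity(observed, expected)
    return float(min(max(value, 0.0), 1.0))


def cdc_pvalue(
    counts: CodonCounts,
    n_resamples: int = 1000,
    seed: int = 0,
    code: GeneticCode | None = None,
) -> float:
    """Optional bootstrap significance for CDC: resample the gene's codons
    with replacement and report the fraction of resampled CDC values at or
    above the observed one.  Not used by pipeline defaults."""
    code = code or standard_code()
    observed = cdc(counts, code)
    rng = np.random.default_rng(seed)
    sense = counts.counts * code.sense_mask
    p = sense / sense.sum()
    hits = 0
    for _ in range(n_resamples):
        resampled = rng.multinomial(counts.n_codons, p)
        cc = CodonCounts(
            counts=resampled,
            n_codons=int(resampled.sum()),
            pos_counts=np.einsum("i,ipb->pb", resampled, POSITION_ONEHOT),
        )
        if cdc(cc, code) >= observed:
            hits += 1
    return hits / n_resamples


def rescale_bias(x: float) -> float:
    """Map an Nc-scale value onto [0, 1] via (61 - x)/41 (0 = no bias)."""
    if isinstance(x, float) and math.isnan(x):
        return float("nan")
    if not 20.0 - 1e-9 <= x <= 61.0 + 1e-9:
        raise ValidationError(f"Nc-scale value {x} outside [20, 61]")
    return (61.0 - x) / 41.0


def cosine_similarity(x, y) -> float:
    """Cosine of the angle between two non-negative vectors; NaN entries are
    dropped pairwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"vector shapes differ: {x.shape} vs {y.shape}")
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise UndefinedInputError("cosine similarity of a zero-norm vector")
    return float(min(1.0, float(np.dot(x, y)) / (nx * ny)))


@dataclass
class CUBMetricsRow:
    """Per-gene bundle of composition and codon-usage-bias metrics."""

    gene_id: str
    set_label: str
    length_codons: int
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    cai: float
    nc: float
    nc_prime: float
    cdc: float
    nc_rescaled: float
    nc_prime_rescaled: float
    rscu: np.ndarray = field(repr=False)
    counts: CodonCounts | None = field(default=None, repr=False)


def reference_counts(
    records,
    reference_ids: set[str] | None = None,
    code: GeneticCode | None = None,
) -> CodonCounts:
    """Aggregate codon counts of a CAI reference gene set.

    When no explicit id list is given, genes annotated as ribosomal
    proteins are used (the conventional highly-expressed reference); if
    none are annotated, all records are pooled as a last resort.
    """
    code = code or standard_code()
    if reference_ids is not None:
        chosen = [r for r in records if r.gene_id in reference_ids]
        if not chosen:
            raise ValidationError("no records match the CAI reference id list")
    else:
        chosen = [r for r in records if "ribosomal protein" in r.product.lower()]
        if not chosen:
            logger.warning(
                "no 'ribosomal protein' annotations; pooling all genes as CAI reference"
            )
            chosen = list(records)
        if not chosen:
            raise ValidationError("empty record list for CAI reference")
    agg = CodonCounts(
        counts=np.zeros(64, dtype=np.int64),
        n_codons=0,
        pos_counts=np.zeros((3, 4), dtype=np.int64),
    )
    for rec in chosen:
        agg = agg + count_codons(rec, code=code)
    return agg


def compute_metrics(
    records,
    partition=None,
    weights: np.ndarray | None = None,
    min_len: int = 100,
    code: GeneticCode | None = None,
    keep_excluded: bool = False,
) -> list[CUBMetricsRow]:
    """One CUBMetricsRow per QC-passing gene of at least ``min_len`` sense
    codons (terminal stop dropped).  Genes flagged is_excluded (HGT) are
    left out unless keep_excluded is set.

    ``partition`` may be a GeneSetPartition or any mapping gene_id -> label.
    ``weights`` defaults to the ribosomal-protein reference heuristic.
    """
    code = code or standard_code()
    records = list(records)
    if not keep_excluded:
        records = [r for r in records if not r.is_excluded]
    if weights is None:
        weights = cai_weights(reference_counts(records, code=code), code=code)
    labels = {}
    if partition is not None:
        labels = getattr(partition, "gene_labels", partition)
    rows = []
    for rec in records:
        counts = count_codons(rec, code=code)
        if counts.n_codons < min_len:
            continue
        gcs = gc_contents(counts)
        nc = nc_wright(counts, code)
        ncp = nc_prime(counts, code)
        rows.append(
            CUBMetricsRow(
                gene_id=rec.gene_id,
                set_label=labels.get(rec.gene_id, ""),
                length_codons=counts.n_codons,
                gc=gcs.gc,
                gc1=gcs.gc1,
                gc2=gcs.gc2,
                gc3=gcs.gc3,
                gc12=gcs.gc12,
                cai=cai(counts, weights, code),
                nc=nc,
                nc_prime=ncp,
                cdc=cdc(counts, code),
                nc_rescaled=rescale_bias(nc),
                nc_prime_rescaled=rescale_bias(ncp),
                rscu=rscu(counts, code),
                counts=counts,
            )
        )
    return rows


def metrics_frame(rows: list[CUBMetricsRow], code: GeneticCode | None = None):
    """Flatten metric rows to a DataFrame, one RSCU column per informative
    codon, suitable for write_table."""
    import pandas as pd

    code = code or standard_code()
    scalar_cols = [
        "gene_id", "set_label", "length_codons", "gc", "gc1", "gc2", "gc3",
        "gc12", "cai", "nc", "nc_prime", "cdc", "nc_rescaled", "nc_prime_rescaled",
    ]
    data = {col: [getattr(r, col) for r in rows] for col in scalar_cols}
    for j, codon in enumerate(code.informative_codons):
        data[f"rscu_{codon}"] = [float(r.rscu[j]) for r in rows]
    return pd.DataFrame(data)
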