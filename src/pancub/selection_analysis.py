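"""Mutation-vs-selection diagnostics per presence class.

ENC-plot deviation against the mutation-only expectation curve, the
neutrality regression of GC12 on GC3, correspondence analysis of the
gene x 59 RSCU matrix with axis-1 factor correlations, CUB-expression
correlation, pooled-RSCU vs tRNA-copy-number similarity, and the supporting
one-way ANOVA and Spearman rank correlation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .codon_metrics import CodonCounts, CUBMetricsRow, cosine_similarity, rscu
from .errors import DegenerateResultError, UndefinedInputError, ValidationError
from .genetic_code import GeneticCode, reverse_complement, standard_code
from .io_formats import ExpressionTable, TRNATable
from .pangenome import SET_LABELS

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)
DEFAULT_FACTORS = (
    "gc", "gc1", "gc2", "gc3", "length", "cai", "nc", "nc_prime", "cdc", "expression",
)


def _set_order(labels) -> list[str]:
    """Gene-set labels in presence order, keeping any unknown labels last."""
    present = {l for l in labels if l}
    ordered = [l for l in SET_LABELS if l in present]
    return ordered + sorted(present - set(SET_LABELS))


def expected_nc(gc3) -> float:
    """Mutation-only expectation 2 + x + 29/(x^2 + (1-x)^2) at x = GC3."""
    x = np.asarray(gc3, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValidationError("GC3 must lie in [0, 1]")
    value = 2.0 + x + 29.0 / (x**2 + (1.0 - x) ** 2)
    return float(value) if np.isscalar(gc3) or x.ndim == 0 else value


@dataclass
class ENCPlotResult:
    genes: pd.DataFrame       # gene_id, set_label, gc3, estimated, expected, deviation, deviated
    sweep: pd.DataFrame       # set_label, threshold, fraction_deviated, n_genes
    threshold_default: float
    n_missing: int


def enc_plot(
    metrics: list[CUBMetricsRow],
    thresholds=DEFAULT_THRESHOLDS,
    threshold_default: float = 0.15,
    nc_field: str = "nc",
) -> ENCPlotResult:
    """Per-gene deviation (expected - estimated)/expected with a deviated
    flag at the default threshold, plus a per-set deviated-fraction sweep.

    Genes whose estimated Nc is missing are excluded and counted.
    """
    rows, n_missing = [], 0
    for m in metrics:
        estimated = getattr(m, nc_field)
        if estimated is None or np.isnan(estimated):
            n_missing += 1
            continue
        exp = expected_nc(m.gc3)
        deviation = (exp - estimated) / exp
        rows.append(
            dict(
                gene_id=m.gene_id,
                set_label=m.set_label,
                gc3=m.gc3,
                estimated_nc=estimated,
                expected_nc=exp,
                deviation=deviation,
                deviated=deviation > threshold_default,
            )
        )
    if n_missing:
        logger.info("enc_plot: %d genes lacked an Nc value", n_missing)
    genes = pd.DataFrame(rows)
    sweep_rows = []
    if not genes.empty:
        for label in _set_order(genes["set_label"]):
            sub = genes[genes["set_label"] == label]
            for t in thresholds:
                sweep_rows.append(
                    dict(
                        set_label=label,
                        threshold=t,
                        fraction_deviated=float((sub["deviation"] > t).mean()),
                        n_genes=len(sub),
                    )
                )
    return ENCPlotResult(
        genes=genes,
        sweep=pd.DataFrame(sweep_rows),
        threshold_default=threshold_default,
        n_missing=n_missing,
    )


@dataclass
class NeutralityResult:
    table: pd.DataFrame  # set_label, slope, intercept, r, p_value, n_genes


def neutrality_plot(metrics: list[CUBMetricsRow]) -> NeutralityResult:
    """Per-set OLS regression of GC12 on GC3 with Pearson r and two-sided p.

    Slope 1 indicates complete neutrality (mutation only), slope 0 absence
    of directional mutation pressure.  Sets with fewer than 3 genes or
    degenerate GC3 variance report missing values.
    """
    rows = []
    by_set: dict[str, list[CUBMetricsRow]] = {}
    for m in metrics:
        by_set.setdefault(m.set_label, []).append(m)
    for label in _set_order(by_set):
        group = by_set[label]
        x = np.array([m.gc3 for m in group])
        y = np.array([m.gc12 for m in group])
        if len(group) < 3 or np.ptp(x) == 0:
            rows.append(
                dict(set_label=label, slope=np.nan, intercept=np.nan,
                     r=np.nan, p_value=np.nan, n_genes=len(group))
            )
            continue
        fit = stats.linregress(x, y)
        rows.append(
            dict(set_label=label, slope=fit.slope, intercept=fit.intercept,
                 r=fit.rvalue, p_value=fit.pvalue, n_genes=len(group))
        )
    return NeutralityResult(table=pd.DataFrame(rows))


@dataclass
class COAResult:
    """Correspondence analysis of the gene x codon RSCU matrix."""

    gene_ids: list[str]
    set_labels: list[str]
    row_coords: np.ndarray          # (n_genes, n_axes) principal coordinates
    col_coords: np.ndarray          # (n_codons_kept, n_axes)
    codons: list[str]               # codons kept (positive column mass)
    inertia_fractions: np.ndarray   # over all axes; sums to 1
    n_axes: int
    sign_convention: str = "largest |codon loading| positive per axis"

    @property
    def major_axes(self) -> np.ndarray:
        """Axes explaining > 10% of total inertia (the major-trend rule)."""
        return np.flatnonzero(self.inertia_fractions[: self.n_axes] > 0.10)

    def coords_frame(self) -> pd.DataFrame:
        data = {"gene_id": self.gene_ids, "set_label": self.set_labels}
        for a in range(self.n_axes):
            data[f"axis{a + 1}"] = self.row_coords[:, a]
        return pd.DataFrame(data)


def coa_rscu(
    metrics: list[CUBMetricsRow],
    n_axes: int = 4,
    code: GeneticCode | None = None,
) -> COAResult:
    """Correspondence analysis on the gene x 59 RSCU matrix.

    Missing RSCU entries (absent families) are imputed as 0; rows with zero
    total and codons never used are dropped.  Row principal coordinates are
    mass-weighted SVD scores of the standardized residual matrix; the sign
    of each axis is fixed so its largest-magnitude codon loading is positive.
    """
    code = code or standard_code()
    if len(metrics) < 2:
        raise ValidationError("correspondence analysis needs at least 2 genes")
    M = np.vstack([np.nan_to_num(m.rscu, nan=0.0) for m in metrics])
    row_keep = M.sum(axis=1) > 0
    metrics = [m for m, k in zip(metrics, row_keep) if k]
    M = M[row_keep]
    col_keep = M.sum(axis=0) > 0
    codons = [c for c, k in zip(code.informative_codons, col_keep) if k]
    M = M[:, col_keep]

    P = M / M.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    inertia = sv**2
    total = inertia.sum()
    if total < 1e-14:
        raise DegenerateResultError("zero inertia: all RSCU profiles identical")
    rank = min(M.shape) - 1
    inertia = inertia[:rank]
    fractions = inertia / inertia.sum()
    n_axes = min(n_axes, rank)
    row_coords = (U[:, :rank] * sv[:rank]) / np.sqrt(r)[:, None]
    col_coords = (Vt[:rank].T * sv[:rank]) / np.sqrt(c)[:, None]
    for a in range(rank):
        j = int(np.argmax(np.abs(col_coords[:, a])))
        if col_coords[j, a] < 0:
            col_coords[:, a] *= -1
            row_coords[:, a] *= -1
    return COAResult(
        gene_ids=[m.gene_id for m in metrics],
        set_labels=[m.set_label for m in metrics],
        row_coords=row_coords[:, :n_axes],
        col_coords=col_coords[:, :n_axes],
        codons=codons,
        inertia_fractions=fractions,
        n_axes=n_axes,
    )


def _factor_values(
    metrics: list[CUBMetricsRow],
    factor: str,
    expression: ExpressionTable | None,
) -> np.ndarray:
    if factor == "expression":
        if expression is None:
            return np.full(len(metrics), np.nan)
        return np.array(
            [expression.get(m.gene_id, np.nan) for m in metrics], dtype=float
        )
    attr = "length_codons" if factor == "length" else factor
    return np.array([getattr(m, attr) for m in metrics], dtype=float)


def axis_factor_correlations(
    coa: COAResult,
    metrics: list[CUBMetricsRow],
    factors=DEFAULT_FACTORS,
    expression: ExpressionTable | None = None,
    axis: int = 0,
) -> pd.DataFrame:
    """Spearman correlation between an ordination axis and each factor, per
    gene set.  Both signed and absolute rho are reported."""
    by_id = {m.gene_id: m for m in metrics}
    rows = []
    coords = {g: coa.row_coords[i, axis] for i, g in enumerate(coa.gene_ids)}
    for label in _set_order(coa.set_labels):
        group = [
            by_id[g]
            for g, l in zip(coa.gene_ids, coa.set_labels)
            if l == label and g in by_id
        ]
        axis_vals = np.array([coords[m.gene_id] for m in group])
        for factor in factors:
            values = _factor_values(group, factor, expression)
            mask = ~np.isnan(values) & ~np.isnan(axis_vals)
            if mask.sum() < 3:
                logger.warning(
                    "factor %r in set %r has <3 non-missing values; skipped",
                    factor, label,
                )
                continue
            rho, p = spearman_rho(axis_vals[mask], values[mask])
            rows.append(
                dict(set_label=label, factor=factor, rho=rho,
                     abs_rho=abs(rho) if not np.isnan(rho) else np.nan,
                     p_value=p, n_genes=int(mask.sum()))
            )
    return pd.DataFrame(rows)


def expression_correlation(
    metrics: list[CUBMetricsRow],
    expression: ExpressionTable,
    cub_field: str = "cai",
) -> pd.DataFrame:
    """Per-set Spearman correlation between a CUB measure and expression."""
    by_set: dict[str, list[CUBMetricsRow]] = {}
    for m in metrics:
        by_set.setdefault(m.set_label, []).append(m)
    rows = []
    for label in _set_order(by_set):
        group = [m for m in by_set[label] if m.gene_id in expression]
        if len(group) < 3:
            rows.append(dict(set_label=label, rho=np.nan, p_value=np.nan,
                             n_genes=len(group)))
            continue
        x = np.array([getattr(m, cub_field) for m in group])
        y = np.array([expression.get(m.gene_id) for m in group])
        mask = ~np.isnan(x) & ~np.isnan(y)
        if mask.sum() < 3:
            rows.append(dict(set_label=label, rho=np.nan, p_value=np.nan,
                             n_genes=int(mask.sum())))
            continue
        rho, p = spearman_rho(x[mask], y[mask])
        rows.append(dict(set_label=label, rho=rho, p_value=p,
                         n_genes=int(mask.sum())))
    return pd.DataFrame(rows)


# --- tRNA mapping -----------------------------------------------------------

def trna_codon_vector(
    trna: TRNATable, wobble: bool = False, code: GeneticCode | None = None
) -> np.ndarray:
    """Copy-number vector over the 59 informative codons.

    Default mapping is the strict Watson-Crick cognate (anticodon = reverse
    complement of the codon).  With ``wobble``, position-34 rules are added:
    G34 also reads T-ending codons, T34 also reads G-ending codons, and A34
    is treated as inosine (reads T-, C- and A-ending codons of its family).
    """
    code = code or standard_code()
    values = np.zeros(len(code.informative_codons))
    for j, codon in enumerate(code.informative_codons):
        total = trna.copy_number(reverse_complement(codon))
        if wobble:
            stem = reverse_complement(codon)[1:]  # positions 35-36 fixed
            third = codon[2]
            for ac34, reads in (("G", "T"), ("T", "G")):
                if third == reads:
                    total += trna.copy_number(ac34 + stem)
            if third in "TCA":
                # inosine at 34 is encoded genomically as A34
                wc34 = reverse_complement(third)
                if wc34 != "A":
                    total += trna.copy_number("A" + stem)
        values[j] = total
    return values


@dataclass
class SimilarityResult:
    table: pd.DataFrame  # set_label, similarity, codon_coverage, n_genes


def trna_similarity_by_set(
    metrics: list[CUBMetricsRow],
    trna: TRNATable,
    wobble: bool = False,
    average: bool = False,
    code: GeneticCode | None = None,
) -> SimilarityResult:
    """Cosine similarity between each set's RSCU profile and tRNA copy
    numbers over the 59 informative codons.

    By default codon counts are pooled over the set's genes before RSCU;
    with ``average`` the per-gene RSCU vectors are averaged instead.
    """
    code = code or standard_code()
    tvec = trna_codon_vector(trna, wobble=wobble, code=code)
    if np.linalg.norm(tvec) == 0:
        raise UndefinedInputError("tRNA table maps to no informative codon")
    coverage = int((tvec > 0).sum())
    by_set: dict[str, list[CUBMetricsRow]] = {}
    for m in metrics:
        by_set.setdefault(m.set_label, []).append(m)
    rows = []
    for label in _set_order(by_set):
        group = by_set[label]
        if average:
            profile = np.nanmean(np.vstack([m.rscu for m in group]), axis=0)
        else:
            pooled = None
            for m in group:
                if m.counts is None:
                    raise ValidationError(
                        "pooled tRNA similarity needs CodonCounts on metric rows"
                    )
                pooled = m.counts if pooled is None else pooled + m.counts
            profile = rscu(pooled, code)
        # a family the whole set never uses is genuinely zero usage here,
        # unlike the per-gene missing convention
        profile = np.nan_to_num(profile, nan=0.0)
        rows.append(
            dict(
                set_label=label,
                similarity=cosine_similarity(profile, tvec),
                codon_coverage=coverage,
                n_genes=len(group),
            )
        )
    return SimilarityResult(table=pd.DataFrame(rows))


# --- basic statistics -------------------------------------------------------

def one_way_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and upper-tail p.

    F uses between/within mean squares with (k-1, N-k) degrees of freedom;
    when both between- and within-group variance are zero, F is defined
    as 0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("ANOVA needs >= 2 groups each with >= 2 values")
    n_total = sum(len(g) for g in groups)
    grand = sum(g.sum() for g in groups) / n_total
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return float(f_stat), p


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation: Pearson correlation of average ranks, with
    a two-sided p from the t approximation.  Zero rank variance in either
    variable yields (nan, nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman_rho needs two equal-length 1-d vectors")
    n = len(x)
    if n < 3:
        raise ValidationError("spearman_rho needs length >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        logger.warning("spearman_rho: degenerate (all-tied) ranks")
        return float("nan"), float("nan")
    rho = float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, p


def anova_by_set(
    metrics: list[CUBMetricsRow], fields=("cdc", "cai", "nc", "nc_prime", "gc", "gc3")
) -> pd.DataFrame:
    """One-way ANOVA of each metric across the gene sets."""
    by_set: dict[str, list[CUBMetricsRow]] = {}
    for m in metrics:
        by_set.setdefault(m.set_label, []).append(m)
    order = _set_order(by_set)
    rows = []
    for fname in fields:
        groups = []
        for label in order:
            vals = np.array([getattr(m, fname) for m in by_set[label]], dtype=float)
            vals = vals[~np.isnan(vals)]
            if len(vals) >= 2:
                groups.append(vals)
        if len(groups) < 2:
            continue
        f_stat, p = one_way_anova(groups)
        rows.append(dict(metric=fname, f_statistic=f_stat, p_value=p,
                         n_groups=len(groups)))
    return pd.DataFrame(rows)
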