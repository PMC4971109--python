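"""Synthetic pangenomes with known mutation/selection structure.

Every pipeline stage gets ground truth: a strain x family presence spectrum
with abundant core and strain-specific families, a per-gene third-position
GC pressure (the mutation knob), a per-family selection strength toward one
preferred codon per family that rises with presence, expression coupled to
selection, and a tRNA table whose high-copy anticodons decode the preferred
codons.

Selection is modeled as a single preferred codon per family with
exponential weighting - the simplest mechanism producing the CAI/tRNA/ENC
signatures of translational selection; it is a stand-in, not a biological
claim.  The mutational weight acts on the third codon base; amino-acid
choice additionally feels the same pressure through a coupling exponent
that decays with selection strength, so that weakly selected genes show a
GC12-GC3 coupling (a positive neutrality slope) while strongly selected
genes do not.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genetic_code import BASE_INDEX, GeneticCode, reverse_complement, standard_code
from .io_formats import (
    ClusterTable,
    ExpressionTable,
    GeneRecord,
    TRNATable,
    write_cds_fasta,
    write_table,
)


def default_preferred_codons(code: GeneticCode | None = None) -> dict[str, str]:
    """One preferred codon per degenerate family: the first C-ending codon,
    else the first G-ending, else the first codon."""
    code = code or standard_code()
    preferred = {}
    for aa, codons in code.degenerate_families().items():
        pick = next(
            (c for c in codons if c[2] == "C"),
            next((c for c in codons if c[2] == "G"), codons[0]),
        )
        preferred[aa] = pick
    return preferred


@dataclass
class SyntheticConfig:
    """Knobs of the generator; identical seeds give byte-identical outputs."""

    n_strains: int = 10
    n_families: int = 500
    seed: int = 0
    presence_spectrum: np.ndarray | None = None  # over counts 1..n_strains
    length_range: tuple[int, int] = (200, 400)   # codons, before presence offset
    length_presence_offset: int = 60             # extra codons for full-presence families
    gc3_range: tuple[float, float] = (0.25, 0.75)
    gc3_shift_frac: float = 0.2  # share of gc3_range by which windows slide with presence
    selection_by_presence: Callable[[int], float] | None = None  # default concave ramp
    s_max: float = 2.2
    s_floor: float = 0.45        # selection offset (x s_max) for shared families
    s_jitter: float = 0.6        # multiplicative half-width of per-family jitter
    expression_alpha: float = 1.0
    expression_sigma: float = 0.4
    aa_gc_coupling: float = 3.0  # amino-acid GC pressure exponent at s = 0
    met_trp_prob: float = 0.04
    high_copy: int = 8
    low_copy: int = 1
    trna_jitter: int = 1
    preferred_codons: dict[str, str] | None = None

    def __post_init__(self):
        if self.n_strains < 2:
            raise ValidationError("need at least 2 strains")
        if self.presence_spectrum is not None:
            spectrum = np.asarray(self.presence_spectrum, dtype=float)
            if len(spectrum) != self.n_strains or spectrum.sum() <= 0:
                raise ValidationError("presence_spectrum must cover counts 1..n_strains")
            self.presence_spectrum = spectrum / spectrum.sum()

    def spectrum(self) -> np.ndarray:
        """U-shaped default: 25% mass at presence 1 and at n_strains each."""
        if self.presence_spectrum is not None:
            return self.presence_spectrum
        p = np.full(self.n_strains, 0.5 / max(self.n_strains - 2, 1))
        p[0] = 0.25
        p[-1] = 0.25
        return p / p.sum()

    def selection(self, presence: int) -> float:
        """Default ramp: 0 for strain-specific families, a linear rise from
        s_floor*s_max for shared families (capped below s_max), and the full
        s_max only for fully present (core) families — a core premium that
        keeps the core set distinct from the highest shared bin."""
        if self.selection_by_presence is not None:
            return float(self.selection_by_presence(presence))
        if presence <= 1:
            return 0.0
        if presence >= self.n_strains:
            return self.s_max
        frac = (presence - 1) / (self.n_strains - 1)
        return 0.85 * self.s_max * (self.s_floor + (1.0 - self.s_floor) * frac)


@dataclass
class SyntheticPangenome:
    """In-memory result of generate_pangenome; write() emits all files."""

    records_by_strain: dict[str, list[GeneRecord]]
    clusters: ClusterTable
    expression: ExpressionTable
    trna: TRNATable
    truth: pd.DataFrame
    config: SyntheticConfig

    @property
    def all_records(self) -> list[GeneRecord]:
        return [r for recs in self.records_by_strain.values() for r in recs]

    def write(self, out_dir: str | Path) -> dict:
        """Write FASTAs, tables and a manifest; returns the manifest dict."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fasta_paths = {}
        for strain, recs in sorted(self.records_by_strain.items()):
            path = out / f"{strain}.fasta"
            write_cds_fasta(recs, path)
            fasta_paths[strain] = path.name
        with open(out / "clusters.tsv", "w", encoding="utf-8", newline="\n") as fh:
            for cid in sorted(self.clusters.clusters):
                fh.write("\t".join([cid] + self.clusters.clusters[cid]) + "\n")
        write_table(
            pd.DataFrame(
                sorted(self.expression.values.items()),
                columns=["gene_id", "abundance"],
            ),
            out / "expression.tsv",
        )
        write_table(
            pd.DataFrame(
                sorted(self.trna.entries.items()),
                columns=["anticodon", "copy_number"],
            ),
            out / "trna.tsv",
        )
        write_table(self.truth, out / "truth.tsv")
        cfg = {
            f.name: getattr(self.config, f.name)
            for f in dc_fields(self.config)
            if isinstance(getattr(self.config, f.name), (int, float, str, bool))
        }
        manifest = {
            "seed": self.config.seed,
            "n_strains": self.config.n_strains,
            "n_families": self.config.n_families,
            "config": cfg,
            "fastas": fasta_paths,
            "clusters": "clusters.tsv",
            "expression": "expression.tsv",
            "trna": "trna.tsv",
            "truth": "truth.tsv",
        }
        with open(out / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest


def _quintile(presence: int, n_strains: int) -> int:
    """Presence-class index 0..4 using the default partition bins; falls
    back to a linear split when there are too few strains for the bins."""
    if n_strains >= 5:
        from .pangenome import SET_LABELS, label_for_count

        return SET_LABELS.index(label_for_count(presence, n_strains))
    return round(4 * (presence - 1) / (n_strains - 1))


class _SequenceSampler:
    """Precomputed family structure for fast mutation/selection sampling."""

    def __init__(self, code: GeneticCode, preferred: dict[str, str]):
        self.code = code
        self.preferred = preferred
        self.aas = sorted(code.degenerate_families())
        self.family_codons = {aa: code.families[aa] for aa in self.aas}
        # third-base GC indicator and preferred indicator per family codon
        self.third_gc = {
            aa: np.array([c[2] in "GC" for c in cods], dtype=float)
            for aa, cods in self.family_codons.items()
        }
        self.is_preferred = {
            aa: np.array([c == preferred.get(aa) for c in cods], dtype=float)
            for aa, cods in self.family_codons.items()
        }
        # mean GC share of the first two bases per family, for the amino-acid
        # level mutational coupling
        self.gc12_share = np.array(
            [
                np.mean([(c[0] in "GC") + (c[1] in "GC") for c in cods]) / 2.0
                for cods in (self.family_codons[aa] for aa in self.aas)
            ]
        )

    def aa_probs(self, gc: float, coupling: float) -> np.ndarray:
        w = np.exp(coupling * (self.gc12_share * np.log(max(gc, 1e-9))
                               + (1 - self.gc12_share) * np.log(max(1 - gc, 1e-9))))
        return w / w.sum()

    def codon_probs(self, aa: str, gc3: float, s: float) -> np.ndarray:
        third = self.third_gc[aa]
        m = third * gc3 / 2.0 + (1 - third) * (1 - gc3) / 2.0
        w = m * np.exp(s * self.is_preferred[aa])
        return w / w.sum()


def generate_gene_sequence(
    length_codons: int,
    gc3: float,
    s: float,
    preferred: dict[str, str] | None = None,
    rng: np.random.Generator | None = None,
    code: GeneticCode | None = None,
    aa_gc_coupling: float = 0.0,
    met_trp_prob: float = 0.04,
) -> str:
    """Sample one CDS under third-base mutational pressure ``gc3`` and
    selection ``s`` toward the preferred codon of each family.

    Within a family, codon c has probability proportional to
    m(c) * exp(s * [c preferred]) where m(c) weights the third base gc3/2
    for G/C and (1-gc3)/2 for A/T.  Amino acids are drawn over the 18
    degenerate families (tilted toward GC-rich families by
    ``aa_gc_coupling``/(1+s); 0 recovers the uniform draw), plus occasional
    Met/Trp.  A terminal TAA stop is appended.
    """
    if length_codons < 1:
        raise ValidationError("length must be >= 1 codon")
    if not 0.0 <= gc3 <= 1.0 or s < 0:
        raise ValidationError("need 0 <= gc3 <= 1 and s >= 0")
    code = code or standard_code()
    rng = rng if rng is not None else np.random.default_rng()
    preferred = preferred or default_preferred_codons(code)
    sampler = _SequenceSampler(code, preferred)
    coupling = aa_gc_coupling / (1.0 + s)
    probs = sampler.aa_probs(gc3, coupling)
    return _realize(sampler, length_codons, gc3, s, probs, met_trp_prob, rng)


def generate_trna_table(
    preferred: dict[str, str],
    high_copy: int = 8,
    low_copy: int = 1,
    rng: np.random.Generator | None = None,
    jitter: int = 0,
    code: GeneticCode | None = None,
) -> TRNATable:
    """One tRNA per sense codon (anticodon = reverse complement); preferred
    codons' anticodons get high copy numbers, the rest low_copy, plus
    optional small integer jitter.

    The high copy number is scaled by half the family's degeneracy
    (2-fold -> high_copy, 4-fold -> 2*high_copy, ...) so that the pooled
    RSCU profile of a fully selected gene set - family size on each
    preferred codon - is proportional to the tRNA vector.
    """
    if not high_copy > low_copy >= 0:
        raise ValidationError("need high_copy > low_copy >= 0")
    code = code or standard_code()
    rng = rng if rng is not None else np.random.default_rng()
    preferred_set = set(preferred.values())
    family_size = {
        codon: len(code.families[aa])
        for aa, codons in code.families.items()
        for codon in codons
    }
    entries = {}
    for codon in code.sense_codons:
        if codon in preferred_set:
            base = max(int(round(high_copy * family_size[codon] / 2.0)), low_copy + 1)
        else:
            base = low_copy
        noise = int(rng.integers(0, jitter + 1)) if jitter > 0 else 0
        entries[reverse_complement(codon)] = base + noise
    return TRNATable(entries=entries)


def generate_pangenome(
    config: SyntheticConfig, code: GeneticCode | None = None
) -> SyntheticPangenome:
    """Draw a full pangenome from the config.

    Per family: a presence count from the spectrum, member strains chosen
    uniformly without replacement, selection s from the presence ramp with
    multiplicative jitter, a gc3 parameter from a window of gc3_range that
    slides from the lower half (strain-specific) to the upper half (core),
    and one realized gene per member strain.  Expression is
    exp(alpha*s + Normal(0, sigma^2)) per gene.  Fully present families
    under strong selection are annotated as ribosomal proteins so the
    default CAI reference heuristic applies.
    """
    code = code or standard_code()
    rng = np.random.default_rng(config.seed)
    preferred = config.preferred_codons or default_preferred_codons(code)
    sampler = _SequenceSampler(code, preferred)
    strains = [f"s{j + 1:02d}" for j in range(config.n_strains)]
    spectrum = config.spectrum()
    lo, hi = config.gc3_range
    # wide windows (slope signal) sliding mildly upward with presence
    # (emulating the GC-vs-presence trend) without making strain-specific
    # genes compositionally extreme
    shift = (hi - lo) * config.gc3_shift_frac
    width = (hi - lo) - shift
    min_len, max_len = config.length_range

    records_by_strain: dict[str, list[GeneRecord]] = {s: [] for s in strains}
    clusters: dict[str, list[str]] = {}
    expression: dict[str, float] = {}
    truth_rows = []

    presence_draws = rng.choice(
        np.arange(1, config.n_strains + 1), size=config.n_families, p=spectrum
    )
    for fam in range(config.n_families):
        k = int(presence_draws[fam])
        members = [strains[i] for i in sorted(rng.choice(config.n_strains, size=k,
                                                         replace=False))]
        frac = (k - 1) / (config.n_strains - 1)
        s_base = config.selection(k)
        s = max(0.0, s_base * (1.0 + config.s_jitter * float(rng.uniform(-1, 1))))
        gc3 = float(rng.uniform(lo + frac * shift, lo + frac * shift + width))
        cid = f"fam{fam:05d}"
        is_ribosomal = k == config.n_strains and s >= 0.9 * config.s_max
        product = (
            f"50S ribosomal protein L{fam % 36 + 1}"
            if is_ribosomal
            else "hypothetical protein"
        )
        # amino-acid level mutational leakage relaxes as presence (and with
        # it selective constraint) grows; held constant within each presence
        # quintile so within-set GC12-GC3 regressions are not contaminated
        # by a coupling gradient across the quintile's presence counts
        quintile = _quintile(k, config.n_strains)
        coupling = config.aa_gc_coupling * (1.0 - quintile / 4.0)
        aa_probs = sampler.aa_probs(gc3, coupling)
        # expression noise shrinks for conserved families (quintile-constant),
        # mirroring the tighter regulation of widely shared genes
        sigma = config.expression_sigma * (1.5 - 0.25 * quintile)
        gene_ids = []
        for strain in members:
            length = int(rng.integers(min_len, max_len + 1)
                         + round(frac * config.length_presence_offset))
            seq = _realize(sampler, length, gc3, s, aa_probs,
                           config.met_trp_prob, rng)
            gene_id = f"{strain}:{cid}"
            records_by_strain[strain].append(
                GeneRecord(gene_id=gene_id, strain_id=strain, sequence=seq,
                           product=product)
            )
            mu = config.expression_alpha * s
            expression[gene_id] = float(
                np.exp(mu + sigma * rng.standard_normal())
            )
            gene_ids.append(gene_id)
            truth_rows.append(
                dict(gene_id=gene_id, cluster_id=cid, presence_count=k,
                     s=s, gc3_param=gc3, expression_noiseless=float(np.exp(mu)))
            )
        clusters[cid] = gene_ids

    trna = generate_trna_table(
        preferred, config.high_copy, config.low_copy, rng,
        jitter=config.trna_jitter, code=code,
    )
    return SyntheticPangenome(
        records_by_strain=records_by_strain,
        clusters=ClusterTable(clusters=clusters),
        expression=ExpressionTable(values=expression),
        trna=trna,
        truth=pd.DataFrame(truth_rows),
        config=config,
    )


def _realize(sampler, length, gc3, s, aa_probs, met_trp_prob, rng) -> str:
    """Inner sequence draw sharing precomputed amino-acid probabilities."""
    n_aa = len(sampler.aas)
    aa_idx = rng.choice(n_aa, size=length, p=aa_probs)
    onefold = rng.random(length) < met_trp_prob
    codons = np.empty(length, dtype=object)
    if onefold.any():
        codons[onefold] = rng.choice(["ATG", "TGG"], size=int(onefold.sum()))
    for i in range(n_aa):
        mask = (aa_idx == i) & ~onefold
        k = int(mask.sum())
        if k == 0:
            continue
        aa = sampler.aas[i]
        codons[mask] = rng.choice(
            sampler.family_codons[aa], size=k, p=sampler.codon_probs(aa, gc3, s)
        )
    return "".join(codons) + "TAA"
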