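"""Synthetic genomes, guide libraries and dropout screens with known truth.

The generators emulate the inputs of a pooled knockout experiment: a small
multi-chromosome genome with multi-exon protein-coding genes (FASTA + GTF),
optional common-variant sites (VCF), planted off-target copies of real
candidate protospacers, and readcount screens where guides against planted
essential genes deplete with an efficiency that is logistic in a planted
positional score table.  Count noise is negative binomial, parameterised by
mean and dispersion r (variance = mu + mu^2/r).

Also provides the brute-force off-target oracle used to validate the
production classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .guide_score import NUCLEOTIDES, ScoreTable, score_guide
from .library_design import (
    GeneModel,
    PROTOSPACER_LEN,
    _pam_sites,
    revcomp,
)
from .screen_data import ReadcountMatrix


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SynthGenomeSpec:
    """Layout of a synthetic genome with planted guide targets."""

    n_chromosomes: int = 1
    chromosome_length: int = 20_000
    n_genes: int = 4
    exons_per_gene: int = 3
    exon_length: int = 120
    intron_length: int = 80
    planted_offtargets: tuple = ()  # (n_sites, n_mismatches, "intergenic"|"genic")
    snp_density: float = 0.0
    seed: int = 0

    def __post_init__(self):
        per_gene = (self.exons_per_gene * self.exon_length
                    + (self.exons_per_gene - 1) * self.intron_length)
        genes_per_chrom = -(-self.n_genes // self.n_chromosomes)
        if genes_per_chrom * (per_gene + 200) + 200 > self.chromosome_length:
            raise SyntheticError(
                "planted genes exceed chromosome length; enlarge chromosomes"
            )


@dataclass(frozen=True)
class SynthScreenSpec:
    """Conditions of a simulated dropout screen.

    ``essential_fraction`` defaults to 0.1, matching the prior expectation
    that roughly a tenth of genes are essential in a given cell line.
    ``dropout_effect`` is the log2 depletion of a fully efficient guide
    against an essential gene; per-guide efficiency is
    logistic(slope * seq_score + intercept) against the planted score table
    (1.0 when no table is planted).
    """

    n_genes: int = 100
    essential_fraction: float = 0.1
    guides_per_gene: int = 4
    replicates: int = 3
    depth: float = 10_000_000.0
    dropout_effect: float = 3.0
    nb_dispersion: float = 10.0
    efficiency_slope: float = 1.5
    efficiency_intercept: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.essential_fraction < 1:
            raise SyntheticError("essential_fraction must lie in (0, 1)")
        if self.depth <= 0:
            raise SyntheticError("depth must be > 0")


@dataclass
class SynthGenome:
    """In-memory synthetic genome plus ground truth."""

    sequences: dict
    models: list
    snps: dict  # chrom -> sorted positions (0-based)
    truth_sites: pd.DataFrame  # planted on- and off-target sites

    def write(self, fasta_path, gtf_path, vcf_path=None, truth_path=None) -> None:
        write_fasta(self.sequences, fasta_path)
        write_gtf(self.models, gtf_path)
        if vcf_path is not None:
            write_vcf(self.snps, self.sequences, vcf_path)
        if truth_path is not None:
            self.truth_sites.to_csv(truth_path, sep="\t", index=False)


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list(NUCLEOTIDES), size=n))


def make_genome(spec: SynthGenomeSpec) -> SynthGenome:
    """Generate a genome with multi-exon genes and planted off-target sites.

    Gene bodies are laid out left to right with intergenic gaps; each gene
    gets one transcript whose CDS exons alternate with introns.  For each
    entry (n, m, where) of ``planted_offtargets``, n protospacers are drawn
    from candidate NGG sites inside coding exons and copies with m mismatches
    (plus an AGG PAM) are written into intergenic or intronic sequence.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    seqs = {c: list(_random_seq(rng, spec.chromosome_length)) for c in chrom_names}
    models: list[GeneModel] = []
    genes_per_chrom = -(-spec.n_genes // spec.n_chromosomes)
    gi = 0
    free_intergenic: list = []  # (chrom, start, end) gaps available for planting
    for ci, chrom in enumerate(chrom_names):
        cursor = 100
        last_end = 0
        for _ in range(genes_per_chrom):
            if gi >= spec.n_genes:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            pos = cursor
            for e in range(spec.exons_per_gene):
                exons.append((pos, pos + spec.exon_length))
                pos += spec.exon_length
                if e < spec.exons_per_gene - 1:
                    pos += spec.intron_length
            body = (cursor, pos)
            ordered = tuple(exons if strand == "+" else exons[::-1])
            models.append(GeneModel(
                gene=f"GENE{gi + 1:04d}", chrom=chrom, strand=strand,
                coding_exons=ordered, gene_body=body,
            ))
            free_intergenic.append((chrom, last_end + 30, cursor - 30))
            last_end = pos
            cursor = pos + 200
            gi += 1
        free_intergenic.append((chrom, last_end + 30, spec.chromosome_length - 30))

    # collect candidate protospacers inside coding exons for planting copies
    truth_rows = []
    genome_str = {c: "".join(s) for c, s in seqs.items()}
    candidates = []
    for m in models:
        seq = genome_str[m.chrom]
        for strand, _, proto, pam, cut, _fp in _pam_sites(seq):
            for s, e in m.coding_exons:
                if s <= cut and cut + 1 <= e - 1:
                    candidates.append((proto, m))
                    truth_rows.append({
                        "protospacer": proto, "chrom": m.chrom, "cut_site": cut,
                        "strand": strand, "gene": m.gene, "kind": "on_target",
                        "mismatches": 0,
                    })
                    break

    gaps = [g for g in free_intergenic if g[2] - g[1] >= PROTOSPACER_LEN + 3]
    introns = []
    for m in models:
        exons = sorted(m.coding_exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 - e1 >= PROTOSPACER_LEN + 9:
                introns.append((m.chrom, e1 + 3, s2 - 3, m.gene))
    occupied: dict = {}  # chrom -> list of planted intervals
    for n_sites, n_mm, where in spec.planted_offtargets:
        for _ in range(n_sites):
            if not candidates:
                raise SyntheticError("no candidate protospacers to copy")
            proto, src = candidates[int(rng.integers(len(candidates)))]
            mutated = list(proto)
            for pos in rng.choice(PROTOSPACER_LEN, size=n_mm, replace=False):
                mutated[pos] = rng.choice(
                    [nt for nt in NUCLEOTIDES if nt != mutated[pos]]
                )
            site = "".join(mutated) + "AGG"
            if where == "intergenic":
                if not gaps:
                    raise SyntheticError("no intergenic gap large enough")
            elif not introns:
                raise SyntheticError("no intron large enough for genic plant")
            for _attempt in range(100):
                if where == "intergenic":
                    chrom, lo, hi = gaps[int(rng.integers(len(gaps)))]
                    gene_hit = ""
                else:
                    chrom, lo, hi, gene_hit = introns[int(rng.integers(len(introns)))]
                start = int(rng.integers(lo, hi - len(site)))
                if all(start + len(site) <= s or start >= e
                       for s, e in occupied.get(chrom, ())):
                    break
            else:
                raise SyntheticError("could not place planted site without overlap")
            occupied.setdefault(chrom, []).append((start, start + len(site)))
            seqs[chrom][start:start + len(site)] = list(site)
            truth_rows.append({
                "protospacer": proto, "chrom": chrom,
                "cut_site": start + PROTOSPACER_LEN - 4, "strand": "+",
                "gene": gene_hit, "kind": f"planted_{where}",
                "mismatches": n_mm,
            })

    genome_str = {c: "".join(s) for c, s in seqs.items()}
    snps: dict = {}
    if spec.snp_density > 0:
        for chrom in chrom_names:
            n = rng.binomial(spec.chromosome_length, spec.snp_density)
            snps[chrom] = sorted(
                int(p) for p in rng.choice(spec.chromosome_length, size=n,
                                           replace=False)
            )
    return SynthGenome(
        sequences=genome_str,
        models=models,
        snps=snps,
        truth_sites=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# screens

def make_guide_library(
    spec: SynthScreenSpec,
    rng: np.random.Generator | None = None,
    forbid_t_tail: bool = False,
) -> pd.DataFrame:
    """Random 20-mer guide library: one row per guide with its target gene.

    ``forbid_t_tail`` redraws any T in the four PAM-proximal positions,
    mimicking source libraries that exclude such guides.
    """
    rng = rng or np.random.default_rng(spec.seed)
    rows = []
    for g in range(spec.n_genes):
        gene = f"GENE{g + 1:04d}"
        for i in range(spec.guides_per_gene):
            seq = list(_random_seq(rng, PROTOSPACER_LEN))
            if forbid_t_tail:
                for pos in range(16, 20):
                    while seq[pos] == "T":
                        seq[pos] = rng.choice(list(NUCLEOTIDES))
            rows.append({"GUIDE": f"{gene}_g{i + 1}", "GENE": gene,
                         "SEQUENCE": "".join(seq)})
    return pd.DataFrame(rows)


def _nb_counts(rng, mean: np.ndarray, r: float) -> np.ndarray:
    """Negative binomial draws with variance mu + mu^2/r."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def make_screen(
    spec: SynthScreenSpec,
    library: pd.DataFrame | None = None,
    score_table: ScoreTable | None = None,
    essential_genes: Sequence[str] | None = None,
) -> tuple[ReadcountMatrix, dict]:
    """Simulate a dropout screen over a guide library.

    T0 counts are negative binomial around uniform abundance.  Endpoint
    abundance of guides targeting essential genes is multiplied by
    2**(-dropout_effect * efficiency) before renormalisation and resampling,
    where efficiency is logistic in the guide's planted sequence score.
    Returns the readcount matrix and a truth dict with the essential gene
    set and per-guide efficiencies.
    """
    rng = np.random.default_rng(spec.seed)
    if library is None:
        library = make_guide_library(spec, rng)
    genes = list(pd.unique(library["GENE"]))
    if essential_genes is None:
        n_ess = max(1, round(spec.essential_fraction * len(genes)))
        essential = set(rng.choice(genes, size=n_ess, replace=False))
    else:
        essential = set(essential_genes)
    n_guides = len(library)
    is_ess = library["GENE"].isin(essential).to_numpy()

    if score_table is not None:
        scores = np.array([score_guide(s, score_table)
                           for s in library["SEQUENCE"]])
        eff = 1.0 / (1.0 + np.exp(-(spec.efficiency_slope * scores
                                    + spec.efficiency_intercept)))
    else:
        eff = np.ones(n_guides)
    depletion = np.where(is_ess, 2.0 ** (-spec.dropout_effect * eff), 1.0)

    t0_mean = spec.depth / n_guides
    t0 = _nb_counts(rng, np.full(n_guides, t0_mean), spec.nb_dispersion)
    counts = {"T0": t0}
    roles = {"T0": "t0_control"}
    base = np.maximum(t0.astype(float), 0.5) * depletion
    for r in range(spec.replicates):
        mean_end = base * (spec.depth / base.sum())
        counts[f"REP{r + 1}"] = _nb_counts(rng, mean_end, spec.nb_dispersion)
        roles[f"REP{r + 1}"] = "endpoint"
    rc = ReadcountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(library["GUIDE"], name="GUIDE")),
        gene_of_guide=pd.Series(library["GENE"].to_numpy(),
                                index=pd.Index(library["GUIDE"], name="GUIDE")),
        sample_roles=roles,
    )
    truth = {
        "essential_genes": essential,
        "guide_efficiency": pd.Series(eff, index=pd.Index(library["GUIDE"])),
        "library": library,
    }
    return rc, truth


def make_score_table(seed: int = 0, sparsity: float = 0.5) -> ScoreTable:
    """Random planted score table: sparse weights, scaled to max |cell| = 1."""
    rng = np.random.default_rng(seed)
    w = rng.normal(0, 1, size=(4, PROTOSPACER_LEN))
    w[rng.random(w.shape) < sparsity] = 0.0
    if np.abs(w).max() == 0:
        w[1, 17] = 1.0
    w = w - w.mean(axis=0)  # delta-frequency columns sum to zero
    w = w / np.abs(w).max()
    df = pd.DataFrame(w, index=list(NUCLEOTIDES),
                      columns=range(1, PROTOSPACER_LEN + 1))
    r, c = np.unravel_index(np.argmax(np.abs(w)), w.shape)
    return ScoreTable(weights=df, provenance=["planted"],
                      scale_anchor=(NUCLEOTIDES[r], int(c) + 1))


# ---------------------------------------------------------------------------
# oracle

def oracle_offtargets(
    protospacer: str,
    genome: Mapping[str, str],
    max_mismatches: int = 2,
) -> pd.DataFrame:
    """Exhaustive scan for NGG sites matching a protospacer.

    Slides over every offset of both strands of every chromosome, checks the
    PAM literally and counts protospacer mismatches position by position.
    Independent of the indexed production classifier; intended for genomes
    up to ~1 Mb.
    """
    rows = []
    L = PROTOSPACER_LEN
    for chrom, seq in genome.items():
        seq = str(seq).upper()
        n = len(seq)
        for p in range(L, n - 2):  # plus strand: protospacer [p-20, p), PAM [p, p+3)
            if seq[p + 1] == "G" and seq[p + 2] == "G":
                mm = sum(1 for a, b in zip(protospacer, seq[p - L:p]) if a != b)
                if mm <= max_mismatches:
                    rows.append({"chrom": chrom, "cut_site": p - 4,
                                 "strand": "+", "mismatches": mm})
        rc_proto = revcomp(protospacer)
        for q in range(0, n - L - 2):  # minus strand: CCN then revcomp protospacer
            if seq[q] == "C" and seq[q + 1] == "C":
                mm = sum(1 for a, b in zip(rc_proto, seq[q + 3:q + 3 + L]) if a != b)
                if mm <= max_mismatches:
                    rows.append({"chrom": chrom, "cut_site": q + 5,
                                 "strand": "-", "mismatches": mm})
    return pd.DataFrame(rows, columns=["chrom", "cut_site", "strand", "mismatches"])


# ---------------------------------------------------------------------------
# writers

def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gtf(models: Sequence[GeneModel], path) -> None:
    """Emit gene/transcript/CDS features (1-based inclusive, GTF attributes)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = (f'gene_id "{m.gene}"; transcript_id "{m.gene}.t1";')
            lo, hi = m.gene_body
            fh.write("\t".join([
                m.chrom, "synth", "gene", str(lo + 1), str(hi), ".",
                m.strand, ".", f'gene_id "{m.gene}";',
            ]) + "\n")
            fh.write("\t".join([
                m.chrom, "synth", "transcript", str(lo + 1), str(hi), ".",
                m.strand, ".", attrs,
            ]) + "\n")
            for s, e in sorted(m.coding_exons):
                fh.write("\t".join([
                    m.chrom, "synth", "CDS", str(s + 1), str(e), ".",
                    m.strand, "0", attrs,
                ]) + "\n")


def write_vcf(snps: Mapping[str, Sequence[int]], sequences: Mapping[str, str],
              path) -> None:
    alt_of = {"A": "G", "C": "T", "G": "A", "T": "C"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, seq in sequences.items():
            fh.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom in sequences:
            for pos in snps.get(chrom, ()):
                ref = sequences[chrom][pos]
                fh.write(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt_of.get(ref, 'A')}"
                         f"\t.\tPASS\t.\n")
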