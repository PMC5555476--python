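"""Genome-scale SpCas9 knockout library design.

Pipeline: enumerate every 20-mer protospacer adjacent to an NGG PAM whose
blunt cut site (between protospacer positions 17 and 18, i.e. 3 bp 5' of
the PAM) falls inside a coding exon; filter on GC content, homopolymers,
restriction sites and common variants; classify candidates by genome-wide
off-target hits within two protospacer mismatches; combine off-target class
with the empirical sequence score into selection ranks; and greedily select
up to four guides per gene, preferring exon diversity.

Coordinates are 0-based half-open internally and 1-based inclusive in all
emitted tables.  One canonical transcript per gene (longest total CDS)
defines the coding exons, numbered ascending from the transcription start
site.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .guide_score import ScoreTable, score_guide

PROTOSPACER_LEN = 20
_COMP = str.maketrans("ACGTN", "TGCAN")

#: Default forbidden restriction sites (AgeI, KpnI, BveI/BspMI, BsmI, BsmBI).
DEFAULT_FORBIDDEN_SITES = ("ACCGGT", "GGTACC", "ACCTGC", "GAATGC", "CGTCTC")


class LibraryDesignError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """Canonical-transcript coding exons plus the full gene body span.

    ``coding_exons`` are 0-based half-open intervals ordered so that exon 1
    is the closest to the transcription start site (ascending genomic
    coordinate on '+', descending on '-').
    """

    gene: str
    chrom: str
    strand: str
    coding_exons: tuple
    gene_body: tuple

    def __post_init__(self):
        if self.strand not in "+-":
            raise LibraryDesignError(f"bad strand {self.strand!r}")
        exons = sorted(self.coding_exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise LibraryDesignError(
                    f"overlapping coding exons in gene {self.gene}"
                )

    def exon_number(self, idx: int) -> int:
        """1-based exon number of ``coding_exons[idx]`` (transcription order)."""
        return idx + 1


@dataclass
class CandidateGuide:
    """A candidate protospacer with its annotations through the pipeline."""

    protospacer: str
    pam: str
    chrom: str
    strand: str
    cut_site: int  # 0-based: plus-strand base immediately 5' of the blunt cut
    target_gene: str
    target_exon: int
    gc_fraction: float
    seq_score: float | None = None
    offtarget_class: int | str | None = None  # 1..4 or "excluded"
    n_target_hits: int | None = None
    n_intergenic_offtargets: int | None = None
    rank: int | None = None
    selection_round: int | None = None
    rejection_reason: str | None = None


@dataclass(frozen=True)
class FilterConfig:
    gc_min: float = 0.40
    gc_max: float = 0.75
    max_homopolymer: int = 3  # runs of length max_homopolymer+1 are rejected
    forbidden_sites: tuple = DEFAULT_FORBIDDEN_SITES
    snp_filter: bool = True

    def __post_init__(self):
        if not 0 <= self.gc_min < self.gc_max <= 1:
            raise LibraryDesignError("require 0 <= gc_min < gc_max <= 1")


@dataclass(frozen=True)
class RankTier:
    rank: int
    classes: frozenset
    min_score: float
    max_score: float
    min_inclusive: bool
    max_inclusive: bool

    def admits(self, offtarget_class, score: float) -> bool:
        if offtarget_class not in self.classes:
            return False
        lo_ok = score >= self.min_score if self.min_inclusive else score > self.min_score
        hi_ok = score <= self.max_score if self.max_inclusive else score < self.max_score
        return lo_ok and hi_ok


#: Selection tiers combining off-target class with sequence-score intervals;
#: a candidate receives the first tier it satisfies.
DEFAULT_RANK_RULE: tuple[RankTier, ...] = (
    RankTier(1, frozenset({1}), 0.0, float("inf"), False, True),
    RankTier(2, frozenset({1, 2, 3}), 0.85, float("inf"), False, True),
    RankTier(3, frozenset({1, 2, 3, 4}), 0.85, float("inf"), False, True),
    RankTier(4, frozenset({1, 2, 3}), 0.0, 0.85, True, True),
    RankTier(5, frozenset({1, 2, 3, 4}), -1.0, 0.85, True, True),
)


@dataclass
class LibraryDesign:
    """Selected guides per gene plus appended controls and bookkeeping."""

    selected: list
    controls: list  # (guide_id, sequence) pairs
    untargeted_genes: list
    conflicts: list = field(default_factory=list)
    guides_per_gene: int = 4

    @property
    def size(self) -> int:
        return len(self.selected) + len(self.controls)

    def summary(self) -> dict:
        per_rank: dict = {}
        for c in self.selected:
            per_rank[c.rank] = per_rank.get(c.rank, 0) + 1
        return {
            "n_selected": len(self.selected),
            "n_controls": len(self.controls),
            "library_size": self.size,
            "per_rank": {str(k): per_rank[k] for k in sorted(per_rank)},
            "n_untargeted_genes": len(self.untargeted_genes),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.selected, start=1):
            rows.append({
                "GUIDE_ID": f"{c.target_gene}_g{i}",
                "GENE": c.target_gene,
                "EXON": c.target_exon,
                "CHROM": c.chrom,
                "CUT_POS": c.cut_site + 1,
                "STRAND": c.strand,
                "PROTOSPACER": c.protospacer,
                "PAM": c.pam,
                "GC": round(c.gc_fraction, 4),
                "SEQSCORE": c.seq_score,
                "CLASS": c.offtarget_class,
                "RANK": c.rank,
                "ROUND": c.selection_round,
            })
        for cid, seq in self.controls:
            rows.append({
                "GUIDE_ID": cid, "GENE": "CONTROL", "EXON": pd.NA,
                "CHROM": pd.NA, "CUT_POS": pd.NA, "STRAND": pd.NA,
                "PROTOSPACER": seq, "PAM": pd.NA, "GC": pd.NA,
                "SEQSCORE": pd.NA, "CLASS": pd.NA, "RANK": pd.NA, "ROUND": pd.NA,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# input readers

def load_genome(genome) -> dict[str, str]:
    """Accept a dict of chromosome sequences, a FASTA path, or a pyfaidx Fasta."""
    if isinstance(genome, dict):
        return {k: str(v).upper() for k, v in genome.items()}
    try:
        from pyfaidx import Fasta
    except ImportError:  # pragma: no cover
        Fasta = None
    if Fasta is not None and isinstance(genome, Fasta):
        return {name: str(genome[name][:]).upper() for name in genome.keys()}
    fa = Fasta(str(genome))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def load_gene_models(gtf_path) -> list[GeneModel]:
    """Build per-gene models from CDS features of a GTF/GFF3 file.

    The transcript with the longest total CDS is the canonical one (ties
    broken by transcript id); the gene body spans all CDS of the gene, or
    the 'gene' feature when present.
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    per_tx: dict = {}
    gene_span: dict = {}
    gene_meta: dict = {}
    for cds in db.features_of_type("CDS"):
        gene = cds.attributes["gene_id"][0]
        tx = cds.attributes["transcript_id"][0]
        per_tx.setdefault((gene, tx), []).append((cds.start - 1, cds.end))
        lo, hi = gene_span.get(gene, (cds.start - 1, cds.end))
        gene_span[gene] = (min(lo, cds.start - 1), max(hi, cds.end))
        gene_meta[gene] = (cds.seqid, cds.strand)
    try:
        for g in db.features_of_type("gene"):
            gid = g.attributes["gene_id"][0]
            gene_span[gid] = (g.start - 1, g.end)
    except Exception:
        pass
    models = []
    for gene in sorted({g for g, _ in per_tx}):
        txs = {tx: exons for (g, tx), exons in per_tx.items() if g == gene}
        canonical = max(
            sorted(txs), key=lambda tx: sum(e - s for s, e in txs[tx])
        )
        exons = sorted(txs[canonical])
        chrom, strand = gene_meta[gene]
        if strand == "-":
            exons = exons[::-1]
        models.append(GeneModel(
            gene=gene, chrom=chrom, strand=strand,
            coding_exons=tuple(exons), gene_body=gene_span[gene],
        ))
    return models


def read_variant_positions(vcf_path) -> dict[str, set]:
    """0-based positions of variant sites per chromosome from a VCF."""
    import pysam

    out: dict[str, set] = {}
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            out.setdefault(rec.chrom, set()).add(rec.start)
    return out


# ---------------------------------------------------------------------------
# candidate enumeration

def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _pam_sites(seq: str):
    """Yield (strand, pam_start, protospacer, pam, cut_site, footprint).

    ``cut_site`` is the 0-based plus-strand coordinate of the base
    immediately 5' of the blunt cut; ``footprint`` is the half-open
    plus-strand interval covered by protospacer + PAM.
    """
    n = len(seq)
    for p in range(PROTOSPACER_LEN, n - 2):
        if seq[p + 1] == "G" and seq[p + 2] == "G":
            proto = seq[p - PROTOSPACER_LEN:p]
            yield "+", p, proto, seq[p:p + 3], p - 4, (p - PROTOSPACER_LEN, p + 3)
    for q in range(0, n - PROTOSPACER_LEN - 2):
        if seq[q] == "C" and seq[q + 1] == "C":
            proto = revcomp(seq[q + 3:q + 3 + PROTOSPACER_LEN])
            pam = revcomp(seq[q:q + 3])
            yield "-", q, proto, pam, q + 5, (q, q + 3 + PROTOSPACER_LEN)


def enumerate_candidates(
    genome, models: Sequence[GeneModel]
) -> list[CandidateGuide]:
    """All NGG-adjacent 20-mers whose cut site lies inside a coding exon.

    The cut is blunt, between protospacer positions 17 and 18; a candidate
    requires both cut-flanking bases inside the exon.  Candidates are
    recorded once per (gene, site); a site inside exons of two genes yields
    one candidate per gene.
    """
    seqs = load_genome(genome)
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        if m.chrom not in seqs:
            raise LibraryDesignError(f"chromosome {m.chrom!r} absent from genome")
        chrom_len = len(seqs[m.chrom])
        for s, e in m.coding_exons:
            if e > chrom_len or s < 0:
                raise LibraryDesignError(
                    f"exon ({s},{e}) of gene {m.gene} beyond chromosome end"
                )
        by_chrom.setdefault(m.chrom, []).append(m)
    out = []
    for chrom, chrom_models in by_chrom.items():
        seq = seqs[chrom]
        for strand, _, proto, pam, cut, _fp in _pam_sites(seq):
            if len(proto) < PROTOSPACER_LEN or set(proto) - set("ACGT"):
                continue
            for m in chrom_models:
                for idx, (s, e) in enumerate(m.coding_exons):
                    if s <= cut and cut + 1 <= e - 1:
                        out.append(CandidateGuide(
                            protospacer=proto, pam=pam, chrom=chrom,
                            strand=strand, cut_site=cut, target_gene=m.gene,
                            target_exon=m.exon_number(idx),
                            gc_fraction=_gc_fraction(proto),
                        ))
                        break
    return out


# ---------------------------------------------------------------------------
# filtering

def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _footprint(cand: CandidateGuide) -> tuple[int, int]:
    """Plus-strand half-open interval covered by protospacer + PAM."""
    if cand.strand == "+":
        pam_start = cand.cut_site + 4
        return pam_start - PROTOSPACER_LEN, pam_start + 3
    q = cand.cut_site - 5
    return q, q + 3 + PROTOSPACER_LEN


def apply_filters(
    cands: Iterable[CandidateGuide],
    cfg: FilterConfig | None = None,
    snps: Mapping[str, set] | None = None,
) -> tuple[list[CandidateGuide], list[CandidateGuide]]:
    """Split candidates into (retained, rejected); rejections carry reasons.

    Rejects GC outside [gc_min, gc_max], homopolymer runs longer than
    ``max_homopolymer``, forbidden sites anywhere in protospacer+PAM on
    either strand, and (when enabled) variant positions overlapping the
    protospacer or PAM.
    """
    cfg = cfg or FilterConfig()
    snps = snps or {}
    retained, rejected = [], []
    for c in cands:
        reason = None
        context = c.protospacer + c.pam
        if not cfg.gc_min <= c.gc_fraction <= cfg.gc_max:
            reason = "gc"
        elif _max_homopolymer(c.protospacer) > cfg.max_homopolymer:
            reason = "homopolymer"
        elif any(site in context or site in revcomp(context)
                 for site in cfg.forbidden_sites):
            reason = "restriction_site"
        elif cfg.snp_filter and c.chrom in snps:
            lo, hi = _footprint(c)
            if any(lo <= pos < hi for pos in snps[c.chrom]):
                reason = "snp"
        if reason is None:
            retained.append(c)
        else:
            c.rejection_reason = reason
            rejected.append(c)
    return retained, rejected


# ---------------------------------------------------------------------------
# off-target classification

_ENCODE = np.full(128, 4, dtype=np.uint8)
for _i, _nt in enumerate("ACGT"):
    _ENCODE[ord(_nt)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


class GenomeSiteIndex:
    """All NGG-PAM protospacer sites of a genome, encoded for fast matching.

    Built once per genome; ``hits`` returns every site within a mismatch
    budget of a query protospacer (PAM fixed to NGG; mismatches counted on
    the 20-mer only).
    """

    def __init__(self, genome):
        seqs = load_genome(genome)
        mats, chroms, cuts, strands = [], [], [], []
        for chrom, seq in seqs.items():
            enc = _encode(seq)
            for strand, _, proto, _pam, cut, _fp in _pam_sites(seq):
                if len(proto) < PROTOSPACER_LEN:
                    continue
                mats.append(_encode(proto))
                chroms.append(chrom)
                cuts.append(cut)
                strands.append(strand)
        self.matrix = (np.vstack(mats) if mats
                       else np.empty((0, PROTOSPACER_LEN), dtype=np.uint8))
        self.chroms = np.array(chroms)
        self.cut_sites = np.array(cuts, dtype=np.int64)
        self.strands = np.array(strands)

    def hits(self, protospacer: str, max_mismatches: int = 2) -> pd.DataFrame:
        if self.matrix.shape[0] == 0:
            return pd.DataFrame(columns=["chrom", "cut_site", "strand", "mismatches"])
        query = _encode(protospacer)
        mm = (self.matrix != query).sum(axis=1)
        sel = mm <= max_mismatches
        return pd.DataFrame({
            "chrom": self.chroms[sel],
            "cut_site": self.cut_sites[sel],
            "strand": self.strands[sel],
            "mismatches": mm[sel].astype(int),
        })


def _site_location(chrom: str, cut_site: int, models: Sequence[GeneModel],
                   target_gene: str) -> str:
    """'target', 'genic' (a different gene's body) or 'intergenic'."""
    loc = "intergenic"
    for m in models:
        if m.chrom == chrom and m.gene_body[0] <= cut_site < m.gene_body[1]:
            if m.gene == target_gene:
                return "target"
            loc = "genic"
    return loc


def classify_offtargets(
    cand: CandidateGuide,
    index: GenomeSiteIndex,
    models: Sequence[GeneModel],
    max_mismatches: int = 2,
) -> int | str:
    """Assign the off-target class of a filtered candidate.

    All genomic NGG sites within ``max_mismatches`` protospacer mismatches
    are located against the gene models (by cut site).  Any hit inside a
    different gene's body (exon or intron) excludes the guide.  Otherwise:
    class 1 = multiple target-gene hits and no off-targets; class 2 = unique
    target hit, no off-targets; class 3 = one or two intergenic off-targets;
    class 4 = three intergenic off-targets; more than three excludes.
    Target-gene hits never count against the off-target budget.
    """
    hits = index.hits(cand.protospacer, max_mismatches)
    if hits.empty:
        raise LibraryDesignError(
            f"no genomic hit found for candidate {cand.protospacer} "
            "(the target site itself must match)"
        )
    n_target = n_intergenic = 0
    for _, h in hits.iterrows():
        loc = _site_location(h["chrom"], int(h["cut_site"]), models,
                             cand.target_gene)
        if loc == "target":
            n_target += 1
        elif loc == "genic":
            cand.offtarget_class = "excluded"
            cand.n_target_hits = n_target
            cand.rejection_reason = "genic_offtarget"
            return "excluded"
        else:
            n_intergenic += 1
    if n_target == 0:
        raise LibraryDesignError(
            f"candidate {cand.protospacer} has hits but none in its target gene"
        )
    cand.n_target_hits = n_target
    cand.n_intergenic_offtargets = n_intergenic
    if n_intergenic == 0:
        cls = 1 if n_target >= 2 else 2
    elif n_intergenic <= 2:
        cls = 3
    elif n_intergenic == 3:
        cls = 4
    else:
        cls = "excluded"
        cand.rejection_reason = "too_many_offtargets"
    cand.offtarget_class = cls
    return cls


# ---------------------------------------------------------------------------
# ranking and selection

def assign_ranks(
    cands: Iterable[CandidateGuide],
    table: ScoreTable | None = None,
    rules: Sequence[RankTier] = DEFAULT_RANK_RULE,
) -> list[CandidateGuide]:
    """Give each candidate the first selection tier it satisfies.

    Scores are computed from ``table`` when given (otherwise ``seq_score``
    must already be set).  Excluded or never-qualifying candidates stay
    unranked.
    """
    out = []
    for c in cands:
        if table is not None:
            c.seq_score = score_guide(c.protospacer, table)
        if c.seq_score is None:
            raise LibraryDesignError("candidate has no sequence score")
        c.rank = None
        if c.offtarget_class != "excluded" and c.offtarget_class is not None:
            for tier in rules:
                if tier.admits(c.offtarget_class, c.seq_score):
                    c.rank = tier.rank
                    break
        out.append(c)
    return out


def select_library(
    cands: Sequence[CandidateGuide],
    guides_per_gene: int = 4,
    controls: Sequence[tuple] = (),
    gene_order: Sequence[str] | None = None,
) -> LibraryDesign:
    """Greedy rank-by-rank selection of up to ``guides_per_gene`` per gene.

    Within each rank, selection proceeds in rounds: every gene still below
    quota picks its highest-scoring unselected candidate, preferring exons
    without a selected guide and falling back to already-targeted exons only
    when no fresh-exon candidate remains in the rank.  Ties break by lower
    exon number, then lexicographic protospacer.  A protospacer shared by
    two genes goes to the first gene in ``gene_order``; the conflict is
    logged.  The procedure is deterministic.
    """
    if gene_order is None:
        seen = {}
        for c in cands:
            seen.setdefault(c.target_gene, None)
        gene_order = list(seen)
    ranks = sorted({c.rank for c in cands if c.rank is not None})
    pools: dict = {}
    for c in cands:
        if c.rank is not None:
            pools.setdefault((c.target_gene, c.rank), []).append(c)

    selected: dict[str, list] = {g: [] for g in gene_order}
    exons_used: dict[str, set] = {g: set() for g in gene_order}
    used_protospacers: set = set()
    conflicts: list = []
    order: list = []

    for rank in ranks:
        rnd = 0
        while True:
            rnd += 1
            progress = False
            for gene in gene_order:
                if len(selected[gene]) >= guides_per_gene:
                    continue
                pool = [c for c in pools.get((gene, rank), ())
                        if c.selection_round is None]
                avail = []
                for c in pool:
                    if c.protospacer in used_protospacers:
                        conflicts.append((gene, c.protospacer))
                        c.selection_round = -1  # consumed by another gene
                        continue
                    avail.append(c)
                if not avail:
                    continue
                fresh = [c for c in avail
                         if c.target_exon not in exons_used[gene]]
                pick_from = fresh if fresh else avail
                best = min(pick_from, key=lambda c: (-c.seq_score,
                                                     c.target_exon,
                                                     c.protospacer))
                best.selection_round = rnd
                selected[gene].append(best)
                exons_used[gene].add(best.target_exon)
                used_protospacers.add(best.protospacer)
                order.append(best)
                progress = True
            if not progress or all(
                len(selected[g]) >= guides_per_gene for g in gene_order
            ):
                break
    untargeted = [g for g in gene_order if not selected[g]]
    return LibraryDesign(
        selected=order, controls=list(controls),
        untargeted_genes=untargeted, conflicts=conflicts,
        guides_per_gene=guides_per_gene,
    )


def design_library(
    genome,
    models: Sequence[GeneModel],
    score_table: ScoreTable,
    snps: Mapping[str, set] | None = None,
    filter_cfg: FilterConfig | None = None,
    guides_per_gene: int = 4,
    controls: Sequence[tuple] = (),
    max_mismatches: int = 2,
) -> tuple[LibraryDesign, dict]:
    """Run the full design pipeline; returns the design and a run summary."""
    cands = enumerate_candidates(genome, models)
    retained, rejected = apply_filters(cands, filter_cfg, snps)
    index = GenomeSiteIndex(genome)
    for c in retained:
        classify_offtargets(c, index, models, max_mismatches)
    ranked = assign_ranks(retained, score_table)
    design = select_library(ranked, guides_per_gene, controls)
    summary = design.summary()
    summary.update({
        "n_candidates": len(cands),
        "n_filtered_out": len(rejected),
        "n_excluded_offtarget": sum(
            1 for c in retained if c.offtarget_class == "excluded"
        ),
        "candidates_per_rank": {
            str(r): sum(1 for c in ranked if c.rank == r)
            for r in sorted({c.rank for c in ranked if c.rank is not None})
        },
    })
    return design, summary


def write_library(design: LibraryDesign, tsv_path, summary_path=None,
                  summary: dict | None = None) -> None:
    design.to_frame().to_csv(tsv_path, sep="\t", index=False)
    if summary_path is not None:
        with open(summary_path, "w") as fh:
            json.dump(summary or design.summary(), fh, indent=2)
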