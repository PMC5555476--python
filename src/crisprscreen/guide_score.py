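"""Positional nucleotide sequence score for SpCas9 guides.

The score is empirical: within each screen sample, core-essential genes with
exactly six retained guides are split into the three most-depleted ("best")
and three remaining ("worst") guides.  Positional nucleotide frequencies of
the two pools are subtracted (best - worst), the per-sample delta tables are
summed, and the summed table is scaled so that its most extreme cell has
absolute value one.  Cells never observed in the source library in either
pool get no data and are assigned a weight of -1, penalising compositions
the training library deliberately avoided.

Position 1 is the PAM-distal end of the 20-mer protospacer; position 20 is
PAM-proximal.  A guide's score is the sum of its per-position weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .essentiality import ReferenceSets
from .screen_data import FoldchangeMatrix

NUCLEOTIDES = ("A", "C", "G", "T")
GUIDE_LENGTH = 20
GUIDES_PER_GENE_REQUIRED = 6  # genes qualify only with exactly this many retained


class GuideScoreError(ValueError):
    pass


@dataclass
class ScoreTable:
    """4 x 20 positional weight matrix for guide scoring.

    ``weights`` rows are A,C,G,T; columns are positions 1..20 (20 =
    PAM-proximal).  After scaling, max |cell| = 1; ``scale_anchor`` records
    the (nucleotide, position) of the extreme cell.
    """

    weights: pd.DataFrame
    provenance: list = field(default_factory=list)
    scale_anchor: tuple[str, int] | None = None

    def __post_init__(self):
        self.weights = self.weights.reindex(index=list(NUCLEOTIDES),
                                            columns=range(1, GUIDE_LENGTH + 1))
        self.weights.index.name = "NT"
        self.weights.columns.name = None
        if self.weights.isna().any().any():
            raise GuideScoreError("score table must cover 4 nucleotides x 20 positions")

    def to_tsv(self, path, sidecar_path=None) -> None:
        out = self.weights.copy()
        out.columns = [f"P{p}" for p in out.columns]
        out.to_csv(path, sep="\t", index_label="NT")
        if sidecar_path is not None:
            meta = {
                "provenance": list(self.provenance),
                "scale_anchor": list(self.scale_anchor) if self.scale_anchor else None,
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def from_tsv(cls, path, sidecar_path=None) -> "ScoreTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.columns = [int(str(c).lstrip("P")) for c in df.columns]
        prov, anchor = [], None
        if sidecar_path is not None:
            with open(sidecar_path) as fh:
                meta = json.load(fh)
            prov = meta.get("provenance", [])
            if meta.get("scale_anchor"):
                nt, pos = meta["scale_anchor"]
                anchor = (nt, int(pos))
        return cls(weights=df.astype(float), provenance=prov, scale_anchor=anchor)


def _check_seq(seq: str) -> str:
    seq = seq.upper()
    if len(seq) != GUIDE_LENGTH:
        raise GuideScoreError(f"guide must be {GUIDE_LENGTH} nt, got {len(seq)}")
    bad = set(seq) - set(NUCLEOTIDES)
    if bad:
        raise GuideScoreError(f"non-ACGT characters in guide: {sorted(bad)}")
    return seq


def _positional_counts(seqs: Iterable[str]) -> pd.DataFrame:
    counts = pd.DataFrame(0, index=list(NUCLEOTIDES),
                          columns=range(1, GUIDE_LENGTH + 1), dtype=float)
    for seq in seqs:
        for pos, nt in enumerate(_check_seq(seq), start=1):
            counts.at[nt, pos] += 1
    return counts


def best_worst_split(fc_sample: pd.Series, guides: Sequence[str]) -> tuple[list, list]:
    """Split a gene's six guides into the three most-depleted and the rest.

    Ties in fold-change are broken by guide sequence lexicographic order so
    the split is deterministic.
    """
    order = sorted(guides, key=lambda g: (fc_sample.loc[g], g))
    return order[:3], order[3:]


def derive_score_table(
    fc_samples: Sequence[FoldchangeMatrix],
    guide_seqs: Mapping[str, str],
    core_genes: Iterable[str],
    sample_labels: Sequence[str] | None = None,
) -> ScoreTable:
    """Derive the delta-frequency score table from screen fold-changes.

    Each replicate column of each matrix is one sample.  Per sample, every
    core gene with exactly six retained guides contributes its best/worst
    pools; frequencies are pooled over genes, delta = freq_best - freq_worst,
    tables summed over samples, then scaled so max |cell| = 1.  Cells with
    zero observations in both pools across all samples are set to -1.
    """
    core = set(core_genes)
    if not fc_samples:
        raise GuideScoreError("at least one fold-change sample is required")
    delta_sum = pd.DataFrame(0.0, index=list(NUCLEOTIDES),
                             columns=range(1, GUIDE_LENGTH + 1))
    observed = pd.DataFrame(0.0, index=list(NUCLEOTIDES),
                            columns=range(1, GUIDE_LENGTH + 1))
    provenance = []
    any_gene = False
    for i, fcm in enumerate(fc_samples):
        for rep in fcm.replicates:
            col = fcm.fc[rep]
            label = (sample_labels[len(provenance)]
                     if sample_labels else f"matrix{i}:{rep}")
            best_seqs, worst_seqs = [], []
            for gene in sorted(core):
                guides = fcm.guides_of_gene(gene)
                if len(guides) != GUIDES_PER_GENE_REQUIRED:
                    continue
                best, worst = best_worst_split(col, guides)
                best_seqs += [guide_seqs[g] for g in best]
                worst_seqs += [guide_seqs[g] for g in worst]
            if not best_seqs:
                continue
            any_gene = True
            provenance.append(label)
            cb = _positional_counts(best_seqs)
            cw = _positional_counts(worst_seqs)
            delta_sum += cb / len(best_seqs) - cw / len(worst_seqs)
            observed += cb + cw
    if not any_gene:
        raise GuideScoreError("no gene with exactly six retained guides in any sample")
    extreme = np.abs(delta_sum.to_numpy()).max()
    if extreme == 0:
        raise GuideScoreError("all-zero table: best and worst pools are identical")
    scaled = delta_sum / extreme
    arr = scaled.to_numpy()
    # among maximal-|weight| cells prefer the positive one (then A<C<G<T, pos)
    ties = np.argwhere(np.isclose(np.abs(arr), 1.0))
    r, c = min(ties, key=lambda rc: (-arr[rc[0], rc[1]], rc[0], rc[1]))
    anchor = (NUCLEOTIDES[r], int(scaled.columns[c]))
    scaled = scaled.where(observed > 0, -1.0)
    return ScoreTable(weights=scaled, provenance=provenance, scale_anchor=anchor)


def score_guide(seq: str, table: ScoreTable) -> float:
    """Score a 20-mer as the sum of per-position nucleotide weights."""
    seq = _check_seq(seq)
    w = table.weights
    return float(sum(w.at[nt, pos] for pos, nt in enumerate(seq, start=1)))


def score_guides(seqs: Iterable[str], table: ScoreTable) -> pd.Series:
    """Vectorised scoring of many guides; returns a Series indexed by sequence."""
    seqs = [_check_seq(s) for s in seqs]
    w = table.weights.to_numpy()
    lut = {nt: i for i, nt in enumerate(NUCLEOTIDES)}
    scores = [w[[lut[nt] for nt in s], range(GUIDE_LENGTH)].sum() for s in seqs]
    return pd.Series(scores, index=pd.Index(seqs, name="GUIDE"), dtype=float)


def quartile_validation(
    fc: FoldchangeMatrix,
    guide_seqs: Mapping[str, str],
    table: ScoreTable,
    refs: ReferenceSets,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Compare dropout of top- vs bottom-scoring essential-targeting guides.

    Guides targeting reference essential genes are scored and split at the
    score quartiles; the mean-across-replicate fold-change distributions of
    the top and bottom quartiles are compared by a two-sided Welch T-test.
    Returns (top_quartile_fc, bottom_quartile_fc, p_value); p is NaN when
    the test is undefined (zero variance in both groups).
    """
    ess_guides = [g for g in fc.guide_ids
                  if fc.gene_of_guide.loc[g] in refs.essentials]
    if len(ess_guides) < 8:
        raise GuideScoreError(
            f"need >= 8 guides targeting reference essentials, got {len(ess_guides)}"
        )
    scores = pd.Series({g: score_guide(guide_seqs[g], table) for g in ess_guides})
    mean_fc = fc.fc.loc[ess_guides].mean(axis=1)
    q1, q3 = scores.quantile([0.25, 0.75])
    bottom = mean_fc[scores[scores <= q1].index].to_numpy()
    top = mean_fc[scores[scores >= q3].index].to_numpy()
    if len(top) == 0 or len(bottom) == 0:
        raise GuideScoreError("empty score quartile")
    if np.var(top) == 0 and np.var(bottom) == 0:
        return top, bottom, float("nan")
    p = stats.ttest_ind(top, bottom, equal_var=False).pvalue
    return top, bottom, float(p)
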