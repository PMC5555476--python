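"""Screen and library quality metrics.

Three families of diagnostics: the fraction of active guides (how many
essential-gene guides deplete past the 5th percentile of nonessential-gene
guides), subsampling studies (how performance depends on guides per gene
and replicates per screen), and the nontargeting-versus-nonessential
control comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .essentiality import (
    ClassifierConfig,
    EssentialityError,
    ReferenceSets,
    bayes_factors,
    precision_recall,
)
from .screen_data import (
    FoldchangeMatrix,
    NormalizationParams,
    ReadcountMatrix,
    compute_foldchange,
)


class ScreenEvalError(ValueError):
    pass


@dataclass
class ActiveGuideReport:
    """Outcome of the fraction-of-active-guides metric."""

    threshold_fc: float
    n_active: int
    n_total_essential_guides: int

    @property
    def fraction_active(self) -> float:
        return self.n_active / self.n_total_essential_guides


@dataclass
class SubsampleResult:
    """Per-condition subsampling outcome (guides-per-gene k or replicate combo)."""

    label: str
    fraction_core_recovered: list
    n_hits: list

    @property
    def mean_fraction(self) -> float:
        return float(np.mean(self.fraction_core_recovered))

    @property
    def sd_fraction(self) -> float:
        return float(np.std(self.fraction_core_recovered, ddof=0))

    @property
    def mean_hits(self) -> float:
        return float(np.mean(self.n_hits))

    @property
    def n_iterations(self) -> int:
        return len(self.n_hits)

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "mean_fraction_core_recovered": self.mean_fraction,
            "sd_fraction_core_recovered": self.sd_fraction,
            "mean_n_hits": self.mean_hits,
            "n_iterations": self.n_iterations,
        }


def fraction_active_guides(
    fc: FoldchangeMatrix,
    refs: ReferenceSets,
    percentile: float = 5.0,
    min_nonessential: int = 20,
) -> ActiveGuideReport:
    """Share of essential-targeting guides depleting below the nonessential tail.

    Guide fold-changes are averaged across replicates; the threshold is the
    given percentile (linear interpolation) of nonessential-targeting guide
    fold-changes, and a guide is active when its fold-change lies strictly
    below it.
    """
    gene = fc.gene_of_guide
    mean_fc = fc.fc.mean(axis=1)
    non = mean_fc[gene.isin(refs.nonessentials).to_numpy()]
    ess = mean_fc[gene.isin(refs.essentials).to_numpy()]
    if len(non) < min_nonessential:
        raise ScreenEvalError(
            f"need >= {min_nonessential} nonessential-targeting guides, "
            f"got {len(non)}"
        )
    if len(ess) == 0:
        raise ScreenEvalError("no guides target reference essential genes")
    threshold = float(np.percentile(non.to_numpy(), percentile))
    n_active = int((ess.to_numpy() < threshold).sum())
    return ActiveGuideReport(
        threshold_fc=threshold,
        n_active=n_active,
        n_total_essential_guides=len(ess),
    )


def _count_hits(
    fcm: FoldchangeMatrix,
    refs: ReferenceSets,
    core: set,
    cfg: ClassifierConfig,
    bf_min: float,
    fdr_max: float,
) -> tuple[float, int]:
    """(fraction of core genes recovered, total hits) at BF/FDR thresholds.

    The operative BF cutoff is the loosest cutoff >= ``bf_min`` whose FDR on
    the reference precision-recall curve stays <= ``fdr_max``.
    """
    bf = bayes_factors(fcm, refs, cfg)
    pr = precision_recall(bf["BF"], refs)
    ok = pr[(pr["fdr"] <= fdr_max) & (pr["bf_cutoff"] > bf_min)]
    if ok.empty:
        return 0.0, 0
    cutoff = float(ok["bf_cutoff"].iloc[-1])
    hits = set(bf.index[bf["BF"] >= cutoff])
    core_present = core & set(bf.index)
    frac = len(hits & core_present) / len(core_present) if core_present else 0.0
    return frac, len(hits)


def subsample_guides(
    rc: ReadcountMatrix,
    refs: ReferenceSets,
    core: set,
    k_range: Iterable[int] = range(2, 8),
    n_iter: int = 10,
    bf_min: float = 3.0,
    fdr_max: float = 0.05,
    seed: int = 0,
    norm: NormalizationParams | None = None,
    cfg: ClassifierConfig | None = None,
) -> list[SubsampleResult]:
    """Performance as a function of guides per gene.

    For each k, ``n_iter`` random subsets of k guides per gene are drawn
    without replacement, fold-changes and Bayes factors recomputed, and hits
    counted at BF > ``bf_min`` with FDR < ``fdr_max``.  Genes with fewer
    than k guides are skipped for that k.  Deterministic given the seed.
    """
    cfg = cfg or ClassifierConfig()
    rng = np.random.default_rng(seed)
    by_gene: dict = {}
    for guide, gene in rc.gene_of_guide.items():
        by_gene.setdefault(gene, []).append(guide)
    results = []
    for k in k_range:
        fracs, hits = [], []
        for _ in range(n_iter):
            chosen = set()
            for gene in sorted(by_gene):
                guides = by_gene[gene]
                if len(guides) < k:
                    continue  # gene skipped at this k
                chosen.update(rng.choice(guides, size=k, replace=False))
            # canonical guide order so identical subsets give identical runs
            sub = rc.subset_guides([g for g in rc.guide_ids if g in chosen])
            fcm = compute_foldchange(sub, norm)
            f, h = _count_hits(fcm, refs, core, cfg, bf_min, fdr_max)
            fracs.append(f)
            hits.append(h)
        results.append(SubsampleResult(f"k={k}", fracs, hits))
    return results


def subsample_replicates(
    fc: FoldchangeMatrix,
    refs: ReferenceSets,
    core: set,
    bf_min: float = 3.0,
    fdr_max: float = 0.05,
    cfg: ClassifierConfig | None = None,
) -> list[SubsampleResult]:
    """Performance of every replicate combination of a 3-replicate screen.

    Runs the classifier on each single replicate, each of the three pairs,
    and the full triple: exactly seven analyses.
    """
    cfg = cfg or ClassifierConfig()
    reps = fc.replicates
    if len(reps) != 3:
        raise ScreenEvalError(f"expected exactly 3 replicates, got {len(reps)}")
    combos = (
        [(r,) for r in reps]
        + list(combinations(reps, 2))
        + [tuple(reps)]
    )
    results = []
    for combo in combos:
        sub = fc.select_replicates(list(combo))
        f, h = _count_hits(sub, refs, core, cfg, bf_min, fdr_max)
        results.append(SubsampleResult("+".join(combo), [f], [h]))
    return results


def control_comparison(
    fc: FoldchangeMatrix,
    nontargeting: Iterable[str],
    refs: ReferenceSets,
) -> dict:
    """Compare nontargeting-control and nonessential-targeting fold-changes.

    Guide fold-changes are averaged across replicates and the two
    populations compared by a two-sided Welch T-test.  With zero variance in
    both groups the test is undefined and p is NaN.
    """
    nt_set = set(nontargeting)
    mean_fc = fc.fc.mean(axis=1)
    nt = mean_fc[[g for g in fc.guide_ids if g in nt_set]].to_numpy()
    non = mean_fc[fc.gene_of_guide.isin(refs.nonessentials).to_numpy()].to_numpy()
    if len(nt) == 0 or len(non) == 0:
        raise ScreenEvalError("both control populations must be non-empty")
    if np.var(nt) == 0 and np.var(non) == 0:
        p = float("nan")
    else:
        p = float(stats.ttest_ind(nt, non, equal_var=False).pvalue)
    return {
        "nontargeting_mean": float(np.mean(nt)),
        "nontargeting_sd": float(np.std(nt, ddof=1)) if len(nt) > 1 else 0.0,
        "nontargeting_n": int(len(nt)),
        "nonessential_mean": float(np.mean(non)),
        "nonessential_sd": float(np.std(non, ddof=1)) if len(non) > 1 else 0.0,
        "nonessential_n": int(len(non)),
        "mean_difference": float(np.mean(nt) - np.mean(non)),
        "p_value": p,
    }
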