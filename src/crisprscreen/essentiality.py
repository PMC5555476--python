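"""Gene essentiality from dropout fold-changes.

The classifier follows the BAGEL family of methods: the fold-change
distributions of guides targeting reference essential and reference
nonessential genes are estimated by Gaussian kernel density, and a gene's
Bayes Factor (BF) is the summed log2 likelihood ratio of its guides'
fold-changes under the two densities.  Reference *genes* are bootstrapped
with replacement each iteration and the mean BF over iterations is reported.

A BF is evidence, not a posterior: multiplying by the prior odds of
essentiality (default P(essential) = 0.1) converts it to posterior log-odds.
Core essential genes across a screen panel are called with an
assayed-in-enough-screens eligibility rule and an "essential in at least
85% of assayed screens" hit rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .screen_data import FoldchangeMatrix

DENSITY_FLOOR = 1e-12


class EssentialityError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceSets:
    """Gold-standard essential and nonessential training gene sets."""

    essentials: frozenset
    nonessentials: frozenset

    def __init__(self, essentials, nonessentials):
        object.__setattr__(self, "essentials", frozenset(essentials))
        object.__setattr__(self, "nonessentials", frozenset(nonessentials))
        if not self.essentials or not self.nonessentials:
            raise EssentialityError("reference sets must be non-empty")
        overlap = self.essentials & self.nonessentials
        if overlap:
            raise EssentialityError(
                f"reference sets overlap: {sorted(overlap)[:5]}"
            )

    @classmethod
    def from_files(cls, essentials_path, nonessentials_path) -> "ReferenceSets":
        """Load plain-text gene lists (one symbol per line, exact strings)."""
        def load(p):
            with open(p) as fh:
                return {line.strip() for line in fh if line.strip()}
        return cls(load(essentials_path), load(nonessentials_path))


@dataclass(frozen=True)
class ClassifierConfig:
    """Pinned internals of the Bayes-factor classifier.

    ``fc_eval_bounds`` clamps fold-changes before density evaluation; when
    None, the training fold-change range is used, which prevents the log
    ratio from being driven by far-tail KDE artefacts.
    """

    bootstrap_iterations: int = 1000
    kde_bandwidth_rule: str = "scott"
    fc_eval_bounds: tuple[float, float] | None = None
    seed: int = 1934
    min_ref_genes: int = 20

    def __post_init__(self):
        if self.bootstrap_iterations < 1:
            raise EssentialityError("bootstrap_iterations must be >= 1")


@dataclass(frozen=True)
class PriorOdds:
    p_essential: float = 0.1

    def __post_init__(self):
        if not 0 < self.p_essential < 1:
            raise EssentialityError("p_essential must lie in (0, 1)")


@dataclass(frozen=True)
class CoreSetRule:
    """Thresholds of the core-essential-gene (CEG) caller."""

    bf_threshold: float = 6.0
    fdr_threshold: float = 0.03
    min_guides_assayed: int = 3
    min_screens_assayed: int = 7
    hit_fraction: float = 0.85

    def __post_init__(self):
        if min(self.bf_threshold, self.fdr_threshold, self.min_guides_assayed,
               self.min_screens_assayed) <= 0:
            raise EssentialityError("core-set thresholds must be positive")
        if not 0 < self.hit_fraction <= 1:
            raise EssentialityError("hit_fraction must lie in (0, 1]")

    def required_hits(self, screens_assayed: int) -> int:
        return math.ceil(self.hit_fraction * screens_assayed)


@dataclass
class BayesFactorTable:
    """Per-gene BF and assayed-guide counts across a panel of screens.

    ``bf`` is genes x screens with NaN where a gene was not assayed;
    ``n_guides_assayed`` has the same shape with zeros there.
    """

    bf: pd.DataFrame
    n_guides_assayed: pd.DataFrame

    def __post_init__(self):
        self.n_guides_assayed = self.n_guides_assayed.reindex_like(self.bf).fillna(0)
        self.n_guides_assayed = self.n_guides_assayed.astype(int)
        present = self.bf.notna().to_numpy()
        assayed = self.n_guides_assayed.to_numpy() >= 1
        if (present & ~assayed).any():
            raise EssentialityError("BF present for gene with zero assayed guides")

    @property
    def genes(self) -> list[str]:
        return list(self.bf.index)

    @property
    def screens(self) -> list[str]:
        return list(self.bf.columns)

    @classmethod
    def from_screens(cls, per_screen: Mapping[str, pd.DataFrame]) -> "BayesFactorTable":
        """Assemble the panel from per-screen frames with BF and NUM_GUIDES."""
        bf = pd.DataFrame({s: d["BF"] for s, d in per_screen.items()})
        ng = pd.DataFrame({s: d["NUM_GUIDES"] for s, d in per_screen.items()})
        return cls(bf=bf, n_guides_assayed=ng.fillna(0))


def _training_fc(fcm: FoldchangeMatrix, genes: frozenset) -> dict[str, np.ndarray]:
    """Flattened fold-changes of each reference gene's retained guides."""
    out = {}
    for gene in sorted(genes):
        guides = fcm.guides_of_gene(gene)
        if guides:
            out[gene] = fcm.fc.loc[guides].to_numpy(dtype=float).ravel()
    return out


def _kde(values: np.ndarray, rule: str) -> gaussian_kde:
    return gaussian_kde(values, bw_method=rule)


def bayes_factors(
    fc: FoldchangeMatrix,
    refs: ReferenceSets,
    cfg: ClassifierConfig | None = None,
) -> pd.DataFrame:
    """Per-gene Bayes factors from guide-level fold-changes.

    Each bootstrap iteration resamples the reference genes (not their guides)
    with replacement, fits Gaussian KDEs to the two training fold-change
    pools, and scores every gene as the sum over its retained guide/replicate
    fold-changes of log2(density_essential / density_nonessential), with
    evaluation clamped to the training range and densities floored at 1e-12.
    The reported BF is the mean over iterations; deterministic given the seed.

    Returns a frame indexed by gene with columns ``BF`` and ``NUM_GUIDES``.
    """
    cfg = cfg or ClassifierConfig()
    if fc.fc.shape[1] < 1:
        raise EssentialityError("fold-change matrix has no replicates")
    ess_fc = _training_fc(fc, refs.essentials)
    non_fc = _training_fc(fc, refs.nonessentials)
    for name, pool in (("essential", ess_fc), ("nonessential", non_fc)):
        if not pool:
            raise EssentialityError(f"no retained guides for {name} reference genes")
        if len(pool) < cfg.min_ref_genes:
            raise EssentialityError(
                f"only {len(pool)} {name} reference genes have retained guides "
                f"(need >= {cfg.min_ref_genes})"
            )

    genes = [g for g in pd.unique(fc.gene_of_guide) if fc.guides_of_gene(g)]
    gene_vals = {g: fc.fc.loc[fc.guides_of_gene(g)].to_numpy(dtype=float).ravel()
                 for g in genes}
    # one flat evaluation vector; per-gene slices recovered afterwards
    offsets = np.cumsum([0] + [len(gene_vals[g]) for g in genes])
    flat = np.concatenate([gene_vals[g] for g in genes])

    ess_genes = list(ess_fc)
    non_genes = list(non_fc)
    rng = np.random.default_rng(cfg.seed)
    bf_sum = np.zeros(len(genes))
    for _ in range(cfg.bootstrap_iterations):
        ess_pick = rng.choice(len(ess_genes), size=len(ess_genes), replace=True)
        non_pick = rng.choice(len(non_genes), size=len(non_genes), replace=True)
        train_e = np.concatenate([ess_fc[ess_genes[i]] for i in ess_pick])
        train_n = np.concatenate([non_fc[non_genes[i]] for i in non_pick])
        lo, hi = cfg.fc_eval_bounds or (
            min(train_e.min(), train_n.min()),
            max(train_e.max(), train_n.max()),
        )
        x = np.clip(flat, lo, hi)
        dens_e = np.maximum(_kde(train_e, cfg.kde_bandwidth_rule)(x), DENSITY_FLOOR)
        dens_n = np.maximum(_kde(train_n, cfg.kde_bandwidth_rule)(x), DENSITY_FLOOR)
        contrib = np.log2(dens_e / dens_n)
        bf_sum += np.add.reduceat(contrib, offsets[:-1])
    bf = bf_sum / cfg.bootstrap_iterations
    return pd.DataFrame(
        {"BF": bf, "NUM_GUIDES": [len(fc.guides_of_gene(g)) for g in genes]},
        index=pd.Index(genes, name="GENE"),
    )


def precision_recall(bf: Mapping[str, float] | pd.Series,
                     refs: ReferenceSets) -> pd.DataFrame:
    """Threshold curve over reference genes ranked by descending BF.

    At each cutoff, precision = TP/(TP+FP) counting reference genes only,
    FDR = 1 - precision and recall = TP / (scored essentials).  Returns a
    frame with columns GENE, bf_cutoff, precision, recall, fdr ordered from
    the strictest cutoff down.
    """
    bf = pd.Series(bf, dtype=float)
    scored = bf.dropna()
    ess = [g for g in scored.index if g in refs.essentials]
    non = [g for g in scored.index if g in refs.nonessentials]
    if not ess or not non:
        raise EssentialityError("both reference classes must be represented")
    ref = scored.loc[ess + non].sort_values(ascending=False, kind="mergesort")
    is_ess = np.array([g in refs.essentials for g in ref.index])
    tp = np.cumsum(is_ess)
    n_seen = np.arange(1, len(ref) + 1)
    precision = tp / n_seen
    recall = tp / len(ess)
    return pd.DataFrame(
        {
            "GENE": ref.index,
            "bf_cutoff": ref.to_numpy(),
            "precision": precision,
            "recall": recall,
            "fdr": 1.0 - precision,
        }
    ).reset_index(drop=True)


def fdr_at_bf(pr: pd.DataFrame, bf_threshold: float) -> float:
    """FDR read off a precision-recall curve at a BF threshold.

    Returns 1 - precision at the smallest cutoff still >= ``bf_threshold``,
    or NaN when no scored reference gene reaches the threshold.
    """
    above = pr[pr["bf_cutoff"] >= bf_threshold]
    if above.empty:
        return float("nan")
    return float(above["fdr"].iloc[-1])


def bf_to_posterior(bf: float, prior: PriorOdds | float = PriorOdds()
                    ) -> tuple[float, float]:
    """Convert a Bayes factor to posterior log2-odds and probability.

    posterior_log2_odds = bf + log2(p/(1-p)); a BF of 3 under the default
    10% prior lands at ~0 log-odds, i.e. a coin-flip posterior.
    """
    p = prior.p_essential if isinstance(prior, PriorOdds) else PriorOdds(prior).p_essential
    odds = bf + math.log2(p / (1.0 - p))
    prob = 2.0 ** odds / (1.0 + 2.0 ** odds)
    return odds, prob


def call_core_essentials(
    bft: BayesFactorTable,
    per_screen_fdr_at_bf: Mapping[str, float],
    rule: CoreSetRule | None = None,
) -> tuple[set, pd.DataFrame]:
    """Call core essential genes across a panel of screens.

    A gene is assayed in a screen iff at least ``min_guides_assayed`` of its
    guides were scored there; eligible iff assayed in at least
    ``min_screens_assayed`` screens; core iff it is called essential
    (BF >= ``bf_threshold`` in a screen whose FDR at that threshold is
    <= ``fdr_threshold``) in at least ceil(hit_fraction x screens_assayed)
    screens.  Returns the core set and a per-gene eligibility report.
    """
    rule = rule or CoreSetRule()
    if len(bft.screens) < rule.min_screens_assayed:
        raise EssentialityError(
            f"panel has {len(bft.screens)} screens; rule requires "
            f">= {rule.min_screens_assayed}"
        )
    screen_ok = {
        s: (per_screen_fdr_at_bf.get(s, float("nan")) <= rule.fdr_threshold)
        for s in bft.screens
    }
    assayed = bft.n_guides_assayed >= rule.min_guides_assayed
    hit = bft.bf.ge(rule.bf_threshold) & assayed
    hit = hit & pd.Series(screen_ok).reindex(bft.screens)
    n_assayed = assayed.sum(axis=1)
    n_hits = hit.sum(axis=1)
    eligible = n_assayed >= rule.min_screens_assayed
    needed = n_assayed.map(rule.required_hits)
    core = eligible & (n_hits >= needed)
    report = pd.DataFrame(
        {
            "screens_assayed": n_assayed,
            "essential_calls": n_hits,
            "required_calls": needed.where(eligible, pd.NA),
            "eligible": eligible,
            "core": core,
        },
        index=bft.bf.index,
    )
    return set(report.index[report["core"]]), report
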