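"""Readcount containers and guide-level log2 fold-change computation.

A pooled knockout screen is delivered as a table of sequencing read counts:
one row per gRNA, one column per sample (the T0/plasmid control plus one or
more endpoint replicates).  Every downstream analysis — essentiality Bayes
factors, sequence-signature derivation, screen QC — consumes the normalized
log2 fold-changes produced here.

Normalization model: a pseudocount is added to every raw count, each sample
is scaled so its pseudocounted counts sum to ``target_depth`` (10 million
reads by default), and fold-change is log2(endpoint / control) per guide per
replicate.  Guides whose *raw* control count is below ``min_control_reads``
are excluded from the fold-change matrix for every replicate of the screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VALID_ROLES = ("t0_control", "plasmid_control", "endpoint")
CONTROL_ROLES = ("t0_control", "plasmid_control")

#: Guide-to-gene values naming control guide classes rather than genes.
CONTROL_CLASSES = ("nontargeting", "reporter-control")


class ScreenDataError(ValueError):
    """Malformed readcount input or invalid normalization request."""


@dataclass(frozen=True)
class NormalizationParams:
    """Depth normalization and control-read filter settings.

    Parameters
    ----------
    target_depth:
        Reads each sample is scaled to after pseudocounting (default 1e7).
    pseudocount:
        Reads added to every raw count so that zeros stay finite in log space.
    min_control_reads:
        Guides with fewer *raw* reads than this in the control sample are
        excluded from fold-change computation.
    """

    target_depth: float = 10_000_000.0
    pseudocount: float = 0.5
    min_control_reads: int = 30

    def __post_init__(self) -> None:
        if self.target_depth <= 0:
            raise ScreenDataError("target_depth must be > 0")
        if self.pseudocount <= 0:
            raise ScreenDataError("pseudocount must be > 0")
        if self.min_control_reads < 0:
            raise ScreenDataError("min_control_reads must be >= 0")


@dataclass
class ReadcountMatrix:
    """Integer guide x sample read counts with a guide→gene map.

    ``counts`` is indexed by guide id with one column per sample;
    ``sample_roles`` tags each sample as ``t0_control``, ``plasmid_control``
    or ``endpoint``.  Exactly one control sample is designated per screen.
    """

    counts: pd.DataFrame
    gene_of_guide: pd.Series
    sample_roles: Mapping[str, str]

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ScreenDataError("read counts must be non-negative")
        if self.counts.index.has_duplicates:
            dups = sorted(self.counts.index[self.counts.index.duplicated()])
            raise ScreenDataError(f"duplicate guide ids: {dups}")
        missing = self.counts.index.difference(self.gene_of_guide.index)
        if len(missing):
            raise ScreenDataError(f"guides without gene assignment: {list(missing)[:5]}")
        self.gene_of_guide = self.gene_of_guide.reindex(self.counts.index)
        for sample, role in self.sample_roles.items():
            if role not in VALID_ROLES:
                raise ScreenDataError(
                    f"unknown sample role {role!r} for sample {sample!r}; "
                    f"expected one of {VALID_ROLES}"
                )
            if sample not in self.counts.columns:
                raise ScreenDataError(f"role given for unknown sample {sample!r}")
        n_ctrl = sum(r in CONTROL_ROLES for r in self.sample_roles.values())
        if n_ctrl != 1:
            raise ScreenDataError(
                f"exactly one control sample must be designated, got {n_ctrl}"
            )

    @property
    def guide_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def control_sample(self) -> str:
        return next(
            s for s, r in self.sample_roles.items() if r in CONTROL_ROLES
        )

    @property
    def endpoint_samples(self) -> list[str]:
        return [s for s in self.counts.columns if self.sample_roles.get(s) == "endpoint"]

    def subset_guides(self, guide_ids: Iterable[str]) -> "ReadcountMatrix":
        """Return a new matrix restricted to ``guide_ids`` (order preserved)."""
        idx = pd.Index(guide_ids)
        return ReadcountMatrix(
            counts=self.counts.loc[idx].copy(),
            gene_of_guide=self.gene_of_guide.loc[idx].copy(),
            sample_roles=dict(self.sample_roles),
        )


@dataclass
class FoldchangeMatrix:
    """Guide-level log2 fold-changes per endpoint replicate.

    ``fc`` holds only guides retained by the control-read filter; ``excluded``
    records the masked guides and the reason for each.
    """

    fc: pd.DataFrame
    gene_of_guide: pd.Series
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["GUIDE", "GENE", "REASON"])
    )

    def __post_init__(self) -> None:
        if not np.isfinite(self.fc.to_numpy(dtype=float)).all():
            raise ScreenDataError("fold-changes must be finite for retained guides")
        self.gene_of_guide = self.gene_of_guide.reindex(self.fc.index)

    @property
    def guide_ids(self) -> list[str]:
        return list(self.fc.index)

    @property
    def replicates(self) -> list[str]:
        return list(self.fc.columns)

    def guides_of_gene(self, gene: str) -> list[str]:
        return list(self.fc.index[self.gene_of_guide == gene])

    def select_replicates(self, replicates: Iterable[str]) -> "FoldchangeMatrix":
        return FoldchangeMatrix(
            fc=self.fc[list(replicates)].copy(),
            gene_of_guide=self.gene_of_guide.copy(),
            excluded=self.excluded.copy(),
        )


def read_readcounts(path, sample_roles: Mapping[str, str]) -> ReadcountMatrix:
    """Parse a readcount TSV (columns: GUIDE, GENE, then one per sample).

    Counts must be integers; a fractional or non-numeric cell raises a parse
    error naming the offending row and column.  Duplicated guide ids are
    rejected.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 3:
        raise ScreenDataError(
            f"{path}: expected GUIDE, GENE and at least one sample column"
        )
    guide_col, gene_col = df.columns[:2]
    sample_cols = list(df.columns[2:])
    guides = df[guide_col].astype(str)
    if guides.duplicated().any():
        dups = sorted(guides[guides.duplicated()].unique())
        raise ScreenDataError(f"{path}: duplicated guide ids: {dups}")
    counts = {}
    for col in sample_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ScreenDataError(
                f"{path}: non-integer count {df[col].iloc[row]!r} at row "
                f"{row + 2} (guide {guides.iloc[row]!r}), column {col!r}"
            )
        counts[col] = numeric.astype(np.int64).to_numpy()
    counts_df = pd.DataFrame(counts, index=pd.Index(guides, name="GUIDE"))
    gene_of_guide = pd.Series(
        df[gene_col].astype(str).to_numpy(), index=counts_df.index, name="GENE"
    )
    return ReadcountMatrix(counts_df, gene_of_guide, dict(sample_roles))


def compute_foldchange(
    rc: ReadcountMatrix, params: NormalizationParams | None = None
) -> FoldchangeMatrix:
    """Normalize and compute log2(endpoint/control) per guide per replicate.

    The pseudocount is added to raw counts *before* depth scaling, so every
    sample's pseudocounted counts sum exactly to ``target_depth`` after
    normalization and all fold-changes are finite.  Guides failing the raw
    control-read filter are masked for all replicates of the screen.
    """
    params = params or NormalizationParams()
    endpoints = rc.endpoint_samples
    if not endpoints:
        raise ScreenDataError("no endpoint samples designated")
    ctrl = rc.control_sample

    pseudo = rc.counts.astype(float) + params.pseudocount
    norm = pseudo * (params.target_depth / pseudo.sum(axis=0))

    keep = rc.counts[ctrl] >= params.min_control_reads
    if not keep.any():
        raise ScreenDataError("no guides pass control-read filter")

    fc = np.log2(norm.loc[keep, endpoints].div(norm.loc[keep, ctrl], axis=0))
    excluded = pd.DataFrame(
        {
            "GUIDE": rc.counts.index[~keep],
            "GENE": rc.gene_of_guide[~keep].to_numpy(),
            "REASON": [
                f"control reads {n} < {params.min_control_reads}"
                for n in rc.counts.loc[~keep, ctrl]
            ],
        }
    )
    return FoldchangeMatrix(
        fc=fc, gene_of_guide=rc.gene_of_guide[keep].copy(), excluded=excluded
    )


def write_foldchange(fcm: FoldchangeMatrix, path, excluded_path=None) -> None:
    """Write fold-changes as TSV (GUIDE, GENE, one column per replicate).

    Masked guides are omitted; if ``excluded_path`` is given, a sidecar TSV
    lists them with exclusion reasons.
    """
    out = fcm.fc.copy()
    out.insert(0, "GENE", fcm.gene_of_guide)
    out.to_csv(path, sep="\t", index_label="GUIDE")
    if excluded_path is not None:
        fcm.excluded.to_csv(excluded_path, sep="\t", index=False)


def read_foldchange(path) -> FoldchangeMatrix:
    """Read a fold-change TSV written by :func:`write_foldchange`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    gene = df.pop("GENE").astype(str)
    return FoldchangeMatrix(fc=df.astype(float), gene_of_guide=gene)
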