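"""Directional gene-set construction from per-contrast DE results.

Builds the named sets used in staged-molt analyses: the lethargus set
(features significant, after p-doubling and BH correction, in both flanking
comparisons and moving in the same direction relative to lethargus), the
cuticle set (its subset that also moves with a cuticle-synthesis contrast at
a laxer FDR), and the reduction of probe-level calls to directional gene
lists via a largest-Fs representative probe plus a minimum-fold filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PipelineThresholds",
    "GeneSet",
    "double_pvalues",
    "bh_adjust",
    "adjust_result",
    "define_l4l_set",
    "define_cuticle_set",
    "reduce_probes_to_genes",
    "GeneListReduction",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineThresholds:
    """Significance thresholds for set construction.

    alpha_l4l
        Adjusted-p cutoff for the lethargus set (default 0.05).
    fdr_cut
        Laxer adjusted-p cutoff for the cuticle subset (default 0.30).
    fold_min
        Minimum linear fold change, applied only when reducing probe lists
        to gene lists for overlap testing (default 2.0).
    double_before_bh
        Double raw p-values (two one-sided criteria must both hold) before
        BH adjustment; swap order for sensitivity analysis.
    """

    alpha_l4l: float = 0.05
    fdr_cut: float = 0.30
    fold_min: float = 2.0
    double_before_bh: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha_l4l", "fdr_cut"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.fold_min < 1:
            raise ValueError(f"fold_min must be >= 1, got {self.fold_min}")


@dataclass
class GeneSet:
    """A named, directional collection of feature/gene identifiers."""

    name: str
    members: dict[str, str]  # id -> 'up' | 'down'
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g: d for g, d in self.members.items() if d not in ("up", "down")}
        if bad:
            raise ValueError(f"invalid directions: {bad}")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def ids(self, direction: str | None = None) -> list[str]:
        if direction is None:
            return sorted(self.members)
        return sorted(g for g, d in self.members.items() if d == direction)


def double_pvalues(p) -> np.ndarray:
    """Double raw p-values, capped at 1.

    Used when a feature must satisfy the significance criterion in two
    statistical tests simultaneously: each test's p is multiplied by 2
    before correction.
    """
    p = np.asarray(p, dtype=float)
    if p.size and ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return np.minimum(2.0 * p, 1.0)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_result(result: pd.DataFrame, thresholds: PipelineThresholds, *, double: bool) -> pd.DataFrame:
    """Attach ``p_doubled`` (when requested) and ``p_adj`` columns to a DE result.

    Order of operations follows ``thresholds.double_before_bh``: by default
    raw p-values are doubled first and BH runs on the doubled values.
    """
    out = result.copy()
    p = out["p_raw"].to_numpy()
    if double:
        if thresholds.double_before_bh:
            out["p_doubled"] = double_pvalues(p)
            out["p_adj"] = bh_adjust(out["p_doubled"].to_numpy())
        else:
            out["p_doubled"] = double_pvalues(p)
            out["p_adj"] = np.minimum(2.0 * bh_adjust(p), 1.0)
    else:
        out["p_adj"] = bh_adjust(p)
    return out


def _require_adjusted(result: pd.DataFrame, label: str) -> None:
    if "p_adj" not in result.columns:
        raise ValueError(f"{label}: run adjust_result first (missing 'p_adj' column)")


def define_l4l_set(
    result_vs_l4: pd.DataFrame,
    result_vs_adult: pd.DataFrame,
    thresholds: PipelineThresholds = PipelineThresholds(),
    *,
    name: str = "L4L",
) -> GeneSet:
    """Lethargus gene set: significant in BOTH flanking contrasts, same direction.

    A feature is a member iff its adjusted p is below ``alpha_l4l`` in both
    comparisons and the fold-change direction relative to lethargus agrees.
    Both results must be indexed by the same features.
    """
    _require_adjusted(result_vs_l4, "result_vs_l4")
    _require_adjusted(result_vs_adult, "result_vs_adult")
    if not result_vs_l4.index.equals(result_vs_adult.index):
        raise ValueError("DE results are not indexed by the same features")
    a, b = result_vs_l4, result_vs_adult
    keep = (
        (a["p_adj"] < thresholds.alpha_l4l)
        & (b["p_adj"] < thresholds.alpha_l4l)
        & (a["direction"] == b["direction"])
    )
    members = dict(zip(a.index[keep], a.loc[keep, "direction"]))
    return GeneSet(
        name=name,
        members=members,
        provenance={
            "alpha": thresholds.alpha_l4l,
            "contrasts": ["vs_l4", "vs_adult"],
            "doubling": thresholds.double_before_bh,
        },
    )


def define_cuticle_set(
    l4l: GeneSet,
    embryo_result: pd.DataFrame,
    thresholds: PipelineThresholds = PipelineThresholds(),
    *,
    name: str = "CUT",
) -> GeneSet:
    """Cuticle gene set: lethargus-set members that also move with a
    cuticle-synthesis contrast at the laxer ``fdr_cut`` threshold, in the
    same direction. Always a subset of the lethargus set. Members missing
    from the embryo result are excluded and counted in the log.
    """
    _require_adjusted(embryo_result, "embryo_result")
    members: dict[str, str] = {}
    missing = 0
    for feat, direction in l4l.members.items():
        if feat not in embryo_result.index:
            missing += 1
            continue
        row = embryo_result.loc[feat]
        if row["p_adj"] < thresholds.fdr_cut and row["direction"] == direction:
            members[feat] = direction
    if missing:
        logger.info(
            "%d lethargus-set member(s) absent from the embryo result were excluded",
            missing,
        )
    return GeneSet(
        name=name,
        members=members,
        provenance={
            "fdr": thresholds.fdr_cut,
            "parent": l4l.name,
            "excluded_missing": missing,
        },
    )


@dataclass(frozen=True)
class GeneListReduction:
    """Directional gene lists after probe reduction, plus the gene universe."""

    up: tuple[str, ...]
    down: tuple[str, ...]
    universe: tuple[str, ...]
    representative: Mapping[str, str]  # gene -> chosen probe


def reduce_probes_to_genes(
    gene_set: GeneSet,
    results: Mapping[str, pd.DataFrame],
    annotation: Mapping[str, str],
    thresholds: PipelineThresholds = PipelineThresholds(),
) -> GeneListReduction:
    """Reduce probe-level set membership to directional gene lists.

    For every gene, the representative probe is the one with the largest Fs
    (largest across the supplied contrasts; ties broken by lexicographically
    smallest probe id). A gene enters the up (down) list iff its
    representative probe belongs to ``gene_set`` with that direction and
    shows at least ``fold_min`` linear fold change in every contrast. The
    universe is the list of unique genes covered by the annotation after
    probe filtering.

    Raises
    ------
    ValueError
        If a probe is not covered by the annotation, or the annotation maps
        one probe to more than one gene (ambiguous probes are rejected, not
        guessed).
    """
    results = dict(results)
    if not results:
        raise ValueError("at least one DE result is required")
    first = next(iter(results.values()))
    for label, res in results.items():
        if not res.index.equals(first.index):
            raise ValueError(f"DE result {label!r} is not aligned with the others")
    probes = first.index
    unmapped = [p for p in probes if p not in annotation]
    if unmapped:
        raise ValueError(
            f"{len(unmapped)} probe(s) missing from the annotation (e.g. {unmapped[:3]}); "
            "filter unmapped probes before reduction"
        )
    gene_of = {p: annotation[p] for p in probes}
    for p, g in gene_of.items():
        if not isinstance(g, str):
            raise ValueError(f"probe {p!r} maps to multiple genes: {g!r}")

    # ranking score: max Fs across contrasts
    score = pd.concat([r["Fs"] for r in results.values()], axis=1).max(axis=1)
    by_gene: dict[str, str] = {}
    for probe in sorted(probes):  # lexicographic order makes ties deterministic
        gene = gene_of[probe]
        best = by_gene.get(gene)
        if best is None or score[probe] > score[best]:
            by_gene[gene] = probe

    min_fold = pd.concat([r["fold"] for r in results.values()], axis=1).min(axis=1)
    up, down = [], []
    for gene in sorted(by_gene):
        probe = by_gene[gene]
        direction = gene_set.members.get(probe)
        if direction is None:
            continue
        if min_fold[probe] < thresholds.fold_min:
            continue
        (up if direction == "up" else down).append(gene)
    universe = tuple(sorted(set(gene_of.values())))
    return GeneListReduction(
        up=tuple(up), down=tuple(down), universe=universe, representative=by_gene
    )
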