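"""Composition-based classification of prion-like (PQN) proteins and the
cysteine-rich abu/pqn paralog group (APPG).

APPG proteins are distinguished from other Q/N-rich proteins by a high
cysteine content (>= 9% of residues), at least one C-x3-C-x3-C repeat
(the Pfam C_tripleX motif), and, typically, a predicted N-terminal signal
sequence. This module scans sequences for those features, applies the
classifier, and groups proteins into paralog families by global-alignment
percent identity with average-linkage clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "CompositionFeatures",
    "ClassifierThresholds",
    "cys_fraction",
    "c_triplex_count",
    "max_qn_window",
    "predict_signal_peptide",
    "classify_appg",
    "pairwise_identity",
    "cluster_families",
    "FamilyClustering",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID = frozenset(AMINO_ACIDS)

#: residues counted as hydrophobic by the signal-peptide heuristic
HYDROPHOBIC = frozenset("AILMFVWC")


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence (standard 20-letter alphabet)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ClassifierThresholds:
    """APPG classifier thresholds.

    min_cys_fraction
        Minimum fraction of cysteines (default 0.09, i.e. >= 9%).
    min_triplex
        Minimum number of C-x3-C-x3-C matches (default 1).
    qn_window / min_qn
        Window length and Q+N count defining Q/N-richness, following the
        prion-prediction convention of >= 30 Q/N in an 80-residue window.
    require_signal
        Also require a predicted signal peptide (default off: 27 of 29
        APPG proteins carry one, so the signal is reported but not gating).
    """

    min_cys_fraction: float = 0.09
    min_triplex: int = 1
    qn_window: int = 80
    min_qn: int = 30
    require_signal: bool = False

    def __post_init__(self) -> None:
        if self.qn_window < 1:
            raise ValueError("qn_window must be >= 1")
        if self.min_qn > self.qn_window:
            raise ValueError("min_qn cannot exceed qn_window")


@dataclass(frozen=True)
class CompositionFeatures:
    """Per-protein scan results and the APPG call."""

    id: str
    length: int
    cys_fraction: float
    c_triplex_count: int
    max_qn_window: int
    window_size: int
    has_signal: bool
    appg_call: bool


def cys_fraction(seq: str) -> float:
    """Fraction of residues that are cysteine."""
    if not seq:
        raise ValueError("empty sequence")
    return seq.count("C") / len(seq)


def c_triplex_count(seq: str) -> int:
    """Number of C-x3-C-x3-C matches (overlapping matches counted).

    A match is a position i with cysteines at i, i+4 and i+8; the six x
    positions may hold any residue, including further cysteines.
    """
    n = len(seq)
    return sum(
        1
        for i in range(n - 8)
        if seq[i] == "C" and seq[i + 4] == "C" and seq[i + 8] == "C"
    )


def max_qn_window(seq: str, window: int = 80) -> int:
    """Maximum Q+N count over all contiguous windows of the given length.

    Sequences shorter than the window are scored over their full length.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    w = min(window, len(seq))
    is_qn = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_qn = ((is_qn == ord("Q")) | (is_qn == ord("N"))).astype(int)
    csum = np.concatenate([[0], np.cumsum(is_qn)])
    return int((csum[w:] - csum[:-w]).max())


def predict_signal_peptide(seq: str) -> bool:
    """Crude N-terminal signal-sequence heuristic.

    True iff some 8-residue window starting within positions 2-25 (1-based)
    contains at least 6 hydrophobic residues (A/I/L/M/F/V/W/C) — a stand-in
    for the hydrophobic core of a secretory signal peptide. Deliberately
    simple and pluggable: pass a different predictor to ``classify_appg``
    for production use.
    """
    n = len(seq)
    if n < 9:
        return False
    for start in range(1, min(25, n - 8) + 1):  # 0-based starts 1..24
        window = seq[start : start + 8]
        if sum(r in HYDROPHOBIC for r in window) >= 6:
            return True
    return False


def classify_appg(
    record: ProteinRecord,
    thresholds: ClassifierThresholds = ClassifierThresholds(),
    *,
    signal_predictor=predict_signal_peptide,
) -> CompositionFeatures:
    """Scan one protein and apply the APPG composition rule.

    The call is positive iff cysteine fraction >= ``min_cys_fraction`` AND
    C-tripleX count >= ``min_triplex`` AND (a signal peptide is predicted OR
    ``require_signal`` is off).
    """
    seq = record.sequence
    cys = cys_fraction(seq)
    triplex = c_triplex_count(seq)
    qn = max_qn_window(seq, thresholds.qn_window)
    signal = bool(signal_predictor(seq))
    call = (
        cys >= thresholds.min_cys_fraction
        and triplex >= thresholds.min_triplex
        and (signal or not thresholds.require_signal)
    )
    return CompositionFeatures(
        id=record.id,
        length=len(seq),
        cys_fraction=cys,
        c_triplex_count=triplex,
        max_qn_window=qn,
        window_size=thresholds.qn_window,
        has_signal=signal,
        appg_call=call,
    )


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2  # linear gap penalty
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity from a global alignment.

    Needleman-Wunsch with match +1, mismatch -1, gap -2 (linear); identity
    is the number of identically aligned residue pairs over the number of
    alignment columns, times 100. Symmetric in its arguments.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    alignment = _aligner().align(seq_a, seq_b)[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length


@dataclass(frozen=True)
class FamilyClustering:
    """Average-linkage tree over proteins on distance 100 - %identity."""

    ids: tuple[str, ...]
    linkage_matrix: np.ndarray  # scipy hierarchy format
    distance: np.ndarray  # condensed upper-triangle distances, id order

    def to_newick(self) -> str:
        """Serialize the dendrogram as a Newick string with branch lengths."""
        from scipy.cluster.hierarchy import to_tree

        root = to_tree(self.linkage_matrix)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        if root.is_leaf():
            return f"{self.ids[root.id]}:0;"
        left = render(root.left, root.dist)
        right = render(root.right, root.dist)
        return f"({left},{right});"


def cluster_families(records: list[ProteinRecord]) -> FamilyClustering:
    """Group proteins into families by sequence-identity clustering.

    Pairwise distances are ``100 - percent identity`` from global alignment;
    the tree is average linkage. Records are sorted by id before clustering,
    so the result is invariant to input order and ties merge the
    lexicographically smallest id pair first.
    """
    if len(records) < 2:
        raise ValueError("clustering needs at least 2 records")
    if len({r.id for r in records}) != len(records):
        raise ValueError("duplicate protein ids")
    ordered = sorted(records, key=lambda r: r.id)
    ids = tuple(r.id for r in ordered)
    n = len(ordered)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 100.0 - pairwise_identity(ordered[i].sequence, ordered[j].sequence)
            dist[i, j] = dist[j, i] = max(d, 0.0)
    condensed = squareform(dist, checks=False)
    lm = linkage(condensed, method="average")
    return FamilyClustering(ids=ids, linkage_matrix=lm, distance=condensed)
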