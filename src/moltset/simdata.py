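"""Synthetic expression matrices and protein sequences with known ground
truth.

The expression generator emulates a stage-structured bulk microarray
experiment: log-normal intensities following the additive fixed-effect model
``Y = mu + STATE + eps`` on log2 scale, with a minority of genes planted as
induced (or repressed) in the lethargus state relative to both flanking
states — mirroring molt-specific genes whose fold changes can reach the
hundreds — plus optional multi-probe features and per-probe affinity
offsets. The protein generator plants APPG-like sequences (cysteine-rich,
carrying C-x3-C-x3-C repeats and a signal-peptide-like N-terminus) on a
background of Q/N-rich prion-like sequences that never jointly satisfy the
APPG composition rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .pqnscan import AMINO_ACIDS, ProteinRecord, c_triplex_count, cys_fraction

__all__ = [
    "SimExpressionConfig",
    "SimTruth",
    "SimProteinConfig",
    "simulate_expression",
    "simulate_proteins",
    "spike_contamination",
]


@dataclass(frozen=True)
class SimExpressionConfig:
    """Study design for the synthetic expression experiment.

    Defaults model a three-state larval design (late L4, L4 lethargus,
    young adult) with five pooled replicates per state — the replicate
    depth of the microarray study this emulates — and a few percent of
    genes strongly induced or repressed during lethargus: planted |log2
    effects| are drawn uniformly from ``log2_effect_range`` (default 2-8,
    i.e. 4-fold up to 256-fold) and the residual noise is Gaussian i.i.d.
    on log2 scale with ``noise_sd`` (default 0.25, a free parameter of the
    generator).
    """

    n_genes: int = 1000
    probes_per_gene: int = 1
    states: tuple[str, ...] = ("L4", "lethargus", "adult")
    lethargus_state: str = "lethargus"
    replicates_per_state: int = 5
    n_up: int = 50
    n_down: int = 30
    log2_effect_range: tuple[float, float] = (2.0, 8.0)
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    gene_baseline_sd: float = 1.5
    probe_effect_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.probes_per_gene < 1:
            raise ValueError("n_genes and probes_per_gene must be >= 1")
        if self.replicates_per_state < 2:
            raise ValueError("replicates_per_state must be >= 2")
        if self.n_up + self.n_down > self.n_genes:
            raise ValueError("n_up + n_down cannot exceed n_genes")
        if len(self.states) < 2 or len(set(self.states)) != len(self.states):
            raise ValueError("states must be >= 2 distinct labels")
        if self.lethargus_state not in self.states:
            raise ValueError(
                f"lethargus_state {self.lethargus_state!r} not among states {self.states}"
            )
        lo, hi = self.log2_effect_range
        if not 0 < lo <= hi:
            raise ValueError("log2_effect_range must satisfy 0 < min <= max")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated expression matrix.

    ``genes`` is a DataFrame indexed by gene id with columns ``label``
    ('up'/'down'/'null') and ``log2_effect`` (signed lethargus-vs-flanking
    effect; 0 for null genes, identical in both flanking contrasts).
    """

    genes: pd.DataFrame
    probe_to_gene: dict[str, str]
    lethargus_state: str
    states: tuple[str, ...] = field(default_factory=tuple)

    def labels(self) -> pd.Series:
        return self.genes["label"]


def simulate_expression(config: SimExpressionConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Draw one synthetic log2 expression matrix plus its ground truth.

    Every value is ``baseline_mean + gene offset + probe offset + state
    effect + N(0, noise_sd)``; the state effect is nonzero only for planted
    genes in the lethargus state. Identical configs (including seed) yield
    bitwise-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    width = len(str(n_genes))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(n_genes)]

    labels = np.array(
        ["up"] * config.n_up
        + ["down"] * config.n_down
        + ["null"] * (n_genes - config.n_up - config.n_down)
    )
    lo, hi = config.log2_effect_range
    magnitude = rng.uniform(lo, hi, size=n_genes)
    sign = np.where(labels == "up", 1.0, np.where(labels == "down", -1.0, 0.0))
    effects = sign * magnitude
    gene_offsets = rng.normal(0.0, config.gene_baseline_sd, size=n_genes)

    sample_ids: list[str] = []
    state_of: dict[str, str] = {}
    for state in config.states:
        for r in range(config.replicates_per_state):
            sid = f"{state}_r{r + 1}"
            sample_ids.append(sid)
            state_of[sid] = state
    is_lethargus = np.array(
        [state_of[s] == config.lethargus_state for s in sample_ids], dtype=float
    )

    probe_ids: list[str] = []
    probe_to_gene: dict[str, str] = {}
    for gid in gene_ids:
        for k in range(config.probes_per_gene):
            pid = gid if config.probes_per_gene == 1 else f"{gid}_p{k + 1:02d}"
            probe_ids.append(pid)
            probe_to_gene[pid] = gid

    n_probes = len(probe_ids)
    gene_index = np.repeat(np.arange(n_genes), config.probes_per_gene)
    probe_offsets = (
        rng.normal(0.0, config.probe_effect_sd, size=n_probes)
        if config.probe_effect_sd > 0
        else np.zeros(n_probes)
    )
    signal = (
        config.baseline_mean
        + gene_offsets[gene_index, None]
        + probe_offsets[:, None]
        + effects[gene_index, None] * is_lethargus[None, :]
    )
    values = signal + rng.normal(0.0, config.noise_sd, size=(n_probes, len(sample_ids)))

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        state_of,
        scale="log2",
    )
    truth = SimTruth(
        genes=pd.DataFrame({"label": labels, "log2_effect": effects}, index=gene_ids),
        probe_to_gene=probe_to_gene,
        lethargus_state=config.lethargus_state,
        states=tuple(config.states),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# proteins


@dataclass(frozen=True)
class SimProteinConfig:
    """Design for the synthetic proteome.

    Defaults mirror a PQN-protein-sized problem: 29 planted APPG-like
    sequences against 78 Q/N-rich background proteins, APPG cysteine
    content at least 9% with at least one C-x3-C-x3-C repeat and a
    signal-peptide-like N-terminus.
    """

    n_appg: int = 29
    n_background: int = 78
    length_range: tuple[int, int] = (150, 450)
    appg_cys_fraction: float = 0.09
    appg_motif_count: int = 1
    appg_signal: bool = True
    qn_rich_fraction: float = 1.0
    appg_family_divergence: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 9 and self.appg_motif_count >= 1:
            raise ValueError("length_range.min must be >= 9 to fit one C-x3-C-x3-C motif")
        if not 0 < lo <= hi:
            raise ValueError("invalid length_range")
        if not 0 <= self.appg_cys_fraction <= 1:
            raise ValueError("appg_cys_fraction must lie in [0, 1]")
        if not 0 <= self.qn_rich_fraction <= 1:
            raise ValueError("qn_rich_fraction must lie in [0, 1]")
        if not 0 <= self.appg_family_divergence <= 1:
            raise ValueError("appg_family_divergence must lie in [0, 1]")
        if self.n_appg < 0 or self.n_background < 0:
            raise ValueError("record counts must be >= 0")


_NON_CYS = np.array(list(AMINO_ACIDS.replace("C", "")))
_HYDROPHOBIC_CORE = np.array(list("AILMFV"))
_SIGNAL_LEN = 16


def _signal_prefix(rng: np.random.Generator) -> list[str]:
    """Signal-peptide-like N-terminus: Met, a charged patch, a hydrophobic core."""
    prefix = ["M"] + list(rng.choice(list("KRNQ"), size=2))
    prefix += list(rng.choice(_HYDROPHOBIC_CORE, size=10))
    prefix += list(rng.choice(list("SAGT"), size=_SIGNAL_LEN - len(prefix)))
    return prefix


def _top_up_cysteines(
    seq: list[str], rng: np.random.Generator, start_at: int, target: int
) -> None:
    """Convert random positions to Cys until the count reaches target."""
    candidates = [i for i in range(start_at, len(seq)) if seq[i] != "C"]
    rng.shuffle(candidates)
    have = seq.count("C")
    for i in candidates:
        if have >= target:
            break
        seq[i] = "C"
        have += 1


def _appg_template(
    rng: np.random.Generator, length: int, cfg: SimProteinConfig
) -> tuple[list[str], list[int], int]:
    """Ancestral APPG-like sequence: signal prefix, motif anchors, high Cys.

    Returns the residue list, the motif anchor positions (kept fixed across
    family members) and the index where mutable sequence begins.
    """
    seq = rng.choice(_NON_CYS, size=length).tolist()
    start_at = 0
    if cfg.appg_signal:
        if length < _SIGNAL_LEN + 9 * cfg.appg_motif_count:
            raise ValueError(
                f"length {length} too short for a signal peptide plus "
                f"{cfg.appg_motif_count} motif(s)"
            )
        seq[:_SIGNAL_LEN] = _signal_prefix(rng)
        start_at = _SIGNAL_LEN
    # place non-overlapping C-x3-C-x3-C motifs after the signal region
    slots = np.arange(start_at, length - 8)
    starts: list[int] = []
    anchors: list[int] = []
    for _ in range(cfg.appg_motif_count):
        free = slots[[all(abs(s - t) >= 9 for t in starts) for s in slots]]
        if free.size == 0:
            raise ValueError("sequence too short to place all motifs")
        s = int(rng.choice(free))
        starts.append(s)
        for off in (0, 4, 8):
            seq[s + off] = "C"
            anchors.append(s + off)
    target = int(np.ceil(cfg.appg_cys_fraction * length))
    _top_up_cysteines(seq, rng, start_at, target)
    return seq, anchors, start_at


def _appg_family_member(
    rng: np.random.Generator,
    template: list[str],
    anchors: list[int],
    start_at: int,
    cfg: SimProteinConfig,
) -> str:
    """Mutate the template into one paralog, preserving the APPG features.

    Non-anchor positions after the signal region are substituted with
    probability ``appg_family_divergence``; motif cysteines and the signal
    prefix are conserved, and the cysteine fraction is topped back up if
    mutation erodes it.
    """
    seq = list(template)
    anchor_set = set(anchors)
    for i in range(start_at, len(seq)):
        if i in anchor_set:
            continue
        if rng.random() < cfg.appg_family_divergence:
            seq[i] = str(rng.choice(_NON_CYS))
    target = int(np.ceil(cfg.appg_cys_fraction * len(seq)))
    _top_up_cysteines(seq, rng, start_at, target)
    return "".join(seq)


def _background_sequence(rng: np.random.Generator, length: int, qn_rich: bool, cfg: SimProteinConfig) -> str:
    if qn_rich:
        # Q/N-heavy residue usage, as in prion-like low-complexity regions
        pool = list("QQQQNNNNAGSTPYLEKRD")
    else:
        pool = list(AMINO_ACIDS.replace("C", ""))
    seq = rng.choice(np.array(pool), size=length).tolist()
    # sprinkle a little cysteine, below the APPG threshold
    max_cys = max(int(cfg.appg_cys_fraction * length) - 1, 0)
    n_cys = int(rng.integers(0, max(max_cys // 2, 1)))
    for i in rng.choice(length, size=n_cys, replace=False):
        seq[int(i)] = "C"
    s = "".join(seq)
    # background must never satisfy the APPG rule jointly: having kept the
    # cysteine fraction below threshold, also strip any accidental motif
    while cys_fraction(s) >= cfg.appg_cys_fraction and c_triplex_count(s) >= max(
        cfg.appg_motif_count, 1
    ):
        idx = s.index("C")
        s = s[:idx] + "A" + s[idx + 1 :]
    return s


def simulate_proteins(
    config: SimProteinConfig,
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Generate APPG-like and background protein records with truth labels.

    Returns the records (APPG first, then background) and a map from record
    id to ``"appg"`` or ``"background"``. APPG records are drawn as a
    paralog family — mutated copies of one ancestral template, so they are
    more similar to each other than to the background — and every one
    satisfies the composition rule (cysteine fraction and motif count at or
    above the configured targets); no background record satisfies both
    jointly.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ProteinRecord] = []
    labels: dict[str, str] = {}
    lo, hi = config.length_range
    if config.n_appg:
        length = int(rng.integers(lo, hi + 1))
        template, anchors, start_at = _appg_template(rng, length, config)
        for i in range(config.n_appg):
            seq = _appg_family_member(rng, template, anchors, start_at, config)
            assert cys_fraction(seq) >= config.appg_cys_fraction
            assert c_triplex_count(seq) >= config.appg_motif_count
            rid = f"appg_{i + 1:03d}"
            records.append(ProteinRecord(rid, seq))
            labels[rid] = "appg"
    n_qn = int(round(config.qn_rich_fraction * config.n_background))
    for i in range(config.n_background):
        length = int(rng.integers(lo, hi + 1))
        seq = _background_sequence(rng, length, qn_rich=(i < n_qn), cfg=config)
        rid = f"bg_{i + 1:03d}"
        records.append(ProteinRecord(rid, seq))
        labels[rid] = "background"
    return records, labels


# ---------------------------------------------------------------------------
# contamination


def spike_contamination(
    matrix: ExpressionMatrix,
    lethargus_profile,
    f: float,
    *,
    samples: list[str] | None = None,
) -> ExpressionMatrix:
    """Mix a fraction ``f`` of lethargus-stage signal into a matrix.

    Mixing is performed on linear intensity scale (pooled RNA is additive in
    molecules): per gene, ``new = (1 - f) * old + f * old * ratio``. A log2
    matrix is converted to linear internally and returned on log2 scale.

    Parameters
    ----------
    lethargus_profile
        Mapping or Series of per-feature lethargus:non-lethargus linear
        ratios (>= 0); features absent from the profile keep ratio 1.
    f
        Contamination fraction in [0, 1]; ``f = 0`` is the identity.
    samples
        Columns to contaminate (default: all).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"contamination fraction must lie in [0, 1], got {f}")
    profile = pd.Series(lethargus_profile, dtype=float)
    if (profile < 0).any():
        raise ValueError("lethargus ratios must be >= 0")
    ratios = profile.reindex(matrix.values.index).fillna(1.0).to_numpy()
    factor = (1.0 - f) + f * ratios

    values = matrix.values.copy()
    cols = samples if samples is not None else list(values.columns)
    if matrix.scale == "log2":
        linear = np.exp2(values[cols].to_numpy())
        values[cols] = np.log2(linear * factor[:, None])
    else:
        values[cols] = values[cols].to_numpy() * factor[:, None]
    return matrix.with_values(values)
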