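"""End-to-end orchestration: normalize -> per-contrast DE -> gene sets ->
probe reduction -> optional overlap testing and protein scanning.

The pipeline mirrors the staged-molt study design: the state of interest
(lethargus) is contrasted against each flanking state, p-values from the
two flanking comparisons are doubled so a transcript must pass both tests,
BH correction is applied, and the lethargus set keeps features significant
in both contrasts with agreeing direction. An optional second experiment
(an embryonic cuticle-synthesis contrast) refines the set at a laxer FDR.
Every run writes a machine-readable report and is reproducible from its
seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .de_stats import StageDesign, run_de
from .gene_sets import (
    GeneSet,
    PipelineThresholds,
    adjust_result,
    define_cuticle_set,
    define_l4l_set,
    reduce_probes_to_genes,
)
from .matrix import ExpressionMatrix
from .normalize import log_transform, quantile_normalize
from .overlap_stats import build_contingency, fisher_exact_test
from .pqnscan import ClassifierThresholds, classify_appg, cluster_families

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

#: feature-id prefixes treated as array control probes and dropped
DEFAULT_CONTROL_PREFIXES = ("AFFX",)


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run."""

    matrix_path: str
    design_path: str
    annotation_path: str
    out_dir: str
    lethargus_state: str = "lethargus"
    scale: str = "log2"
    embryo_matrix_path: str | None = None
    embryo_design_path: str | None = None
    embryo_lethargus_state: str | None = None
    fasta_path: str | None = None
    external_list_path: str | None = None
    n_perm: int = 1000
    seed: int = 0
    quantile: bool = True
    control_prefixes: tuple[str, ...] = DEFAULT_CONTROL_PREFIXES
    permutation_scope: str = "shared"
    thresholds: PipelineThresholds = field(default_factory=PipelineThresholds)
    classifier: ClassifierThresholds = field(default_factory=ClassifierThresholds)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "thresholds" in raw and isinstance(raw["thresholds"], dict):
            raw["thresholds"] = PipelineThresholds(**raw["thresholds"])
        if "classifier" in raw and isinstance(raw["classifier"], dict):
            raw["classifier"] = ClassifierThresholds(**raw["classifier"])
        if "control_prefixes" in raw:
            raw["control_prefixes"] = tuple(raw["control_prefixes"])
        return cls(**raw)

    def validate_paths(self) -> None:
        required = {
            "matrix_path": self.matrix_path,
            "design_path": self.design_path,
            "annotation_path": self.annotation_path,
        }
        optional = {
            "embryo_matrix_path": self.embryo_matrix_path,
            "embryo_design_path": self.embryo_design_path,
            "fasta_path": self.fasta_path,
            "external_list_path": self.external_list_path,
        }
        for name, p in {**required, **{k: v for k, v in optional.items() if v}}.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")


def _filter_controls(
    matrix: ExpressionMatrix, prefixes: tuple[str, ...]
) -> tuple[ExpressionMatrix, int]:
    keep = [f for f in matrix.values.index if not str(f).startswith(prefixes)]
    n_dropped = matrix.n_features - len(keep)
    if n_dropped:
        logger.info("dropped %d control feature(s) by prefix %s", n_dropped, prefixes)
        matrix = matrix.with_values(matrix.values.loc[keep])
    return matrix, n_dropped


def _lethargus_contrasts(
    matrix: ExpressionMatrix, lethargus_state: str
) -> list[StageDesign]:
    states: list[str] = []
    for s in matrix.sample_ids:
        st = matrix.state_of[s]
        if st not in states:
            states.append(st)
    if lethargus_state not in states:
        raise ValueError(f"state {lethargus_state!r} absent from the design")
    others = [s for s in states if s != lethargus_state]
    if not others:
        raise ValueError("need at least one non-lethargus state to contrast")
    leth = tuple(matrix.samples_in_state(lethargus_state))
    return [
        StageDesign(
            name=f"{lethargus_state}_vs_{other}",
            group_a=leth,
            group_b=tuple(matrix.samples_in_state(other)),
        )
        for other in others
    ]


def _prepare(matrix: ExpressionMatrix, config: PipelineConfig) -> tuple[ExpressionMatrix, int]:
    matrix, n_controls = _filter_controls(matrix, tuple(config.control_prefixes))
    if matrix.scale == "linear":
        matrix = log_transform(matrix)
    if config.quantile:
        matrix = quantile_normalize(matrix)
    return matrix, n_controls


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis described by ``config``.

    Writes per-contrast DE tables, gene-set TSVs, reduced gene lists,
    optional overlap statistics and protein-scan outputs under
    ``config.out_dir``, plus ``report.json`` summarizing counts, thresholds
    and the seed. Returns the report as a dict. Any stage failure raises
    with the stage name attached.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "thresholds": {
            "alpha_l4l": config.thresholds.alpha_l4l,
            "fdr_cut": config.thresholds.fdr_cut,
            "fold_min": config.thresholds.fold_min,
            "double_before_bh": config.thresholds.double_before_bh,
        },
        "stages": [],
    }

    def stage(name):
        report["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        stage("read")
        design = io.read_design_table(config.design_path)
        matrix = io.read_expression_table(config.matrix_path, design, scale=config.scale)
        annotation = io.read_annotation_table(config.annotation_path)
        report["n_features_input"] = matrix.n_features
        report["n_samples"] = matrix.n_samples

        stage("normalize")
        matrix, n_controls = _prepare(matrix, config)
        report["n_control_features_dropped"] = n_controls
        unmapped = [f for f in matrix.values.index if f not in annotation]
        if unmapped:
            logger.info("dropping %d unmapped feature(s)", len(unmapped))
            matrix = matrix.with_values(matrix.values.drop(index=unmapped))
        report["n_unmapped_features_dropped"] = len(unmapped)
        report["n_features_analyzed"] = matrix.n_features

        stage("de")
        contrasts = _lethargus_contrasts(matrix, config.lethargus_state)[:2]
        if len(contrasts) < 2:
            raise ValueError("the lethargus set rule needs two flanking contrasts")
        results = {}
        for i, contrast in enumerate(contrasts):
            res = run_de(
                matrix,
                contrast,
                n_perm=config.n_perm,
                seed=config.seed + i,
                scope=config.permutation_scope,
            )
            res = adjust_result(res, config.thresholds, double=True)
            res.to_csv(out / f"de_{contrast.name}.tsv", sep="\t")
            results[contrast.name] = res
        report["contrasts"] = [c.name for c in contrasts]

        stage("sets")
        res_a, res_b = (results[c.name] for c in contrasts)
        l4l = define_l4l_set(res_a, res_b, config.thresholds)
        io.write_gene_set(l4l, out / "set_L4L.tsv")
        report["n_l4l"] = len(l4l)
        report["n_l4l_up"] = len(l4l.ids("up"))
        report["n_l4l_down"] = len(l4l.ids("down"))

        cut: GeneSet | None = None
        if config.embryo_matrix_path:
            embryo_design = io.read_design_table(config.embryo_design_path)
            embryo = io.read_expression_table(
                config.embryo_matrix_path, embryo_design, scale=config.scale
            )
            embryo, _ = _prepare(embryo, config)
            embryo_state = config.embryo_lethargus_state or config.lethargus_state
            embryo_contrast = _lethargus_contrasts(embryo, embryo_state)[0]
            embryo_res = run_de(
                embryo,
                embryo_contrast,
                n_perm=config.n_perm,
                seed=config.seed + 97,
                scope=config.permutation_scope,
            )
            embryo_res = adjust_result(embryo_res, config.thresholds, double=False)
            embryo_res.to_csv(out / f"de_{embryo_contrast.name}_embryo.tsv", sep="\t")
            cut = define_cuticle_set(l4l, embryo_res, config.thresholds)
            io.write_gene_set(cut, out / "set_CUT.tsv")
            report["n_cut"] = len(cut)
            report["cut_subset_of_l4l"] = set(cut.members) <= set(l4l.members)

        stage("reduce")
        reduction = reduce_probes_to_genes(l4l, results, annotation, config.thresholds)
        pd.DataFrame({"gene": list(reduction.up), "direction": "up"}).to_csv(
            out / "genes_up.tsv", sep="\t", index=False
        )
        pd.DataFrame({"gene": list(reduction.down), "direction": "down"}).to_csv(
            out / "genes_down.tsv", sep="\t", index=False
        )
        report["n_genes_up"] = len(reduction.up)
        report["n_genes_down"] = len(reduction.down)
        report["n_universe"] = len(reduction.universe)

        if config.external_list_path:
            stage("overlap")
            external = [
                line.strip()
                for line in Path(config.external_list_path).read_text().splitlines()
                if line.strip()
            ]
            rows = []
            for label, genes in (("up", reduction.up), ("down", reduction.down)):
                table = build_contingency(genes, external, reduction.universe)
                odds, p = fisher_exact_test(table)
                rows.append(
                    {
                        "list": label,
                        "a": table.a,
                        "b": table.b,
                        "c": table.c,
                        "d": table.d,
                        "odds_ratio": odds,
                        "p": p,
                    }
                )
            pd.DataFrame(rows).to_csv(out / "overlap.tsv", sep="\t", index=False)
            report["overlap"] = rows

        if config.fasta_path:
            stage("pqnscan")
            records = io.read_fasta(config.fasta_path)
            feats = [classify_appg(r, config.classifier) for r in records]
            pd.DataFrame(
                [
                    {
                        "id": f.id,
                        "length": f.length,
                        "cys_fraction": f.cys_fraction,
                        "c_triplex_count": f.c_triplex_count,
                        "max_qn_window": f.max_qn_window,
                        "has_signal": f.has_signal,
                        "appg_call": f.appg_call,
                    }
                    for f in feats
                ]
            ).to_csv(out / "pqn_features.tsv", sep="\t", index=False)
            report["n_proteins"] = len(records)
            report["n_appg_called"] = sum(f.appg_call for f in feats)
            if len(records) >= 2:
                tree = cluster_families(records)
                (out / "families.nwk").write_text(tree.to_newick() + "\n")
    except Exception as exc:
        current = report["stages"][-1] if report["stages"] else "init"
        raise RuntimeError(f"pipeline failed in stage {current!r}: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
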