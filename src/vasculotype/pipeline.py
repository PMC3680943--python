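"""End-to-end orchestration: collapse, filter, class discovery, moderated DE
contrasts, marker/clinical characterisation, and the recurrence predictor.

``run_full_pipeline`` is deterministic for a fixed config and input files and
writes every stage's output plus the fully-resolved config next to them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import cluster as _cluster
from . import de as _de
from . import predictor as _predictor
from . import subtypes as _subtypes
from .exceptions import ValidationError
from .expression import (
    ExpressionMatrix,
    GeneSet,
    collapse_probes,
    iqr_filter,
    read_gene_set,
    read_matrix,
    read_samples,
)

logger = logging.getLogger("vasculotype")

__all__ = ["PipelineConfig", "run_full_pipeline"]


@dataclass
class PipelineConfig:
    """Resolved pipeline parameters (defaults follow the published method)."""

    matrix: str = ""
    annotation: str = ""
    out_dir: str = "vasculotype_out"
    probe_map: str | None = None
    marker_genes: str | None = None  # path to a plain-text gene set
    iqr_threshold: float = 2.0
    n_boot: int = 10000
    k_predictor: int = 6
    fdr_threshold: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("iqr_threshold", "fdr_threshold"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_boot < 1:
            raise ValidationError("n_boot must be >= 1")
        if self.k_predictor < 1:
            raise ValidationError("k_predictor must be >= 1")
        if self.seed < 0:
            raise ValidationError("seed must be >= 0")
        for name in ("matrix", "annotation"):
            if not Path(getattr(self, name)).exists():
                raise ValidationError(f"{name} path does not exist: {getattr(self, name)}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        stray = set(data) - known
        if stray:
            raise ValidationError(f"unknown config keys: {sorted(stray)}")
        return cls(**data)


def _check_ids(matrix: ExpressionMatrix, samples: pd.DataFrame) -> None:
    matrix_ids = set(matrix.sample_ids)
    annot_ids = set(samples["sample_id"])
    orphans = sorted(matrix_ids ^ annot_ids)
    if orphans:
        raise ValidationError(f"sample ids not shared by matrix and annotation: {orphans}")


def _de_contrast(
    matrix: ExpressionMatrix, mask_a, mask_b, samples: pd.DataFrame
) -> pd.DataFrame:
    ids_a = samples.loc[mask_a, "sample_id"].tolist()
    ids_b = samples.loc[mask_b, "sample_id"].tolist()
    sub = matrix.subset_samples(ids_a + ids_b)
    labels = [0] * len(ids_a) + [1] * len(ids_b)
    return _de.moderated_de(sub, labels)


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle into ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix = read_matrix(config.matrix)
    samples = read_samples(config.annotation)
    _check_ids(matrix, samples)
    samples = samples.set_index("sample_id").loc[list(matrix.sample_ids)].reset_index()
    logger.info("loaded matrix %d genes x %d samples", matrix.n_genes, matrix.n_samples)

    if config.probe_map:
        pm = pd.read_csv(config.probe_map, sep="\t", header=0)
        probe_map = dict(zip(pm.iloc[:, 0].astype(str), pm.iloc[:, 1].astype(str)))
        matrix = collapse_probes(matrix, probe_map)
        logger.info("collapsed probes -> %d genes", matrix.n_genes)

    filtered = iqr_filter(matrix, config.iqr_threshold)
    logger.info(
        "IQR filter > %s kept %d of %d genes",
        config.iqr_threshold, filtered.n_genes, matrix.n_genes,
    )

    report: dict = {
        "config": dataclasses.asdict(config),
        "n_genes_input": matrix.n_genes,
        "n_genes_filtered": filtered.n_genes,
    }

    # --- class discovery -------------------------------------------------
    all_tree = _cluster.bootstrap_support(filtered, config.n_boot, config.seed)
    (out / "tree_all.nwk").write_text(all_tree.to_newick(), encoding="utf-8")

    tumor_ids = samples.loc[
        samples["tissue"] == "tumor_vasculature", "sample_id"
    ].tolist()
    tumor_filtered = filtered.subset_samples(tumor_ids)
    tumor_tree = _cluster.bootstrap_support(tumor_filtered, config.n_boot, config.seed)
    (out / "tree_tumor.nwk").write_text(tumor_tree.to_newick(), encoding="utf-8")
    cut = _cluster.cut_k(tumor_tree, 2)
    discovered = pd.Series(cut).map({0: "A", 1: "B"}).rename("subtype")
    discovered.rename_axis("sample_id").to_frame().to_csv(out / "clusters_tumor.csv")

    scores, fractions = _cluster.pca_first_components(
        tumor_filtered, min(3, len(tumor_ids) - 1, tumor_filtered.n_genes)
    )
    report["pca_variance_fractions"] = [float(f) for f in fractions]

    annot = samples.set_index("sample_id")
    subtype = annot.loc[tumor_ids, "subtype"]
    if subtype.isna().any():
        subtype = discovered.reindex(tumor_ids)
        report["subtype_source"] = "discovered"
    else:
        report["subtype_source"] = "annotation"

    # --- DE contrasts -----------------------------------------------------
    contrasts = {}
    de_tables = {}
    is_tumor = samples["tissue"] == "tumor_vasculature"
    de_tables["tumor_vs_normal"] = _de_contrast(matrix, ~is_tumor, is_tumor, samples)
    tumor_annot = samples[is_tumor]
    sub_col = tumor_annot.set_index("sample_id")["subtype"]
    sub_col = sub_col.fillna(discovered.reindex(sub_col.index))
    de_tables["B_vs_A"] = _de_contrast(
        matrix,
        samples["sample_id"].isin(sub_col.index[sub_col == "A"]),
        samples["sample_id"].isin(sub_col.index[sub_col == "B"]),
        samples,
    )
    mvd = tumor_annot["mvd_class"]
    if mvd.notna().sum() >= 4 and mvd.dropna().nunique() == 2:
        de_tables["high_vs_low_mvd"] = _de_contrast(
            matrix,
            samples["sample_id"].isin(tumor_annot.loc[mvd == "low", "sample_id"]),
            samples["sample_id"].isin(tumor_annot.loc[mvd == "high", "sample_id"]),
            samples,
        )
    for name, table in de_tables.items():
        table.to_csv(out / f"de_{name}.tsv", sep="\t", index=False)
        contrasts[name] = int((table["q"] <= config.fdr_threshold).sum())
        logger.info("DE %s: %d genes at q <= %s", name, contrasts[name], config.fdr_threshold)
    report["n_significant"] = contrasts

    # --- markers and clinical associations -------------------------------
    if config.marker_genes:
        markers = read_gene_set(config.marker_genes, name="markers")
        try:
            ms = _subtypes.marker_score(matrix.subset_samples(tumor_ids), markers)
            ms.scores.rename_axis("sample_id").to_csv(out / "marker_scores.csv")
            a_scores = ms.scores[subtype == "A"]
            b_scores = ms.scores[subtype == "B"]
            if len(a_scores) >= 2 and len(b_scores) >= 2:
                _t, p = _de.two_sample_t(b_scores, a_scores)
                report["marker_welch_p"] = float(p)
        except ValidationError as err:
            logger.warning("marker scoring skipped: %s", err)

    assoc = _subtypes.clinical_association(subtype, samples[is_tumor])
    assoc.to_csv(out / "clinical_association.csv", index=False)

    # --- recurrence predictor --------------------------------------------
    outcome = annot.loc[tumor_ids, "recurrence"]
    if outcome.notna().all() and outcome.nunique() == 2 and outcome.value_counts().min() >= 2:
        cv = _predictor.loocv_run(
            matrix.subset_samples(tumor_ids), subtype, outcome, k=config.k_predictor
        )
        cv.folds.assign(genes=cv.folds["genes"].map(lambda g: ";".join(g))).to_csv(
            out / "predictor_folds.csv", index=False
        )
        report["predictor"] = {
            "accuracy": cv.accuracy,
            "fisher_p": cv.fisher_p,
            "k": config.k_predictor,
        }
        logger.info("LOOCV accuracy %.3f (p=%.4g)", cv.accuracy, cv.fisher_p)
    else:
        report["predictor"] = None
        logger.info("recurrence predictor skipped: outcome labels unusable")

    (out / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True), encoding="utf-8"
    )
    (out / "config_resolved.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(config)), encoding="utf-8"
    )
    return report
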