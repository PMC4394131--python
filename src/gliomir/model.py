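"""Study-level model object and its fitted results.

:class:`GliomaMirnaStudy` bundles every input of the cross-grade
prognostic-microRNA analysis; :meth:`GliomaMirnaStudy.fit` runs the
staged analysis (group assignment -> per-grade differential expression
-> z-combination & signature selection -> DE-mRNA pool & target
intersection -> lineage-transition correlations -> per-tumor stage
similarity -> Cox / Kaplan-Meier survival association) and returns a
:class:`StudyResults` carrying each stage's tables, a text ``summary()``
and a ``save()`` writer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import (
    GRADE_GBM,
    GRADE_GIIIA,
    ExpressionMatrix,
    ValidationError,
    read_annotation_tsv,
)
from .diffexp import differential_expression
from .lineage import (
    StageProfileSet,
    control_lineage_correlation,
    correlate_transition_with_contrast,
    transition_foldchanges,
    tumor_stage_correlations,
)
from .meta import combine_grades, select_de_mrnas, select_signature
from .pipeline import PipelineConfig, assign_prognosis_groups
from .survival import cox_all_stages, km_median_split
from .targets import TargetTable, intersect_targets

__all__ = ["GliomaMirnaStudy", "StudyResults"]


@dataclass
class StudyResults:
    """Fitted tables for every stage of the analysis."""

    config: PipelineConfig
    annotation: pd.DataFrame
    de_mirna: dict
    combined: object
    signature: object
    combined_mrna: object | None = None
    de_mrna_pool: pd.Index | None = None
    targets: pd.DataFrame | None = None
    transitions: list | None = None
    transition_correlations: pd.DataFrame | None = None
    control_correlations: pd.DataFrame | None = None
    tumor_correlations: object | None = None
    stage_cox: object | None = None
    km: object | None = None
    truth: object | None = None
    sim_config: object | None = None

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        lines = []
        add = lines.append
        add("Cross-grade prognostic microRNA analysis")
        add("=" * 56)
        t = self.combined.table
        add(f"microRNAs tested (shared across platforms): {len(t)}")
        add(
            f"signature (FDR<{self.config.fdr_threshold}, |z|>={self.config.z_threshold}): "
            f"{len(self.signature)} "
            f"({len(self.signature.up_in_poor)} up / {len(self.signature.down_in_poor)} down in poor)"
        )
        if self.de_mrna_pool is not None:
            add(f"DE mRNA pool (joint p<{self.config.mrna_p_threshold}, >=2-fold): {len(self.de_mrna_pool)}")
        if self.targets is not None:
            add(f"predicted targets (>= {self.config.min_db} databases): {len(self.targets)}")
        if self.transition_correlations is not None:
            add("")
            add("Stage-transition vs prognosis fold-change correlations (Spearman):")
            for _, row in self.transition_correlations.iterrows():
                if row["omitted"]:
                    add(f"  {row['transition']:<10} {row['contrast']:<22} omitted (too few passing microRNAs)")
                else:
                    add(
                        f"  {row['transition']:<10} {row['contrast']:<22} "
                        f"rho={row['rho']:+.3f}  p={row['p']:.3g}  n={int(row['n_features'])}"
                    )
        if self.control_correlations is not None and len(self.control_correlations):
            add("Control lineages:")
            for _, row in self.control_correlations.iterrows():
                add(
                    f"  {row['control']:<10} {row['contrast']:<22} "
                    f"rho={row['rho']:+.3f}  p={row['p']:.3g}  n={int(row['n_features'])}"
                )
        if self.tumor_correlations is not None:
            add("")
            rho = self.tumor_correlations.rho
            add(
                f"Per-tumor stage similarity over {self.tumor_correlations.n_shared_features} "
                f"shared microRNAs ({len(rho)} tumors); mean rho by stage:"
            )
            add("  " + "  ".join(f"{s}={rho[s].mean():.2f}" for s in rho.columns))
        if self.stage_cox is not None:
            add("")
            add("Cox regression of survival on stage similarity (per-stage):")
            tab = self.stage_cox.table
            for stage, row in tab.iterrows():
                if row["error"] is not None and not isinstance(row["error"], float):
                    add(f"  {stage:<5} failed: {row['error']}")
                else:
                    add(
                        f"  {stage:<5} HR={row['hr']:8.2f}  95% CI=({row['ci_low']:.2f}, {row['ci_high']:.2f})  "
                        f"p={row['p']:.3g}"
                    )
            add(f"  highest hazard ratio: {self.stage_cox.best_stage}")
        if self.km is not None:
            add(
                f"Median-split Kaplan-Meier (OP1 similarity): log-rank chi2="
                f"{self.km.logrank_chi2:.2f}, p={self.km.logrank_p:.3g}"
            )
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        ann = self.annotation.copy()
        ann.index.name = "sample_id"
        ann.to_csv(out / "annotation_groups.tsv", sep="\t")
        for grade, de in self.de_mirna.items():
            df = de.copy()
            df.index.name = "feature_id"
            df.to_csv(out / f"de_mirna_{grade}.tsv", sep="\t")
        ct = self.combined.table.copy()
        ct.index.name = "feature_id"
        ct.to_csv(out / "combined_mirna.tsv", sep="\t")
        sig = pd.concat(
            [
                pd.DataFrame({"feature_id": self.signature.up_in_poor, "direction": "up_in_poor"}),
                pd.DataFrame({"feature_id": self.signature.down_in_poor, "direction": "down_in_poor"}),
            ]
        )
        sig.to_csv(out / "signature.tsv", sep="\t", index=False)
        if self.combined_mrna is not None:
            cm = self.combined_mrna.table.copy()
            cm.index.name = "feature_id"
            cm.to_csv(out / "combined_mrna.tsv", sep="\t")
        if self.targets is not None:
            self.targets.to_csv(out / "targets.tsv", sep="\t", index=False)
        if self.transition_correlations is not None:
            self.transition_correlations.to_csv(out / "transition_correlations.tsv", sep="\t", index=False)
        if self.control_correlations is not None:
            self.control_correlations.to_csv(out / "control_correlations.tsv", sep="\t", index=False)
        if self.tumor_correlations is not None:
            rho = self.tumor_correlations.rho.copy()
            rho.index.name = "sample_id"
            rho.to_csv(out / "tumor_stage_rho.tsv", sep="\t")
        if self.stage_cox is not None:
            self.stage_cox.table.to_csv(out / "stage_cox.tsv", sep="\t")
        if self.km is not None:
            for name, curve in self.km.curves.items():
                curve.to_csv(out / f"km_curve_{name}.tsv", sep="\t", index=False)
        manifest = {
            "gliomir_version": __version__,
            "pipeline_config": self.config.to_dict(),
            "sim_config": self.sim_config.to_dict() if self.sim_config is not None else None,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        with open(out / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")


class GliomaMirnaStudy:
    """The full study: cohort matrices, stage profiles, tumors, targets.

    Required inputs are the two prognosis-cohort microRNA matrices and
    their sample annotation; every other input is optional and its
    analysis stage is skipped when absent.
    """

    def __init__(
        self,
        mirna_seq: ExpressionMatrix,
        mirna_array: ExpressionMatrix,
        annotation: pd.DataFrame,
        *,
        mrna_seq: ExpressionMatrix | None = None,
        mrna_array: ExpressionMatrix | None = None,
        stages: StageProfileSet | None = None,
        tumors: ExpressionMatrix | None = None,
        tumor_survival: pd.DataFrame | None = None,
        target_tables: tuple | None = None,
        controls: dict | None = None,
        config: PipelineConfig | None = None,
        truth=None,
        sim_config=None,
    ) -> None:
        self.mirna_seq = mirna_seq
        self.mirna_array = mirna_array
        self.annotation = annotation
        self.mrna_seq = mrna_seq
        self.mrna_array = mrna_array
        self.stages = stages
        self.tumors = tumors
        self.tumor_survival = tumor_survival
        self.target_tables = target_tables
        self.controls = controls or {}
        self.config = config or PipelineConfig()
        self.truth = truth
        self.sim_config = sim_config

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_simulation(cls, sim_config, config: PipelineConfig | None = None) -> "GliomaMirnaStudy":
        from .simulate import simulate_all

        b = simulate_all(sim_config)
        return cls(
            b["mirna_seq"],
            b["mirna_array"],
            b["annotation"],
            mrna_seq=b["mrna_seq"],
            mrna_array=b["mrna_array"],
            stages=b["stages"],
            tumors=b["tumors"],
            tumor_survival=b["tumor_survival"],
            target_tables=b["target_tables"],
            controls=b["controls"],
            config=config,
            truth=b["truth"],
            sim_config=sim_config,
        )

    @classmethod
    def from_tsv_dir(cls, path, config: PipelineConfig | None = None) -> "GliomaMirnaStudy":
        """Read a directory written by :func:`gliomir.simulate.write_simulation`
        (or hand-assembled in the same layout)."""
        p = Path(path)

        def opt(name):
            return (p / name) if (p / name).exists() else None

        stages = StageProfileSet.read_tsv(p / "stage_profiles.tsv") if opt("stage_profiles.tsv") else None
        tumors = (
            ExpressionMatrix.read_tsv(p / "tumor_intensity.tsv", "intensity")
            if opt("tumor_intensity.tsv")
            else None
        )
        survival = None
        if opt("tumor_survival.tsv"):
            survival = pd.read_csv(p / "tumor_survival.tsv", sep="\t", index_col=0)
            survival["event"] = survival["event"].astype(bool)
        tables = tuple(
            TargetTable.read_tsv(f, db_name=f.stem.removeprefix("targets_"))
            for f in sorted(p.glob("targets_*.tsv"))
        ) or None
        controls = {}
        for f in sorted(p.glob("control_*.tsv")):
            label = f.stem.removeprefix("control_")
            controls[label] = pd.read_csv(f, sep="\t", index_col=0)["logfc"].rename(label)
        return cls(
            ExpressionMatrix.read_tsv(p / "mirna_counts_GIIIA.tsv", "counts"),
            ExpressionMatrix.read_tsv(p / "mirna_intensity_GBM.tsv", "intensity"),
            read_annotation_tsv(p / "annotation.tsv"),
            mrna_seq=ExpressionMatrix.read_tsv(p / "mrna_counts_GIIIA.tsv", "counts")
            if opt("mrna_counts_GIIIA.tsv")
            else None,
            mrna_array=ExpressionMatrix.read_tsv(p / "mrna_intensity_GBM.tsv", "intensity")
            if opt("mrna_intensity_GBM.tsv")
            else None,
            stages=stages,
            tumors=tumors,
            tumor_survival=survival,
            target_tables=tables,
            controls=controls,
            config=config,
        )

    # -- fitting -----------------------------------------------------------

    def fit(self) -> StudyResults:
        cfg = self.config
        ann = assign_prognosis_groups(self.annotation, cfg)

        de_mirna = {
            GRADE_GIIIA: differential_expression(self.mirna_seq, ann),
            GRADE_GBM: differential_expression(self.mirna_array, ann),
        }
        combined = combine_grades(
            de_mirna[GRADE_GIIIA],
            de_mirna[GRADE_GBM],
            denominator=cfg.combine_denominator,
            fdr_threshold=cfg.fdr_threshold,
            z_threshold=cfg.z_threshold,
        )
        signature = select_signature(combined, cfg.fdr_threshold, cfg.z_threshold)

        combined_mrna = de_mrna_pool = targets_df = None
        if self.mrna_seq is not None and self.mrna_array is not None:
            de_mrna_III = differential_expression(self.mrna_seq, ann)
            de_mrna_IV = differential_expression(self.mrna_array, ann)
            combined_mrna = combine_grades(
                de_mrna_III, de_mrna_IV, denominator=cfg.combine_denominator
            )
            de_mrna_pool = select_de_mrnas(
                combined_mrna, cfg.mrna_p_threshold, cfg.mrna_min_abs_logfc
            )
            if self.target_tables is not None and len(signature) and len(de_mrna_pool):
                targets_df = intersect_targets(
                    signature.features, de_mrna_pool, self.target_tables, cfg.min_db
                )

        transitions = trans_corr = ctrl_corr = None
        if self.stages is not None:
            transitions = transition_foldchanges(
                self.stages,
                p_threshold=cfg.transition_p_threshold,
                min_abs_logfc=cfg.transition_min_abs_logfc,
                min_passing=cfg.min_passing,
            )
            contrasts = {
                f"{g}_poor_vs_good": de_mirna[g]["logfc"] for g in (GRADE_GIIIA, GRADE_GBM)
            }
            idh = self._idh_contrast(ann)
            if idh is not None:
                contrasts["IDHwt_vs_IDHmut"] = idh
            rows = []
            for tfc in transitions:
                for label, fc in contrasts.items():
                    if tfc.omitted:
                        rows.append((tfc.label, label, np.nan, np.nan, 0, True))
                    else:
                        c = correlate_transition_with_contrast(tfc, fc, label)
                        rows.append((tfc.label, label, c.rho, c.p, c.n_features, False))
            trans_corr = pd.DataFrame(
                rows, columns=["transition", "contrast", "rho", "p", "n_features", "omitted"]
            )
            crows = []
            for ctrl_label, ctrl_fc in self.controls.items():
                for label, fc in contrasts.items():
                    c = control_lineage_correlation(ctrl_fc, fc, ctrl_label)
                    crows.append((ctrl_label, label, c.rho, c.p, c.n_features))
            ctrl_corr = pd.DataFrame(
                crows, columns=["control", "contrast", "rho", "p", "n_features"]
            )

        tumor_corr = stage_cox = km = None
        if self.tumors is not None and self.stages is not None:
            shared = self.tumors.feature_ids.intersection(self.stages.feature_ids)
            tumor_corr = tumor_stage_correlations(self.tumors, self.stages, shared)
            if self.tumor_survival is not None:
                stage_cox = cox_all_stages(tumor_corr, self.tumor_survival)
                km = km_median_split(tumor_corr.rho["OP1"], self.tumor_survival)

        return StudyResults(
            config=cfg,
            annotation=ann,
            de_mirna=de_mirna,
            combined=combined,
            signature=signature,
            combined_mrna=combined_mrna,
            de_mrna_pool=de_mrna_pool,
            targets=targets_df,
            transitions=transitions,
            transition_correlations=trans_corr,
            control_correlations=ctrl_corr,
            tumor_correlations=tumor_corr,
            stage_cox=stage_cox,
            km=km,
            truth=self.truth,
            sim_config=self.sim_config,
        )

    def _idh_contrast(self, ann: pd.DataFrame):
        """IDH wild-type vs mutant differential fold changes on the
        sequencing cohort (confounding-control contrast), when both
        genotype groups have >= 2 samples."""
        if "idh_status" not in ann.columns:
            return None
        sub = ann.loc[ann.index.intersection(self.mirna_seq.sample_ids)]
        if (sub["idh_status"] == "mut").sum() < 2 or (sub["idh_status"] == "wt").sum() < 2:
            return None
        de = differential_expression(
            self.mirna_seq, sub, contrast=("mut", "wt"), group_col="idh_status"
        )
        return de["logfc"]
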