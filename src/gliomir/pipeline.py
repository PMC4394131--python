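"""Pipeline configuration, prognosis-group assignment and orchestration.

`run_pipeline` is a thin wrapper: it builds a
:class:`gliomir.model.GliomaMirnaStudy` from a simulated bundle or a
directory of TSV inputs, fits it, and writes every stage's tables plus a
run manifest to the output directory.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import GRADE_GBM, GRADE_GIIIA, GROUP_GOOD, GROUP_POOR, GROUP_UNASSIGNED, InvalidConfigError

logger = logging.getLogger("gliomir")

__all__ = ["PipelineConfig", "assign_prognosis_groups", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis thresholds and prognosis cut-offs.

    Cut-offs (months): a sample is good-prognosis if it survived longer
    than ``good_min_months`` for its grade and poor-prognosis if shorter
    than ``poor_max_months``; anything between (or without survival
    data) stays unassigned.
    """

    good_min_months_giiia: float = 48.0
    poor_max_months_giiia: float = 10.0
    good_min_months_gbm: float = 48.0
    poor_max_months_gbm: float = 4.0
    fdr_threshold: float = 0.05
    z_threshold: float = 2.0
    mrna_p_threshold: float = 0.05
    mrna_min_abs_logfc: float = 1.0
    min_db: int = 2
    min_passing: int = 5
    transition_p_threshold: float = 0.05
    transition_min_abs_logfc: float = 1.0
    combine_denominator: str = "sqrt2"
    seed: int = 0

    def __post_init__(self) -> None:
        for grade, good, poor in (
            (GRADE_GIIIA, self.good_min_months_giiia, self.poor_max_months_giiia),
            (GRADE_GBM, self.good_min_months_gbm, self.poor_max_months_gbm),
        ):
            if not good > poor:
                raise InvalidConfigError(
                    f"{grade}: good_min_months ({good}) must exceed poor_max_months ({poor})"
                )
        if self.combine_denominator not in ("sqrt2", "2"):
            raise InvalidConfigError("combine_denominator must be 'sqrt2' or '2'")

    def cutoffs(self, grade: str) -> tuple[float, float]:
        if grade == GRADE_GIIIA:
            return self.good_min_months_giiia, self.poor_max_months_giiia
        if grade == GRADE_GBM:
            return self.good_min_months_gbm, self.poor_max_months_gbm
        raise InvalidConfigError(f"unknown grade {grade!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def assign_prognosis_groups(annotation: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Assign good/poor/unassigned prognosis groups from survival months.

    Grade-specific rule: good if survival > good_min_months, poor if
    survival < poor_max_months, otherwise unassigned.  Samples without
    survival data are left unassigned with a warning.
    """
    ann = annotation.copy()
    months = ann.get("survival_months")
    if months is None:
        raise InvalidConfigError("annotation lacks a survival_months column")
    group = np.full(len(ann), GROUP_UNASSIGNED, dtype=object)
    missing = months.isna().to_numpy()
    if missing.any():
        logger.warning(
            "%d sample(s) lack survival data; left unassigned", int(missing.sum())
        )
    for grade in (GRADE_GIIIA, GRADE_GBM):
        good_min, poor_max = config.cutoffs(grade)
        in_grade = (ann["grade"] == grade).to_numpy() & ~missing
        m = months.to_numpy(dtype=float)
        group[in_grade & (m > good_min)] = GROUP_GOOD
        group[in_grade & (m < poor_max)] = GROUP_POOR
    ann["group"] = group
    for grade in (GRADE_GIIIA, GRADE_GBM):
        sub = ann.loc[ann["grade"] == grade, "group"]
        logger.info(
            "%s: %d good / %d poor / %d unassigned",
            grade,
            int((sub == GROUP_GOOD).sum()),
            int((sub == GROUP_POOR).sum()),
            int((sub == GROUP_UNASSIGNED).sum()),
        )
    return ann


def run_pipeline(sim_config=None, pipeline_config: PipelineConfig | None = None,
                 outdir=None, input_dir=None):
    """Run the end-to-end analysis and (optionally) write its report bundle.

    Exactly one of ``sim_config`` (generate inputs) or ``input_dir``
    (read TSV inputs) must be given.  Returns the fitted
    :class:`gliomir.model.StudyResults`.
    """
    from .model import GliomaMirnaStudy

    pipeline_config = pipeline_config or PipelineConfig()
    if (sim_config is None) == (input_dir is None):
        raise InvalidConfigError("provide exactly one of sim_config or input_dir")
    if sim_config is not None:
        study = GliomaMirnaStudy.from_simulation(sim_config, config=pipeline_config)
    else:
        study = GliomaMirnaStudy.from_tsv_dir(input_dir, config=pipeline_config)
    results = study.fit()
    if outdir is not None:
        results.save(Path(outdir))
    return results
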