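"""End-to-end orchestration: simulate -> segment -> features ->
aggregate -> screen.

Stages hand data over as plain files (CSV / PNG) when run through
:func:`run_pipeline`, so each stage is independently re-runnable and
inspectable; :func:`screen_cohort` offers the same chain in memory for
programmatic use.  Runs are deterministic given the seed and inputs, and
a copy of the run configuration is written next to the outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable, aggregate_features
from .features import FEATURE_NAMES, features_frame
from .io import read_image, read_table, to_grayscale, write_table
from .segmentation import SegmentationParams, segment_nuclei
from .simulate import CohortSpec, iter_cohort, generate_cohort
from .stats import ScreeningReport, compare_groups

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    simulate: bool = True
    n_patients_per_group: int = 22
    image_size: tuple[int, int] = (512, 512)
    manifest: str | None = None  # existing cohort manifest when simulate=False
    input_dir: str | None = None
    nuclei_per_image: int | None = None
    images_per_patient: int | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    alpha: float = 0.05
    m_tests: int | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["segmentation"] = dataclasses.asdict(self.segmentation)
        d["image_size"] = list(self.image_size)
        return d


def extract_image_features(gray: np.ndarray, params: SegmentationParams | None = None,
                           **meta) -> pd.DataFrame:
    """Segment one grayscale/RGB image and compute the 63 features of
    every recovered nucleus."""
    regions = segment_nuclei(gray, params)
    return features_frame(regions, **meta)


def screen_cohort(spec: CohortSpec, params: SegmentationParams | None = None,
                  alpha: float = 0.05, m_tests: int | None = None
                  ) -> tuple[ScreeningReport, CohortTable, pd.DataFrame]:
    """In-memory full run on a synthetic cohort.

    Returns the screening report, the patient cohort table, and the
    per-nucleus feature table.
    """
    frames = []
    for pid, g_name, images in iter_cohort(spec):
        for i_idx, (gray, _labels, _specs) in enumerate(images, start=1):
            feats = extract_image_features(
                gray, params, patient_id=pid, group=g_name,
                image_path=f"{pid}_img{i_idx}")
            frames.append(feats)
            log.debug("%s image %d: %d nuclei", pid, i_idx, len(feats))
    per_nucleus = pd.concat(frames, ignore_index=True)
    cohort = aggregate_features(per_nucleus)
    report = compare_groups(cohort, alpha=alpha, m_tests=m_tests)
    return report, cohort, per_nucleus


def run_pipeline(config: RunConfig) -> ScreeningReport:
    """File-based end-to-end run.

    Writes ``features_per_nucleus.csv``, ``patients.csv``,
    ``report.csv`` and ``run_config.yaml`` under ``config.out_dir``.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    with open(os.path.join(config.out_dir, "run_config.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)

    if config.simulate:
        sim_dir = os.path.join(config.out_dir, "cohort")
        spec = CohortSpec(n_patients_per_group=config.n_patients_per_group,
                          seed=config.seed, image_size=tuple(config.image_size))
        if config.nuclei_per_image is not None:
            spec.low = dataclasses.replace(spec.low, nuclei_per_image=config.nuclei_per_image)
            spec.high = dataclasses.replace(spec.high, nuclei_per_image=config.nuclei_per_image)
        if config.images_per_patient is not None:
            spec.low = dataclasses.replace(spec.low, images_per_patient=config.images_per_patient)
            spec.high = dataclasses.replace(spec.high, images_per_patient=config.images_per_patient)
        manifest = generate_cohort(spec, sim_dir)
        input_dir = sim_dir
        log.info("simulated cohort: %d images", len(manifest))
    else:
        if not config.manifest:
            raise ValueError("manifest required when simulate=False")
        manifest = read_table(config.manifest)
        input_dir = config.input_dir or os.path.dirname(os.path.abspath(config.manifest))

    frames = []
    for rec in manifest.to_dict("records"):
        gray = to_grayscale(read_image(os.path.join(input_dir, rec["image_path"])))
        feats = extract_image_features(gray, config.segmentation,
                                       patient_id=rec["patient_id"],
                                       group=rec["group"],
                                       image_path=rec["image_path"])
        log.info("%s: %d nuclei", rec["image_path"], len(feats))
        frames.append(feats)
    per_nucleus = pd.concat(frames, ignore_index=True)
    write_table(per_nucleus, os.path.join(config.out_dir, "features_per_nucleus.csv"),
                columns=list(per_nucleus.columns))

    cohort = aggregate_features(per_nucleus)
    write_table(cohort.to_frame(), os.path.join(config.out_dir, "patients.csv"))

    report = compare_groups(cohort, alpha=config.alpha, m_tests=config.m_tests)
    write_table(report.rows, os.path.join(config.out_dir, "report.csv"))
    log.info("%d / %d features significant after FDR",
             len(report.significant_adj), len(FEATURE_NAMES))
    return report
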