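"""End-to-end orchestration: phantom -> preprocessing -> features ->
selection -> models -> evaluation, from a single config.

One master seed derives all stage seeds through ``numpy.random.SeedSequence``
spawning (cohort generation, per-task model fitting), so a run is a pure
function of (config, seed) and reruns produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import ExtractionConfig, extract_case_features, feature_table
from .filters import FilterConfig
from .image import (DEFAULT_RING_DISTANCES, make_ring_set, normalize_gray,
                    resample_isotropic, resample_mask_isotropic)
from .modeling import TaskSpec, split_cohort
from .phantom import ImageParams, PhantomCase, default_profiles, generate_cohort
from .pipeline import ModelConfig, SubtypeClassificationModel
from .selection import ICC_THRESHOLD, reproducibility_filter

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """All knobs of a pipeline run; round-trips through YAML/JSON."""

    seed: int = 0
    n_cases: int = 100
    n_external: int = 0
    prevalences: tuple[float, float, float] = (0.694, 0.140, 0.166)
    split_ratio: float = 0.7
    ring_distances: tuple[float, ...] = DEFAULT_RING_DISTANCES
    ring_mode: str = "in-plane"
    grid_shape: tuple[int, int, int] = (96, 96, 48)
    grid_spacing: tuple[float, float, float] = (0.9, 0.9, 2.0)
    tumor_semiaxis_range_mm: tuple[float, float] = (5.0, 12.0)
    bin_width: float = 25.0
    full_filter_bank: bool = True
    icc_threshold: float = ICC_THRESHOLD
    f_fraction: float = 0.20
    l1_C: float = 1.0
    svm_C: float = 1.0
    svm_kernel: str = "rbf"
    resegmentation_fraction: float = 0.1
    tasks: tuple[int, ...] = (1, 2, 3, 4)
    normalize_after_resample: bool = True
    output_dir: str = "perirad_run"

    def __post_init__(self):
        if abs(sum(self.prevalences) - 1.0) > 1e-9:
            raise ValueError("prevalences must sum to 1")
        if not 0 < self.split_ratio < 1:
            raise ValueError("split ratio must be in (0, 1)")
        if not 0 < self.icc_threshold <= 1 or not 0 < self.f_fraction <= 1:
            raise ValueError("selection thresholds out of range")
        if any(t not in (1, 2, 3, 4) for t in self.tasks):
            raise ValueError("tasks must be drawn from {1, 2, 3, 4}")
        min_ring = min(self.ring_distances)
        for p in default_profiles():
            if p.rim_width >= min_ring + 4.0:
                raise ValueError("profile rim width incompatible with ring grid")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = json.dumps(self.to_dict(), indent=2) if path.suffix == ".json" \
            else yaml.safe_dump(self.to_dict())
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        d = json.loads(path.read_text()) if path.suffix == ".json" \
            else yaml.safe_load(path.read_text())
        return cls.from_dict(d)

    def extraction_config(self) -> ExtractionConfig:
        filters = FilterConfig() if self.full_filter_bank else \
            FilterConfig(remaps=(), log_sigmas_mm=(), wavelet=None)
        return ExtractionConfig(bin_width=self.bin_width, filters=filters)

    def image_params(self) -> ImageParams:
        return ImageParams(shape=self.grid_shape, spacing=self.grid_spacing,
                           tumor_semiaxis_range_mm=self.tumor_semiaxis_range_mm)

    def model_config(self) -> ModelConfig:
        return ModelConfig(svm_kernel=self.svm_kernel, svm_C=self.svm_C,
                           l1_C=self.l1_C, f_fraction=self.f_fraction)


# ---------------------------------------------------------------------------
# Case-level preprocessing + extraction


def preprocess_and_extract(case: PhantomCase, config: RunConfig):
    """Resample, normalize, build rings, and extract all feature vectors.

    Returns (intratumoral vector, {ring: vector}, reseg vectors or None).
    """
    vol = resample_isotropic(case.volume, 1.0)
    if config.normalize_after_resample:
        vol = normalize_gray(vol)
    else:
        vol = resample_isotropic(normalize_gray(case.volume), 1.0)
    mask = resample_mask_isotropic(case.tumor_mask_r1s1, 1.0)
    rings = make_ring_set(mask, config.ring_distances, config.ring_mode)
    masks = {"intratumoral": mask}
    for d, r in rings.items():
        masks[f"ring_{d:g}"] = r
    if case.has_resegmentation:
        masks["reseg_r1s2"] = resample_mask_isotropic(case.tumor_mask_r1s2, 1.0)
        masks["reseg_r2"] = resample_mask_isotropic(case.tumor_mask_r2, 1.0)
    vectors = extract_case_features(vol, masks, config.extraction_config(),
                                    case_id=case.case_id)
    intr = vectors["intratumoral"]
    ring_vecs = {d: vectors[f"ring_{d:g}"] for d in config.ring_distances}
    reseg = None
    if case.has_resegmentation:
        reseg = {"r1s1": intr, "r1s2": vectors["reseg_r1s2"],
                 "r2": vectors["reseg_r2"]}
    return intr, ring_vecs, reseg


def extract_cohort_features(cases, config: RunConfig):
    """Feature matrices for a case list.

    Returns (intratumoral df, {ring: df}, (r1s1, r1s2, r2) reseg dfs).
    """
    intr_rows, reseg_rows = [], {"r1s1": [], "r1s2": [], "r2": []}
    ring_rows = {d: [] for d in config.ring_distances}
    for case in cases:
        intr, rings, reseg = preprocess_and_extract(case, config)
        intr_rows.append(intr)
        for d, v in rings.items():
            ring_rows[d].append(v)
        if reseg is not None:
            for k, v in reseg.items():
                reseg_rows[k].append(v)
    def to_df(vecs):
        df = pd.DataFrame([v.values for v in vecs],
                          index=[v.case_id for v in vecs])
        return df
    intr_df = to_df(intr_rows)
    ring_dfs = {d: to_df(vs) for d, vs in ring_rows.items()}
    reseg_dfs = tuple(to_df(reseg_rows[k]) if reseg_rows[k] else None
                      for k in ("r1s1", "r1s2", "r2"))
    return intr_df, ring_dfs, reseg_dfs


# ---------------------------------------------------------------------------
# Full pipeline


def run_pipeline(config: RunConfig, allow_small: bool = False) -> dict:
    """Execute every stage for all requested tasks; returns the report dict.

    Writes cohort table, feature matrices, and the consolidated JSON report
    under ``config.output_dir``.  Bit-reproducible given (config, seed).
    """
    t0 = time.time()
    out = Path(config.output_dir)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(8)]

    stage = "phantom"
    try:
        profiles = _profiles_with_prevalences(config.prevalences)
        cases, cohort = _generate(config, profiles, seeds[0], "center1",
                                  config.n_cases, allow_small)
        ext_cases, ext_cohort = ([], None)
        if config.n_external > 0:
            ext_cases, ext_cohort = _generate(config, profiles, seeds[1],
                                              "center2", config.n_external,
                                              allow_small)
        stage = "features"
        intr_df, ring_dfs, reseg_dfs = extract_cohort_features(
            cases + ext_cases, config)
        all_cohort = pd.concat([cohort] + ([ext_cohort] if ext_cohort is not None
                                           else []), ignore_index=True)
        all_cohort = all_cohort.set_index("case_id")
        stage = "icc"
        if reseg_dfs[0] is not None and len(reseg_dfs[0]) >= 3:
            icc_retained, icc_stats = reproducibility_filter(
                *reseg_dfs, threshold=config.icc_threshold)
        else:
            logger.warning("resegmentation subset too small for ICC; "
                           "skipping the reproducibility stage")
            icc_retained = list(intr_df.columns)
        stage = "split"
        center1 = all_cohort[all_cohort["center"] == "center1"]
        train_tbl, test_tbl = split_cohort(center1.reset_index(),
                                           config.split_ratio, seeds[2])
        tags = pd.Series("internal-test", index=all_cohort.index)
        tags.loc[train_tbl["case_id"]] = "training"
        if config.n_external > 0:
            tags.loc[all_cohort["center"] == "center2"] = "external-test"

        report = {
            "config": config.to_dict(),
            "cohort": {
                "n_cases": int(len(all_cohort)),
                "subtype_counts": all_cohort["subtype"].value_counts()
                    .sort_index().to_dict(),
                "n_resegmented": int(all_cohort["has_resegmentation"].sum()),
            },
            "feature_counts": {
                "per_roi": int(intr_df.shape[1]),
                "image_types": config.extraction_config().image_type_names(),
                "icc_retained": len(icc_retained),
                "icc_retained_pct": round(
                    100.0 * len(icc_retained) / intr_df.shape[1], 1),
            },
            "tasks": {},
        }
        # create the output directory only once generation has succeeded,
        # so a rejected config leaves no empty directory behind
        out.mkdir(parents=True, exist_ok=True)
        for task_id in config.tasks:
            stage = f"task{task_id}"
            task = TaskSpec(task_id)
            task_tags = tags.copy()
            if task.is_ternary and config.n_external > 0:
                # all center-1 cases train; center-2 is the test cohort
                task_tags.loc[all_cohort["center"] == "center1"] = "training"
            model = SubtypeClassificationModel(
                intratumoral=intr_df, rings=ring_dfs,
                clinical=all_cohort, cohort=task_tags, task=task,
                icc_retained=icc_retained, config=config.model_config())
            res = model.fit(seed=seeds[3] + task_id)
            report["tasks"][str(task_id)] = res.to_report_dict()
            (out / f"task{task_id}_summary.txt").write_text(res.summary() + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    all_cohort.to_csv(out / "cohort.csv")
    intr_df.to_csv(out / "features_intratumoral.csv")
    for d, df in ring_dfs.items():
        df.to_csv(out / f"features_ring{d:g}mm.csv")
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _profiles_with_prevalences(prevalences):
    base = default_profiles()
    return tuple(dataclasses.replace(p, prevalence=pr)
                 for p, pr in zip(base, prevalences))


def _generate(config, profiles, seed, center, n, allow_small):
    if n < 30 and not allow_small:
        raise ValueError("cohort size must be >= 30 (pass allow_small for fixtures)")
    if n < 30:
        return _small_cohort(config, profiles, seed, center, n)
    return generate_cohort(profiles, n, seed, config.image_params(),
                           config.resegmentation_fraction, center)


def _small_cohort(config, profiles, seed, center, n):
    """Deterministic small cohort with guaranteed per-class representation
    (fixture scale bypasses the multinomial draw so no class empties)."""
    from .phantom import generate_case
    prev = np.array([p.prevalence for p in profiles])
    counts = np.maximum(1, np.floor(prev * n).astype(int))
    while counts.sum() > n:
        counts[counts.argmax()] -= 1
    while counts.sum() < n:
        counts[counts.argmax()] += 1
    assignments = np.repeat(np.arange(len(profiles)), counts)
    n_reseg = max(3, int(round(config.resegmentation_fraction * n)))
    rng = np.random.default_rng(seed)
    reseg_idx = set(rng.choice(n, size=min(n_reseg, n), replace=False).tolist())
    case_seeds = np.random.SeedSequence(seed).spawn(n)
    cases, rows = [], []
    for i in range(n):
        prof = profiles[assignments[i]]
        cid = f"{center}_{i:04d}"
        cseed = int(case_seeds[i].generate_state(1)[0] % (2 ** 31))
        case = generate_case(prof, config.image_params(), cseed, case_id=cid,
                             with_resegmentation=(i in reseg_idx))
        cases.append(case)
        row = {"case_id": cid, "subtype": case.subtype, "center": center,
               "has_resegmentation": case.has_resegmentation}
        row.update(case.clinical.to_dict())
        rows.append(row)
    return cases, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixtures


def fixture_config(output_dir: str = "perirad_fixture",
                   full_filter_bank: bool = False) -> RunConfig:
    """A <= 12-case, <= 48^3-voxel configuration for tests and demos."""
    return RunConfig(
        seed=7, n_cases=12, n_external=0,
        prevalences=(0.5, 0.25, 0.25),
        grid_shape=(48, 48, 24), grid_spacing=(0.9, 0.9, 2.0),
        tumor_semiaxis_range_mm=(5.0, 7.0),
        full_filter_bank=full_filter_bank,
        resegmentation_fraction=0.34,
        output_dir=output_dir)


def make_fixtures(output_dir: str = "perirad_fixture") -> tuple[list, pd.DataFrame, pd.DataFrame]:
    """Tiny deterministic cohort plus its intratumoral feature matrix.

    Returns (cases, cohort table, feature matrix); also writes
    ``fixture_features.csv`` under ``output_dir``.
    """
    config = fixture_config(output_dir)
    profiles = _profiles_with_prevalences(config.prevalences)
    cases, cohort = _small_cohort(config, profiles, config.seed, "center1",
                                  config.n_cases)
    intr_df, _, _ = extract_cohort_features(cases, config)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(out / "fixture_cohort.csv", index=False)
    intr_df.to_csv(out / "fixture_features.csv", float_format="%.10g")
    return cases, cohort, intr_df
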