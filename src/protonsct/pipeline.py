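"""End-to-end pipeline: phantoms -> training -> synthesis -> planning ->
robustness -> report CSVs.

One global seed fans out to every stochastic stage through named sub-seeds
(a hash of the stage name mixed into a ``SeedSequence``), so each stage is
independently reproducible and a rerun with the same configuration emits
identical outputs.  A JSON manifest records configuration and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .phantom import PhantomSpec, make_cohort
from .gan import MISynthesisGAN, TrainConfig
from .mi import MIConfig
from .sct_eval import evaluate_sct, aggregate_mae
from .dose import make_plan
from .dvh import diff_table, cohort_table
from .robust import RobustSettings, RobustnessEvaluation

log = logging.getLogger("protonsct")

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Configuration of the full desk-scale study."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    n_subjects: int = 22
    n_holdout: int = 2
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    train: TrainConfig = field(default_factory=lambda: TrainConfig.phantom_scale())
    mi_bins: int = 16
    robust: RobustSettings = field(default_factory=RobustSettings)
    prescription: float = 60.0

    def validate(self) -> None:
        if self.n_subjects < self.n_holdout + 2:
            raise ValueError("need at least 2 training subjects beyond the holdout")
        self.phantom.validate()
        self.train.validate()
        self.robust.validate()


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage; returns the report directory.

    Writes per-stage outputs under ``cfg.out_dir`` plus ``manifest.json``
    with versions, seeds and timing.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}

    def _stage(name):
        t0 = time.time()
        log.info("stage %s ...", name)
        return t0

    def _done(name, t0):
        manifest["stages"][name] = {"seed": stage_seed(cfg.seed, name),
                                    "seconds": round(time.time() - t0, 2)}
        log.info("stage %s done in %.1f s", name, time.time() - t0)

    # 1. cohort
    t0 = _stage("phantoms")
    cohort = make_cohort(cfg.phantom, cfg.n_subjects, stage_seed(cfg.seed, "phantoms"))
    holdout, develop = cohort[: cfg.n_holdout], cohort[cfg.n_holdout:]
    _done("phantoms", t0)

    # 2. training
    t0 = _stage("train")
    tcfg = TrainConfig(**{**cfg.train.__dict__, "seed": stage_seed(cfg.seed, "train")})
    model = MISynthesisGAN(develop, mi_cfg=MIConfig(n_bins=cfg.mi_bins))
    results = model.fit(tcfg)
    results.save(out / "model")
    _done("train", t0)

    # 3. synthesis + image evaluation on the holdout
    t0 = _stage("synthesize")
    maes, counts = [], []
    scts = []
    for s in holdout:
        sct = results.predict_sct(s.mri)
        scts.append(sct)
        m, mask = evaluate_sct(s.ct, sct)
        maes.append(m)
        counts.append(int(mask.sum()))
    report = aggregate_mae(maes, counts)
    pd.DataFrame({"subject_id": [s.subject_id for s in holdout],
                  "mae_hu": report.per_subject_mae,
                  "n_voxels": counts}).to_csv(out / "image_mae.csv", index=False)
    _done("synthesize", t0)

    # 4. planning on CT + robustness on CT and sCT
    t0 = _stage("robustness")
    diff_nom, diff_worst = [], []
    for s, sct in zip(holdout, scts):
        rois = {"CTV": s.masks["CTV"], "brainstem": s.masks.get("brainstem")}
        plan = make_plan(s.ct, rois["CTV"], prescription=cfg.prescription)
        rs = RobustSettings(**{**cfg.robust.__dict__, "seed": stage_seed(cfg.seed, "robustness")})
        res_ct = RobustnessEvaluation(plan, s.ct, rois, rs).run()
        res_sct = RobustnessEvaluation(plan, sct, rois, rs).run()
        diff_nom.append(diff_table(res_ct.nominal, res_sct.nominal, cfg.prescription))
        diff_worst.append(diff_table(res_ct.worst, res_sct.worst, cfg.prescription))
    cohort_table(diff_nom).to_csv(out / "dvh_diff_nominal_pct.csv")
    cohort_table(diff_worst).to_csv(out / "dvh_diff_worst_pct.csv")
    _done("robustness", t0)

    manifest["image_mae_mean_hu"] = report.cohort_mean
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
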