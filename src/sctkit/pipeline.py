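"""End-to-end runs: phantom cohort -> preprocessing -> training -> evaluation.

`run_ablation` trains all four arms on the identical cohort and seed and
emits one comparative table (rows = arms; columns = image metrics, the
structural MIND distance between MR and sCT, and gamma pass rates), mirroring
the layout of a method-comparison study.  In the phantom world the dose pair
per test case is generated from the CT-view and MR-view anatomy, so gamma
columns probe the anatomical-discrepancy effect (identical across arms by
construction) while the image metrics and MIND distance separate the arms.

Every run directory receives a provenance manifest (tool version, resolved
configuration, seed, input checksums) sufficient to regenerate its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dosimetry import GammaCriteria, dvh_metrics, gamma_index, group_comparison
from .grid import ImageGrid, Modality
from .imagemetrics import evaluate_case
from .mind import MINDConfig, mind_loss
from .phantom import PhantomSpec, generate_dose, generate_pair, generate_structures
from .preprocess import body_mask, clip_hu, ct_to_net, mr_to_net, remove_external
from .trainer import ARMS, TrainConfig, train, synthesize

__all__ = ["RunConfig", "PhantomCohort", "build_cohort", "run_ablation",
           "version_and_provenance", "evaluate_generator"]


@dataclass
class RunConfig:
    """Resolved configuration of a full run; round-trips through YAML."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_train: int = 8
    n_val: int = 2
    n_test: int = 4
    gamma_criteria_percent_mm: Tuple[float, ...] = (1.0, 2.0, 3.0)
    out_dir: str = "runs/ablation"
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))
        return path

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # lists for YAML friendliness; from_dict restores tuples
        return json.loads(json.dumps(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        ph = PhantomSpec(**d.pop("phantom"))
        tr = dict(d.pop("train"))
        weights = tr.pop("weights", None)
        if weights is not None:
            from .objective import LossWeights

            tr["weights"] = LossWeights(**weights)
        for key in ("depths", "heads"):
            if key in tr:
                tr[key] = tuple(tr[key])
        tc = TrainConfig(**tr)
        if "gamma_criteria_percent_mm" in d:
            d["gamma_criteria_percent_mm"] = tuple(d["gamma_criteria_percent_mm"])
        return cls(phantom=ph, train=tc, **d)


@dataclass
class PhantomCohort:
    """In-memory cohort: preprocessed training arrays plus raw test cases."""

    train_mr: List[np.ndarray]
    train_ct: List[np.ndarray]
    test_cases: List[dict]  # per case: mr, ct (ImageGrids), mask, group, doses


def _preprocess_pair(mr: ImageGrid, ct: ImageGrid) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    ct = clip_hu(ct)
    mask = body_mask(ct)
    ct = remove_external(ct, mask)
    return mr_to_net(mr).astype(np.float32), ct_to_net(ct).astype(np.float32), mask


def build_cohort(spec: PhantomSpec, n_train: int, n_val: int, n_test: int,
                 with_dose: bool = True) -> PhantomCohort:
    """Generate and preprocess a phantom cohort.  Test cases are split
    half/half into Group 1 (aligned anatomy) and Group 2 (the configured
    discrepancy level)."""
    train_mr, train_ct = [], []
    idx = 0
    for _ in range(n_train + n_val):
        mr, ct, _ = generate_pair(spec, slice_index=idx)
        m, c, _ = _preprocess_pair(mr, ct)
        train_mr.append(m)
        train_ct.append(c)
        idx += 1
    test_cases = []
    for k in range(n_test):
        group = 1 if k < n_test - n_test // 2 else 2
        case_spec = dataclasses.replace(
            spec, discrepancy_level=0.0 if group == 1 else max(spec.discrepancy_level, 0.5)
        )
        mr, ct, labels = generate_pair(case_spec, slice_index=idx)
        ct_c = clip_hu(ct)
        mask = body_mask(ct_c)
        case = {
            "id": f"case_{idx:03d}",
            "mr": mr,
            "ct": remove_external(ct_c, mask),
            "mask": mask,
            "group": group,
            "labels": labels,
        }
        if with_dose:
            case["dose_ct"] = generate_dose(case_spec, labels, source="ct")
            case["dose_mr"] = generate_dose(case_spec, labels, source="mr")
            case["structures"] = generate_structures(labels)
        test_cases.append(case)
        idx += 1
    return PhantomCohort(train_mr=train_mr, train_ct=train_ct, test_cases=test_cases)


def evaluate_generator(generator, cohort: PhantomCohort,
                       mind_cfg: MINDConfig = MINDConfig()) -> pd.DataFrame:
    """Per-test-case image metrics of synthesized CT against the paired
    phantom CT, plus the structural MIND distance between MR and sCT."""
    rows = []
    for case in cohort.test_cases:
        sct = synthesize(generator, case["mr"])
        rep = evaluate_case(case["ct"], sct, case["mask"])
        rows.append(
            {
                "id": case["id"],
                "group": case["group"],
                **rep.as_dict(),
                "mind_mr_sct": mind_loss(mr_to_net(case["mr"]), ct_to_net(sct), mind_cfg),
            }
        )
    return pd.DataFrame(rows)


def gamma_table(cohort: PhantomCohort, criteria_percent_mm: Sequence[float] = (1.0, 2.0, 3.0),
                threshold_percent: float = 10.0) -> pd.DataFrame:
    """Per-case local and global gamma pass rates between the CT-anatomy and
    MR-anatomy phantom dose fields, at each %/mm criterion."""
    rows = []
    for case in cohort.test_cases:
        if "dose_ct" not in case:
            continue
        row = {"id": case["id"], "group": case["group"]}
        for c in criteria_percent_mm:
            for mode in ("local", "global"):
                crit = GammaCriteria(dose_diff_percent=c, dta_mm=c,
                                     threshold_percent=threshold_percent, mode=mode)
                res = gamma_index(case["dose_ct"], case["dose_mr"], crit)
                row[f"gamma_{mode}_{c:g}pct_{c:g}mm"] = res.pass_rate
        rows.append(row)
    return pd.DataFrame(rows)


def run_ablation(cfg: RunConfig) -> pd.DataFrame:
    """Train all four arms on one cohort/seed and emit the comparative table
    (one row per arm).  Results, per-case tables, the resolved config and a
    provenance manifest are written under ``cfg.out_dir``."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = build_cohort(cfg.phantom, cfg.n_train, cfg.n_val, cfg.n_test)
    gammas = gamma_table(cohort, cfg.gamma_criteria_percent_mm)
    gamma_means = gammas.drop(columns=["id", "group"]).mean() if len(gammas) else pd.Series(dtype=float)

    rows = []
    for arm in ("baseline", "swin_only", "mind_only", "proposed"):
        try:
            arm_cfg = dataclasses.replace(cfg.train, arm=arm, seed=cfg.seed)
            result = train(arm_cfg, cohort.train_mr, cohort.train_ct, out_dir=out_dir / arm)
            per_case = evaluate_generator(result.G_mr2ct, cohort)
        except Exception as exc:  # noqa: BLE001 - name the failing arm
            raise RuntimeError(f"ablation arm {arm!r} failed: {exc}") from exc
        per_case.to_csv(out_dir / arm / "per_case_metrics.csv", index=False)
        rows.append(
            {
                "arm": arm,
                "mae_hu": per_case["mae"].mean(),
                "psnr_db": per_case["psnr"].mean(),
                "ssim": per_case["ssim"].mean(),
                "kl_divergence": per_case["kl_divergence"].mean(),
                "mind_mr_sct": per_case["mind_mr_sct"].mean(),
                **gamma_means.to_dict(),
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "ablation_table.csv", index=False)
    gammas.to_csv(out_dir / "gamma_per_case.csv", index=False)
    cfg.to_yaml(out_dir / "resolved_config.yaml")
    version_and_provenance(out_dir, cfg.as_dict(), cfg.seed,
                           inputs=[out_dir / "resolved_config.yaml"])
    return table


def version_and_provenance(out_dir: str | Path, resolved_config: dict, seed: int,
                           inputs: Sequence[str | Path] = ()) -> Path:
    """Write a provenance manifest next to a run's outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for p in inputs:
        p = Path(p)
        if p.exists():
            checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    manifest = {
        "tool": "sctkit",
        "version": __version__,
        "seed": seed,
        "resolved_config": resolved_config,
        "input_checksums": checksums,
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
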