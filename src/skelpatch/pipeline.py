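"""End-to-end seeded experiments: phantom cohort -> preprocessing ->
skeletonization -> patch sampling -> training -> whole-volume prediction ->
metric report, including the ratio sweep (1:1 ... 1:5) with and without the
auxiliary classifier.

Splits are by case (never by patch) in the 120:19:15 train/val/test
proportions of the cohort the pipeline models; every sweep cell shares the
same cohort and splits so ratio/aux effects are paired.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BinaryMask, ImageVolume
from .evaluate import (
    ConfusionCounts,
    confusion_from_patches,
    metric_panel,
    seg_scores,
    stratified_report,
)
from .nn import (
    LossConfig,
    NetworkSpec,
    TrainConfig,
    build_model,
    classify_patches,
    patch_decision,
    predict_volume,
    train,
)
from .patches import SamplingPlan, build_dataset
from .phantom import PhantomCase, PhantomSpec, generate_phantom
from .preprocess import PreprocessConfig, preprocess_volume
from .skeleton import SkeletonConfig, SkeletonVoxelSet, skeletonize_vessels

SPLIT_PROPORTIONS = (120, 19, 15)  # train : val : test


def split_counts(n: int, proportions=SPLIT_PROPORTIONS) -> tuple[int, int, int]:
    """Largest-remainder apportionment of n cases into train/val/test.

    Rounding rule: floor each share, then hand remaining cases to the splits
    with the largest fractional remainders (ties broken in train, val, test
    order)."""
    total = sum(proportions)
    raw = [n * p / total for p in proportions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = sorted(range(3), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in range(rem):
        counts[order[i]] += 1
    return tuple(counts)  # type: ignore[return-value]


def split_cases(case_ids: list[str], seed: int, proportions=SPLIT_PROPORTIONS):
    """Shuffle case ids and split by :func:`split_counts`."""
    rng = np.random.default_rng(seed)
    ids = list(case_ids)
    rng.shuffle(ids)
    n_tr, n_va, n_te = split_counts(len(ids), proportions)
    return ids[:n_tr], ids[n_tr : n_tr + n_va], ids[n_tr + n_va :]


@dataclass
class ExperimentConfig:
    n_cases: int = 20
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    skeleton: SkeletonConfig = field(default_factory=SkeletonConfig)
    plan: SamplingPlan = field(default_factory=SamplingPlan)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    ratio_sweep: tuple[int, ...] = (2,)
    aux_sweep: tuple[bool, ...] = (True,)
    master_seed: int = 0
    fallback_min_voxels: int = 10  # patch decision without aux heads
    out_dir: str | None = None

    def __post_init__(self):
        if not self.ratio_sweep or not self.aux_sweep:
            raise ValueError("sweep lists must be nonempty")


def desk_profile(
    n_cases: int = 20,
    master_seed: int = 0,
    ratio_sweep=(2,),
    aux_sweep=(True, False),
    epochs: int = 5,
    out_dir: str | None = None,
) -> ExperimentConfig:
    """CPU-sized experiment profile: 96^3 phantoms at 0.3 mm, 32^3 patches,
    base-8 depth-3 network, short Adam schedule. The paper-scale profile
    (64^3 patches, base 16, depth 4, batch 16, 500 epochs) is reached by
    constructing :class:`ExperimentConfig` directly."""
    return ExperimentConfig(
        n_cases=n_cases,
        phantom=PhantomSpec(
            volume_shape=(96, 96, 96),
            spacing_mm=(0.3, 0.3, 0.3),
            n_vessels=2,
            vessel_radius_range_mm=(0.6, 1.1),
            n_aneurysms=1,
            aneurysm_diameter_range_mm=(2.5, 6.0),
            rician_sigma=10.0,
            bias_amplitude=0.15,
            curviness=0.6,
        ),
        preprocess=PreprocessConfig(bias_correction=True),
        skeleton=SkeletonConfig(threshold_percentile=99.0, min_component_voxels=500),
        plan=SamplingPlan(
            patch_size=(32, 32, 32), n_positive_per_aneurysm=2, min_negative_distance_mm=5.0
        ),
        network=NetworkSpec(depth=3, base_channels=8, aux_tap_levels=("bridge", "mid")),
        train=TrainConfig(batch_size=4, epochs=epochs, learning_rate=5e-3),
        loss=LossConfig(),
        ratio_sweep=tuple(ratio_sweep),
        aux_sweep=tuple(aux_sweep),
        master_seed=master_seed,
        out_dir=out_dir,
    )


@dataclass
class PreparedCase:
    """A case after preprocessing and skeletonization."""

    case_id: str
    image: ImageVolume
    aneurysm_mask: BinaryMask
    skeleton: SkeletonVoxelSet
    max_diameter_mm: float


def prepare_cohort(cfg: ExperimentConfig) -> list[PreparedCase]:
    """Generate and prepare the phantom cohort (shared by all sweep cells)."""
    seed_rng = np.random.default_rng(cfg.master_seed)
    case_seeds = seed_rng.integers(2**31, size=cfg.n_cases)
    prepared = []
    for i, s in enumerate(case_seeds):
        spec = dataclasses.replace(cfg.phantom, seed=int(s))
        case = generate_phantom(spec)
        img = preprocess_volume(case.image, cfg.preprocess)
        skel, _ = skeletonize_vessels(img, cfg.skeleton)
        diam = max((d for _, d in case.aneurysm_centers), default=0.0)
        prepared.append(
            PreparedCase(f"case{i:03d}", img, case.aneurysm_mask, skel, diam)
        )
    return prepared


def _cases_for(prepared: list[PreparedCase], ids: list[str]):
    sel = [c for c in prepared if c.case_id in set(ids)]
    return [(c.case_id, c.image, c.aneurysm_mask, c.skeleton) for c in sel]


def run_cell(
    cfg: ExperimentConfig,
    prepared: list[PreparedCase],
    splits: tuple[list[str], list[str], list[str]],
    ratio: int,
    aux_on: bool,
    seed: int,
) -> dict:
    """Train and evaluate one (ratio, aux) cell; returns a metric row."""
    train_ids, val_ids, test_ids = splits
    plan = dataclasses.replace(
        cfg.plan, ratio_normal_per_aneurysm=ratio, seed=seed
    )
    train_set = build_dataset(_cases_for(prepared, train_ids), plan)
    val_set = build_dataset(_cases_for(prepared, val_ids), plan, require_positives=False)
    test_set = build_dataset(_cases_for(prepared, test_ids), plan, require_positives=False)

    net_spec = dataclasses.replace(
        cfg.network, aux_tap_levels=cfg.network.aux_tap_levels if aux_on else ()
    )
    loss_cfg = dataclasses.replace(cfg.loss, aux_enabled=aux_on)
    train_cfg = dataclasses.replace(cfg.train, seed=seed)
    model = build_model(net_spec, seed=seed)
    model, history = train(model, train_set.samples, val_set.samples, train_cfg, loss_cfg)

    # patch-level classification panel on the held-out patch mix
    rule = "aux" if aux_on else "voxels"
    preds = classify_patches(model, test_set.samples)
    decisions = [
        patch_decision(p, rule=rule, min_voxels=cfg.fallback_min_voxels) for p in preds
    ]
    confusion = confusion_from_patches(decisions, [s.label for s in test_set.samples])
    panel = metric_panel(confusion)

    # case-level DSC on held-out volumes
    triples = []
    diameters = {}
    for c in prepared:
        if c.case_id not in set(test_ids):
            continue
        pred = predict_volume(
            model, c.image, c.skeleton, patch_size=cfg.plan.patch_size,
            stride=max(cfg.plan.patch_size[0] // 2, 1),
        )
        triples.append((c.case_id, c.aneurysm_mask.astype_bool(), pred.mask().astype_bool()))
        diameters[c.case_id] = c.max_diameter_mm
    scores = seg_scores(triples)

    row = {
        "ratio": ratio,
        "aux": aux_on,
        "seed": seed,
        "n_train_patches": len(train_set),
        "n_test_patches": len(test_set),
        **{k: (np.nan if v is None else v) for k, v in panel.items()},
        "dsc_mean": scores.mean_dsc,
        "dsc_std": scores.std_dsc,
        "per_case_dsc": scores.per_case_dsc,
        "per_case_ids": scores.case_ids,
        "diameters_mm": diameters,
        "final_train_loss": float(history["train_loss"].iloc[-1]),
        "first_train_loss": float(history["train_loss"].iloc[0]),
    }
    return row


def run_experiment(cfg: ExperimentConfig) -> pd.DataFrame:
    """Run the full sweep; one report row per (ratio, aux) cell.

    With ``cfg.out_dir`` set, per-cell JSON results are persisted and cells
    already on disk are skipped (resumable sweeps)."""
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    prepared = prepare_cohort(cfg)
    splits = split_cases([c.case_id for c in prepared], cfg.master_seed)
    rows = []
    for ratio in cfg.ratio_sweep:
        for aux_on in cfg.aux_sweep:
            cell_name = f"ratio{ratio}_aux{int(aux_on)}_seed{cfg.master_seed}"
            cell_path = out / f"{cell_name}.json" if out else None
            if cell_path and cell_path.exists():
                rows.append(json.loads(cell_path.read_text()))
                continue
            try:
                row = run_cell(cfg, prepared, splits, ratio, aux_on, cfg.master_seed)
            except Exception as e:  # keep the sweep alive, mark the cell
                warnings.warn(f"cell {cell_name} failed: {e}")
                row = {"ratio": ratio, "aux": aux_on, "seed": cfg.master_seed, "failed": str(e)}
            rows.append(row)
            if cell_path:
                cell_path.write_text(json.dumps(row, default=float))
    report = pd.DataFrame(rows)
    if out:
        report.to_csv(out / "report.csv", index=False)
    return report


def ratio_aux_ablation(
    seeds: tuple[int, ...] = (0, 1, 2),
    n_cases: int = 20,
    ratio: int = 2,
    epochs: int = 5,
) -> pd.DataFrame:
    """Paired aux-on/aux-off comparison at a fixed ratio over several master
    seeds (cohort and splits shared within a seed)."""
    rows = []
    for seed in seeds:
        cfg = desk_profile(
            n_cases=n_cases, master_seed=seed, ratio_sweep=(ratio,),
            aux_sweep=(True, False), epochs=epochs,
        )
        rows.append(run_experiment(cfg))
    return pd.concat(rows, ignore_index=True)
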