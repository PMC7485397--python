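"""End-to-end study orchestration at desk scale.

simulate -> segment/perturb -> patch -> train CNN -> extract features ->
ICC-filter -> LASSO signature -> quantitative SWE parameters -> evaluate on
held-out cohorts -> render tables.

Three cohorts are generated (training, independent validation, external
validation); the validation cohorts never touch network training or
signature fitting, which is enforced by a case-id disjointness check that
aborts the run on violation.  All stages draw their randomness from seeds
derived from one pipeline seed, so a rerun with the same configuration
reproduces every artifact bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from . import diagnostics as dx
from .exceptions import IncompleteRunError, LeakageError
from .features import CNNFeatureExtractor, NetworkConfig, TrainingConfig
from .io_roi import extract_patch, write_cohort
from .quant import quant_table
from .reproducibility import ICCFeatureFilter
from .signature import LassoSignature, youden_threshold
from .synthetic import BIRADS_LEVELS, Case, CohortSpec, generate_cohort, perturb_mask

QUANT_PARAMS = ("e_max", "e_mean", "e_ratio", "e_sd")


@dataclass
class PipelineConfig:
    """Full study configuration; defaults give a desk-scale separable run."""

    training: CohortSpec = field(default_factory=lambda: CohortSpec(n_benign=20, n_malignant=20))
    validation: CohortSpec = field(default_factory=lambda: CohortSpec(n_benign=8, n_malignant=8))
    external: CohortSpec = field(default_factory=lambda: CohortSpec(n_benign=4, n_malignant=4))
    net_config: NetworkConfig | None = None
    train_config: TrainingConfig | None = None
    patch_size: tuple[int, int] = (96, 128)  # (height, width) of network input
    patch_margin: int = 2
    icc_threshold: float = 0.6
    cv_folds: int = 5
    perturb_magnitude: float = 1.5
    roi_area_mm2: float = 2.0
    quant_jitter_sd: float = 2.0
    include_birads: bool = True  # ordinal radiologist-like category row in tables
    seed: int = 0
    outdir: str | None = None
    write_images: bool = False  # per-case rasters on disk (CLI turns this on)

    def resolved_net_config(self) -> NetworkConfig:
        return self.net_config or NetworkConfig(input_size=(*self.patch_size, 3))

    def resolved_train_config(self) -> TrainingConfig:
        return self.train_config or TrainingConfig(epochs=15, seed=self.seed)


def _check_disjoint(cohorts: dict[str, list[Case]]) -> None:
    names = list(cohorts)
    ids = {name: {c.case_id for c in cases} for name, cases in cohorts.items()}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            overlap = ids[a] & ids[b]
            if overlap:
                raise LeakageError(
                    f"case ids shared between {a} and {b}: {sorted(overlap)[:5]}"
                )


def _patches(cases: list[Case], modality: str, size, margin: int,
             mask_override: dict[str, np.ndarray] | None = None) -> np.ndarray:
    stack = []
    for c in cases:
        if modality == "bmode":
            image, mask = c.bmode, c.bmode_mask
        else:
            image, mask = c.swe_color, c.swe_mask
        if mask_override is not None:
            mask = mask_override[c.case_id]
        p = extract_patch(image, mask, margin=margin, target_size=size,
                         source_modality=modality, case_id=c.case_id)
        stack.append(p.pixels)
    return np.stack(stack)


def _labels(cases: list[Case]) -> np.ndarray:
    return np.array([c.label for c in cases])


def _binary(cases: list[Case]) -> np.ndarray:
    return np.array([c.label == "malignant" for c in cases])


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    config: PipelineConfig
    cohorts: dict[str, list[Case]]
    extractors: dict[str, CNNFeatureExtractor]
    icc_filters: dict[str, ICCFeatureFilter]
    signatures: dict[str, LassoSignature]
    rad_scores: dict[tuple[str, str], np.ndarray]  # (modality, cohort) -> scores
    quant: dict[str, pd.DataFrame]
    reports: dict[str, list[dx.DiagnosticReport]]
    tables: dict[str, pd.DataFrame]
    outdir: Path | None
    log: list[dict]


def run_pipeline(cfg: PipelineConfig) -> RunResult:
    """Execute every stage; returns all fitted models and rendered tables."""
    log: list[dict] = []

    def stage(name: str):
        log.append({"stage": name, "t": time.time()})

    rng_seed = cfg.seed % (2**31 - 1)
    stage("simulate")
    specs = {}
    for i, (name, spec) in enumerate(
        (("training", cfg.training), ("validation", cfg.validation), ("external", cfg.external))
    ):
        specs[name] = dataclasses.replace(spec, seed=(rng_seed + 1000 * (i + 1)) % (2**31 - 1))
    cohorts = {
        name: generate_cohort(spec, case_id_prefix=name[:5])
        for name, spec in specs.items()
    }
    _check_disjoint(cohorts)

    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        if cfg.write_images:
            for name, cases in cohorts.items():
                write_cohort(outdir / "cohorts" / name, cases)

    train_cases = cohorts["training"]
    y_train = _labels(train_cases)
    # penalty search needs one case per class per fold; clamp at small n
    min_class = int(np.bincount(_binary(train_cases).astype(int)).min())
    cv_folds = min(cfg.cv_folds, min_class)
    if cv_folds != cfg.cv_folds:
        log.append({"stage": "fit-signature",
                    "warning": f"cv_folds clamped to {cv_folds} (class size)"})

    stage("segment-perturb")
    # simulated repeat segmentations: rater 1 session 2, rater 2
    repeat_masks: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    for modality in ("bmode", "swe"):
        r1s2, r2 = {}, {}
        for i, c in enumerate(train_cases):
            base = c.bmode_mask if modality == "bmode" else c.swe_mask
            r1s2[c.case_id] = perturb_mask(base, cfg.perturb_magnitude,
                                           seed=(rng_seed + 7 * i + 1) % (2**31 - 1))
            r2[c.case_id] = perturb_mask(base, cfg.perturb_magnitude,
                                         seed=(rng_seed + 7 * i + 2) % (2**31 - 1))
        repeat_masks[modality] = {"r1s2": r1s2, "r2": r2}

    extractors, icc_filters, signatures = {}, {}, {}
    scores: dict[tuple[str, str], np.ndarray] = {}
    net_cfg = cfg.resolved_net_config()
    size = net_cfg.input_size[:2]

    for modality in ("bmode", "swe"):
        stage(f"train-cnn:{modality}")
        X_train = _patches(train_cases, modality, size, cfg.patch_margin)
        extractor = CNNFeatureExtractor(
            net_config=net_cfg, train_config=cfg.resolved_train_config()
        ).fit(X_train, y_train)
        extractors[modality] = extractor

        stage(f"features:{modality}")
        feats = {"training": extractor.transform(X_train)}
        for name in ("validation", "external"):
            feats[name] = extractor.transform(
                _patches(cohorts[name], modality, size, cfg.patch_margin)
            )
        f_r1s2 = extractor.transform(
            _patches(train_cases, modality, size, cfg.patch_margin,
                     mask_override=repeat_masks[modality]["r1s2"])
        )
        f_r2 = extractor.transform(
            _patches(train_cases, modality, size, cfg.patch_margin,
                     mask_override=repeat_masks[modality]["r2"])
        )

        stage(f"icc-filter:{modality}")
        icc_filter = ICCFeatureFilter(threshold=cfg.icc_threshold)
        icc_filter.fit(feats["training"], X_retest=f_r1s2, X_other_rater=f_r2)
        icc_filters[modality] = icc_filter

        stage(f"fit-signature:{modality}")
        sig = LassoSignature(cv_folds=cv_folds, modality=modality, seed=rng_seed)
        sig.fit(icc_filter.transform(feats["training"]), y_train)
        signatures[modality] = sig
        for name in cohorts:
            scores[(modality, name)] = sig.decision_function(icc_filter.transform(feats[name]))

        if outdir:
            mdir = outdir / "models"
            mdir.mkdir(exist_ok=True)
            sig.signature_.to_json(mdir / f"{modality}_signature.json")
            icc_filter.to_frame().to_csv(outdir / f"models/{modality}_icc.csv", index=False)
            for name in cohorts:
                fdir = outdir / "features"
                fdir.mkdir(exist_ok=True)
                pd.DataFrame(
                    feats[name],
                    index=[c.case_id for c in cohorts[name]],
                ).to_csv(fdir / f"{modality}_{name}.csv")

    stage("swe-quant")
    quant = {
        name: quant_table(cases, roi_area=cfg.roi_area_mm2,
                          jitter_sd=cfg.quant_jitter_sd, seed=rng_seed + 17)
        for name, cases in cohorts.items()
    }

    # training-derived operating points
    stage("thresholds")
    y_bin_train = _binary(train_cases)
    thresholds: dict[str, float] = {}
    for modality in ("bmode", "swe"):
        thresholds[f"{modality}_rs"] = signatures[modality].threshold_
    for p in QUANT_PARAMS:
        thresholds[p] = youden_threshold(
            quant["training"][p].to_numpy(), y_bin_train
        ).threshold

    # combined quantitative model: unpenalized logistic on the four parameters
    combined = LogisticRegression(C=np.inf, max_iter=2000)
    combined.fit(quant["training"][list(QUANT_PARAMS)], y_bin_train)
    combined_scores = {
        name: combined.decision_function(quant[name][list(QUANT_PARAMS)])
        for name in cohorts
    }
    thresholds["combined_swe"] = youden_threshold(
        combined_scores["training"], y_bin_train
    ).threshold

    has_birads = cfg.include_birads and all(
        c.birads_like is not None for cs in cohorts.values() for c in cs
    )
    if not has_birads:
        log.append({"stage": "thresholds",
                    "warning": "no ordinal category supplied; ordinal row omitted"})
    if has_birads:
        rank = {lvl: i for i, lvl in enumerate(BIRADS_LEVELS)}
        birads_scores = {
            name: np.array([rank[c.birads_like] for c in cases], dtype=float)
            for name, cases in cohorts.items()
        }
        thresholds["birads"] = youden_threshold(
            birads_scores["training"], y_bin_train
        ).threshold

    stage("evaluate")
    reports: dict[str, list[dx.DiagnosticReport]] = {}
    tables: dict[str, pd.DataFrame] = {}
    for name, cases in cohorts.items():
        y = _binary(cases)
        rows = [
            dx.evaluate_classifier("B-US-RS", scores[("bmode", name)], y,
                                   thresholds["bmode_rs"],
                                   positive_higher=signatures["bmode"].orientation_
                                   == "higher_is_malignant"),
            dx.evaluate_classifier("SWE-RS", scores[("swe", name)], y,
                                   thresholds["swe_rs"],
                                   positive_higher=signatures["swe"].orientation_
                                   == "higher_is_malignant"),
        ]
        for p in QUANT_PARAMS:
            rows.append(dx.evaluate_classifier(p, quant[name][p].to_numpy(), y,
                                               thresholds[p]))
        rows.append(dx.evaluate_classifier("combined_swe", combined_scores[name], y,
                                           thresholds["combined_swe"]))
        if has_birads:
            rows.append(dx.evaluate_classifier("birads_like", birads_scores[name], y,
                                               thresholds["birads"]))
        reports[name] = rows
        tables[name] = dx.report_table(rows)

    stage("report")
    if outdir:
        rdir = outdir / "reports"
        rdir.mkdir(exist_ok=True)
        for name, table in tables.items():
            table.to_csv(rdir / f"{name}_performance.csv", index=False)
            table.to_json(rdir / f"{name}_performance.json", orient="records", indent=2)
        for name, q in quant.items():
            (outdir / "quant").mkdir(exist_ok=True)
            q.to_csv(outdir / "quant" / f"{name}.csv", index=False)
        scatter = []
        for (modality, name), s in scores.items():
            for case, value in zip(cohorts[name], s):
                scatter.append({"modality": modality, "cohort": name,
                                "case_id": case.case_id, "label": case.label,
                                "rad_score": float(value)})
        pd.DataFrame(scatter).to_csv(rdir / "rad_scores.csv", index=False)
        (outdir / "run_log.json").write_text(json.dumps(
            {"config_hash": _config_hash(cfg), "seed": cfg.seed, "stages": log},
            indent=2, default=str))

    return RunResult(
        config=cfg, cohorts=cohorts, extractors=extractors, icc_filters=icc_filters,
        signatures=signatures, rad_scores=scores, quant=quant, reports=reports,
        tables=tables, outdir=outdir, log=log,
    )


def report_tables(run_dir: str | Path, make_figures: bool = True) -> dict[str, pd.DataFrame]:
    """Re-render tables and summary figures from a completed run directory."""
    run_dir = Path(run_dir)
    rdir = run_dir / "reports"
    if not rdir.exists():
        raise IncompleteRunError(f"no reports under {run_dir}; run the pipeline first")
    tables = {}
    for path in sorted(rdir.glob("*_performance.csv")):
        tables[path.stem.replace("_performance", "")] = pd.read_csv(path)
    if not tables:
        raise IncompleteRunError("run directory holds no performance tables")
    scatter_path = rdir / "rad_scores.csv"
    if make_figures and scatter_path.exists():
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = pd.read_csv(scatter_path)
        fig, axes = plt.subplots(1, df["cohort"].nunique(), figsize=(11, 3.5),
                                 sharey=True, squeeze=False)
        for ax, (name, grp) in zip(axes.ravel(), df.groupby("cohort")):
            for j, (label, sub) in enumerate(grp.groupby("label")):
                jitter = np.linspace(-0.15, 0.15, len(sub))
                ax.plot(np.full(len(sub), j) + jitter, sub["rad_score"], "o", ms=3,
                        label=label)
            ax.set_title(name)
            ax.set_xticks([0, 1])
            ax.set_xticklabels(sorted(grp["label"].unique()))
        axes.ravel()[0].set_ylabel("rad-score")
        fig.tight_layout()
        fig.savefig(rdir / "rad_score_scatter.png", dpi=120)
        plt.close(fig)
    return tables
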