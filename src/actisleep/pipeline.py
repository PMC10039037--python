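"""End-to-end evaluation pipeline: cohort in, Table-style reports out.

Given a cohort of raw recordings with PSG hypnograms (from disk or the
synthetic generator), runs every configured classifier (plus Webster-rescored
variants of the legacy count algorithms), computes per-subject confusion
statistics and sleep endpoints, aggregates cohort "mean (SD)" metric grids,
Bland-Altman agreement per endpoint, and applies the sensitivity/specificity
selection rule. Outputs are deterministic for a fixed config + seed: the
JSON reports are canonical (sorted keys) and byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .classifiers import (
    LinearWindowModel,
    SadehParams,
    SazonovParams,
    VanHeesParams,
    classify_linear_window,
    classify_sadeh,
    classify_sazonov,
    classify_vanhees_from_raw,
    count_threshold_model,
    reference_classifier,
)
from .core import SleepWakeSeries, align_pair, binarize_hypnogram
from .counts import compute_counts, combine_axes
from .errors import ParameterError
from .evaluation import (
    ENDPOINTS,
    METRICS,
    bland_altman,
    cohort_aggregate,
    confusion,
    endpoints,
    select_algorithms,
)
from .io import downsample_mean, read_accel_csv, read_hypnogram_csv, write_epochs_csv
from .presets import load_presets
from .rescoring import RescoreRuleSet, webster_rescore
from .rf import apply_rf, extract_rf_features
from .synthetic import SynthConfig, gen_cohort

log = logging.getLogger("actisleep")

KNOWN_ALGORITHMS = (
    "all_sleep", "all_wake", "vanhees", "random_forest",
    "cole_kripke", "oakley", "sadeh", "sazonov", "count_threshold",
)
LEGACY_COUNT_ALGORITHMS = ("cole_kripke", "oakley", "sadeh", "sazonov")


@dataclass
class RunConfig:
    mode: str = "synthetic"                       # synthetic | directory
    input_dir: str | None = None
    output_dir: str = "actisleep_out"
    seed: int = 0
    algorithms: list[str] = field(
        default_factory=lambda: [
            "all_sleep", "all_wake", "vanhees",
            "cole_kripke", "oakley", "sadeh", "sazonov",
        ]
    )
    rescore: list[str] = field(default_factory=lambda: list(LEGACY_COUNT_ALGORITHMS))
    axis_combination: str = "vector_magnitude"
    count_threshold: float = 0.0
    sens_min: float = 75.0
    spec_min: float = 45.0
    onset_consecutive_epochs: int = 1
    log_level: str = "INFO"
    synthetic: dict = field(default_factory=dict)  # SynthConfig overrides
    preset_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("synthetic", "directory"):
            raise ParameterError(f"unknown input mode {self.mode!r}")
        if self.mode == "directory" and not self.input_dir:
            raise ParameterError("directory mode requires input_dir")
        unknown = [a for a in self.algorithms if a not in KNOWN_ALGORITHMS]
        if unknown:
            raise ParameterError(f"unknown algorithms: {unknown}")
        bad_rescore = [a for a in self.rescore if a not in self.algorithms]
        if bad_rescore:
            raise ParameterError(f"rescore list not in algorithms: {bad_rescore}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ParameterError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)

    def canonical_json(self) -> str:
        """Analysis-defining fields only: where outputs land and how loudly
        we log do not change the numbers, so they stay out of the hash."""
        d = dataclasses.asdict(self)
        d.pop("output_dir")
        d.pop("log_level")
        return json.dumps(d, sort_keys=True)


def _load_directory_cohort(cfg: RunConfig):
    """Subjects are file pairs <sid>_accel.csv / <sid>_hypnogram.csv."""
    root = Path(cfg.input_dir)
    for hyp_path in sorted(root.glob("*_hypnogram.csv")):
        sid = hyp_path.name[: -len("_hypnogram.csv")]
        accel_path = root / f"{sid}_accel.csv"
        if not accel_path.exists():
            log.warning("subject %s: missing acceleration file, skipped", sid)
            continue
        yield sid, accel_path, hyp_path


def _predict_counts_based(
    name: str, combined: np.ndarray, grid, cfg: RunConfig, presets: dict
) -> SleepWakeSeries:
    if name == "cole_kripke" or name == "oakley":
        return classify_linear_window(
            combined, LinearWindowModel.from_preset(name, presets), grid
        )
    if name == "sadeh":
        return classify_sadeh(combined, SadehParams.from_preset(presets), grid)
    if name == "sazonov":
        return classify_sazonov(combined, SazonovParams.from_preset(presets), grid)
    if name == "count_threshold":
        return classify_linear_window(
            combined, count_threshold_model(cfg.count_threshold), grid
        )
    raise ParameterError(name)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full evaluation and write reports to ``cfg.output_dir``.

    Returns the report dictionary (also written as ``report.json``).
    """
    logging.basicConfig(level=cfg.log_level)
    t_start = time.perf_counter()
    out = Path(cfg.output_dir)
    (out / "subjects").mkdir(parents=True, exist_ok=True)
    presets = load_presets(overrides=cfg.preset_overrides)

    # ------------------------------------------------------------------ load
    subjects = []  # (sid, RawRecording, psg SleepWakeSeries)
    n_warnings = 0
    if cfg.mode == "synthetic":
        sc = SynthConfig(**{"seed": cfg.seed, **cfg.synthetic})
        for rec, truth in gen_cohort(sc):
            subjects.append((truth.subject_id, rec, binarize_hypnogram(truth.hypnogram)))
    else:
        for sid, accel_path, hyp_path in _load_directory_cohort(cfg):
            try:
                rec = read_accel_csv(accel_path, subject_id=sid)
                hyp = read_hypnogram_csv(hyp_path)
            except Exception as exc:  # noqa: BLE001 - subject-level isolation
                log.warning("subject %s skipped: %s", sid, exc)
                n_warnings += 1
                continue
            subjects.append((sid, rec, binarize_hypnogram(hyp)))
    if not subjects:
        raise ParameterError("empty cohort: no usable subjects")
    log.info("cohort loaded: %d subjects (%.1fs)", len(subjects), time.perf_counter() - t_start)

    # ------------------------------------------------------- per-subject run
    count_based = [a for a in cfg.algorithms
                   if a in LEGACY_COUNT_ALGORITHMS or a == "count_threshold"]
    rf_requested = "random_forest" in cfg.algorithms
    feature_tables, truths_for_rf = [], []
    predictions: dict[str, list[SleepWakeSeries]] = {}
    psg_list = []
    for sid, rec, psg in subjects:
        t0 = time.perf_counter()
        preds = {}
        if any(a in ("all_sleep", "all_wake") for a in cfg.algorithms):
            for mode in ("all_sleep", "all_wake"):
                if mode in cfg.algorithms:
                    preds[mode] = reference_classifier(psg.grid, mode)
        if count_based:
            counts = compute_counts(downsample_mean(rec))
            combined = combine_axes(counts, cfg.axis_combination)
            for name in count_based:
                preds[name] = _predict_counts_based(
                    name, combined, counts.grid, cfg, presets
                )
        if "vanhees" in cfg.algorithms:
            preds["vanhees"] = classify_vanhees_from_raw(
                rec, psg.grid, VanHeesParams.from_preset(presets)
            )
        for name in cfg.rescore:
            preds[f"{name}_rsc"] = webster_rescore(preds[name], RescoreRuleSet())
        if rf_requested:
            feature_tables.append(extract_rf_features(rec, psg.grid))
            truths_for_rf.append(psg)
        psg_list.append(psg)
        for name, p in preds.items():
            predictions.setdefault(name, []).append(p)
            write_epochs_csv(p, out / "subjects" / f"{sid}_{name}.csv")
        log.info("subject %s scored (%.1fs)", sid, time.perf_counter() - t0)

    if rf_requested:
        # leave-one-subject-out: each night is predicted by a forest trained
        # on all the other nights
        if len(subjects) < 2:
            raise ParameterError("random_forest requires at least 2 subjects")
        for i, ft in enumerate(feature_tables):
            train_X = np.vstack([feature_tables[j].values
                                 for j in range(len(subjects)) if j != i])
            train_y = np.concatenate([truths_for_rf[j].labels
                                      for j in range(len(subjects)) if j != i])
            import sklearn.ensemble

            model = sklearn.ensemble.RandomForestClassifier(
                n_estimators=100, random_state=cfg.seed, n_jobs=1
            )
            model.fit(train_X, train_y)
            p = apply_rf(ft, model)
            predictions.setdefault("random_forest", []).append(p)
            sid = subjects[i][0]
            write_epochs_csv(p, out / "subjects" / f"{sid}_random_forest.csv")

    # ------------------------------------------------------------ evaluation
    summaries, table2 = [], {}
    for name, preds in sorted(predictions.items()):
        stats, ep_pred, ep_true = [], {e: [] for e in ENDPOINTS}, {e: [] for e in ENDPOINTS}
        for p, psg in zip(preds, psg_list):
            pa, ta = align_pair(p, psg)
            stats.append(confusion(pa, ta))
            pe = endpoints(pa, onset_consecutive_epochs=cfg.onset_consecutive_epochs)
            te = endpoints(ta, onset_consecutive_epochs=cfg.onset_consecutive_epochs)
            for e in ENDPOINTS:
                pv, tv = getattr(pe, e), getattr(te, e)
                if pv is not None and tv is not None:
                    ep_pred[e].append(pv)
                    ep_true[e].append(tv)
        summaries.append(cohort_aggregate(stats, algorithm=name))
        table2[name] = {}
        for e in ENDPOINTS:
            if len(ep_pred[e]) >= 1:
                ba = bland_altman(ep_pred[e], ep_true[e])
                table2[name][e] = {
                    "me": ba.me, "rmse": ba.rmse, "correlation": ba.pearson_r,
                    "ci95_upper": ba.loa_upper, "ci95_lower": ba.loa_lower,
                    "ci_width": ba.ci_width, "n": ba.n,
                }
            else:
                table2[name][e] = None
    select_algorithms(summaries, cfg.sens_min, cfg.spec_min)

    # --------------------------------------------------------------- reports
    table1 = {
        s.algorithm: {
            "n_subjects": s.n_subjects,
            "selected": s.selected,
            **{m: {"mean": s.mean[m], "sd": s.sd[m], "n_undefined": s.n_undefined[m]}
               for m in METRICS},
        }
        for s in summaries
    }
    manifest = {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(cfg.canonical_json().encode()).hexdigest(),
        "seed": cfg.seed,
        "preset_version": presets["version"],
        "axis_combination": cfg.axis_combination,
        "n_subjects": len(subjects),
        "algorithms": sorted(predictions),
    }
    report = {"manifest": manifest, "table1": table1, "table2": table2}
    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2))
    _write_table1_csv(summaries, out / "table1.csv")
    _write_table2_csv(table2, out / "table2.csv")
    log.info("pipeline finished (%.1fs), %d warnings", time.perf_counter() - t_start, n_warnings)
    return report


def _write_table1_csv(summaries, path) -> None:
    lines = ["algorithm,selected," + ",".join(METRICS)]
    for s in summaries:
        cells = [s.algorithm, str(s.selected).lower()]
        cells += [f'"{s.formatted(m)}"' for m in METRICS]
        lines.append(",".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def _write_table2_csv(table2, path) -> None:
    lines = ["algorithm,endpoint,me,rmse,correlation,ci95_upper,ci95_lower,ci_width,n"]
    for name in sorted(table2):
        for e in ENDPOINTS:
            row = table2[name][e]
            if row is None:
                continue
            fmt = lambda v: "" if v is None else f"{v:.4f}"
            lines.append(
                f"{name},{e},{fmt(row['me'])},{fmt(row['rmse'])},{fmt(row['correlation'])},"
                f"{fmt(row['ci95_upper'])},{fmt(row['ci95_lower'])},{fmt(row['ci_width'])},{row['n']}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
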