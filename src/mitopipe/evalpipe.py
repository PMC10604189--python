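"""Evaluation protocol, metric suite, and end-to-end pipeline orchestration.

Metrics follow the conventions of the two-class mitosis benchmark tables:
the positive class is mitotic; per-class rows treat each class in turn as
positive; per-class "accuracy" is that class's recall; the Average row is
the unweighted macro mean over the two classes (balanced accuracy for the
accuracy column); F-score is the harmonic and G-measure the geometric mean
of precision and recall; MCC is the standard binary formula. All values are
reported on the percentage scale, rounded half-up to 2 decimals only at
report time.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import cboa, dbn, features as feat, segmentation as seg, synthdata

METRIC_COLUMNS = ("Accuy", "Precn", "Recal", "FScore", "MCC", "GMeasure")
_KEYS = ("accuracy", "precision", "recall", "f_score", "mcc", "g_measure")


# ---------------------------------------------------------------------------
# confusion matrix and metrics


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self):
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class EvalMetrics:
    """Six metrics per class plus macro averages, percent scale, unrounded."""

    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    degenerate: bool = False        # any undefined denominator was zeroed

    def rounded(self) -> "EvalMetrics":
        r = lambda v: float(Decimal(repr(v)).quantize(Decimal("0.01"),
                                                      rounding=ROUND_HALF_UP))
        return EvalMetrics(
            per_class={c: {k: r(v) for k, v in d.items()}
                       for c, d in self.per_class.items()},
            macro={k: r(v) for k, v in self.macro.items()},
            degenerate=self.degenerate)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls, d in self.per_class.items():
            rows.append([cls.capitalize()] + [d[k] for k in _KEYS])
        rows.append(["Average"] + [self.macro[k] for k in _KEYS])
        return pd.DataFrame(rows, columns=("Class",) + METRIC_COLUMNS)


def confusion(y_true, y_pred, positive: str = synthdata.MITOTIC
              ) -> ConfusionMatrix:
    """Binary counts with the mitotic class as positive."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences must have equal length")
    allowed = set(synthdata.CLASSES)
    if not set(y_true) <= allowed or not set(y_pred) <= allowed:
        raise ValueError(f"labels must be drawn from {sorted(allowed)}")
    tp = sum(t == positive and p == positive for t, p in zip(y_true, y_pred))
    fn = sum(t == positive and p != positive for t, p in zip(y_true, y_pred))
    fp = sum(t != positive and p == positive for t, p in zip(y_true, y_pred))
    tn = sum(t != positive and p != positive for t, p in zip(y_true, y_pred))
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def _class_metrics(tp, fn, fp, tn):
    degenerate = False

    def ratio(num, den):
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    prec = ratio(tp, tp + fp)
    rec = ratio(tp, tp + fn)
    f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    g = float(np.sqrt(prec * rec))
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den == 0:
        degenerate = True
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / float(np.sqrt(den))
    vals = {"accuracy": 100 * rec, "precision": 100 * prec,
            "recall": 100 * rec, "f_score": 100 * f, "mcc": 100 * mcc,
            "g_measure": 100 * g}
    return vals, degenerate


def metrics_from_cm(cm: ConfusionMatrix) -> EvalMetrics:
    """Six metrics per class + unweighted macro average."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    pos, d1 = _class_metrics(cm.tp, cm.fn, cm.fp, cm.tn)
    neg, d2 = _class_metrics(cm.tn, cm.fp, cm.fn, cm.tp)
    macro = {k: (pos[k] + neg[k]) / 2 for k in _KEYS}
    return EvalMetrics(per_class={synthdata.MITOTIC: pos,
                                  synthdata.NONMITOTIC: neg},
                       macro=macro, degenerate=d1 or d2)


def reconstruct_cm_from_rates(prec_pos: float, rec_pos: float,
                              prec_neg: float, rec_neg: float,
                              n_total: int) -> ConfusionMatrix:
    """Invert printed per-class precision/recall (2-decimal percent) rates.

    Exhaustively searches all integer confusion matrices at ``n_total`` and
    returns the unique one whose four rates round to the given values;
    raises if none or several exist.
    """
    tol = 0.005 + 1e-9
    sols = []
    for tp in range(n_total + 1):
        for fn in range(n_total + 1 - tp):
            for fp in range(n_total + 1 - tp - fn):
                tn = n_total - tp - fn - fp

                def ok(num, den, rate):
                    return den > 0 and abs(round(100 * num / den, 2) - rate) < tol

                if (ok(tp, tp + fp, prec_pos) and ok(tp, tp + fn, rec_pos)
                        and ok(tn, tn + fn, prec_neg)
                        and ok(tn, tn + fp, rec_neg)):
                    sols.append(ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn))
    if len(sols) != 1:
        raise ValueError(
            f"no unique confusion matrix at n={n_total}: {len(sols)} solutions")
    return sols[0]


# ---------------------------------------------------------------------------
# splits


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.60
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly in (0, 1)")


def split_dataset(items, labels, spec: SplitSpec):
    """Seeded (stratified) split; returns (train_idx, test_idx)."""
    n = len(items)
    if n == 0:
        raise ValueError("dataset must be non-empty")
    n_train = int(round(spec.train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError("split would leave one side empty")
    idx = np.arange(n)
    tr, te = train_test_split(
        idx, train_size=n_train, random_state=spec.seed, shuffle=True,
        stratify=np.asarray(labels) if spec.stratified else None)
    return np.sort(tr), np.sort(te)


# ---------------------------------------------------------------------------
# pipeline


@dataclass(frozen=True)
class PipelineConfig:
    master_seed: int = 0
    n_mitotic: int = 75
    n_nonmitotic: int = 75
    tile_spec: synthdata.TileSpec = synthdata.TileSpec(width=64, height=64)
    splits: tuple[float, ...] = (0.60,)
    patch_size: int = 32
    n_seg_train: int = 50
    n_seg_test: int = 10
    seg_nuclei: tuple[int, int] = (2, 4)     # mitotic/nonmitotic per seg tile
    unet: seg.UNetConfig = seg.UNetConfig(depth=2, base_channels=8)
    unet_train: seg.TrainOptions = seg.TrainOptions(epochs=8)
    backbone: feat.BackboneConfig = feat.BackboneConfig()
    backbone_epochs: int = 10
    cboa_pop: int = 6
    cboa_iters: int = 5
    cv_folds: int = 3


@dataclass
class SplitReport:
    train_fraction: float
    n_train: int
    n_test: int
    train_cm: ConfusionMatrix
    test_cm: ConfusionMatrix
    train_metrics: EvalMetrics
    test_metrics: EvalMetrics
    tuned_cv_error: float
    best_hyperparams: dict


@dataclass
class PipelineReport:
    dice: float
    splits: list[SplitReport]
    cboa_traces: dict[float, pd.DataFrame]

    def to_json(self) -> str:
        def cm_d(cm):
            return {"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn}
        payload = {
            "dice": self.dice,
            "splits": [{
                "train_fraction": s.train_fraction,
                "n_train": s.n_train, "n_test": s.n_test,
                "train_cm": cm_d(s.train_cm), "test_cm": cm_d(s.test_cm),
                "train_metrics": s.train_metrics.rounded().macro,
                "test_metrics": s.test_metrics.rounded().macro,
                "tuned_cv_error": s.tuned_cv_error,
                "best_hyperparams": s.best_hyperparams,
            } for s in self.splits],
        }
        return json.dumps(payload, sort_keys=True)


def _stage_seeds(master_seed: int, n: int = 8):
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return [int(s % (2 ** 31)) for s in state]


def _candidate_patch(tile, net, patch_size):
    """Largest segmented candidate, falling back to the tile centre crop."""
    result = net.segment(tile.image)
    cands = seg.extract_candidates(result, tile.image, patch_size=patch_size)
    if cands:
        return max(cands, key=lambda c: c.area).patch
    h, w = tile.image.shape[:2]
    r0 = (h - patch_size) // 2
    c0 = (w - patch_size) // 2
    return tile.image[r0:r0 + patch_size, c0:c0 + patch_size]


def run_pipeline(config: PipelineConfig = PipelineConfig(),
                 out_dir: str | None = None) -> PipelineReport:
    """Generate -> segment -> extract -> features -> tune DBN -> evaluate.

    One master seed fans out to per-stage seeds, so reruns with the same
    configuration produce bit-identical reports.
    """
    s_gen, s_seg, s_unet, s_bb, s_split, s_tune, s_final, _ = _stage_seeds(
        config.master_seed)

    # 1. data ------------------------------------------------------------
    tiles, manifest = synthdata.generate_dataset(
        config.n_mitotic, config.n_nonmitotic, config.tile_spec, seed=s_gen)
    labels = np.array([t.label for t in tiles])
    from dataclasses import replace as _replace
    seg_spec = _replace(config.tile_spec, n_mitotic=config.seg_nuclei[0],
                        n_nonmitotic=config.seg_nuclei[1])
    seg_tiles = synthdata.generate_segmentation_tiles(
        config.n_seg_train + config.n_seg_test, seg_spec, seed=s_seg)

    # 2. segmentation ----------------------------------------------------
    opts = seg.TrainOptions(**{**config.unet_train.__dict__, "seed": s_unet})
    net, _ = seg.train_unet(seg_tiles[:config.n_seg_train], config.unet, opts)
    dice_vals = [seg.dice_score(net.segment(t.image).mask, t.mask)
                 for t in seg_tiles[config.n_seg_train:]]
    dice = float(np.mean(dice_vals))

    # 3. candidate patches ----------------------------------------------
    patches = np.stack([_candidate_patch(t, net, config.patch_size)
                        for t in tiles]).astype(float)
    y = (labels == synthdata.MITOTIC).astype(int)

    split_reports = []
    traces = {}
    for frac in config.splits:
        tr, te = split_dataset(tiles, labels, SplitSpec(
            train_fraction=frac, seed=s_split))

        # 4. features (backbone trained on the training split only) ------
        model = feat.build_backbone(config.backbone, seed=s_bb)
        feat.train_backbone(model, patches[tr], y[tr],
                            epochs=config.backbone_epochs, seed=s_bb)
        vectors, _ = feat.extract_features(patches, model)
        mat = np.stack([v.values for v in vectors])
        x_tr, lo, span = dbn.min_max_scale(mat[tr])
        x_te, _, _ = dbn.min_max_scale(mat[te], lo, span)

        # 5. CBOA hyperparameter tuning ----------------------------------
        cfg = cboa.CBOAConfig(pop_size=config.cboa_pop,
                              t_max=config.cboa_iters,
                              bounds=cboa.DEFAULT_HYPERPARAM_BOUNDS,
                              rng_seed=s_tune)
        best_cfg, best_fit, trace = cboa.tune_dbn(
            x_tr, y[tr], config=cfg, k_folds=config.cv_folds)
        traces[frac] = trace

        # 6. final train + evaluate --------------------------------------
        final_cfg = dbn.DBNConfig(**{**best_cfg.__dict__, "seed": s_final})
        clf = dbn.fit_dbn(x_tr, y[tr], final_cfg)
        to_names = np.where(np.asarray(clf.predict(x_tr)) == 1,
                            synthdata.MITOTIC, synthdata.NONMITOTIC)
        cm_tr = confusion(labels[tr], to_names)
        to_names = np.where(np.asarray(clf.predict(x_te)) == 1,
                            synthdata.MITOTIC, synthdata.NONMITOTIC)
        cm_te = confusion(labels[te], to_names)
        split_reports.append(SplitReport(
            train_fraction=frac, n_train=len(tr), n_test=len(te),
            train_cm=cm_tr, test_cm=cm_te,
            train_metrics=metrics_from_cm(cm_tr),
            test_metrics=metrics_from_cm(cm_te),
            tuned_cv_error=best_fit.error_rate_percent,
            best_hyperparams={
                "layer_sizes": list(best_cfg.layer_sizes),
                "rbm_lr": best_cfg.rbm_train.epsilon,
                "pretrain_epochs": best_cfg.rbm_train.epochs,
                "finetune_lr": best_cfg.finetune_lr,
            }))

    report = PipelineReport(dice=dice, splits=split_reports,
                            cboa_traces=traces)
    if out_dir:
        write_report(report, manifest, out_dir)
    return report


def write_report(report: PipelineReport, manifest: pd.DataFrame,
                 out_dir: str) -> None:
    """CSV + Markdown tables, confusion matrices, tuning traces, manifest."""
    os.makedirs(out_dir, exist_ok=True)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    md = [f"# Pipeline report\n", f"Segmentation Dice: {report.dice:.4f}\n"]
    for s in report.splits:
        pct = int(round(100 * s.train_fraction))
        for name, metrics, cm in (("TR", s.train_metrics, s.train_cm),
                                  ("TS", s.test_metrics, s.test_cm)):
            frame = metrics.rounded().to_frame()
            tag = f"{name.lower()}_{pct}"
            frame.to_csv(os.path.join(out_dir, f"metrics_{tag}.csv"),
                         index=False)
            md.append(f"\n## {name} set ({pct if name == 'TR' else 100 - pct}%)\n")
            header = "| " + " | ".join(frame.columns) + " |"
            sep = "|" + "---|" * len(frame.columns)
            body = ["| " + " | ".join(str(v) for v in row) + " |"
                    for row in frame.itertuples(index=False)]
            md.append("\n".join([header, sep] + body))
            md.append(f"\nConfusion: tp={cm.tp} fn={cm.fn} fp={cm.fp} tn={cm.tn}\n")
        report.cboa_traces[s.train_fraction].to_csv(
            os.path.join(out_dir, f"cboa_trace_{pct}.csv"), index=False)
    md.append("\n")
    with open(os.path.join(out_dir, "report.md"), "w") as fh:
        fh.write("\n".join(md))
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        fh.write(report.to_json())
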