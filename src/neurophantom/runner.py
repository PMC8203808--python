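"""Experiment orchestration on phantom cohorts.

Four experiments, each for {SVM, CNN} x {modulated_gm, minimal_t1w}:

* E1 internal cross-validation: AD vs CN with repeated stratified 90/10
  splits, identical splits for every cell, corrected resampled t-test CIs;
* E2 retrain on all internal AD+CN, test on internal MCIc vs MCInc;
* E3 same model applied to the external AD vs SCD cohort;
* E4 same model applied to the external MCIc vs MCInc cohort;

plus map rendering (SVM p-map clusters, CNN averaged guided-backprop
saliency) with overlap against the generator's ground-truth ROI.

The SVM path uses voxel features at full phantom resolution; the CNN path
trains on (optionally downsampled) volumes, a desk-scale choice that keeps
the numpy conv engine tractable. The positive class (AD / MCIc) is labeled
1 throughout; the SVM consumes +/-1 labels internally.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.model_selection import train_test_split

from . import eval_stats, preprocess, svm_pmap
from .eval_stats import EvalResult, PairedPredictions
from .images import BrainMask, VolumeImage, load_mask, load_nifti, save_nifti
from .nn import (AllConvNet, AugmentConfig, NetworkSpec, TrainConfig,
                 average_saliency, build_network, guided_backprop_saliency,
                 mixup_augment, train_cnn)
from .phantoms import Cohort, ParticipantRecord, PhantomConfig, cohort_hash, synth_cohort

log = logging.getLogger("neurophantom")

TASKS = {
    "internal_cv": ("internal", ("AD", "CN")),
    "internal_mci": ("internal", ("MCIc", "MCInc")),
    "external_ad_scd": ("external", ("AD", "SCD")),
    "external_mci": ("external", ("MCIc", "MCInc")),
}
POSITIVE = {"AD", "MCIc"}


@dataclass
class ExperimentConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    classifiers: tuple = ("svm", "cnn")
    representations: tuple = ("modulated_gm", "minimal_t1w")
    k_splits: int = 20
    cnn_k_splits: int | None = None  # CNN may consume only the first m splits
    test_fraction: float = 0.1
    n_boot: int = 500
    family_alpha: float = 0.05
    n_comparisons: int = 4
    c_grid: tuple = svm_pmap.DEFAULT_C_GRID
    cnn_filters: tuple = (8, 16, 16, 8)  # reduced-depth desk-scale network
    cnn_shape: tuple = (16, 16, 16)
    cnn_train: TrainConfig = field(default_factory=lambda: TrainConfig(
        max_epochs=25, early_stop_patience=10, batch_size=8))
    augment: AugmentConfig = field(default_factory=lambda: AugmentConfig(per_class_target=150))
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.classifiers or not self.representations:
            raise ValueError("classifier and representation sets must be nonempty")


def cohort_from_dir(out_dir: str | Path) -> Cohort:
    """Reload a previously generated cohort from its output directory."""
    out_dir = Path(out_dir)
    df = pd.read_csv(out_dir / "participants.tsv", sep="\t")
    records = [
        ParticipantRecord(str(r.id), r.group, r.cohort, float(r.icv), r.site, int(r.seed))
        for r in df.itertuples()
    ]
    image_paths: dict[str, dict[str, Path]] = {}
    for rep in ("modulated_gm", "minimal_t1w"):
        paths = {r.id: out_dir / f"{r.id}_{rep}.nii.gz" for r in records}
        if all(p.exists() for p in paths.values()):
            image_paths[rep] = paths
    cfg = PhantomConfig.from_yaml(out_dir / "phantom_config.yaml")
    return Cohort(
        records=records,
        image_paths=image_paths,
        out_dir=out_dir,
        template_path=out_dir / "template.nii.gz",
        mask_path=out_dir / "brain_mask.nii.gz",
        roi_path=out_dir / "roi_mask.nii.gz",
        ground_truth={"atrophy_effect": dict(cfg.atrophy_effect)},
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    return float(2.0 * (a & b).sum() / denom) if denom else 0.0


class ExperimentRunner:
    """Stateful driver binding a config to a generated cohort."""

    def __init__(self, cfg: ExperimentConfig):
        self.cfg = cfg
        self.out_dir = Path(cfg.out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.cohort: Cohort | None = None
        self.mask: BrainMask | None = None
        self._img_cache: dict = {}
        self._vol_cache: dict = {}

    # -- data ---------------------------------------------------------------
    def ensure_cohort(self) -> Cohort:
        ph_dir = self.out_dir / "phantoms"
        if (ph_dir / "participants.tsv").exists():
            self.cohort = cohort_from_dir(ph_dir)
        else:
            self.cohort = synth_cohort(self.cfg.phantom, ph_dir,
                                       representations=self.cfg.representations)
        self.mask = load_mask(self.cohort.mask_path)
        log.info("cohort ready: %d records (hash %s)",
                 len(self.cohort.records), cohort_hash(self.cohort))
        return self.cohort

    def _load_preprocessed(self, rep: str, pid: str) -> VolumeImage:
        """Per-image normalization: ICV division for GM maps, within-mask
        z-normalization for minimal-T1w images."""
        key = (rep, pid)
        if key not in self._img_cache:
            img = load_nifti(self.cohort.image_paths[rep][pid])
            if rep == "modulated_gm":
                img = preprocess.icv_normalize(img, self.cohort.record(pid).icv)
            else:
                img = preprocess.znormalize_in_mask(img, self.mask)
            self._img_cache[key] = img
        return self._img_cache[key]

    def features(self, rep: str, ids: list[str]) -> preprocess.FeatureMatrix:
        imgs = {pid: self._load_preprocessed(rep, pid) for pid in ids}
        return preprocess.stack_features(imgs, self.mask, ids)

    def volumes(self, rep: str, ids: list[str]) -> np.ndarray:
        """(N, 1, D, H, W) float32 stack at the CNN training resolution."""
        out = []
        for pid in ids:
            key = (rep, pid, self.cfg.cnn_shape)
            if key not in self._vol_cache:
                data = self._load_preprocessed(rep, pid).data
                if tuple(data.shape) != tuple(self.cfg.cnn_shape):
                    factors = [t / s for t, s in zip(self.cfg.cnn_shape, data.shape)]
                    data = ndimage.zoom(data, factors, order=1)
                self._vol_cache[key] = data.astype(np.float32)
            out.append(self._vol_cache[key])
        return np.stack(out)[:, None]

    def labels(self, ids: list[str]) -> np.ndarray:
        return np.array([1 if self.cohort.record(i).group in POSITIVE else 0
                         for i in ids])

    # -- classifiers --------------------------------------------------------
    def _fit_svm(self, rep: str, train_ids: list[str], seed: int):
        X = self.features(rep, train_ids)
        scaler = preprocess.fit_feature_scaler(X)
        Xs = preprocess.apply_scaler(scaler, X)
        y = np.where(self.labels(train_ids) == 1, 1, -1)
        model = svm_pmap.train_linear_svm(Xs, y, c_grid=self.cfg.c_grid, seed=seed)
        return model, scaler

    def _eval_svm(self, model, scaler, rep: str, test_ids: list[str]):
        Xt = preprocess.apply_scaler(scaler, self.features(rep, test_ids))
        scores = model.decision_function(Xt.values)
        preds = (scores >= 0).astype(int)
        return scores, preds

    def _fit_cnn(self, rep: str, train_ids: list[str], seed: int):
        cfg = self.cfg
        y = self.labels(train_ids)
        tr_ids, val_ids = train_test_split(
            train_ids, test_size=cfg.cnn_train.val_fraction,
            stratify=y, random_state=seed)
        xtr = self.volumes(rep, tr_ids)
        ytr = self.labels(tr_ids)
        aug = dataclasses.replace(cfg.augment, seed=seed)
        xaug, yaug = mixup_augment(xtr, ytr, aug)
        mu, sd = float(xaug.mean()), float(xaug.std())
        sd = sd if sd > 0 else 1.0
        norm = lambda a: ((a - mu) / sd).astype(np.float32)  # noqa: E731
        xval = self.volumes(rep, val_ids)
        spec = NetworkSpec(filters=cfg.cnn_filters, strict=False)
        model = build_network(spec, seed=seed)
        tcfg = dataclasses.replace(cfg.cnn_train, seed=seed)
        history = train_cnn(model, norm(xaug), yaug, norm(xval),
                            self.labels(val_ids), tcfg)
        return model, (mu, sd), history

    def _eval_cnn(self, model: AllConvNet, norm_stats, rep: str, test_ids: list[str]):
        mu, sd = norm_stats
        xt = (self.volumes(rep, test_ids) - mu) / sd
        scores = model.predict_proba(xt.astype(np.float32))[:, 1]
        preds = (scores >= 0.5).astype(int)
        return scores, preds

    # -- E1 -----------------------------------------------------------------
    def run_internal_cv(self) -> dict:
        """20x stratified 90/10 AD-CN cross-validation per cell."""
        assert self.cohort is not None, "call ensure_cohort() first"
        ids = self.cohort.ids("internal", ("AD", "CN"))
        labels_by_id = {i: int(self.labels([i])[0]) for i in ids}
        scheme = eval_stats.make_splits(labels_by_id, k=self.cfg.k_splits,
                                        test_fraction=self.cfg.test_fraction,
                                        seed=self.cfg.seed)
        results: dict = {}
        for clf in self.cfg.classifiers:
            n_splits = (self.cfg.cnn_k_splits or self.cfg.k_splits) if clf == "cnn" \
                else self.cfg.k_splits
            for rep in self.cfg.representations:
                aucs, accs = [], []
                for si, (tr, te) in enumerate(scheme.splits[:n_splits]):
                    self._assert_disjoint(tr, te)
                    seed = self.cfg.seed * 1000 + si
                    if clf == "svm":
                        model, scaler = self._fit_svm(rep, tr, seed)
                        scores, preds = self._eval_svm(model, scaler, rep, te)
                    else:
                        model, norm_stats, _ = self._fit_cnn(rep, tr, seed)
                        scores, preds = self._eval_cnn(model, norm_stats, rep, te)
                    yte = self.labels(te)
                    aucs.append(eval_stats.auc(scores, yte))
                    accs.append(eval_stats.accuracy(preds, yte))
                res = eval_stats.summarize_cv(
                    aucs, accs, n_train=len(scheme.splits[0][0]),
                    n_test=len(scheme.splits[0][1]))
                res.meta = {"classifier": clf, "representation": rep,
                            "split_hash": scheme.hash(), "n_splits_used": n_splits}
                results[(clf, rep)] = res
                log.info("E1 %s/%s AUC=%.3f CI=%s", clf, rep, res.mean_auc, res.ci_auc)
        self._write_cv_csv(results, "internal_cv.csv")
        results["scheme"] = scheme
        return results

    # -- E2-E4 --------------------------------------------------------------
    def run_transfer(self) -> dict:
        """Retrain per cell on all internal AD+CN; test on the three held-out
        tasks with bootstrap CIs and the declared 4-comparison McNemar family."""
        assert self.cohort is not None
        train_ids = self.cohort.ids("internal", ("AD", "CN"))
        tasks = {k: v for k, v in TASKS.items() if k != "internal_cv"}
        fitted: dict = {}
        for clf in self.cfg.classifiers:
            for rep in self.cfg.representations:
                seed = self.cfg.seed * 1000 + 999
                if clf == "svm":
                    fitted[(clf, rep)] = self._fit_svm(rep, train_ids, seed)
                else:
                    model, norm_stats, hist = self._fit_cnn(rep, train_ids, seed)
                    fitted[(clf, rep)] = (model, norm_stats)
                    self._write_history(hist, f"cnn_history_{rep}.csv")

        results: dict = {}
        preds_store: dict = {}
        for task, (coh, groups) in tasks.items():
            test_ids = self.cohort.ids(coh, groups)
            if set(test_ids) & set(train_ids):
                raise RuntimeError("train/test id leakage detected")
            yte = self.labels(test_ids)
            for (clf, rep), f in fitted.items():
                if clf == "svm":
                    scores, preds = self._eval_svm(*f, rep, test_ids)
                else:
                    scores, preds = self._eval_cnn(*f, rep, test_ids)
                ci_auc = eval_stats.bootstrap_ci(
                    scores, yte, eval_stats.auc, n_boot=self.cfg.n_boot,
                    seed=self.cfg.seed)
                ci_acc = eval_stats.bootstrap_ci(
                    preds, yte, lambda p, l: eval_stats.accuracy(p, l),
                    n_boot=self.cfg.n_boot, seed=self.cfg.seed)
                res = EvalResult(
                    per_split_auc=[eval_stats.auc(scores, yte)],
                    per_split_acc=[eval_stats.accuracy(preds, yte)],
                    mean_auc=eval_stats.auc(scores, yte),
                    mean_acc=eval_stats.accuracy(preds, yte),
                    ci_auc=ci_auc, ci_acc=ci_acc, ci_method="bootstrap",
                    n_train=len(train_ids), n_test=len(test_ids),
                    meta={"task": task, "classifier": clf, "representation": rep})
                results[(task, clf, rep)] = res
                preds_store[(task, clf, rep)] = (preds == yte)
                log.info("%s %s/%s AUC=%.3f CI=%s", task, clf, rep,
                         res.mean_auc, ci_auc)
            results[("mcnemar", task)] = self._mcnemar_family(task, test_ids, preds_store)
        self._write_transfer_csv(results, "transfer.csv")
        results["train_ids"] = train_ids
        results["fitted"] = fitted
        return results

    def _mcnemar_family(self, task: str, test_ids, preds_store) -> dict:
        """Declared family (4 comparisons): SVM-vs-CNN on each representation,
        representation-vs-representation for each classifier."""
        alpha = eval_stats.bonferroni_alpha(self.cfg.family_alpha,
                                            self.cfg.n_comparisons)
        out = {"bonferroni_alpha": alpha, "comparisons": {}}
        pairs = []
        if set(self.cfg.classifiers) >= {"svm", "cnn"}:
            for rep in self.cfg.representations:
                pairs.append(((("svm", rep), ("cnn", rep)), f"svm_vs_cnn@{rep}"))
        if len(self.cfg.representations) >= 2:
            r1, r2 = self.cfg.representations[:2]
            for clf in self.cfg.classifiers:
                pairs.append(((((clf, r1)), ((clf, r2))), f"{r1}_vs_{r2}@{clf}"))
        for (a, b), name in pairs:
            pa = preds_store.get((task, *a))
            pb = preds_store.get((task, *b))
            if pa is None or pb is None:
                continue
            paired = PairedPredictions(list(test_ids), pa, pb)
            stat, p = eval_stats.mcnemar_test(paired)
            out["comparisons"][name] = {
                "statistic": stat, "p": p, "b": paired.b, "c": paired.c,
                "significant": p < alpha}
        return out

    # -- maps ---------------------------------------------------------------
    def render_maps(self, fitted: dict, train_ids: list[str]) -> dict:
        """P-maps, cluster masks and averaged saliency from the full-training
        models; Dice overlap against the generator's ROI."""
        roi = load_mask(self.cohort.roi_path)
        maps_dir = self.out_dir / "maps"
        maps_dir.mkdir(exist_ok=True)
        out: dict = {}
        y_svm = np.where(self.labels(train_ids) == 1, 1, -1)
        for (clf, rep), f in fitted.items():
            if clf == "svm":
                model, scaler = f
                Xs = preprocess.apply_scaler(scaler, self.features(rep, train_ids))
                pmap = svm_pmap.analytic_pmap(Xs, y_svm)
                pmap = svm_pmap.threshold_pmap(pmap, self.mask)
                pvol = preprocess.devectorize(pmap.p_values, self.mask)
                pvol.data[~self.mask.data] = 1.0
                save_nifti(pvol, maps_dir / f"svm_pmap_{rep}.nii.gz")
                cl = svm_pmap.cluster_mask(pmap, self.mask, largest_only=True)
                save_nifti(VolumeImage(cl.astype(float), spacing=self.mask.spacing,
                                       affine=self.mask.affine),
                           maps_dir / f"svm_clusters_{rep}.nii.gz")
                out[(clf, rep)] = {"dice_roi": dice(cl, roi.data),
                                   "n_clusters": len(pmap.clusters)}
            else:
                model, norm_stats = f
                ad_ids = [i for i in train_ids
                          if self.cohort.record(i).group == "AD"]
                scores, preds = self._eval_cnn(model, norm_stats, rep, ad_ids)
                correct = [i for i, p in zip(ad_ids, preds) if p == 1]
                if not correct:
                    log.warning("no correctly classified AD subjects for %s/%s; "
                                "saliency skipped", clf, rep)
                    out[(clf, rep)] = {"dice_roi": float("nan"), "skipped": True}
                    continue
                mu, sd = norm_stats
                smaps = {}
                for pid in correct:
                    x = (self.volumes(rep, [pid])[0] - mu) / sd
                    smaps[pid] = guided_backprop_saliency(model, x, target_class=1)
                avg = average_saliency(smaps, correct)
                sal = avg.data[0] if avg.data.ndim == 4 else avg.data
                if tuple(sal.shape) != tuple(self.mask.shape):
                    factors = [t / s for t, s in zip(self.mask.shape, sal.shape)]
                    sal = ndimage.zoom(sal, factors, order=1)
                save_nifti(VolumeImage(sal, spacing=self.mask.spacing,
                                       affine=self.mask.affine),
                           maps_dir / f"cnn_saliency_{rep}.nii.gz")
                out[(clf, rep)] = {
                    "dice_roi": dice(np.abs(sal) > 0, roi.data),
                    "n_averaged": len(correct)}
        return out

    # -- plumbing -----------------------------------------------------------
    @staticmethod
    def _assert_disjoint(train_ids, test_ids) -> None:
        if set(train_ids) & set(test_ids):
            raise RuntimeError("train/test overlap inside a split")

    def _write_cv_csv(self, results: dict, name: str) -> None:
        with (self.out_dir / name).open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["classifier", "representation", "auc", "auc_lo", "auc_hi",
                        "acc", "acc_lo", "acc_hi", "ci_method", "split_hash"])
            for key, res in results.items():
                if not isinstance(key, tuple):
                    continue
                clf, rep = key
                w.writerow([clf, rep, f"{res.mean_auc:.4f}",
                            f"{res.ci_auc[0]:.4f}", f"{res.ci_auc[1]:.4f}",
                            f"{res.mean_acc:.4f}", f"{res.ci_acc[0]:.4f}",
                            f"{res.ci_acc[1]:.4f}", res.ci_method,
                            res.meta.get("split_hash", "")])

    def _write_transfer_csv(self, results: dict, name: str) -> None:
        with (self.out_dir / name).open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["task", "classifier", "representation", "auc",
                        "auc_lo", "auc_hi", "acc", "acc_lo", "acc_hi"])
            for key, res in results.items():
                if not (isinstance(key, tuple) and len(key) == 3):
                    continue
                task, clf, rep = key
                w.writerow([task, clf, rep, f"{res.mean_auc:.4f}",
                            f"{res.ci_auc[0]:.4f}", f"{res.ci_auc[1]:.4f}",
                            f"{res.mean_acc:.4f}", f"{res.ci_acc[0]:.4f}",
                            f"{res.ci_acc[1]:.4f}"])

    def _write_history(self, history: dict, name: str) -> None:
        with (self.out_dir / name).open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "lr", "train_loss", "val_auc"])
            for row in zip(history["epoch"], history["lr"],
                           history["train_loss"], history["val_auc"]):
                w.writerow(row)
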