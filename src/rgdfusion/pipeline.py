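"""End-to-end RGD runs: k-fold cross-validation and ablations.

Per fold: train the five backbones on the training split, compute their
training-set predictions -> divergence adjacency, compute radiomics FR and
GCN-fused FG, jointly fine-tune the five fusion heads + GCN weights with
focal loss, weight the heads by their validation accuracy, and evaluate the
ensemble on the held-out fold.  Everything is reproducible from one master
seed; patient disjointness between train and test is verified at run time.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._seeding import derive_seed, rng_for
from .backbones import (
    BACKBONE_NAMES,
    BackboneSpec,
    OptimizerConfig,
    build_backbone,
    train_backbone,
)
from .cohort import load_manifest, make_folds, preprocess_volume
from .graph_fusion import build_adjacency
from .heads import (
    FocalParams,
    FusionModel,
    ensemble_predict,
    ensemble_weights,
    finetune_heads,
)
from .metrics import EvalReport, aggregate_folds, write_report
from .phantom import PhantomSpec, generate_cohort
from .radiomics import GLCMParams, HOGParams, LBPParams, radiomics_vector

logger = logging.getLogger("rgdfusion")

__all__ = ["RunConfig", "CVResult", "run_cv", "run_ablation", "ABLATION_ARMS"]

ABLATION_ARMS = (
    "cnn_1", "cnn_2", "cnn_3", "cnn_4", "cnn_5",
    "cnn_1+r", "cnn_1+g", "cnn_1+r+g",
    "cnn_s", "cnn_s+r", "rgd",
)


@dataclass
class RunConfig:
    """Full run configuration; serialises losslessly to YAML.

    Optimizer defaults follow the reference recipe (Adam, lr 1e-4, weight
    decay 1e-4, up to 100 epochs); :meth:`phantom_default` is the desk-scale
    preset actually used for phantom experiments.
    """

    # data
    phantom: dict = field(default_factory=lambda: dataclasses.asdict(PhantomSpec()))
    manifest: str | None = None  # overrides phantom generation when set

    # backbones
    backbone_names: tuple[str, ...] = BACKBONE_NAMES
    scale: str = "tiny"
    feature_dim: int = 256

    # radiomics
    lbp: dict = field(default_factory=lambda: dataclasses.asdict(LBPParams()))
    hog: dict = field(default_factory=lambda: dataclasses.asdict(HOGParams()))
    glcm: dict = field(default_factory=lambda: dataclasses.asdict(GLCMParams()))

    # fusion
    adjacency_variant: str = "a1s"
    gcn_hidden: int = 256
    gcn_out: int = 128
    focal: dict = field(default_factory=lambda: dataclasses.asdict(FocalParams()))

    # optimisation
    lr: float = 1e-4
    weight_decay: float = 1e-4
    backbone_epochs: int = 100
    head_epochs: int = 30
    head_lr: float = 1e-3
    batch_size: int = 32

    # evaluation
    k_folds: int = 10
    val_fraction: float = 0.1
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        # canonical container types so configs compare equal across a
        # YAML round-trip (tuples inside dicts become lists and stay lists)
        self.phantom = _listify(dict(self.phantom))
        self.lbp = _listify(dict(self.lbp))
        self.hog = _listify(dict(self.hog))
        self.glcm = _listify(dict(self.glcm))
        self.backbone_names = tuple(self.backbone_names)

    @classmethod
    def phantom_default(cls, n_per_class: int = 100, k_folds: int = 5,
                        seed: int = 0) -> "RunConfig":
        """Desk-scale preset: tiny backbones, compact feature widths and a
        short training schedule sized to the easy phantom task."""
        cfg = cls(
            phantom=dataclasses.asdict(PhantomSpec(n_per_class=n_per_class,
                                                   seed=seed)),
            feature_dim=32,
            gcn_hidden=64,
            gcn_out=32,
            lr=1e-3,
            backbone_epochs=8,
            head_epochs=30,
            k_folds=k_folds,
            seed=seed,
        )
        return cfg

    # -- (de)serialisation --------------------------------------------------

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        text = yaml.safe_dump(_listify(d), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, src: str | Path) -> "RunConfig":
        s = str(src)
        text = Path(s).read_text() if "\n" not in s and Path(s).exists() else s
        d = yaml.safe_load(text)
        cfg = cls(**{k: _tuplify(v) for k, v in d.items()})
        return cfg

    def phantom_spec(self) -> PhantomSpec:
        d = dict(self.phantom)
        d["crop_shape"] = tuple(d["crop_shape"])
        return PhantomSpec(**d)

    def radiomics_params(self):
        hog = dict(self.hog)
        hog["cell_shape"] = tuple(hog["cell_shape"])
        if hog.get("block_shape") is not None:
            hog["block_shape"] = tuple(hog["block_shape"])
        glcm = dict(self.glcm)
        glcm["z_direction_distances"] = tuple(glcm["z_direction_distances"])
        glcm["inplane_distances"] = tuple(glcm["inplane_distances"])
        return LBPParams(**self.lbp), HOGParams(**hog), GLCMParams(**glcm)


def _listify(x):
    if isinstance(x, dict):
        return {k: _listify(v) for k, v in x.items()}
    if isinstance(x, tuple):
        return [_listify(v) for v in x]
    if isinstance(x, list):
        return [_listify(v) for v in x]
    return x


def _tuplify(x):
    return tuple(x) if isinstance(x, list) else x


@dataclass
class CVResult:
    reports: list[EvalReport]
    aggregate: dict[str, tuple[float, float]]
    ensemble_scores: np.ndarray  # per-sample final probability
    labels: np.ndarray
    fold_of_sample: np.ndarray
    backbone_fold_accuracy: np.ndarray  # (k, n_models) single-CNN test acc
    fused_fold_accuracy: np.ndarray  # (k, n_models) fused-head test acc
    weights_per_fold: list[tuple[float, ...]]

    @property
    def mean_accuracy(self) -> float:
        return self.aggregate["accuracy"][0]

    def best_single_backbone_accuracy(self) -> float:
        """Highest per-model mean test accuracy of the plain backbones."""
        return float(self.backbone_fold_accuracy.mean(axis=0).max())


def _load_cohort(config: RunConfig):
    if config.manifest:
        return load_manifest(config.manifest)
    return generate_cohort(config.phantom_spec())


def _prepare(config: RunConfig):
    """Cohort -> preprocessed volumes, labels, patients, radiomics FR."""
    cohort = _load_cohort(config)
    lbp, hog, glcm = config.radiomics_params()
    vols, labels, patients, fr = [], [], [], []
    for vol, label, pid in cohort:
        pv = preprocess_volume(vol)
        vols.append(pv.voxels)
        labels.append(label)
        patients.append(pid)
        fr.append(radiomics_vector(pv, lbp, hog, glcm).fr)
    return (
        np.stack(vols),
        np.asarray(labels, dtype=int),
        np.asarray(patients),
        np.stack(fr).astype(np.float32),
    )


def _carve_validation(train_idx, patients, labels, frac, rng):
    """Split off a patient-disjoint validation subset (~frac of the training
    patients, stratified by each patient's majority label)."""
    pts = np.unique(patients[train_idx])
    in_train = np.zeros(len(patients), dtype=bool)
    in_train[train_idx] = True
    plabel = {
        p: int(round(labels[(patients == p) & in_train].mean())) for p in pts
    }
    val_pts: set[str] = set()
    for cls in sorted(set(plabel.values())):
        cls_pts = [p for p in pts if plabel[p] == cls]
        k = max(1, int(round(frac * len(cls_pts))))
        order = rng.permutation(len(cls_pts))
        val_pts.update(cls_pts[i] for i in order[:k])
    val_mask = np.isin(patients, list(val_pts)) & in_train
    val_idx = np.where(val_mask)[0]
    core_idx = np.asarray([i for i in train_idx if i not in set(val_idx)])
    return core_idx, val_idx


def _fold_indices(split, patients):
    for f in range(split.k):
        test_pts = split.test_patients(f)
        test_idx = np.where(np.isin(patients, list(test_pts)))[0]
        train_idx = np.where(~np.isin(patients, list(test_pts)))[0]
        yield f, train_idx, test_idx


def run_cv(config: RunConfig, outdir: str | Path | None = None) -> CVResult:
    """Full cross-validated RGD run; returns per-fold and aggregate reports.

    When ``outdir`` is given, per-fold metric tables, adjacency matrices and
    per-nodule decision CSVs are written there.
    """
    X, y, patients, FR = _prepare(config)
    nodules = [type("N", (), {"patient_id": p})() for p in patients]
    split = make_folds(nodules, k=config.k_folds, seed=config.seed)
    focal = FocalParams(**config.focal)
    n_models = len(config.backbone_names)

    reports: list[EvalReport] = []
    ens_scores = np.full(len(y), np.nan)
    fold_of = np.full(len(y), -1, dtype=int)
    bb_acc = np.zeros((split.k, n_models))
    fused_acc = np.zeros((split.k, n_models))
    weights_hist = []
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    for f, train_idx, test_idx in _fold_indices(split, patients):
        if set(patients[train_idx]) & set(patients[test_idx]):
            raise RuntimeError(f"patient leakage between train and test, fold {f}")
        rng = rng_for(config.seed, "val-split", f)
        core_idx, val_idx = _carve_validation(
            train_idx, patients, y, config.val_fraction, rng
        )
        logger.info(
            "fold %d: train=%d val=%d test=%d", f, len(core_idx),
            len(val_idx), len(test_idx),
        )

        opt = OptimizerConfig(
            lr=config.lr,
            weight_decay=config.weight_decay,
            max_epochs=config.backbone_epochs,
            batch_size=config.batch_size,
        )
        backbones, train_preds = [], []
        feats = {"core": [], "val": [], "test": []}
        for mi, name in enumerate(config.backbone_names):
            spec = BackboneSpec(
                name=name, scale=config.scale, feature_dim=config.feature_dim
            )
            bseed = derive_seed(config.seed, "fold", f, "model", name)
            net = build_backbone(spec, seed=bseed)
            preds = train_backbone(
                net, X[core_idx], y[core_idx], loss=focal,
                optimizer=opt, seed=bseed,
            )
            train_preds.append(preds)
            backbones.append(net)
            for key, idx in (("core", core_idx), ("val", val_idx),
                             ("test", test_idx)):
                out_b = net.apply(X[idx])
                feats[key].append(out_b.features)
                if key == "test":
                    bb_acc[f, mi] = float(
                        (out_b.hard_prediction == y[idx]).mean()
                    )

        A = build_adjacency(train_preds, config.adjacency_variant)
        stacked = {
            k: np.stack(v, axis=1) for k, v in feats.items()
        }  # (n, n_models, fd)
        fusion = finetune_heads(
            stacked["core"],
            FR[core_idx],
            A,
            y[core_idx],
            loss=focal,
            gcn_hidden=config.gcn_hidden,
            gcn_out=config.gcn_out,
            epochs=config.head_epochs,
            lr=config.head_lr,
            weight_decay=config.weight_decay,
            seed=derive_seed(config.seed, "fold", f, "heads"),
        )
        val_probs = fusion.predict(stacked["val"], FR[val_idx])
        accs = [
            float(((p >= config.threshold).astype(int) == y[val_idx]).mean())
            for p in val_probs
        ]
        w = ensemble_weights(accs)
        weights_hist.append(w.weights)

        test_probs = fusion.predict(stacked["test"], FR[test_idx])
        for mi in range(n_models):
            fused_acc[f, mi] = float(
                ((test_probs[mi] >= config.threshold).astype(int)
                 == y[test_idx]).mean()
            )
        P = ensemble_predict(test_probs, w)
        ens_scores[test_idx] = P
        fold_of[test_idx] = f
        reports.append(
            EvalReport.from_scores(y[test_idx], P,
                                   threshold=config.threshold, fold=f)
        )
        if out is not None:
            np.savetxt(out / f"adjacency_fold{f}.csv", A, delimiter=",")
            import pandas as pd

            pd.DataFrame(
                {
                    "patient_id": patients[test_idx],
                    "label": y[test_idx],
                    **{f"p_{nm}": test_probs[mi]
                       for mi, nm in enumerate(config.backbone_names)},
                    "p_ensemble": P,
                    "decision": (P >= config.threshold).astype(int),
                }
            ).to_csv(out / f"decisions_fold{f}.csv", index=False)

    agg = aggregate_folds(reports)
    if out is not None:
        write_report(reports, out / "report.csv")
    return CVResult(
        reports=reports,
        aggregate=agg,
        ensemble_scores=ens_scores,
        labels=y,
        fold_of_sample=fold_of,
        backbone_fold_accuracy=bb_acc,
        fused_fold_accuracy=fused_acc,
        weights_per_fold=weights_hist,
    )


# ---------------------------------------------------------------------------
# ablation


def _parse_arm(arm: str):
    a = arm.lower().replace(" ", "")
    if a == "rgd":
        return ("rgd", None, False, False)
    if a.startswith("cnn_s"):
        rest = a[len("cnn_s"):]
        return ("cnn_s", None, "+r" in rest, False)
    if a.startswith("cnn_"):
        head, _, mods = a.partition("+")
        idx = int(head[len("cnn_"):]) - 1
        mods = "+" + mods if mods else ""
        return ("cnn_i", idx, "+r" in mods, "+g" in mods)
    raise ValueError(f"unknown ablation arm {arm!r}")


def run_ablation(config: RunConfig, arms: list[str]):
    """Accuracy table over ablation arms (single CNNs, +R / +G fusions, the
    five-feature concatenation CNN_s, and full RGD) on the configured data.

    Shares one set of trained backbones per fold across all arms.  Returns a
    pandas DataFrame with one row per arm: per-fold accuracies and the mean.
    """
    import pandas as pd

    parsed = [_parse_arm(a) for a in arms]  # validates early
    X, y, patients, FR = _prepare(config)
    nodules = [type("N", (), {"patient_id": p})() for p in patients]
    split = make_folds(nodules, k=config.k_folds, seed=config.seed)
    focal = FocalParams(**config.focal)
    FR0 = np.zeros((len(y), 0), dtype=np.float32)  # "no radiomics" block

    acc = {arm: [] for arm in arms}
    for f, train_idx, test_idx in _fold_indices(split, patients):
        rng = rng_for(config.seed, "val-split", f)
        core_idx, val_idx = _carve_validation(
            train_idx, patients, y, config.val_fraction, rng
        )
        opt = OptimizerConfig(
            lr=config.lr, weight_decay=config.weight_decay,
            max_epochs=config.backbone_epochs, batch_size=config.batch_size,
        )
        backbones, train_preds, feats = [], [], {}
        for name in config.backbone_names:
            spec = BackboneSpec(name=name, scale=config.scale,
                                feature_dim=config.feature_dim)
            bseed = derive_seed(config.seed, "fold", f, "model", name)
            net = build_backbone(spec, seed=bseed)
            train_preds.append(
                train_backbone(net, X[core_idx], y[core_idx], loss=focal,
                               optimizer=opt, seed=bseed)
            )
            backbones.append(net)
        for key, idx in (("core", core_idx), ("val", val_idx), ("test", test_idx)):
            feats[key] = np.stack(
                [b.apply(X[idx]).features for b in backbones], axis=1
            )
        A = build_adjacency(train_preds, config.adjacency_variant)

        def fit_fusion(fr_block):
            return finetune_heads(
                feats["core"], fr_block[core_idx], A, y[core_idx], loss=focal,
                gcn_hidden=config.gcn_hidden, gcn_out=config.gcn_out,
                epochs=config.head_epochs, lr=config.head_lr,
                weight_decay=config.weight_decay,
                seed=derive_seed(config.seed, "fold", f, "heads"),
            )

        fusion_rg = fusion_g = None
        need_rg = any(k in ("rgd",) or (k == "cnn_i" and r and g)
                      for k, _, r, g in parsed)
        if need_rg:
            fusion_rg = fit_fusion(FR)
        if any(k == "cnn_i" and g and not r for k, _, r, g in parsed):
            fusion_g = fit_fusion(FR0)

        for arm, (kind, mi, use_r, use_g) in zip(arms, parsed):
            if kind == "rgd":
                val_p = fusion_rg.predict(feats["val"], FR[val_idx])
                w = ensemble_weights([
                    float(((p >= 0.5).astype(int) == y[val_idx]).mean())
                    for p in val_p
                ])
                P = ensemble_predict(
                    fusion_rg.predict(feats["test"], FR[test_idx]), w
                )
                a = float(((P >= 0.5).astype(int) == y[test_idx]).mean())
            elif kind == "cnn_s":
                flat = {k: v.reshape(v.shape[0], -1) for k, v in feats.items()}
                blocks = (
                    (np.hstack([flat["core"], FR[core_idx]]),
                     np.hstack([flat["test"], FR[test_idx]]))
                    if use_r
                    else (flat["core"], flat["test"])
                )
                a = _linear_head_accuracy(
                    blocks[0], y[core_idx], blocks[1], y[test_idx], focal,
                    config, derive_seed(config.seed, "fold", f, "cnn_s", use_r),
                )
            elif use_r and use_g:
                p = fusion_rg.predict(feats["test"], FR[test_idx])[mi]
                a = float(((p >= 0.5).astype(int) == y[test_idx]).mean())
            elif use_g:
                p = fusion_g.predict(feats["test"], FR0[test_idx])[mi]
                a = float(((p >= 0.5).astype(int) == y[test_idx]).mean())
            elif use_r:
                a = _linear_head_accuracy(
                    np.hstack([feats["core"][:, mi, :], FR[core_idx]]),
                    y[core_idx],
                    np.hstack([feats["test"][:, mi, :], FR[test_idx]]),
                    y[test_idx], focal, config,
                    derive_seed(config.seed, "fold", f, "cnn_r", mi),
                )
            else:  # plain single CNN
                p = backbones[mi].apply(X[test_idx]).probability
                a = float(((p >= 0.5).astype(int) == y[test_idx]).mean())
            acc[arm].append(a)

    rows = []
    for arm in arms:
        vals = acc[arm]
        rows.append({"arm": arm,
                     **{f"fold_{i}": v for i, v in enumerate(vals)},
                     "mean": float(np.mean(vals))})
    return pd.DataFrame(rows)


def _linear_head_accuracy(Xtr, ytr, Xte, yte, focal, config, seed):
    """Train a focal-loss linear probe on standardised features; test accuracy."""
    from .nn import Adam, Dense, Tensor, sigmoid

    mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
    sd[sd < 1e-12] = 1.0
    Xtr = ((Xtr - mu) / sd).astype(np.float32)
    Xte = ((Xte - mu) / sd).astype(np.float32)
    rng = rng_for(seed, "linear-head")
    head = Dense(Xtr.shape[1], 1, rng)
    optim = Adam(head.parameters(), lr=config.head_lr,
                 weight_decay=config.weight_decay)
    from .heads import focal_loss_tensor

    for _ in range(config.head_epochs):
        order = rng.permutation(Xtr.shape[0])
        for i in range(0, Xtr.shape[0], 64):
            idx = order[i : i + 64]
            logit = head(Tensor(Xtr[idx]))
            p = sigmoid(logit.reshape(logit.shape[0]))
            L = focal_loss_tensor(ytr[idx], p, focal)
            optim.zero_grad()
            L.backward()
            optim.step()
    logit = head(Tensor(Xte))
    p = 1.0 / (1.0 + np.exp(-logit.data.reshape(-1)))
    return float(((p >= 0.5).astype(int) == yte).mean())
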