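"""End-to-end orchestration of the model-building workflow.

A run executes: load -> preprocess -> split -> relocate -> truncate ->
select -> (augment) -> summarize -> correlate, writing every artifact to a
run directory together with a manifest and the resolved configuration, so
that re-running an identical configuration reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate, protocol
from .dataset import Medium, SolubilityDataset, load_dataset, save_dataset
from .preprocess import DescriptorPreprocessor
from .synthetic import SyntheticSpec, generate_latent_dataset
from .dataset import CompoundRecord

__all__ = ["RunConfig", "run_workflow", "report_figures", "save_model", "load_model"]


class WorkflowError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Fully resolved configuration of one model-building run."""

    response: str = "fassif"
    dataset_source: str = "table1"          # fixture id, CSV path or "synthetic"
    descriptor_source: str = "synthetic"    # CSV path or "synthetic"
    cube_root: bool = True
    normality: bool = True
    skew_limit: float = 2.0
    kurt_limit: float = 7.0
    cv_groups: int = 7
    vip_keep: int = 100
    q2_tol: float = 1e-6
    max_components: int = 10
    component_threshold: float = 0.01
    relocation_criterion: str = "both"
    pca_components: int = 2
    augmentation: list[str] = field(default_factory=list)
    seed: int = 0
    synthetic: dict = field(default_factory=lambda: {"n": 86, "p": 120, "k": 2,
                                                     "n_informative": 5,
                                                     "noise_sd": 0.3})
    outdir: str = "runs/run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _synthetic_inputs(cfg: RunConfig):
    """Descriptor matrix + compound table sharing one latent response."""
    spec = SyntheticSpec(seed=cfg.seed, **cfg.synthetic)
    X, y, truth = generate_latent_dataset(spec)
    rng = np.random.default_rng(cfg.seed + 1)
    z = ((y - y.mean()) / y.std(ddof=0)).to_numpy()
    fassif = np.clip(-4.0 + z, -9.0, -2.0)
    # buffer solubility tracks the response closely; intestinal fluid a bit less
    phb = np.clip(fassif + rng.normal(0, 0.45, len(y)), -9.0, -2.0)
    hif = np.clip(fassif + rng.normal(0, 0.55, len(y)), -9.0, -2.0)
    phb_missing = rng.random(len(y)) < 0.25
    hif_missing = rng.random(len(y)) < 0.45
    records = []
    for i, name in enumerate(X.index):
        records.append(CompoundRecord(
            name=name, mw=float(rng.uniform(210, 900)),
            logd65=float(rng.uniform(-0.2, 9.0)),
            psa=float(rng.uniform(3, 320)), rotb=int(rng.integers(0, 22)),
            logs_phb=None if phb_missing[i] else float(phb[i]),
            logs_fassif=float(fassif[i]),
            logs_hif=None if hif_missing[i] else float(hif[i]),
            tm_c=float(rng.uniform(70, 350)),
        ))
    return X, SolubilityDataset(records), truth


def save_model(model, directory: str | Path) -> None:
    """Serialize a fitted PLS model as a YAML + CSV bundle."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    names = model.feature_names_in_
    pd.DataFrame(model.x_weights_, index=names).to_csv(d / "weights.csv")
    pd.DataFrame(model.x_loadings_, index=names).to_csv(d / "loadings.csv")
    pd.DataFrame(model.x_scores_, index=model.row_names_).to_csv(d / "scores.csv")
    meta = {
        "n_components": int(model.n_components_),
        "descriptors": list(names),
        "y_loadings": [float(v) for v in model.y_loadings_],
        "x_mean": [float(v) for v in model.x_mean_],
        "y_mean": float(model.y_mean_),
        "coef": [float(v) for v in model.coef_],
        "r2": float(model.r2_),
        "rmse_tr": float(model.rmse_tr_),
    }
    (d / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))


def load_model(directory: str | Path):
    from .latent import NipalsPLS

    d = Path(directory)
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    model = NipalsPLS(n_components=meta["n_components"])
    weights = pd.read_csv(d / "weights.csv", index_col=0)
    loadings = pd.read_csv(d / "loadings.csv", index_col=0)
    scores = pd.read_csv(d / "scores.csv", index_col=0)
    model.feature_names_in_ = meta["descriptors"]
    model.x_weights_ = weights.to_numpy()
    model.x_loadings_ = loadings.to_numpy()
    model.x_scores_ = scores.to_numpy()
    model.row_names_ = list(scores.index)
    model.y_loadings_ = np.asarray(meta["y_loadings"], dtype=float)
    model.x_mean_ = np.asarray(meta["x_mean"], dtype=float)
    model.y_mean_ = float(meta["y_mean"])
    model.coef_ = np.asarray(meta["coef"], dtype=float)
    model.n_components_ = int(meta["n_components"])
    model.r2_ = float(meta["r2"])
    model.rmse_tr_ = float(meta["rmse_tr"])
    return model


def run_workflow(cfg: RunConfig) -> Path:
    """Execute the full protocol; returns the run directory."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    log: list[str] = [f"config_hash {cfg.content_hash()}", f"seed {cfg.seed}"]

    def stage(name):
        log.append(f"stage {name}")

    try:
        stage("load")
        if cfg.descriptor_source == "synthetic":
            X_raw, ds, _truth = _synthetic_inputs(cfg)
            if cfg.dataset_source not in ("synthetic", "table1"):
                ds = load_dataset(cfg.dataset_source)
        else:
            ds = load_dataset(cfg.dataset_source)
            X_raw = pd.read_csv(cfg.descriptor_source, index_col=0)
        medium = Medium.coerce(cfg.response)
        with_resp = [r.name for r in ds if r.solubility(medium) is not None]
        ds_model = ds.subset(with_resp)
        X_raw = X_raw.loc[[n for n in X_raw.index if n in set(with_resp)]]
        save_dataset(ds, out / "dataset.csv")
        X_raw.to_csv(out / "descriptors.csv")
        manifest["dataset"] = "dataset.csv"
        manifest["descriptors"] = "descriptors.csv"
    except WorkflowError:
        raise
    except Exception as e:
        raise WorkflowError("load", str(e)) from e

    try:
        stage("preprocess")
        prep = DescriptorPreprocessor(cube_root=cfg.cube_root, normality=cfg.normality,
                                      skew_limit=cfg.skew_limit, kurt_limit=cfg.kurt_limit)
        X = prep.fit(X_raw).transform(X_raw)
        prep.to_yaml(out / "preprocess.yaml")
        manifest["preprocess_state"] = "preprocess.yaml"
    except Exception as e:
        raise WorkflowError("preprocess", str(e)) from e

    try:
        stage("split")
        split = protocol.sorted_thirds_split(ds_model, medium)
        stage("relocate")
        split = protocol.relocate_outliers(split, X, criterion=cfg.relocation_criterion,
                                           n_components=cfg.pca_components)
        for name, why in split.relocations:
            log.append(f"relocated {name} ({why})")
        rows = ([{"name": n, "set": "Tr"} for n in split.train]
                + [{"name": n, "set": "Te"} for n in split.test])
        pd.DataFrame(rows).to_csv(out / "split.csv", index=False)
        manifest["split"] = "split.csv"
    except Exception as e:
        raise WorkflowError("split", str(e)) from e

    try:
        stage("select")
        y = pd.Series({r.name: r.solubility(medium) for r in ds_model})
        Xtr, ytr = X.loc[split.train], y.loc[split.train]
        est = protocol.VipGreedyPLS(keep=cfg.vip_keep, groups=cfg.cv_groups,
                                    q2_tol=cfg.q2_tol,
                                    max_components=cfg.max_components,
                                    component_threshold=cfg.component_threshold)
        est.fit(Xtr, ytr)
        for s in est.trace_.steps:
            if s.accepted:
                log.append(f"eliminated {s.descriptor} (pass {s.pass_index}, "
                           f"Q2 {s.q2_before:.4f} -> {s.q2_after:.4f})")
        est.trace_.to_frame().to_csv(out / "trace.csv", index=False)
        manifest["trace"] = "trace.csv"
        save_model(est.model_, out / "model")
        manifest["model"] = "model/meta.yaml"
    except Exception as e:
        raise WorkflowError("select", str(e)) from e

    try:
        stage("augment")
        aug_note = {}
        if cfg.augmentation:
            res = protocol.augment_experimental(
                Xtr[est.selected_], ds_model, ytr, list(cfg.augmentation),
                groups=cfg.cv_groups, max_components=cfg.max_components,
                threshold=cfg.component_threshold, q2_tol=cfg.q2_tol)
            aug_note = {"q2_base": float(res.q2_base),
                        "q2_augmented": float(res.q2_augmented),
                        "retained": bool(res.retained),
                        "leak_flag": bool(res.leak_flag),
                        "n_train_augmented": len(res.rows)}
            log.append(f"augmentation {cfg.augmentation} retained={res.retained}")
    except Exception as e:
        raise WorkflowError("augment", str(e)) from e

    try:
        stage("summarize")
        y_te = y.loc[split.test]
        pred_te = pd.Series(est.predict(X.loc[split.test]), index=split.test)
        summary = protocol.build_summary(est.model_, split, y_te, pred_te,
                                         model_id=f"{medium.value}-pls", q2=est.q2_,
                                         augmentation=list(cfg.augmentation))
        doc = {k: v for k, v in vars(summary).items()}
        doc["augmentation_detail"] = aug_note
        (out / "summary.yaml").write_text(yaml.safe_dump(doc, sort_keys=False))
        manifest["summary"] = "summary.yaml"
        pred_te.rename("predicted").to_frame().assign(observed=y_te).to_csv(
            out / "predictions_test.csv")
    except Exception as e:
        raise WorkflowError("summarize", str(e)) from e

    try:
        stage("correlate")
        reports = []
        for a, b in ((Medium.PHB65, Medium.FASSIF), (Medium.PHB65, Medium.HIF),
                     (Medium.FASSIF, Medium.HIF)):
            try:
                reports.extend(evaluate.stratified_correlation(ds, a, b))
            except Exception:
                continue
        rows = [{"medium_a": r.medium_a.value, "medium_b": r.medium_b.value,
                 "stratum": r.stratum, "n": r.n,
                 "r2": "" if r.r2 is None else round(r.r2, 6)} for r in reports]
        pd.DataFrame(rows).to_csv(out / "correlations.csv", index=False)
        manifest["correlations"] = "correlations.csv"
    except Exception as e:
        raise WorkflowError("correlate", str(e)) from e

    cfg.to_yaml(out / "config.yaml")
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    (out / "run.log").write_text("\n".join(log) + "\n")
    return out


def report_figures(run_dir: str | Path) -> list[Path]:
    """Observed-vs-predicted and medium-vs-medium reports for a finished run.

    Writes PNG scatter plots and, next to each, the numeric table it was
    drawn from. Returns the list of files written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = Path(run_dir)
    written: list[Path] = []
    pred_path = run / "predictions_test.csv"
    if not pred_path.exists():
        raise WorkflowError("report", f"missing stage output: {pred_path}")
    preds = pd.read_csv(pred_path, index_col=0)
    fig, ax = plt.subplots(figsize=(4, 4))
    if len(preds):
        ax.scatter(preds["observed"], preds["predicted"], s=18)
        lims = [min(preds.min()) - 0.3, max(preds.max()) + 0.3]
        ax.plot(lims, lims, "k--", lw=0.8)
    else:
        ax.text(0.5, 0.5, "empty test set", ha="center", va="center")
    ax.set_xlabel("observed log S_app")
    ax.set_ylabel("predicted log S_app")
    fig.tight_layout()
    fig.savefig(run / "fig_observed_vs_predicted.png", dpi=120)
    plt.close(fig)
    written += [run / "fig_observed_vs_predicted.png"]

    corr_path = run / "correlations.csv"
    if corr_path.exists():
        corr = pd.read_csv(corr_path)
        ds = load_dataset(run / "dataset.csv")
        strata_colors = {"lt3": "#bbbbbb", "3to4": "#777777", "gt4": "#222222"}
        pairs = corr[corr.stratum == "all"][["medium_a", "medium_b"]].values
        if len(pairs):
            fig, axes = plt.subplots(1, len(pairs), figsize=(4 * len(pairs), 4))
            axes = np.atleast_1d(axes)
            for ax, (a, b) in zip(axes, pairs):
                xs, ys, names = [], [], []
                from .dataset import paired_values
                xs, ys, names = paired_values(ds, a, b)
                logd = {r.name: r.logd65 for r in ds}
                colors = []
                for n in names:
                    v = logd[n]
                    colors.append(strata_colors["lt3"] if v < 3
                                  else strata_colors["3to4"] if v < 4
                                  else strata_colors["gt4"])
                ax.scatter(xs, ys, c=colors, s=18)
                ax.set_xlabel(f"log S_app {a}")
                ax.set_ylabel(f"log S_app {b}")
            fig.tight_layout()
            fig.savefig(run / "fig_medium_correlations.png", dpi=120)
            plt.close(fig)
            written += [run / "fig_medium_correlations.png"]
        corr.to_csv(run / "fig_medium_correlations.csv", index=False)
        written += [run / "fig_medium_correlations.csv"]
    preds.to_csv(run / "fig_observed_vs_predicted.csv")
    written += [run / "fig_observed_vs_predicted.csv"]
    return written
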