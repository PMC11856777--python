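"""End-to-end experiment orchestration: generate -> train -> corrupt ->
evaluate -> report, for both toy and synthetic-EHR studies.

These functions are the programmatic face of the package; the `kuq` command
line wraps them thinly. A single global seed fans out deterministically to
per-member initialization seeds and data-split seeds, so every numeric output
is reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import checkpoints, ood_eval, synthetic_ehr, token_encoding, toy_data
from .nn.train import TrainConfig, train_model
from .ood_eval import EnnEstimator, KuReport, OodBatch, SngpEstimator, run_ood_experiment
from .synthetic_ehr import CohortConfig
from .uq_models import (
    build_ehr_ensemble,
    build_ehr_sngp_pool,
    build_toy_ensemble,
    build_toy_sngp_pool,
)

log = logging.getLogger("kuq")

__all__ = [
    "ToyRunConfig",
    "EhrRunConfig",
    "split_indices",
    "run_toy_experiment",
    "run_ehr_experiment",
    "save_reports",
    "comparison_table",
]

CORRUPTION_FRACTIONS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 1))


def _fit_or_load(model, train, val, tc: TrainConfig, ckpt: Path | None,
                 extra_meta: dict | None = None):
    """Train a member, or load it from an existing checkpoint (stage resume)."""
    if ckpt is not None and ckpt.exists():
        log.info("resuming from checkpoint %s", ckpt.name)
        return checkpoints.load_checkpoint(ckpt)
    train_model(model, train, val, tc)
    if ckpt is not None:
        ckpt.parent.mkdir(parents=True, exist_ok=True)
        meta = {"train_config": vars(tc), **(extra_meta or {})}
        checkpoints.save_checkpoint(model, ckpt, metadata=meta)
    return model


def _ckpt_path(ckpt_dir, name: str) -> Path | None:
    return None if ckpt_dir is None else Path(ckpt_dir) / f"{name}.npz"


def split_indices(n: int, seed: int, frac_train: float = 0.7,
                  frac_val: float = 0.15) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic train/val/test permutation split."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_tr = int(frac_train * n)
    n_va = int(frac_val * n)
    return order[:n_tr], order[n_tr:n_tr + n_va], order[n_tr + n_va:]


# ---------------------------------------------------------------------------
# toy experiments
# ---------------------------------------------------------------------------

TOY_LENGTH_SCALES = {"moons": 0.2, "stripes": 0.5}


@dataclass
class ToyRunConfig:
    dataset: str = "moons"  # "moons" | "stripes"
    n: int = 1500
    noise: float = 0.1  # moons only
    percentile: float = 90.0
    rff_dim: int = 256
    length_scale: float = 5.0  # GP kernel scale in hidden-space units
    spectral_bound: float = 0.95
    # ENN members: minibatch Adam; SNGP: fewer full-batch epochs (the GP head
    # converges fast and a long SGD schedule over-adapts the backbone geometry
    # that the posterior variance relies on)
    enn_lr: float = 2e-3
    enn_max_epochs: int = 150
    enn_batch_size: int = 128
    sngp_lr: float = 1e-3
    sngp_max_epochs: int = 80
    sngp_batch_size: int | None = None
    patience: int = 15
    seed: int = 0


def make_toy_dataset(cfg: ToyRunConfig) -> toy_data.LabeledPoints:
    if cfg.dataset == "moons":
        return toy_data.make_two_moons(cfg.n, cfg.noise, seed=cfg.seed)
    if cfg.dataset == "stripes":
        return toy_data.make_stripes(toy_data.DEFAULT_STRIPES, cfg.n, seed=cfg.seed)
    raise ValueError("dataset must be 'moons' or 'stripes'")


def run_toy_experiment(cfg: ToyRunConfig,
                       estimators: tuple[str, ...] = ("enn", "sngp"),
                       checkpoint_dir: str | Path | None = None,
                       ) -> dict[str, KuReport]:
    """Train both estimators on one toy dataset and run the 90th-percentile
    OoD detection experiment against its rejection-sampled OoD companion."""
    t0 = time.time()
    data = make_toy_dataset(cfg)
    tr, va, te = split_indices(len(data), seed=cfg.seed + 1)
    Xtr, ytr = data.coords[tr], data.labels[tr]
    Xva, yva = data.coords[va], data.labels[va]
    Xte, yte = data.coords[te], data.labels[te]
    train_points = toy_data.LabeledPoints(Xtr, ytr)
    ls = TOY_LENGTH_SCALES[cfg.dataset]
    ood = toy_data.make_ood_points(train_points, length_scale=ls, m=len(te),
                                   seed=cfg.seed + 2)
    log.info("toy %s: n=%d, ood m=%d (length scale %.2f)",
             cfg.dataset, cfg.n, len(ood), ls)

    reports: dict[str, KuReport] = {}
    if "enn" in estimators:
        members = build_toy_ensemble(cfg.seed)
        for i, m in enumerate(members):
            members[i] = _fit_or_load(
                m, ((Xtr,), ytr), ((Xva,), yva),
                TrainConfig(lr=cfg.enn_lr, max_epochs=cfg.enn_max_epochs,
                            patience=cfg.patience,
                            batch_size=cfg.enn_batch_size, seed=cfg.seed + i),
                _ckpt_path(checkpoint_dir, f"toy-{cfg.dataset}-enn-{i}"))
        reports["enn"] = run_ood_experiment(
            EnnEstimator(members), ((Xte,), yte),
            [OodBatch("ood", (ood.coords,), ood.nn_dist)],
            variant="toy", q=cfg.percentile,
            experiment_id=f"toy-{cfg.dataset}",
            metadata={"seed": cfg.seed, "n": cfg.n, "range_source": "members"})
        log.info("toy %s ENN done in %.1fs", cfg.dataset, time.time() - t0)
    if "sngp" in estimators:
        pool = build_toy_sngp_pool(cfg.seed, rff_dim=cfg.rff_dim,
                                   length_scale=cfg.length_scale,
                                   spectral_bound=cfg.spectral_bound)
        for i, m in enumerate(pool):
            pool[i] = _fit_or_load(
                m, ((Xtr,), ytr), ((Xva,), yva),
                TrainConfig(lr=cfg.sngp_lr, max_epochs=cfg.sngp_max_epochs,
                            patience=cfg.patience,
                            batch_size=cfg.sngp_batch_size,
                            seed=cfg.seed + 100 + i),
                _ckpt_path(checkpoint_dir, f"toy-{cfg.dataset}-sngp-{i}"))
        reports["sngp"] = run_ood_experiment(
            SngpEstimator(pool), ((Xte,), yte),
            [OodBatch("ood", (ood.coords,), ood.nn_dist)],
            variant="toy", q=cfg.percentile,
            experiment_id=f"toy-{cfg.dataset}",
            metadata={"seed": cfg.seed, "n": cfg.n, "range_source": "models"})
        log.info("toy %s SNGP done in %.1fs", cfg.dataset, time.time() - t0)
    return reports


# ---------------------------------------------------------------------------
# synthetic EHR experiment
# ---------------------------------------------------------------------------

@dataclass
class EhrRunConfig:
    n_patients: int = 2000
    percentile: float = 70.0
    smoke: bool = False  # reduced model sizes / epochs for fast runs
    time_width: int = 16
    heads: int = 4
    rff_dim: int = 256
    length_scale: float = 1.0
    lr: float = 1e-4
    max_epochs: int = 60
    patience: int = 5
    batch_size: int = 32
    max_tokens: int | None = None
    fractions: tuple[float, ...] = CORRUPTION_FRACTIONS
    frac_train: float = 0.7
    frac_val: float = 0.15
    seed: int = 0

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(n_patients=self.n_patients, seed=self.seed)


def _smoke_overrides(cfg: EhrRunConfig) -> EhrRunConfig:
    """Reduced problem sizes for fast runs: fewer/narrower attention heads,
    shorter schedules, capped sequence length, and a larger test share so the
    undetected-fraction estimates stay stable despite the small cohort."""
    cfg.heads = 2
    cfg.lr = max(cfg.lr, 2e-4)
    cfg.max_epochs = min(cfg.max_epochs, 15)
    cfg.patience = min(cfg.patience, 3)
    cfg.max_tokens = cfg.max_tokens or 48
    cfg.rff_dim = min(cfg.rff_dim, 256)
    cfg.frac_train = 0.55
    cfg.frac_val = 0.15
    return cfg


def prepare_ehr_data(cfg: EhrRunConfig):
    """Generate the cohort, split it and embed every split."""
    vocab = synthetic_ehr.default_vocabulary()
    episodes = synthetic_ehr.generate_cohort(cfg.cohort_config(), vocab)
    tr, va, te = split_indices(len(episodes), seed=cfg.seed + 11,
                               frac_train=cfg.frac_train, frac_val=cfg.frac_val)
    eps_tr = [episodes[i] for i in tr]
    eps_va = [episodes[i] for i in va]
    eps_te = [episodes[i] for i in te]
    scaler = token_encoding.ValueScaler.fit(eps_tr, vocab)

    def embed(eps):
        return token_encoding.embed_cohort(eps, vocab, time_width=cfg.time_width,
                                           scaler=scaler, max_tokens=cfg.max_tokens)

    return vocab, scaler, (eps_tr, eps_va, eps_te), embed


def corrupt_test_set(eps_te, eps_tr, fractions, seed: int, vocab):
    """Assign each test episode a corruption level (equal numbers per level,
    round-robin) and produce its RTR and PTS variants with d_proxy records."""
    rtr_eps, rtr_d = [], []
    pts_eps, pts_d = [], []
    for i, ep in enumerate(eps_te):
        frac = fractions[i % len(fractions)]
        r_ep, r_rec = synthetic_ehr.random_token_replacement(
            ep, frac, seed=seed + 13 * i)
        p_ep, p_rec = synthetic_ehr.patient_token_swapping(
            ep, frac, eps_tr, seed=seed + 13 * i + 1, vocab=vocab)
        rtr_eps.append(r_ep)
        rtr_d.append(r_rec.d_proxy)
        pts_eps.append(p_ep)
        pts_d.append(p_rec.d_proxy)
    return (rtr_eps, np.array(rtr_d)), (pts_eps, np.array(pts_d))


def run_ehr_experiment(cfg: EhrRunConfig,
                       estimators: tuple[str, ...] = ("enn", "sngp"),
                       return_artifacts: bool = False,
                       checkpoint_dir: str | Path | None = None):
    """Train transformer ensembles on the synthetic cohort and evaluate
    undetected-OoD fractions for RTR and PTS at the 70th-percentile threshold."""
    if cfg.smoke:
        cfg = _smoke_overrides(cfg)
    t0 = time.time()
    vocab, scaler, (eps_tr, eps_va, eps_te), embed = prepare_ehr_data(cfg)
    Xtr, mtr = embed(eps_tr)
    Xva, mva = embed(eps_va)
    Xte, mte = embed(eps_te)
    ytr = np.array([e.label for e in eps_tr])
    yva = np.array([e.label for e in eps_va])
    yte = np.array([e.label for e in eps_te])
    d_in = Xtr.shape[2]

    vocab_hash = hashlib.md5(
        ",".join(vocab.concepts + vocab.kinds).encode()).hexdigest()
    (rtr_eps, rtr_d), (pts_eps, pts_d) = corrupt_test_set(
        eps_te, eps_tr, cfg.fractions, seed=cfg.seed + 17, vocab=vocab)
    Xrtr, mrtr = embed(rtr_eps)
    Xpts, mpts = embed(pts_eps)
    ood_sets = [OodBatch("rtr", (Xrtr, mrtr), rtr_d),
                OodBatch("pts", (Xpts, mpts), pts_d)]
    log.info("ehr cohort: %d train / %d val / %d test episodes, d_in=%d, T=%d",
             len(eps_tr), len(eps_va), len(eps_te), d_in, Xtr.shape[1])

    tc = dict(lr=cfg.lr, max_epochs=cfg.max_epochs, patience=cfg.patience,
              batch_size=cfg.batch_size)
    reports: dict[str, KuReport] = {}
    artifacts: dict = {"vocab": vocab, "scaler": scaler, "config": cfg,
                       "test": ((Xte, mte), yte)}
    if "enn" in estimators:
        members = build_ehr_ensemble(d_in, cfg.seed, heads=cfg.heads,
                                     smoke=cfg.smoke)
        for i, m in enumerate(members):
            members[i] = _fit_or_load(
                m, ((Xtr, mtr), ytr), ((Xva, mva), yva),
                TrainConfig(**tc, seed=cfg.seed + i),
                _ckpt_path(checkpoint_dir, f"ehr-enn-{i}"),
                extra_meta={"vocab_hash": vocab_hash})
            log.info("ehr ENN member %d ready (%.1fs elapsed)", i, time.time() - t0)
        artifacts["enn"] = EnnEstimator(members)
        reports["enn"] = run_ood_experiment(
            artifacts["enn"], ((Xte, mte), yte), ood_sets,
            variant="ehr", q=cfg.percentile, experiment_id="ehr-synthetic",
            metadata={"seed": cfg.seed, "n_patients": cfg.n_patients,
                      "smoke": cfg.smoke, "range_source": "members"})
    if "sngp" in estimators:
        pool = build_ehr_sngp_pool(d_in, cfg.seed, heads=cfg.heads,
                                   rff_dim=cfg.rff_dim,
                                   length_scale=cfg.length_scale, smoke=cfg.smoke)
        for i, m in enumerate(pool):
            pool[i] = _fit_or_load(
                m, ((Xtr, mtr), ytr), ((Xva, mva), yva),
                TrainConfig(**tc, seed=cfg.seed + 200 + i),
                _ckpt_path(checkpoint_dir, f"ehr-sngp-{i}"),
                extra_meta={"vocab_hash": vocab_hash})
            log.info("ehr SNGP model %d ready (%.1fs elapsed)", i, time.time() - t0)
        artifacts["sngp"] = SngpEstimator(pool)
        reports["sngp"] = run_ood_experiment(
            artifacts["sngp"], ((Xte, mte), yte), ood_sets,
            variant="ehr", q=cfg.percentile, experiment_id="ehr-synthetic",
            metadata={"seed": cfg.seed, "n_patients": cfg.n_patients,
                      "smoke": cfg.smoke, "range_source": "models"})
    if return_artifacts:
        return reports, artifacts
    return reports


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def save_reports(reports: dict[str, KuReport], outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, rep in reports.items():
        p = outdir / f"{rep.experiment_id}-{name}.report.yaml"
        rep.save(p)
        paths.append(p)
    return paths


def comparison_table(reports: list[KuReport]) -> str:
    """Side-by-side text table of AUROC/AUPRC (min/max) and undetected-%."""
    if not reports:
        raise ValueError("need at least one report")
    exp_ids = {r.experiment_id for r in reports}
    if len(exp_ids) > 1:
        raise ValueError(f"incompatible experiment ids: {sorted(exp_ids)}")
    lines = [f"experiment: {reports[0].experiment_id}",
             f"{'estimator':<10} {'AUROC (min/max)':<26} {'AUPRC (min/max)':<26} undetected %"]
    for r in reports:
        und = "  ".join(f"{k}={v:.1f}" for k, v in sorted(r.undetected_pct.items()))
        lines.append(
            f"{r.estimator:<10} "
            f"{r.auroc:.3f} ({r.auroc_range[0]:.3f}/{r.auroc_range[1]:.3f})    "
            f"{r.auprc:.3f} ({r.auprc_range[0]:.3f}/{r.auprc_range[1]:.3f})    "
            f"{und}")
    return "\n".join(lines)
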