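"""The combinatorial-generalization experimental protocol.

For each fold, a fresh dataset with a freshly sampled exclusion set is
generated, a model variant (guided / unguided / BU-channel) is trained to a
convergence criterion, and noncombinatorial (NC) vs combinatorial-
generalization (CG) accuracies are logged per epoch.  Variants being compared
consume identical datasets, fold seeds and hyperparameter candidates.

Desk-scale defaults shrink images, backbone and datasets (see the scaling
table in the methods note); the paper-scale dataset sizes remain available
under size="paper" for example-count accounting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cg_tasks
from .model import CounterstreamClassifier


@dataclass
class HPGrid:
    optimizers: tuple = ("sgd-momentum", "adam")
    learning_rates: tuple = (0.0001, 0.001, 0.002, 0.05, 0.1, 0.2)
    batch_sizes: tuple = (10, 32, 48)
    weight_decays: tuple = (0.0001, 0.0002)
    n_sampled_combinations: int = 30

    def all_combinations(self) -> list[dict]:
        return [
            {"optimizer": o, "lr": lr, "batch_size": b, "weight_decay": wd}
            for o, lr, b, wd in itertools.product(
                self.optimizers, self.learning_rates, self.batch_sizes, self.weight_decays
            )
        ]

    def sample(self, seed: int) -> list[dict]:
        """Uniformly sample combinations without replacement (seeded)."""
        combos = self.all_combinations()
        rng = np.random.default_rng(seed)
        n = min(self.n_sampled_combinations, len(combos))
        idx = rng.choice(len(combos), size=n, replace=False)
        return [combos[i] for i in idx]


@dataclass
class RunConfig:
    task: str = "chargrid6"
    model: str = "guided"
    size: str = "scaled"  # sufficient | extended | scaled | paper
    folds: int = 5
    convergence_threshold: float = 1.0  # min improvement (accuracy points)
    convergence_window: int = 300  # epochs
    criterion: float = 85.0  # accuracy criterion on the excluded set
    max_epochs: int = 2000
    seed: int = 0
    hyper: dict = field(default_factory=dict)  # optimizer/lr/batch/weight decay overrides

    def __post_init__(self):
        if self.folds < 1:
            raise ValueError("folds must be >= 1")


# --------------------------------------------------------------------------- scaled task registry

# Desk-scale analogs of the paper-scale tasks (single CPU, minutes not days):
# smaller class counts, images and training sets, shallow backbone.
SCALED_TASKS = {
    "chargrid6": dict(
        family="chargrid", n_classes=6, chars_per_image=6, examples_per_image=5,
        n_images={"scaled": 150, "sufficient": 2500, "extended": 10000, "paper": 2500},
        n_test=100, max_epochs=50, convergence_window=16, channels=(8, 16, 16),
        hyper={"optimizer": "adam", "lr": 0.002, "batch_size": 10, "weight_decay": 0.0001},
    ),
    "chargrid24": dict(
        family="chargrid", n_classes=10, chars_per_image=8, examples_per_image=6,
        n_images={"scaled": 120, "sufficient": 10000, "extended": 40000, "paper": 10000},
        n_test=100, max_epochs=30, convergence_window=10, channels=(8, 16, 16),
        hyper={"optimizer": "adam", "lr": 0.002, "batch_size": 10, "weight_decay": 0.0001},
    ),
    "persons": dict(
        family="persons", n_person_identities=8,
        n_images={"scaled": 150, "sufficient": 1600, "extended": 6400, "paper": 1600},
        n_test=100, max_epochs=50, convergence_window=12, channels=(8, 16, 16),
        hyper={"optimizer": "adam", "lr": 0.002, "batch_size": 10, "weight_decay": 0.0001},
    ),
}


def build_split(task: str, size: str, seed: int, n_excluded_persons_pairs: int = 6):
    """Generate a split plus its task config and encoder for one fold."""
    spec = SCALED_TASKS[task]
    n_images = spec["n_images"][size]
    if spec["family"] == "chargrid":
        n_test = spec["n_test"] if size == "scaled" else 2000
        split = cg_tasks.make_chargrid_dataset(
            n_images=n_images,
            n_classes=spec["n_classes"],
            chars_per_image=spec["chars_per_image"],
            examples_per_image=spec["examples_per_image"] if task != "chargrid24" or size == "scaled" else 16,
            seed=seed,
            n_test_nc=n_test,
            n_test_cg=n_test,
        )
        return split, cg_tasks.chargrid_task_config(split), cg_tasks.encode_chargrid
    n_test = spec["n_test"] if size == "scaled" else 1180
    split = cg_tasks.make_persons_dataset(
        n_images=n_images,
        n_person_identities=spec["n_person_identities"],
        excluded_pairs=n_excluded_persons_pairs,
        seed=seed,
        n_test_nc=n_test,
        n_test_cg=n_test,
    )
    return split, cg_tasks.persons_task_config(split), cg_tasks.encode_persons


def chance_level(task_config) -> float:
    """Chance accuracy (%): 1 / answer-space size, averaged over spaces."""
    sizes = list(task_config.answer_spaces.values())
    return 100.0 * float(np.mean([1.0 / s for s in sizes]))


# --------------------------------------------------------------------------- convergence

def convergence_check(history, window: int, threshold: float) -> bool:
    """True iff max(accuracy over the last `window` epochs) improved on
    max(accuracy before the window) by less than `threshold` points."""
    h = list(history)
    if len(h) < window + 1:
        return False
    return (max(h[-window:]) - max(h[:-window])) < threshold


# --------------------------------------------------------------------------- the experiment

def train_one(
    task: str,
    model: str,
    size: str,
    fold_seed: int,
    hyper: dict | None = None,
    max_epochs: int | None = None,
    convergence_window: int | None = None,
    convergence_threshold: float = 1.0,
) -> tuple[CounterstreamClassifier, pd.DataFrame, dict]:
    """Train one model variant on one freshly generated fold; returns the
    fitted estimator, its per-epoch history and split metadata."""
    spec = SCALED_TASKS[task]
    split, tc, encode = build_split(task, size, seed=fold_seed)
    Xtr, ytr, masks, occ = encode(split, split.train)
    Xnc, ync, _, _ = encode(split, split.test_nc)
    Xcg, ycg, _, _ = encode(split, split.test_cg)
    defaults = dict(spec.get("hyper", {}))
    defaults.update(hyper or {})
    hyper = defaults
    clf = CounterstreamClassifier(
        task_config=tc,
        mode=model,
        channels=spec.get("channels", (8, 16, 16)),
        optimizer=hyper.get("optimizer", "adam"),
        lr=hyper.get("lr", 2e-3),
        batch_size=hyper.get("batch_size", 32),
        weight_decay=hyper.get("weight_decay", 1e-4),
        hidden_readout=128,
        seg_pos_weight=8.0,
        max_epochs=max_epochs if max_epochs is not None else spec["max_epochs"],
        convergence_window=convergence_window if convergence_window is not None else spec["convergence_window"],
        convergence_threshold=convergence_threshold,
        monitor="nc",
        random_state=fold_seed,
    )
    clf.fit(Xtr, ytr, masks=masks, occurrence=occ, eval_sets={"nc": (Xnc, ync), "cg": (Xcg, ycg)})
    meta = {"chance": chance_level(tc), "n_train": len(ytr), "fold_seed": fold_seed}
    return clf, clf.history_, meta


def run_cg_experiment(cfg: RunConfig) -> dict:
    """Run the full protocol for one model variant: `folds` independent folds,
    each on a fresh dataset with a fresh exclusion set.  Returns the per-epoch
    results table, the cross-fold summary and per-fold convergence flags."""
    rows = []
    converged_flags = []
    finals = []
    for fold in range(cfg.folds):
        fold_seed = cfg.seed * 1000 + fold
        clf, hist, meta = train_one(
            cfg.task, cfg.model, cfg.size, fold_seed,
            hyper=cfg.hyper,
            max_epochs=min(cfg.max_epochs, SCALED_TASKS[cfg.task]["max_epochs"]) if cfg.size == "scaled" else cfg.max_epochs,
            convergence_threshold=cfg.convergence_threshold,
        )
        nc_series = hist["nc_acc"].tolist()
        window = clf.convergence_window or cfg.convergence_window
        converged = convergence_check(nc_series, min(window, len(nc_series) - 1 or 1), cfg.convergence_threshold)
        converged_flags.append(bool(converged))
        for _, r in hist.iterrows():
            rows.append(
                {
                    "fold": fold, "epoch": int(r["epoch"]), "nc_acc": r["nc_acc"],
                    "cg_acc": r["cg_acc"], "loss": r["loss"], "model": cfg.model,
                    "task": cfg.task, "chance": meta["chance"],
                }
            )
        finals.append({"fold": fold, "nc_acc": nc_series[-1], "cg_acc": hist["cg_acc"].iloc[-1]})
    table = pd.DataFrame(rows)
    return {
        "table": table,
        "summary": summarize(table),
        "finals": pd.DataFrame(finals),
        "converged": converged_flags,
        "config": cfg,
    }


def summarize(table: pd.DataFrame, window: int = 30) -> pd.DataFrame:
    """Rolling-window mean per fold, then cross-fold mean and SD per epoch.

    A window longer than the history collapses to a single summary point."""
    if table.empty:
        return pd.DataFrame(columns=["epoch", "nc_mean", "nc_sd", "cg_mean", "cg_sd"])
    per_fold = []
    n_epochs = table.groupby("fold")["epoch"].count().min()
    if window > n_epochs:
        g = table.groupby("fold")[["nc_acc", "cg_acc"]].mean()
        return pd.DataFrame(
            {
                "epoch": [int(table["epoch"].max())],
                "nc_mean": [g["nc_acc"].mean()], "nc_sd": [g["nc_acc"].std(ddof=0)],
                "cg_mean": [g["cg_acc"].mean()], "cg_sd": [g["cg_acc"].std(ddof=0)],
            }
        )
    for fold, grp in table.groupby("fold"):
        grp = grp.sort_values("epoch")
        sm = grp[["nc_acc", "cg_acc"]].rolling(window, min_periods=1).mean()
        per_fold.append(pd.DataFrame({"fold": fold, "epoch": grp["epoch"].values,
                                      "nc": sm["nc_acc"].values, "cg": sm["cg_acc"].values}))
    allf = pd.concat(per_fold)
    out = allf.groupby("epoch").agg(
        nc_mean=("nc", "mean"), nc_sd=("nc", lambda s: s.std(ddof=0)),
        cg_mean=("cg", "mean"), cg_sd=("cg", lambda s: s.std(ddof=0)),
    ).reset_index()
    return out


# --------------------------------------------------------------------------- hyperparameter search

def grid_search(cfg: RunConfig, grid: HPGrid, objective=None, models: list[str] | None = None) -> dict:
    """Evaluate sampled hyperparameter combinations — the identical list for
    every model variant — and select per variant by final NC validation
    accuracy.  ``objective(model, combo) -> score`` defaults to a short
    training run."""
    combos = grid.sample(cfg.seed)
    if not combos:
        raise ValueError("empty hyperparameter grid")
    models = models or [cfg.model]

    def default_objective(model, combo):
        _clf, hist, _meta = train_one(
            cfg.task, model, cfg.size, cfg.seed * 1000, hyper=combo,
            max_epochs=min(10, cfg.max_epochs),
        )
        return float(hist["nc_acc"].iloc[-1])

    objective = objective or default_objective
    rows = []
    best = {}
    for model in models:
        scores = []
        for combo in combos:
            score = objective(model, combo)
            if not np.isfinite(score):
                score = -np.inf
            scores.append(score)
            rows.append({"model": model, **combo, "nc_acc": score})
        if all(s == -np.inf for s in scores):
            raise RuntimeError("all hyperparameter runs diverged")
        best[model] = combos[int(np.argmax(scores))]
    return {"best": best, "leaderboard": pd.DataFrame(rows), "combinations": combos}


# --------------------------------------------------------------------------- exclusion-fraction sweep

def run_exclusion_sweep(task: str, models: list[str], fractions: list[float], seed: int = 0) -> pd.DataFrame:
    """Scaled analog of the excluded-fraction stress test: re-run the scaled
    chargrid experiment at increasing exclusion-set sizes and report final CG
    accuracy per model."""
    spec = SCALED_TASKS[task]
    n_classes = spec["n_classes"]
    max_extra = n_classes * (n_classes - 1) - (n_classes - 1)
    rows = []
    for frac in fractions:
        extra = int(round(frac * max_extra))
        split = cg_tasks.make_chargrid_dataset(
            n_images=spec["n_images"]["scaled"], n_classes=n_classes,
            chars_per_image=spec["chars_per_image"],
            examples_per_image=spec["examples_per_image"], seed=seed,
            n_test_nc=spec["n_test"], n_test_cg=spec["n_test"],
            extra_excluded_pairs=extra,
        )
        tc = cg_tasks.chargrid_task_config(split)
        Xtr, ytr, masks, occ = cg_tasks.encode_chargrid(split, split.train)
        Xcg, ycg, _, _ = cg_tasks.encode_chargrid(split, split.test_cg)
        for model in models:
            clf = CounterstreamClassifier(
                task_config=tc, mode=model, max_epochs=spec["max_epochs"],
                convergence_window=spec["convergence_window"], random_state=seed,
            )
            clf.fit(Xtr, ytr, masks=masks, occurrence=occ)
            rows.append({"fraction": frac, "model": model, "cg_acc": 100.0 * clf.score(Xcg, ycg)})
    return pd.DataFrame(rows)
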