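"""The 9-architecture x 2-topology feedforward-network grid over the three
training sets, with the 20-repetition evaluation protocol.

Architectures I-IX map to 1-3 hidden layers in three groups that differ only
in the first-layer neuron cap (n1 for I-III, n2 for IV-VI, n3 for VII-IX).
Topology A repeats the first-layer size in every hidden layer; topology B
shrinks deeper layers as [n, n/2, n/3] (rounded half up).  Every
configuration is trained 20 times on random stratified 70/15/15 splits and
summarised by the element-wise mean confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ann import train_once
from .features import FEATURE_NAMES
from .selection import DesignMatrix

ARCHITECTURES = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX"]
TOPOLOGIES = ["A", "B"]

#: Hidden-layer count per architecture.
ARCH_DEPTH = {
    "I": 1, "II": 2, "III": 3,
    "IV": 1, "V": 2, "VI": 3,
    "VII": 1, "VIII": 2, "IX": 3,
}

#: Which neuron cap (n1/n2/n3) an architecture uses.
ARCH_GROUP = {
    "I": 0, "II": 0, "III": 0,
    "IV": 1, "V": 1, "VI": 1,
    "VII": 2, "VIII": 2, "IX": 2,
}

#: Default (n1, n2, n3) caps per (set_id, topology).
DEFAULT_NMAX = {
    (1, "A"): (45, 40, 35),
    (1, "B"): (40, 30, 25),
    (2, "A"): (36, 30, 20),
    (2, "B"): (36, 30, 20),
    (3, "A"): (9, 6, 4),
    (3, "B"): (9, 6, 4),
}


def _round_half_up(v: float) -> int:
    return int(np.floor(v + 0.5))


def layer_sizes(architecture: str, topology: str, n_first: int) -> list[int]:
    """Resolve hidden-layer sizes for one configuration.

    Topology A: [n, n, ...]; topology B: [n, n/2, n/3] rounded half up,
    truncated to the architecture's depth; every size is at least 1.
    """
    if n_first < 1:
        raise ValueError("n_first must be >= 1")
    depth = ARCH_DEPTH[architecture]
    if topology == "A":
        sizes = [n_first] * depth
    elif topology == "B":
        sizes = [max(1, _round_half_up(n_first / k)) for k in (1, 2, 3)][:depth]
    else:
        raise ValueError(f"unknown topology {topology!r}")
    return sizes


@dataclass
class ANNConfiguration:
    set_id: int
    architecture: str
    topology: str
    n_first: int
    layer_sizes: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.layer_sizes:
            self.layer_sizes = layer_sizes(self.architecture, self.topology,
                                           self.n_first)

    @property
    def key(self) -> str:
        return f"set{self.set_id}-{self.architecture}-{self.topology}"


@dataclass
class EvalResult:
    config: ANNConfiguration
    mean_cm: np.ndarray
    accuracy_mean: float
    accuracy_sd: float
    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float
    mse: float
    per_rep_accuracies: np.ndarray


def performance_P(result: EvalResult | np.ndarray) -> float:
    """Overall performance in %: 100 x trace / total of the mean confusion
    matrix (100 means no misclassifications)."""
    cm = result.mean_cm if isinstance(result, EvalResult) else np.asarray(result)
    total = cm.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    return float(100.0 * np.trace(cm) / total)


def evaluate_configuration(X: np.ndarray, y: np.ndarray,
                           config: ANNConfiguration, reps: int = 20,
                           base_seed: int = 0) -> EvalResult:
    """Train one configuration ``reps`` times and average the confusion
    matrices; accuracy / sensitivity (SF recall) / specificity (NSF recall)
    are summarised over repetitions in percent."""
    seeds = np.random.SeedSequence(base_seed).generate_state(reps)
    cms, mses = [], []
    acc, sens, spec = [], [], []
    for seed in seeds:
        cm, mse, _ = train_once(X, y, config.layer_sizes, int(seed))
        cms.append(cm)
        mses.append(mse)
        acc.append(100.0 * np.trace(cm) / cm.sum())
        pos = cm[0].sum()
        neg = cm[1].sum()
        sens.append(100.0 * cm[0, 0] / pos if pos else np.nan)
        spec.append(100.0 * cm[1, 1] / neg if neg else np.nan)
    acc = np.asarray(acc)
    return EvalResult(
        config=config,
        mean_cm=np.mean(cms, axis=0),
        accuracy_mean=float(acc.mean()),
        accuracy_sd=float(acc.std(ddof=1)),
        sensitivity_mean=float(np.nanmean(sens)),
        sensitivity_sd=float(np.nanstd(sens, ddof=1)),
        specificity_mean=float(np.nanmean(spec)),
        specificity_sd=float(np.nanstd(spec, ddof=1)),
        mse=float(100.0 * np.mean(mses)),
        per_rep_accuracies=acc,
    )


def grid_configurations(set_ids=(1, 2, 3), nmax: dict | None = None,
                        size_overrides: dict | None = None) -> list[ANNConfiguration]:
    """Enumerate the full configuration grid (3 sets x 9 architectures x 2
    topologies = 54 by default).

    ``size_overrides`` maps (set_id, architecture, topology) to explicit
    layer-size lists, for reproducing published grids whose deeper topology-B
    layers deviate from the n/2, n/3 rule.
    """
    nmax = nmax or DEFAULT_NMAX
    size_overrides = size_overrides or {}
    configs = []
    for set_id in set_ids:
        for arch in ARCHITECTURES:
            for topo in TOPOLOGIES:
                n_first = nmax[(set_id, topo)][ARCH_GROUP[arch]]
                cfg = ANNConfiguration(set_id, arch, topo, n_first)
                override = size_overrides.get((set_id, arch, topo))
                if override is not None:
                    cfg.layer_sizes = list(override)
                configs.append(cfg)
    return configs


def run_grid(designs: dict[int, DesignMatrix], nmax: dict | None = None,
             reps: int = 20, base_seed: int = 0,
             size_overrides: dict | None = None,
             architectures: list[str] | None = None):
    """Evaluate every configuration over the provided design matrices.

    Returns (results, failures); a configuration that raises is recorded in
    ``failures`` and the grid continues.  ``architectures`` restricts the
    grid (useful for reduced runs)."""
    configs = grid_configurations(tuple(sorted(designs)), nmax, size_overrides)
    if architectures is not None:
        configs = [c for c in configs if c.architecture in architectures]
    results, failures = [], []
    root = np.random.SeedSequence(base_seed)
    cfg_seeds = root.generate_state(len(configs))
    for config, seed in zip(configs, cfg_seeds):
        design = designs[config.set_id]
        try:
            results.append(
                evaluate_configuration(design.X, design.y, config,
                                       reps=reps, base_seed=int(seed))
            )
        except Exception as exc:
            failures.append({"config": config.key, "error": str(exc)})
    return results, failures


def compare_models(results: list[EvalResult],
                   best: EvalResult | None = None) -> pd.DataFrame:
    """Two-sided Wilcoxon signed-rank tests of each configuration against the
    best one, paired by repetition index; no multiplicity correction.
    All-zero differences give p = 1 by convention."""
    if best is None:
        best = max(results, key=lambda r: r.accuracy_mean)
    rows = []
    for res in results:
        diffs = best.per_rep_accuracies - res.per_rep_accuracies
        if np.allclose(diffs, 0.0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(best.per_rep_accuracies,
                                     res.per_rep_accuracies).pvalue)
        rows.append({
            "config": res.config.key,
            "accuracy_mean": res.accuracy_mean,
            "p_value": p,
            "is_best": res is best,
        })
    return pd.DataFrame(rows)


def summarize_by_group(table: pd.DataFrame, labels) -> pd.DataFrame:
    """Mean +/- SD of each channel-averaged feature per (group, state):
    the tabular SF-vs-NSF comparison of the extracted features."""
    avg = table[table["channel"] == "avg"].copy()
    label_map = labels if isinstance(labels, dict) else dict(
        zip(sorted(avg["subject_id"].unique()), np.asarray(labels))
    )
    if isinstance(labels, pd.Series):
        label_map = labels.to_dict()
    avg["group"] = avg["subject_id"].map(
        lambda s: "SF" if label_map[s] == 1 else "NSF"
    )
    rows = []
    for (group, state), block in avg.groupby(["group", "state"]):
        for feat in FEATURE_NAMES:
            rows.append({
                "group": group, "state": state, "feature": feat,
                "mean": block[feat].mean(), "sd": block[feat].std(ddof=1),
                "n": len(block),
            })
    return pd.DataFrame(rows)


def results_table(results: list[EvalResult]) -> pd.DataFrame:
    """Summary frame mirroring the grid-report layout (one row per
    configuration)."""
    rows = []
    for r in results:
        rows.append({
            "set_id": r.config.set_id,
            "architecture": r.config.architecture,
            "topology": r.config.topology,
            "layer_sizes": "+".join(map(str, r.config.layer_sizes)),
            "P": performance_P(r),
            "accuracy_mean": r.accuracy_mean,
            "accuracy_sd": r.accuracy_sd,
            "sensitivity_mean": r.sensitivity_mean,
            "sensitivity_sd": r.sensitivity_sd,
            "specificity_mean": r.specificity_mean,
            "specificity_sd": r.specificity_sd,
            "mse": r.mse,
        })
    return pd.DataFrame(rows)
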