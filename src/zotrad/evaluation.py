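"""Repeated train/test evaluation of the selection + classification pipeline.

Two pipeline variants differ only in where the GA feature selection sits
relative to the train/test split:

* **Procedure A** — selection on the whole dataset, then a stratified
  80/20 split, decision tree fit on the train rows restricted to the
  selected features, ROC AUC on the test rows.  Selection has seen the
  test rows: any score advantage over Procedure B is feature-selection
  leakage.
* **Procedure B** — split first; the GA sees the training rows only and
  the test rows stay untouched until scoring.

Both procedures are repeated over many stratified splits (default 100)
with per-repeat seeds derived from one master seed; A and B use
identical split sequences so that the placement of selection is the only
difference.  Per-feature selection rates across repeats provide a
stability-based feature-importance ranking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from ._seeds import derive_seed
from .features import FeatureName, FeatureTable
from .selection import GAConfig, evolve

__all__ = [
    "SplitConfig",
    "RepeatOutcome",
    "ProcedureResult",
    "SelectionRateReport",
    "LeakageGuardError",
    "stratified_split",
    "run_procedure_a",
    "run_procedure_b",
    "leakage_gap",
    "selection_rates",
    "summarize",
]


class LeakageGuardError(RuntimeError):
    """Selection was handed rows outside the designated training set."""


@dataclass(frozen=True)
class SplitConfig:
    """Repeated stratified hold-out settings (default 80/20 x 100)."""

    train_fraction: float = 0.8
    n_repeats: int = 100
    master_seed: int = 0


def stratified_split(
    table: FeatureTable, train_fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive row partition preserving class proportions.

    Per class, rows are shuffled (seeded) and the first
    ``round(n_class * train_fraction)`` go to the training set (round
    half up).  Raises if any class would have an empty train or test
    share.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    y = table.labels()
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_tr = int(np.floor(len(idx) * train_fraction + 0.5))
        if n_tr == 0 or n_tr == len(idx):
            raise ValueError(
                f"class {cls}: split {train_fraction} leaves an empty train or test share"
            )
        train.append(idx[:n_tr])
        test.append(idx[n_tr:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


@dataclass
class RepeatOutcome:
    test_auc: float
    selected_names: list[str]
    split_seed: int


@dataclass
class ProcedureResult:
    """Per-repetition test AUCs and selected feature sets for one variant."""

    procedure: str
    per_repeat: list[RepeatOutcome]
    feature_names: list[str]
    table_hash: str
    mean_auc: float = field(init=False)
    sd_auc: float = field(init=False)

    def __post_init__(self) -> None:
        aucs = self.aucs()
        self.mean_auc = float(aucs.mean())
        self.sd_auc = float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0

    def aucs(self) -> np.ndarray:
        return np.array([r.test_auc for r in self.per_repeat])

    @property
    def n_repeats(self) -> int:
        return len(self.per_repeat)

    def to_json(self) -> str:
        return json.dumps(
            {
                "procedure": self.procedure,
                "per_repeat": [asdict(r) for r in self.per_repeat],
                "feature_names": self.feature_names,
                "table_hash": self.table_hash,
                "mean_auc": self.mean_auc,
                "sd_auc": self.sd_auc,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "ProcedureResult":
        d = json.loads(s)
        return cls(
            procedure=d["procedure"],
            per_repeat=[RepeatOutcome(**r) for r in d["per_repeat"]],
            feature_names=d["feature_names"],
            table_hash=d["table_hash"],
        )


def _fit_and_score(
    table: FeatureTable,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    selected: list[str],
    tree_seed: int,
) -> float:
    X = table.X[selected].to_numpy(np.float64) if selected else np.zeros((table.n_samples, 1))
    y = table.labels()
    clf = DecisionTreeClassifier(random_state=tree_seed % 2**31)
    clf.fit(X[train_idx], y[train_idx])
    scores = clf.predict_proba(X[test_idx])
    scores = scores[:, 1] if scores.shape[1] == 2 else np.zeros(len(test_idx))
    return float(roc_auc_score(y[test_idx], scores))


def _guarded_selection(
    view: FeatureTable, allowed_row_ids: list, ga_config: GAConfig
):
    """Run the GA on ``view`` after asserting it contains no foreign rows."""
    if not set(view.row_ids) <= set(allowed_row_ids):
        raise LeakageGuardError(
            "feature selection was handed rows outside the training set"
        )
    return evolve(view, ga_config)


def _run(
    table: FeatureTable,
    ga_config: GAConfig,
    split_config: SplitConfig,
    procedure: str,
) -> ProcedureResult:
    outcomes: list[RepeatOutcome] = []
    for r in range(split_config.n_repeats):
        split_seed = derive_seed(split_config.master_seed, "split", r)
        ga_seed = derive_seed(split_config.master_seed, "ga", r)
        tree_seed = derive_seed(split_config.master_seed, "tree", r)
        tr, te = stratified_split(table, split_config.train_fraction, split_seed)
        cfg = GAConfig(**{**asdict(ga_config), "seed": ga_seed})
        if procedure == "A":
            result = evolve(table, cfg)
        else:
            train_view = table.subset_rows(tr)
            train_ids = [table.row_ids[i] for i in tr]
            result = _guarded_selection(train_view, train_ids, cfg)
        auc = _fit_and_score(table, tr, te, result.selected_names, tree_seed)
        outcomes.append(RepeatOutcome(auc, result.selected_names, split_seed))
    return ProcedureResult(
        procedure=procedure,
        per_repeat=outcomes,
        feature_names=table.feature_names,
        table_hash=table.content_hash(),
    )


def run_procedure_a(
    table: FeatureTable, ga_config: GAConfig, split_config: SplitConfig
) -> ProcedureResult:
    """Selection-before-split: the GA sees the whole dataset each repeat."""
    return _run(table, ga_config, split_config, "A")


def run_procedure_b(
    table: FeatureTable, ga_config: GAConfig, split_config: SplitConfig
) -> ProcedureResult:
    """Split-before-selection: the GA sees training rows only."""
    return _run(table, ga_config, split_config, "B")


def leakage_gap(result_a: ProcedureResult, result_b: ProcedureResult) -> float:
    """Mean test-AUC advantage of selection-before-split over after-split."""
    if result_a.table_hash != result_b.table_hash:
        raise ValueError("results come from different tables")
    if result_a.n_repeats != result_b.n_repeats:
        raise ValueError("results differ in number of repetitions")
    return result_a.mean_auc - result_b.mean_auc


@dataclass
class SelectionRateReport:
    """Per-feature selection frequency across repetitions (percent)."""

    rates: pd.Series  # index: feature name, values in [0, 100]
    n_repeats: int
    top: pd.DataFrame  # columns: feature, rate_percent, region, filter

    def to_csv(self, path: str) -> None:
        df = self.rates.rename("selection_rate_percent").rename_axis("feature")
        df.sort_values(ascending=False).to_csv(path)


def _annotate(name: str) -> tuple[str, str]:
    try:
        fn = FeatureName.parse(name)
    except ValueError:
        return "TUMOR", "none"
    filt = "none"
    if fn.filter_tag:
        filt = "wavelet" if fn.filter_tag.startswith("W-") else "laplacian"
    return fn.region_tag, filt


def selection_rates(result: ProcedureResult, top_k: int = 10) -> SelectionRateReport:
    """Selection-rate feature importance, with region/filter annotation.

    Rate = 100 x (repeats selecting the feature) / n_repeats.  The top-k
    listing is sorted by descending rate, ties broken lexicographically
    by rendered name.
    """
    if not result.per_repeat:
        raise ValueError("empty result")
    counts = pd.Series(0, index=pd.Index(result.feature_names), dtype=float)
    for rep in result.per_repeat:
        counts[rep.selected_names] += 1
    rates = 100.0 * counts / result.n_repeats
    order = sorted(rates.index, key=lambda nm: (-rates[nm], nm))[:top_k]
    top = pd.DataFrame(
        {
            "feature": order,
            "rate_percent": [rates[nm] for nm in order],
            "region": [_annotate(nm)[0] for nm in order],
            "filter": [_annotate(nm)[1] for nm in order],
        }
    )
    return SelectionRateReport(rates=rates, n_repeats=result.n_repeats, top=top)


def summarize(result: ProcedureResult, n_grid: int = 256) -> dict:
    """Mean/sd and density-plot series of the per-repeat AUC distribution.

    Returns a JSON-serializable dict with a histogram (density
    normalized) and, when the spread is nonzero, a Gaussian KDE series
    renormalized to integrate to 1 on its grid.
    """
    aucs = result.aucs()
    out: dict = {
        "procedure": result.procedure,
        "n_repeats": result.n_repeats,
        "mean_auc": float(aucs.mean()),
        "sd_auc": float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
    }
    hist, edges = np.histogram(aucs, bins="auto", density=True)
    out["histogram"] = {"density": hist.tolist(), "edges": edges.tolist()}
    if len(aucs) > 1 and aucs.std() > 0:
        kde = stats.gaussian_kde(aucs)
        lo, hi = aucs.min() - 3 * kde.factor, aucs.max() + 3 * kde.factor
        grid = np.linspace(lo, hi, n_grid)
        dens = kde(grid)
        dens /= np.trapezoid(dens, grid)
        out["kde"] = {"grid": grid.tolist(), "density": dens.tolist()}
    return out
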