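"""Rediscovery-rate evaluation engine.

The central metric is the rediscovery rate (RDR): draw disjoint training and
validation cell sets, rank isoforms by training p-value, and measure the
fraction of the top-ranked set that is significant (p < alpha) in the
validation set.  With simulated ground truth the TrueRDR additionally requires
a rediscovered isoform to be truly differentially expressed, and the RDR ratio
TrueRDR / RDR measures specificity.  Top-k ROC/AUC and the type-I error rate
(FPR) round out the metric set.  All metrics are reported per expression
stratum (high / low) and top fraction, aggregated over replicates.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import CountMatrix, Stratum, stratify_by_expression
from .de_tests import DEResult, run_method
from .sim import SimConfig, SimTruth, make_null_dataset, simulate_dataset

TOP_FRACTIONS = (0.05, 0.10, 0.20, 1.0)


@dataclasses.dataclass(frozen=True)
class SplitPlan:
    """One replicate's disjoint train/validation cell assignment."""

    replicate_index: int
    train_cells: tuple
    validation_cells: tuple

    def __post_init__(self) -> None:
        if set(self.train_cells) & set(self.validation_cells):
            raise ValueError("train and validation cells overlap")


def make_splits(
    m: CountMatrix,
    n_per_set_per_group: int,
    n_replicates: int = 50,
    rng: np.random.Generator | None = None,
) -> list[SplitPlan]:
    """Draw disjoint equal-size train/validation cell sets within each group.

    Per replicate and group, 2k cells are sampled without replacement; the
    first k form the training set and the next k the validation set, so the
    two sets are always disjoint and balanced across groups.
    """
    rng = rng if rng is not None else np.random.default_rng()
    g1, g2 = m.group_masks()
    k = n_per_set_per_group
    for mask, name in ((g1, m.groups()[0]), (g2, m.groups()[1])):
        if 2 * k > mask.sum():
            raise ValueError(
                f"group {name!r} has {int(mask.sum())} cells; "
                f"needs {2 * k} for disjoint sets of {k}"
            )
    plans = []
    for r in range(n_replicates):
        train, val = [], []
        for mask in (g1, g2):
            cells = m.cell_ids[mask]
            perm = rng.permutation(len(cells))
            train.extend(cells[perm[:k]])
            val.extend(cells[perm[k : 2 * k]])
        plans.append(SplitPlan(r + 1, tuple(train), tuple(val)))
    return plans


# -- elementary metrics ----------------------------------------------------


def fpr(result: DEResult, alpha: float = 0.05, subset: Iterable | None = None) -> float:
    """Fraction of subset isoforms with (non-missing) p < alpha."""
    p = result.pvalues
    if subset is not None:
        subset = list(subset)
        if len(subset) == 0:
            raise ValueError("empty subset")
        p = p.loc[subset]
    elif len(p) == 0:
        raise ValueError("empty result")
    vals = p.to_numpy(dtype=float)
    return float(np.sum(vals[np.isfinite(vals)] < alpha) / len(vals))


def top_k(
    result: DEResult, fraction: float, subset: Iterable | None = None
) -> list:
    """The ceil(fraction * |subset|) isoforms with smallest p.

    Ranking is by (p ascending, |statistic| descending, isoform id), which is
    deterministic under ties; missing p-values rank last.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    tab = result.table
    if subset is not None:
        subset = set(subset)
        tab = tab[tab["isoform_id"].isin(subset)]
    if len(tab) == 0:
        raise ValueError("empty subset")
    p = tab["pvalue"].to_numpy(dtype=float)
    p = np.where(np.isfinite(p), p, 2.0)  # missing p ranks last
    s = np.abs(tab["statistic"].to_numpy(dtype=float))
    s = np.where(np.isfinite(s), s, 0.0)
    ids = tab["isoform_id"].to_numpy()
    order = np.lexsort((ids, -s, p))
    k = math.ceil(fraction * len(tab))
    return list(ids[order[:k]])


def rdr(
    train: DEResult,
    validation: DEResult,
    fraction: float,
    alpha: float = 0.05,
    subset: Iterable | None = None,
) -> float:
    """Rediscovery rate: fraction of training top-k significant in validation."""
    top = top_k(train, fraction, subset)
    if len(top) == 0:
        raise ValueError("empty top set")
    pv = validation.pvalues.loc[top].to_numpy(dtype=float)
    sig = np.isfinite(pv) & (pv < alpha)
    return float(sig.sum() / len(top))


def true_rdr(
    train: DEResult,
    validation: DEResult,
    truth: SimTruth,
    fraction: float,
    alpha: float = 0.05,
    subset: Iterable | None = None,
) -> float:
    """RDR restricted to truly DE isoforms (rediscovered AND true DE)."""
    top = top_k(train, fraction, subset)
    if len(top) == 0:
        raise ValueError("empty top set")
    pv = validation.pvalues.loc[top].to_numpy(dtype=float)
    sig = np.isfinite(pv) & (pv < alpha)
    flags = truth.flag_for(top)
    return float((sig & flags).sum() / len(top))


def rdr_ratio(true_rdr_value: float, rdr_value: float) -> float:
    """TrueRDR / RDR; NaN (missing) when the observed RDR is zero."""
    if rdr_value == 0:
        return float("nan")
    return true_rdr_value / rdr_value


def roc_auc(
    result: DEResult,
    truth: SimTruth,
    fraction: float = 1.0,
    subset: Iterable | None = None,
) -> float:
    """Tie-corrected AUC of -log10(p) against truth on the top-k restriction.

    Equals the Mann-Whitney probability that a random true-DE isoform scores
    above a random non-DE isoform (ties count half).  Returns NaN when the
    restriction contains a single class.
    """
    top = top_k(result, fraction, subset)
    pv = result.pvalues.loc[top].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        score = np.where(np.isfinite(pv), -np.log10(np.maximum(pv, 1e-300)), -np.inf)
    labels = truth.flag_for(top)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = stats.rankdata(score)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


# -- benchmark sweep -------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class BenchmarkConfig:
    """Configuration of a full resampling benchmark sweep."""

    methods: tuple = ("wilcoxon",)
    scenario: str = "alternative"  # 'null' regenerates with de_fraction = 0
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    n_per_set_per_group: int = 40
    n_replicates: int = 50
    fractions: tuple = TOP_FRACTIONS
    alpha: float = 0.05
    stratum_threshold: float = 1.0
    stratum_cell_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("null", "alternative"):
            raise ValueError("scenario must be 'null' or 'alternative'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if 2 * self.n_per_set_per_group > self.sim.n_cells_per_group:
            raise ValueError(
                "2 * n_per_set_per_group exceeds the simulated cells per group"
            )


@dataclasses.dataclass
class BenchmarkResult:
    """Tidy long-format metric table plus a failure log."""

    table: pd.DataFrame  # method, replicate, stratum, top_fraction, metric, value
    failures: list

    def summary(self) -> pd.DataFrame:
        """Median and quartiles per (method, stratum, top_fraction, metric)."""
        return (
            self.table.groupby(["method", "stratum", "top_fraction", "metric"])["value"]
            .describe(percentiles=[0.25, 0.5, 0.75])
            .reset_index()[
                ["method", "stratum", "top_fraction", "metric", "count", "25%", "50%", "75%"]
            ]
            .rename(columns={"25%": "q1", "50%": "median", "75%": "q3"})
        )


def _replicate_records(
    cfg: BenchmarkConfig, rep: int, failures: list
) -> list[dict]:
    ss = np.random.SeedSequence([int(cfg.seed) % (2**31), rep])
    sim_rng, split_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    sim_cfg = cfg.sim
    if cfg.scenario == "null":
        sim_cfg = dataclasses.replace(sim_cfg, de_fraction=0.0)
    matrix, truth = simulate_dataset(sim_cfg, rng=sim_rng)
    plan = make_splits(matrix, cfg.n_per_set_per_group, 1, rng=split_rng)[0]
    m_train = matrix.subset_cells(np.asarray(plan.train_cells, dtype=object))
    m_val = matrix.subset_cells(np.asarray(plan.validation_cells, dtype=object))
    high, low = stratify_by_expression(
        m_train, cfg.stratum_threshold, cfg.stratum_cell_fraction
    )
    records = []
    for method in cfg.methods:
        try:
            res_train = run_method(method, m_train)
            res_val = run_method(method, m_val)
        except Exception as exc:
            failures.append({"method": method, "replicate": rep, "error": str(exc)})
            continue
        for stratum in (high, low):
            if len(stratum) == 0:
                failures.append(
                    {"method": method, "replicate": rep,
                     "error": f"empty stratum {stratum.name}"}
                )
                continue
            ids = stratum.member_ids
            f = fpr(res_train, cfg.alpha, ids)
            for frac in cfg.fractions:
                r = rdr(res_train, res_val, frac, cfg.alpha, ids)
                tr = true_rdr(res_train, res_val, truth, frac, cfg.alpha, ids)
                ratio = rdr_ratio(tr, r)
                auc = roc_auc(res_train, truth, frac, ids)
                for metric, value in (
                    ("FPR", f),
                    ("RDR", r),
                    ("TrueRDR", tr),
                    ("RDR_ratio", ratio),
                    ("AUC", auc),
                ):
                    if not np.isfinite(value):
                        failures.append(
                            {"method": method, "replicate": rep,
                             "error": f"missing {metric} ({stratum.name}, {frac})"}
                        )
                        continue
                    records.append(
                        {
                            "method": method,
                            "replicate": rep,
                            "stratum": stratum.name,
                            "top_fraction": frac,
                            "metric": metric,
                            "value": value,
                        }
                    )
    return records


def run_benchmark(cfg: BenchmarkConfig) -> BenchmarkResult:
    """Run the full simulate / split / test / score sweep.

    Per replicate: simulate a data set (regenerated with no DE under the null
    scenario), draw one disjoint train/validation split, run every configured
    method on both halves, and record FPR, RDR, TrueRDR, RDR ratio and AUC per
    stratum and top fraction.  Failures in one (method, replicate) are logged
    and never abort the sweep.  The per-replicate random streams are derived
    independently from the global seed, so adding a method leaves the
    simulator's draws unchanged.
    """
    failures: list = []
    records: list = []
    for rep in range(1, cfg.n_replicates + 1):
        records.extend(_replicate_records(cfg, rep, failures))
    table = pd.DataFrame(
        records,
        columns=["method", "replicate", "stratum", "top_fraction", "metric", "value"],
    )
    return BenchmarkResult(table=table, failures=failures)


def run_null_resampling(
    m: CountMatrix,
    methods: Sequence[str],
    n_per_group: int,
    n_replicates: int,
    alpha: float = 0.05,
    seed: int = 0,
) -> BenchmarkResult:
    """Type-I-error sweep on a user matrix via label-ignoring resampling.

    For real (non-simulated) matrices the null is constructed by pooling the
    cells and drawing pseudo-groups, rather than regenerating data.
    """
    failures: list = []
    records: list = []
    for rep in range(1, n_replicates + 1):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), rep]))
        null = make_null_dataset(m, n_per_group, rng)
        high, low = stratify_by_expression(null)
        for method in methods:
            try:
                res = run_method(method, null)
            except Exception as exc:
                failures.append({"method": method, "replicate": rep, "error": str(exc)})
                continue
            for stratum in (high, low):
                if len(stratum) == 0:
                    continue
                records.append(
                    {
                        "method": method,
                        "replicate": rep,
                        "stratum": stratum.name,
                        "top_fraction": 1.0,
                        "metric": "FPR",
                        "value": fpr(res, alpha, stratum.member_ids),
                    }
                )
    table = pd.DataFrame(
        records,
        columns=["method", "replicate", "stratum", "top_fraction", "metric", "value"],
    )
    return BenchmarkResult(table=table, failures=failures)
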