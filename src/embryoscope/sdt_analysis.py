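"""Signal-detection statistics for the binary categorisation task.

Sensitivity is the equal-variance Gaussian d' = z(H) - z(F) with z the
inverse standard-normal CDF.  Hits and false alarms are designated on
category P: a hit is a correct classification of a P stimulus, a false alarm
an incorrect classification of a P stimulus (i.e., responding P to a Q
stimulus); the designation is arbitrary and swapping it leaves equal-variance
d' unchanged.  A hit rate of 0.80 with a false-alarm rate of 0.20 gives
d' = 1.68, the training criterion.

Also provided: exact-binomial / Gaussian chance thresholds for a block of
trials, learning summaries (blocks to criterion across subjects), classical
paired-t / one-way ANOVA / Pearson tests, and condition-level reports with
seeded bootstrap confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy import stats
from scipy.special import ndtri


class DegenerateInputError(ValueError):
    """A statistic's denominator is zero (e.g. zero-variance input)."""


class ExtremeRateError(ValueError):
    """Hit/FA rate of exactly 0 or 1 with correction='none': d' is infinite."""


# --------------------------------------------------------------------------- #
# d-prime

@dataclass(frozen=True)
class SDTResult:
    """2x2 tally of a block of binary decisions, with derived rates.

    Rates reflect the chosen correction: with ``log_linear`` 0.5 is added to
    each of the four counts before forming rates, keeping d' finite.
    """

    n_hit: int
    n_miss: int
    n_fa: int
    n_cr: int
    correction: str = "none"   # "none" | "log_linear"

    def __post_init__(self) -> None:
        if min(self.n_hit, self.n_miss, self.n_fa, self.n_cr) < 0:
            raise ValueError("counts must be >= 0")
        if self.correction not in ("none", "log_linear"):
            raise ValueError("correction must be 'none' or 'log_linear'")

    @property
    def n_trials(self) -> int:
        return self.n_hit + self.n_miss + self.n_fa + self.n_cr

    @property
    def hit_rate(self) -> float:
        if self.correction == "log_linear":
            return (self.n_hit + 0.5) / (self.n_hit + self.n_miss + 1.0)
        denom = self.n_hit + self.n_miss
        if denom == 0:
            raise DegenerateInputError("no positive-category trials")
        return self.n_hit / denom

    @property
    def fa_rate(self) -> float:
        if self.correction == "log_linear":
            return (self.n_fa + 0.5) / (self.n_fa + self.n_cr + 1.0)
        denom = self.n_fa + self.n_cr
        if denom == 0:
            raise DegenerateInputError("no negative-category trials")
        return self.n_fa / denom

    @property
    def dprime(self) -> float:
        return compute_dprime(self)

    def with_correction(self, correction: str) -> "SDTResult":
        return SDTResult(self.n_hit, self.n_miss, self.n_fa, self.n_cr, correction)


def tally_sdt(
    trials: Iterable[tuple[str, str]] | Iterable,
    positive_category: str = "P",
    correction: str = "none",
) -> SDTResult:
    """Tally (response, true_label) pairs into the SDT 2x2 table.

    A hit is responding ``positive_category`` when it is the true label; a
    false alarm is responding it when it is not.  Accepts (response, label)
    tuples or objects with ``response`` / ``true_label`` attributes.
    """
    n_hit = n_miss = n_fa = n_cr = 0
    for t in trials:
        if isinstance(t, tuple):
            response, label = t
        else:
            response, label = t.response, t.true_label
        if response not in ("P", "Q") or label not in ("P", "Q"):
            raise ValueError(f"labels must be 'P' or 'Q', got {response!r}/{label!r}")
        if label == positive_category:
            if response == positive_category:
                n_hit += 1
            else:
                n_miss += 1
        else:
            if response == positive_category:
                n_fa += 1
            else:
                n_cr += 1
    return SDTResult(n_hit, n_miss, n_fa, n_cr, correction)


def dprime_from_rates(hit_rate: float, fa_rate: float) -> float:
    """d' = z(H) - z(F); rates must lie strictly inside (0, 1)."""
    if not (0.0 < hit_rate < 1.0 and 0.0 < fa_rate < 1.0):
        raise ExtremeRateError(
            f"rates must be strictly inside (0, 1); got H={hit_rate}, F={fa_rate}"
        )
    return float(ndtri(hit_rate) - ndtri(fa_rate))


def compute_dprime(result: SDTResult, correction: Optional[str] = None) -> float:
    """d' of a tally, optionally overriding its stored correction.

    With ``none``, extreme rates (0 or 1) raise ExtremeRateError rather than
    returning a silent infinity; ``log_linear`` is always finite.
    """
    if correction is not None:
        result = result.with_correction(correction)
    return dprime_from_rates(result.hit_rate, result.fa_rate)


# --------------------------------------------------------------------------- #
# chance thresholds

def block_chance_threshold(
    n_trials: int, alpha: float = 0.05, method: str = "binomial_exact"
) -> tuple[int, float]:
    """Minimum correct count in a block that is significantly above chance.

    Returns ``(k, dprime)``: the smallest k with P(X >= k) <= alpha for
    X ~ Binomial(n, 1/2) (or its Gaussian approximation), and the d' of a
    balanced block at accuracy k/n (per-category rates equal to the overall
    accuracy).  At n=40, alpha=0.05 the exact threshold is k=26.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if method == "binomial_exact":
        # P(X >= k) = sf(k - 1)
        ks = np.arange(0, n_trials + 1)
        tail = stats.binom.sf(ks - 1, n_trials, 0.5)
        passing = ks[tail <= alpha]
        k = int(passing[0]) if len(passing) else n_trials + 1
    elif method == "gaussian":
        # smallest k with 1 - Phi((k - n/2) / sqrt(n/4)) <= alpha
        z = stats.norm.isf(alpha)
        k = int(math.ceil(n_trials / 2.0 + z * math.sqrt(n_trials / 4.0)))
        k = min(k, n_trials + 1)
    else:
        raise ValueError("method must be 'binomial_exact' or 'gaussian'")
    if k > n_trials:
        dprime = math.inf
    else:
        acc = k / n_trials
        acc = min(acc, 1.0 - 1e-12)
        dprime = float(2.0 * ndtri(acc)) if acc > 0.0 else -math.inf
    return k, dprime


# --------------------------------------------------------------------------- #
# classical tests

@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    name: str


def paired_ttest(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided paired t-test; identical vectors give t = 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired inputs must have matching lengths")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.allclose(d, d[0]) and not np.allclose(d, 0.0):
        raise DegenerateInputError("zero variance of paired differences")
    if np.allclose(d, 0.0):
        return TestResult(0.0, len(x) - 1, 1.0, "paired_t")
    res = stats.ttest_rel(x, y)
    return TestResult(float(res.statistic), float(len(x) - 1), float(res.pvalue), "paired_t")


def oneway_anova(*groups: Sequence[float]) -> TestResult:
    """One-way ANOVA F over >= 2 groups; df reported as between df."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in arrays):
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate(arrays)
    if np.allclose(pooled.var(), 0.0):
        raise DegenerateInputError("zero total variance")
    res = stats.f_oneway(*arrays)
    return TestResult(
        float(res.statistic), float(len(arrays) - 1), float(res.pvalue), "oneway_anova"
    )


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson r with df = n - 2 and a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched vectors of length >= 3")
    if np.allclose(x.var(), 0.0) or np.allclose(y.var(), 0.0):
        raise DegenerateInputError("zero variance input to correlation")
    res = stats.pearsonr(x, y)
    return TestResult(float(res.statistic), float(len(x) - 2), float(res.pvalue), "pearson_r")


# --------------------------------------------------------------------------- #
# learning summaries

@dataclass(frozen=True)
class LearningSummary:
    """Blocks-to-criterion across subjects.

    SEM uses the unbiased (n-1) sd; for a single subject the SEM is reported
    as 0 by convention.  Non-converged subjects are listed separately and
    excluded from the moments.
    """

    blocks_to_criterion: dict[str, int]
    non_converged: tuple[str, ...]
    mean: float
    median: float
    sem: float
    range: tuple[int, int]

    @property
    def n(self) -> int:
        return len(self.blocks_to_criterion)


def summarize_learning(
    logs: Sequence,
    threshold: float = 1.68,
    run_length: int = 3,
) -> Optional[LearningSummary]:
    """Cross-subject summary of training duration from criterion-phase logs.

    Each log must expose ``subject_id`` and per-block d' values via
    ``block_dprimes()``; blocks-to-criterion is the block completing the
    first qualifying run.  Returns None for empty input.
    """
    from .experiment_engine import reached_criterion

    if not logs:
        return None
    reached: dict[str, int] = {}
    failed: list[str] = []
    for log in logs:
        idx = reached_criterion(log.block_dprimes(), threshold, run_length)
        if idx is None:
            failed.append(log.subject_id)
        else:
            reached[log.subject_id] = idx
    if not reached:
        return LearningSummary({}, tuple(failed), math.nan, math.nan, math.nan, (0, 0))
    vals = np.array(sorted(reached.values()))
    sem = 0.0 if len(vals) == 1 else float(vals.std(ddof=1) / math.sqrt(len(vals)))
    return LearningSummary(
        blocks_to_criterion=reached,
        non_converged=tuple(failed),
        mean=float(vals.mean()),
        median=float(np.median(vals)),
        sem=sem,
        range=(int(vals.min()), int(vals.max())),
    )


# --------------------------------------------------------------------------- #
# condition reports

#: Stable column order of condition_report output.
REPORT_COLUMNS = [
    "condition",
    "n_trials",
    "accuracy",
    "dprime",
    "dprime_lo",
    "dprime_hi",
    "above_chance",
    "mean_our",
    "mean_oer",
]


def _bootstrap_dprime_ci(
    records: list[tuple[str, str]],
    n_boot: int,
    alpha: float,
    seed: int,
) -> tuple[float, float]:
    rng = default_rng(seed)
    responses = np.array([r for r, _ in records])
    labels = np.array([l for _, l in records])
    n = len(records)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        tally = tally_sdt(
            list(zip(responses[idx], labels[idx])), correction="log_linear"
        )
        boots[i] = compute_dprime(tally)
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def condition_report(
    conditions: dict[str, tuple],
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """One row per condition: accuracy, d' with bootstrap CI, mean ratings.

    ``conditions`` maps a condition name to ``(log, ratings)`` where ``log``
    exposes ``records`` (with response/true_label/correct) and ``ratings`` is
    a possibly-empty sequence of RatingRecord.  CIs are seeded percentile
    bootstraps (log-linear d'); ``above_chance`` flags CIs excluding 0.
    """
    rows = []
    for i, (name, (log, ratings)) in enumerate(conditions.items()):
        records = [(r.response, r.true_label) for r in log.records]
        if not records:
            raise ValueError(f"condition {name!r} has no trials")
        accuracy = float(np.mean([r.correct for r in log.records]))
        tally = tally_sdt(records, correction="log_linear")
        dp = compute_dprime(tally)
        lo, hi = _bootstrap_dprime_ci(records, n_boot, alpha, seed + i)
        rows.append(
            {
                "condition": name,
                "n_trials": len(records),
                "accuracy": accuracy,
                "dprime": dp,
                "dprime_lo": lo,
                "dprime_hi": hi,
                "above_chance": bool(lo > 0.0),
                "mean_our": float(np.mean([r.our for r in ratings])) if ratings else math.nan,
                "mean_oer": float(np.mean([r.oer for r in ratings])) if ratings else math.nan,
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


# --------------------------------------------------------------------------- #
# plotting (optional outputs; Agg-safe)

def plot_learning_curve(
    block_dprimes: Sequence[float],
    path,
    threshold: float = 1.68,
    chance_dprime: Optional[float] = None,
) -> None:
    """Per-block d' trajectory with the criterion and chance lines."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    blocks = np.arange(1, len(block_dprimes) + 1)
    ax.plot(blocks, block_dprimes, "o-", color="tab:blue")
    ax.axhline(threshold, color="tab:red", ls=":", label=f"criterion d'={threshold}")
    if chance_dprime is not None:
        ax.axhline(chance_dprime, color="gray", ls="--", label="p<0.05 vs chance")
    ax.set_xlabel("trial block")
    ax.set_ylabel("d'")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_condition_report(report: pd.DataFrame, path) -> None:
    """Bar chart of d' per condition with bootstrap CIs."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    x = np.arange(len(report))
    err = np.vstack(
        [report["dprime"] - report["dprime_lo"], report["dprime_hi"] - report["dprime"]]
    )
    ax.bar(x, report["dprime"], yerr=err, color="tab:green", capsize=3)
    ax.set_xticks(x)
    ax.set_xticklabels(report["condition"], rotation=30, ha="right", fontsize=8)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_ylabel("d'")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
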