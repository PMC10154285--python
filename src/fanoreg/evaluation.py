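"""Benchmarking utilities: hypergeometric random-classifier comparison and
confusion summaries of inference reports against synthetic truth labels."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy import stats

from fanoreg.inference import InferenceReport

__all__ = ["ClassifierComparison", "random_classifier_comparison", "confusion_vs_truth"]


@dataclass(frozen=True)
class ClassifierComparison:
    """How a method's hit count compares with a random picker of equal size.

    ``X ~ Hypergeometric(N, K, n_picked)`` is the hit count of a classifier
    that picks ``n_picked`` of ``N`` genes uniformly at random against a
    reference set of ``K`` positives; probabilities are fractions in [0, 1].
    """

    N: int
    K: int
    n_picked: int
    k_hits: int
    p_worse: float  # P(X < k_hits): random classifier strictly worse
    p_better: float  # P(X > k_hits)
    p_tie: float


def random_classifier_comparison(
    N: int, K: int, n_picked: int, k_hits: int
) -> ClassifierComparison:
    """Exact tail probabilities for the random-picker comparison.

    "Worse"/"better" are strict inequalities on hit count; ties are
    reported separately so the three probabilities sum to one.
    """
    if not 0 <= K <= N:
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not 0 <= n_picked <= N:
        raise ValueError(f"need 0 <= n_picked <= N, got {n_picked}")
    if not 0 <= k_hits <= min(n_picked, K):
        raise ValueError(f"k_hits={k_hits} infeasible for n_picked={n_picked}, K={K}")
    dist = stats.hypergeom(N, K, n_picked)
    return ClassifierComparison(
        N=N,
        K=K,
        n_picked=n_picked,
        k_hits=k_hits,
        p_worse=float(dist.cdf(k_hits - 1)),
        p_better=float(dist.sf(k_hits)),
        p_tie=float(dist.pmf(k_hits)),
    )


def confusion_vs_truth(report: InferenceReport, truth: Mapping[str, str]) -> pd.DataFrame:
    """Cross-tabulate inference calls against ground-truth labels.

    Rows are calls, columns truth labels.  ``undetermined`` is abstention,
    not a negative prediction -- the table should be read accordingly.
    """
    report_genes = {gc.gene for gc in report.calls}
    if report_genes != set(truth):
        missing = report_genes ^ set(truth)
        raise ValueError(f"gene sets differ between report and truth: {sorted(missing)[:5]} ...")
    rows = [{"call": gc.call.value, "truth": truth[gc.gene]} for gc in report.calls]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame()
    return pd.crosstab(df["call"], df["truth"])
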