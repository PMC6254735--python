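"""Enrichment scoring and significance against a synonymous null.

Per biological replicate, a design's enrichment score is

    W_i = log2( (post_count / post_total) / (pre_count / pre_total) )

with a post-selection count of 0 replaced by 0.5, and designs with a
pre-selection count below 10 masked for that replicate only.  Replicates
combine by the count-weighted average W_avg = sum(C_i W_i) / sum(C_i).
Significance is called against the distribution of synonymous-design
scores: a design is enriched when W_avg >= mu + 2 sigma (depleted calls
are reported symmetrically), with a bootstrap CI on mu for reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quant import CountMatrix, SampleSheet

PRE_COUNT_MIN = 10
ZERO_FLOOR = 0.5
BOOTSTRAP_B = 20000


def enrichment_score(
    pre_count: float, post_count: float, pre_total: int, post_total: int
) -> float:
    """Log2 frequency ratio of one design between post and pre samples."""
    if pre_total <= 0 or post_total <= 0:
        raise ValueError("empty sample")
    if pre_count <= 0:
        raise ValueError("pre-selection count must be positive after filtering")
    post = ZERO_FLOOR if post_count == 0 else post_count
    return float(np.log2((post / post_total) / (pre_count / pre_total)))


def enrichment_scores(
    pre: np.ndarray, post: np.ndarray, pre_total: int, post_total: int
) -> np.ndarray:
    """Vectorized :func:`enrichment_score`; caller masks low pre counts."""
    if pre_total <= 0 or post_total <= 0:
        raise ValueError("empty sample")
    pre = np.asarray(pre, dtype=float)
    post = np.where(np.asarray(post, dtype=float) == 0, ZERO_FLOOR, post)
    return np.log2((post / post_total) / (pre / pre_total))


def weighted_average(per_replicate: Sequence[tuple[float, float]]) -> float:
    """Count-weighted average of replicate scores: sum(C W) / sum(C)."""
    weights = np.array([c for c, _ in per_replicate], dtype=float)
    scores = np.array([w for _, w in per_replicate], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("no weight")
    return float(np.sum(weights * scores) / weights.sum())


@dataclass(frozen=True)
class NullModel:
    """Synonymous-score null: mean, spread, and a bootstrap CI on the mean."""

    mu: float
    sigma: float
    ci_low: float
    ci_high: float
    B: int
    seed: int
    n: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mu <= self.ci_high):
            raise ValueError("CI must bracket mu")


def fit_null(
    synonymous_scores: Sequence[float], B: int = BOOTSTRAP_B, seed: int = 0
) -> NullModel:
    """Fit the synonymous null and bootstrap a 95% CI for its mean.

    ``B`` resamples of size n with replacement; 2.5th/97.5th percentiles of
    the resampled means form the CI.  Fully seeded and reproducible.
    """
    scores = np.asarray(list(synonymous_scores), dtype=float)
    if scores.size < 2:
        raise ValueError("null underdetermined")
    mu = float(scores.mean())
    sigma = float(scores.std(ddof=1))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, scores.size, size=(B, scores.size))
    boot_means = scores[idx].mean(axis=1)
    ci_low, ci_high = np.percentile(boot_means, [2.5, 97.5])
    return NullModel(
        mu=mu, sigma=sigma, ci_low=float(ci_low), ci_high=float(ci_high),
        B=B, seed=seed, n=scores.size,
    )


def call_significant(w_avg: float, null: NullModel) -> tuple[bool, bool, float]:
    """(enriched, depleted, one-sided p) against the synonymous null.

    Enriched iff w_avg >= mu + 2 sigma (inclusive); depleted symmetric at
    mu - 2 sigma.  The p-value is the upper normal tail of N(mu, sigma^2);
    with sigma = 0 it degenerates to {0, 1}.
    """
    if null.sigma == 0:
        enriched = w_avg > null.mu
        depleted = w_avg < null.mu
        return enriched, depleted, 0.0 if enriched else 1.0
    enriched = w_avg >= null.mu + 2 * null.sigma
    depleted = w_avg <= null.mu - 2 * null.sigma
    p = float(stats.norm.sf(w_avg, loc=null.mu, scale=null.sigma))
    return enriched, depleted, p


def condition_pvalue(
    w_avg: float, all_scores: Sequence[float], method: str = "normal"
) -> float:
    """One-sided upper-tail p of ``w_avg`` among all scored designs.

    ``method='normal'`` fits a normal to the condition's score distribution;
    ``method='empirical'`` uses the add-one-smoothed empirical tail
    (1 + #{scores > w}) / (n + 1), so the maximum observed score gets
    p = 1/(n+1).
    """
    scores = np.asarray(list(all_scores), dtype=float)
    if scores.size < 10:
        raise ValueError("too few scores in condition")
    if method == "normal":
        return float(stats.norm.sf(w_avg, loc=scores.mean(), scale=scores.std(ddof=1)))
    if method == "empirical":
        return float((1 + np.sum(scores > w_avg)) / (scores.size + 1))
    raise ValueError(f"unknown method {method!r}")


def filter_low_counts(
    counts: CountMatrix, sheet: SampleSheet, threshold: int = PRE_COUNT_MIN
) -> dict[tuple[str, int], pd.Series]:
    """Per-replicate retention mask: pre-selection count >= threshold.

    Masking is per replicate: a design failing in one replicate can still
    score in another.  Keys are (condition, replicate).
    """
    masks = {}
    for pre, post in sheet.pairs():
        if pre is None:
            raise ValueError("unpaired sample")
        masks[(post.condition, post.replicate)] = (
            counts.counts[pre.sample_id] >= threshold
        )
    return masks


def score_experiment(
    counts: CountMatrix,
    sheet: SampleSheet,
    manifest: pd.DataFrame,
    threshold: int = PRE_COUNT_MIN,
    weight_phase: str = "pre",
    B: int = BOOTSTRAP_B,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, NullModel]]:
    """Score every design in every condition and call significance.

    ``manifest`` must carry design_id, gene and is_synonymous columns.
    The weight C_i in the weighted average is the replicate's count in
    ``weight_phase`` ('pre' by default; 'post' or 'pre+post' available).
    Returns the per-design results table and the fitted null per condition.
    """
    if weight_phase not in ("pre", "post", "pre+post"):
        raise ValueError("weight_phase must be pre, post or pre+post")
    manifest = manifest.set_index("design_id") if "design_id" in manifest.columns else manifest
    masks = filter_low_counts(counts, sheet, threshold)

    rows = []
    conditions = sorted({s.condition for s in sheet.samples})
    for condition in conditions:
        pairs = [
            (pre, post) for pre, post in sheet.pairs() if post.condition == condition
        ]
        per_design: dict[str, list[tuple[float, float]]] = {}
        for pre, post in pairs:
            keep = masks[(condition, post.replicate)]
            pre_col = counts.counts[pre.sample_id]
            post_col = counts.counts[post.sample_id]
            pre_total = int(counts.matched_reads[pre.sample_id])
            post_total = int(counts.matched_reads[post.sample_id])
            kept = keep[keep].index
            w = enrichment_scores(
                pre_col[kept].to_numpy(), post_col[kept].to_numpy(),
                pre_total, post_total,
            )
            for design_id, w_i, c_pre, c_post in zip(
                kept, w, pre_col[kept], post_col[kept]
            ):
                if weight_phase == "pre":
                    c = float(c_pre)
                elif weight_phase == "post":
                    c = float(c_post)
                else:
                    c = float(c_pre + c_post)
                per_design.setdefault(design_id, []).append((c, float(w_i)))
        for design_id, reps in per_design.items():
            rows.append(
                {
                    "design_id": design_id,
                    "condition": condition,
                    "gene": manifest.loc[design_id, "gene"],
                    "is_synonymous": bool(manifest.loc[design_id, "is_synonymous"]),
                    "n_replicates": len(reps),
                    "w_avg": weighted_average(reps),
                }
            )
    results = pd.DataFrame(rows)
    if results.empty:
        return results, {}

    nulls: dict[str, NullModel] = {}
    enriched, depleted, pvals = [], [], []
    for condition, sub in results.groupby("condition", sort=True):
        syn = sub.loc[sub["is_synonymous"], "w_avg"]
        nulls[condition] = fit_null(syn.to_numpy(), B=B, seed=seed)
    for row in results.itertuples():
        e, d, p = call_significant(row.w_avg, nulls[row.condition])
        enriched.append(e)
        depleted.append(d)
        pvals.append(p)
    results["enriched"] = enriched
    results["depleted"] = depleted
    results["p_value"] = pvals
    return results, nulls


def summarize(
    results: pd.DataFrame, annotation: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Roll significant-enrichment counts up by gene and by category.

    ``annotation`` maps gene -> category (biosynthesis, degradation,
    regulation, transport); every scored gene must be annotated.
    """
    missing = sorted(set(results["gene"]) - set(annotation))
    if missing:
        raise ValueError(f"unannotated gene(s): {missing}")
    res = results.copy()
    res["category"] = res["gene"].map(annotation)

    def roll(group_col: str) -> pd.DataFrame:
        g = res.groupby(["condition", group_col])
        out = g.agg(
            n_scored=("design_id", "size"),
            n_enriched=("enriched", "sum"),
            n_depleted=("depleted", "sum"),
            mean_w=("w_avg", "mean"),
            median_w=("w_avg", "median"),
        ).reset_index()
        out["n_enriched"] = out["n_enriched"].astype(int)
        out["n_depleted"] = out["n_depleted"].astype(int)
        return out

    return roll("gene"), roll("category")
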