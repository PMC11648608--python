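"""Min-max normalization and the 0-100 multicriteria synthesis score.

Replacement outcomes (percentage changes per domain) are normalized within
a pool of candidate foods so the best performer in each domain scores 1 and
the worst scores 0 — ``score(x) = 1 - (x - best) / (worst - best)``, where
"best" is the most favorable (most negative) change. Subdomain scores are
then averaged with the weighting tree: health, environment, and cost count
one third each; nutrition and mortality split the health third; GHG, land,
and water split the environment third with planetary-boundary weights
(0.65/0.17/0.18). The result is scaled to 0-100 and ranked.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import pandas as pd

from .core_tables import DOMAINS, SynthesisWeights, TableError

#: Alternative weighting schemes shipped for sensitivity comparisons.
WEIGHT_SCHEMES: dict[str, SynthesisWeights] = {
    "main": SynthesisWeights(),
    "equal_env": SynthesisWeights(ghg=1 / 3, land=1 / 3, water=1 / 3),
    # equal weight on each of the six subdomains: top-level weights become
    # 2/6 health, 3/6 environment, 1/6 cost with uniform subweights
    "equal_subdomains": SynthesisWeights(
        health=2 / 6,
        environment=3 / 6,
        cost=1 / 6,
        nutrition=0.5,
        mortality=0.5,
        ghg=1 / 3,
        land=1 / 3,
        water=1 / 3,
    ),
}

_DOMAIN_TO_SUBSCORE = {
    "nutrition_pp": "nutrition",
    "mortality_pct": "mortality",
    "ghg_pct": "ghg",
    "land_pct": "land",
    "water_pct": "water",
    "cost_pct": "cost",
}


def normalize_changes(changes: Mapping[str, float]) -> dict[str, float]:
    """Min-max normalize one domain's changes across foods to [0, 1].

    The most favorable change (largest reduction) maps to 1, the least
    favorable to 0. A degenerate pool (all changes equal) carries no
    information and scores every food 1, with a warning.
    """
    if len(changes) < 2:
        raise TableError("normalization needs at least two foods")
    values = {k: float(v) for k, v in changes.items()}
    best = min(values.values())
    worst = max(values.values())
    if worst == best:
        warnings.warn(
            "degenerate spread in domain changes (all equal); scoring all foods 1",
            stacklevel=2,
        )
        return {k: 1.0 for k in values}
    return {k: 1.0 - (v - best) / (worst - best) for k, v in values.items()}


def summary_score(
    normalized: Mapping[str, float], weights: SynthesisWeights | None = None
) -> float:
    """Weighted 0-100 score from six normalized subdomain scores."""
    if weights is None:
        weights = SynthesisWeights()
    missing = set(_DOMAIN_TO_SUBSCORE.values()) - set(normalized)
    if missing:
        raise TableError(f"missing subdomain scores: {sorted(missing)}")
    health = weights.nutrition * normalized["nutrition"] + weights.mortality * normalized["mortality"]
    env = (
        weights.ghg * normalized["ghg"]
        + weights.land * normalized["land"]
        + weights.water * normalized["water"]
    )
    return 100.0 * (
        weights.health * health + weights.environment * env + weights.cost * normalized["cost"]
    )


def rank_foods(scores: Mapping[str, float]) -> list[tuple[str, float, int]]:
    """Descending by score; ties broken lexicographically by food id."""
    if not scores:
        raise TableError("no scores to rank")
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(fid, score, rank) for rank, (fid, score) in enumerate(ordered, start=1)]


def synthesize(
    changes: pd.DataFrame,
    weights: SynthesisWeights | None = None,
) -> pd.DataFrame:
    """Score and rank a pool of replacement outcomes.

    ``changes`` is the tidy output of :func:`dietswap.replacement.run_all`
    (columns scenario, domain, value, plus metadata). Pools are formed per
    (region, replace, basis) group; normalization and ranking happen within
    each pool.
    """
    if weights is None:
        weights = SynthesisWeights()
    required = {"scenario", "domain", "value", "region", "replace", "alternative", "basis"}
    missing = required - set(changes.columns)
    if missing:
        raise TableError(f"changes table missing columns: {sorted(missing)}")
    out_rows = []
    for (region, replace, basis), group in changes.groupby(
        ["region", "replace", "basis"], sort=True
    ):
        wide = group.pivot_table(
            index="alternative", columns="domain", values="value", aggfunc="first"
        )
        missing_domains = set(DOMAINS) - set(wide.columns)
        if missing_domains:
            raise TableError(
                f"pool ({region}, {replace}, {basis}) missing domains: "
                f"{sorted(missing_domains)}"
            )
        normalized = {
            _DOMAIN_TO_SUBSCORE[d]: normalize_changes(wide[d].to_dict()) for d in DOMAINS
        }
        scores = {
            fid: summary_score({s: normalized[s][fid] for s in normalized}, weights)
            for fid in wide.index
        }
        for fid, score, rank in rank_foods(scores):
            out_rows.append(
                {
                    "region": region,
                    "replace": replace,
                    "basis": basis,
                    "alternative": fid,
                    **{f"score_{s}": normalized[s][fid] for s in normalized},
                    "summary_score": score,
                    "rank": rank,
                }
            )
    return pd.DataFrame(out_rows)


def rank_correlation(scores_a: Mapping[str, float], scores_b: Mapping[str, float]) -> float:
    """Spearman rank correlation between two scorings of the same pool."""
    common = sorted(set(scores_a) & set(scores_b))
    if len(common) < 2:
        raise TableError("need at least two common foods for a rank correlation")
    a = pd.Series([scores_a[f] for f in common]).rank()
    b = pd.Series([scores_b[f] for f in common]).rank()
    return float(a.corr(b, method="pearson"))
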