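"""Condition association for mutated features, and mutation co-occurrence.

Each independent evolution (ALE) is the replicate unit. For a (feature,
condition) pair the 2x2 table counts ALEs by condition-label presence and
by whether the ALE acquired >= 1 mutation mapping to the feature:

    [[a, b],    a = condition & mutated      b = condition & not mutated
     [c, d]]    c = no condition & mutated   d = neither

A one-sided (enrichment-direction) Fisher's exact test is used because the
question is directional: a feature and a condition are *associated* when
the odds ratio exceeds 1 and the Bonferroni-corrected p-value is below
0.01 (the stricter alpha limits association false positives).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import MutatedFeatureInstance

AleKey = Tuple[str, str]  # (experiment_id, ale_id)


@dataclass(frozen=True)
class ConditionLabel:
    """One experiment-design label, e.g. ('carbon-source', 'glycerol')."""

    condition_type: str
    label: str


@dataclass
class AssociationResult:
    feature_id: str
    scale: str
    condition: ConditionLabel
    table: Tuple[Tuple[int, int], Tuple[int, int]]
    odds_ratio: float  # may be inf; NaN when a zero margin is uninformative
    p_raw: float
    p_corrected: float = 1.0
    associated: bool = False


def read_conditions(path: str) -> pd.DataFrame:
    """Condition TSV: experiment_id, condition_type, label (multi-label OK)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    from .errors import SchemaError

    missing = [
        c for c in ("experiment_id", "condition_type", "label") if c not in df.columns
    ]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def ale_condition_labels(
    conditions: pd.DataFrame, ales: Iterable[AleKey]
) -> Dict[AleKey, Set[ConditionLabel]]:
    """ALEs inherit their experiment's condition labels."""
    by_exp: Dict[str, Set[ConditionLabel]] = {}
    for row in conditions.itertuples(index=False):
        by_exp.setdefault(row.experiment_id, set()).add(
            ConditionLabel(row.condition_type, row.label)
        )
    return {ale: by_exp.get(ale[0], set()) for ale in ales}


def ale_feature_presence(
    instances: Iterable[MutatedFeatureInstance],
) -> Dict[Tuple[str, str], Set[AleKey]]:
    """(scale, feature) → set of ALEs with >= 1 mutation mapping to it."""
    out: Dict[Tuple[str, str], Set[AleKey]] = {}
    for inst in instances:
        ale = (inst.mutation_key[0], inst.mutation_key[1])
        out.setdefault((inst.annotation_type, inst.feature_id), set()).add(ale)
    return out


def build_contingency(
    feature_ales: Set[AleKey],
    condition_ales: Set[AleKey],
    all_ales: Sequence[AleKey],
) -> Tuple[Tuple[int, int], Tuple[int, int]]:
    """2x2 counts of ALEs by (condition label present, feature mutated)."""
    a = b = c = d = 0
    for ale in all_ales:
        has_cond = ale in condition_ales
        has_mut = ale in feature_ales
        if has_cond and has_mut:
            a += 1
        elif has_cond:
            b += 1
        elif has_mut:
            c += 1
        else:
            d += 1
    return ((a, b), (c, d))


@lru_cache(maxsize=65536)
def _fisher_greater_p(a: int, b: int, c: int, d: int) -> float:
    # identical tables recur across many (feature, condition) pairs
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(p)


def fisher_one_sided(
    table: Sequence[Sequence[int]],
) -> Tuple[float, float]:
    """One-sided (enrichment) Fisher's exact test on a 2x2 table.

    Returns ``(odds_ratio, p)``. The odds ratio is ``(a*d)/(b*c)``: +inf
    when ``b*c == 0`` with ``a*d > 0``, NaN when a zero margin leaves the
    table uninformative (both products zero).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be non-negative")
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return odds, _fisher_greater_p(int(a), int(b), int(c), int(d))


def associate_all(
    instances: Sequence[MutatedFeatureInstance],
    conditions: pd.DataFrame,
    all_ales: Sequence[AleKey],
    alpha: float = 0.01,
    scales: Optional[Sequence[str]] = None,
) -> List[AssociationResult]:
    """Test every mutated (feature, condition) pair; Bonferroni over all tests.

    ``all_ales`` must list every ALE in the cohort, mutated or not (absence
    of a mutation is information in the 2x2 table).
    """
    presence = ale_feature_presence(instances)
    if scales is not None:
        presence = {k: v for k, v in presence.items() if k[0] in scales}
    labels = ale_condition_labels(conditions, all_ales)
    unique_conditions = sorted(
        {cl for s in labels.values() for cl in s},
        key=lambda c: (c.condition_type, c.label),
    )
    cond_ales = {
        cl: {ale for ale, s in labels.items() if cl in s}
        for cl in unique_conditions
    }
    results: List[AssociationResult] = []
    for (scale, fid), f_ales in sorted(presence.items()):
        for cl in unique_conditions:
            tab = build_contingency(f_ales, cond_ales[cl], all_ales)
            odds, p = fisher_one_sided(tab)
            results.append(
                AssociationResult(
                    feature_id=fid,
                    scale=scale,
                    condition=cl,
                    table=tab,
                    odds_ratio=odds,
                    p_raw=p,
                )
            )
    m = max(1, len(results))
    for r in results:
        r.p_corrected = min(1.0, r.p_raw * m)
        r.associated = bool(
            r.odds_ratio > 1 and r.p_corrected < alpha
        )  # NaN odds never associates
    return results


def associations_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    rows = [
        (
            r.scale,
            r.feature_id,
            r.condition.condition_type,
            r.condition.label,
            r.table[0][0],
            r.table[0][1],
            r.table[1][0],
            r.table[1][1],
            r.odds_ratio,
            r.p_raw,
            r.p_corrected,
            int(r.associated),
        )
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "scale",
            "feature_id",
            "condition_type",
            "condition_label",
            "a",
            "b",
            "c",
            "d",
            "odds_ratio",
            "p_raw",
            "p_corrected",
            "associated",
        ],
    )


def log_odds_matrix(
    results: Sequence[AssociationResult],
    features: Sequence[Tuple[str, str]],
    conditions: Sequence[ConditionLabel],
) -> pd.DataFrame:
    """Natural-log Haldane-Anscombe-corrected odds ratios for a heatmap.

    The 0.5 continuity correction, ``((a+.5)(d+.5))/((b+.5)(c+.5))``,
    renders infinite odds ratios finitely. Row order follows ``features``
    ((scale, feature_id) pairs), column order follows ``conditions``.
    """
    lookup = {
        ((r.scale, r.feature_id), r.condition): r.table for r in results
    }
    mat = np.full((len(features), len(conditions)), np.nan)
    for i, feat in enumerate(features):
        for j, cond in enumerate(conditions):
            tab = lookup.get((feat, cond))
            if tab is None:
                continue
            (a, b), (c, d) = tab
            mat[i, j] = math.log(
                ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            )
    return pd.DataFrame(
        mat,
        index=[f"{s}:{f}" for s, f in features],
        columns=[f"{c.condition_type}:{c.label}" for c in conditions],
    )


def co_occurrence_correlation(
    feature_a_ales: Set[AleKey],
    feature_b_ales: Set[AleKey],
    all_ales: Sequence[AleKey],
) -> float:
    """Pearson correlation of two binary per-ALE mutation-presence vectors.

    Perfectly complementary vectors give -1 (the antagonistic-epistasis
    pattern where replicates mutate one target or the other, never both).
    Constant vectors make the correlation undefined: returns NaN.
    """
    if len(all_ales) < 2:
        raise ValueError("need >= 2 ALEs")
    va = np.array([ale in feature_a_ales for ale in all_ales], dtype=float)
    vb = np.array([ale in feature_b_ales for ale in all_ales], dtype=float)
    if va.std() == 0 or vb.std() == 0:
        return float("nan")
    return float(np.corrcoef(va, vb)[0, 1])
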