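"""Length-weighted permutation test for mutation convergence, significance
calls, and key-mutation extraction.

The null model assumes every nucleotide of the genome is equally likely to
be hit by a spontaneous mutation, so a feature's probability of being
mutated is proportional to its nucleotide length. Scales that do not cover
the whole genome get a reserved *non-annotated remainder* pseudo-feature
completing the probability space; it participates in the null but is never
called significant. Each permutation iteration distributes the experiment's
``n`` mutations across the scale's features with a single multinomial draw;
the empirical p-value uses add-one smoothing, ``(1 + b) / (1 + N)`` with
``b`` the number of iterations meeting or exceeding the observed count,
so finite permutations can never report p = 0.

A feature is significantly enriched when it hosts more than one mutation
and its Bonferroni-corrected permutation p-value is below 0.05. Every
mutation mapping (directly or through scale propagation) to at least one
significant feature is a *key mutation*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import _intervals as iv
from .annotations import SCALES, AnnotationFramework
from .errors import ConfigurationError, FeatureLookupError
from .mapping import MutationKey, MutatedFeatureInstance

#: Reserved id of the non-annotated remainder pseudo-feature.
REMAINDER_ID = "__remainder__"

DEFAULT_ITERATIONS = 10_000
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class NullModel:
    """Length-proportional mutation probabilities for one annotation scale."""

    annotation_type: str
    feature_ids: Tuple[str, ...]  # remainder last when present
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ConfigurationError("null probabilities must be >= 0 and sum to 1")

    def index_of(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise FeatureLookupError(
                f"feature {feature_id!r} absent from the "
                f"{self.annotation_type} null model"
            ) from None


@dataclass
class EnrichmentResult:
    """Per-feature enrichment outcome for one experiment at one scale."""

    annotation_type: str
    table: pd.DataFrame  # feature_id, length_nt, observed_count, p_raw, p_corrected, significant
    iterations: int
    seed: int
    n_mutations: int

    @property
    def significant_features(self) -> Set[str]:
        t = self.table
        return set(t.loc[t["significant"], "feature_id"])


@dataclass
class KeyMutationSet:
    """Mutations contributing to significant convergence, with justifications."""

    experiment_id: str
    mutations: Dict[MutationKey, List[Tuple[str, str]]] = field(default_factory=dict)

    @property
    def keys(self) -> Set[MutationKey]:
        return set(self.mutations)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                k[0],
                k[1],
                k[2],
                k[3],
                k[4],
                ";".join(f"{scale}:{fid}" for scale, fid in sorted(just)),
            )
            for k, just in sorted(self.mutations.items())
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "experiment_id",
                "ale_id",
                "position",
                "span",
                "mutation_type",
                "justifications",
            ],
        )


def build_null_model(fw: AnnotationFramework, annotation_type: str) -> NullModel:
    """Length-proportional null over a scale's features plus the remainder.

    Feature lengths may overlap (regulatory features inside genes, shared
    TUs), so the raw length vector can exceed the covered union; the vector
    is renormalized to sum to one, with the remainder computed from the
    coordinate union of covered positions.
    """
    fids = sorted(fw.feature_ids_at_scale(annotation_type))
    if not fids:
        raise ConfigurationError(f"no features at scale {annotation_type!r}")
    lengths = np.array(
        [fw.feature_length(annotation_type, fid) for fid in fids], dtype=float
    )
    covered = iv.union_length(fw.scale_coverage(annotation_type))
    remainder = max(0, fw.genome_length - covered)
    if remainder > 0:
        fids.append(REMAINDER_ID)
        lengths = np.append(lengths, float(remainder))
    probs = lengths / lengths.sum()
    return NullModel(annotation_type, tuple(fids), probs)


def permutation_test(
    null: NullModel,
    n_mutations: int,
    observed_counts: Mapping[str, int],
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 42,
) -> Dict[str, float]:
    """Empirical upper-tail p-values from multinomial permutations.

    Per iteration, ``n_mutations`` mutations are distributed across the
    scale's features by one multinomial draw from the null probabilities;
    ``p_raw(f) = (1 + #{iterations with count(f) >= observed}) /
    (1 + iterations)``. Deterministic given ``seed``.
    """
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    idx = {fid: null.index_of(fid) for fid in observed_counts}
    rng = np.random.default_rng(seed)
    sims = rng.multinomial(n_mutations, null.probabilities, size=iterations)
    out = {}
    for fid, obs in observed_counts.items():
        b = int(np.count_nonzero(sims[:, idx[fid]] >= obs))
        out[fid] = (1 + b) / (1 + iterations)
    return out


def exact_tail_oracle(p_feature: float, n_mutations: int, k: int) -> float:
    """P(X >= k) for X ~ Binomial(n, p): the closed-form single-feature null."""
    if not (0.0 <= p_feature <= 1.0):
        raise ValueError("p_feature must be in [0, 1]")
    if not (0 <= k <= n_mutations):
        raise ValueError("require 0 <= k <= n_mutations")
    return float(stats.binom.sf(k - 1, n_mutations, p_feature))


def bonferroni(p_raw: Sequence[float], m: int) -> np.ndarray:
    """Family-wise correction: ``min(1, p * m)``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, np.asarray(p_raw, dtype=float) * m)


def observed_counts(
    instances: Iterable[MutatedFeatureInstance], annotation_type: str
) -> Dict[str, int]:
    """Mutations per feature at one scale (once per mutation per feature)."""
    seen: Set[Tuple[MutationKey, str]] = set()
    counts: Dict[str, int] = {}
    for inst in instances:
        if inst.annotation_type != annotation_type:
            continue
        pair = (inst.mutation_key, inst.feature_id)
        if pair in seen:
            continue
        seen.add(pair)
        counts[inst.feature_id] = counts.get(inst.feature_id, 0) + 1
    return counts


def run_enrichment(
    fw: AnnotationFramework,
    instances: Sequence[MutatedFeatureInstance],
    n_mutations: int,
    annotation_type: str,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 42,
    alpha: float = DEFAULT_ALPHA,
    m_tests: Optional[int] = None,
) -> EnrichmentResult:
    """Permutation enrichment for one experiment at one scale.

    ``n_mutations`` is the experiment's consolidated mutation count (not the
    instance count). The Bonferroni denominator defaults to the number of
    real features actually mutated at this scale; pass ``m_tests`` to
    correct over a wider family (the all-scales runner corrects over every
    test of the experiment). The remainder pseudo-feature receives a
    p-value but is never flagged significant.
    """
    null = build_null_model(fw, annotation_type)
    counts = observed_counts(instances, annotation_type)
    tested = sorted(fid for fid in counts if fid != REMAINDER_ID)
    m = m_tests if m_tests is not None else max(1, len(tested))
    p_raw = permutation_test(null, n_mutations, counts, iterations, seed)
    rows = []
    for fid in sorted(counts):
        pr = p_raw[fid]
        pc = float(bonferroni([pr], m)[0])
        sig = bool(counts[fid] > 1 and pc < alpha and fid != REMAINDER_ID)
        length = (
            fw.feature_length(annotation_type, fid) if fid != REMAINDER_ID else 0
        )
        rows.append((fid, length, counts[fid], pr, pc, sig))
    table = pd.DataFrame(
        rows,
        columns=[
            "feature_id",
            "length_nt",
            "observed_count",
            "p_raw",
            "p_corrected",
            "significant",
        ],
    )
    return EnrichmentResult(annotation_type, table, iterations, seed, n_mutations)


def run_enrichment_all_scales(
    fw: AnnotationFramework,
    instances: Sequence[MutatedFeatureInstance],
    n_mutations: int,
    scales: Sequence[str] = SCALES,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 42,
    alpha: float = DEFAULT_ALPHA,
) -> Dict[str, EnrichmentResult]:
    """Enrichment per annotation type; scales without features are skipped.

    One experiment is one statistical family: the Bonferroni denominator is
    the total number of feature tests performed across every scale, which
    keeps the per-experiment family-wise false-positive rate at ``alpha``
    even though the scales are tested jointly.
    """
    usable = []
    m_total = 0
    for scale in scales:
        try:
            build_null_model(fw, scale)
        except ConfigurationError:
            continue
        usable.append(scale)
        m_total += len(
            [f for f in observed_counts(instances, scale) if f != REMAINDER_ID]
        )
    m_total = max(1, m_total)
    results = {}
    for i, scale in enumerate(usable):
        results[scale] = run_enrichment(
            fw, instances, n_mutations, scale, iterations, seed + i, alpha,
            m_tests=m_total,
        )
    return results


def identify_key_mutations(
    instances: Sequence[MutatedFeatureInstance],
    results: Mapping[str, EnrichmentResult],
    experiment_id: str = "",
) -> KeyMutationSet:
    """Mutations mapping to >= 1 significant feature at any considered scale."""
    significant = {
        scale: res.significant_features for scale, res in results.items()
    }
    kms = KeyMutationSet(experiment_id=experiment_id)
    for inst in instances:
        sig = significant.get(inst.annotation_type, set())
        if inst.feature_id in sig:
            kms.mutations.setdefault(inst.mutation_key, [])
            pair = (inst.annotation_type, inst.feature_id)
            if pair not in kms.mutations[inst.mutation_key]:
                kms.mutations[inst.mutation_key].append(pair)
    return kms


#: Fig-style cumulative order in which broader annotation types are added.
CUMULATIVE_SCALE_ORDER = (
    "genomic_feature",
    "gene_and_intergenic",
    "TU",
    "operon",
    "regulon",
    "pathway",
    "COG",
)


def key_mutation_proportions(
    instances: Sequence[MutatedFeatureInstance],
    results: Mapping[str, EnrichmentResult],
    scale_order: Sequence[str] = CUMULATIVE_SCALE_ORDER,
) -> pd.DataFrame:
    """Proportion of mutated genomic features hosting key mutations, per
    cumulative annotation-scale prefix.

    A mutated genomic feature counts toward the proportion at prefix ``S``
    when at least one of its mutations is key under the scales in ``S``.
    The proportion is non-decreasing as broader scales are added. With zero
    mutated features the proportion is undefined and reported as NaN.
    """
    by_exp: Dict[str, List[MutatedFeatureInstance]] = {}
    for inst in instances:
        by_exp.setdefault(inst.mutation_key[0], []).append(inst)
    rows = []
    for exp_id, exp_instances in sorted(by_exp.items()):
        mutated_features = {
            i.feature_id
            for i in exp_instances
            if i.annotation_type == "genomic_feature"
        }
        feature_mutations: Dict[str, Set[MutationKey]] = {}
        for i in exp_instances:
            if i.annotation_type == "genomic_feature":
                feature_mutations.setdefault(i.feature_id, set()).add(i.mutation_key)
        for k in range(1, len(scale_order) + 1):
            prefix = scale_order[:k]
            subset = {s: results[s] for s in prefix if s in results}
            keys = identify_key_mutations(
                [i for i in exp_instances if i.annotation_type in prefix],
                subset,
                exp_id,
            ).keys
            if not mutated_features:
                prop = float("nan")
            else:
                n_key = sum(
                    1
                    for fid, muts in feature_mutations.items()
                    if muts & keys
                )
                prop = n_key / len(mutated_features)
            rows.append((exp_id, prefix[-1], k, prop))
    return pd.DataFrame(
        rows, columns=["experiment_id", "up_to_scale", "n_scales", "proportion"]
    )
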